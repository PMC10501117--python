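"""Assay readouts from trajectories: OP_AA, OP_OH, peroxide equivalents,
channel attribution of DHA formation, synergy and online/offline arithmetic.

Readouts use the 600 s reaction-stage window: the pH-2 derivatization stage
is simulated for protocol fidelity but the instrument's DHA quantification
reflects oxidation during the reaction bath.  Attribution credits each mole
of DHA to the channel tag of the reaction that formed it; DHA formed by
ascorbyl-radical consumption (disproportionation or metal-mediated A.-
oxidation) is apportioned to upstream channels in proportion to each
channel's cumulative A.- production extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .network import NetworkSpec
from .simulate import Trajectory, REACTION_STAGE_S
from .scenarios import ScenarioSpec

#: species counted as peroxides by the H2O2-equivalents accounting
PEROXIDE_SPECIES = ("H2O2", "ROOH")


class ObservableError(ValueError):
    pass


def op_aa(traj: Trajectory, window: float = REACTION_STAGE_S):
    """DHA formed over the reaction window.

    Returns ``(amount_M, rate_M_per_s)``: concentration of DHA formed in the
    assay liquid and its mean formation rate over the window.
    """
    if "DHA" not in traj.species:
        raise ObservableError("network has no DHA species; OP_AA undefined")
    amount = traj.conc_at("DHA", window) - traj.conc_of("DHA")[0]
    return float(amount), float(amount / window)


def op_oh(traj: Trajectory, window: float = REACTION_STAGE_S):
    """Hydroxyl-radical trapping rate via the terephthalate probe.

    Returns ``(amount_M, rate_M_per_s)`` of 2-hydroxyterephthalate formed.
    """
    if "hTA" not in traj.species:
        raise ObservableError("network has no hTA species; OP_OH undefined")
    amount = traj.conc_at("hTA", window) - traj.conc_of("hTA")[0]
    return float(amount), float(amount / window)


def h2o2_equivalents(
    traj: Trajectory,
    response_factors: Optional[Mapping[str, float]] = None,
    at: float = REACTION_STAGE_S,
) -> float:
    """Peroxide content expressed as H2O2 equivalents (mol L-1).

    Sums peroxide species concentrations at the sampling time, each weighted
    by its declared relative response factor (H2O2 = 1 by definition; the
    full peroxidase/fluorescein kinetics are deliberately out of scope).
    """
    factors = dict.fromkeys(PEROXIDE_SPECIES, 1.0)
    if response_factors:
        factors.update(response_factors)
    if factors.get("H2O2", 1.0) != 1.0:
        raise ObservableError("H2O2 response factor must be 1")
    total = 0.0
    for sp, f in factors.items():
        if f < 0:
            raise ObservableError(f"negative response factor for {sp}")
        if sp in traj.species:
            total += f * traj.conc_at(sp, at)
    return float(total)


def attribute_dha(traj: Trajectory, net: NetworkSpec,
                  window: float = REACTION_STAGE_S) -> Dict[str, float]:
    """Fraction of cumulative DHA formation per channel tag.

    Direct DHA (reactions not consuming A.-) is credited to the reaction's
    channel; DHA from A.--consuming reactions is apportioned by each
    channel's share of cumulative A.- production.  Fractions sum to 1
    whenever any DHA formed; an all-zero run returns an empty map.
    """
    extents = traj.extents_at(window)
    direct: Dict[str, float] = {}
    from_radical = 0.0
    radical_prod: Dict[str, float] = {}
    for j, r in enumerate(net.reactions):
        ext = extents[j]
        if ext == 0.0:
            continue
        nu_dha = r.products.get("DHA", 0)
        nu_arad = r.products.get("A.-", 0) - r.reactants.get("A.-", 0)
        if nu_arad > 0:
            ch = r.channel or r.id
            radical_prod[ch] = radical_prod.get(ch, 0.0) + nu_arad * ext
        if nu_dha > 0:
            if r.reactants.get("A.-", 0) > 0:
                from_radical += nu_dha * ext
            else:
                ch = r.channel or r.id
                direct[ch] = direct.get(ch, 0.0) + nu_dha * ext

    credited = dict(direct)
    prod_total = sum(radical_prod.values())
    if from_radical > 0 and prod_total > 0:
        for ch, p in radical_prod.items():
            credited[ch] = credited.get(ch, 0.0) + from_radical * p / prod_total
    total = sum(credited.values())
    if total <= 0:
        return {}
    return {ch: v / total for ch, v in credited.items() if v > 0}


def synergy(individual: Sequence[float], mixture: float) -> float:
    """Percent enhancement of a mixture over the sum of individual rates.

    100 * (mixture - sum) / sum; positive is synergistic, negative
    antagonistic.
    """
    s = float(sum(individual))
    if s <= 0:
        raise ObservableError("sum of individual rates must be > 0")
    return 100.0 * (mixture - s) / s


def mixture_synergy(spec: ScenarioSpec, cfg=None,
                    window: float = REACTION_STAGE_S) -> float:
    """Model synergy of a mixture scenario against its own parts.

    Re-runs each component alone *at the mixture's own mass* (the assay
    comparison keeps amounts fixed between individual and mixed runs) and
    returns 100 * (mixture - sum of parts) / sum of parts.
    """
    from dataclasses import replace

    from .scenarios import compile_scenario
    from .simulate import run_assay_protocol

    if len(spec.components) < 2:
        raise ObservableError("synergy needs a mixture of >= 2 components")

    def dha(s: ScenarioSpec) -> float:
        net = compile_scenario(s, cfg)
        return op_aa(run_assay_protocol(net), window)[0]

    parts = [dha(replace(spec, components=[c], name=c.kind))
             for c in spec.components]
    return synergy(parts, dha(spec))


def percent_reduction(online: float, offline: float) -> float:
    """Percent decrease of an offline value relative to the online one."""
    if online <= 0:
        raise ObservableError("online value must be > 0")
    return 100.0 * (online - offline) / online


# ---------------------------------------------------------------------------
# aggregate report
# ---------------------------------------------------------------------------

@dataclass
class AssayReport:
    """All assay quantities for one scenario run.

    Rates are in pmol min-1 for the liquid volume associated with one minute
    of sampling; mass normalization (nmol per ug particle) is available when
    the scenario's particle mass is known.
    """

    scenario: str
    dha_nmol_per_L: float
    dha_rate_pmol_min: float
    oh_rate_pmol_min: Optional[float]
    h2o2_equiv_nmol_per_L: float
    attribution: Dict[str, float] = field(default_factory=dict)
    op_aa_nmol_per_ug: Optional[float] = None
    op_aa_nmol_per_m3: Optional[float] = None

    def to_frame(self):
        import pandas as pd

        row = {
            "scenario": self.scenario,
            "DHA_nmol_per_L": self.dha_nmol_per_L,
            "OP_AA_pmol_min": self.dha_rate_pmol_min,
            "OP_OH_pmol_min": self.oh_rate_pmol_min,
            "H2O2_equiv_nmol_per_L": self.h2o2_equiv_nmol_per_L,
            "OP_AA_nmol_per_ug": self.op_aa_nmol_per_ug,
            "OP_AA_nmol_per_m3": self.op_aa_nmol_per_m3,
        }
        for ch, f in sorted(self.attribution.items()):
            row[f"frac_{ch}"] = f
        return pd.DataFrame([row])

    def attribution_frame(self):
        import pandas as pd

        return pd.DataFrame(
            sorted(self.attribution.items()),
            columns=["channel", "fraction"],
        )

    def to_text(self) -> str:
        lines = [
            f"scenario: {self.scenario}",
            f"DHA formed          : {self.dha_nmol_per_L:.4g} nmol/L "
            f"({self.dha_rate_pmol_min:.4g} pmol/min)",
            f"H2O2 equivalents    : {self.h2o2_equiv_nmol_per_L:.4g} nmol/L",
        ]
        if self.oh_rate_pmol_min is not None:
            lines.append(f"OH trapped (hTA)    : {self.oh_rate_pmol_min:.4g} pmol/min")
        if self.op_aa_nmol_per_ug is not None:
            lines.append(f"OP_AA mass-normalized: {self.op_aa_nmol_per_ug:.4g} nmol/ug")
        if self.op_aa_nmol_per_m3 is not None:
            lines.append(f"OP_AA per air volume : {self.op_aa_nmol_per_m3:.4g} nmol/m3")
        if self.attribution:
            lines.append("DHA attribution:")
            for ch, f in sorted(self.attribution.items(),
                                key=lambda kv: -kv[1]):
                lines.append(f"  {ch:<18s} {100 * f:6.2f} %")
        return "\n".join(lines)


def assay_report(
    traj: Trajectory,
    net: NetworkSpec,
    scenario: Optional[ScenarioSpec] = None,
    response_factors: Optional[Mapping[str, float]] = None,
    window: float = REACTION_STAGE_S,
) -> AssayReport:
    """Compute the full report for one run.

    ``scenario`` supplies the liquid flow and particle mass needed for
    pmol min-1 rates and per-ug/per-m3 normalizations; without it only
    concentration-based quantities are reported.
    """
    amount_M, _ = op_aa(traj, window)
    q_L_min = scenario.q_liquid_mLmin / 1000.0 if scenario else 1e-3
    dha_rate_pmol_min = amount_M / (window / 60.0) * q_L_min * 1e12
    oh_rate = None
    if "hTA" in traj.species:
        oh_M, _ = op_oh(traj, window)
        oh_rate = oh_M / (window / 60.0) * q_L_min * 1e12
    equiv = h2o2_equivalents(traj, response_factors, at=window)

    per_ug = per_m3 = None
    if scenario is not None and scenario.total_mass_ugm3() > 0:
        mass_ug_per_L = scenario.liquid_mass_ug_per_L(scenario.total_mass_ugm3())
        if mass_ug_per_L > 0:
            per_ug = amount_M * 1e9 / mass_ug_per_L
            per_m3 = amount_M * 1e9 * scenario.liquid_volume_per_m3_air()

    return AssayReport(
        scenario=(scenario.name if scenario else net.name) or net.name,
        dha_nmol_per_L=amount_M * 1e9,
        dha_rate_pmol_min=dha_rate_pmol_min,
        oh_rate_pmol_min=oh_rate,
        h2o2_equiv_nmol_per_L=equiv * 1e9,
        attribution=attribute_dha(traj, net, window),
        op_aa_nmol_per_ug=per_ug,
        op_aa_nmol_per_m3=per_m3,
    )
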