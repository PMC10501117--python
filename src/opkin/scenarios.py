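"""Scenario compilation: aerosol-side descriptions to liquid-phase networks.

The online instruments sample air at ``Q_air`` (16 L min-1 for the ascorbate
channel, 7 L min-1 for the peroxide channel) into a liquid wash flow
``q_liquid``.  At steady state the particle mass concentration in the liquid
is ``C_air * Q_air * collection_efficiency / q_liquid``; component masses
are then converted to molar concentrations:

* Fe(II)/Cu(II): via the sulfate-salt molar mass by default (the nebulized
  materials are the sulfates) or the elemental mass (``metal_mass_basis``);
* BSOA: ROOH at Y_ROOH = 0.80 mol per mol SOA, average molar mass 205 g/mol;
* NSOA: 1,2-/1,4-naphthoquinone at the configured mass yields plus a HULIS
  fraction (default 30% of NSOA mass).

All conversions happen here; the reaction network itself is purely
liquid-phase (mol L-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import yaml

from .mechanisms import (
    MechanismConfig,
    full_mechanism,
)
from .network import NetworkSpec

# molar masses, g mol-1
M_FESO4 = 151.91
M_CUSO4 = 159.61
M_FE = 55.845
M_CU = 63.546
M_NQN = 158.15
M_HULIS_DEFAULT = 250.0

COMPONENT_KINDS = ("FeII", "CuII", "BSOA", "NSOA")


@dataclass(frozen=True)
class Component:
    kind: str
    mass_ugm3: float

    def __post_init__(self):
        if self.kind not in COMPONENT_KINDS:
            raise ValueError(
                f"unknown component kind {self.kind!r}; expected one of "
                f"{COMPONENT_KINDS}"
            )
        if self.mass_ugm3 < 0:
            raise ValueError("component mass must be >= 0")


@dataclass
class ScenarioSpec:
    """Aerosol components plus assay reagents and sampling flows."""

    components: List[Component] = field(default_factory=list)
    AA_0: float = 2.0e-4            # mol L-1 ascorbic acid in the wash flow
    TA_0: float = 0.0               # mol L-1 terephthalate (1e-2 for OP_OH)
    HEPES_0: float = 1.0e-2         # mol L-1
    Q_air_Lmin: float = 16.0        # ascorbate channel sampling flow
    q_liquid_mLmin: float = 1.0     # liquid wash flow
    collection_efficiency: float = 1.0
    Y_ROOH: float = 0.80            # mol ROOH per mol BSOA
    M_BSOA: float = 205.0           # g mol-1
    NQN12_yield: float = 0.036      # mass fraction of NSOA
    NQN14_yield: float = 0.004
    HULIS_fraction: float = 0.30
    M_HULIS: float = M_HULIS_DEFAULT
    metal_mass_basis: str = "salt"  # or "metal"
    fe_hulis: bool = False          # enable the Fe-HULIS extension
    name: str = ""

    def __post_init__(self):
        if self.q_liquid_mLmin < 0 or self.Q_air_Lmin < 0:
            raise ValueError("flows must be >= 0")
        if not 0.0 < self.collection_efficiency <= 1.0 and self.collection_efficiency != 0.0:
            raise ValueError("collection_efficiency must be in [0, 1]")
        for y in (self.Y_ROOH, self.NQN12_yield, self.NQN14_yield,
                  self.HULIS_fraction):
            if not 0.0 <= y <= 1.0:
                raise ValueError("yields must be in [0, 1]")
        if self.metal_mass_basis not in ("salt", "metal"):
            raise ValueError("metal_mass_basis must be 'salt' or 'metal'")

    # -- unit conversions --------------------------------------------------

    def liquid_mass_ug_per_L(self, mass_ugm3: float) -> float:
        """Particle mass concentration in the wash liquid, ug per L."""
        if self.q_liquid_mLmin == 0:
            raise ValueError("q_liquid must be > 0")
        q_liquid_Lmin = self.q_liquid_mLmin / 1000.0
        air_m3min = self.Q_air_Lmin / 1000.0
        return mass_ugm3 * air_m3min * self.collection_efficiency / q_liquid_Lmin

    def liquid_volume_per_m3_air(self) -> float:
        """Litres of wash liquid associated with 1 m3 of sampled air."""
        return (self.q_liquid_mLmin / 1000.0) / (self.Q_air_Lmin / 1000.0)

    def total_mass_ugm3(self) -> float:
        return sum(c.mass_ugm3 for c in self.components)

    def has(self, kind: str) -> bool:
        return any(c.kind == kind and c.mass_ugm3 > 0 for c in self.components)

    # -- serialization -----------------------------------------------------

    def to_yaml(self) -> str:
        d = {
            "name": self.name,
            "components": [{"kind": c.kind, "mass_ugm3": c.mass_ugm3}
                           for c in self.components],
        }
        for key in ("AA_0", "TA_0", "HEPES_0", "Q_air_Lmin", "q_liquid_mLmin",
                    "collection_efficiency", "Y_ROOH", "M_BSOA", "NQN12_yield",
                    "NQN14_yield", "HULIS_fraction", "M_HULIS",
                    "metal_mass_basis", "fe_hulis"):
            d[key] = getattr(self, key)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioSpec":
        d = yaml.safe_load(text) or {}
        comps = [Component(c["kind"], float(c["mass_ugm3"]))
                 for c in d.pop("components", [])]
        return cls(components=comps, **d)


def compile_scenario(spec: ScenarioSpec,
                     cfg: Optional[MechanismConfig] = None) -> NetworkSpec:
    """Compile a scenario into a merged mechanism with initial concentrations.

    Initial concentrations are linear in each component's air mass; fragment
    merging uses set semantics, so compilation is order-independent.
    """
    cfg = cfg or MechanismConfig()
    init: Dict[str, float] = {"AH-": spec.AA_0, "HEPES": spec.HEPES_0}
    use_bsoa = spec.has("BSOA")
    use_nsoa = spec.has("NSOA")
    use_ta = spec.TA_0 > 0

    for comp in spec.components:
        ug_L = spec.liquid_mass_ug_per_L(comp.mass_ugm3)
        g_L = ug_L * 1e-6
        if comp.kind == "FeII":
            m = M_FESO4 if spec.metal_mass_basis == "salt" else M_FE
            init["Fe2+"] = init.get("Fe2+", 0.0) + g_L / m
        elif comp.kind == "CuII":
            m = M_CUSO4 if spec.metal_mass_basis == "salt" else M_CU
            init["Cu2+"] = init.get("Cu2+", 0.0) + g_L / m
        elif comp.kind == "BSOA":
            init["ROOH"] = init.get("ROOH", 0.0) + g_L * spec.Y_ROOH / spec.M_BSOA
        elif comp.kind == "NSOA":
            init["NQN12"] = init.get("NQN12", 0.0) + g_L * spec.NQN12_yield / M_NQN
            init["NQN14"] = init.get("NQN14", 0.0) + g_L * spec.NQN14_yield / M_NQN
            hulis = g_L * spec.HULIS_fraction / spec.M_HULIS
            init["HULIS"] = init.get("HULIS", 0.0) + hulis
            if spec.fe_hulis:
                init["HULISred"] = init.get("HULISred", 0.0) + hulis
    if use_ta:
        init["TA"] = spec.TA_0

    net = full_mechanism(cfg, bsoa=use_bsoa, nsoa=use_nsoa,
                         fe_hulis=spec.fe_hulis, ta=use_ta)
    net = net.with_initial(**init)
    net.name = spec.name or "scenario"
    return net


# ---------------------------------------------------------------------------
# shipped presets: the experimental envelope midpoints (SOA 245-408 ug m-3,
# metals 5-35 ug m-3, SOA:Fe ~ 10:1, SOA:Cu ~ 50:1)
# ---------------------------------------------------------------------------

SOA_MASS = 300.0
FE_MASS_ALONE = 20.0
CU_MASS_ALONE = 20.0


def _preset(name: str, comps: List[Component], **kw) -> ScenarioSpec:
    return ScenarioSpec(components=comps, name=name, **kw)


PRESETS: Dict[str, ScenarioSpec] = {
    "Fe_only": _preset("Fe_only", [Component("FeII", FE_MASS_ALONE)]),
    "Cu_only": _preset("Cu_only", [Component("CuII", CU_MASS_ALONE)]),
    "BSOA": _preset("BSOA", [Component("BSOA", SOA_MASS)]),
    "NSOA": _preset("NSOA", [Component("NSOA", SOA_MASS)]),
    "BSOA+Fe": _preset("BSOA+Fe", [Component("BSOA", SOA_MASS),
                                   Component("FeII", SOA_MASS / 10)]),
    "BSOA+Cu": _preset("BSOA+Cu", [Component("BSOA", SOA_MASS),
                                   Component("CuII", SOA_MASS / 50)]),
    "NSOA+Fe": _preset("NSOA+Fe", [Component("NSOA", SOA_MASS),
                                   Component("FeII", SOA_MASS / 10)],
                       fe_hulis=True),
    "NSOA+Cu": _preset("NSOA+Cu", [Component("NSOA", SOA_MASS),
                                   Component("CuII", SOA_MASS / 50)]),
}


def get_preset(name: str) -> ScenarioSpec:
    try:
        spec = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
    return replace(spec, components=list(spec.components))
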