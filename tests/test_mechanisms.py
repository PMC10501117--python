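"""Curated mechanisms: printed rate constants, conservation, channel behaviour."""

import numpy as np
import pytest

from opkin import (
    MechanismConfig,
    NetworkSpec,
    attribute_dha,
    bsoa_extension,
    core_metal_ascorbate_network,
    fe_hulis_extension,
    full_mechanism,
    nsoa_extension,
    op_aa,
    run_assay_protocol,
    serialize_network,
    ta_probe_extension,
)

#: rate constants printed in the literature for the anchored reactions
PRINTED_CONSTANTS = {
    "R5": 55.0,       # Fe(II) + H2O2
    "R3": 480.0,      # Cu(II) + H2O2
    "R9": 1.6e2,      # AH- + H2O2
    "R8": 7.9e9,      # AH- + .OH
    "B2": 1.0e4,      # AH- + RO
    "B1": 0.0015,     # ROOH homolysis
    "B4": 4.0e4,      # Fe(II) + organic hydroperoxide
}


def _run(net, **conc):
    net = net.with_initial(**conc)
    traj = run_assay_protocol(net)
    return net, traj


class TestConfig:
    def test_cu_direct_constant_must_exceed_fe(self):
        with pytest.raises(ValueError):
            MechanismConfig(k_direct_Fe3_AH=50.0, k_direct_Cu2_AH=50.0)

    def test_weak_fe_hulis_fenton_warns(self):
        with pytest.warns(UserWarning):
            MechanismConfig(k_FeHULIS_H2O2=10.0)

    def test_temperature_scale_multiplies_selected_reaction(self):
        cfg = MechanismConfig(temperature_scale={"R5": 2.0})
        net = core_metal_ascorbate_network(cfg)
        r5 = next(r for r in net.reactions if r.id == "R5")
        assert r5.rate_constant == pytest.approx(110.0)


class TestCoreNetwork:
    def test_printed_rate_constants_survive_serialization(self, cfg):
        net = full_mechanism(cfg, bsoa=True, nsoa=True, fe_hulis=True, ta=True)
        text = serialize_network(net)
        k_by_id = {r.id: r.rate_constant for r in net.reactions}
        for rid, k in PRINTED_CONSTANTS.items():
            assert k_by_id[rid] == k
            assert f"{k:.10g}" in text

    def test_every_reaction_carries_source_tag(self, cfg):
        net = full_mechanism(cfg, bsoa=True, nsoa=True, fe_hulis=True, ta=True)
        assert all(r.source for r in net.reactions)

    def test_validates_and_conserves_metals(self, cfg):
        net, traj = _run(core_metal_ascorbate_network(cfg),
                         **{"AH-": 2e-4, "HEPES": 1e-2, "Fe2+": 2e-6,
                            "Cu2+": 1e-6})
        fe = traj.conc_of("Fe2+") + traj.conc_of("Fe3+")
        cu = traj.conc_of("Cu+") + traj.conc_of("Cu2+")
        assert np.all(np.abs(fe - fe[0]) / fe[0] < 1e-6)
        assert np.all(np.abs(cu - cu[0]) / cu[0] < 1e-6)

    def test_cu_h2o2_chain_produces_oh(self, cfg):
        # with only Cu(II) + H2O2 initialized the R3 -> R4 chain makes .OH
        net = core_metal_ascorbate_network(cfg).with_initial(
            **{"Cu2+": 1e-6, "H2O2": 1e-5})
        traj = run_assay_protocol(net)
        assert traj.extent_of("R4")[-1] > 0

    def test_no_oxidant_blank_forms_no_dha(self, cfg):
        net, traj = _run(core_metal_ascorbate_network(cfg),
                         **{"AH-": 2e-4, "HEPES": 1e-2})
        amount, _ = op_aa(traj)
        assert amount == pytest.approx(0.0, abs=1e-11)

    def test_ascorbate_moiety_conserved(self, cfg):
        net, traj = _run(core_metal_ascorbate_network(cfg),
                         **{"AH-": 2e-4, "HEPES": 1e-2, "Fe2+": 5e-6})
        total = (traj.conc_of("AH2") + traj.conc_of("AH-")
                 + traj.conc_of("A.-") + traj.conc_of("DHA"))
        assert np.all(np.abs(total - total[0]) / total[0] < 1e-6)


class TestBsoaExtension:
    def test_mass_to_rooh_arithmetic(self):
        # 1 ug BSOA -> 0.80 * 1e-6 g / 205 g/mol = 3.90 nmol ROOH
        nmol = 0.80 * 1e-6 / 205.0 * 1e9
        assert nmol == pytest.approx(3.90, abs=0.01)

    def test_homolysis_extent_closed_form(self, cfg):
        frag = bsoa_extension(MechanismConfig(include_fe_rooh=False))
        net, traj = _run(frag, ROOH=1e-6, **{"AH-": 2e-4})
        extent_600 = np.interp(600.0, traj.times, traj.extent_of("B1"))
        assert extent_600 == pytest.approx(1e-6 * (1 - np.exp(-0.9)), rel=1e-5)

    def test_oh_channel_dominates_ro_channel(self, cfg):
        net = full_mechanism(cfg, bsoa=True).with_initial(
            **{"AH-": 2e-4, "HEPES": 1e-2, "ROOH": 2e-5})
        traj = run_assay_protocol(net)
        att = attribute_dha(traj, net)
        assert att["OH"] > 10 * att["RO"]


class TestNsoaExtension:
    def test_zero_yield_reduces_to_blank(self, cfg):
        net = full_mechanism(cfg, nsoa=True).with_initial(
            **{"AH-": 2e-4, "HEPES": 1e-2})
        traj = run_assay_protocol(net)
        amount, _ = op_aa(traj)
        assert amount == pytest.approx(0.0, abs=1e-11)

    def test_nqn12_dominates_attribution(self, cfg):
        net = full_mechanism(cfg, nsoa=True).with_initial(
            **{"AH-": 2e-4, "HEPES": 1e-2, "NQN12": 1e-6, "NQN14": 1.1e-7})
        traj = run_assay_protocol(net)
        att = attribute_dha(traj, net)
        assert att["NQN12"] > 0.8
        assert att["NQN12"] > att["NQN14"]


class TestFeHulisExtension:
    def test_total_iron_conserved_including_complexes(self, cfg):
        net = full_mechanism(cfg, nsoa=True, fe_hulis=True).with_initial(
            **{"AH-": 2e-4, "HEPES": 1e-2, "Fe2+": 3e-6, "HULIS": 5e-6,
               "HULISred": 5e-6})
        traj = run_assay_protocol(net)
        fe = (traj.conc_of("Fe2+") + traj.conc_of("Fe3+")
              + traj.conc_of("FeHULIS2") + traj.conc_of("FeHULIS3"))
        assert np.all(np.abs(fe - fe[0]) / fe[0] < 1e-6)

    def test_extension_raises_oh_share(self, cfg):
        base = full_mechanism(cfg, nsoa=True).with_initial(
            **{"AH-": 2e-4, "HEPES": 1e-2, "Fe2+": 3e-6,
               "NQN12": 1.1e-6, "NQN14": 1.2e-7, "HULIS": 5.8e-6})
        ext = full_mechanism(cfg, nsoa=True, fe_hulis=True).with_initial(
            **{"AH-": 2e-4, "HEPES": 1e-2, "Fe2+": 3e-6,
               "NQN12": 1.1e-6, "NQN14": 1.2e-7, "HULIS": 5.8e-6,
               "HULISred": 5.8e-6})
        att_base = attribute_dha(run_assay_protocol(base), base)
        att_ext = attribute_dha(run_assay_protocol(ext), ext)
        assert att_ext["OH"] > att_base["OH"]

    def test_inert_without_hulis(self, cfg):
        core = core_metal_ascorbate_network(cfg).with_initial(
            **{"AH-": 2e-4, "HEPES": 1e-2, "Fe2+": 3e-6})
        ext = full_mechanism(cfg, fe_hulis=True).with_initial(
            **{"AH-": 2e-4, "HEPES": 1e-2, "Fe2+": 3e-6})
        a1, _ = op_aa(run_assay_protocol(core))
        a2, _ = op_aa(run_assay_protocol(ext))
        assert a2 == pytest.approx(a1, rel=1e-6)


class TestTaProbe:
    def test_no_oh_source_no_hta(self, cfg):
        net = full_mechanism(cfg, ta=True).with_initial(
            **{"AH-": 2e-4, "HEPES": 1e-2, "TA": 1e-2})
        traj = run_assay_protocol(net)
        assert traj.conc_of("hTA")[-1] == pytest.approx(0.0, abs=1e-12)

    def test_hta_nondecreasing_with_fenton_source(self, cfg):
        net = full_mechanism(cfg, ta=True).with_initial(
            **{"AH-": 2e-4, "HEPES": 1e-2, "TA": 1e-2, "Fe2+": 5e-6,
               "H2O2": 1e-5})
        traj = run_assay_protocol(net)
        h = traj.conc_of("hTA")
        assert h[-1] > 0
        assert np.all(np.diff(h) >= -1e-15)

    def test_ta_competes_with_ascorbate_for_oh(self, cfg):
        # raising [TA] from 0 to 10 mM strictly decreases the AH- + .OH extent
        def oh_extent(ta):
            init = {"AH-": 2e-4, "HEPES": 1e-2, "Fe2+": 5e-6, "H2O2": 1e-5}
            if ta:
                init["TA"] = ta
            net = full_mechanism(MechanismConfig(), ta=bool(ta)).with_initial(**init)
            traj = run_assay_protocol(net)
            return traj.extent_of("R8")[-1]

        assert oh_extent(1e-2) < oh_extent(0.0)
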