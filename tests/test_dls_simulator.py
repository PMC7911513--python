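"""Forward simulator: diffusion law, evaporation model, ACF synthesis."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from platekd import (
    EvaporationParams,
    FormulationTruth,
    InstrumentConfig,
    analyze_plate,
    evaporation_trajectory,
    fit_kd_measurements,
    forward_diffusion,
    inject_second_population,
    simulate_plate,
    synthesize_acf,
)
from platekd.plate_model import WellAddress, WellAssignment, classify_position

from conftest import make_block_layout

# independent numeric oracles, evaluated by hand from the closed forms:
# q = (4 pi 1.331 / 830e-9) sin(79 deg) and Gamma = D q^2
Q_ORACLE = 1.978e7
GAMMA_ORACLE = 5.087e4  # for D = 1.30e-10 m^2/s


class TestForwardDiffusion:
    def test_zero_kd_is_identity(self):
        truth = FormulationTruth.from_radius("f", 1.9, 0.0)
        for c in (0.0, 0.002, 0.014):
            assert forward_diffusion(c, truth) == truth.d0_m2_s

    @pytest.mark.parametrize(
        "kd,c_mg_ml,factor", [(57.0, 10.0, 1.570), (-14.8, 10.0, 0.852)]
    )
    def test_table_average_kd_values(self, kd, c_mg_ml, factor):
        truth = FormulationTruth.from_radius("f", 1.9, kd)
        d = forward_diffusion(c_mg_ml / 1000.0, truth)
        assert d == pytest.approx(factor * truth.d0_m2_s, rel=1e-12)

    def test_unphysical_negative_diffusion_rejected(self):
        truth = FormulationTruth.from_radius("f", 1.9, -120.0)
        with pytest.raises(ValueError):
            forward_diffusion(0.010, truth)  # 1 + kD c = -0.2


def _center_assignment(c_mg_ml: float) -> WellAssignment:
    return WellAssignment(
        WellAddress(7, 7), formulation_id="f", concentration_mg_ml=c_mg_ml
    )


class TestEvaporation:
    def test_zero_rate_keeps_concentration(self):
        a = _center_assignment(2.0)
        vf, c = evaporation_trajectory(a, False, 3600.0, EvaporationParams.off())
        assert (vf, c) == (1.0, 2.0)

    @given(
        st.floats(min_value=0.0, max_value=0.2),
        st.floats(min_value=1.0, max_value=5.0),
        st.floats(min_value=0.1, max_value=30.0),
        st.floats(min_value=0.0, max_value=8 * 3600.0),
        st.booleans(),
    )
    def test_mass_conservation_before_floor(self, rate, edge_factor, c0, t, is_edge):
        params = EvaporationParams.deterministic(
            base_rate_per_h=rate, edge_factor=edge_factor, min_volume_fraction=0.05
        )
        a = _center_assignment(c0)
        vf, c = evaporation_trajectory(a, is_edge, t, params)
        if vf > params.min_volume_fraction:
            assert c * vf == pytest.approx(c0, rel=1e-12)

    def test_concentration_monotone_in_elapsed_time(self):
        a = _center_assignment(2.0)
        params = EvaporationParams.deterministic()
        cs = [
            evaporation_trajectory(a, True, t, params)[1]
            for t in np.linspace(0, 10 * 3600, 50)
        ]
        assert all(c2 >= c1 for c1, c2 in zip(cs, cs[1:]))

    def test_volume_floor_engages(self):
        a = _center_assignment(0.5)
        params = EvaporationParams.deterministic(base_rate_per_h=0.5, min_volume_fraction=0.4)
        vf, _ = evaporation_trajectory(a, True, 20 * 3600.0, params)
        assert vf == 0.4

    def test_default_calibration_drift_at_2_mg_ml(self):
        # a dilute center well read at the end of a full-plate run shows
        # ~2.5% apparent increase of D for a lysozyme-like formulation
        truth = FormulationTruth.from_radius("lys", 1.9, 91.8)
        a = _center_assignment(2.0)
        _, c_eff = evaporation_trajectory(a, False, 384 * 75.0, EvaporationParams.deterministic())
        drift = forward_diffusion(c_eff / 1000.0, truth) / forward_diffusion(0.002, truth) - 1
        assert 100 * drift == pytest.approx(2.5, abs=0.1)

    def test_drift_ordering_dilute_vs_concentrated(self):
        # evaporation suppression at high concentration: apparent D drift
        # is largest at 2 mg/mL, smaller at 10 and 14 mg/mL
        truth = FormulationTruth.from_radius("lys", 1.9, 91.8)
        t_end = 384 * 75.0
        drifts = []
        for c0 in (2.0, 10.0, 14.0):
            a = _center_assignment(c0)
            _, c_eff = evaporation_trajectory(a, False, t_end, EvaporationParams.deterministic())
            drifts.append(
                forward_diffusion(c_eff / 1000.0, truth) / forward_diffusion(c0 / 1000.0, truth) - 1
            )
        assert drifts[0] > drifts[1] > drifts[2] > 0

    def test_edge_wells_lose_volume_faster(self):
        a = _center_assignment(2.0)
        params = EvaporationParams.deterministic()
        vf_edge, _ = evaporation_trajectory(a, True, 3600.0, params)
        vf_center, _ = evaporation_trajectory(a, False, 3600.0, params)
        assert vf_edge < vf_center


class TestSynthesizeAcf:
    def test_noiseless_closed_form(self, noiseless_instrument):
        acf = synthesize_acf(1.30e-10, noiseless_instrument)
        beta = noiseless_instrument.coherence_beta
        gamma = acf.meta["gammas"][0]
        # g2(tau) - 1 = beta exp(-2 Gamma tau) exactly, -> beta at tau -> 0
        assert np.allclose(
            acf.g2 - 1.0, beta * np.exp(-2 * gamma * acf.lag_times_s), atol=1e-14
        )
        assert acf.g2[-1] == pytest.approx(1.0, abs=1e-12)
        # decay rate against the hand-evaluated oracle Gamma = D q^2
        gamma = acf.meta["gammas"][0]
        assert gamma == pytest.approx(GAMMA_ORACLE, rel=1e-3)
        assert noiseless_instrument.q_m == pytest.approx(Q_ORACLE, rel=1e-3)

    def test_same_seed_is_bit_identical(self, instrument):
        a = synthesize_acf(1.3e-10, instrument, rng=42)
        b = synthesize_acf(1.3e-10, instrument, rng=42)
        assert np.array_equal(a.g2, b.g2)

    def test_nonpositive_d_rejected(self, instrument):
        with pytest.raises(ValueError):
            synthesize_acf(0.0, instrument)


class TestSecondPopulation:
    def test_vanishing_fraction_changes_nothing(self, noiseless_instrument):
        acf = synthesize_acf(1.3e-10, noiseless_instrument)
        mixed = inject_second_population(acf, 42.8, 1e-9)
        assert np.allclose(mixed.g2, acf.g2, atol=1e-6)
        assert mixed.meta["anomaly"]

    def test_full_fraction_is_single_exponential_at_gamma2(self, noiseless_instrument):
        acf = synthesize_acf(1.3e-10, noiseless_instrument)
        mixed = inject_second_population(acf, 42.8, 1.0 - 1e-12)
        gamma2 = noiseless_instrument.gamma_for_radius(42.8)
        expect = 1.0 + noiseless_instrument.coherence_beta * np.exp(
            -2.0 * gamma2 * acf.lag_times_s
        )
        assert np.allclose(mixed.g2, expect, atol=1e-9)

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.1, 1.5])
    def test_fraction_outside_open_interval_rejected(self, f, noiseless_instrument):
        acf = synthesize_acf(1.3e-10, noiseless_instrument)
        with pytest.raises(ValueError):
            inject_second_population(acf, 42.8, f)


class TestSimulatePlate:
    def test_missing_truth_rejected(self, block_layout, instrument):
        with pytest.raises(KeyError):
            simulate_plate(block_layout, {}, instrument)

    def test_same_seed_gives_identical_measurements(self, block_layout, instrument, lysozyme_truth):
        truths = {"lys": lysozyme_truth}
        a = simulate_plate(block_layout, truths, instrument, seed=7)
        b = simulate_plate(block_layout, truths, instrument, seed=7)
        assert a.measurements_frame().equals(b.measurements_frame())
        assert a.truth.equals(b.truth)

    def test_noiseless_roundtrip_recovers_kd_exactly(
        self, block_layout, noiseless_instrument, lysozyme_truth
    ):
        truths = {"lys": lysozyme_truth}
        sim = simulate_plate(
            block_layout, truths, noiseless_instrument, EvaporationParams.off(), seed=1
        )
        ms = analyze_plate(sim, regularize=False)
        res = fit_kd_measurements(ms, screen=False)["lys"]
        assert abs(res.kd_ml_g - 91.8) / 91.8 <= 1e-9
        assert abs(res.d0_m2_s - lysozyme_truth.d0_m2_s) / lysozyme_truth.d0_m2_s <= 1e-9

    def test_truth_sidecar_conserves_mass(self, block_layout, instrument, lysozyme_truth):
        sim = simulate_plate(block_layout, {"lys": lysozyme_truth}, instrument, seed=3)
        t = sim.truth
        samples = t[t["role"] == "sample"]
        assert np.allclose(
            samples["c_eff_mg_ml"] * samples["volume_fraction"],
            samples["concentration_mg_ml"],
            rtol=1e-12,
        )

    def test_solvent_wells_get_flat_noise_acfs(self, instrument, lysozyme_truth):
        layout = make_block_layout(concentrations=(2.0,), replicates=2)
        layout.add(WellAssignment(WellAddress(10, 10), role="control"))
        sim = simulate_plate(layout, {"lys": lysozyme_truth}, instrument, seed=5)
        control = [a for a in sim.acfs if a.well == WellAddress(10, 10)][0]
        assert abs(np.mean(control.g2) - 1.0) < 0.01
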