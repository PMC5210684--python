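import math
from dataclasses import replace

import numpy as np
import pytest

from cyclenoise import (
    BurstModel,
    ModelSpec,
    PartitionModel,
    RegulationProfile,
    ValidationError,
    beta,
    calibrate_rate,
    make_cell_cycle,
    make_strategy,
    mean_protein,
    noise_decomposition,
    stage_occupancy,
)
from cyclenoise.analytics import noise_coefficients
from cyclenoise.simulator import (
    EVENT_DIVISION,
    ExtendedModelSpec,
    estimate_extended_stats,
    estimate_stats,
    invariant_y0,
    simulate_extended,
    simulate_lineage,
    simulate_two_colour,
)

from conftest import random_model


def _small_fig1(target=60.0):
    """A cheap stand-in for the headline model: fewer stages/molecules."""
    cyc = make_cell_cycle(10, 2.0)
    model = ModelSpec(cyc, make_strategy("constant", 1.0, cyc),
                      BurstModel.geometric1(3.0), PartitionModel.from_alpha(1.0))
    return calibrate_rate(model, target)


class TestSimulateLineage:
    def test_no_sources_stays_zero(self):
        cyc = make_cell_cycle(4, 1.0)
        model = ModelSpec(cyc, RegulationProfile((0.0,) * 4),
                          BurstModel.deterministic(1), PartitionModel.from_alpha(1.0))
        traj = simulate_lineage(model, 50, 0, seed=1, x0=0, y0=0.0)
        assert np.all(traj.x == 0)
        assert np.all(traj.z == 0.0)

    def test_reproducible(self):
        model = _small_fig1()
        a = simulate_lineage(model, 100, 10, seed=42)
        b = simulate_lineage(model, 100, 10, seed=42)
        np.testing.assert_array_equal(a.time, b.time)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_array_equal(a.event, b.event)

    def test_trajectory_structure(self):
        model = _small_fig1()
        n_total = 80
        traj = simulate_lineage(model, n_total - 20, 20, seed=3)
        assert np.all(traj.x >= 0)
        assert np.all(np.diff(traj.time) > 0)
        assert len(traj.division_times) == n_total
        assert traj.generation[-1] == n_total
        # stage resets to 1 right after each division
        div = traj.event == EVENT_DIVISION
        assert np.all(traj.stage[div] == 1)
        # bursts raise x, stage advances leave it unchanged
        dx = np.diff(traj.x)
        assert np.all(dx[traj.event[1:] == "burst"] > 0)
        assert np.all(dx[traj.event[1:] == "stage-advance"] == 0)

    def test_y_halves_at_division(self):
        traj = simulate_lineage(_small_fig1(), 30, 0, seed=5)
        idx = np.flatnonzero(traj.event == EVENT_DIVISION)
        lam = traj.time[idx] - traj.time[idx - 1]
        # y just before division = stored y * 2 (division halves it exactly)
        ks = _small_fig1().regulation.ks[-1]  # constant profile
        mB = 3.0
        y_pre = traj.y[idx - 1] + mB * ks * lam
        np.testing.assert_allclose(2 * traj.y[idx], y_pre, rtol=1e-9)

    def test_invalid_counts(self):
        with pytest.raises(ValidationError):
            simulate_lineage(_small_fig1(), 0, 0, seed=1)
        with pytest.raises(ValidationError):
            simulate_lineage(_small_fig1(), 10, -1, seed=1)

    def test_mean_within_ci(self):
        model = _small_fig1()
        traj = simulate_lineage(model, 3000, 50, seed=7)
        s = estimate_stats(traj, 50)
        assert abs(s.mean_x - mean_protein(model)) < 3 * s.se_mean_x

    def test_empirical_stage_occupancy(self):
        cyc = make_cell_cycle(3, lambdas=(1.0, 4.0, 2.0))
        model = ModelSpec(cyc, RegulationProfile((1.0, 1.0, 1.0)),
                          BurstModel.deterministic(1), PartitionModel.from_alpha(1.0))
        traj = simulate_lineage(model, 4000, 20, seed=9)
        dt = np.diff(traj.time)
        tot = dt.sum()
        frac = np.array([dt[traj.stage[:-1] == i + 1].sum() / tot for i in range(3)])
        np.testing.assert_allclose(frac, stage_occupancy(cyc), atol=0.01)

    def test_invariant_y0_equals_molecules_per_cycle(self):
        model = _small_fig1()
        from cyclenoise import molecules_per_cycle

        _, molecules = molecules_per_cycle(model)
        assert invariant_y0(model) == pytest.approx(molecules, rel=1e-9)


class TestEstimateStats:
    def test_eta_within_ci_of_closed_form(self):
        model = _small_fig1()
        s = estimate_stats(simulate_lineage(model, 8000, 50, seed=11), 50)
        expect = noise_decomposition(model).eta_total
        assert abs(s.eta_hat - expect) < 3 * s.se_eta

    def test_difference_form_agrees(self):
        s = estimate_stats(simulate_lineage(_small_fig1(), 5000, 50, seed=13), 50)
        assert abs(s.eta_hat - s.eta_diff) < 4 * s.se_eta

    def test_mean_x_matches_mean_y(self):
        s = estimate_stats(simulate_lineage(_small_fig1(), 5000, 50, seed=15), 50)
        assert abs(s.mean_x - s.mean_y) < 4 * s.se_mean_x

    def test_burn_in_exhausts_trajectory(self):
        traj = simulate_lineage(_small_fig1(), 10, 0, seed=17)
        with pytest.raises(ValidationError):
            estimate_stats(traj, 50)

    def test_random_models_within_three_se(self):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 10:
            model = random_model(rng)
            if mean_protein(model) < 5:  # keep relative noise moderate
                continue
            s = estimate_stats(simulate_lineage(model, 1500, 50, seed=checked), 50)
            expect = noise_decomposition(model)
            assert abs(s.mean_x - expect.mean_x) < 3 * s.se_mean_x
            assert abs(s.eta_hat - expect.eta_total) < 3 * s.se_eta
            checked += 1

    def test_poisson_identity_in_simulation(self):
        rng = np.random.default_rng(31)
        cyc = make_cell_cycle(5, lambdas=tuple(rng.uniform(1, 5, 5)))
        model = ModelSpec(cyc, RegulationProfile(tuple(rng.uniform(5, 40, 5))),
                          BurstModel.deterministic(1), PartitionModel.from_alpha(1.0))
        s = estimate_stats(simulate_lineage(model, 6000, 50, seed=33), 50)
        assert abs(s.eta_hat * s.mean_x - 1.0) < 3 * s.se_eta * s.mean_x


class TestDegradation:
    def test_runs_and_lowers_mean(self):
        model = replace(_small_fig1(), degradation_rate=0.5)
        traj = simulate_lineage(model, 2000, 50, seed=19)
        s = estimate_stats(traj, 50)
        stable_mean = mean_protein(replace(model, degradation_rate=0.0))
        assert s.mean_x < stable_mean
        assert s.mean_x > 0

    def test_decay_events_present(self):
        model = replace(_small_fig1(), degradation_rate=0.5)
        traj = simulate_lineage(model, 200, 0, seed=21)
        assert np.any(traj.event == "decay")


class TestTwoColour:
    def test_matches_closed_form(self):
        model = _small_fig1()
        res = simulate_two_colour(model, 4000, 50, seed=23)
        expect = noise_decomposition(model).eta_total
        assert abs(res.eta_hat - expect) < 3 * res.se_eta
        assert abs(res.mean_x - mean_protein(model)) < 0.05 * mean_protein(model)

    def test_zero_burst_variance_alpha_zero(self):
        """Deterministic single-molecule bursts with perfect halving leave
        only Poisson-arrival noise: eta * mean = 1/3 + 2/(3 (1 + beta))."""
        cyc = make_cell_cycle(8, 1.0)
        model = ModelSpec(cyc, make_strategy("constant", 80.0, cyc),
                          BurstModel.deterministic(1), PartitionModel.from_alpha(0.0))
        res = simulate_two_colour(model, 4000, 50, seed=25)
        c_burst, _ = noise_coefficients(beta(model), 1.0, 0.0)
        expect = c_burst / mean_protein(model)
        assert expect > 0
        assert abs(res.eta_hat - expect) < 3.5 * res.se_eta

    def test_reproducible(self):
        model = _small_fig1()
        a = simulate_two_colour(model, 300, 20, seed=27)
        b = simulate_two_colour(model, 300, 20, seed=27)
        assert a == b

    def test_degradation_rejected(self):
        with pytest.raises(ValidationError):
            simulate_two_colour(replace(_small_fig1(), degradation_rate=0.1), 10, 0, 1)


def _extended(cyc, window=None, k_tx=20.0, k_tl=10.0, mrna_decay=20.0,
              protein_decay=0.0, **kw):
    """Always-on promoter; `window` restricts transcription to a stage range
    by zeroing k_on outside it and making k_off huge there."""
    n = cyc.n
    k_on = [1e4] * n
    k_off = [0.0] * n
    if window is not None:
        lo, hi = window
        for i in range(n):
            if not (lo <= i < hi):
                k_on[i] = 0.0
                k_off[i] = 1e4
    return ExtendedModelSpec(
        cycle=cyc, k_on=tuple(k_on), k_off=tuple(k_off), k_tx=k_tx,
        mrna_decay=mrna_decay, k_tl=k_tl, protein_decay=protein_decay, **kw)


class TestExtendedModel:
    def test_no_translation_no_protein(self):
        cyc = make_cell_cycle(4, 1.0)
        ext = _extended(cyc, k_tl=0.0)
        traj = simulate_extended(ext, 100, 0, seed=1)
        assert np.all(traj.protein <= traj.protein[0])  # only decay of the seed
        ext0 = ExtendedModelSpec(cycle=cyc, k_on=(0.0,) * 4, k_off=(1.0,) * 4,
                                 k_tx=5.0, mrna_decay=10.0, k_tl=0.0)
        traj0 = simulate_extended(ext0, 100, 0, seed=2)
        assert np.all(traj0.protein == 0)

    def test_fast_mrna_limit_matches_bursty_model(self):
        """With an always-on promoter and fast mRNA turnover, each mRNA
        makes a geometric (from 0) number of proteins with mean
        k_tl / mrna_decay, so the corrected noise approaches the bursty
        closed form with matched burst moments."""
        cyc = make_cell_cycle(6, 1.0)
        k_tx, k_tl, gm = 12.0, 120.0, 60.0
        ext = _extended(cyc, k_tx=k_tx, k_tl=k_tl, mrna_decay=gm)
        traj = simulate_extended(ext, 3000, 100, seed=3)
        s = estimate_extended_stats(traj, 100)
        matched = ModelSpec(
            cyc, make_strategy("constant", k_tx, cyc),
            BurstModel.geometric0(k_tl / gm), PartitionModel.from_alpha(1.0))
        expect = noise_decomposition(matched)
        assert s.mean_protein == pytest.approx(expect.mean_x, rel=0.05)
        # mRNA lifetime is short but not zero, so allow a coarse tolerance
        assert s.eta_hat == pytest.approx(expect.eta_total, rel=0.20)

    def test_end_window_buffers_noise(self):
        """Transcription confined to the cycle end gives lower corrected
        protein noise than a constant rate, at matched mean."""
        cyc = make_cell_cycle(6, 1.0)
        const = _extended(cyc, k_tx=10.0)
        # end third of the cycle; matched mean via the bursty-analog means
        analog = lambda prof_ks, ktx: mean_protein(ModelSpec(
            cyc, RegulationProfile(prof_ks), BurstModel.geometric0(0.5),
            PartitionModel.from_alpha(1.0)))
        m_const = analog((10.0,) * 6, 10.0)
        k_end = 10.0 * m_const / analog((0, 0, 0, 0, 10.0, 10.0), 10.0)
        end = _extended(cyc, window=(4, 6), k_tx=k_end)
        s_const = estimate_extended_stats(simulate_extended(const, 2500, 100, 4), 100)
        s_end = estimate_extended_stats(simulate_extended(end, 2500, 100, 5), 100)
        assert s_end.mean_protein == pytest.approx(s_const.mean_protein, rel=0.1)
        assert s_end.eta_hat < s_const.eta_hat

    def test_cycle_memory_validation(self):
        cyc = make_cell_cycle(2, 1.0)
        with pytest.raises(ValidationError):
            _extended(cyc, memory_rho=1.5)
        with pytest.raises(ValidationError):
            _extended(cyc, memory_sd=-0.1)

    def test_memory_runs_reproducibly(self):
        cyc = make_cell_cycle(3, 1.0)
        ext = _extended(cyc, memory_rho=0.5, memory_sd=0.2)
        a = simulate_extended(ext, 50, 0, seed=6)
        b = simulate_extended(ext, 50, 0, seed=6)
        np.testing.assert_array_equal(a.time, b.time)
        np.testing.assert_array_equal(a.protein, b.protein)
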