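import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kdapp import (
    DomainError,
    QCThresholds,
    ReporterMatrix,
    aggregate_replicates,
    assess_and_filter,
    compute_fraction_bound,
    fit_hill,
    fit_titration,
    hill_theta,
    minmax_scale,
    replicate_cv,
)
from kdapp.binding import HillFit, MeanProfile, ThetaProfile


class TestHillTheta:
    @pytest.mark.parametrize("n", [0.1, 0.5, 1.0, 2.0, 7.3])
    def test_half_bound_at_kd(self, n):
        assert hill_theta(38.0, 38.0, n) == pytest.approx(0.5, abs=1e-15)

    def test_near_saturation_at_top_of_titration(self):
        assert hill_theta(3000, 38, 1) == pytest.approx(0.987492, abs=1e-6)

    def test_weak_binder_low_occupancy(self):
        assert hill_theta(10, 100, 2) == pytest.approx(1 / 101, rel=1e-9)

    @given(
        L=st.floats(1e-2, 1e4), kd=st.floats(1e-2, 1e4),
    )
    @settings(max_examples=100, deadline=None)
    def test_n1_reduces_to_langmuir(self, L, kd):
        assert hill_theta(L, kd, 1.0) == pytest.approx(L / (L + kd), rel=1e-12)

    def test_monotone_in_L_and_kd(self):
        L = np.geomspace(0.1, 1e4, 50)
        for n in (0.5, 1, 2):
            th = hill_theta(L, 38.0, n)
            assert np.all(np.diff(th) > 0)
        for n in (0.5, 1, 2):
            kds = np.geomspace(1, 1e4, 50)
            th = np.array([hill_theta(100.0, kd, n) for kd in kds])
            assert np.all(np.diff(th) < 0)

    @pytest.mark.parametrize("args", [(0, 10, 1), (10, 0, 1), (10, 10, 0), (-1, 5, 1)])
    def test_domain_errors(self, args):
        with pytest.raises(DomainError):
            hill_theta(*args)


class TestComputeFractionBound:
    def test_reference_channel_self_ratio_is_one(self, toy_matrix, tmt10_map):
        for p in compute_fraction_bound(toy_matrix, tmt10_map):
            assert p.theta[-1] == pytest.approx(1.0)
            assert p.complete

    def test_direct_ratio_arithmetic(self):
        from kdapp import build_channel_map

        cm = build_channel_map(100, 2, 3, ["a", "b", "c"])
        df = pd.DataFrame([[10.0, 20.0, 40.0]], index=["P"], columns=["a", "b", "c"])
        m = ReporterMatrix("e", "b", "r", df)
        (p,) = compute_fraction_bound(m, cm)
        assert np.allclose(p.theta, [0.25, 0.5, 1.0])

    def test_missing_reference_flags_incomplete(self, toy_matrix, tmt10_map):
        df = toy_matrix.intensities.copy()
        df.loc["P2", "131"] = np.nan
        m = ReporterMatrix("e", "b", "r", df)
        profiles = {p.protein: p for p in compute_fraction_bound(m, tmt10_map)}
        assert not profiles["P2"].complete
        assert profiles["P1"].complete


class TestMinmaxScale:
    def test_basic_scaling(self):
        p = ThetaProfile("P", "r1", np.array([0.1, 0.55, 1.0]), True)
        assert np.allclose(minmax_scale(p).theta, [0.0, 0.5, 1.0])

    def test_idempotent_on_unit_range(self):
        p = ThetaProfile("P", "r1", np.array([0.0, 0.25, 1.0]), True)
        assert np.allclose(minmax_scale(p).theta, p.theta)

    def test_constant_profile_flagged_degenerate(self):
        p = ThetaProfile("P", "r1", np.array([0.7, 0.7, 0.7]), True)
        assert minmax_scale(p).degenerate

    def test_incomplete_profile_rejected(self):
        p = ThetaProfile("P", "r1", np.array([0.1, np.nan, 1.0]), False)
        with pytest.raises(ValueError):
            minmax_scale(p)


class TestAggregateReplicates:
    def _profiles(self, rows):
        return [
            ThetaProfile("P", f"r{i}", np.asarray(row, float), True)
            for i, row in enumerate(rows)
        ]

    def test_identical_replicates_zero_sem(self):
        mp = aggregate_replicates(self._profiles([[0.1, 0.5, 1.0]] * 3), n_boot=200, seed=1)
        assert np.allclose(mp.sem_theta, 0.0)
        assert mp.n_replicates == 3

    def test_pointwise_mean(self):
        mp = aggregate_replicates(
            self._profiles([[0.4, 0.4, 0.4], [0.5, 0.5, 0.5], [0.6, 0.6, 0.6]]),
            n_boot=50, seed=1,
        )
        assert np.allclose(mp.mean_theta, 0.5)

    def test_seed_determinism(self):
        rows = [[0.2, 0.5, 0.9], [0.3, 0.6, 1.0], [0.1, 0.4, 0.8]]
        a = aggregate_replicates(self._profiles(rows), n_boot=300, seed=7)
        b = aggregate_replicates(self._profiles(rows), n_boot=300, seed=7)
        assert np.array_equal(a.sem_theta, b.sem_theta)

    def test_no_usable_replicates_raises(self):
        bad = [ThetaProfile("P", "r1", np.array([1.0, 2.0]), False)]
        with pytest.raises(ValueError):
            aggregate_replicates(bad)


class TestFitHill:
    @pytest.mark.parametrize("kd,n", [(100, 1), (38, 1), (10, 2), (1000, 0.5)])
    def test_noiseless_recovery(self, tmt10_map, kd, n):
        L = np.asarray(tmt10_map.concentrations)
        y = hill_theta(L, kd, n)
        fit = fit_hill(MeanProfile("P", y, np.zeros_like(y), 3), tmt10_map)
        assert fit.converged
        assert fit.kd_app == pytest.approx(kd, rel=1e-6)
        assert fit.hill_n == pytest.approx(n, rel=1e-5)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_flat_noise_profile_fails_qc(self, tmt10_map):
        rng = np.random.default_rng(5)
        y = 0.5 + 0.05 * rng.standard_normal(10)
        fit = fit_hill(MeanProfile("BG", y, np.zeros_like(y), 3), tmt10_map)
        accepted = assess_and_filter([fit], QCThresholds.preset("dna"))
        assert accepted == []
        assert not fit.qc_pass


class TestAssessAndFilter:
    def test_kd_at_top_concentration_rejected_on_endpoint(self, tmt10_map):
        # Kd equal to the top concentration: predicted saturation is only 0.5
        L = np.asarray(tmt10_map.concentrations)
        y = hill_theta(L, 3000.0, 1.0)
        fit = fit_hill(MeanProfile("P", y, np.zeros_like(y), 3), tmt10_map)
        assert fit.theta_pred_high == pytest.approx(0.5, abs=1e-6)
        assert assess_and_filter([fit], QCThresholds.preset("dna")) == []

    def test_r2_boundary_separates_presets(self):
        fit = HillFit("P", 50.0, 1.0, 0.94, 0.01, 0.99, converged=True)
        assert assess_and_filter([fit], QCThresholds.preset("dna")) == []
        fit2 = HillFit("P", 50.0, 1.0, 0.94, 0.01, 0.99, converged=True)
        assert assess_and_filter([fit2], QCThresholds.preset("nucleosome")) == [fit2]

    def test_nonconverged_never_passes(self):
        fit = HillFit("P", np.nan, np.nan, np.nan, np.nan, np.nan, converged=False)
        assert assess_and_filter([fit], QCThresholds.preset("dna")) == []

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            QCThresholds(r2_min=1.5)
        with pytest.raises(ValueError):
            QCThresholds(r2_min=0.95, theta_low_max=0.8, theta_high_min=0.7)


class TestReplicateCV:
    def test_textbook_value(self):
        assert replicate_cv([90.0, 100.0, 110.0]) == pytest.approx(0.10)

    def test_identical_replicates(self):
        assert replicate_cv([50.0, 50.0, 50.0]) == 0.0

    def test_single_replicate_omitted(self):
        assert replicate_cv([42.0]) is None


class TestScaleEquivariance:
    def test_rescaling_a_replicate_changes_nothing(self, tmt10_map):
        rng = np.random.default_rng(11)
        L = np.asarray(tmt10_map.concentrations)
        base = 1e6 * hill_theta(L, 80.0, 1.0) * np.exp(rng.normal(0, 0.1, (3, 10)))
        cols = list(tmt10_map.channel_labels)

        def run(scale_rep0):
            mats = []
            for r in range(3):
                vals = base[r] * (scale_rep0 if r == 0 else 1.0)
                df = pd.DataFrame([vals], index=["P"], columns=cols)
                mats.append(ReporterMatrix("e", "b", f"r{r}", df))
            return fit_titration(
                mats, tmt10_map, QCThresholds.preset("dna"),
                n_boot=50, seed=3, normalize=False,
            )

        a, b = run(1.0), run(137.5)
        assert a.kd_app_nM[0] == pytest.approx(b.kd_app_nM[0], rel=1e-9)
        assert bool(a.qc_pass[0]) == bool(b.qc_pass[0])
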