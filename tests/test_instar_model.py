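"""Gaussian head-width instar models: fitting, classification, decision
boundaries, misclassification risk, Brooks–Dyar ratios, molt detection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import thermaldev as td


def toy_models(m1=0.329, m2=0.421, s1=0.02, s2=0.02):
    return [
        td.InstarSizeModel(td.Stage.L1, mean=m1, sd=s1, min=m1 - 5 * s1,
                           max=m1 + 5 * s1, n=50),
        td.InstarSizeModel(td.Stage.L2, mean=m2, sd=s2, min=m2 - 5 * s2,
                           max=m2 + 5 * s2, n=50),
    ]


class TestFitSizeModel:
    def test_moments_match_numpy(self, rng):
        vals = rng.normal(0.42, 0.02, 200)
        models = td.fit_size_model([(td.Stage.L2, v) for v in vals])
        (m,) = models
        assert m.mean == pytest.approx(vals.mean())
        assert m.sd == pytest.approx(vals.std(ddof=1))
        assert m.min == pytest.approx(vals.min())
        assert m.max == pytest.approx(vals.max())
        assert m.n == 200

    def test_degenerate_variance_rejected(self):
        with pytest.raises(td.ValidationError, match="identical"):
            td.fit_size_model([(td.Stage.L1, 0.3)] * 3)

    def test_single_reading_rejected(self):
        with pytest.raises(td.ValidationError):
            td.fit_size_model([(td.Stage.L1, 0.3)])

    def test_truncated_normal_sample_recovers_mean(self):
        cfg = td.SimulationConfig(seed=2016)
        draws = td.gen_head_widths(cfg, td.Stage.L1, n=591)
        models = td.fit_size_model([(td.Stage.L1, v) for v in draws]
                                   + [(td.Stage.L2, v) for v in (0.40, 0.44)])
        m = models[0]
        sem = 0.017 / np.sqrt(591)
        assert abs(m.mean - 0.329) < 3 * sem


class TestClassification:
    def test_printed_means_assigned_to_own_instars(self, width_models):
        for width, expected in [(0.329, td.Stage.L1), (0.421, td.Stage.L2),
                                (0.522, td.Stage.L3)]:
            res = td.classify_width(width_models, width)
            assert res.assigned == expected
            # density-comparison oracle
            dens = {m.instar: stats.norm.pdf(width, m.mean, m.sd)
                    for m in width_models}
            assert max(dens, key=dens.get) == expected

    def test_midpoint_tie_goes_to_earlier_instar(self):
        models = toy_models()
        res = td.classify_width(models, (0.329 + 0.421) / 2)
        assert res.posterior[td.Stage.L1] == pytest.approx(0.5, abs=1e-12)
        assert res.posterior[td.Stage.L2] == pytest.approx(0.5, abs=1e-12)
        assert res.assigned == td.Stage.L1

    def test_out_of_range_flagged_not_rejected(self, width_models):
        res = td.classify_width(width_models, 0.60)  # above L3 max 0.582
        assert res.assigned == td.Stage.L3
        assert res.out_of_range

    def test_invalid_width_rejected(self, width_models):
        with pytest.raises(td.ValidationError):
            td.classify_width(width_models, -0.3)

    @given(st.floats(min_value=0.05, max_value=1.0))
    def test_posteriors_normalize_everywhere(self, width):
        res = td.classify_width(toy_models(), width)
        assert sum(res.posterior.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(p >= 0 for p in res.posterior.values())

    def test_priors_shift_assignment(self):
        models = toy_models()
        mid = (0.329 + 0.421) / 2
        res = td.classify_width(models, mid + 1e-6,
                                priors={td.Stage.L1: 0.9, td.Stage.L2: 0.1})
        assert res.assigned == td.Stage.L1


class TestBoundaries:
    def test_equal_sd_boundary_is_midpoint(self):
        bounds = td.decision_boundaries(toy_models())
        assert bounds == [pytest.approx(0.375, abs=1e-12)]

    def test_unequal_sd_boundary_matches_grid_oracle(self, width_models):
        bounds = td.decision_boundaries(width_models)
        l1, l2 = width_models[0], width_models[1]
        grid = np.arange(l1.mean, l2.mean, 1e-4)
        diff = (stats.norm.pdf(grid, l1.mean, l1.sd)
                - stats.norm.pdf(grid, l2.mean, l2.sd))
        crossing = grid[np.where(np.diff(np.sign(diff)))[0][0]]
        assert 0.329 < bounds[0] < 0.421
        assert abs(bounds[0] - crossing) < 0.005

    def test_boundary_is_the_assignment_switch_point(self, width_models):
        for b in td.decision_boundaries(width_models):
            below = td.classify_width(width_models, b - 1e-6).assigned
            above = td.classify_width(width_models, b + 1e-6).assigned
            assert above == td.Stage(below + 1)

    def test_affine_equivariance_under_rescaling(self, width_models):
        c = 2.5
        scaled = [
            td.InstarSizeModel(m.instar, mean=c * m.mean, sd=c * m.sd,
                               min=c * m.min, max=c * m.max, n=m.n)
            for m in width_models
        ]
        b0 = td.decision_boundaries(width_models)
        b1 = td.decision_boundaries(scaled)
        assert np.allclose(b1, [c * b for b in b0], rtol=1e-9)


class TestMisclassification:
    def test_rows_sum_to_one(self, width_models):
        mat = td.misclassification_matrix(width_models)
        assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-10)

    def test_diagonal_dominates_for_reference_models(self, width_models):
        mat = td.misclassification_matrix(width_models)
        assert (np.diag(mat.values) > 0.95).all()

    def test_matches_monte_carlo_oracle(self, width_models, rng):
        mat = td.misclassification_matrix(width_models)
        means = np.array([m.mean for m in width_models])
        sds = np.array([m.sd for m in width_models])
        for i, m in enumerate(width_models):
            draws = rng.normal(m.mean, m.sd, 100_000)
            # independent assignment path: direct density comparison
            logpdf = stats.norm.logpdf(draws[:, None], means[None, :], sds[None, :])
            assigned = np.argmax(logpdf, axis=1)
            freq = np.bincount(assigned, minlength=3) / len(draws)
            assert np.allclose(mat.values[i], freq, atol=0.005)

    def test_identical_models_confuse_completely(self):
        m = dict(mean=0.4, sd=0.02, min=0.3, max=0.5, n=10)
        models = [td.InstarSizeModel(td.Stage.L1, **m),
                  td.InstarSizeModel(td.Stage.L2, **m)]
        mat = td.misclassification_matrix(models)
        assert np.allclose(mat.values, 0.5, atol=1e-12)

    def test_self_consistency_with_classifier(self, width_models, rng):
        mat = td.misclassification_matrix(width_models)
        m = width_models[1]  # L2, the most confusable instar
        draws = rng.normal(m.mean, m.sd, 20_000)
        hits = np.mean([td.classify_width(width_models, w).assigned == m.instar
                        for w in draws[:4000]])
        assert abs(hits - mat.loc["L2", "L2"]) < 0.02


class TestBrooksDyar:
    def test_reference_ratios(self, width_models):
        res = td.brooks_dyar(width_models)
        assert res.ratios[0] == pytest.approx(0.421 / 0.329, rel=1e-12)
        assert res.ratios[1] == pytest.approx(0.522 / 0.421, rel=1e-12)
        assert res.ratios[0] == pytest.approx(1.280, abs=5e-4)
        assert res.ratios[1] == pytest.approx(1.240, abs=5e-4)
        assert all(r > 1 for r in res.ratios)

    def test_geometric_progression_has_zero_constancy(self):
        a, r = 0.3, 1.3
        models = [
            td.InstarSizeModel(stage, mean=a * r**i, sd=0.01,
                               min=a * r**i - 0.05, max=a * r**i + 0.05, n=10)
            for i, stage in enumerate(td.instar_model.LARVAL_INSTARS)
        ]
        res = td.brooks_dyar(models)
        assert res.constancy == pytest.approx(0.0, abs=1e-12)


class TestMoltDetection:
    def make_traj(self, widths):
        return td.WidthTrajectory("x", tuple(range(1, len(widths) + 1)),
                                  tuple(widths))

    def test_single_clear_jump(self):
        res = td.detect_molts(self.make_traj([0.33, 0.33, 0.52, 0.52]))
        assert len(res.molts) == 1
        assert res.molts[0].day == 3
        assert res.instar_count == 2

    def test_constant_trajectory_no_molt(self):
        res = td.detect_molts(self.make_traj([0.33] * 5))
        assert res.molts == ()
        assert res.instar_count == 1

    def test_default_threshold_misses_small_first_molt(self):
        # mean plateaus step by 0.092 then 0.101 mm: the classic 0.1 mm rule
        # cannot see the first molt of a small larva
        widths = [0.329] * 3 + [0.421] * 3 + [0.522] * 3
        res = td.detect_molts(self.make_traj(widths), threshold=0.1)
        assert len(res.molts) == 1
        res08 = td.detect_molts(self.make_traj(widths), threshold=0.08)
        assert len(res08.molts) == 2
        assert res08.instar_count == 3

    def test_noisy_single_frame_does_not_trigger(self):
        # one high frame then return: running mean absorbs it
        widths = [0.330, 0.331, 0.329, 0.333, 0.330, 0.331]
        res = td.detect_molts(self.make_traj(widths), threshold=0.1)
        assert res.molts == ()

    def test_trajectory_validation(self):
        with pytest.raises(td.ValidationError):
            td.WidthTrajectory("x", (1, 1), (0.3, 0.4))
        with pytest.raises(td.ValidationError):
            td.WidthTrajectory("x", (1, 2), (0.3, -0.4))
        with pytest.raises(td.ValidationError):
            td.detect_molts(td.WidthTrajectory("x", (1,), (0.3,)))
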