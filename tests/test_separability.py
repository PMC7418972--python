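"""Domain-classification pipeline: proxy A-distance, probability pooling,
separability fitting and the end-to-end criterion."""

import numpy as np
import pytest

from datarep.betadiv import BetaShape
from datarep.exceptions import InvalidInputError
from datarep.patching import PatchSet
from datarep.separability import (
    DataRepresentativeness,
    DomainSample,
    drc_from_domains,
    evaluate_domain_classifier,
    fit_separability,
    gaussian_domains,
    pool_probabilities,
    proxy_a_distance,
    stability_sweep,
    train_domain_classifier,
)


class StubModel:
    """Minimal predict_proba carrier for pooling tests."""

    classes_ = np.array([0, 1])

    def __init__(self, probs_u):
        self.probs_u = np.asarray(probs_u, dtype=float)

    def predict_proba(self, X):
        p = self.probs_u[: len(X)]
        return np.column_stack([1 - p, p])

    def get_params(self):
        return {"cv": 0}


class TestProxyADistance:
    @pytest.mark.parametrize("error,expected", [(0.0, 2.0), (0.5, 0.0), (0.25, 1.0)])
    def test_linear_map_endpoints_and_midpoint(self, error, expected):
        assert proxy_a_distance(error) == expected

    def test_above_chance_error_clamps_to_zero(self):
        assert proxy_a_distance(0.7) == 0.0
        assert proxy_a_distance(1.0) == 0.0

    @pytest.mark.parametrize("bad", [-0.1, 1.2])
    def test_out_of_range_error_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            proxy_a_distance(bad)

    def test_affine_decreasing_on_informative_range(self):
        errors = np.linspace(0, 0.5, 11)
        values = [proxy_a_distance(e) for e in errors]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert all(0 <= v <= 2 for v in values)


class TestPooling:
    def test_pooled_multiset_contains_both_class_probabilities(self):
        test = DomainSample(np.zeros((3, 2)), [0, 1, 0])
        pooled = pool_probabilities(StubModel([0.5, 0.7, 0.1]), test)
        assert sorted(pooled) == pytest.approx(sorted([0.5, 0.5, 0.7, 0.3, 0.1, 0.9]))

    def test_pooled_mean_is_exactly_half(self):
        probs = np.random.default_rng(0).random(200)
        test = DomainSample(np.zeros((200, 2)), np.zeros(200, dtype=int))
        pooled = pool_probabilities(StubModel(probs), test)
        assert pooled.mean() == pytest.approx(0.5, abs=1e-12)
        assert len(pooled) == 400

    def test_empty_test_set_rejected(self):
        test = DomainSample(np.zeros((0, 2)), np.zeros(0, dtype=int))
        with pytest.raises(InvalidInputError):
            pool_probabilities(StubModel([]), test)

    def test_exact_half_ties_break_toward_domain_t(self):
        test = DomainSample(np.zeros((2, 2)), [0, 1])
        result = evaluate_domain_classifier(StubModel([0.5, 0.5]), test)
        assert result.n_ties == 2
        assert result.cv_error == 0.5  # the U row is called T, the T row is right


class TestSeparabilityFit:
    def test_recovers_shapes_from_pooled_beta_sample(self):
        rng = np.random.default_rng(42)
        draws = rng.beta(50, 50, size=5000)
        pooled = np.concatenate([draws, 1 - draws])
        fit = fit_separability(pooled)
        assert fit.proper
        assert fit.shape.alpha == pytest.approx(50, rel=0.10)
        assert fit.shape.beta == pytest.approx(50, rel=0.10)
        assert fit.n_probabilities == 10000

    def test_large_pooled_sample_fits_nearly_symmetric_shape(self):
        rng = np.random.default_rng(3)
        draws = rng.beta(8, 8, size=6000)
        pooled = np.concatenate([draws, 1 - draws])
        fit = fit_separability(pooled)
        skew = abs(fit.shape.alpha - fit.shape.beta) / (fit.shape.alpha + fit.shape.beta)
        assert skew < 0.02

    def test_constant_probabilities_flagged_degenerate(self):
        fit = fit_separability(np.full(100, 0.5))
        assert not fit.proper
        assert fit.reason == "degenerate-sample"

    def test_exact_endpoints_without_clipping_are_improper(self):
        probs = np.concatenate([np.zeros(50), np.ones(50), [0.4, 0.6]])
        fit = fit_separability(probs, clip_epsilon=0.0)
        assert not fit.proper
        assert fit.reason == "unbounded-likelihood"

    def test_endpoint_masses_with_clipping_yield_improper_shapes(self):
        """Completely separable domains: half the probabilities at each
        endpoint drive the MLE into the degenerate-shape regime."""
        probs = np.concatenate([np.zeros(500), np.ones(500)])
        fit = fit_separability(probs, clip_epsilon=1e-6)
        assert fit.clip_applied
        assert not fit.proper
        assert fit.reason == "shape-out-of-range"

    def test_too_few_probabilities_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_separability([0.5] * 9)

    def test_probabilities_outside_unit_interval_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_separability(np.linspace(-0.1, 0.5, 20))


class TestDomainClassifier:
    def test_identical_domains_score_chance_error(self):
        train, test = gaussian_domains(2000, delta=0.0, seed=11)
        model = train_domain_classifier(train, seed=11)
        result = evaluate_domain_classifier(model, test)
        assert result.cv_error == pytest.approx(0.5, abs=0.03)

    def test_far_separated_domains_score_near_zero_error(self):
        train, test = gaussian_domains(1000, delta=8.0, seed=12)
        model = train_domain_classifier(train, seed=12)
        result = evaluate_domain_classifier(model, test)
        assert result.cv_error <= 0.01

    def test_moderate_separation_matches_analytic_bayes_error(self):
        """At mean separation 2 the optimal rule errs Phi(-1) ~ 0.1587."""
        train, test = gaussian_domains(5000, delta=2.0, seed=13)
        model = train_domain_classifier(train, seed=13)
        result = evaluate_domain_classifier(model, test)
        assert result.cv_error == pytest.approx(0.1587, abs=0.02)

    def test_single_domain_training_rejected(self):
        sample = DomainSample(np.random.default_rng(1).random((50, 3)),
                              np.zeros(50, dtype=int))
        with pytest.raises(InvalidInputError):
            train_domain_classifier(sample)

    def test_zero_variance_features_warn(self):
        sample = DomainSample(np.ones((60, 2)),
                              np.repeat([0, 1], 30))
        with pytest.warns(UserWarning, match="zero variance"):
            train_domain_classifier(sample, folds=3)


class TestEndToEnd:
    def test_same_master_seed_reproduces_report_exactly(self):
        train, test = gaussian_domains(600, delta=1.0, seed=21)
        a = drc_from_domains(train, test, seed=5)
        b = drc_from_domains(train, test, seed=5)
        assert a.report == b.report
        assert a.classifier.cv_error == b.classifier.cv_error

    def test_disjoint_intensity_ranges_flagged_improper_with_max_distance(self):
        train, test = gaussian_domains(600, delta=25.0, seed=22)
        result = drc_from_domains(train, test, seed=6)
        assert not result.fit.proper
        assert np.isnan(result.report.drc)
        assert result.report.verdict == "not_representative"
        assert not result.report.proper
        assert result.proxy_a_distance >= 1.95

    def test_overlapping_scan_ids_between_train_and_test_rejected(self):
        x = np.random.default_rng(2).random((40, 2))
        y = np.repeat([0, 1], 20)
        ids = np.array(["scanA"] * 40)
        sample = DomainSample(x, y, scan_id=ids)
        with pytest.raises(InvalidInputError, match="share scan ids"):
            drc_from_domains(sample, sample)

    def test_estimator_exposes_fitted_attributes(self):
        train, test = gaussian_domains(600, delta=1.0, seed=23)
        est = DataRepresentativeness(random_state=1)
        est.fit(train, train.domain)
        est.evaluate(test)
        assert 0 <= est.cv_error_ <= 1
        assert 0 <= est.proxy_a_distance_ <= 2
        assert est.report_.bm1 == BetaShape(25, 25)
        params = est.get_params()
        assert params["band"] == 0.05


def synthetic_scan_patchsets(n_scans, mean_shift, seed, n_patches=200, k=3):
    """Cheap stand-in scans: random patch matrices with a domain shift."""
    rng = np.random.default_rng(seed)
    sets = []
    for i in range(n_scans):
        patches = rng.normal(mean_shift, 1.0, size=(n_patches, k * k))
        centers = np.column_stack([rng.integers(1, 20, n_patches)] * 2)
        sets.append(PatchSet(patches=patches, centers=centers, k=k,
                             subject_id=f"s{i}", scanner_id=f"d{mean_shift}"))
    return sets


class TestStabilitySweep:
    def test_single_cell_yields_single_row(self):
        t = synthetic_scan_patchsets(6, 0.0, 31)
        u = synthetic_scan_patchsets(6, 0.5, 32)
        table = stability_sweep(t, u, [50], reps=1, bm1_list=[(25, 25)],
                                seed=1, n_build_scans=4, n_test_scans=2)
        assert len(table) == 1
        assert set(table.columns) >= {
            "condition", "rep", "n_patches", "bm1_alpha", "bm1_beta",
            "kl_bm1", "kl_bm2", "drc", "proxy_a_distance", "cv_error",
            "proper", "verdict",
        }

    def test_rows_scale_with_grid(self):
        t = synthetic_scan_patchsets(6, 0.0, 33)
        u = synthetic_scan_patchsets(6, 0.5, 34)
        table = stability_sweep(t, u, [30, 60], reps=2,
                                bm1_list=[(25, 25), (50, 50)],
                                seed=2, n_build_scans=4, n_test_scans=2)
        assert len(table) == 2 * 2 * 2
        assert table.groupby(["n_patches", "rep"]).ngroups == 4

    def test_insufficient_scans_rejected(self):
        t = synthetic_scan_patchsets(3, 0.0, 35)
        u = synthetic_scan_patchsets(6, 0.5, 36)
        with pytest.raises(InvalidInputError, match="need"):
            stability_sweep(t, u, [30], reps=1, bm1_list=[(25, 25)],
                            seed=3, n_build_scans=4, n_test_scans=2)

    def test_replicate_scatter_shrinks_with_patch_budget(self):
        """More test patches stabilise the criterion across replicates."""
        t = synthetic_scan_patchsets(8, 0.0, 37, n_patches=400)
        u = synthetic_scan_patchsets(8, 0.8, 38, n_patches=400)
        table = stability_sweep(t, u, [20, 300], reps=4, bm1_list=[(25, 25)],
                                seed=4, n_build_scans=5, n_test_scans=3)
        spread = table.groupby("n_patches").drc.std()
        assert spread.loc[300] <= spread.loc[20]
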