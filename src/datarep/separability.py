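"""Domain separability: the domain-classification pipeline.

Two data sets are compared by training a discriminator ("domain
classifier") to tell which of them an instance came from.  Three
summaries are derived from the held-out behaviour of that classifier:

* the held-out error ``e``, converted to the proxy A-distance
  ``d_A = 2 (1 - 2 e)`` clamped into [0, 2];
* the pooled class probabilities of the held-out instances (both the
  probability of domain T and of domain U are kept per instance, so the
  pooled sample has mean exactly 0.5);
* a beta distribution fitted to those pooled probabilities — the
  *separability distribution* — which feeds the representativeness
  criterion in :mod:`datarep.betadiv`.

The discriminator is an L2-regularised logistic regression whose
regularisation strength is chosen by internal stratified
cross-validation; the error entering the proxy A-distance is measured
on a held-out split (for imaging data: held-out scans) never seen
during training.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from ._seeds import spawn_seeds
from .betadiv import (
    VERDICT_NOT_REPRESENTATIVE,
    BetaShape,
    DRCReport,
    drc as evaluate_drc,
)
from .exceptions import ImproperDistributionError, InvalidInputError
from .patching import PatchSet, sample_patches

__all__ = [
    "DomainSample",
    "DomainClassifierResult",
    "SeparabilityFit",
    "DomainDRCResult",
    "DataRepresentativeness",
    "proxy_a_distance",
    "train_domain_classifier",
    "pool_probabilities",
    "fit_separability",
    "drc_from_domains",
    "stability_sweep",
    "gaussian_domains",
    "domain_sample_from_patchsets",
]

DOMAIN_T = 0
DOMAIN_U = 1

# Sanity window for fitted beta shapes.  Above the ceiling the MLE has
# effectively diverged; below the floor essentially all probability mass
# sits at the endpoints (a symmetric beta with shape 0.2 puts about half
# its mass within 1e-3 of 0 or 1), the continuous-density description
# has broken down and the fit is treated as improper — the
# completely-separable failure mode.
MIN_PROPER_SHAPE = 0.2
MAX_PROPER_SHAPE = 1e6


@dataclass
class DomainSample:
    """A feature matrix with per-row domain labels (T=0, U=1).

    ``scan_id`` records provenance so that scan-level train/test splits
    can be enforced; ``coords`` optionally carries patch-centre
    positions.
    """

    features: np.ndarray
    domain: np.ndarray
    scan_id: np.ndarray | None = None
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.domain = np.asarray(self.domain)
        if self.features.ndim != 2:
            raise InvalidInputError(
                f"features must be 2-D, got shape {self.features.shape}"
            )
        if len(self.domain) != len(self.features):
            raise InvalidInputError("domain labels must match feature rows")
        if not np.all(np.isfinite(self.features)):
            raise InvalidInputError("features contain missing/non-finite values")
        if not np.all(np.isin(self.domain, (DOMAIN_T, DOMAIN_U))):
            raise InvalidInputError("domain labels must be 0 (T) or 1 (U)")
        if self.scan_id is None:
            self.scan_id = np.array(["" for _ in range(len(self.features))])
        else:
            self.scan_id = np.asarray(self.scan_id)
            if len(self.scan_id) != len(self.features):
                raise InvalidInputError("scan_id must match feature rows")

    def __len__(self) -> int:
        return len(self.features)

    @staticmethod
    def concatenate(samples: "list[DomainSample]") -> "DomainSample":
        return DomainSample(
            features=np.vstack([s.features for s in samples]),
            domain=np.concatenate([s.domain for s in samples]),
            scan_id=np.concatenate([s.scan_id for s in samples]),
        )


@dataclass
class DomainClassifierResult:
    """Held-out evaluation of a fitted domain classifier."""

    cv_error: float
    test_probabilities: np.ndarray  # pooled (p, 1-p) pairs
    c_selected: float
    n_folds: int
    n_ties: int = 0


@dataclass
class SeparabilityFit:
    """Beta distribution fitted to pooled domain-classification
    probabilities, with a properness flag.

    ``proper`` is False when the fit failed, diverged, or the fitted
    shapes fall outside the sanity window — the situation arising when
    the two domains are completely separable.
    """

    shape: BetaShape | None
    n_probabilities: int
    proper: bool
    clip_applied: bool
    method: str | None = None  # "mle" or "moments"
    reason: str | None = None  # set when proper is False


@dataclass
class DomainDRCResult:
    """End-to-end output: criterion report plus classifier diagnostics."""

    report: DRCReport
    classifier: DomainClassifierResult
    fit: SeparabilityFit
    proxy_a_distance: float


def proxy_a_distance(cv_error: float) -> float:
    """Proxy A-distance ``2 (1 - 2 e)`` for a domain-classifier error.

    An error of 0 (perfectly separable domains) maps to 2; an error of
    0.5 (indistinguishable domains) maps to 0.  Errors above 0.5, which
    occur by chance, are clamped so the result stays in [0, 2].
    """
    cv_error = float(cv_error)
    if not (0.0 <= cv_error <= 1.0):
        raise InvalidInputError(f"cv_error must lie in [0, 1], got {cv_error}")
    return max(2.0 * (1.0 - 2.0 * cv_error), 0.0)


def train_domain_classifier(
    train: DomainSample,
    folds: int = 5,
    seed: int = 0,
    Cs=None,
    max_iter: int = 500,
) -> LogisticRegressionCV:
    """Fit the L2 logistic domain discriminator on a build set.

    Regularisation strength is selected by stratified ``folds``-fold
    cross-validation under log loss (the proper score for the
    probability outputs the pipeline consumes).  Deterministic given
    ``seed``.
    """
    counts = np.bincount(train.domain, minlength=2)
    if counts[DOMAIN_T] == 0 or counts[DOMAIN_U] == 0:
        raise InvalidInputError(
            "training sample must contain both domains "
            f"(got {counts[DOMAIN_T]} T, {counts[DOMAIN_U]} U rows)"
        )
    if counts.min() < 2 * folds:
        raise InvalidInputError(
            f"need at least 2 instances per domain per fold "
            f"({folds} folds, smallest domain has {counts.min()} rows)"
        )
    if np.ptp(train.features, axis=0).max() == 0.0:
        warnings.warn(
            "all features have zero variance; classifier reduces to its "
            "intercept",
            stacklevel=2,
        )
    if Cs is None:
        Cs = np.logspace(-4, 4, 9)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        Cs=Cs,
        cv=cv,
        scoring="neg_log_loss",
        solver="lbfgs",
        max_iter=max_iter,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # scikit-learn emits transition-period FutureWarnings for
        # LogisticRegressionCV attributes; they do not affect results.
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(train.features, train.domain)
    return model


def evaluate_domain_classifier(
    model, test: DomainSample
) -> DomainClassifierResult:
    """Held-out error and pooled probabilities on a test sample.

    The predicted domain is the argmax probability; an exact tie at 0.5
    is broken toward domain T and counted.
    """
    if len(test) == 0:
        raise InvalidInputError("test sample is empty")
    prob_u = model.predict_proba(test.features)[:, list(model.classes_).index(DOMAIN_U)]
    predicted = np.where(prob_u > 0.5, DOMAIN_U, DOMAIN_T)  # ties -> T
    n_ties = int(np.sum(prob_u == 0.5))
    error = float(np.mean(predicted != test.domain))
    pooled = np.concatenate([prob_u, 1.0 - prob_u])
    c_sel = float(np.atleast_1d(model.C_)[0]) if hasattr(model, "C_") else math.nan
    folds = model.get_params().get("cv")
    n_folds = getattr(folds, "n_splits", folds if isinstance(folds, int) else 0)
    return DomainClassifierResult(
        cv_error=error,
        test_probabilities=pooled,
        c_selected=c_sel,
        n_folds=int(n_folds or 0),
        n_ties=n_ties,
    )


def pool_probabilities(model, test: DomainSample) -> np.ndarray:
    """Both class probabilities of every held-out instance, pooled.

    Each instance contributes the pair (p, 1-p), so the pooled multiset
    is symmetric around — and has mean exactly — 0.5.
    """
    return evaluate_domain_classifier(model, test).test_probabilities


def fit_separability(
    probabilities, clip_epsilon: float = 1e-6
) -> SeparabilityFit:
    """Maximum-likelihood beta fit on pooled probabilities.

    Values are clipped into ``[clip_epsilon, 1 - clip_epsilon]`` first;
    cross-validated logistic probabilities can reach numerical 0/1 even
    for overlapping domains.  Properness then keys on the sanity of the
    fitted shapes, not on raw extremes: a fit is improper when the
    optimiser fails, the shapes are non-finite/non-positive, or they
    fall outside ``[MIN_PROPER_SHAPE, MAX_PROPER_SHAPE]``.  When the MLE
    optimiser fails outright, a method-of-moments fit is attempted as a
    fallback and recorded as such.
    """
    x = np.asarray(probabilities, dtype=float).ravel()
    if len(x) < 10:
        raise InvalidInputError(
            f"need at least 10 probabilities to fit, got {len(x)}"
        )
    if clip_epsilon < 0:
        raise InvalidInputError(f"clip_epsilon must be >= 0, got {clip_epsilon}")
    if np.any(x < 0) or np.any(x > 1):
        raise InvalidInputError("probabilities must lie in [0, 1]")

    n = len(x)
    if np.ptp(x) == 0.0:
        return SeparabilityFit(
            shape=None,
            n_probabilities=n,
            proper=False,
            clip_applied=False,
            reason="degenerate-sample",
        )
    clip_applied = bool(np.any(x < clip_epsilon) or np.any(x > 1 - clip_epsilon))
    if clip_epsilon == 0 and (np.any(x == 0) or np.any(x == 1)):
        # Endpoint observations make the beta likelihood unbounded.
        return SeparabilityFit(
            shape=None,
            n_probabilities=n,
            proper=False,
            clip_applied=False,
            reason="unbounded-likelihood",
        )
    if clip_epsilon > 0:
        x = np.clip(x, clip_epsilon, 1.0 - clip_epsilon)

    shape, method, reason = None, None, None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, b, _, _ = beta_dist.fit(x, floc=0.0, fscale=1.0)
        method = "mle"
    except Exception:
        a, b = _moments_fit(x)
        method = "moments"
    if a is None or b is None or not (math.isfinite(a) and math.isfinite(b)):
        return SeparabilityFit(
            shape=None,
            n_probabilities=n,
            proper=False,
            clip_applied=clip_applied,
            method=method,
            reason="fit-diverged",
        )
    if not (MIN_PROPER_SHAPE <= a <= MAX_PROPER_SHAPE
            and MIN_PROPER_SHAPE <= b <= MAX_PROPER_SHAPE):
        reason = "shape-out-of-range"
        try:
            degenerate_shape = BetaShape(max(a, 1e-12), max(b, 1e-12))
        except ImproperDistributionError:
            degenerate_shape = None
        return SeparabilityFit(
            shape=degenerate_shape,
            n_probabilities=n,
            proper=False,
            clip_applied=clip_applied,
            method=method,
            reason=reason,
        )
    return SeparabilityFit(
        shape=BetaShape(float(a), float(b)),
        n_probabilities=n,
        proper=True,
        clip_applied=clip_applied,
        method=method,
    )


def _moments_fit(x: np.ndarray):
    """Method-of-moments beta shapes; (None, None) if undefined."""
    m = float(np.mean(x))
    v = float(np.var(x))
    if v <= 0 or v >= m * (1 - m):
        return None, None
    c = m * (1 - m) / v - 1.0
    return m * c, (1 - m) * c


class DataRepresentativeness(BaseEstimator):
    """Scikit-learn style estimator for the full similarity analysis.

    ``fit(X, y)`` trains the domain discriminator on a build set whose
    rows are labelled 0 (domain T, training data) or 1 (domain U,
    unseen data).  ``evaluate(X, y)`` then measures held-out error,
    proxy A-distance, the separability beta and the representativeness
    criterion on a disjoint test set, storing them as fitted attributes
    (``cv_error_``, ``proxy_a_distance_``, ``separability_``,
    ``report_``) and returning a :class:`DomainDRCResult`.

    Parameters
    ----------
    bm1 : (alpha, beta)
        Benchmark prior for similar domains (default Beta(25, 25)).
    bm2 : (alpha, beta)
        Benchmark prior for dissimilar domains (default the flat
        Beta(1, 1)).
    band : float
        Half-width of the inconclusive zone around a criterion of 1.
    folds : int
        Folds of the internal regularisation-selection CV.
    clip_epsilon : float
        Probability clipping applied before the beta fit.
    random_state : int
        Seed for all internal randomness.
    """

    def __init__(
        self,
        bm1=(25.0, 25.0),
        bm2=(1.0, 1.0),
        band: float = 0.05,
        folds: int = 5,
        Cs=None,
        max_iter: int = 500,
        clip_epsilon: float = 1e-6,
        random_state: int = 0,
    ):
        self.bm1 = bm1
        self.bm2 = bm2
        self.band = band
        self.folds = folds
        self.Cs = Cs
        self.max_iter = max_iter
        self.clip_epsilon = clip_epsilon
        self.random_state = random_state

    def fit(self, X, y):
        train = X if isinstance(X, DomainSample) else DomainSample(X, y)
        self.classifier_ = train_domain_classifier(
            train,
            folds=self.folds,
            seed=self.random_state,
            Cs=self.Cs,
            max_iter=self.max_iter,
        )
        self.n_features_in_ = train.features.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "classifier_")
        X = X.features if isinstance(X, DomainSample) else X
        return self.classifier_.predict(X)

    def predict_proba(self, X):
        check_is_fitted(self, "classifier_")
        X = X.features if isinstance(X, DomainSample) else X
        return self.classifier_.predict_proba(X)

    def evaluate(self, X, y=None) -> DomainDRCResult:
        """Score a held-out test set and derive all similarity measures."""
        check_is_fitted(self, "classifier_")
        test = X if isinstance(X, DomainSample) else DomainSample(X, y)
        clf_result = evaluate_domain_classifier(self.classifier_, test)
        fit = fit_separability(
            clf_result.test_probabilities, clip_epsilon=self.clip_epsilon
        )
        pad = proxy_a_distance(clf_result.cv_error)
        report = _report_from_fit(fit, self.bm1, self.bm2, self.band)
        self.cv_error_ = clf_result.cv_error
        self.proxy_a_distance_ = pad
        self.separability_ = fit
        self.report_ = report
        return DomainDRCResult(
            report=report, classifier=clf_result, fit=fit, proxy_a_distance=pad
        )


def _report_from_fit(fit: SeparabilityFit, bm1, bm2, band: float) -> DRCReport:
    """Criterion report for a separability fit; improper fits degrade to
    a flagged not-representative verdict instead of raising."""
    bm1 = BetaShape.coerce(bm1)
    bm2 = BetaShape.coerce(bm2)
    if not fit.proper or fit.shape is None:
        return DRCReport(
            kl_bm1=math.nan,
            kl_bm2=math.nan,
            drc=math.nan,
            verdict=VERDICT_NOT_REPRESENTATIVE,
            bm1=bm1,
            bm2=bm2,
            pi_tu=None,
            band=band,
            proper=False,
            n_probabilities=fit.n_probabilities,
        )
    report = evaluate_drc(fit.shape, bm1, bm2, band=band)
    return dataclasses.replace(report, n_probabilities=fit.n_probabilities)


def drc_from_domains(
    train: DomainSample,
    test: DomainSample,
    bm1=(25.0, 25.0),
    bm2=(1.0, 1.0),
    seed: int = 0,
    band: float = 0.05,
    folds: int = 5,
    clip_epsilon: float = 1e-6,
) -> DomainDRCResult:
    """Full pipeline: train discriminator, pool held-out probabilities,
    fit the separability beta, and evaluate criterion + proxy A-distance.

    Train and test must not share scans; if scan identifiers are present
    on both samples an overlap raises.
    """
    train_ids = set(np.unique(train.scan_id)) - {""}
    test_ids = set(np.unique(test.scan_id)) - {""}
    overlap = train_ids & test_ids
    if overlap:
        raise InvalidInputError(
            f"train and test share scan ids: {sorted(overlap)[:5]}"
        )
    est = DataRepresentativeness(
        bm1=bm1,
        bm2=bm2,
        band=band,
        folds=folds,
        clip_epsilon=clip_epsilon,
        random_state=seed,
    )
    est.fit(train, train.domain)
    return est.evaluate(test)


def domain_sample_from_patchsets(
    t_sets: list[PatchSet], u_sets: list[PatchSet]
) -> DomainSample:
    """Stack per-scan patch sets from the two domains into one sample."""
    feats, labels, ids = [], [], []
    for dom, sets in ((DOMAIN_T, t_sets), (DOMAIN_U, u_sets)):
        for ps in sets:
            feats.append(ps.patches)
            labels.append(np.full(len(ps), dom))
            tag = f"{ps.scanner_id}/{ps.subject_id}"
            ids.append(np.full(len(ps), tag, dtype=object))
    return DomainSample(
        features=np.vstack(feats),
        domain=np.concatenate(labels),
        scan_id=np.concatenate(ids),
    )


def stability_sweep(
    domain_t_scans: list[PatchSet],
    domain_u_scans: list[PatchSet],
    patch_counts,
    reps: int,
    bm1_list,
    seed: int = 0,
    n_build_scans: int = 15,
    n_test_scans: int = 5,
    bm2=(1.0, 1.0),
    band: float = 0.05,
    condition: str = "",
) -> pd.DataFrame:
    """Replicated similarity analysis over a grid of patch budgets.

    Per repetition, ``n_build_scans`` scans per domain build the domain
    classifier and ``n_test_scans`` disjoint scans per domain test it;
    from every scan ``patch_count`` patches are drawn at random.  Each
    (patch_count, rep) cell is evaluated against every benchmark prior
    in ``bm1_list`` using the single fitted separability distribution.

    Returns a tidy table with one row per (patch_count, rep, bm1).
    """
    patch_counts = [int(c) for c in np.atleast_1d(patch_counts)]
    bm1_shapes = [BetaShape.coerce(b) for b in np.atleast_2d(bm1_list)]
    need = n_build_scans + n_test_scans
    for name, scans in (("T", domain_t_scans), ("U", domain_u_scans)):
        if len(scans) < need:
            raise InvalidInputError(
                f"domain {name} has {len(scans)} scans; need "
                f"{n_build_scans} build + {n_test_scans} test"
            )
    rep_seeds = spawn_seeds(seed, reps * len(patch_counts))
    rows = []
    for ci, count in enumerate(patch_counts):
        for rep in range(reps):
            rep_seed = rep_seeds[ci * reps + rep]
            rng = np.random.default_rng(rep_seed)
            sampled = {}
            for dom_name, scans in (("T", domain_t_scans), ("U", domain_u_scans)):
                order = rng.permutation(len(scans))
                chosen = [scans[i] for i in order[:need]]
                sub_seeds = rng.integers(0, 2**31, size=need)
                sampled[dom_name] = [
                    sample_patches(ps, count, int(s))
                    for ps, s in zip(chosen, sub_seeds)
                ]
            train = domain_sample_from_patchsets(
                sampled["T"][:n_build_scans], sampled["U"][:n_build_scans]
            )
            test = domain_sample_from_patchsets(
                sampled["T"][n_build_scans:], sampled["U"][n_build_scans:]
            )
            result = drc_from_domains(
                train, test, bm1=bm1_shapes[0], bm2=bm2, seed=rep_seed, band=band
            )
            pad = result.proxy_a_distance
            for bm1 in bm1_shapes:
                report = _report_from_fit(result.fit, bm1, bm2, band)
                rows.append(
                    {
                        "condition": condition,
                        "rep": rep,
                        "n_patches": count,
                        "bm1_alpha": bm1.alpha,
                        "bm1_beta": bm1.beta,
                        "kl_bm1": report.kl_bm1,
                        "kl_bm2": report.kl_bm2,
                        "drc": report.drc,
                        "proxy_a_distance": pad,
                        "cv_error": result.classifier.cv_error,
                        "proper": report.proper,
                        "verdict": report.verdict,
                    }
                )
    return pd.DataFrame(rows)


def gaussian_domains(
    n_per_domain: int,
    delta: float,
    seed: int = 0,
    dim: int = 2,
    holdout: float = 0.5,
) -> tuple[DomainSample, DomainSample]:
    """Two unit-variance Gaussian domains separated by ``delta`` along
    the first axis, split into build and held-out halves.

    A generic feature-space test bed: domain T is N(0, I), domain U is
    N(delta * e1, I).  Used for calibration experiments where the
    ground-truth Bayes error of the discrimination problem,
    ``Phi(-delta / 2)``, is known analytically.
    """
    if n_per_domain < 4:
        raise InvalidInputError("need at least 4 instances per domain")
    rng = np.random.default_rng(seed)
    n_test = int(round(n_per_domain * holdout))
    n_train = n_per_domain - n_test
    xs, ys, split = [], [], []
    for dom, mean in ((DOMAIN_T, 0.0), (DOMAIN_U, float(delta))):
        x = rng.standard_normal((n_per_domain, dim))
        x[:, 0] += mean
        xs.append(x)
        ys.append(np.full(n_per_domain, dom))
        split.append(
            np.concatenate([np.zeros(n_train, bool), np.ones(n_test, bool)])
        )
    x = np.vstack(xs)
    y = np.concatenate(ys)
    is_test = np.concatenate(split)
    ids = np.where(is_test, "heldout", "build")
    train = DomainSample(x[~is_test], y[~is_test], scan_id=ids[~is_test])
    test = DomainSample(x[is_test], y[is_test], scan_id=ids[is_test])
    return train, test
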