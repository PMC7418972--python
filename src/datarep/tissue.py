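"""Tissue classification under dataset shift.

The downstream task whose generalisation the similarity measures are
meant to predict: classifying each patch as CSF, grey matter or white
matter from its flattened intensities.  The experiment of interest
compares, over a sweep of unseen-patch budgets,

* a classifier built on training-domain patches *plus* a budget of
  unseen-domain patches, against
* a classifier built on the unseen-domain budget alone,

both evaluated on held-out unseen scans.  When the domains match, the
extra training data helps at every budget; when they are grossly
mismatched there is a turning point where the training data actively
hurts and the unseen-only classifier wins.

The default model is a small one-hidden-layer network on raw patch
vectors — a desk-scale surrogate for the convolutional networks used on
real data.  The hidden layer matters: two acquisition protocols with
opposite contrast orderings admit no common *linear* map from intensity
to tissue, so a linear model keeps a residual error gap at large unseen
budgets no matter how much unseen data is added; the network surrogate
reproduces both the turning point and the large-budget convergence.  A
multinomial linear backend and arbitrary scikit-learn classifiers
remain available through ``backend``/``model_factory``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from ._seeds import spawn_seeds
from .exceptions import InvalidInputError
from .patching import MaskedImage, PatchSet, extract_patches, normalize_image, sample_patches
from .synthetic_mri import BACKGROUND, LabeledPhantom

__all__ = [
    "TissuePatchSet",
    "TissueClassifier",
    "extract_tissue_patches",
    "sample_tissue_patches",
    "build_tissue_classifier",
    "learning_curve_experiment",
    "paint_predictions",
    "KIND_TRAIN_PLUS_UNSEEN",
    "KIND_UNSEEN_ONLY",
]

KIND_TRAIN_PLUS_UNSEEN = "training_plus_unseen"
KIND_UNSEEN_ONLY = "unseen_only"


@dataclass
class TissuePatchSet:
    """A PatchSet with a tissue label per patch.

    The label of a patch is the phantom class of its centre pixel,
    matching the middle-pixel convention of the patch extractor.
    """

    patches: PatchSet
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.patches):
            raise InvalidInputError("labels must match patches")
        if np.any(self.labels == BACKGROUND):
            raise InvalidInputError("tissue labels must be foreground classes")

    def __len__(self) -> int:
        return len(self.patches)


def extract_tissue_patches(
    img: MaskedImage, ph: LabeledPhantom, k: int = 15, normalize: bool = True
) -> TissuePatchSet:
    """Patches of a scan labelled by the phantom class at each centre."""
    if img.shape != ph.labels.shape:
        raise InvalidInputError("image and phantom geometries differ")
    if normalize:
        img = normalize_image(img)
    ps = extract_patches(img, k=k)
    labels = ph.labels[ps.centers[:, 0], ps.centers[:, 1]]
    return TissuePatchSet(patches=ps, labels=labels)


def sample_tissue_patches(tps: TissuePatchSet, n: int, seed: int) -> TissuePatchSet:
    """Uniform subsample without replacement, labels kept aligned."""
    if len(tps) == 0:
        raise InvalidInputError("cannot sample from an empty TissuePatchSet")
    rng = np.random.default_rng(seed)
    if n >= len(tps):
        if n > len(tps):
            warnings.warn(
                f"requested {n} patches but only {len(tps)} available",
                stacklevel=2,
            )
        idx = rng.permutation(len(tps))
    else:
        idx = rng.choice(len(tps), size=n, replace=False)
    ps = tps.patches
    sub = PatchSet(
        patches=ps.patches[idx],
        centers=ps.centers[idx],
        k=ps.k,
        subject_id=ps.subject_id,
        scanner_id=ps.scanner_id,
    )
    return TissuePatchSet(patches=sub, labels=tps.labels[idx])


class TissueClassifier(BaseEstimator, ClassifierMixin):
    """Three-class patch classifier (default: small network surrogate).

    Parameters
    ----------
    backend : {"mlp", "linear"}
        "mlp" (default) fits a one-hidden-layer network of
        ``hidden_units`` units; "linear" fits a multinomial logistic
        regression with inverse regularisation ``C``.
    model_factory : callable, optional
        Returns an unfitted scikit-learn classifier; overrides
        ``backend`` entirely.
    """

    def __init__(self, backend: str = "mlp", hidden_units: int = 24,
                 alpha: float = 1e-3, C: float = 1.0, max_iter: int = 60,
                 random_state: int = 0, model_factory=None):
        self.backend = backend
        self.hidden_units = hidden_units
        self.alpha = alpha
        self.C = C
        self.max_iter = max_iter
        self.random_state = random_state
        self.model_factory = model_factory

    def _make_model(self):
        if self.model_factory is not None:
            return self.model_factory()
        if self.backend == "mlp":
            from sklearn.neural_network import MLPClassifier

            return MLPClassifier(
                hidden_layer_sizes=(self.hidden_units,),
                alpha=self.alpha,
                max_iter=self.max_iter,
                random_state=self.random_state,
            )
        if self.backend == "linear":
            return LogisticRegression(
                C=self.C,
                max_iter=max(self.max_iter, 300),
                random_state=self.random_state,
            )
        raise InvalidInputError(f"unknown backend {self.backend!r}")

    def fit(self, X, y):
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 3:
            raise InvalidInputError(
                f"need all 3 tissue classes in training data, got {classes}"
            )
        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            self.model__ = self._make_model().fit(np.asarray(X, dtype=float), y)
        self.classes_ = self.model__.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "model__")
        return self.model__.predict(np.asarray(X, dtype=float))

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def error(self, X, y):
        return 1.0 - self.score(X, y)


def build_tissue_classifier(
    tps: TissuePatchSet, model_cfg: dict | None = None, seed: int = 0
) -> TissueClassifier:
    """Fit the 3-class surrogate model on a labelled patch set."""
    cfg = dict(model_cfg or {})
    clf = TissueClassifier(random_state=seed, **cfg)
    return clf.fit(tps.patches.patches, tps.labels)


def _stack(sets: list[TissuePatchSet]) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.vstack([t.patches.patches for t in sets]),
        np.concatenate([t.labels for t in sets]),
    )


def learning_curve_experiment(
    domain_t_scans: list[TissuePatchSet],
    domain_u_scans: list[TissuePatchSet],
    unseen_budgets,
    reps: int = 3,
    seed: int = 0,
    n_build_unseen: int = 5,
    n_test_unseen: int = 3,
    train_patches_per_scan: int = 500,
    test_patches_per_scan: int = 500,
    model_cfg: dict | None = None,
    condition: str = "",
) -> pd.DataFrame:
    """Error-versus-budget curves for the two classifier kinds.

    For each repetition and unseen-patch budget (patches per build
    scan), trains one classifier on training-domain patches plus the
    unseen budget and one on the unseen budget alone, and evaluates
    both on held-out unseen scans that never contribute build patches.

    Returns a tidy table (condition, rep, n_unseen_patches,
    classifier_kind, test_error).
    """
    unseen_budgets = [int(b) for b in np.atleast_1d(unseen_budgets)]
    if any(b < 1 for b in unseen_budgets):
        raise InvalidInputError("budgets must be positive")
    if len(domain_u_scans) < n_build_unseen + n_test_unseen:
        raise InvalidInputError(
            f"domain U has {len(domain_u_scans)} scans; need "
            f"{n_build_unseen} build + {n_test_unseen} test"
        )
    rep_seeds = spawn_seeds(seed, reps)
    rows = []
    for rep in range(reps):
        rng = np.random.default_rng(rep_seeds[rep])
        order = rng.permutation(len(domain_u_scans))
        u_build = [domain_u_scans[i] for i in order[:n_build_unseen]]
        u_test = [domain_u_scans[i] for i in order[n_build_unseen:
                                                   n_build_unseen + n_test_unseen]]
        t_sets = [
            sample_tissue_patches(t, train_patches_per_scan, int(s))
            for t, s in zip(domain_t_scans,
                            rng.integers(0, 2**31, len(domain_t_scans)))
        ]
        test_sets = [
            sample_tissue_patches(t, test_patches_per_scan, int(s))
            for t, s in zip(u_test, rng.integers(0, 2**31, len(u_test)))
        ]
        x_test, y_test = _stack(test_sets)
        x_train, y_train = _stack(t_sets)
        for budget in unseen_budgets:
            u_sets = [
                sample_tissue_patches(t, budget, int(s))
                for t, s in zip(u_build, rng.integers(0, 2**31, len(u_build)))
            ]
            x_u, y_u = _stack(u_sets)
            fits = {
                KIND_TRAIN_PLUS_UNSEEN: (
                    np.vstack([x_train, x_u]),
                    np.concatenate([y_train, y_u]),
                ),
                KIND_UNSEEN_ONLY: (x_u, y_u),
            }
            for kind, (x, y) in fits.items():
                clf = TissueClassifier(
                    random_state=rep_seeds[rep], **(model_cfg or {})
                )
                clf.fit(x, y)
                rows.append(
                    {
                        "condition": condition,
                        "rep": rep,
                        "n_unseen_patches": budget,
                        "classifier_kind": kind,
                        "test_error": clf.error(x_test, y_test),
                    }
                )
    return pd.DataFrame(rows)


def paint_predictions(
    clf: TissueClassifier, img: MaskedImage, k: int = 15, normalize: bool = True
) -> np.ndarray:
    """Inspection utility: predicted class painted at each patch centre.

    Returns a label grid (background where no patch was classified).
    No accuracy claims are attached to this image; it exists to eyeball
    what the classifier does spatially.
    """
    if normalize:
        img = normalize_image(img)
    ps = extract_patches(img, k=k)
    out = np.zeros(img.shape, dtype=np.uint8)
    if len(ps):
        pred = clf.predict(ps.patches)
        out[ps.centers[:, 0], ps.centers[:, 1]] = pred
    return out
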