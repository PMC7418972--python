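"""Canned desk-scale experiments tying the modules together.

Each function realises one study condition end to end — rendering (or
drawing) the domains, running the domain-classification pipeline, and
returning tidy result tables — so that the same code path serves the
test suite, the command line and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._seeds import spawn_seeds
from .config import DEFAULT_BM1_LIST
from .patching import PatchSet, extract_patches, normalize_image
from .separability import (
    DataRepresentativeness,
    drc_from_domains,
    gaussian_domains,
    stability_sweep,
)
from .synthetic_mri import scanner_presets, simulate_cohort
from .tissue import extract_tissue_patches, learning_curve_experiment

__all__ = [
    "render_cohort_patchsets",
    "near_identical_scanner_drc",
    "gaussian_separation_drc",
    "gaussian_monotonicity_sweep",
    "separable_scanner_condition",
    "turning_point_experiment",
]


def render_cohort_patchsets(
    scanner_name: str, n_scans: int, seed: int, size: int = 256, k: int = 15
) -> list[PatchSet]:
    """Render a cohort for one scanner preset and extract all patches."""
    cfg = {c.name: c for c in scanner_presets()}[scanner_name]
    scans = simulate_cohort(cfg, n_scans, seed, size=size)
    return [extract_patches(normalize_image(s), k=k) for s in scans]


def near_identical_scanner_drc(
    seed: int,
    reps: int = 5,
    patches_per_scan: int = 500,
    bm1_list=None,
    t_scans: list[PatchSet] | None = None,
    u_scans: list[PatchSet] | None = None,
) -> pd.DataFrame:
    """Criterion sweep for two domains imaged on the *same* scanner.

    Domain T and domain U are scanner-1 cohorts of different subjects:
    the closest realisable condition to "training data fully
    representative".  Five scans per domain build the domain classifier
    and five disjoint scans test it.
    """
    s_t, s_u = spawn_seeds(seed, 2)
    if t_scans is None:
        t_scans = render_cohort_patchsets("scanner1", 10, s_t)
    if u_scans is None:
        u_scans = render_cohort_patchsets("scanner1", 10, s_u)
    return stability_sweep(
        t_scans,
        u_scans,
        [patches_per_scan],
        reps=reps,
        bm1_list=bm1_list or DEFAULT_BM1_LIST,
        seed=seed,
        n_build_scans=5,
        n_test_scans=5,
        condition="scanner1-vs-scanner1",
    )


def gaussian_separation_drc(
    seed: int,
    delta: float = 2.0,
    n_per_domain: int = 5000,
    reps: int = 5,
    bm1_list=None,
) -> pd.DataFrame:
    """Criterion sweep for two overlapping Gaussian domains.

    Domains are unit-variance 2-D Gaussians with mean separation
    ``delta``; the domain classifier is trained on half the sample and
    both class probabilities of the held-out half are pooled.
    """
    bm1_list = bm1_list or DEFAULT_BM1_LIST
    rows = []
    for rep, rep_seed in enumerate(spawn_seeds(seed, reps)):
        train, test = gaussian_domains(n_per_domain, delta, seed=rep_seed)
        est = DataRepresentativeness(random_state=rep_seed)
        est.fit(train, train.domain)
        result = est.evaluate(test)
        for bm1 in bm1_list:
            from .separability import _report_from_fit

            report = _report_from_fit(result.fit, bm1, (1.0, 1.0), 0.05)
            rows.append(
                {
                    "rep": rep,
                    "delta": delta,
                    "bm1_alpha": bm1[0],
                    "bm1_beta": bm1[1],
                    "drc": report.drc,
                    "verdict": report.verdict,
                    "proper": report.proper,
                    "cv_error": result.classifier.cv_error,
                    "proxy_a_distance": result.proxy_a_distance,
                }
            )
    return pd.DataFrame(rows)


def gaussian_monotonicity_sweep(
    seed: int,
    deltas=(0.0, 0.5, 1.0, 2.0, 4.0),
    reps: int = 5,
    n_per_domain: int = 2000,
    bm1=(25.0, 25.0),
) -> pd.DataFrame:
    """Proxy A-distance and criterion across a mean-separation ladder."""
    rows = []
    for delta in deltas:
        for rep, rep_seed in enumerate(spawn_seeds(seed + int(delta * 1000), reps)):
            train, test = gaussian_domains(n_per_domain, delta, seed=rep_seed)
            result = drc_from_domains(train, test, bm1=bm1, seed=rep_seed)
            rows.append(
                {
                    "delta": delta,
                    "rep": rep,
                    "cv_error": result.classifier.cv_error,
                    "proxy_a_distance": result.proxy_a_distance,
                    "drc": result.report.drc,
                    "proper": result.fit.proper,
                }
            )
    return pd.DataFrame(rows)


def separable_scanner_condition(
    seed: int,
    reps: int = 2,
    patches_per_scan: int = 500,
    t_scans: list[PatchSet] | None = None,
    u_scans: list[PatchSet] | None = None,
) -> pd.DataFrame:
    """The completely-separable condition: scanner 1 vs the 1.5 T
    long-TR preset (inverted contrast)."""
    s_t, s_u = spawn_seeds(seed + 1, 2)
    if t_scans is None:
        t_scans = render_cohort_patchsets("scanner1", 10, s_t)
    if u_scans is None:
        u_scans = render_cohort_patchsets("scanner7", 10, s_u)
    return stability_sweep(
        t_scans,
        u_scans,
        [patches_per_scan],
        reps=reps,
        bm1_list=[(25.0, 25.0)],
        seed=seed,
        n_build_scans=5,
        n_test_scans=5,
        condition="scanner1-vs-scanner7",
    )


def turning_point_experiment(
    seed: int,
    budgets=(50, 200, 1000),
    reps: int = 3,
    size: int = 256,
) -> pd.DataFrame:
    """Learning curves for a matched and a grossly mismatched condition.

    Matched: training and unseen data both from scanner 1 (different
    subjects).  Mismatched: training data from scanner 1, unseen data
    from the contrast-inverted long-TR preset (scanner 6).
    """
    presets = {c.name: c for c in scanner_presets()}
    s_t, s_match, s_mis = spawn_seeds(seed + 2, 3)

    def tissue_cohort(name, cohort_seed, n):
        from .synthetic_mri import generate_phantom, simulate_scan

        sets = []
        for s in spawn_seeds(cohort_seed, n):
            ph = generate_phantom(s, size=size)
            img = simulate_scan(ph, presets[name], s + 17)
            sets.append(extract_tissue_patches(img, ph, k=15))
        return sets

    t_scans = tissue_cohort("scanner1", s_t, 5)
    tables = []
    for condition, scanner, cohort_seed in (
        ("matched", "scanner1", s_match),
        ("mismatched", "scanner6", s_mis),
    ):
        u_scans = tissue_cohort(scanner, cohort_seed, 8)
        tables.append(
            learning_curve_experiment(
                t_scans,
                u_scans,
                list(budgets),
                reps=reps,
                seed=seed,
                n_build_unseen=5,
                n_test_unseen=3,
                condition=condition,
            )
        )
    return pd.concat(tables, ignore_index=True)
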