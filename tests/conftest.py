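"""Shared fixtures: synthetic scanner cohorts rendered once per session."""

import numpy as np
import pytest

from datarep.patching import extract_patches, normalize_image
from datarep.synthetic_mri import generate_phantom, scanner_presets, simulate_scan
from datarep.tissue import extract_tissue_patches
from datarep._seeds import spawn_seeds

PRESETS = {cfg.name: cfg for cfg in scanner_presets()}


def render_patchsets(scanner: str, seed: int, n_scans: int = 10, size: int = 256,
                     k: int = 15):
    """Cohort of fully extracted patch sets for one scanner preset."""
    cfg = PRESETS[scanner]
    sets = []
    for s in spawn_seeds(seed, n_scans):
        ph = generate_phantom(s, size=size)
        img = simulate_scan(ph, cfg, s + 13)
        sets.append(extract_patches(normalize_image(img), k=k))
    return sets


def render_tissue_sets(scanner: str, seed: int, n_scans: int, size: int = 256,
                       k: int = 15):
    cfg = PRESETS[scanner]
    sets = []
    for s in spawn_seeds(seed, n_scans):
        ph = generate_phantom(s, size=size)
        img = simulate_scan(ph, cfg, s + 13)
        sets.append(extract_tissue_patches(img, ph, k=k))
    return sets


@pytest.fixture(scope="session")
def scanner1_cohort_a():
    """Domain T: ten scanner-1 scans (subjects drawn from seed pool A)."""
    return render_patchsets("scanner1", seed=101)


@pytest.fixture(scope="session")
def scanner1_cohort_b():
    """Domain U for the near-identical condition: ten scanner-1 scans of
    *different* subjects (seed pool B)."""
    return render_patchsets("scanner1", seed=202)


@pytest.fixture(scope="session")
def scanner7_cohort():
    """Domain U for the completely-separable condition (1.5 T long-TR)."""
    return render_patchsets("scanner7", seed=303)
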