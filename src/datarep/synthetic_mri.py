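"""Synthetic multi-scanner T1-weighted MRI test bed.

Real multi-scanner MRI studies vary acquisition parameters (field
strength B0, repetition time TR, echo time TE, flip angle) and thereby
tissue contrast.  This module emulates that situation end to end with
no downloads: procedural three-tissue brain phantoms (CSF, grey matter,
white matter) are rendered through a closed-form spoiled gradient echo
(SPGR) steady-state signal model

    S = PD * sin(a) * (1 - E1) / (1 - cos(a) * E1) * exp(-TE / T2*),
    E1 = exp(-TR / T1),

with per-tissue relaxation times taken from standard literature ranges
per field strength, plus additive Gaussian noise.  Only the *contrast
ordering* across tissues matters to the similarity method; the module
makes no claim of pulse-sequence fidelity (no partial volume, no bias
field, no Rician noise floor).

``scanner_presets`` ships seven acquisition settings ordered by
decreasing rendered similarity to the first: a graded TR sweep at 3.0 T
(presets 1-5), a long-TR / long-TE 3.0 T protocol with inverted
contrast (preset 6) and a 1.5 T protocol (preset 7).  Comparing preset
1 against each of the others reproduces, at desk scale, a ladder of
conditions from near-identical domains to completely separable ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError
from .patching import MaskedImage

__all__ = [
    "ScannerConfig",
    "TissueEntry",
    "TissueProperties",
    "DEFAULT_TISSUES",
    "LabeledPhantom",
    "BACKGROUND",
    "CSF",
    "GM",
    "WM",
    "TISSUE_NAMES",
    "generate_phantom",
    "spgr_signal",
    "simulate_scan",
    "simulate_cohort",
    "scanner_presets",
]

BACKGROUND, CSF, GM, WM = 0, 1, 2, 3
TISSUE_NAMES = {CSF: "csf", GM: "gm", WM: "wm"}


@dataclass(frozen=True)
class ScannerConfig:
    """Acquisition parameters driving the synthetic signal model.

    Times are in milliseconds, the field strength in Tesla, the flip
    angle in degrees.  ``noise_sigma`` is the additive-noise standard
    deviation as a fraction of the maximum tissue signal.
    """

    name: str
    b0: float = 3.0
    tr: float = 10.0
    te: float = 4.0
    flip_deg: float = 12.0
    sequence: str = "spgr"
    noise_sigma: float = 0.02

    def __post_init__(self) -> None:
        if self.b0 <= 0 or self.tr <= 0 or self.te <= 0:
            raise InvalidInputError(
                f"{self.name}: b0, tr, te must all be positive"
            )
        if self.te >= self.tr:
            raise InvalidInputError(
                f"{self.name}: echo time {self.te} must be below "
                f"repetition time {self.tr}"
            )
        if not (0.0 < self.flip_deg <= 180.0):
            raise InvalidInputError(
                f"{self.name}: flip angle must be in (0, 180], got {self.flip_deg}"
            )
        if self.noise_sigma < 0:
            raise InvalidInputError(f"{self.name}: noise_sigma must be >= 0")


@dataclass(frozen=True)
class TissueEntry:
    """Relaxation/density triple for one tissue at one field strength."""

    t1: float  # ms
    t2star: float  # ms
    proton_density: float  # relative, in [0, 1]

    def __post_init__(self) -> None:
        if not (self.t1 > self.t2star > 0):
            raise InvalidInputError(
                f"require t1 > t2star > 0, got t1={self.t1}, t2star={self.t2star}"
            )
        if not (0 < self.proton_density <= 1):
            raise InvalidInputError("proton_density must be in (0, 1]")


# Literature-range tissue parameters per field strength (editable).
DEFAULT_TISSUES: dict[float, dict[int, TissueEntry]] = {
    3.0: {
        CSF: TissueEntry(t1=4160.0, t2star=1500.0, proton_density=1.00),
        GM: TissueEntry(t1=1330.0, t2star=66.0, proton_density=0.86),
        WM: TissueEntry(t1=830.0, t2star=53.0, proton_density=0.77),
    },
    1.5: {
        CSF: TissueEntry(t1=4000.0, t2star=1500.0, proton_density=1.00),
        GM: TissueEntry(t1=1200.0, t2star=84.0, proton_density=0.86),
        WM: TissueEntry(t1=650.0, t2star=66.0, proton_density=0.77),
    },
}


class TissueProperties:
    """Lookup of tissue parameters for the field strength of a scanner."""

    def __init__(self, table: dict[float, dict[int, TissueEntry]] | None = None):
        self.table = table or DEFAULT_TISSUES

    def at_field(self, b0: float) -> dict[int, TissueEntry]:
        fields = sorted(self.table)
        nearest = min(fields, key=lambda f: abs(f - b0))
        return self.table[nearest]


@dataclass
class LabeledPhantom:
    """A 2-D tissue-label grid: 0 background, 1 CSF, 2 GM, 3 WM."""

    labels: np.ndarray
    mask: np.ndarray
    subject_seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.labels.shape != self.mask.shape:
            raise InvalidInputError("labels and mask shapes differ")
        if not np.array_equal(self.mask, self.labels != BACKGROUND):
            raise InvalidInputError("mask must equal labels != background")
        present = set(np.unique(self.labels))
        if not {CSF, GM, WM} <= present:
            raise InvalidInputError(
                f"all three tissue classes must be present, got {present}"
            )


def _ellipse(rr, cc, center, semi, angle):
    """Boolean inside-test of a rotated ellipse on coordinate grids."""
    dy = rr - center[0]
    dx = cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = ca * dy + sa * dx
    v = -sa * dy + ca * dx
    return (u / semi[0]) ** 2 + (v / semi[1]) ** 2 <= 1.0


def generate_phantom(seed: int, size: int = 256) -> LabeledPhantom:
    """Procedural brain-like phantom: GM ring, WM interior, CSF
    ventricles, with per-seed jitter emulating subject variability.

    Deterministic given ``seed``; every phantom contains all three
    tissue classes and a brain mask covering a plausible fraction of
    the image.
    """
    if size < 64:
        raise InvalidInputError(f"phantom size must be >= 64, got {size}")
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    center = (
        size / 2 + rng.uniform(-0.02, 0.02) * size,
        size / 2 + rng.uniform(-0.02, 0.02) * size,
    )
    a = size * rng.uniform(0.36, 0.42)  # vertical semi-axis
    b = size * rng.uniform(0.28, 0.34)  # horizontal semi-axis
    tilt = rng.uniform(-0.15, 0.15)

    brain = _ellipse(rr, cc, center, (a, b), tilt)
    wm_scale = rng.uniform(0.68, 0.76)
    wm_center = (
        center[0] + rng.uniform(-0.01, 0.01) * size,
        center[1] + rng.uniform(-0.01, 0.01) * size,
    )
    wm = _ellipse(rr, cc, wm_center, (a * wm_scale, b * wm_scale), tilt)

    labels = np.zeros((size, size), dtype=np.uint8)
    labels[brain] = GM
    labels[wm] = WM

    # Lateral-ventricle-like CSF blobs, mirrored about the midline.  CSF
    # structures are kept narrow relative to the default 15-px patch so
    # that patches are tissue mixtures rather than pure CSF.
    vent_a = max(a * rng.uniform(0.10, 0.13), 3.0)
    vent_b = max(b * rng.uniform(0.035, 0.05), 1.6)
    offset_r = rng.uniform(-0.04, 0.00) * size
    offset_c = rng.uniform(0.04, 0.06) * size
    vent_tilt = rng.uniform(0.3, 0.6)
    for sign in (-1.0, 1.0):
        vent = _ellipse(
            rr,
            cc,
            (center[0] + offset_r, center[1] + sign * offset_c),
            (vent_a, vent_b),
            sign * vent_tilt,
        )
        labels[vent & wm] = CSF
    # Thin CSF rim between brain edge and cortex (subarachnoid space).
    rim_scale = min(rng.uniform(0.965, 0.980), 1.0 - 1.5 / min(a, b))
    inner = _ellipse(rr, cc, center, (a * rim_scale, b * rim_scale), tilt)
    labels[brain & ~inner] = CSF

    mask = labels != BACKGROUND
    return LabeledPhantom(labels=labels, mask=mask, subject_seed=int(seed))


def spgr_signal(cfg: ScannerConfig, tissue: TissueEntry) -> float:
    """Steady-state spoiled gradient echo signal for one tissue."""
    alpha = math.radians(cfg.flip_deg)
    e1 = math.exp(-cfg.tr / tissue.t1)
    s = (
        tissue.proton_density
        * math.sin(alpha)
        * (1.0 - e1)
        / (1.0 - math.cos(alpha) * e1)
        * math.exp(-cfg.te / tissue.t2star)
    )
    return max(s, 0.0)


def simulate_scan(
    ph: LabeledPhantom,
    cfg: ScannerConfig,
    seed: int,
    tissues: TissueProperties | None = None,
) -> MaskedImage:
    """Render a phantom under an acquisition setting.

    Each foreground pixel takes the SPGR signal of its tissue class
    plus zero-mean Gaussian noise of scale ``noise_sigma`` times the
    maximum tissue signal; background stays exactly 0.  Deterministic
    given ``seed``.
    """
    tissues = tissues or TissueProperties()
    table = tissues.at_field(cfg.b0)
    signal = {t: spgr_signal(cfg, entry) for t, entry in table.items()}
    lut = np.zeros(4, dtype=float)
    for t, s in signal.items():
        lut[t] = s
    pixels = lut[ph.labels]
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, cfg.noise_sigma * max(signal.values()), ph.labels.shape)
        pixels = pixels + noise
    pixels[~ph.mask] = 0.0
    return MaskedImage(
        pixels=pixels,
        mask=ph.mask.astype(np.uint8),
        subject_id=f"subj{ph.subject_seed}",
        scanner_id=cfg.name,
    )


def scanner_presets() -> list[ScannerConfig]:
    """Seven acquisition settings ordered by decreasing similarity to
    the first.

    Presets 1-5 form a TR sweep around an optimised 3.0 T T1-weighted
    SPGR protocol; preset 6 is a long-TR/long-TE 3.0 T protocol whose
    contrast ordering is inverted relative to preset 1; preset 7 is a
    1.5 T protocol.  The numeric values are an emulation chosen for
    their rendered contrast ladder, not a reproduction of any
    particular scanner.
    """
    return [
        ScannerConfig(name="scanner1", b0=3.0, tr=10.0, te=4.0, flip_deg=12.0),
        ScannerConfig(name="scanner2", b0=3.0, tr=14.0, te=4.0, flip_deg=12.0),
        ScannerConfig(name="scanner3", b0=3.0, tr=20.0, te=4.0, flip_deg=12.0),
        ScannerConfig(name="scanner4", b0=3.0, tr=40.0, te=4.0, flip_deg=12.0),
        ScannerConfig(name="scanner5", b0=3.0, tr=120.0, te=4.0, flip_deg=12.0),
        ScannerConfig(
            name="scanner6", b0=3.0, tr=3000.0, te=120.0, flip_deg=90.0,
            sequence="long-tr",
        ),
        ScannerConfig(
            name="scanner7", b0=1.5, tr=3500.0, te=250.0, flip_deg=90.0,
            sequence="long-tr",
        ),
    ]


def simulate_cohort(
    cfg: ScannerConfig,
    n_subjects: int,
    seed: int,
    size: int = 256,
    subject_seeds=None,
    tissues: TissueProperties | None = None,
) -> list[MaskedImage]:
    """Render ``n_subjects`` phantoms under one acquisition setting.

    ``subject_seeds`` may pin the anatomy (e.g. to image the same
    subjects on two scanners); by default subjects are derived from
    ``seed``.
    """
    from ._seeds import spawn_seeds

    if subject_seeds is None:
        subject_seeds = spawn_seeds(seed, n_subjects)
    noise_seeds = spawn_seeds(seed + 1, n_subjects)
    scans = []
    for s_seed, n_seed in zip(subject_seeds, noise_seeds):
        ph = generate_phantom(s_seed, size=size)
        scans.append(simulate_scan(ph, cfg, n_seed, tissues=tissues))
    return scans
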