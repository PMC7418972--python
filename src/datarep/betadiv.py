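"""Kullback-Leibler divergence between beta distributions and the
data representativeness criterion (DRC).

The similarity of two data sets is summarised by a beta distribution
``pi_tu`` fitted to the class probabilities of a domain classifier.  The
DRC compares that distribution against two fixed benchmark priors:

* ``bm1`` — a concentrated symmetric beta (e.g. Beta(25, 25)) standing
  for the probability profile of two *similar* domains;
* ``bm2`` — the flat Beta(1, 1), the worst-case profile of two
  *dissimilar* domains.

The criterion is the ratio of the information lost when each benchmark
is used to approximate the separability distribution::

    DRC = KL(pi_tu || bm1) / KL(pi_tu || bm2)

A ratio below 1 means the separability profile looks more like the
similar-domains benchmark than like the dissimilar one, i.e. the
training data can be considered representative of the unseen data.
All divergences are reported in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import betaln, digamma
from scipy.stats import beta as beta_dist

from .exceptions import (
    DegenerateRatioError,
    ImproperDistributionError,
    NumericIntegrationError,
)

__all__ = [
    "BetaShape",
    "DRCReport",
    "VERDICT_REPRESENTATIVE",
    "VERDICT_NOT_REPRESENTATIVE",
    "VERDICT_INCONCLUSIVE",
    "kl_beta",
    "kl_beta_numeric",
    "drc",
]

VERDICT_REPRESENTATIVE = "representative"
VERDICT_NOT_REPRESENTATIVE = "not_representative"
VERDICT_INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class BetaShape:
    """Shape pair (alpha, beta) of a beta distribution on (0, 1).

    Both shapes must be finite and strictly positive; anything else
    describes an improper distribution and is rejected at construction.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            value = getattr(self, name)
            if not isinstance(value, (int, float, np.integer, np.floating)):
                raise ImproperDistributionError(
                    f"shape parameter {name!r} must be a real number, got {value!r}"
                )
            value = float(value)
            if not math.isfinite(value) or value <= 0.0:
                raise ImproperDistributionError(
                    f"improper distribution: shape parameter {name!r} = {value} "
                    "(must be finite and > 0)"
                )
            object.__setattr__(self, name, value)

    def as_tuple(self) -> tuple[float, float]:
        return (self.alpha, self.beta)

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def pdf(self, theta):
        return beta_dist.pdf(theta, self.alpha, self.beta)

    def logpdf(self, theta):
        return beta_dist.logpdf(theta, self.alpha, self.beta)

    @classmethod
    def coerce(cls, value) -> "BetaShape":
        """Accept a BetaShape or an (alpha, beta) pair."""
        if isinstance(value, cls):
            return value
        try:
            a, b = value
        except (TypeError, ValueError) as exc:
            raise ImproperDistributionError(
                f"cannot interpret {value!r} as a beta shape pair"
            ) from exc
        return cls(float(a), float(b))


@dataclass(frozen=True)
class DRCReport:
    """Outcome of one criterion evaluation.

    ``kl_bm1`` and ``kl_bm2`` are the numerator and denominator
    divergences (nats); ``drc`` their ratio; ``verdict`` the three-way
    decision against the band around 1.
    """

    kl_bm1: float
    kl_bm2: float
    drc: float
    verdict: str
    bm1: BetaShape
    bm2: BetaShape
    pi_tu: BetaShape | None
    band: float = 0.05
    proper: bool = True
    n_probabilities: int | None = None

    def to_dict(self) -> dict:
        return {
            "kl_bm1": self.kl_bm1,
            "kl_bm2": self.kl_bm2,
            "drc": self.drc,
            "verdict": self.verdict,
            "bm1": None if self.bm1 is None else self.bm1.as_tuple(),
            "bm2": None if self.bm2 is None else self.bm2.as_tuple(),
            "pi_tu": None if self.pi_tu is None else self.pi_tu.as_tuple(),
            "band": self.band,
            "proper": self.proper,
            "n_probabilities": self.n_probabilities,
        }


def kl_beta(p, q) -> float:
    """Closed-form KL(p || q) in nats between two beta distributions.

    Uses the standard expression in log-beta and digamma functions::

        KL = ln B(aq, bq) - ln B(ap, bp)
             + (ap - aq) psi(ap) + (bp - bq) psi(bp)
             + (aq - ap + bq - bp) psi(ap + bp)

    Always nonnegative; zero exactly when the shapes coincide.
    """
    p = BetaShape.coerce(p)
    q = BetaShape.coerce(q)
    ap, bp = p.alpha, p.beta
    aq, bq = q.alpha, q.beta
    value = (
        betaln(aq, bq)
        - betaln(ap, bp)
        + (ap - aq) * digamma(ap)
        + (bp - bq) * digamma(bp)
        + (aq - ap + bq - bp) * digamma(ap + bp)
    )
    # Guard against tiny negative round-off for nearly equal shapes.
    return max(float(value), 0.0)


def kl_beta_numeric(p, q, tolerance: float = 1e-8) -> float:
    """KL(p || q) by direct quadrature of the defining integral.

    Serves as an independent check of :func:`kl_beta`.  The integrand
    ``p(t) * log(p(t)/q(t))`` diverges (integrably) at an endpoint
    whenever a shape of ``p`` is below 1, so each half of (0, 1) is
    handled by double-exponential (tanh-sinh) quadrature, which is
    designed for integrable endpoint singularities; the right half is
    integrated in the reflected variable ``u = 1 - t`` with
    log1p-based log-densities so that boundary-layer mass near 1 is
    not lost to floating-point rounding.  ``tolerance`` is enforced
    absolutely for order-unity divergences and relatively for large
    ones.
    """
    p = BetaShape.coerce(p)
    q = BetaShape.coerce(q)
    if not (tolerance > 0):
        raise NumericIntegrationError(f"tolerance must be > 0, got {tolerance}")
    ap, bp = p.alpha, p.beta
    aq, bq = q.alpha, q.beta
    lbp = betaln(ap, bp)
    lbq = betaln(aq, bq)

    def make_integrand(reflected: bool):
        def f(t):
            with np.errstate(all="ignore"):
                if reflected:  # t is distance from 1
                    lx, l1x = np.log1p(-t), np.log(t)
                else:
                    lx, l1x = np.log(t), np.log1p(-t)
                lp = (ap - 1) * lx + (bp - 1) * l1x - lbp
                lq = (aq - 1) * lx + (bq - 1) * l1x - lbq
                out = np.exp(lp) * (lp - lq)
            return np.nan_to_num(out, nan=0.0)

        return f

    split = p.mean
    total = 0.0
    err = 0.0
    ok = True
    for reflected, hi in ((False, split), (True, 1.0 - split)):
        res = integrate.tanhsinh(
            make_integrand(reflected), 0.0, hi,
            atol=tolerance / 8, rtol=tolerance / 8, maxlevel=14,
        )
        total += float(res.integral)
        err += abs(float(res.error))
        ok = ok and bool(res.success)
    if not ok or not math.isfinite(total) or err > max(
        tolerance, tolerance * abs(total)
    ):
        raise NumericIntegrationError(
            f"quadrature did not converge: value={total}, error={err}, "
            f"tolerance={tolerance}"
        )
    return max(total, 0.0)


def drc(pi_tu, bm1, bm2=(1.0, 1.0), band: float = 0.05) -> DRCReport:
    """Evaluate the representativeness criterion for a fitted separability
    distribution against a pair of benchmark priors.

    Parameters
    ----------
    pi_tu : BetaShape or (alpha, beta)
        Separability distribution fitted to pooled domain-classifier
        probabilities.
    bm1, bm2 : BetaShape or (alpha, beta)
        Benchmark priors for similar and dissimilar domains.  ``bm2``
        defaults to the flat Beta(1, 1).
    band : float
        Half-width of the inconclusive zone around a ratio of 1.

    Returns
    -------
    DRCReport

    Raises
    ------
    DegenerateRatioError
        If ``pi_tu`` equals ``bm2`` exactly, making the ratio 0/0-like
        undefined; this indicates a configuration error.
    """
    pi_tu = BetaShape.coerce(pi_tu)
    bm1 = BetaShape.coerce(bm1)
    bm2 = BetaShape.coerce(bm2)
    if band < 0:
        raise NumericIntegrationError(f"band must be >= 0, got {band}")

    kl2 = kl_beta(pi_tu, bm2)
    if kl2 == 0.0:
        raise DegenerateRatioError(
            "separability distribution coincides with benchmark prior 2 "
            f"({bm2.as_tuple()}); the criterion ratio is undefined"
        )
    kl1 = kl_beta(pi_tu, bm1)
    ratio = kl1 / kl2
    verdict = classify_ratio(ratio, band)
    return DRCReport(
        kl_bm1=kl1,
        kl_bm2=kl2,
        drc=ratio,
        verdict=verdict,
        bm1=bm1,
        bm2=bm2,
        pi_tu=pi_tu,
        band=band,
    )


def classify_ratio(ratio: float, band: float) -> str:
    """Three-way verdict for a criterion ratio against the band around 1."""
    if ratio < 1.0 - band:
        return VERDICT_REPRESENTATIVE
    if ratio > 1.0 + band:
        return VERDICT_NOT_REPRESENTATIVE
    return VERDICT_INCONCLUSIVE
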