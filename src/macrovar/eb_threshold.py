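"""Empirical Bayes posterior-median thresholding with a spike-and-slab prior.

The scalar model is ``z ~ Normal(theta, s^2)`` with prior
``theta ~ (1 - w) * delta_0 + w * Laplace(scale 1/a)`` (slab density
``(a/2) exp(-a|theta|)`` on the standardised scale).  The posterior median of
``theta`` given ``z`` is a genuine thresholding rule: it is exactly zero for
``|z| <= t(w, a) * s`` and shrinks large ``|z|`` by at most ``a`` noise units.
All quantities are computed from the closed-form normal/Laplace convolution,
in logs for stability.

Conventions
-----------
``w`` is the prior probability that a coefficient is *nonzero* (the slab
weight).  The sparsity tuning parameter ``lam`` used elsewhere in this
package is the prior point mass at zero, ``lam = 1 - w``: larger ``lam``
means a sparser solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, log_ndtr, ndtri

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
_WEIGHT_EPS = 1e-12


@dataclass
class EbConfig:
    """Hyperparameters of the spike-and-slab thresholding rule.

    Parameters
    ----------
    prior_zero_weight : float
        Prior point mass at zero, in (0, 1).  The slab weight is
        ``1 - prior_zero_weight``.
    laplace_scale_a : float
        Rate ``a`` of the Laplace slab (density ``(a/2) exp(-a|theta|)`` on
        the standardised scale); larger ``a`` means a lighter-tailed slab.
    noise_scale : float or "estimate"
        Standard deviation of the observation noise, or ``"estimate"`` to
        resolve it from the data with :func:`estimate_noise_scale`.
    """

    prior_zero_weight: float = 0.85
    laplace_scale_a: float = 0.5
    noise_scale: float | str = "estimate"

    def __post_init__(self) -> None:
        if not 0.0 < self.prior_zero_weight < 1.0:
            raise ValueError("prior_zero_weight must lie strictly in (0, 1)")
        if self.laplace_scale_a <= 0:
            raise ValueError("laplace_scale_a must be positive")
        if self.noise_scale != "estimate" and not (
            np.isfinite(self.noise_scale) and self.noise_scale > 0
        ):
            raise ValueError("noise_scale must be positive or 'estimate'")


def _log_slab_marginal(x: np.ndarray, a: float) -> np.ndarray:
    """log density of z when theta is drawn from the Laplace slab (x >= 0)."""
    left = -a * x + log_ndtr(x - a)
    right = a * x + log_ndtr(-(x + a))
    return np.log(a / 2.0) + a * a / 2.0 + np.logaddexp(left, right)


def _log_norm_pdf(x: np.ndarray) -> np.ndarray:
    return -0.5 * x * x - _LOG_SQRT_2PI


def posterior_nonzero_prob(z, w: float, a: float) -> np.ndarray:
    """Posterior probability that theta != 0 given a standardised z."""
    x = np.abs(np.asarray(z, dtype=float))
    logit = (
        np.log(w) - np.log1p(-w) + _log_slab_marginal(x, a) - _log_norm_pdf(x)
    )
    return expit(logit)


def eb_posterior_median(z, config: EbConfig | None = None, **kwargs) -> np.ndarray:
    """Posterior median of theta for each entry of ``z``.

    Entries with ``|z|`` below the threshold come out exactly zero; large
    entries are shrunk toward zero by at most ``a`` noise units.  The rule is
    antisymmetric and monotone in ``z``.
    """
    if config is None:
        config = EbConfig(**kwargs)
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("eb_posterior_median requires finite input")
    s = config.noise_scale
    if s == "estimate":
        s = estimate_noise_scale(z)
    w = 1.0 - config.prior_zero_weight
    a = config.laplace_scale_a

    sign = np.sign(z)
    x = np.abs(z) / s

    log_phi1 = log_ndtr(x - a)  # log Phi(x - a)
    log_sf2 = log_ndtr(-(x + a))  # log (1 - Phi(x + a))
    post_p = posterior_nonzero_prob(x, w, a)

    # Solve Phi(x - a - m) = [Phi(x-a) + exp(2ax) * sf(x+a)] / (2 * P(theta!=0|z))
    with np.errstate(divide="ignore", over="ignore"):
        log_num = np.logaddexp(log_phi1, 2.0 * a * x + log_sf2)
        log_q = log_num - np.log(2.0 * post_p)
    q = np.exp(np.minimum(log_q, 0.0))
    m = np.where(log_q >= 0.0, -np.inf, x - a - ndtri(q))
    med = np.maximum(m, 0.0)
    return sign * med * s


def threshold_from_weight(w: float, a: float) -> float:
    """Smallest |z| (noise units) at which the posterior median is nonzero."""

    def crossing(x: float) -> float:
        # median > 0  <=>  P(theta > 0 | x) > 1/2
        log_phi1 = log_ndtr(x - a)
        log_sf2 = log_ndtr(-(x + a))
        log_pos_frac = log_phi1 - np.logaddexp(log_phi1, 2.0 * a * x + log_sf2)
        p = posterior_nonzero_prob(x, w, a)
        return p * np.exp(log_pos_frac) - 0.5

    lo, hi = 0.0, a + 2.0
    while crossing(hi) < 0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover - pathological w
            return hi
    return brentq(crossing, lo, hi, xtol=1e-12)


def weight_from_threshold(t: float, a: float) -> float:
    """Slab weight whose posterior-median threshold equals ``t`` noise units."""
    log_phi1 = log_ndtr(t - a)
    log_sf2 = log_ndtr(-(t + a))
    # fraction of slab posterior mass above zero at z = t
    c = np.exp(log_phi1 - np.logaddexp(log_phi1, 2.0 * a * t + log_sf2))
    if 2.0 * c <= 1.0:
        return 1.0 - _WEIGHT_EPS
    r = np.exp(_log_norm_pdf(np.asarray(t)) - _log_slab_marginal(np.asarray(t), a))
    w = r / (r + 2.0 * c - 1.0)
    return float(np.clip(w, _WEIGHT_EPS, 1.0 - _WEIGHT_EPS))


def universal_weight(n: int, a: float) -> float:
    """Slab weight whose threshold is the universal threshold sqrt(2 log n)."""
    return weight_from_threshold(np.sqrt(2.0 * np.log(max(n, 2))), a)


def estimate_slab_weight_mml(
    z, a: float, w_lo: float = _WEIGHT_EPS, w_hi: float = 1.0 - _WEIGHT_EPS
) -> float:
    """Marginal-maximum-likelihood slab weight, constrained to [w_lo, w_hi].

    The marginal log likelihood ``sum_j log((1-w) phi(z_j) + w g(z_j))`` is
    concave in ``w``; its derivative is monotone, so the constrained maximiser
    is found by a bracketed root search on the score.
    """
    x = np.abs(np.asarray(z, dtype=float))
    if w_lo >= w_hi:
        return w_hi
    # beta_j = g(z_j)/phi(z_j) - 1; score(w) = sum beta / (1 + w beta)
    log_ratio = np.minimum(_log_slab_marginal(x, a) - _log_norm_pdf(x), 500.0)
    beta = np.expm1(log_ratio)

    def score(w: float) -> float:
        return float(np.sum(beta / (1.0 + w * beta)))

    if score(w_lo) <= 0:
        return w_lo
    if score(w_hi) >= 0:
        return w_hi
    return float(brentq(score, w_lo, w_hi, xtol=1e-10))


def estimate_noise_scale(z) -> float:
    """Robust noise-scale estimate: MAD / 0.6745, falling back to the SD."""
    z = np.asarray(z, dtype=float)
    if z.size < 10:
        raise ValueError("need at least 10 values to estimate the noise scale")
    mad = np.median(np.abs(z - np.median(z)))
    if mad > 0:
        return float(mad / 0.6745)
    sd = float(np.std(z))
    if sd > 0:
        return sd
    raise ValueError("degenerate input: both MAD and SD are zero")
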