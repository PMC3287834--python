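import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import norm


def posterior_median_quadrature(z: float, w: float, a: float) -> float:
    """Numerical posterior median for the spike-and-slab model.

    Independent oracle: integrates the un-normalised posterior density
    (point mass at 0 plus Laplace slab convolved with the normal
    likelihood) by adaptive quadrature and inverts the CDF by root finding.
    """

    def slab(theta):
        return w * norm.pdf(z - theta) * (a / 2.0) * np.exp(-a * abs(theta))

    def integral(lo, hi):
        pts = sorted({lo, hi, *[p for p in (0.0, z) if lo < p < hi]})
        return sum(
            quad(slab, p0, p1, limit=400, epsabs=1e-13, epsrel=1e-13)[0]
            for p0, p1 in zip(pts[:-1], pts[1:])
        )

    L = abs(z) + 40.0
    atom = (1.0 - w) * norm.pdf(z)
    total = atom + integral(-L, L)
    below0 = integral(-L, 0.0) / total
    if below0 <= 0.5 <= below0 + atom / total:
        return 0.0

    def cdf(t):
        val = integral(-L, t)
        if t >= 0:
            val += atom
        return val / total

    side = (-L, -1e-13) if below0 > 0.5 else (1e-13, L)
    return brentq(lambda t: cdf(t) - 0.5, *side, xtol=1e-12, rtol=8.9e-16)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared by pipeline-level tests."""
    from dataclasses import replace

    from macrovar.synthetic_data import gaw17_like_preset, simulate_cohort

    cfg = replace(
        gaw17_like_preset(n_replicates=4, seed=11),
        n_individuals=240,
        n_common=30,
        n_genes=12,
    )
    gm, gene_map, phen = simulate_cohort(cfg)
    return cfg, gm, gene_map, phen
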