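"""Penalized orthogonal-components regression (POCRE) as a two-class LDA.

The phenotype is coded +1 (case) / -1 (control) and regressed on a centered
design matrix by sequentially building mutually orthogonal components.  Each
component's loading vector is obtained by empirical Bayes posterior-median
thresholding of the (noise-standardised) cross-covariance between the
deflated design and the current response residual, so loadings are sparse
and exact zeros propagate into the back-mapped coefficient vector beta.
Classification applies the LDA threshold c = 0 to the fitted linear score.

The sparsity tuning parameter ``lam`` in (0, 1) is the prior point mass at
zero of the spike-and-slab prior; larger values give sparser fits.  By
default the slab weight actually used for each component is estimated by
bounded marginal maximum likelihood on ``[w_universal(p), 1 - lam]``
(Johnstone-Silverman practice), so ``lam`` acts as a sparsity floor; pass
``weight_mode="fixed"`` to use ``1 - lam`` exactly.

The model/results split follows the statsmodels convention::

    model = PocreLDA(y, X, column_names=names)
    res = model.fit(lam=0.85)
    print(res.summary())
    labels = res.classify(X_new)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from . import eb_threshold as eb

DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.80, 0.901, 0.01), 2))


@dataclass
class PocreFit:
    """Raw output of the sequential component construction."""

    weights: np.ndarray  # p x K sparse unit-norm loadings (deflated scale)
    x_loadings: np.ndarray  # p x K deflation projections
    scores: np.ndarray  # n x K orthogonal components
    q: np.ndarray  # K component regression coefficients
    beta: np.ndarray  # p back-mapped coefficients
    n_components: int


def fit_pocre(
    y: np.ndarray,
    X: np.ndarray,
    lam: float,
    max_comp: int | None = None,
    tol: float = 1e-10,
    slab_scale: float = 0.5,
    weight_mode: str = "bounded_mml",
    penalty: str = "eb",
) -> PocreFit:
    """Sequential sparse orthogonal components for a centered (y, X).

    Requires ``y`` and the columns of ``X`` to be centered (raises
    otherwise); use :class:`PocreLDA` for automatic centering.  With
    ``penalty="none"`` the thresholding step is disabled (every component is
    the plain PLS1 direction) — the unpenalized limit, useful for testing.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if not 0.0 < lam < 1.0:
        raise ValueError(f"lam must lie in (0, 1), got {lam}")
    n, p = X.shape
    scale = np.abs(X).max(initial=1.0)
    if np.abs(X.mean(axis=0)).max(initial=0.0) > 1e-8 * max(scale, 1.0):
        raise ValueError("X columns must be centered")
    if abs(y.mean()) > 1e-8 * max(np.abs(y).max(initial=1.0), 1.0):
        raise ValueError("y must be centered")
    if max_comp is None:
        max_comp = min(n - 1, 30)

    Xd = X.copy()
    r = y.copy()
    w_uni = eb.universal_weight(p, slab_scale) if penalty == "eb" else None
    W, P, T, Q = [], [], [], []
    for _ in range(max_comp):
        v = Xd.T @ r
        if not np.all(np.isfinite(v)):
            raise FloatingPointError("non-finite cross-covariance")
        if np.abs(v).max(initial=0.0) <= tol:
            break
        if penalty == "none":
            gamma = v
        else:
            if v.size >= 10:
                s = eb.estimate_noise_scale(v)
            else:  # too few columns for the MAD estimate
                s = float(np.std(v))
                if s == 0.0:
                    s = float(np.abs(v).max())
            z = v / s
            w_hi = 1.0 - lam
            if weight_mode == "fixed":
                w = w_hi
            elif weight_mode == "bounded_mml":
                w = eb.estimate_slab_weight_mml(
                    z, slab_scale, w_lo=min(w_uni, w_hi), w_hi=w_hi
                )
            else:
                raise ValueError(f"unknown weight_mode {weight_mode!r}")
            gamma = eb.eb_posterior_median(
                z, prior_zero_weight=1.0 - w, laplace_scale_a=slab_scale,
                noise_scale=1.0,
            )
        ng = np.linalg.norm(gamma)
        if ng == 0.0:
            break
        wk = gamma / ng
        t = Xd @ wk
        tt = float(t @ t)
        if tt <= tol:
            break
        pk = Xd.T @ t / tt
        qk = float(t @ r) / tt
        Xd = Xd - np.outer(t, pk)
        r = r - qk * t
        W.append(wk)
        P.append(pk)
        T.append(t)
        Q.append(qk)

    K = len(W)
    if K == 0:
        return PocreFit(
            np.empty((p, 0)), np.empty((p, 0)), np.empty((n, 0)),
            np.empty(0), np.zeros(p), 0,
        )
    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    Tm = np.column_stack(T)
    Qv = np.array(Q)
    # P'W is unit upper triangular; beta = W (P'W)^{-1} q reproduces the
    # component-pathway predictions exactly: X beta = T q.
    M = Pm.T @ Wm
    beta = Wm @ solve_triangular(M, Qv, lower=False)
    return PocreFit(Wm, Pm, Tm, Qv, beta, K)


class PocreLDA:
    """Two-class LDA via POCRE on a covariate + genotype design matrix.

    Parameters
    ----------
    endog : array-like
        Binary phenotype; {0, 1} or {-1, +1} (stored as +/-1).  Both classes
        must be present.
    exog : array-like, shape (n, p)
        Design matrix; centered internally (column means stored).
    column_names : sequence of str, optional
    slab_scale : float
        Laplace rate ``a`` of the slab prior (heavy-tailed default 0.5).
    weight_mode : {"bounded_mml", "fixed"}
        How the slab weight is resolved per component (see module docstring).
    standardize : bool
        Scale each column to unit variance before fitting (default True), so
        components maximise *correlation* with the response residual and the
        thresholded cross-covariances are comparable across columns measured
        in different units (years, dosages, macrovariant scores).
        Coefficients are reported on the original column scale.
    """

    def __init__(
        self,
        endog,
        exog,
        column_names=None,
        slab_scale: float = 0.5,
        weight_mode: str = "bounded_mml",
        standardize: bool = True,
    ):
        y = np.asarray(endog, dtype=float).ravel()
        uniq = np.unique(y)
        if set(uniq) <= {0.0, 1.0}:
            y = 2.0 * y - 1.0
        elif not set(uniq) <= {-1.0, 1.0}:
            raise ValueError("endog must be coded {0,1} or {-1,+1}")
        if len(np.unique(y)) != 2:
            raise ValueError("both phenotype classes must be present")
        X = np.asarray(exog, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("exog must be 2-D with one row per individual")
        self.endog = y
        self.exog_means = X.mean(axis=0)
        Xc = X - self.exog_means
        # a column (numerically) constant in this sample is exactly zero
        # after centering; the relative test catches float-dust variation
        col_range = np.ptp(X, axis=0)
        col_absmax = np.abs(X).max(axis=0)
        Xc[:, col_range <= 1e-9 * np.maximum(col_absmax, 1e-300)] = 0.0
        if standardize:
            scales = Xc.std(axis=0)
            self.exog_scales = np.where(scales > 0, scales, 1.0)
        else:
            self.exog_scales = np.ones(X.shape[1])
        self.exog = Xc / self.exog_scales
        self.column_names = (
            list(column_names)
            if column_names is not None
            else [f"x{j}" for j in range(X.shape[1])]
        )
        if len(self.column_names) != X.shape[1]:
            raise ValueError("column_names length mismatch")
        self.slab_scale = slab_scale
        self.weight_mode = weight_mode

    @classmethod
    def from_design(cls, endog, design, **kwargs) -> "PocreLDA":
        """Build from a :class:`~macrovar.preprocess.DesignMatrix`."""
        return cls(endog, design.values, column_names=design.names, **kwargs)

    def fit(
        self,
        lam: float = 0.85,
        max_comp: int | None = None,
        tol: float = 1e-10,
        penalty: str = "eb",
    ) -> "PocreLDAResults":
        raw = fit_pocre(
            self.endog - self.endog.mean(),
            self.exog,
            lam,
            max_comp=max_comp,
            tol=tol,
            slab_scale=self.slab_scale,
            weight_mode=self.weight_mode,
            penalty=penalty,
        )
        return PocreLDAResults(self, raw, lam)

    def fit_select_lambda(
        self,
        endog_test,
        exog_test,
        grid=DEFAULT_LAMBDA_GRID,
        max_comp: int | None = None,
    ) -> "PocreLDAResults":
        """Fit one model per candidate lambda, keep the test-set minimiser.

        The test set is scored with each candidate's classifier and the
        candidate with the smallest misclassification rate wins; ties go to
        the smallest lambda.  The returned results carry the whole
        ``lambda_path`` (lambda, test error, components, support size).
        """
        grid = sorted(grid)
        if not grid:
            raise ValueError("lambda grid must be nonempty")
        y_test = np.asarray(endog_test, dtype=float).ravel()
        if set(np.unique(y_test)) <= {0.0, 1.0}:
            y_test = 2.0 * y_test - 1.0
        best = None
        path = []
        for lam in grid:
            res = self.fit(lam=lam, max_comp=max_comp)
            err = float(np.mean(res.classify(exog_test) != y_test))
            path.append((lam, err, res.n_components, int(res.nonzero_mask.sum())))
            if best is None or err < best[0]:
                best = (err, lam, res)
        _, lam, res = best
        res.lambda_path = path
        return res


class PocreLDAResults:
    """Fitted POCRE-LDA: sparse coefficients, components, and a classifier."""

    def __init__(self, model: PocreLDA, raw: PocreFit, lam: float):
        self.model = model
        self.params = raw.beta / model.exog_scales  # original column scale
        self.intercept = float(model.endog.mean())
        self.scores = raw.scores
        self.loadings = raw.weights
        self.x_loadings = raw.x_loadings
        self.component_coefficients = raw.q
        self.n_components = raw.n_components
        self.lambda_ = lam
        self.lambda_path: list | None = None

    @property
    def nonzero_mask(self) -> np.ndarray:
        """Exact-support indicator |beta_j| > 0 (EB zeros are exact)."""
        return self.params != 0.0

    def predict(self, exog) -> np.ndarray:
        """Linear LDA score for new rows (uncentered input)."""
        X = np.asarray(exog, dtype=float)
        if X.shape[1] != self.params.shape[0]:
            raise ValueError(
                f"expected {self.params.shape[0]} design columns, got {X.shape[1]}"
            )
        return (X - self.model.exog_means) @ self.params + self.intercept

    def classify(self, exog) -> np.ndarray:
        """+1 where the LDA score exceeds c = 0, else -1 (ties -> control)."""
        score = self.predict(exog)
        return np.where(score > 0.0, 1.0, -1.0)

    def summary(self, top: int = 20) -> str:
        """Plain-text summary: fit metadata and the largest nonzero effects."""
        nz = np.flatnonzero(self.nonzero_mask)
        order = nz[np.argsort(-np.abs(self.params[nz]))]
        lines = [
            "POCRE-LDA Results",
            "=" * 52,
            f"n individuals:     {self.model.exog.shape[0]}",
            f"design columns:    {self.model.exog.shape[1]}",
            f"lambda:            {self.lambda_:g}",
            f"components:        {self.n_components}",
            f"nonzero effects:   {len(nz)}",
            f"intercept:         {self.intercept:.6g}",
            "-" * 52,
            f"{'column':<30}{'beta':>14}",
        ]
        for j in order[:top]:
            lines.append(f"{self.model.column_names[j]:<30}{self.params[j]:>14.6g}")
        if len(order) > top:
            lines.append(f"... {len(order) - top} further nonzero effects")
        lines.append("=" * 52)
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        """Dump (column_id, beta) with a sidecar metadata header."""
        with open(path, "w") as fh:
            fh.write(f"# lambda={self.lambda_:g}\tK={self.n_components}\t")
            fh.write(f"intercept={self.intercept:.12g}\n")
            fh.write("column_id\tbeta\n")
            for name, b in zip(self.model.column_names, self.params):
                fh.write(f"{name}\t{b:.12g}\n")
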