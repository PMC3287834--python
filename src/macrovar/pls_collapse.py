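"""Supervised collapsing of a gene's rare variants into macrovariants.

Each gene's rare-variant matrix is reduced by univariate-response partial
least squares (PLS1 with NIPALS-style deflation): components are linear
combinations of the member variants chosen to explain the covariance between
genotype and phenotype.  Cross-validation picks the number of components per
gene; a gene whose CV prefers the intercept-only model yields no
macrovariant and contributes nothing to the association design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MacroVariant:
    """A per-gene supervised component used as a single design column."""

    gene: str
    component_index: int  # 1-based
    scores: np.ndarray  # per-individual value, mean 0 on the training data


@dataclass
class PlsGeneModel:
    """Fitted PLS1 collapse of one gene's rare variants.

    ``weights`` (k x K) apply to the deflated member matrix; ``x_loadings``
    (k x K) are the deflation projections; ``y_loadings`` (K,) regress the
    response residual on each score.  ``column_means`` reproduce the training
    centering when scoring new data.
    """

    gene: str
    member_variants: list[str]
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    n_components: int
    column_means: np.ndarray
    y_mean: float = 0.0
    cv_error_path: np.ndarray | None = None


def fit_pls1(
    y: np.ndarray,
    Xg: np.ndarray,
    n_comp: int,
    gene: str = "",
    member_variants: list[str] | None = None,
    tol: float = 1e-10,
) -> PlsGeneModel:
    """Fit PLS1 with up to ``n_comp`` components.

    Component c uses weight ``w_c`` proportional to the deflated-matrix /
    residual cross-covariance, normalised to unit length with the
    largest-magnitude entry made positive (sign convention for
    reproducibility); the matrix is deflated by the projection on the score
    and the residual by its regression on the score.  Stops early when the
    cross-covariance is numerically zero.
    """
    y = np.asarray(y, dtype=float)
    Xg = np.asarray(Xg, dtype=float)
    if Xg.ndim != 2 or Xg.shape[0] != y.shape[0]:
        raise ValueError("y and Xg must share the individual axis")
    if n_comp < 0:
        raise ValueError("n_comp must be >= 0")
    n, k = Xg.shape
    col_means = Xg.mean(axis=0)
    y_mean = float(y.mean())
    Xd = Xg - col_means
    r = y - y_mean
    scale0 = max(np.abs(Xd).max(initial=0.0) * np.abs(r).max(initial=0.0), 1.0)

    W, P, Q = [], [], []
    n_comp = min(n_comp, k, max(n - 1, 0))
    for _ in range(n_comp):
        v = Xd.T @ r
        nv = np.linalg.norm(v)
        if nv <= tol * scale0:
            break
        w = v / nv
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w = -w
        t = Xd @ w
        tt = float(t @ t)
        if tt <= tol:
            break
        p = Xd.T @ t / tt
        q = float(t @ r) / tt
        Xd = Xd - np.outer(t, p)
        r = r - q * t
        W.append(w)
        P.append(p)
        Q.append(q)

    K = len(W)
    return PlsGeneModel(
        gene=gene,
        member_variants=list(member_variants or []),
        weights=np.column_stack(W) if K else np.empty((k, 0)),
        x_loadings=np.column_stack(P) if K else np.empty((k, 0)),
        y_loadings=np.array(Q),
        n_components=K,
        column_means=col_means,
        y_mean=y_mean,
    )


def _component_scores(model: PlsGeneModel, Xg_new: np.ndarray) -> np.ndarray:
    """Scores (n x K) of new data under the stored weight/deflation sequence."""
    Xd = np.asarray(Xg_new, dtype=float) - model.column_means
    T = np.empty((Xd.shape[0], model.n_components))
    for c in range(model.n_components):
        t = Xd @ model.weights[:, c]
        T[:, c] = t
        Xd = Xd - np.outer(t, model.x_loadings[:, c])
    return T


def score_macrovariants(model: PlsGeneModel, Xg_new: np.ndarray) -> list[MacroVariant]:
    """Deterministically score a (possibly new) member matrix.

    ``Xg_new`` must hold the model's member variants in order; scoring the
    training matrix reproduces the training scores exactly.
    """
    Xg_new = np.asarray(Xg_new, dtype=float)
    if Xg_new.shape[1] != model.column_means.shape[0]:
        raise ValueError(
            f"gene {model.gene!r}: expected {model.column_means.shape[0]} member "
            f"variants, got {Xg_new.shape[1]}"
        )
    T = _component_scores(model, Xg_new)
    return [
        MacroVariant(model.gene, c + 1, T[:, c]) for c in range(model.n_components)
    ]


def predict_pls1(model: PlsGeneModel, Xg_new: np.ndarray, n_comp: int | None = None) -> np.ndarray:
    """Response prediction from the first ``n_comp`` components."""
    K = model.n_components if n_comp is None else min(n_comp, model.n_components)
    T = _component_scores(model, Xg_new)
    return model.y_mean + T[:, :K] @ model.y_loadings[:K]


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment balanced across the two phenotype classes."""
    assign = np.empty(len(y), dtype=int)
    for cls in np.unique(y > np.mean(y)):
        idx = np.where((y > np.mean(y)) == cls)[0]
        idx = rng.permutation(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return assign


def cv_select_ncomp(
    y: np.ndarray,
    Xg: np.ndarray,
    max_comp: int | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Choose the component count in {0..max_comp} by out-of-fold squared error.

    0 means the intercept-only model wins (the gene yields no macrovariant).
    Folds are a seeded random partition stratified by case/control status.
    Ties go to the smaller count.  Returns (best, mean CV error per
    candidate).
    """
    y = np.asarray(y, dtype=float)
    Xg = np.asarray(Xg, dtype=float)
    n, k = Xg.shape
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < 2 * folds:
        raise ValueError(f"n={n} too small for {folds}-fold cross-validation")
    if max_comp is None:
        max_comp = min(5, k)
    max_comp = min(max_comp, k, n - 1)
    if max_comp < 1:
        raise ValueError("max_comp must be >= 1")

    rng = np.random.default_rng(seed)
    assign = _stratified_folds(y, folds, rng)
    sse = np.zeros(max_comp + 1)
    for f in range(folds):
        test = assign == f
        train = ~test
        model = fit_pls1(y[train], Xg[train], max_comp)
        T = _component_scores(model, Xg[test])
        pred = np.full(test.sum(), model.y_mean)
        sse[0] += float(np.sum((y[test] - pred) ** 2))
        for c in range(max_comp):
            if c < model.n_components:
                pred = pred + model.y_loadings[c] * T[:, c]
            sse[c + 1] += float(np.sum((y[test] - pred) ** 2))
    cv_err = sse / n
    best = int(np.argmin(cv_err))  # argmin takes the smallest index on ties
    return best, cv_err


def build_gene_models(
    y: np.ndarray,
    dosages: np.ndarray,
    variant_ids: list[str],
    groups: dict[str, list[str]],
    max_comp: int | None = None,
    folds: int = 5,
    seed: int = 0,
) -> dict[str, PlsGeneModel]:
    """Fit a CV-sized PLS1 collapse for every gene with grouped rare variants.

    ``y`` is the collapse replicate's +/-1 phenotype.  Genes whose CV chooses
    0 components are retained in the result (with ``n_components == 0``) but
    yield no macrovariants.
    """
    col_of = {v: j for j, v in enumerate(variant_ids)}
    models: dict[str, PlsGeneModel] = {}
    for gi, gene in enumerate(sorted(groups)):
        members = groups[gene]
        Xg = dosages[:, [col_of[v] for v in members]]
        best, cv_err = cv_select_ncomp(
            y, Xg, max_comp=max_comp, folds=folds, seed=seed + gi
        )
        model = fit_pls1(y, Xg, best, gene=gene, member_variants=members)
        model.cv_error_path = cv_err
        models[gene] = model
    return models
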