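"""Representational similarity and PLS association machinery.

Subject-by-subject dissimilarity matrices link encoded parameters to
clinical and demographic variables through rank correlation of their lower
triangles.  Partial least squares finds paired latent components of a
predictor block and a response block with maximal cross-covariance;
component significance comes from row-permutation nulls (behavioral mode)
or variogram-matched spatial surrogates (transcriptomic mode), with
Benjamini–Hochberg control across components, Pearson-correlation loadings,
and bootstrap-normalized gene weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DissimilarityMatrix",
    "PLSResult",
    "dissimilarity",
    "rsa_compare",
    "regress_covariates",
    "pls_fit",
    "pls_permutation",
    "pls_loadings",
    "gene_pls",
]


@dataclass
class DissimilarityMatrix:
    values: np.ndarray
    name: str = ""
    kind: str = "numeric"  # numeric | categorical | parameter-block

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not (np.allclose(v, v.T) and np.allclose(np.diag(v), 0) and np.all(v >= 0)):
            raise ValueError("dissimilarity must be symmetric, nonnegative, "
                             "zero-diagonal")
        self.values = v

    def lower_triangle(self) -> np.ndarray:
        il = np.tril_indices(self.values.shape[0], k=-1)
        return self.values[il]


def dissimilarity(values, kind: str = "numeric", name: str = "") -> DissimilarityMatrix:
    """Pairwise subject dissimilarity.

    Numeric variables use the absolute (Euclidean, for vectors) distance;
    categorical variables are 0 on match and 1 otherwise.
    """
    if kind == "categorical":
        arr = np.asarray(values)
        if arr.ndim != 1:
            raise ValueError("categorical dissimilarity needs a 1-D variable")
        mat = (arr[:, None] != arr[None, :]).astype(float)
        return DissimilarityMatrix(mat, name=name, kind=kind)
    if kind in ("numeric", "parameter-block"):
        arr = np.asarray(values, dtype=float)
        if np.any(~np.isfinite(arr)):
            raise ValueError("missing values in dissimilarity input")
        if arr.ndim == 1:
            mat = np.abs(arr[:, None] - arr[None, :])
        else:
            diff = arr[:, None, :] - arr[None, :, :]
            mat = np.sqrt((diff**2).sum(axis=2))
        return DissimilarityMatrix(mat, name=name, kind=kind)
    raise ValueError(f"unknown dissimilarity kind {kind!r}")


def rsa_compare(
    param_dissim_draws: list[DissimilarityMatrix],
    other_draws: list[DissimilarityMatrix],
    target_dissim: DissimilarityMatrix,
) -> dict:
    """Which parameter block tracks a target dissimilarity more closely?

    Kendall τ between lower triangles is computed per draw for each block;
    an unpaired t-test compares the two sets of τ values.  Returns the τ
    samples and the test.
    """
    def taus(draws):
        tgt = target_dissim.lower_triangle()
        if np.all(tgt == tgt[0]):
            raise ValueError("constant target lower triangle: τ undefined")
        out = []
        for d in draws:
            tri = d.lower_triangle()
            if np.all(tri == tri[0]):
                raise ValueError("constant parameter lower triangle: τ undefined")
            out.append(stats.kendalltau(tri, tgt).statistic)
        return np.asarray(out)

    tau_a = taus(param_dissim_draws)
    tau_b = taus(other_draws)
    test = stats.ttest_ind(tau_a, tau_b)
    return {
        "tau_a": tau_a,
        "tau_b": tau_b,
        "t": float(test.statistic),
        "p": float(test.pvalue),
    }


def regress_covariates(
    responses: pd.DataFrame | np.ndarray, covariates: pd.DataFrame
) -> np.ndarray:
    """OLS-residualize response columns on covariates.

    Categorical covariates (site, sex) become indicator contrasts; an
    intercept is always included; collinear columns are dropped.
    """
    y = np.asarray(responses, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    design = [np.ones((y.shape[0], 1))]
    for col in covariates.columns:
        vals = covariates[col]
        if vals.dtype.kind in "OUSb" or str(vals.dtype) == "category":
            design.append(pd.get_dummies(vals, drop_first=True).to_numpy(float))
        else:
            design.append(np.asarray(vals, dtype=float)[:, None])
    x = np.concatenate(design, axis=1)
    # rank-deficient designs: project onto the leading singular subspace
    u, sv, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(sv > sv[0] * 1e-10))
    if rank < x.shape[1]:
        import warnings

        warnings.warn("collinear covariate columns dropped")
        x = u[:, :rank] * sv[:rank]
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


@dataclass
class PLSResult:
    x_scores: np.ndarray  # (n, n_comp)
    y_scores: np.ndarray
    x_weights: np.ndarray  # (p, n_comp)
    y_weights: np.ndarray  # (q, n_comp)
    singular_values: np.ndarray
    score_correlations: np.ndarray
    p_values: np.ndarray | None = None
    p_fdr: np.ndarray | None = None
    x_loadings: np.ndarray | None = None
    y_loadings: np.ndarray | None = None
    bootstrap_z: np.ndarray | None = None
    dropped_columns: list = field(default_factory=list)


def _zscore_cols(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize; returns (standardized columns, keep mask)."""
    a = np.asarray(a, dtype=float)
    sd = a.std(axis=0, ddof=0)
    keep = sd > 0
    z = (a[:, keep] - a[:, keep].mean(axis=0)) / sd[keep]
    return z, keep


def pls_fit(x: np.ndarray, y: np.ndarray, n_components: int | None = None) -> PLSResult:
    """Partial least squares by successive SVDs of the cross-covariance.

    Columns of both blocks are z-scored; each component takes the leading
    singular pair of X'Y, then X is deflated by its score.  Zero-variance
    columns are dropped (recorded in ``dropped_columns``).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] == 1 and x.shape[0] != 1:
        y = y.T
    if x.shape[0] != y.shape[0]:
        raise ValueError("X and Y must have aligned rows")
    xz, keep_x = _zscore_cols(x)
    yz, keep_y = _zscore_cols(y)
    dropped = list(np.where(~keep_x)[0]) + [("y", i) for i in np.where(~keep_y)[0]]
    n = x.shape[0]
    max_comp = min(xz.shape[1], yz.shape[1], n - 1)
    k = max_comp if n_components is None else min(n_components, max_comp)
    xd = xz.copy()
    x_scores = np.empty((n, k))
    y_scores = np.empty((n, k))
    x_weights = np.empty((xz.shape[1], k))
    y_weights = np.empty((yz.shape[1], k))
    svals = np.empty(k)
    corrs = np.empty(k)
    for c in range(k):
        cov = xd.T @ yz / (n - 1)
        u, s, vt = np.linalg.svd(cov, full_matrices=False)
        w_x, w_y = u[:, 0], vt[0]
        # sign convention: largest-|weight| predictor positive
        if w_x[np.argmax(np.abs(w_x))] < 0:
            w_x, w_y = -w_x, -w_y
        t = xd @ w_x
        s_y = yz @ w_y
        x_scores[:, c] = t
        y_scores[:, c] = s_y
        x_weights[:, c] = w_x
        y_weights[:, c] = w_y
        svals[c] = s[0]
        corrs[c] = (
            stats.pearsonr(t, s_y).statistic if t.std() > 0 and s_y.std() > 0 else 0.0
        )
        denom = t @ t
        if denom > 0:
            xd = xd - np.outer(t, (xd.T @ t) / denom)
    return PLSResult(
        x_scores=x_scores,
        y_scores=y_scores,
        x_weights=x_weights,
        y_weights=y_weights,
        singular_values=svals,
        score_correlations=corrs,
        dropped_columns=dropped,
    )


def pls_permutation(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    n_components: int | None = None,
) -> PLSResult:
    """Permutation significance of PLS components.

    Rows of Y are shuffled; the null distribution of each component's
    singular value yields ``p = (1 + #{null ≥ observed})/(1 + n_perm)``,
    Benjamini–Hochberg adjusted across components.
    """
    import warnings

    if n_perm < 100:
        warnings.warn("n_perm < 100: permutation p-values are coarse")
    result = pls_fit(x, y, n_components)
    rng = np.random.default_rng(seed)
    k = result.singular_values.size
    null = np.empty((n_perm, k))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] == 1:
        y = y.T
    for i in range(n_perm):
        perm = rng.permutation(y.shape[0])
        null[i] = pls_fit(x, y[perm], n_components).singular_values[:k]
    p = (1.0 + (null >= result.singular_values).sum(axis=0)) / (1.0 + n_perm)
    result.p_values = p
    result.p_fdr = multipletests(p, method="fdr_bh")[1]
    return result


def pls_loadings(
    result: PLSResult, x: np.ndarray, y: np.ndarray, component: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson-correlation loadings of original variables on a component.

    X variables are correlated with the X score, Y variables with the Y
    score; constant variables load 0.
    """
    def corr_cols(a, score):
        a = np.atleast_2d(np.asarray(a, dtype=float))
        if a.shape[0] != score.size:
            a = a.T
        out = np.zeros(a.shape[1])
        for j in range(a.shape[1]):
            col = a[:, j]
            if col.std() > 0 and score.std() > 0:
                out[j] = stats.pearsonr(col, score).statistic
        return out

    return (
        corr_cols(x, result.x_scores[:, component]),
        corr_cols(y, result.y_scores[:, component]),
    )


def average_loadings(
    loadings: np.ndarray, n_regions: int, n_states: int, n_features: int
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse per-column brain loadings to a region map and a feature
    profile.

    Expects the feature-matrix column ordering of
    :func:`ndcvae.features.build_feature_matrix`; only the dynamic-feature
    block (the first ``n_features·n_states·n_regions`` columns) enters the
    averages.
    """
    block = loadings[: n_features * n_states * n_regions].reshape(
        n_features, n_states, n_regions
    )
    region_map = block.mean(axis=(0, 1))
    feature_profile = block.mean(axis=(1, 2))
    return region_map, feature_profile


def gene_pls(
    expression: np.ndarray,
    brain_map: np.ndarray,
    distances: np.ndarray,
    n_perm: int = 1000,
    n_boot: int = 1000,
    z_threshold: float = 3.0,
    n_top: int | None = None,
    seed: int = 0,
) -> dict:
    """PLS of regional gene expression against a brain loading map.

    Component significance is assessed against variogram-matched surrogate
    maps of ``brain_map``; bootstrap resampling of regions (with component
    sign realigned to the original weights) gives per-gene weight standard
    errors, ``z = weight/SE``, and |z|-thresholded positive/negative gene
    sets.  ``n_top`` additionally returns the top and bottom n genes ranked
    by Pearson correlation with the map (validation mode).
    """
    import warnings

    from .spatial_null import surrogate_maps

    expr = np.asarray(expression, dtype=float)
    bmap = np.asarray(brain_map, dtype=float)
    n_regions, n_genes = expr.shape
    if n_regions < 20:
        warnings.warn("fewer than 20 regions: surrogate variogram unstable")
    rng = np.random.default_rng(seed)
    fit = pls_fit(expr, bmap[:, None], n_components=1)
    w_obs = fit.x_weights[:, 0]
    s_obs = fit.singular_values[0]

    surr = surrogate_maps(bmap, distances, n=n_perm, seed=seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = pls_fit(expr, surr[i][:, None], n_components=1).singular_values[0]
    p_surr = (1.0 + np.sum(null >= s_obs)) / (1.0 + n_perm)

    boots = np.empty((n_boot, n_genes))
    for b in range(n_boot):
        idx = rng.integers(0, n_regions, size=n_regions)
        while np.std(bmap[idx]) == 0:
            idx = rng.integers(0, n_regions, size=n_regions)
        w_b = pls_fit(expr[idx], bmap[idx][:, None], n_components=1).x_weights[:, 0]
        if np.dot(w_b, w_obs) < 0:  # realign component sign
            w_b = -w_b
        boots[b] = w_b
    se = boots.std(axis=0, ddof=1)
    z = np.divide(w_obs, se, out=np.zeros_like(w_obs), where=se > 0)
    out = {
        "weights": w_obs,
        "singular_value": float(s_obs),
        "score_correlation": float(fit.score_correlations[0]),
        "p_surrogate": float(p_surr),
        "z": z,
        "positive_set": np.where(z > z_threshold)[0],
        "negative_set": np.where(z < -z_threshold)[0],
    }
    if n_top is not None:
        corrs = np.array(
            [
                stats.pearsonr(expr[:, g], bmap).statistic
                if expr[:, g].std() > 0
                else 0.0
                for g in range(n_genes)
            ]
        )
        order = np.argsort(corrs)
        out["bottom_ranked"] = order[:n_top]
        out["top_ranked"] = order[::-1][:n_top]
        out["map_correlations"] = corrs
    return out
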