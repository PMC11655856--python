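"""Dynamic features of inferred state series, and feature-cluster selection.

Nine scalar descriptors per series — spanning distributional shape
(mean, standard deviation, kernel-density entropy), predictability
(lag-3 nonlinear autocorrelation scale, fourth-derivative spread),
non-stationarity (Phillips–Perron unit-root statistic, kinematic-walker
divergence, visibility-graph degree likelihood) and stochasticity
(Lo–MacKinlay variance-ratio z) — plus a tenth, sliding-window dynamic
connectivity variability computed jointly across regions.

A correlation-graph clustering picks representative features from a larger
candidate battery, and the assembly step concatenates the per-region,
per-state features with region- and subject-level encoded parameters into
the predictor matrix used for association analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "FEATURE_NAMES",
    "basic_stats",
    "kernel_entropy",
    "trev3_denom",
    "std_nth_der",
    "pp_meanstat",
    "walker_distdiff",
    "visibility_expnlogL",
    "var_ratio_stat",
    "feature_vector",
    "dynamic_variability",
    "cluster_features",
    "build_feature_matrix",
]

FEATURE_NAMES = (
    "mean",
    "standard_deviation",
    "kernel_entropy",
    "trev3_denom",
    "std_nth_der_4",
    "pp_meanstat",
    "walker_distdiff",
    "visibility_expnlogL",
    "var_ratio_4_1_stat",
    "dynamic_variability",
)


def _series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if np.any(~np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


def basic_stats(series) -> tuple[float, float]:
    """Arithmetic mean and sample (ddof=1) standard deviation."""
    x = _series(series)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(x.mean()), float(x.std(ddof=1))


def kernel_entropy(series, n_grid: int = 512) -> float:
    """Differential entropy (nats) of a Gaussian-kernel density estimate.

    Silverman's rule sets the bandwidth; the density is evaluated on a
    uniform grid spanning the data ± 3 bandwidths and the entropy is the
    Riemann sum of −p ln p.
    """
    x = _series(series)
    if x.size < 10:
        raise ValueError("need at least 10 samples")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant series: entropy degenerate")
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    bw = 0.9 * spread * x.size ** (-0.2)
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, n_grid)
    dx = grid[1] - grid[0]
    dens = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / bw) ** 2).sum(axis=1)
    dens /= x.size * bw * np.sqrt(2 * np.pi)
    mask = dens > 0
    return float(-np.sum(dens[mask] * np.log(dens[mask])) * dx)


def trev3_denom(series, full_ratio: bool = False) -> float:
    """Scale of the lag-3 nonlinear autocorrelation.

    With ``d_t = x_{t+3} − x_t``: returns ``mean(d²)^{3/2}`` (the
    normalizing denominator of the trev statistic).  ``full_ratio=True``
    returns the normalized ratio ``mean(d³)/mean(d²)^{3/2}`` instead.
    """
    x = _series(series)
    if x.size <= 3:
        raise ValueError("need more than 3 samples")
    d = x[3:] - x[:-3]
    denom = float(np.mean(d**2) ** 1.5)
    if not full_ratio:
        return denom
    if denom == 0:
        raise ValueError("constant series: trev ratio undefined")
    return float(np.mean(d**3) / denom)


def std_nth_der(series, n: int = 4) -> float:
    """Sample standard deviation of the n-th finite difference."""
    x = _series(series)
    if x.size <= n + 1:
        raise ValueError(f"need more than {n + 1} samples")
    return float(np.diff(x, n=n).std(ddof=1))


def _pp_ztau(x: np.ndarray, lags: int) -> float:
    """Phillips–Perron Z_tau at one Bartlett truncation lag.

    OLS of x_t on (1, x_{t−1}); the Dickey–Fuller t-ratio is corrected with
    the Newey–West long-run variance of the residuals.
    """
    y, ylag = x[1:], x[:-1]
    n = y.size
    design = np.column_stack([np.ones(n), ylag])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rss = resid @ resid
    s2 = rss / (n - 2)
    xtx_inv = np.linalg.inv(design.T @ design)
    se_rho = np.sqrt(s2 * xtx_inv[1, 1])
    t_rho = (coef[1] - 1.0) / se_rho
    gamma0 = rss / n
    lam2 = gamma0
    for j in range(1, lags + 1):
        w = 1.0 - j / (lags + 1.0)
        lam2 += 2.0 * w * (resid[j:] @ resid[:-j]) / n
    lam2 = max(lam2, 1e-12)
    lam = np.sqrt(lam2)
    s = np.sqrt(s2)
    return float(
        np.sqrt(gamma0 / lam2) * t_rho - (lam2 - gamma0) * n * se_rho / (2.0 * lam * s)
    )


def pp_meanstat(series, max_lags: int = 5) -> float:
    """Mean Phillips–Perron Z_tau statistic over truncation lags 0…max_lags."""
    x = _series(series)
    if x.size < 20:
        raise ValueError("need at least 20 samples")
    return float(np.mean([_pp_ztau(x, q) for q in range(max_lags + 1)]))


def walker_distdiff(series, alpha: float = 0.5) -> float:
    """Distributional divergence between a series and a pursuing walker.

    The walker starts at the first sample and moves a fraction ``alpha``
    toward the previous observation each step; the statistic is the
    two-sample Kolmogorov–Smirnov distance between walker positions and the
    original samples.
    """
    x = _series(series)
    if x.size < 10:
        raise ValueError("need at least 10 samples")
    w = np.empty_like(x)
    w[0] = x[0]
    for t in range(x.size - 1):
        w[t + 1] = w[t] + alpha * (x[t] - w[t])
    return float(stats.ks_2samp(w, x, method="asymp").statistic)


def visibility_degrees(x: np.ndarray) -> np.ndarray:
    """Degrees of the natural visibility graph of a series.

    Points a < b are linked iff every intermediate sample lies strictly
    below the chord from (a, x_a) to (b, x_b).
    """
    n = x.size
    deg = np.zeros(n, dtype=int)
    t = np.arange(n)
    for a in range(n - 1):
        max_slope = -np.inf
        for b in range(a + 1, n):
            slope = (x[b] - x[a]) / (t[b] - t[a])
            if b == a + 1 or slope > max_slope:
                deg[a] += 1
                deg[b] += 1
            max_slope = max(max_slope, slope)
    return deg


def visibility_expnlogL(series) -> float:
    """Mean negative log-likelihood of visibility-graph degrees under an
    exponential fit.

    The series is z-scored, the natural visibility graph built, degrees
    shifted by their minimum, and an exponential rate fitted by maximum
    likelihood; the statistic is the mean negative log-likelihood of the
    shifted degrees.
    """
    x = _series(series)
    if x.size < 5:
        raise ValueError("need at least 5 samples")
    sd = x.std()
    if sd > 0:
        x = (x - x.mean()) / sd
    k = visibility_degrees(x)
    kshift = k - k.min()
    mean_k = kshift.mean()
    if mean_k == 0:
        raise ValueError("degenerate degree distribution")
    lam = 1.0 / mean_k
    return float(-np.mean(np.log(lam) - lam * kshift))


def var_ratio_stat(series, q: int = 4) -> float:
    """Lo–MacKinlay variance-ratio z-statistic of the random-walk hypothesis.

    Compares the variance of overlapping q-period increments (bias
    corrected) with q times the 1-period increment variance; returns the
    homoscedastic z ``(VR − 1)/√[2(2q−1)(q−1)/(3qn)]``.
    """
    x = _series(series)
    if x.size < 10 * q:
        raise ValueError(f"need at least {10 * q} samples")
    n = x.size - 1
    mu = (x[-1] - x[0]) / n
    d1 = np.diff(x) - mu
    var1 = (d1 @ d1) / (n - 1)
    if var1 == 0:
        raise ValueError("zero-variance increments: variance ratio undefined")
    dq = x[q:] - x[:-q] - q * mu
    # the m normalizer scales the overlapping q-period sum back to a
    # per-period variance, so VR is a direct ratio with var1
    m = q * (n - q + 1) * (1.0 - q / n)
    varq = (dq @ dq) / m
    vr = varq / var1
    z_denom = np.sqrt(2.0 * (2 * q - 1) * (q - 1) / (3.0 * q * n))
    return float((vr - 1.0) / z_denom)


def feature_vector(series) -> dict[str, float]:
    """The nine per-series features (dynamic variability needs all regions
    and is added by :func:`build_feature_matrix`)."""
    mean, sd = basic_stats(series)
    return {
        "mean": mean,
        "standard_deviation": sd,
        "kernel_entropy": kernel_entropy(series),
        "trev3_denom": trev3_denom(series),
        "std_nth_der_4": std_nth_der(series),
        "pp_meanstat": pp_meanstat(series),
        "walker_distdiff": walker_distdiff(series),
        "visibility_expnlogL": visibility_expnlogL(series),
        "var_ratio_4_1_stat": var_ratio_stat(series),
    }


def dynamic_variability(
    states: np.ndarray, window: int = 20, step: int = 4
) -> np.ndarray:
    """Sliding-window dynamic-connectivity variability per region.

    ``states`` is (n_regions, n_time).  For each left-aligned window ``i``
    (count = floor((T − L)/S) + 1), ``F_{i,k}`` holds region k's Pearson
    correlations with every other region.  ``V_k`` is one minus the mean
    correlation of F-vectors over distinct window pairs, so identical
    connectivity across windows gives 0 and anticorrelated patterns
    approach 2.  Windows whose F-vector is degenerate (constant) are
    excluded pairwise.
    """
    states = np.asarray(states, dtype=float)
    n_regions, n_time = states.shape
    if n_regions < 3:
        raise ValueError("need at least 3 regions")
    n_win = (n_time - window) // step + 1
    if n_win < 2:
        raise ValueError("need at least 2 windows")
    f = np.empty((n_win, n_regions, n_regions - 1))
    valid = np.ones((n_win, n_regions), dtype=bool)
    for i in range(n_win):
        seg = states[:, i * step : i * step + window]
        sd = seg.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(seg)
        for k in range(n_regions):
            row = np.delete(corr[k], k)
            f[i, k] = row
            if sd[k] == 0 or np.any(~np.isfinite(row)) or np.std(row) == 0:
                valid[i, k] = False
    v = np.full(n_regions, np.nan)
    for k in range(n_regions):
        ok = np.where(valid[:, k])[0]
        if ok.size < 2:
            continue
        cc = np.corrcoef(f[ok, k])
        iu = np.triu_indices(ok.size, k=1)
        v[k] = 1.0 - cc[iu].mean()
    return v


def cluster_features(feature_corr: np.ndarray) -> tuple[list[list[int]], list[int]]:
    """Cluster features by |correlation| > 0.5 and pick representatives.

    Connected components of the thresholded correlation graph are the
    clusters; each cluster's representative maximizes the sum of absolute
    correlations with the other members (ties break to the lowest index).
    Returns ``(clusters, representatives)``.
    """
    c = np.asarray(feature_corr, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1] or not np.allclose(c, c.T):
        raise ValueError("feature_corr must be square and symmetric")
    adj = (np.abs(c) > 0.5).astype(int)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters, reps = [], []
    for comp in range(n_comp):
        members = np.where(labels == comp)[0]
        clusters.append(members.tolist())
        if members.size == 1:
            reps.append(int(members[0]))
        else:
            sums = np.abs(c[np.ix_(members, members)]).sum(axis=1) - 1.0
            reps.append(int(members[np.argmax(sums)]))
    return clusters, reps


def build_feature_matrix(
    states: np.ndarray,
    theta_r: np.ndarray,
    theta_s: np.ndarray,
    subject_ids: list | None = None,
    window: int = 20,
    step: int = 4,
) -> pd.DataFrame:
    """Assemble the subjects × predictors block from specific-state series.

    ``states`` is (n_sub, n_regions, n_time, n_states); ``theta_r`` is
    (n_sub, n_regions, m_r); ``theta_s`` is (n_sub, m_s).  Columns are
    ordered feature-major — for each feature, for each state, all regions —
    followed by the region-level parameter blocks and the subject-level
    parameters.  Column names embed feature/state/region identity.
    """
    states = np.asarray(states, dtype=float)
    n_sub, n_regions, n_time, n_states = states.shape
    m_r = theta_r.shape[2]
    m_s = theta_s.shape[1]
    per_series = {
        name: np.empty((n_sub, n_states, n_regions)) for name in FEATURE_NAMES
    }
    for s in range(n_sub):
        for st in range(n_states):
            v = dynamic_variability(states[s, :, :, st], window, step)
            per_series["dynamic_variability"][s, st] = v
            for r in range(n_regions):
                fv = feature_vector(states[s, r, :, st])
                for name, val in fv.items():
                    per_series[name][s, st, r] = val
    cols, names = [], []
    for name in FEATURE_NAMES:
        for st in range(n_states):
            block = per_series[name][:, st, :]  # (n_sub, n_regions)
            cols.append(block)
            names.extend(
                f"{name}_state{st}_region{r}" for r in range(n_regions)
            )
    for p in range(m_r):
        cols.append(theta_r[:, :, p])
        names.extend(f"theta_r{p}_region{r}" for r in range(n_regions))
    cols.append(theta_s)
    names.extend(f"theta_s{p}" for p in range(m_s))
    mat = np.concatenate(cols, axis=1)
    index = subject_ids if subject_ids is not None else list(range(n_sub))
    if len(set(names)) != len(names):
        raise ValueError("duplicate column names in feature matrix")
    return pd.DataFrame(mat, index=index, columns=names)
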