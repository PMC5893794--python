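"""Neural-representation discriminability analysis.

From correctly decoded bins (decoder active for the cued movement, inside
that movement's cue), the per-movement mean MWP spatial pattern over the 96
channels is computed; patterns are compared by pairwise Euclidean distance,
each movement's aggregate separability is its summed distance to all
others, and separability is regressed against individual decoder accuracy.
PCA of the selected bins (components 1 and 2) with a per-movement Gaussian
fit visualizes cluster overlap, and mean MWP can be mapped onto the
physical 10x10 array layout as a heat map.  Also provides the MWP-vs-
threshold-crossing correlation used as a feature sanity check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from gripdecode.decoder import DecodeTrace
from gripdecode.features import FeatureMatrix
from gripdecode.preprocess import BinnedCounts
from gripdecode.synth import REST, ArrayLayout, CueSchedule


class RepresentError(ValueError):
    pass


@dataclass
class RepresentationSummary:
    movements: tuple
    mean_mwp: pd.DataFrame            # movement x channel
    distances: pd.DataFrame           # movement x movement Euclidean
    aggregate: pd.Series              # per-movement summed distance
    pca_coords: np.ndarray | None = None
    pca_labels: np.ndarray | None = None
    explained_variance: np.ndarray | None = None
    gaussians: dict | None = None


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def select_active_bins(
    trace: DecodeTrace, schedule: CueSchedule
) -> dict[str, np.ndarray]:
    """Per movement, indices of bins where the decoder is active for that
    movement AND the cue is that movement (both conditions simultaneously)."""
    cue = schedule.labels_for_times(trace.bin_starts_s)
    return {
        m: np.flatnonzero((trace.states == m) & (cue == m))
        for m in trace.movements
    }


def pca_project(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Top-2 PCA of selected MWP bins.

    Channel means are removed; no variance scaling (MWP is already
    standardized, rescaling would distort spatial geometry).  The sign of
    each component is fixed so its largest-|loading| channel is positive,
    making the projection deterministic.  Returns (coords, variance
    fractions).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise RepresentError("need at least 3 bins for PCA")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < 2:
        raise RepresentError("input rank below 2")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    comps = pca.components_
    for k in range(2):
        j = np.argmax(np.abs(comps[k]))
        if comps[k, j] < 0:
            comps[k] *= -1
            coords[:, k] *= -1
    return coords, pca.explained_variance_ratio_


def fit_cluster_gaussians(
    coords: np.ndarray, labels: np.ndarray, reg: float = 1e-9
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """One Gaussian (mean, covariance) per movement cluster in PC space.

    Visualization-only; singular covariances are ridge-regularized with the
    smallest epsilon that makes them positive definite (logged on return via
    the regularized flag in the covariance itself being modified).
    """
    out = {}
    for m in dict.fromkeys(labels):
        pts = coords[labels == m]
        if len(pts) < 3:
            raise RepresentError(f"fewer than 3 points for cluster {m!r}")
        mu = pts.mean(axis=0)
        cov = np.cov(pts.T)
        eps = reg
        while np.linalg.eigvalsh(cov).min() <= 0:
            cov = cov + eps * np.eye(2)
            eps *= 10
        out[m] = (mu, cov)
    return out


def mean_mwp_map(
    features: FeatureMatrix,
    bin_sets: dict[str, np.ndarray],
    layout: ArrayLayout,
) -> dict[str, np.ndarray]:
    """Per-movement 10x10 heat-map grid of mean MWP.

    The 96 channel means are placed at their physical positions; the 4
    corner reference cells are NaN (non-active).  Movements with empty bin
    sets are skipped.
    """
    grids = {}
    for m, idx in bin_sets.items():
        if len(idx) == 0:
            continue
        mean = features.values[idx].mean(axis=0)
        grid = np.full((layout.rows, layout.cols), np.nan)
        for c, (r, col) in enumerate(layout.positions):
            grid[r, col] = mean[c]
        grids[m] = grid
    return grids


def pairwise_separability(
    mean_vectors: pd.DataFrame | np.ndarray,
    movements: tuple | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Euclidean distance matrix between mean MWP patterns and, per
    movement, the aggregate (summed) distance to all others."""
    if isinstance(mean_vectors, pd.DataFrame):
        movements = tuple(mean_vectors.index)
        M = mean_vectors.to_numpy(dtype=float)
    else:
        M = np.asarray(mean_vectors, dtype=float)
        movements = movements or tuple(range(len(M)))
    if len(M) < 2:
        raise RepresentError("need at least 2 movements")
    D = squareform(pdist(M, metric="euclidean"))
    dist = pd.DataFrame(D, index=list(movements), columns=list(movements))
    agg = dist.sum(axis=1)           # diagonal is zero
    agg.name = "aggregate_distance"
    return dist, agg


def summarize_representation(
    features: FeatureMatrix,
    trace: DecodeTrace,
    schedule: CueSchedule,
    layout: ArrayLayout | None = None,
) -> RepresentationSummary:
    """End-to-end representation summary from a decoded block."""
    sets = select_active_bins(trace, schedule)
    nonempty = {m: i for m, i in sets.items() if len(i)}
    if len(nonempty) < 2:
        raise RepresentError("fewer than 2 movements with selected bins")
    means = pd.DataFrame(
        {m: features.values[i].mean(axis=0) for m, i in nonempty.items()}
    ).T
    dist, agg = pairwise_separability(means)
    all_idx = np.concatenate([nonempty[m] for m in nonempty])
    labels = np.concatenate(
        [np.full(len(nonempty[m]), m, dtype=object) for m in nonempty]
    )
    coords, evr = pca_project(features.values[all_idx])
    # Gaussian cluster fits are visualization-only: clusters too small to
    # support a covariance estimate are left out rather than failing the run.
    big = np.isin(labels, [m for m in nonempty if len(nonempty[m]) >= 3])
    gauss = fit_cluster_gaussians(coords[big], labels[big])
    return RepresentationSummary(
        tuple(nonempty), means, dist, agg, coords, labels, evr, gauss
    )


def regress_accuracy_on_separability(
    accuracies_pct: dict[str, float] | pd.Series,
    aggregates: dict[str, float] | pd.Series,
) -> RegressionResult:
    """OLS of per-movement accuracy on aggregate distance.

    R-squared and a two-sided p-value on the slope from its t statistic
    with n-2 degrees of freedom.
    """
    acc = pd.Series(accuracies_pct, dtype=float)
    agg = pd.Series(aggregates, dtype=float).reindex(acc.index)
    if acc.isna().any() or agg.isna().any():
        raise RepresentError("accuracy/aggregate movement sets differ")
    if len(acc) < 3:
        raise RepresentError("need at least 3 movements for regression")
    if np.isclose(agg.std(), 0):
        raise RepresentError("zero variance in the separability predictor")
    res = stats.linregress(agg.to_numpy(), acc.to_numpy())
    return RegressionResult(res.slope, res.intercept, res.rvalue**2,
                            res.pvalue, len(acc))


def correlate_mwp_tc(
    features: FeatureMatrix, counts: BinnedCounts, window_s: float = 55.0
) -> tuple[float, float]:
    """Pearson correlation between channel-averaged MWP and channel-summed
    threshold-crossing counts per 100 ms bin over the first ``window_s``."""
    mwp_t = features.bin_starts_s
    tc_t = counts.bin_edges_s[:-1]
    n = min(np.sum(mwp_t < mwp_t[0] + window_s),
            np.sum(tc_t < tc_t[0] + window_s))
    if n < 10:
        raise RepresentError("need at least 10 overlapping bins")
    a = features.values[:n].mean(axis=1)
    b = counts.global_counts[:n].astype(float)
    if np.isclose(a.std(), 0) or np.isclose(b.std(), 0):
        raise RepresentError("constant series: correlation undefined")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
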