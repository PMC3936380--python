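"""Background-corrected tests of niche divergence and conservatism.

Following the multivariate background approach: environmental variables
at occurrence and background points are reduced by PCA to niche axes; on
each axis the observed difference between lineage means is compared to a
null distribution of background divergence obtained by jackknife
resampling of the background points.  An observed difference above the
null interval is niche divergence (lineages are more different than
their available environments); below it, niche conservatism (lineages
are more similar than expected from their backgrounds); inside it,
neither can be claimed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon

__all__ = [
    "NicheAxes",
    "pca_env",
    "minimum_convex_polygon",
    "sample_background",
    "classify_divergence",
    "NicheTestResult",
    "niche_divergence_test",
]


@dataclass
class NicheAxes:
    """PCA loadings and variance shares defining shared niche axes."""

    loadings: pd.DataFrame          # variables x axes
    variance_explained: np.ndarray  # percent per axis, non-increasing
    means: pd.Series
    scales: pd.Series               # ones when standardize=False

    @property
    def axes(self) -> list[str]:
        return list(self.loadings.columns)

    def scores(self, env: pd.DataFrame) -> pd.DataFrame:
        """Project rows of ``env`` onto the niche axes."""
        X = env[self.loadings.index].to_numpy(float)
        Z = (X - self.means.to_numpy()) / self.scales.to_numpy()
        return pd.DataFrame(Z @ self.loadings.to_numpy(),
                            columns=self.axes, index=env.index)


def pca_env(env: pd.DataFrame, standardize: bool = True,
            n_axes: int | None = None) -> NicheAxes:
    """PCA of an environmental matrix (correlation PCA when standardized).

    Axes are ordered by eigenvalue; each axis is sign-fixed so its
    largest-magnitude loading is positive.  Constant columns are dropped
    with a warning.
    """
    env = env.select_dtypes("number")
    if env.shape[0] < 2 or env.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 numeric variables")
    if env.isna().any().any():
        raise ValueError("missing values in environmental matrix")
    sd = env.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant columns: {constant}")
        env = env.drop(columns=constant)
        sd = sd.drop(constant)
    means = env.mean()
    scales = sd if standardize else pd.Series(1.0, index=env.columns)
    Z = (env - means) / scales
    cov = np.cov(Z.to_numpy(float), rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    k = n_axes or len(eigval)
    eigvec = eigvec[:, :k]
    for a in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, a])), a] < 0:
            eigvec[:, a] = -eigvec[:, a]
    loadings = pd.DataFrame(eigvec, index=env.columns,
                            columns=[f"PC{i + 1}" for i in range(eigvec.shape[1])])
    var_pct = 100.0 * eigval[:k] / eigval.sum()
    return NicheAxes(loadings=loadings, variance_explained=var_pct,
                     means=means, scales=scales)


def minimum_convex_polygon(points: np.ndarray | pd.DataFrame) -> Polygon:
    """Convex hull around occurrence coordinates (lon, lat)."""
    if isinstance(points, pd.DataFrame):
        points = points[["lon", "lat"]].to_numpy(float)
    points = np.asarray(points, float)
    if len(points) < 3:
        raise ValueError("need at least 3 points for a polygon")
    hull = MultiPoint([Point(p) for p in points]).convex_hull
    if not isinstance(hull, Polygon):
        raise ValueError("points are collinear; buffer them or add occurrences")
    return hull


def sample_background(polygon: Polygon, n: int = 1000, seed=None) -> np.ndarray:
    """Uniform points inside a polygon by bounding-box rejection sampling."""
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = polygon.bounds
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        batch = max(n - filled, 64)
        xs = rng.uniform(minx, maxx, size=2 * batch)
        ys = rng.uniform(miny, maxy, size=2 * batch)
        for x, y in zip(xs, ys):
            if polygon.contains(Point(x, y)):
                out[filled] = (x, y)
                filled += 1
                if filled == n:
                    break
    return out


def classify_divergence(observed: float, lower: float, upper: float) -> str:
    """Call one axis: divergence above the null interval, conservatism below.

    The decision depends only on the observed between-lineage difference
    and the middle-95% interval of background divergence.
    """
    if lower > upper:
        raise ValueError("interval bounds reversed")
    if observed > upper:
        return "divergence"
    if observed < lower:
        return "conservatism"
    return "neither"


@dataclass
class NicheTestResult:
    """Per-axis observed divergence vs jackknife background null."""

    table: pd.DataFrame      # observed, null_lower, null_upper, call per axis
    n_jackknife: int
    resample_fraction: float
    axes: NicheAxes | None = None

    def calls(self) -> dict[str, str]:
        return dict(self.table["call"])


def niche_divergence_test(occ1: pd.DataFrame, occ2: pd.DataFrame,
                          bg1: pd.DataFrame, bg2: pd.DataFrame,
                          axes: NicheAxes | None = None,
                          n_axes: int | None = None,
                          n_jackknife: int = 1000, fraction: float = 0.75,
                          replace: bool = True, seed=None,
                          alpha: float = 0.05) -> NicheTestResult:
    """Run the divergence/conservatism test on each niche axis.

    Inputs are environmental tables (rows = points, columns = variables;
    non-numeric columns are ignored).  When ``axes`` is omitted a PCA is
    fitted on the pooled occurrence + background rows so all point sets
    share axes.  Each jackknife replicate resamples ``fraction`` of each
    background set (with replacement by default) and records the absolute
    difference of background means; the null interval is the central
    (1 - alpha) span of those replicates.
    """
    if len(bg1) == 0 or len(bg2) == 0:
        raise ValueError("empty background set")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    env_cols = [c for c in occ1.columns
                if c in bg1.columns and pd.api.types.is_numeric_dtype(occ1[c])
                and c not in ("lon", "lat")]
    if axes is None:
        pooled = pd.concat([d[env_cols] for d in (occ1, occ2, bg1, bg2)],
                           ignore_index=True)
        axes = pca_env(pooled, n_axes=n_axes)
    rng = np.random.default_rng(seed)
    s_occ1, s_occ2 = axes.scores(occ1[env_cols]), axes.scores(occ2[env_cols])
    s_bg1, s_bg2 = axes.scores(bg1[env_cols]), axes.scores(bg2[env_cols])

    rows = []
    m1 = max(1, int(round(fraction * len(s_bg1))))
    m2 = max(1, int(round(fraction * len(s_bg2))))
    b1 = s_bg1.to_numpy()
    b2 = s_bg2.to_numpy()
    null = np.empty((n_jackknife, len(axes.axes)))
    for r in range(n_jackknife):
        i1 = rng.choice(len(b1), size=m1, replace=replace)
        i2 = rng.choice(len(b2), size=m2, replace=replace)
        null[r] = np.abs(b1[i1].mean(axis=0) - b2[i2].mean(axis=0))
    lo, hi = np.percentile(null, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    for a, axis in enumerate(axes.axes):
        observed = abs(s_occ1[axis].mean() - s_occ2[axis].mean())
        rows.append({
            "axis": axis,
            "variance_explained": axes.variance_explained[a],
            "observed": observed,
            "null_lower": lo[a],
            "null_upper": hi[a],
            "call": classify_divergence(observed, lo[a], hi[a]),
        })
    table = pd.DataFrame(rows).set_index("axis")
    return NicheTestResult(table=table, n_jackknife=n_jackknife,
                           resample_fraction=fraction, axes=axes)
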