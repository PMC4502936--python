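"""Association tests: Mantel randomization, latitudinal rank correlations,
and sample-size bias diagnostics.

The Mantel test asks whether labels (countries, families) that are close in
one distance matrix (geography, phylogeny) also have similar infection
estimates (small absolute differences).  Because matrix entries are not
independent, significance comes from randomization: the rows/columns of one
matrix are permuted jointly and the correlation recomputed.  The test is
one-tailed (greater): the directional hypothesis is that nearby labels are
similar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .geospatial import DistanceMatrix
from .screen_data import ScreenTable

__all__ = [
    "MantelResult",
    "value_difference_matrix",
    "mantel",
    "latitude_correlation",
    "sample_size_bias_binned",
    "infection_vs_samplesize_slope",
]


def value_difference_matrix(values: dict[str, float]) -> DistanceMatrix:
    """|v_a − v_b| matrix over labels with finite values.

    Labels whose value is missing or non-finite are dropped (and reported in
    the returned matrix's label set simply by absence); translation of all
    values leaves the matrix unchanged.
    """
    labels = [l for l, v in values.items() if v is not None and np.isfinite(v)]
    if len(labels) < 2:
        raise ValueError("need at least 2 labels with finite values")
    v = np.array([values[l] for l in labels], dtype=float)
    return DistanceMatrix(labels, np.abs(v[:, None] - v[None, :]))


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    n_labels: int
    seed: int | None


def _tri(values: np.ndarray) -> np.ndarray:
    iu = np.tril_indices(values.shape[0], k=-1)
    return values[iu]


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> MantelResult:
    """Mantel test: Pearson r of the lower triangles, permutation p-value.

    d2's labels are jointly row/column permuted ``n_permutations`` times;
    p = (1 + #{r_perm >= r_obs}) / (1 + n_permutations), one-tailed greater.
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must carry the same labels in the same order")
    n = len(d1)
    if n < 3:
        raise ValueError("Mantel test needs at least 3 labels")
    x = _tri(d1.values)
    y = _tri(d2.values)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a distance-matrix triangle; Mantel r undefined")

    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    m = len(x)
    r_obs = float(np.dot(xs, ys) / m)

    rng = np.random.default_rng(seed)
    iu = np.tril_indices(n, k=-1)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    rows = perms[:, iu[0]]  # (P, m)
    cols = perms[:, iu[1]]
    yp = d2.values[rows, cols]
    yp = (yp - yp.mean(axis=1, keepdims=True)) / yp.std(axis=1, keepdims=True)
    r_perm = yp @ xs / m
    p = (1.0 + np.sum(r_perm >= r_obs)) / (1.0 + n_permutations)
    return MantelResult(r_obs, float(p), n_permutations, n, seed)


def latitude_correlation(
    estimates: dict[str, float],
    centroids: pd.DataFrame,
    axis: str = "absolute_latitude",
) -> tuple[float, float]:
    """Spearman rank correlation of per-country estimates vs |latitude| or longitude.

    Latitude enters as absolute value (distance from the equator); longitude
    is signed.  Ties get average ranks; p is two-sided.
    """
    if axis not in ("absolute_latitude", "longitude"):
        raise ValueError(f"axis must be 'absolute_latitude' or 'longitude', got {axis!r}")
    lut = centroids.set_index("country")
    pairs = [
        (estimates[c], lut.loc[c, "latitude"] if axis == "absolute_latitude" else lut.loc[c, "longitude"])
        for c in estimates
        if c in lut.index and np.isfinite(estimates[c])
    ]
    if len(pairs) < 3:
        raise ValueError("need at least 3 countries with estimates and coordinates")
    est = np.array([p[0] for p in pairs])
    coord = np.array([p[1] for p in pairs])
    if axis == "absolute_latitude":
        coord = np.abs(coord)
    if np.all(est == est[0]):
        import warnings

        warnings.warn("all estimates tied; rank correlation undefined", stacklevel=2)
        return 0.0, 1.0
    rho, p = stats.spearmanr(est, coord)
    return float(rho), float(p)


def sample_size_bias_binned(table: ScreenTable, bin_width: int = 10) -> tuple[float, float]:
    """Spearman correlation of sample-size bin vs per-bin sample incidence.

    Screens are binned by n into (0,10], (10,20], ... (upper-bound edges, the
    same convention as the prevalence histogram); per bin the share of
    screens with any positive is the sample incidence.  A systematic trend
    indicates that screening effort is biased toward (or away from) infected
    populations.
    """
    k, n = table.counts
    idx = np.ceil(n / bin_width).astype(int) - 1
    nb = idx.max() + 1
    counts = np.bincount(idx, minlength=nb)
    hits = np.bincount(idx, weights=(k >= 1).astype(float), minlength=nb)
    nonempty = counts > 0
    if nonempty.sum() < 3:
        raise ValueError("need at least 3 non-empty sample-size bins")
    mids = (np.arange(nb) + 0.5) * bin_width
    incid = hits[nonempty] / counts[nonempty]
    rho, p = stats.spearmanr(mids[nonempty], incid)
    return float(rho), float(p)


def infection_vs_samplesize_slope(table: ScreenTable) -> tuple[float, float]:
    """Binomial-regression slope of infection probability on sample size.

    Logistic regression of (k_i of n_i) on n_i; the slope is the change in
    log-odds of an individual being infected per additional sampled
    individual.  A positive slope would indicate that well-sampled
    populations are preferentially infected (sampling bias).  Complete
    separation is flagged by a non-finite slope/SE.
    """
    k, n = table.counts
    if len(np.unique(n)) < 2:
        raise ValueError("need at least 2 distinct sample sizes")
    endog = np.column_stack([k, n - k])
    exog = sm.add_constant(n.astype(float))
    try:
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        slope = float(res.params[1])
        se = float(res.bse[1])
    except Exception:
        return float("nan"), float("nan")
    if not np.isfinite(slope) or not np.isfinite(se):
        return float("nan"), float("nan")
    return slope, se
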