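"""Cluster-based permutation comparison of two groups of daily JIDs.

The multiple-comparisons problem of testing 2500 bins is handled
nonparametrically: a two-sample t-statistic is computed per bin, contiguous
supra-threshold bins (cluster-forming p < 0.01, two-sided) are grouped into
signed clusters, and the size of the largest observed cluster is referred to
the distribution of maximal cluster sizes obtained by re-running the whole
procedure under random relabellings of the days.  A cluster whose size
exceeds the 95th percentile of that null distribution is declared
significant; permutation p-values are reported alongside.

Positive and negative supra-threshold bins are clustered separately and the
null statistic is the maximum over both signs, which controls the two-sided
family.  Bins with zero variance in both groups (the perpetually empty JID
corners) are set to t = 0 and excluded from clusters.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, stats

from .errors import IncompatibilityError, InferenceError
from .jid import JID, JIDGrid

logger = logging.getLogger(__name__)

POOLED = "pooled"
WELCH = "welch"

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclass
class TMap:
    """Bin-wise two-sample t-statistics over a JID grid.

    Sign convention: positive t means group A's mean exceeds group B's.
    ``df`` is scalar for the pooled-variance test and a per-bin array for
    Welch.  ``flagged`` marks zero-variance-in-both-groups bins (t forced
    to 0, never clustered).
    """

    grid: JIDGrid
    t_values: np.ndarray
    df: float | np.ndarray
    n_a: int
    n_b: int
    variant: str = POOLED
    flagged: np.ndarray | None = None


@dataclass
class Cluster:
    """A contiguous set of same-sign supra-threshold bins."""

    member_bins: frozenset
    sign: int
    size: int
    p_value: float | None = None
    significant: bool | None = None

    def bounding_box(self, grid: JIDGrid) -> dict[str, float]:
        """Cluster extent in log10-seconds coordinates (bin centers)."""
        rows = [b[0] for b in self.member_bins]
        cols = [b[1] for b in self.member_bins]
        c = grid.centers
        return {
            "iti_k_lo": float(c[min(rows)]),
            "iti_k_hi": float(c[max(rows)]),
            "iti_k1_lo": float(c[min(cols)]),
            "iti_k1_hi": float(c[max(cols)]),
        }


@dataclass
class ClusterTestResult:
    observed_tmap: TMap
    observed_clusters: list[Cluster]
    null_max_sizes: np.ndarray
    threshold_95: float
    B: int
    seed: int | None
    alpha_cluster_forming: float
    connectivity: int
    exhaustive: bool = False

    @property
    def max_observed_size(self) -> int:
        return max((c.size for c in self.observed_clusters), default=0)

    @property
    def any_significant(self) -> bool:
        return any(c.significant for c in self.observed_clusters)

    def null_summary(self) -> dict[str, float]:
        q = np.percentile(self.null_max_sizes, [2.5, 50, 95, 97.5])
        return {
            "median": float(q[1]),
            "q2.5": float(q[0]),
            "q95": float(q[2]),
            "q97.5": float(q[3]),
        }


def _stack(jids: list[JID]) -> tuple[np.ndarray, JIDGrid]:
    grid = jids[0].grid
    for j in jids[1:]:
        if j.grid != grid:
            raise IncompatibilityError("JIDs have mismatched grids")
    return np.stack([j.matrix for j in jids]).reshape(len(jids), -1), grid


def _t_flat(
    sum_a: np.ndarray,
    sumsq_a: np.ndarray,
    sum_t: np.ndarray,
    sumsq_t: np.ndarray,
    n_a: int,
    n_b: int,
    variant: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """t, df, zero-variance flag from group-A and total sufficient statistics."""
    sum_b = sum_t - sum_a
    sumsq_b = sumsq_t - sumsq_a
    mean_a, mean_b = sum_a / n_a, sum_b / n_b
    ss_a = np.maximum(sumsq_a - n_a * mean_a**2, 0.0)
    ss_b = np.maximum(sumsq_b - n_b * mean_b**2, 0.0)
    if variant == POOLED:
        df = float(n_a + n_b - 2)
        sp2 = (ss_a + ss_b) / df
        se2 = sp2 * (1.0 / n_a + 1.0 / n_b)
        df_out: np.ndarray | float = df
    elif variant == WELCH:
        v_a = ss_a / (n_a - 1)
        v_b = ss_b / (n_b - 1)
        se2 = v_a / n_a + v_b / n_b
        with np.errstate(divide="ignore", invalid="ignore"):
            df_out = se2**2 / (
                (v_a / n_a) ** 2 / (n_a - 1) + (v_b / n_b) ** 2 / (n_b - 1)
            )
        df_out = np.where(np.isfinite(df_out), df_out, 1.0)
    else:
        raise InferenceError(f"unknown t-test variant {variant!r}")
    flagged = se2 <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / np.sqrt(se2)
    t[flagged] = 0.0
    return t, df_out, flagged


def binwise_tmap(
    group_a: list[JID], group_b: list[JID], variant: str = POOLED
) -> TMap:
    """Two-sample t-statistic per 2D bin, group A vs group B daily values."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise InferenceError("each group needs at least 2 daily JIDs")
    xa, grid = _stack(group_a)
    xb, grid_b = _stack(group_b)
    if grid != grid_b:
        raise IncompatibilityError("groups live on different grids")
    x = np.concatenate([xa, xb])
    t, df, flagged = _t_flat(
        xa.sum(0), (xa**2).sum(0), x.sum(0), (x**2).sum(0),
        len(group_a), len(group_b), variant,
    )
    n_flag = int(flagged.sum())
    if n_flag:
        logger.info("binwise_tmap: %d zero-variance bin(s) set to t=0", n_flag)
    nb = grid.n_bins
    return TMap(
        grid=grid,
        t_values=t.reshape(nb, nb),
        df=df if np.isscalar(df) else np.asarray(df).reshape(nb, nb),
        n_a=len(group_a),
        n_b=len(group_b),
        variant=variant,
        flagged=flagged.reshape(nb, nb),
    )


def _signed_masks(tmap: TMap, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, tmap.df)
    pos = tmap.t_values > t_crit
    neg = tmap.t_values < -t_crit
    if tmap.flagged is not None:
        pos &= ~tmap.flagged
        neg &= ~tmap.flagged
    return pos, neg


def form_clusters(
    tmap: TMap, alpha: float = 0.01, connectivity: int = 4
) -> list[Cluster]:
    """Connected components of supra-threshold bins, per sign.

    The cluster-forming threshold is the two-sided t critical value at
    ``alpha`` for the map's degrees of freedom; contiguity defaults to
    4-neighbour (edge-sharing).
    """
    if not 0.0 < alpha < 1.0:
        raise InferenceError(f"alpha must lie in (0, 1), got {alpha}")
    structure = _STRUCTURES[connectivity]
    clusters: list[Cluster] = []
    for sign, mask in zip((1, -1), _signed_masks(tmap, alpha)):
        labels, n = ndimage.label(mask, structure=structure)
        for lab in range(1, n + 1):
            rows, cols = np.nonzero(labels == lab)
            members = frozenset(zip(rows.tolist(), cols.tolist()))
            clusters.append(Cluster(member_bins=members, sign=sign, size=len(members)))
    return clusters


def max_cluster_size(clusters: list[Cluster]) -> int:
    """Largest cluster size across both signs; 0 when there are none."""
    return max((c.size for c in clusters), default=0)


def _max_size_from_masks(pos: np.ndarray, neg: np.ndarray, structure) -> int:
    out = 0
    for mask in (pos, neg):
        if mask.any():
            labels, n = ndimage.label(mask, structure=structure)
            if n:
                out = max(out, int(np.bincount(labels.ravel())[1:].max()))
    return out


def permutation_test(
    group_a: list[JID],
    group_b: list[JID],
    B: int = 1000,
    seed: int | None = 0,
    alpha: float = 0.01,
    connectivity: int = 4,
    variant: str = POOLED,
    exhaustive: bool = False,
) -> ClusterTestResult:
    """Max-cluster-size permutation test of group A vs group B daily JIDs.

    For each of ``B`` random relabellings preserving the group sizes, the
    full pipeline (bin-wise t-map, cluster formation at ``alpha``, maximum
    cluster size over both signs) is re-run; observed clusters receive
    ``p = (1 + #{null >= size}) / (B + 1)`` and are flagged significant when
    their size strictly exceeds the 95th percentile of the null.

    With ``exhaustive=True`` all distinct group-A index sets are enumerated
    (feasible for small groups only); ``B`` and ``seed`` are then ignored
    and p-values are exact: ``#{null >= size} / n_splits``.
    """
    tmap = binwise_tmap(group_a, group_b, variant=variant)
    observed = form_clusters(tmap, alpha=alpha, connectivity=connectivity)

    n_a, n_b = len(group_a), len(group_b)
    n = n_a + n_b
    x, _ = _stack(group_a + group_b)
    x2 = x**2
    sum_t, sumsq_t = x.sum(0), x2.sum(0)
    structure = _STRUCTURES[connectivity]
    nb = tmap.grid.n_bins

    def null_stat(idx_a: np.ndarray) -> int:
        t, df, flagged = _t_flat(
            x[idx_a].sum(0), x2[idx_a].sum(0), sum_t, sumsq_t, n_a, n_b, variant
        )
        t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
        tm = t.reshape(nb, nb)
        crit = t_crit if np.isscalar(t_crit) else t_crit.reshape(nb, nb)
        fl = flagged.reshape(nb, nb)
        return _max_size_from_masks(
            (tm > crit) & ~fl, (tm < -crit) & ~fl, structure
        )

    if exhaustive:
        n_splits = math.comb(n, n_a)
        if n_splits > 200_000:
            raise InferenceError(
                f"exhaustive enumeration infeasible: {n_splits} splits"
            )
        null = np.fromiter(
            (
                null_stat(np.asarray(combo, dtype=np.intp))
                for combo in itertools.combinations(range(n), n_a)
            ),
            dtype=np.int64,
            count=n_splits,
        )
        B_eff = n_splits
    else:
        if B < 1:
            raise InferenceError(f"B must be >= 1, got {B}")
        rng = np.random.default_rng(seed)
        null = np.empty(B, dtype=np.int64)
        for b in range(B):
            null[b] = null_stat(rng.permutation(n)[:n_a])
        B_eff = B

    threshold_95 = float(np.percentile(null, 95))
    for c in observed:
        ge = int(np.count_nonzero(null >= c.size))
        c.p_value = ge / B_eff if exhaustive else (1 + ge) / (B_eff + 1)
        c.significant = c.size > threshold_95
    return ClusterTestResult(
        observed_tmap=tmap,
        observed_clusters=observed,
        null_max_sizes=null,
        threshold_95=threshold_95,
        B=B_eff,
        seed=None if exhaustive else seed,
        alpha_cluster_forming=alpha,
        connectivity=connectivity,
        exhaustive=exhaustive,
    )


def result_to_dict(result: ClusterTestResult) -> dict:
    """JSON-serialisable view: cluster table, null summary, full null vector."""
    grid = result.observed_tmap.grid
    return {
        "n_a": result.observed_tmap.n_a,
        "n_b": result.observed_tmap.n_b,
        "variant": result.observed_tmap.variant,
        "alpha_cluster_forming": result.alpha_cluster_forming,
        "connectivity": result.connectivity,
        "B": result.B,
        "seed": result.seed,
        "exhaustive": result.exhaustive,
        "threshold_95": result.threshold_95,
        "null_summary": result.null_summary(),
        "clusters": [
            {
                "sign": c.sign,
                "size": c.size,
                "p_value": c.p_value,
                "significant": bool(c.significant),
                "bounding_box_log10_s": c.bounding_box(grid),
            }
            for c in sorted(
                result.observed_clusters, key=lambda c: -c.size
            )
        ],
        "null_max_sizes": result.null_max_sizes.tolist(),
        "t_map": result.observed_tmap.t_values.tolist(),
        "grid": {
            "lo": grid.lo,
            "hi": grid.hi,
            "n_bins": grid.n_bins,
            "bandwidth": grid.bandwidth,
        },
    }


def write_result(result: ClusterTestResult, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(result_to_dict(result), fh, indent=1)
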