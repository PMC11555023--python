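"""Joint interval distributions (JIDs) of inter-touch intervals.

A JID summarises one day of touchscreen behaviour as a two-dimensional
probability distribution relating each inter-touch interval (ITI) at index
``k`` to the immediately following interval at index ``k+1``.  Both axes are
log10-transformed seconds; short consecutive intervals (fast, fluent
interaction) land in the lower-left corner, rhythmic behaviour on the
diagonal, and long pauses in the upper right.

The estimator follows the standard recipe for this statistic: overlapping
next-interval pairs, an isotropic Gaussian kernel density in log10 space
(bandwidth = kernel standard deviation, default 0.1), evaluated at the
centers of a uniform 50 x 50 grid spanning roughly 30 ms to 100 s, then
normalised to a probability mass (sum 1) or density (integrates to 1 over
log10-area).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, EmptyInputError, IncompatibilityError

logger = logging.getLogger(__name__)

#: Default grid bounds in log10 seconds: 30 ms .. 100 s.
DEFAULT_LO = math.log10(0.03)
DEFAULT_HI = 2.0
DEFAULT_N_BINS = 50
DEFAULT_BANDWIDTH = 0.1

PROBABILITY_MASS = "probability_mass"
DENSITY = "density"


@dataclass(frozen=True)
class JIDGrid:
    """Uniform log10-seconds grid on which JIDs are discretised.

    Parameters
    ----------
    lo, hi : float
        Lower/upper edge in log10 seconds. Defaults cover 30 ms to 100 s.
    n_bins : int
        Bins per dimension (default 50).
    bandwidth : float
        Standard deviation of the isotropic Gaussian smoothing kernel, in
        log10 units (default 0.1).
    """

    lo: float = DEFAULT_LO
    hi: float = DEFAULT_HI
    n_bins: int = DEFAULT_N_BINS
    bandwidth: float = DEFAULT_BANDWIDTH

    def __post_init__(self) -> None:
        if not self.hi > self.lo:
            raise DomainError(f"grid needs hi > lo, got [{self.lo}, {self.hi}]")
        if self.n_bins < 2:
            raise DomainError(f"grid needs n_bins >= 2, got {self.n_bins}")
        if not self.bandwidth > 0:
            raise DomainError(f"bandwidth must be > 0, got {self.bandwidth}")

    @property
    def bin_width(self) -> float:
        return (self.hi - self.lo) / self.n_bins

    @property
    def edges(self) -> np.ndarray:
        """``n_bins + 1`` uniform bin edges."""
        return self.lo + np.arange(self.n_bins + 1) * self.bin_width

    @property
    def centers(self) -> np.ndarray:
        """Bin centers, where the kernel density is evaluated."""
        return self.lo + (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)


@dataclass
class JID:
    """A discretised joint interval distribution.

    ``matrix[i, j]`` holds the mass/density at log10(ITI_k) = centers[i]
    (rows, axis 0) and log10(ITI_{k+1}) = centers[j] (columns, axis 1).
    """

    grid: JIDGrid
    matrix: np.ndarray
    n_pairs: int
    normalization: str = PROBABILITY_MASS

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.grid.n_bins, self.grid.n_bins):
            raise IncompatibilityError(
                f"matrix shape {self.matrix.shape} does not match grid "
                f"({self.grid.n_bins} x {self.grid.n_bins})"
            )


@dataclass
class DifferenceMap:
    """Signed element-wise difference of two JIDs on a shared grid."""

    grid: JIDGrid
    matrix: np.ndarray
    label: str = ""

    def quadrant_mass(self) -> dict[str, float]:
        """Net signed mass by quadrant around the grid midpoint.

        ``fast_fast`` is the lower-left quadrant (both intervals below the
        midpoint), ``slow_slow`` the upper-right, ``mixed`` the rest.  A
        reporting convention, not a fitted quantity.
        """
        mid = self.grid.midpoint
        below = self.grid.centers < mid
        ff = float(self.matrix[np.ix_(below, below)].sum())
        ss = float(self.matrix[np.ix_(~below, ~below)].sum())
        total = float(self.matrix.sum())
        return {"fast_fast": ff, "slow_slow": ss, "mixed": total - ff - ss}


def make_pairs(itis: np.ndarray) -> np.ndarray:
    """Overlapping next-interval pairs (x_1,x_2), (x_2,x_3), ...

    Parameters
    ----------
    itis : array-like of float
        Inter-touch intervals in seconds; all strictly positive.

    Returns
    -------
    ndarray of shape (max(len(itis)-1, 0), 2)
    """
    itis = np.asarray(itis, dtype=float)
    if itis.size and np.any(itis <= 0):
        raise DomainError("all ITIs must be > 0 (log10 undefined otherwise)")
    if itis.size < 2:
        return np.empty((0, 2))
    return np.column_stack([itis[:-1], itis[1:]])


def compute_jid(
    pairs: np.ndarray,
    grid: JIDGrid | None = None,
    normalization: str = PROBABILITY_MASS,
) -> JID:
    """Estimate a JID from next-interval pairs by 2D Gaussian KDE.

    The density is the mean over pairs of isotropic 2D Gaussians
    (sd = ``grid.bandwidth`` on both axes, no cross-term) centred at the
    log10-transformed pair, evaluated at the grid's bin centers.  Pairs may
    lie outside the grid; their kernel mass simply falls off the grid before
    renormalisation (no clipping).

    Parameters
    ----------
    pairs : ndarray (n, 2)
        Strictly positive ITI pairs in seconds.
    grid : JIDGrid, optional
        Grid and bandwidth; defaults to the standard 50 x 50, bw 0.1.
    normalization : {"probability_mass", "density"}
        ``probability_mass``: entries sum to 1.  ``density``: entries sum to
        1 / bin_area, i.e. the matrix integrates to 1 over log10-area.
    """
    if grid is None:
        grid = JIDGrid()
    pairs = np.asarray(pairs, dtype=float)
    if pairs.size == 0:
        raise EmptyInputError("compute_jid requires at least one ITI pair")
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise DomainError(f"pairs must have shape (n, 2), got {pairs.shape}")
    if np.any(pairs <= 0):
        raise DomainError("all ITIs must be > 0 (log10 undefined otherwise)")
    if normalization not in (PROBABILITY_MASS, DENSITY):
        raise DomainError(f"unknown normalization {normalization!r}")

    lx = np.log10(pairs[:, 0])
    ly = np.log10(pairs[:, 1])
    bw = grid.bandwidth
    off = 5.0 * bw
    inside = (
        (lx > grid.lo - off) & (lx < grid.hi + off)
        & (ly > grid.lo - off) & (ly < grid.hi + off)
    )
    if not np.any(inside):
        logger.warning(
            "degenerate density: all %d pairs lie > 5 sd outside the grid",
            pairs.shape[0],
        )

    c = grid.centers
    # separable isotropic kernel: matrix[a, b] = sum_i gx[i, a] * gy[i, b]
    gx = np.exp(-0.5 * ((c[None, :] - lx[:, None]) / bw) ** 2)
    gy = np.exp(-0.5 * ((c[None, :] - ly[:, None]) / bw) ** 2)
    raw = gx.T @ gy
    raw /= pairs.shape[0] * 2.0 * math.pi * bw * bw  # mean kernel density

    total = raw.sum()
    if total > 0:
        if normalization == PROBABILITY_MASS:
            matrix = raw / total
        else:
            matrix = raw / (total * grid.bin_width**2)
    else:
        matrix = raw
    return JID(grid=grid, matrix=matrix, n_pairs=pairs.shape[0],
               normalization=normalization)


def _check_compatible(jids: list[JID]) -> None:
    g0, n0 = jids[0].grid, jids[0].normalization
    for j in jids[1:]:
        if j.grid != g0:
            raise IncompatibilityError("JIDs have mismatched grids")
        if j.normalization != n0:
            raise IncompatibilityError("JIDs have mismatched normalizations")


def average_jid(jids: list[JID]) -> JID:
    """Element-wise unweighted mean of JIDs sharing a grid and normalization.

    ``n_pairs`` of the result is the sum of the inputs' pair counts; a
    probability-mass average still sums to 1.
    """
    if not jids:
        raise EmptyInputError("average_jid requires at least one JID")
    _check_compatible(jids)
    matrix = np.mean([j.matrix for j in jids], axis=0)
    return JID(
        grid=jids[0].grid,
        matrix=matrix,
        n_pairs=int(sum(j.n_pairs for j in jids)),
        normalization=jids[0].normalization,
    )


def jid_difference(a: JID, b: JID, label: str = "") -> DifferenceMap:
    """Signed difference map ``a - b``; sums to 0 for probability-mass inputs."""
    _check_compatible([a, b])
    return DifferenceMap(grid=a.grid, matrix=a.matrix - b.matrix, label=label)
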