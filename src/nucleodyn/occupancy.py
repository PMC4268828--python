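"""Windowed differential nucleosome occupancy with an empirical inert-region null.

The genome is tiled with non-overlapping windows of constant size.  For two
MNase-seq time points with per-window fragment counts ``r_i`` (earlier, t1)
and ``s_i`` (later, t2), each window gets a depth-normalized log-ratio

    q_i = log2( (r_i + c) / (s~_i + c) ),    s~_i = s_i * R_tot / S_tot,

where ``c`` is a pseudocount and ``s~_i`` rescales the t2 counts to the t1
library depth, so uniform depth changes cancel exactly.  The statistic is
centred by subtracting its mean over scored windows, ``||q_i|| = q_i − Q_mean``.
Under the null that a window merely fluctuates stochastically, the centred
values from transcriptionally inert windows (no expressed gene, negligible
RNA signal) provide an empirical distribution ``N_cum``; the one-sided
p-value of a window is the tail probability of its centred value under that
distribution.  Positive centred values mean fewer fragments at the later
time point — nucleosome *depletion*; negative values mean *enrichment*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import GenomeIndex

__all__ = [
    "WindowGrid",
    "InertNull",
    "LLRResult",
    "tile_genome",
    "count_in_windows",
    "log_ratio",
    "center",
    "build_null",
    "empirical_pvalue",
    "label_windows",
    "running_mean",
    "select_inert_windows",
    "differential_occupancy",
]

LABELS = ("depleted", "enriched", "unchanged", "low_coverage")


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping constant-size tiling of a genome.

    Terminal remainder windows (shorter than ``window_size``) are kept and
    flagged ``partial``.
    """

    index: GenomeIndex
    window_size: int
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    partial: np.ndarray

    @property
    def n(self) -> int:
        return len(self.starts)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "partial": self.partial,
            }
        )


def tile_genome(index: GenomeIndex, window_size: int) -> WindowGrid:
    """Tile every chromosome from 0 with non-overlapping windows."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    partial: list[bool] = []
    for name, length in zip(index.names, index.lengths):
        edges = list(range(0, length, window_size)) + [length]
        for a, b in zip(edges[:-1], edges[1:]):
            chroms.append(name)
            starts.append(a)
            ends.append(b)
            partial.append(b - a < window_size)
    return WindowGrid(
        index=index,
        window_size=window_size,
        chroms=np.asarray(chroms, dtype=object),
        starts=np.asarray(starts, dtype=np.int64),
        ends=np.asarray(ends, dtype=np.int64),
        partial=np.asarray(partial, dtype=bool),
    )


def count_in_windows(midpoints: dict[str, np.ndarray], grid: WindowGrid) -> np.ndarray:
    """Count fragment midpoints per window (half-open assignment).

    The sum of the returned vector equals the number of midpoints on
    chromosomes of the grid; a midpoint at or beyond a chromosome end is an
    error.
    """
    counts = np.zeros(grid.n, dtype=np.int64)
    for chrom in np.unique(grid.chroms):
        mids = midpoints.get(chrom)
        if mids is None or len(mids) == 0:
            continue
        length = grid.index.length(chrom)
        if mids.min() < 0 or mids.max() >= length:
            raise ValueError(f"midpoint outside chromosome {chrom} (length {length})")
        sel = np.flatnonzero(grid.chroms == chrom)
        # windows tile from 0, so the window index is a searchsorted on ends
        idx = np.searchsorted(grid.ends[sel], mids, side="right")
        counts[sel] += np.bincount(idx, minlength=len(sel))
    return counts


def log_ratio(
    r: np.ndarray,
    s: np.ndarray,
    pseudocount: float = 0.5,
    min_count: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window depth-normalized log2 ratio and low-coverage mask.

    The t2 counts are rescaled to the t1 library depth before the
    pseudocount is applied, which makes the statistic exactly invariant to
    uniform scaling of either library.  Windows with ``r_i + s_i <
    min_count`` are masked ``low_coverage`` and take no part in centring,
    the null, or labelling.
    """
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    if r.shape != s.shape:
        raise ValueError("count vectors differ in length")
    if np.any(r < 0) or np.any(s < 0):
        raise ValueError("counts must be nonnegative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    r_tot, s_tot = r.sum(), s.sum()
    scale = r_tot / s_tot if s_tot > 0 else 1.0
    s_norm = s * scale
    # the coverage floor is applied on the depth-normalized scale so that
    # uniform library scaling cannot move windows across the mask boundary
    low = (r + s_norm) < min_count
    if pseudocount == 0 and np.any((r[~low] == 0) | (s[~low] == 0)):
        raise ValueError("pseudocount 0 with zero counts in unmasked windows")
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.log2(r + pseudocount) - np.log2(s_norm + pseudocount)
    q[low & ~np.isfinite(q)] = 0.0
    return q, low


def center(q: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Subtract the mean of the unmasked values (``||Q|| = Q − Q_mean``)."""
    q = np.asarray(q, dtype=float)
    if mask is None:
        mask = np.zeros(len(q), dtype=bool)
    if mask.all():
        raise ValueError("all windows masked; nothing to centre")
    return q - q[~mask].mean()


@dataclass(frozen=True)
class InertNull:
    """Empirical null: sorted centred values from transcriptionally inert windows."""

    values: np.ndarray  # sorted ascending
    inert_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    @property
    def n(self) -> int:
        return len(self.values)

    def cdf(self, x) -> np.ndarray:
        """Empirical CDF N_cum(x) = P(value <= x)."""
        return np.searchsorted(self.values, np.asarray(x, dtype=float), side="right") / self.n


def build_null(
    centered: np.ndarray,
    inert_mask: np.ndarray,
    low_mask: np.ndarray | None = None,
    min_inert: int = 100,
) -> InertNull:
    """Build the empirical null from inert, adequately covered windows."""
    inert_mask = np.asarray(inert_mask, dtype=bool)
    usable = inert_mask if low_mask is None else (inert_mask & ~np.asarray(low_mask, bool))
    idx = np.flatnonzero(usable)
    if len(idx) < min_inert:
        raise ValueError(
            f"only {len(idx)} inert windows (need >= {min_inert}); "
            "supply more data or a smaller window size"
        )
    values = np.sort(np.asarray(centered, dtype=float)[idx])
    if values[0] == values[-1]:
        raise ValueError("degenerate null: all inert values identical")
    return InertNull(values=values, inert_index=idx)


def empirical_pvalue(centered, null: InertNull, side: str) -> np.ndarray:
    """One-sided empirical p-value with add-one rank smoothing.

    ``depletion_at_t2`` is the right tail of the centred statistic (the
    sign convention puts the earlier time point in the numerator, so a
    loss of fragments at t2 pushes the value up);
    ``enrichment_at_t2`` is the symmetric left tail.  p = (1 + #{null
    beyond the observed value}) / (1 + m); never exactly 0.
    """
    x = np.asarray(centered, dtype=float)
    m = null.n
    if side == "depletion_at_t2":
        beyond = m - np.searchsorted(null.values, x, side="left")  # null >= x
    elif side == "enrichment_at_t2":
        beyond = np.searchsorted(null.values, x, side="right")  # null <= x
    else:
        raise ValueError(f"invalid side {side!r}")
    return (1.0 + beyond) / (1.0 + m)


def _bh_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini–Hochberg step-up over the given p-values."""
    n = len(p)
    if n == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = alpha * (np.arange(1, n + 1) / n)
    passing = np.flatnonzero(ranked <= thresh)
    reject = np.zeros(n, dtype=bool)
    if len(passing):
        k = passing[-1]
        reject[order[: k + 1]] = True
    return reject


def label_windows(
    p_right: np.ndarray,
    p_left: np.ndarray,
    alpha: float = 0.05,
    correction: str = "bh",
    low_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Classify windows as depleted / enriched / unchanged / low_coverage."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    p_right = np.asarray(p_right, dtype=float)
    p_left = np.asarray(p_left, dtype=float)
    n = len(p_right)
    if low_mask is None:
        low_mask = np.zeros(n, dtype=bool)
    scored = ~low_mask
    if correction == "bh":
        sig_r = np.zeros(n, dtype=bool)
        sig_l = np.zeros(n, dtype=bool)
        sig_r[scored] = _bh_reject(p_right[scored], alpha)
        sig_l[scored] = _bh_reject(p_left[scored], alpha)
    elif correction == "none":
        sig_r = scored & (p_right < alpha)
        sig_l = scored & (p_left < alpha)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    # opposite tails of one value cannot both be extreme at alpha <= 0.5
    assert not np.any(sig_r & sig_l), "both tails significant for one window"
    labels = np.full(n, "unchanged", dtype=object)
    labels[sig_r] = "depleted"
    labels[sig_l] = "enriched"
    labels[low_mask] = "low_coverage"
    return labels


def running_mean(
    values: np.ndarray, span: int, chroms: np.ndarray | None = None
) -> np.ndarray:
    """Centred moving average; edges shrink to the available neighbours.

    When *chroms* is given the average never crosses a chromosome boundary.
    """
    if span < 1 or span % 2 == 0:
        raise ValueError("span must be odd and >= 1")
    values = np.asarray(values, dtype=float)
    if chroms is not None:
        out = np.empty_like(values)
        chroms = np.asarray(chroms)
        # chromosome blocks are contiguous in grid order
        change = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
        for a, b in zip(np.r_[0, change], np.r_[change, len(values)]):
            out[a:b] = running_mean(values[a:b], span)
        return out
    half = span // 2
    csum = np.cumsum(np.r_[0.0, values])
    n = len(values)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def select_inert_windows(
    grid: WindowGrid,
    expressed_genes: pd.DataFrame | None = None,
    rna_midpoints: dict[str, np.ndarray] | None = None,
    max_rna_per_kbp: float = 1.0,
) -> np.ndarray:
    """Mask of transcriptionally inert windows.

    A window is inert when it overlaps no expressed gene and (when RNA-seq
    midpoints are supplied) carries fewer than *max_rna_per_kbp* reads per
    kilobase.
    """
    inert = np.ones(grid.n, dtype=bool)
    if expressed_genes is not None and len(expressed_genes):
        for chrom, sub in expressed_genes.groupby("chrom", sort=False):
            sel = np.flatnonzero(grid.chroms == chrom)
            if not len(sel):
                continue
            gs = np.sort(sub["start"].to_numpy())
            ge = sub["end"].to_numpy()[np.argsort(sub["start"].to_numpy(), kind="stable")]
            # overlap test: some gene with start < window_end and end > window_start
            for i in sel:
                j = np.searchsorted(gs, grid.ends[i], side="left")
                if np.any(ge[:j] > grid.starts[i]):
                    inert[i] = False
    if rna_midpoints is not None:
        rna = count_in_windows(rna_midpoints, grid)
        kbp = (grid.ends - grid.starts) / 1000.0
        inert &= rna / np.maximum(kbp, 1e-9) < max_rna_per_kbp
    return inert


def inert_mask_from_regions(grid: WindowGrid, regions: pd.DataFrame) -> np.ndarray:
    """Mask of windows entirely contained in a set of inert regions."""
    mask = np.zeros(grid.n, dtype=bool)
    for chrom, sub in regions.groupby("chrom", sort=False):
        sel = np.flatnonzero(grid.chroms == chrom)
        if not len(sel):
            continue
        sub = sub.sort_values("start")
        rs = sub["start"].to_numpy()
        re_ = sub["end"].to_numpy()
        j = np.searchsorted(rs, grid.starts[sel], side="right") - 1
        ok = (j >= 0) & (grid.ends[sel] <= re_[np.maximum(j, 0)])
        mask[sel] = ok
    return mask


@dataclass
class LLRResult:
    """Per-window differential occupancy result on one grid."""

    grid: WindowGrid
    r: np.ndarray
    s: np.ndarray
    q: np.ndarray
    centered: np.ndarray
    p_right: np.ndarray  # depletion at t2
    p_left: np.ndarray  # enrichment at t2
    label: np.ndarray
    low_mask: np.ndarray
    inert_mask: np.ndarray
    null: InertNull
    q_mean: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.grid.chroms,
                "start": self.grid.starts,
                "end": self.grid.ends,
                "count_t1": self.r,
                "count_t2": self.s,
                "q": self.q,
                "centered": self.centered,
                "p_depletion": self.p_right,
                "p_enrichment": self.p_left,
                "label": self.label,
                "inert": self.inert_mask,
            }
        )

    @property
    def fold_change_track(self) -> np.ndarray:
        """log2 fold-change of the later vs. the earlier time point (−centred)."""
        return -self.centered


def differential_occupancy(
    midpoints_t1: dict[str, np.ndarray],
    midpoints_t2: dict[str, np.ndarray],
    grid: WindowGrid,
    inert_mask: np.ndarray | None = None,
    pseudocount: float = 0.5,
    min_count: int = 20,
    alpha: float = 0.05,
    correction: str = "bh",
    min_inert: int = 100,
) -> LLRResult:
    """Run the whole statistic on one window grid.

    When *inert_mask* is None every adequately covered window feeds the
    null (appropriate only when no annotation is available; a warning is
    emitted).
    """
    r = count_in_windows(midpoints_t1, grid)
    s = count_in_windows(midpoints_t2, grid)
    q, low = log_ratio(r, s, pseudocount=pseudocount, min_count=min_count)
    centered = center(q, low)
    if inert_mask is None:
        warnings.warn(
            "no inert annotation supplied; using all scored windows as the null",
            stacklevel=2,
        )
        inert_mask = np.ones(grid.n, dtype=bool)
    null = build_null(centered, inert_mask, low, min_inert=min_inert)
    p_right = empirical_pvalue(centered, null, "depletion_at_t2")
    p_left = empirical_pvalue(centered, null, "enrichment_at_t2")
    label = label_windows(p_right, p_left, alpha=alpha, correction=correction, low_mask=low)
    return LLRResult(
        grid=grid,
        r=r,
        s=s,
        q=q,
        centered=centered,
        p_right=p_right,
        p_left=p_left,
        label=label,
        low_mask=low,
        inert_mask=np.asarray(inert_mask, dtype=bool),
        null=null,
        q_mean=float(q[~low].mean()),
    )
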