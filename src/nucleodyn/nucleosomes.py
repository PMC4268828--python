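"""Single-nucleosome dyad calling and repositioning classification.

Fragment midpoints of a mononucleosome library are centred on nucleosome
dyads, so a kernel-smoothed midpoint density peaks at dyad positions.  Dyads
are called greedily from local maxima with a minimum separation of one
nucleosome footprint (147 bp), matched between time points by mutual nearest
neighbours within half a footprint (73 bp), and classified *repositioned*
when the matched dyad moved by more than 10 bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "DyadDensity",
    "dyad_density",
    "call_dyads",
    "match_calls",
    "unmasked_regions",
    "SHIFT_THRESHOLD",
]

SHIFT_THRESHOLD = 10  # bp; a matched dyad that moved by more than this is repositioned
MATCH_RADIUS = 73  # bp; half a nucleosome footprint
MIN_SEPARATION = 147  # bp; one nucleosome footprint


@dataclass(frozen=True)
class DyadDensity:
    """Kernel-smoothed midpoint density on one chromosome.

    ``values[i]`` is the density at genomic position ``offset + i``.  The
    support is padded past the outermost midpoints so the kernel mass is
    conserved (total mass equals the number of midpoints).
    """

    chrom: str
    offset: int
    values: np.ndarray

    @property
    def positions(self) -> np.ndarray:
        return self.offset + np.arange(len(self.values))


def dyad_density(
    midpoints: np.ndarray, bandwidth: float = 30.0, chrom: str = "chr"
) -> DyadDensity:
    """Gaussian-kernel smoothed per-bp midpoint density."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    midpoints = np.asarray(midpoints, dtype=np.int64)
    if len(midpoints) == 0:
        return DyadDensity(chrom=chrom, offset=0, values=np.zeros(0))
    pad = int(np.ceil(6 * bandwidth))
    lo = int(midpoints.min()) - pad
    hi = int(midpoints.max()) + pad + 1
    counts = np.bincount(midpoints - lo, minlength=hi - lo).astype(float)
    values = gaussian_filter1d(counts, sigma=bandwidth, mode="constant", truncate=6.0)
    return DyadDensity(chrom=chrom, offset=lo, values=values)


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of local maxima; the left edge of a plateau wins."""
    if len(values) < 3:
        return np.zeros(0, dtype=np.int64)
    inner = np.flatnonzero((values[1:-1] > values[:-2]) & (values[1:-1] >= values[2:])) + 1
    return inner


def call_dyads(
    density: DyadDensity,
    min_separation: int = MIN_SEPARATION,
    min_height: float = 0.0,
) -> pd.DataFrame:
    """Greedy dyad calls from density maxima.

    Maxima are accepted in order of descending height (ties to the leftmost
    coordinate); any maximum closer than *min_separation* to an accepted
    call is suppressed.  Returns a frame with columns ``chrom``, ``dyad``,
    ``height`` sorted by position.
    """
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    peaks = _local_maxima(density.values)
    if len(peaks) == 0:
        return pd.DataFrame(columns=["chrom", "dyad", "height"])
    heights = density.values[peaks]
    keep = heights >= min_height
    peaks, heights = peaks[keep], heights[keep]
    order = np.lexsort((peaks, -heights))  # height desc, then position asc
    accepted: list[int] = []
    acc_sorted: list[int] = []  # kept sorted for O(log n) proximity checks
    import bisect

    for i in order:
        pos = int(peaks[i])
        j = bisect.bisect_left(acc_sorted, pos)
        if j > 0 and pos - acc_sorted[j - 1] < min_separation:
            continue
        if j < len(acc_sorted) and acc_sorted[j] - pos < min_separation:
            continue
        bisect.insort(acc_sorted, pos)
        accepted.append(i)
    idx = np.asarray(sorted(accepted, key=lambda i: peaks[i]), dtype=np.int64)
    return pd.DataFrame(
        {
            "chrom": density.chrom,
            "dyad": (peaks[idx] + density.offset).astype(np.int64),
            "height": density.values[peaks[idx]],
        }
    )


def _nearest(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """For each element of *a*, the index of the nearest element of sorted *b*.

    Ties (equidistant neighbours) resolve to the left neighbour.
    """
    j = np.searchsorted(b, a)
    j_left = np.clip(j - 1, 0, len(b) - 1)
    j_right = np.clip(j, 0, len(b) - 1)
    d_left = np.abs(a - b[j_left])
    d_right = np.abs(a - b[j_right])
    return np.where(d_left <= d_right, j_left, j_right)


def match_calls(
    calls_t0: pd.DataFrame,
    calls_t: pd.DataFrame,
    max_match: int = MATCH_RADIUS,
    shift_threshold: int = SHIFT_THRESHOLD,
) -> pd.DataFrame:
    """Mutual-nearest-neighbour matching of dyad calls between time points.

    Matched pairs within *max_match* bp get status ``stable`` or
    ``repositioned`` (shift strictly greater than *shift_threshold*);
    unmatched t0 calls are ``lost`` and unmatched t calls ``gained``.
    """
    a = np.sort(calls_t0["dyad"].to_numpy(dtype=np.int64))
    b = np.sort(calls_t["dyad"].to_numpy(dtype=np.int64))
    chrom = None
    for frame in (calls_t0, calls_t):
        if len(frame):
            chroms = frame["chrom"].unique()
            if len(chroms) > 1:
                raise ValueError("match_calls works on one chromosome at a time")
            chrom = chroms[0]
    rows = []
    if len(a) and len(b):
        nn_ab = _nearest(a, b)
        nn_ba = _nearest(b, a)
        mutual = nn_ba[nn_ab] == np.arange(len(a))
        close = np.abs(a - b[nn_ab]) <= max_match
        matched_a = mutual & close
        matched_b = np.zeros(len(b), dtype=bool)
        matched_b[nn_ab[matched_a]] = True
    elif len(a):
        matched_a = np.zeros(len(a), dtype=bool)
        matched_b = np.zeros(0, dtype=bool)
    else:
        matched_a = np.zeros(0, dtype=bool)
        matched_b = np.zeros(len(b), dtype=bool)
    for i in np.flatnonzero(matched_a):
        j = nn_ab[i]
        shift = int(abs(a[i] - b[j]))
        rows.append(
            {
                "chrom": chrom,
                "dyad_t0": int(a[i]),
                "dyad_t": int(b[j]),
                "shift": shift,
                "status": "repositioned" if shift > shift_threshold else "stable",
            }
        )
    for i in np.flatnonzero(~matched_a):
        rows.append(
            {"chrom": chrom, "dyad_t0": int(a[i]), "dyad_t": -1, "shift": -1, "status": "lost"}
        )
    for j in np.flatnonzero(~matched_b):
        rows.append(
            {"chrom": chrom, "dyad_t0": -1, "dyad_t": int(b[j]), "shift": -1, "status": "gained"}
        )
    df = pd.DataFrame(rows, columns=["chrom", "dyad_t0", "dyad_t", "shift", "status"])
    anchor = df["dyad_t0"].where(df["dyad_t0"] >= 0, df["dyad_t"])
    return df.loc[anchor.sort_values(kind="stable").index].reset_index(drop=True)


def unmasked_regions(events: pd.DataFrame, flank: int = MATCH_RADIUS) -> pd.DataFrame:
    """Differentially unmasked regions: ±flank around repositioned/lost dyads.

    Returns merged half-open intervals ``[dyad − flank, dyad + flank + 1)``.
    """
    sel = events[events["status"].isin(("repositioned", "lost"))]
    if sel.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    rows = []
    for chrom, sub in sel.groupby("chrom", sort=False):
        dyads = np.sort(sub["dyad_t0"].to_numpy())
        starts = np.maximum(dyads - flank, 0)
        ends = dyads + flank + 1
        merged_s, merged_e = [starts[0]], [ends[0]]
        for st, en in zip(starts[1:], ends[1:]):
            if st <= merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], en)
            else:
                merged_s.append(st)
                merged_e.append(en)
        for st, en in zip(merged_s, merged_e):
            rows.append({"chrom": chrom, "start": int(st), "end": int(en)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
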