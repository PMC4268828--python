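"""Gene classification from two-time-point counts and length-scaled metagenes.

Genes are classed *up* (log2 fold-change > 0.6), *down* (< −0.6) or
*constitutive* (within ±0.01) on median-of-ratios-normalized counts, with a
floor of >100 reads per gene at each time point; everything else is
*unclassified*.  The metagene aggregates MNase fragment midpoints over a
gene class: gene bodies are cut into 50-bp windows, each gene's window
vector is linearly rescaled onto a fixed number of body bins, 5-kbp flanks
are kept in absolute 50-bp bins, minus-strand genes are reversed so the TSS
is always on the left, and bins are summed over genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GeneClassTable", "classify_genes", "MetageneProfile", "scaled_profile"]

UP_CUT = 0.6
DOWN_CUT = -0.6
CONST_BAND = 0.01
MIN_READS = 100


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """DESeq-style median-of-ratios size factors for an (genes × samples) array."""
    if np.any(counts.sum(axis=0) == 0):
        raise ValueError("a library has zero total counts")
    pos = np.all(counts > 0, axis=1)
    if not pos.any():
        raise ValueError("no gene has positive counts in every library")
    log_geo = np.log(counts[pos]).mean(axis=1, keepdims=True)
    return np.exp(np.median(np.log(counts[pos]) - log_geo, axis=0))


@dataclass
class GeneClassTable:
    """Per-gene class, log2 fold-change and totals."""

    table: pd.DataFrame  # gene, count_t1, count_t2, log2fc, gene_class
    size_factors: np.ndarray

    def genes_in(self, gene_class: str) -> pd.Series:
        return self.table.loc[self.table["gene_class"] == gene_class, "gene"]


def classify_genes(
    counts_t1: pd.Series | np.ndarray,
    counts_t2: pd.Series | np.ndarray,
    genes: pd.Series | None = None,
    up_cut: float = UP_CUT,
    down_cut: float = DOWN_CUT,
    const_band: float = CONST_BAND,
    min_reads: int = MIN_READS,
) -> GeneClassTable:
    """Threshold classification of genes on normalized two-time-point counts."""
    c1 = np.asarray(counts_t1, dtype=float)
    c2 = np.asarray(counts_t2, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("count vectors differ in length")
    if np.any(c1 < 0) or np.any(c2 < 0):
        raise ValueError("counts must be nonnegative")
    sf = _size_factors(np.column_stack([c1, c2]))
    n1, n2 = c1 / sf[0], c2 / sf[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(n2) - np.log2(n1)
    expressed = (c1 > min_reads) & (c2 > min_reads)
    cls = np.full(len(c1), "unclassified", dtype=object)
    cls[expressed & (log2fc > up_cut)] = "up"
    cls[expressed & (log2fc < down_cut)] = "down"
    cls[expressed & (np.abs(log2fc) <= const_band)] = "constitutive"
    names = (
        pd.Series(genes).reset_index(drop=True)
        if genes is not None
        else pd.Series([f"gene_{i}" for i in range(len(c1))])
    )
    table = pd.DataFrame(
        {
            "gene": names,
            "count_t1": c1.astype(np.int64),
            "count_t2": c2.astype(np.int64),
            "log2fc": log2fc,
            "gene_class": cls,
        }
    )
    return GeneClassTable(table=table, size_factors=sf)


@dataclass
class MetageneProfile:
    """Summed midpoint counts on the TSS→TTS axis.

    ``bins`` has length ``flank_bins + body_bins + flank_bins``; flank bins
    are absolute 50-bp windows, body bins are proportional gene-body
    coordinates.  ``flank_coverage`` counts, per bin, how many genes
    contributed a non-truncated flank window there.
    """

    bins: np.ndarray
    flank_bins: int
    body_bins: int
    n_genes: int
    flank_coverage: np.ndarray

    @property
    def upstream(self) -> np.ndarray:
        return self.bins[: self.flank_bins]

    @property
    def body(self) -> np.ndarray:
        return self.bins[self.flank_bins : self.flank_bins + self.body_bins]

    @property
    def downstream(self) -> np.ndarray:
        return self.bins[self.flank_bins + self.body_bins :]

    def per_million(self, library_size: int) -> np.ndarray:
        return self.bins * 1e6 / library_size


def _bin_counts(mids: np.ndarray, lo: float, hi: float, nbins: int) -> np.ndarray:
    """Counts of midpoints in nbins equal half-open bins over [lo, hi)."""
    sel = mids[(mids >= lo) & (mids < hi)]
    if len(sel) == 0:
        return np.zeros(nbins)
    idx = ((sel - lo) * nbins / (hi - lo)).astype(np.int64)
    return np.bincount(np.clip(idx, 0, nbins - 1), minlength=nbins).astype(float)


def scaled_profile(
    midpoints: dict[str, np.ndarray],
    genes: pd.DataFrame,
    body_bins: int = 100,
    flank: int = 5_000,
    flank_bin: int = 50,
    chrom_lengths: dict[str, int] | None = None,
) -> MetageneProfile:
    """Metagene over a gene set: scaled body, absolute flanks, TSS left.

    Gene bodies shorter than *body_bins* bp are skipped with a warning.
    Flank windows that would run off the chromosome are masked (contribute
    nothing and are excluded from ``flank_coverage``).
    """
    if len(genes) == 0:
        raise ValueError("empty gene set")
    flank_bins = flank // flank_bin
    total = np.zeros(flank_bins + body_bins + flank_bins)
    coverage = np.zeros_like(total)
    n_used = 0
    n_skipped = 0
    for rec in genes.itertuples(index=False):
        length = rec.end - rec.start
        if length < body_bins:
            n_skipped += 1
            continue
        mids = midpoints.get(rec.chrom, np.zeros(0, dtype=np.int64))
        chrom_len = chrom_lengths.get(rec.chrom) if chrom_lengths else None

        # body: ~50-bp windows tiling the body, rescaled onto body_bins
        n_body_windows = max(length // flank_bin, 1)
        body = _bin_counts(mids, rec.start, rec.end, n_body_windows)
        if n_body_windows == body_bins:
            body_scaled = body
        else:
            src = np.linspace(0.0, 1.0, n_body_windows)
            dst = np.linspace(0.0, 1.0, body_bins)
            if n_body_windows == 1:
                body_scaled = np.full(body_bins, body[0])
            else:
                # rescale densities; preserve per-window density shape
                body_scaled = np.interp(dst, src, body)

        up = _bin_counts(mids, rec.start - flank, rec.start, flank_bins)
        down = _bin_counts(mids, rec.end, rec.end + flank, flank_bins)
        up_ok = np.ones(flank_bins, dtype=bool)
        down_ok = np.ones(flank_bins, dtype=bool)
        if rec.start - flank < 0:
            n_bad = int(np.ceil((flank - rec.start) / flank_bin))
            up_ok[:n_bad] = False
            up[:n_bad] = 0.0
        if chrom_len is not None and rec.end + flank > chrom_len:
            n_bad = int(np.ceil((rec.end + flank - chrom_len) / flank_bin))
            down_ok[flank_bins - n_bad :] = False
            down[flank_bins - n_bad :] = 0.0

        if rec.strand == "-":
            vec = np.concatenate([down[::-1], body_scaled[::-1], up[::-1]])
            cov = np.concatenate([down_ok[::-1], np.ones(body_bins), up_ok[::-1]])
        else:
            vec = np.concatenate([up, body_scaled, down])
            cov = np.concatenate([up_ok, np.ones(body_bins), down_ok])
        total += vec
        coverage += cov
        n_used += 1
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} genes shorter than {body_bins} bp", stacklevel=2)
    if n_used == 0:
        raise ValueError("no gene long enough for the requested body bins")
    return MetageneProfile(
        bins=total,
        flank_bins=flank_bins,
        body_bins=body_bins,
        n_genes=n_used,
        flank_coverage=coverage,
    )
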