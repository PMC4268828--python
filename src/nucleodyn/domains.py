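"""Multi-scale depletion domains, peak embedding, annotation and association.

Depletion/enrichment calling is repeated over a ladder of window sizes
(5/25/50/100 kbp by default) to expose kilobase- to megabase-scale domains.
TF peaks are called *embedded* in the depleted domains when at least a
fraction of their length is covered; embedded fractions for two interval
sets are compared with Fisher's exact test.  A consensus-motif scanner
counts NF-κB-style IUPAC matches inside and outside domains.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from . import occupancy
from .occupancy import LLRResult, tile_genome

__all__ = [
    "multiscale_domains",
    "domains_bed",
    "merge_intervals",
    "overlap_embedded",
    "annotate_location",
    "fisher_association",
    "fisher_pvalue_exact",
    "motif_scan",
    "IUPAC",
]

DEFAULT_SCALES = (5_000, 25_000, 50_000, 100_000)

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def multiscale_domains(
    midpoints_t1: dict[str, np.ndarray],
    midpoints_t2: dict[str, np.ndarray],
    index,
    scales: tuple[int, ...] = DEFAULT_SCALES,
    inert_regions_mask=None,
    **kwargs,
) -> dict[int, LLRResult]:
    """Run the occupancy statistic independently at each window size.

    *inert_regions_mask* may be a callable ``grid -> bool mask`` (evaluated
    per scale) or None.
    """
    results: dict[int, LLRResult] = {}
    for scale in scales:
        if scale <= 0:
            raise ValueError("scales must be positive")
        grid = tile_genome(index, scale)
        mask = inert_regions_mask(grid) if callable(inert_regions_mask) else inert_regions_mask
        results[scale] = occupancy.differential_occupancy(
            midpoints_t1, midpoints_t2, grid, inert_mask=mask, **kwargs
        )
    return results


def domains_bed(result: LLRResult, label: str = "depleted") -> pd.DataFrame:
    """Windows carrying the given label as a BED-style frame."""
    sel = result.label == label
    return pd.DataFrame(
        {
            "chrom": result.grid.chroms[sel],
            "start": result.grid.starts[sel],
            "end": result.grid.ends[sel],
            "name": label,
            "score": np.round(-np.log10(
                result.p_right[sel] if label == "depleted" else result.p_left[sel]
            ), 4),
            "strand": ".",
        }
    )


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals per chromosome."""
    rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for st, en in zip(starts[1:], ends[1:]):
            if st <= cur_e:
                cur_e = max(cur_e, en)
            else:
                rows.append({"chrom": chrom, "start": int(cur_s), "end": int(cur_e)})
                cur_s, cur_e = st, en
        rows.append({"chrom": chrom, "start": int(cur_s), "end": int(cur_e)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _coverage(starts_q, ends_q, merged_starts, merged_ends) -> np.ndarray:
    """bp of each query interval covered by the merged (disjoint sorted) set."""
    lengths = merged_ends - merged_starts
    cum = np.concatenate([[0], np.cumsum(lengths)])

    def cov_to(pos):
        # covered bp in (-inf, pos)
        j = np.searchsorted(merged_starts, pos, side="right")
        full = cum[np.maximum(j - 1, 0)]
        inside = np.clip(pos - merged_starts[np.maximum(j - 1, 0)], 0, lengths[np.maximum(j - 1, 0)])
        return np.where(j > 0, full + inside, 0)

    return cov_to(ends_q) - cov_to(starts_q)


@dataclass
class EmbeddingReport:
    """Per-peak overlap fractions with a domain set and the embedded subset."""

    peaks: pd.DataFrame  # with 'overlap_fraction' and 'embedded' columns
    min_frac: float

    @property
    def n_embedded(self) -> int:
        return int(self.peaks["embedded"].sum())

    @property
    def n_total(self) -> int:
        return len(self.peaks)


def overlap_embedded(
    peaks: pd.DataFrame,
    domains: pd.DataFrame,
    min_frac: float = 0.25,
    relative_to: str = "peak",
) -> EmbeddingReport:
    """Embedding of peaks in a domain set.

    A peak is *embedded* when ≥ *min_frac* of its length (default; with
    ``relative_to='domain'``, of the overlapped window's length) is covered
    by the union of the domains.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0,1]")
    if relative_to not in ("peak", "domain"):
        raise ValueError("relative_to must be 'peak' or 'domain'")
    peaks = peaks.copy().reset_index(drop=True)
    if np.any(peaks["end"] <= peaks["start"]):
        raise ValueError("zero-length peak")
    frac = np.zeros(len(peaks))
    merged = merge_intervals(domains) if len(domains) else domains
    for chrom, sub in peaks.groupby("chrom", sort=False):
        if relative_to == "peak":
            dom = merged[merged["chrom"] == chrom] if len(merged) else merged
            if dom is None or len(dom) == 0:
                continue
            cov = _coverage(
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                dom["start"].to_numpy(),
                dom["end"].to_numpy(),
            )
            frac[sub.index] = cov / (sub["end"] - sub["start"]).to_numpy()
        else:
            # fraction of the best single domain window covered by the peak
            dom = domains[domains["chrom"] == chrom].sort_values("start")
            if len(dom) == 0:
                continue
            ds = dom["start"].to_numpy()
            de = dom["end"].to_numpy()
            for i, (ps, pe) in zip(sub.index, zip(sub["start"], sub["end"])):
                j0 = np.searchsorted(de, ps, side="right")
                j1 = np.searchsorted(ds, pe, side="left")
                best = 0.0
                for j in range(j0, j1):
                    ov = min(pe, de[j]) - max(ps, ds[j])
                    if ov > 0:
                        best = max(best, ov / (de[j] - ds[j]))
                frac[i] = best
    peaks["overlap_fraction"] = frac
    peaks["embedded"] = frac >= min_frac
    return EmbeddingReport(peaks=peaks, min_frac=min_frac)


def annotate_location(
    intervals: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_flank: int = 1_000,
) -> pd.Series:
    """Classify intervals as promoter / intragenic / intergenic by midpoint.

    Promoter means the midpoint lies within ±*promoter_flank* bp of a TSS
    and takes precedence over intragenic.
    """
    classes = pd.Series("intergenic", index=intervals.index, dtype=object)
    for chrom, sub in intervals.groupby("chrom", sort=False):
        g = genes[genes["chrom"] == chrom]
        mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
        if len(g) == 0:
            continue
        tss = np.sort(g["tss"].to_numpy())
        j = np.searchsorted(tss, mids)
        d_left = np.abs(mids - tss[np.clip(j - 1, 0, len(tss) - 1)])
        d_right = np.abs(mids - tss[np.clip(j, 0, len(tss) - 1)])
        near_tss = np.minimum(d_left, d_right) <= promoter_flank
        order = np.argsort(g["start"].to_numpy(), kind="stable")
        gs = g["start"].to_numpy()[order]
        ge = g["end"].to_numpy()[order]
        # running max of ends lets a binary search answer point-in-any-gene
        ge_run = np.maximum.accumulate(ge)
        k = np.searchsorted(gs, mids, side="right")
        inside = (k > 0) & (ge_run[np.maximum(k - 1, 0)] > mids)
        cls = np.where(near_tss, "promoter", np.where(inside, "intragenic", "intergenic"))
        classes.loc[sub.index] = cls
    return classes


def fisher_pvalue_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer enumeration of the hypergeometric.

    Sums the probability of every table (with the observed margins) whose
    probability does not exceed the observed table's, using exact integer
    weights, so ties cost nothing to resolve.
    """
    r, n = a + b, a + b + c + d
    col = a + c
    lo, hi = max(0, r + col - n), min(r, col)
    weights = [comb(r, x) * comb(n - r, col - x) for x in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    num = sum(w for w in weights if w <= w_obs)
    return num / comb(n, col)


def fisher_association(
    set_a_hits: int, set_a_total: int, set_b_hits: int, set_b_total: int
) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for a 2×2 association.

    The table is ``[[a_hits, a_total − a_hits], [b_hits, b_total − b_hits]]``;
    the odds ratio is the sample (cross-product) odds ratio.  The p-value
    sums hypergeometric probabilities not exceeding the observed one —
    with exact integer arithmetic for small tables (ties cost nothing to
    resolve) and the vectorized hypergeometric pmf beyond that.
    """
    a, b = set_a_hits, set_a_total - set_a_hits
    c, d = set_b_hits, set_b_total - set_b_hits
    if min(a, b, c, d) < 0 or set_a_total <= 0 or set_b_total <= 0:
        raise ValueError("hits must lie in [0, total] and totals be positive")
    if a + c == 0 or b + d == 0:
        raise ValueError("empty table margin; association undefined")
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    n, r, col = a + b + c + d, a + b, a + c
    if n <= 500:
        return odds, fisher_pvalue_exact(a, b, c, d)
    lo, hi = max(0, r + col - n), min(r, col)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r, col)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return odds, min(p, 1.0)


def _iupac_regex(pattern: str) -> str:
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {ch!r} in pattern")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(parts)


def reverse_complement(pattern: str) -> str:
    return pattern.upper().translate(_COMPLEMENT)[::-1]


def motif_scan(
    sequence: str,
    iupac_pattern: str = "GGRRNNYYCC",
    both_strands: bool = True,
) -> pd.DataFrame:
    """All (overlapping) match positions of an IUPAC consensus.

    Positions are 0-based starts on the forward sequence; reverse-strand
    matches are found by scanning the reverse complement of the pattern and
    reported with strand '−'.  A palindromic site therefore appears once
    per strand.
    """
    seq = sequence.upper()
    rows = []
    fwd = re.compile(f"(?=({_iupac_regex(iupac_pattern)}))")
    for m in fwd.finditer(seq):
        rows.append({"position": m.start(), "strand": "+"})
    if both_strands:
        rev = re.compile(f"(?=({_iupac_regex(reverse_complement(iupac_pattern))}))")
        for m in rev.finditer(seq):
            rows.append({"position": m.start(), "strand": "-"})
    df = pd.DataFrame(rows, columns=["position", "strand"])
    return df.sort_values(["position", "strand"], kind="stable").reset_index(drop=True)
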