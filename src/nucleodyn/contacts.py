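"""Viewpoint contact calling: sliding-window domainogram with permutation FDR.

3C-seq reads at restriction-fragment ends are made binary (a fragment end is
either contact-positive or not).  Enrichment is scored in sliding windows of
geometrically increasing size (2–200 kbp, step one tenth of the window)
as the window's positive-end fraction over a background rate estimated from
3,000 randomly sampled fragment ends.  Permuting the binary labels over
fragment ends calibrates a score threshold controlling the false discovery
rate; windows above it are called interacting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .domains import fisher_association

__all__ = [
    "ContactProfile",
    "DomainogramResult",
    "binarize",
    "window_ladder",
    "sliding_enrichment",
    "permutation_fdr",
    "contacts_vs_depletion",
]

WMIN = 2_000
WMAX = 200_000
N_LADDER = 12
N_BACKGROUND = 3_000
MIN_ENDS = 3


def binarize(reads: np.ndarray) -> np.ndarray:
    """1 iff a fragment end carries at least one read."""
    reads = np.asarray(reads)
    if np.any(reads < 0):
        raise ValueError("read counts must be nonnegative")
    return (reads >= 1).astype(np.int8)


@dataclass
class ContactProfile:
    """Binary viewpoint-contact signal over sorted fragment-end positions."""

    chrom: str
    viewpoint: int
    ends: np.ndarray
    reads: np.ndarray
    binary: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        ends = np.asarray(self.ends, dtype=np.int64)
        order = np.argsort(ends, kind="stable")
        ends = ends[order]
        if len(np.unique(ends)) != len(ends):
            raise ValueError("fragment-end positions must be unique")
        self.ends = ends
        self.reads = np.asarray(self.reads)[order]
        self.binary = binarize(self.reads)

    @classmethod
    def from_table(cls, df: pd.DataFrame, chrom: str, viewpoint: int) -> "ContactProfile":
        return cls(chrom=chrom, viewpoint=viewpoint, ends=df["end_pos"].to_numpy(),
                   reads=df["reads"].to_numpy())


def window_ladder(wmin: int = WMIN, wmax: int = WMAX, n: int = N_LADDER) -> np.ndarray:
    """Geometric ladder of window sizes (bp)."""
    if wmin <= 0 or wmax < wmin:
        raise ValueError("need 0 < wmin <= wmax")
    return np.unique(np.round(np.geomspace(wmin, wmax, n)).astype(np.int64))


@dataclass
class DomainogramResult:
    """Scores on the (window size × position) plane."""

    windows: pd.DataFrame  # wsize, start, end, i0, i1, n_ends, n_pos, score, masked
    background_rate: float
    background_index: np.ndarray
    threshold: float | None = None
    significant: np.ndarray | None = None

    def score_matrix(self) -> pd.DataFrame:
        """Long-format unmasked scores, convenient for heat-map plotting."""
        ok = ~self.windows["masked"]
        return self.windows.loc[ok, ["wsize", "start", "end", "score"]]


def _window_frame(ends: np.ndarray, sizes: np.ndarray) -> pd.DataFrame:
    lo, hi = int(ends.min()), int(ends.max())
    rows = []
    for w in sizes:
        step = max(int(w) // 10, 1)
        for start in range(lo, max(hi - int(w), lo) + 1, step):
            end = start + int(w)
            i0 = int(np.searchsorted(ends, start, side="left"))
            i1 = int(np.searchsorted(ends, end, side="left"))
            rows.append((int(w), start, end, i0, i1))
    df = pd.DataFrame(rows, columns=["wsize", "start", "end", "i0", "i1"])
    df["n_ends"] = df["i1"] - df["i0"]
    return df


def sliding_enrichment(
    profile: ContactProfile,
    sizes: np.ndarray | None = None,
    n_background: int = N_BACKGROUND,
    min_ends: int = MIN_ENDS,
    seed: int | np.random.Generator = 0,
) -> DomainogramResult:
    """Per-window positive-fraction enrichment over a sampled background rate.

    The background rate is the positive fraction among *n_background*
    fragment ends sampled uniformly without replacement (all ends when
    fewer exist).  Windows with fewer than *min_ends* ends are masked.
    """
    if len(profile.ends) < 2:
        raise ValueError("need at least 2 fragment ends")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = window_ladder() if sizes is None else np.asarray(sizes, dtype=np.int64)
    win = _window_frame(profile.ends, sizes)
    n = len(profile.ends)
    k = min(n_background, n)
    bg_idx = np.sort(rng.choice(n, size=k, replace=False))
    bg_rate = float(profile.binary[bg_idx].mean())
    csum = np.concatenate([[0], np.cumsum(profile.binary)])
    n_pos = csum[win["i1"].to_numpy()] - csum[win["i0"].to_numpy()]
    win["n_pos"] = n_pos
    masked = win["n_ends"].to_numpy() < min_ends
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = n_pos / win["n_ends"].to_numpy()
        score = frac / bg_rate if bg_rate > 0 else np.full(len(win), np.nan)
    score = np.where(masked, np.nan, score)
    win["score"] = score
    win["masked"] = masked
    return DomainogramResult(windows=win, background_rate=bg_rate, background_index=bg_idx)


def permutation_fdr(
    profile: ContactProfile,
    result: DomainogramResult,
    n_perm: int = 1_000,
    fdr: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> DomainogramResult:
    """Permutation-calibrated score threshold at the requested FDR.

    Binary labels are shuffled over fragment ends *n_perm* times and scored
    on the same windows with the same background indices.  The threshold is
    the smallest observed score t with
    ``mean_perm #{perm score ≥ t} / #{observed score ≥ t} < fdr``; if no
    score qualifies the significant set is empty.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    binary = profile.binary.astype(np.int64)
    n_pos_total = int(binary.sum())
    if n_pos_total == 0 or n_pos_total == len(binary):
        warnings.warn("degenerate all-negative/all-positive signal; nothing to call")
        result.threshold = None
        result.significant = np.zeros(len(result.windows), dtype=bool)
        return result
    win = result.windows
    i0 = win["i0"].to_numpy()
    i1 = win["i1"].to_numpy()
    n_ends = win["n_ends"].to_numpy().astype(float)
    unmasked = ~win["masked"].to_numpy()
    obs = win["score"].to_numpy()[unmasked]
    perm_scores = []
    for _ in range(n_perm):
        perm = rng.permutation(binary)
        csum = np.concatenate([[0], np.cumsum(perm)])
        n_pos = csum[i1] - csum[i0]
        bg = perm[result.background_index].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            sc = (n_pos / n_ends) / bg
        perm_scores.append(sc[unmasked])
    pooled = np.sort(np.concatenate(perm_scores))
    obs_sorted = np.sort(obs)
    candidates = np.unique(obs_sorted)
    n_obs_ge = len(obs_sorted) - np.searchsorted(obs_sorted, candidates, side="left")
    n_perm_ge = (len(pooled) - np.searchsorted(pooled, candidates, side="left")) / n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_hat = n_perm_ge / n_obs_ge
    ok = np.flatnonzero(fdr_hat < fdr)
    if len(ok) == 0:
        result.threshold = None
        result.significant = np.zeros(len(win), dtype=bool)
        return result
    threshold = float(candidates[ok[0]])
    sig = np.zeros(len(win), dtype=bool)
    scores = win["score"].to_numpy()
    sig[unmasked.nonzero()[0]] = obs >= threshold
    result.threshold = threshold
    result.significant = sig & ~np.isnan(scores)
    return result


def significant_windows(result: DomainogramResult) -> pd.DataFrame:
    if result.significant is None:
        raise ValueError("run permutation_fdr first")
    return result.windows.loc[result.significant, ["wsize", "start", "end", "n_ends", "n_pos", "score"]]


def contacts_vs_depletion(
    result: DomainogramResult,
    depleted: pd.DataFrame,
    chrom: str,
) -> dict:
    """Association of significant contact windows with depleted occupancy windows.

    Counts contact windows whose midpoint falls in a depleted window,
    among significant vs. non-significant windows, and runs Fisher's exact
    test on the 2×2 table.  Returns counts, odds ratio and p (p/OR are None
    when there is nothing to test).
    """
    if result.significant is None:
        raise ValueError("run permutation_fdr first")
    win = result.windows
    unmasked = ~win["masked"].to_numpy()
    mids = ((win["start"] + win["end"]) // 2).to_numpy()
    dep = depleted[depleted["chrom"] == chrom].sort_values("start")
    in_dep = np.zeros(len(win), dtype=bool)
    if len(dep):
        ds = dep["start"].to_numpy()
        de = dep["end"].to_numpy()
        j = np.searchsorted(ds, mids, side="right")
        in_dep = (j > 0) & (mids < de[np.maximum(j - 1, 0)])
    sig = result.significant & unmasked
    non = ~result.significant & unmasked
    out = {
        "n_significant": int(sig.sum()),
        "n_significant_in_depleted": int((sig & in_dep).sum()),
        "n_other": int(non.sum()),
        "n_other_in_depleted": int((non & in_dep).sum()),
        "odds_ratio": None,
        "p_value": None,
    }
    if out["n_significant"] == 0:
        return out
    odds, p = fisher_association(
        out["n_significant_in_depleted"],
        out["n_significant"],
        out["n_other_in_depleted"],
        out["n_other"],
    )
    out["odds_ratio"] = odds
    out["p_value"] = p
    return out
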