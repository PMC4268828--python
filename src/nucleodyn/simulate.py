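"""Seeded synthetic MNase-seq landscapes with planted ground truth.

The generator builds the minimal statistical structure the analysis is
designed to detect: a per-bp nucleosome-dyad weight track that is
homogeneous in background chromatin and phased (Gaussian peaks every NRL bp)
downstream of expressed TSSs; planted kilobase-scale occupancy changes
(multiplicative depletion/enrichment) and dyad shifts; mononucleosome
fragments sampled with Poisson counts and clipped-normal lengths around
track-distributed midpoints; expression-classed genes with two-time-point
count tables; TF peaks placed inside depleted domains at a chosen odds; and
viewpoint contact profiles with Bernoulli-positive fragment ends.  Every
generator takes an explicit seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import GenomeIndex

__all__ = [
    "LandscapeSpec",
    "PlantedEvent",
    "TruthTable",
    "simulate_landscape",
    "apply_events",
    "sample_fragments",
    "simulate_annotations",
    "simulate_fragment_ends",
    "simulate_contacts",
]

ARRAY_SD = 15.0  # bp spread of a positioned dyad around its phased site


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of a synthetic mononucleosome landscape."""

    genome_length: int = 10_000_000
    chrom_names: tuple[str, ...] = ("chr1",)
    nrl: int = 190
    frag_len_mean: float = 147.0
    frag_len_sd: float = 10.0
    base_occupancy: float = 30.0  # expected fragments per nucleosome
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 10 * self.nrl:
            raise ValueError("genome_length must be >= 10 * nrl")
        if self.frag_len_sd < 0:
            raise ValueError("frag_len_sd must be >= 0")
        if self.base_occupancy <= 0:
            raise ValueError("base_occupancy must be positive")

    @property
    def index(self) -> GenomeIndex:
        per = self.genome_length // len(self.chrom_names)
        return GenomeIndex(self.chrom_names, tuple([per] * len(self.chrom_names)))


@dataclass(frozen=True)
class PlantedEvent:
    """A planted occupancy change or dyad shift on one interval."""

    kind: str  # depletion | enrichment | shift
    chrom: str
    start: int
    end: int
    factor: float = 1.0
    shift_bp: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("depletion", "enrichment", "shift"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError("invalid event interval")
        if self.factor <= 0:
            raise ValueError("factor must be positive")
        if self.kind == "depletion" and self.factor >= 1:
            raise ValueError("depletion needs factor < 1")
        if self.kind == "enrichment" and self.factor <= 1:
            raise ValueError("enrichment needs factor > 1")
        if self.kind == "shift" and self.shift_bp == 0:
            raise ValueError("shift events need shift_bp != 0")


@dataclass
class TruthTable:
    """Ground truth of everything planted, for recovery tests."""

    events: list[PlantedEvent]
    gene_classes: pd.DataFrame  # gene, chrom, start, end, strand, class, lfc
    inert_regions: pd.DataFrame
    tf_peaks: pd.DataFrame
    contact_targets: pd.DataFrame = field(default_factory=pd.DataFrame)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.events])


Track = dict[str, np.ndarray]


def simulate_landscape(spec: LandscapeSpec, genes: pd.DataFrame | None = None) -> Track:
    """Per-bp dyad weight track: homogeneous background, phased arrays in genes.

    The background weight is 1/NRL per bp (one nucleosome per NRL on
    average).  Within each expressed gene, dyads are positioned: Gaussian
    peaks of unit mass every NRL bp downstream of the TSS, on a small
    residual floor.  The track integrates to (approximately) the number of
    nucleosomes, so fragment counts scale with ``base_occupancy``.
    """
    index = spec.index
    track: Track = {
        name: np.full(index.length(name), 1.0 / spec.nrl) for name in index.names
    }
    if genes is None or len(genes) == 0:
        return track
    half = int(4 * ARRAY_SD)
    kernel_x = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (kernel_x / ARRAY_SD) ** 2)
    kernel /= kernel.sum()
    for rec in genes.itertuples(index=False):
        if rec.chrom not in index:
            raise ValueError(f"gene {rec.name} on unknown chromosome {rec.chrom}")
        length = index.length(rec.chrom)
        if rec.start < 0 or rec.end > length:
            raise ValueError(f"gene {rec.name} outside the genome")
        body = track[rec.chrom][rec.start : rec.end]
        phased = np.full(rec.end - rec.start, 0.1 / spec.nrl)
        step = spec.nrl
        if rec.strand == "-":
            centers = np.arange(rec.end - rec.start - step // 2, -1, -step)
        else:
            centers = np.arange(step // 2, rec.end - rec.start, step)
        for c in centers:
            lo = max(int(c) - half, 0)
            hi = min(int(c) + half + 1, len(phased))
            phased[lo:hi] += kernel[lo - (int(c) - half) : hi - (int(c) - half)]
        body[:] = phased
    return track


def apply_events(track: Track, events: list[PlantedEvent]) -> Track:
    """Apply planted events to a copy of the track.

    Depletion/enrichment multiply the interval by ``factor``; shift events
    translate the interval's profile by ``shift_bp`` (edges keep the
    original values).  Overlapping events are contradictory and rejected.
    """
    by_chrom: dict[str, list[PlantedEvent]] = {}
    for ev in events:
        if ev.chrom not in track:
            raise ValueError(f"event on unknown chromosome {ev.chrom}")
        if ev.end > len(track[ev.chrom]):
            raise ValueError("event interval outside the genome")
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for evs in by_chrom.values():
        evs.sort(key=lambda e: e.start)
        for prev, nxt in zip(evs[:-1], evs[1:]):
            if nxt.start < prev.end:
                raise ValueError(
                    f"overlapping events at {prev.chrom}:{nxt.start} are contradictory"
                )
    out = {c: v.copy() for c, v in track.items()}
    for ev in events:
        seg = out[ev.chrom][ev.start : ev.end]
        if ev.kind in ("depletion", "enrichment"):
            seg *= ev.factor
        else:
            d = ev.shift_bp
            shifted = seg.copy()
            if d > 0:
                shifted[d:] = seg[:-d]
            else:
                shifted[:d] = seg[-d:]
            out[ev.chrom][ev.start : ev.end] = shifted
    return out


def sample_fragments(
    track: Track,
    occupancy: float,
    frag_len_mean: float = 147.0,
    frag_len_sd: float = 10.0,
    seed: int | np.random.Generator = 0,
    min_len: int = 50,
) -> dict[str, pd.DataFrame]:
    """Sample mononucleosome fragments from a dyad-weight track.

    The fragment count per chromosome is Poisson with mean
    ``occupancy × track mass``; midpoints are independent draws
    proportional to the track; lengths are normal draws clipped at
    *min_len*.  Returns per-chromosome frames with ``start``/``end``
    (0-based half-open) and ``midpoint``.
    """
    if occupancy <= 0:
        raise ValueError("occupancy must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[str, pd.DataFrame] = {}
    for chrom in sorted(track):
        weights = track[chrom]
        mass = weights.sum()
        n = rng.poisson(occupancy * mass)
        if n == 0:
            out[chrom] = pd.DataFrame(columns=["start", "end", "midpoint"])
            continue
        cdf = np.cumsum(weights)
        cdf /= cdf[-1]
        mids = np.searchsorted(cdf, rng.random(n), side="right").astype(np.int64)
        lengths = np.round(rng.normal(frag_len_mean, frag_len_sd, size=n)).astype(np.int64)
        lengths = np.maximum(lengths, min_len)
        starts = np.maximum(mids - lengths // 2, 0)
        ends = np.minimum(starts + lengths, len(weights))
        starts = np.minimum(starts, ends - 1)
        out[chrom] = pd.DataFrame(
            {"start": starts, "end": ends, "midpoint": (starts + ends) // 2}
        ).sort_values("midpoint", kind="stable").reset_index(drop=True)
    return out


def fragments_to_midpoints(frags: dict[str, pd.DataFrame]) -> dict[str, np.ndarray]:
    return {
        c: np.sort(df["midpoint"].to_numpy(dtype=np.int64)) for c, df in frags.items() if len(df)
    }


def _place_nonoverlapping(
    rng: np.random.Generator, n: int, length: int, genome: int, gap: int
) -> np.ndarray:
    """Random non-overlapping interval starts via spacing sampling."""
    slack = genome - n * (length + gap)
    if slack < 0:
        raise ValueError(f"{n} intervals of {length} bp exceed genome capacity")
    cuts = np.sort(rng.random(n)) * slack
    return (cuts + np.arange(n) * (length + gap)).astype(np.int64)


def simulate_annotations(
    spec: LandscapeSpec,
    n_genes: int = 200,
    class_fractions: dict[str, float] | None = None,
    tf_enrichment_odds: float = 4.0,
    seed: int | np.random.Generator = 0,
    events: list[PlantedEvent] | None = None,
    n_peaks: int = 200,
    gene_length: int = 10_000,
    peak_width: int = 300,
    base_count: tuple[int, int] = (200, 2_000),
) -> tuple[TruthTable, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Genes, expression classes, count table and TF peaks with ground truth.

    Genes are placed non-overlapping on the first chromosome.  Up/down/
    constitutive genes receive integer two-time-point counts whose planted
    log2 fold-changes are > 0.6, < −0.6 and 0; remaining genes are
    unexpressed (zero counts).  TF peaks fall inside planted depletion
    events with probability ``odds·f / (odds·f + (1 − f))`` where *f* is
    the depleted genome fraction.  Returns ``(truth, genes, counts, peaks)``.
    """
    if class_fractions is None:
        class_fractions = {"up": 0.15, "down": 0.1, "constitutive": 0.5}
    if sum(class_fractions.values()) > 1 + 1e-9:
        raise ValueError("class fractions must sum to <= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    index = spec.index
    chrom = index.names[0]
    chrom_len = index.length(chrom)
    starts = _place_nonoverlapping(rng, n_genes, gene_length, chrom_len, gap=2_000)
    strands = rng.choice(["+", "-"], size=n_genes)
    genes = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + gene_length,
            "name": [f"gene_{i:04d}" for i in range(n_genes)],
            "score": 0,
            "strand": strands,
        }
    )
    genes["tss"] = np.where(strands == "+", genes["start"], genes["end"] - 1)
    genes["tts"] = np.where(strands == "+", genes["end"] - 1, genes["start"])

    labels = []
    for cls, frac in class_fractions.items():
        labels += [cls] * int(round(frac * n_genes))
    labels += ["unexpressed"] * (n_genes - len(labels))
    labels = np.asarray(labels[:n_genes], dtype=object)
    rng.shuffle(labels)

    lfc = np.zeros(n_genes)
    lfc[labels == "up"] = rng.uniform(0.8, 2.0, size=(labels == "up").sum())
    lfc[labels == "down"] = -rng.uniform(0.8, 2.0, size=(labels == "down").sum())
    t1 = rng.integers(base_count[0], base_count[1], size=n_genes)
    t1[labels == "unexpressed"] = 0
    t2 = np.round(t1 * np.exp2(lfc)).astype(np.int64)
    t2[labels == "constitutive"] = t1[labels == "constitutive"]
    counts = pd.DataFrame(
        {"gene": genes["name"], "count_t1": t1, "count_t2": t2}
    )

    # transcriptionally inert regions: the complement of expressed genes and of
    # planted events (± a margin); regions with planted activity cannot feed a
    # null of pure stochastic fluctuation
    events = events or []
    margin = 2 * spec.nrl
    expressed = genes[labels != "unexpressed"]
    blocked = [
        (max(int(s) - margin, 0), int(e) + margin)
        for s, e in zip(expressed["start"], expressed["end"])
    ] + [
        (max(ev.start - margin, 0), ev.end + margin)
        for ev in events
        if ev.chrom == chrom
    ]
    blocked.sort()
    inert_rows = []
    pos = 0
    for lo, hi in blocked:
        if lo > pos:
            inert_rows.append({"chrom": chrom, "start": pos, "end": lo})
        pos = max(pos, hi)
    if pos < chrom_len:
        inert_rows.append({"chrom": chrom, "start": pos, "end": chrom_len})
    inert = pd.DataFrame(inert_rows, columns=["chrom", "start", "end"])

    # TF peaks biased into depleted intervals at the requested odds
    dep = [e for e in events if e.kind == "depletion" and e.chrom == chrom]
    dep_len = sum(e.end - e.start for e in dep)
    f = dep_len / chrom_len
    p_in = tf_enrichment_odds * f / (tf_enrichment_odds * f + (1 - f)) if dep_len else 0.0
    peak_rows = []
    dep_starts = np.asarray([e.start for e in dep], dtype=np.int64)
    dep_ends = np.asarray([e.end for e in dep], dtype=np.int64)
    dep_cum = np.concatenate([[0], np.cumsum(dep_ends - dep_starts)])
    for i in range(n_peaks):
        inside = rng.random() < p_in
        if inside:
            u = rng.integers(0, dep_cum[-1] - peak_width)
            j = np.searchsorted(dep_cum, u, side="right") - 1
            start = int(dep_starts[j] + min(u - dep_cum[j], dep_ends[j] - dep_starts[j] - peak_width))
        else:
            while True:
                start = int(rng.integers(0, chrom_len - peak_width))
                mid = start + peak_width // 2
                j = np.searchsorted(dep_starts, mid, side="right") - 1
                if j < 0 or mid >= dep_ends[j]:
                    break
        peak_rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + peak_width,
                "name": f"peak_{i:04d}",
                "score": 0,
                "strand": ".",
                "signalValue": float(rng.uniform(2, 20)),
                "pValue": -1.0,
                "qValue": -1.0,
                "peak": peak_width // 2,
                "planted_inside": inside,
            }
        )
    peaks = pd.DataFrame(peak_rows)

    gene_classes = genes[["name", "chrom", "start", "end", "strand"]].copy()
    gene_classes = gene_classes.rename(columns={"name": "gene"})
    gene_classes["gene_class"] = labels
    gene_classes["true_lfc"] = lfc
    truth = TruthTable(
        events=list(events),
        gene_classes=gene_classes,
        inert_regions=inert,
        tf_peaks=peaks,
    )
    return truth, genes, counts, peaks


def simulate_fragment_ends(
    chrom_length: int,
    mean_spacing: int = 500,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Restriction-fragment-end positions: a sorted Poisson-process sample."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = max(int(chrom_length // mean_spacing), 2)
    ends = rng.choice(chrom_length, size=n, replace=False)
    return np.sort(ends.astype(np.int64))


def simulate_contacts(
    viewpoint: int,
    fragment_ends: np.ndarray,
    contact_targets: pd.DataFrame,
    signal_rate: float = 0.9,
    background_rate: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Binary-ish viewpoint contact table over fragment ends.

    Each fragment end is independently read-positive with
    *background_rate*, or *signal_rate* inside a contact target; positive
    ends get 1 + Poisson(2) reads.  Returns a frame with ``end_pos`` and
    ``reads``.
    """
    if not (0 <= background_rate <= 1 and 0 <= signal_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if signal_rate < background_rate:
        raise ValueError("signal_rate must be >= background_rate")
    fragment_ends = np.sort(np.asarray(fragment_ends, dtype=np.int64))
    if viewpoint not in fragment_ends:
        raise ValueError("viewpoint must be one of the fragment ends")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate = np.full(len(fragment_ends), background_rate)
    for rec in contact_targets.itertuples(index=False):
        rate[(fragment_ends >= rec.start) & (fragment_ends < rec.end)] = signal_rate
    positive = rng.random(len(fragment_ends)) < rate
    reads = np.where(positive, 1 + rng.poisson(2.0, size=len(fragment_ends)), 0)
    return pd.DataFrame({"end_pos": fragment_ends, "reads": reads})
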