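"""Readers and writers for the interval formats the pipeline touches.

All internal coordinates are 0-based half-open (BED convention); conversion,
where a format requires it, happens only at the format boundary.  Interval
collections are plain :class:`pandas.DataFrame` objects with at least the
columns ``chrom``, ``start``, ``end``; gene models additionally carry
``strand``, ``tss`` and ``tts``.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeIndex",
    "ParseError",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_intervals",
    "read_genes",
    "read_fragments",
    "write_bed",
    "write_bed12",
    "write_narrowpeak",
    "write_bedgraph",
    "read_bedgraph",
    "read_table",
    "write_table",
]

BED_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")
NARROWPEAK_COLUMNS = BED_COLUMNS + ("signalValue", "pValue", "qValue", "peak")


class ParseError(ValueError):
    """Malformed record in a genomic text format; message names the line."""


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome names and lengths (a parsed chrom.sizes)."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    _length_of: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        object.__setattr__(self, "_length_of", dict(zip(self.names, self.lengths)))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._length_of

    def length(self, chrom: str) -> int:
        try:
            return self._length_of[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))


def read_chrom_sizes(path: str | os.PathLike) -> GenomeIndex:
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'name<TAB>length'")
            names.append(fields[0])
            try:
                lengths.append(int(fields[1]))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: length {fields[1]!r} not an integer") from None
    return GenomeIndex(tuple(names), tuple(lengths))


def write_chrom_sizes(index: GenomeIndex, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in zip(index.names, index.lengths):
            fh.write(f"{name}\t{length}\n")


def _validate_interval(chrom, start, end, index: GenomeIndex | None, where: str) -> None:
    if start < 0 or start >= end:
        raise ParseError(f"{where}: invalid interval [{start},{end})")
    if index is not None:
        if chrom not in index:
            raise ParseError(f"{where}: unknown chromosome {chrom!r}")
        if end > index.length(chrom):
            raise ParseError(f"{where}: interval end {end} beyond chromosome end")


def read_intervals(
    path: str | os.PathLike,
    format: str = "BED",
    index: GenomeIndex | None = None,
) -> pd.DataFrame:
    """Read BED3/6, narrowPeak or BED12 into a DataFrame.

    BED12 records are returned as gene models (see :func:`read_genes`).
    Coordinates are validated against *index* when one is provided; the
    error message names the offending line.
    """
    fmt = format.upper()
    if fmt == "BED12":
        return read_genes(path, index=index)
    if fmt not in ("BED", "NARROWPEAK"):
        raise ValueError(f"unknown format {format!r}")
    rows = []
    ncols_needed = 10 if fmt == "NARROWPEAK" else 3
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < ncols_needed:
                raise ParseError(f"{path}:{lineno}: expected >= {ncols_needed} columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            _validate_interval(chrom, start, end, index, f"{path}:{lineno}")
            rec = {"chrom": chrom, "start": start, "end": end}
            if len(fields) > 3:
                rec["name"] = fields[3]
            if len(fields) > 4:
                rec["score"] = fields[4]
            if len(fields) > 5:
                strand = fields[5]
                if strand not in ("+", "-", "."):
                    raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
                rec["strand"] = strand
            if fmt == "NARROWPEAK":
                rec["signalValue"] = float(fields[6])
                rec["pValue"] = float(fields[7])
                rec["qValue"] = float(fields[8])
                rec["peak"] = int(fields[9])
            rows.append(rec)
    df = pd.DataFrame(rows)
    if df.empty:
        cols = list(NARROWPEAK_COLUMNS) if fmt == "NARROWPEAK" else list(BED_COLUMNS[:3])
        df = pd.DataFrame(columns=cols)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def read_genes(path: str | os.PathLike, index: GenomeIndex | None = None) -> pd.DataFrame:
    """Read gene models from BED12.

    The TSS is ``start`` on the + strand and ``end - 1`` on the − strand;
    the TTS is the opposite terminus.  Only the gene span is retained
    (block structure is ignored — the pipeline works on whole gene bodies).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED12 needs >= 6 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            _validate_interval(chrom, start, end, index, f"{path}:{lineno}")
            strand = fields[5]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: gene strand must be + or -")
            tss, tts = (start, end - 1) if strand == "+" else (end - 1, start)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "name": fields[3],
                    "score": fields[4],
                    "strand": strand,
                    "tss": tss,
                    "tts": tts,
                }
            )
    df = pd.DataFrame(rows, columns=list(BED_COLUMNS) + ["tss", "tts"])
    for col in ("start", "end", "tss", "tts"):
        df[col] = df[col].astype(np.int64)
    return df


def fragment_midpoint(start: int, end: int) -> int:
    """Midpoint of a half-open fragment, rounding down for even lengths."""
    return (start + end) // 2


def read_fragments(
    path: str | os.PathLike, index: GenomeIndex | None = None
) -> dict[str, np.ndarray]:
    """Read fragments (BED, or BAM via pysam) into sorted midpoints per chromosome.

    Duplicate fragments keep their multiplicity.  Zero-length intervals are
    rejected.  The returned arrays are sorted int64 positions.
    """
    path = os.fspath(path)
    if path.endswith(".bam"):
        return _read_fragments_bam(path, index)
    mids: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            if end <= start:
                raise ParseError(f"{path}:{lineno}: zero-length or inverted fragment")
            _validate_interval(chrom, start, end, index, f"{path}:{lineno}")
            mids.setdefault(chrom, []).append(fragment_midpoint(start, end))
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in mids.items()}


def _read_fragments_bam(path: str, index: GenomeIndex | None) -> dict[str, np.ndarray]:
    try:
        import pysam
    except ImportError as exc:  # pragma: no cover - pysam present in practice
        raise ImportError("BAM input requires pysam; supply BED instead") from exc
    mids: dict[str, list[int]] = {}
    with pysam.AlignmentFile(path, "rb") as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_paired and not (aln.is_proper_pair and aln.is_read1):
                continue
            start = aln.reference_start
            end = start + abs(aln.template_length) if aln.is_paired else aln.reference_end
            if end is None or end <= start:
                continue
            chrom = aln.reference_name
            if index is not None and chrom not in index:
                raise ParseError(f"{path}: unknown chromosome {chrom!r}")
            mids.setdefault(chrom, []).append(fragment_midpoint(start, end))
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in mids.items()}


def _fmt(value) -> str:
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)


def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def write_bed12(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write gene models as single-block BED12 records."""
    with open(path, "w") as fh:
        for rec in genes.itertuples(index=False):
            size = rec.end - rec.start
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name}\t{rec.score}\t"
                f"{rec.strand}\t{rec.start}\t{rec.end}\t0\t1\t{size},\t0,\n"
            )


def write_narrowpeak(peaks: pd.DataFrame, path: str | os.PathLike) -> None:
    df = peaks.copy()
    for col, default in (
        ("name", "."),
        ("score", 0),
        ("strand", "."),
        ("signalValue", 0.0),
        ("pValue", -1.0),
        ("qValue", -1.0),
        ("peak", -1),
    ):
        if col not in df.columns:
            df[col] = default
    df.to_csv(path, sep="\t", header=False, index=False, columns=list(NARROWPEAK_COLUMNS))


def write_bedgraph(grid, values, path: str | os.PathLike, name: str = "track") -> None:
    """Write one value per grid window as bedGraph.

    Adjacent equal-valued windows are written separately (window identity
    is preserved for downstream round-tripping).
    """
    values = np.asarray(values, dtype=float)
    if len(values) != grid.n:
        raise ValueError(f"{len(values)} values for {grid.n} windows")
    buf = io.StringIO()
    buf.write(f"track type=bedGraph name={name}\n")
    for chrom, start, end, v in zip(grid.chroms, grid.starts, grid.ends, values):
        buf.write(f"{chrom}\t{start}\t{end}\t{v:.6f}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
            rows.append(
                {
                    "chrom": fields[0],
                    "start": int(fields[1]),
                    "end": int(fields[2]),
                    "value": float(fields[3]),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Tab-delimited table with a header row."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
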