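"""Genomic interval model, overlap arithmetic, genome binning, and format I/O.

All coordinates are 0-based half-open (BED convention) internally.  GTF input
(1-based, end-inclusive) is converted at the reader boundary.  Strand is
carried on intervals but ignored by every overlap operation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np


class BedFormatError(ValueError):
    """Raised on malformed BED/bedGraph/chrom-sizes input, naming the line."""


@dataclass(frozen=True)
class GenomeAssembly:
    """An ordered set of named chromosomes with lengths in bp."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be > 0")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Bases shared by two intervals; 0 when on different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(
    a: GenomicInterval, b: GenomicInterval, min_frac: float, strict: bool = True
) -> bool:
    """True when each interval is covered beyond ``min_frac`` by the mutual overlap.

    The comparison is strict (>) by default, matching the "> 50% reciprocal
    overlap" sharing rule; set ``strict=False`` for >=.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    ov = overlap_bp(a, b)
    fa, fb = ov / a.length, ov / b.length
    if strict:
        return fa > min_frac and fb > min_frac
    return fa >= min_frac and fb >= min_frac


class IntervalSet:
    """A sorted collection of intervals backed by parallel numpy arrays.

    Sorting key is (chrom, start, end).  Optional per-interval payload
    (name, score, strand) is preserved.  The set may contain internal
    overlaps; ``merged()`` returns the self-merged union.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        self.chroms = np.array([iv.chrom for iv in ivs], dtype=object)
        self.starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        self.ends = np.array([iv.end for iv in ivs], dtype=np.int64)
        self.strands = np.array([iv.strand for iv in ivs], dtype=object)
        self.names = np.array([iv.name for iv in ivs], dtype=object)
        self.scores = np.array([iv.score for iv in ivs], dtype=object)

    @classmethod
    def from_arrays(
        cls,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        strands: Sequence[str] | None = None,
        names: Sequence[str | None] | None = None,
        scores: Sequence[float | None] | None = None,
    ) -> "IntervalSet":
        n = len(starts)
        obj = cls.__new__(cls)
        order = np.lexsort((np.asarray(ends), np.asarray(starts), np.asarray(chroms, dtype=object)))
        obj.chroms = np.asarray(chroms, dtype=object)[order]
        obj.starts = np.asarray(starts, dtype=np.int64)[order]
        obj.ends = np.asarray(ends, dtype=np.int64)[order]
        if np.any(obj.starts >= obj.ends) or np.any(obj.starts < 0):
            raise ValueError("invalid interval coordinates in from_arrays")
        for attr, vals, default in (
            ("strands", strands, "."),
            ("names", names, None),
            ("scores", scores, None),
        ):
            arr = np.full(n, default, dtype=object)
            if vals is not None:
                arr = np.asarray(list(vals), dtype=object)[order]
            setattr(obj, attr, arr)
        return obj

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> GenomicInterval:
        return GenomicInterval(
            self.chroms[i],
            int(self.starts[i]),
            int(self.ends[i]),
            self.strands[i],
            self.names[i],
            self.scores[i],
        )

    def merged(self, gap: int = 0) -> "IntervalSet":
        """Self-merge intervals overlapping or within ``gap`` bp of each other."""
        if len(self) == 0:
            return IntervalSet()
        out_c, out_s, out_e = [], [], []
        cur_c, cur_s, cur_e = self.chroms[0], self.starts[0], self.ends[0]
        for c, s, e in zip(self.chroms[1:], self.starts[1:], self.ends[1:]):
            if c == cur_c and s <= cur_e + gap:
                cur_e = max(cur_e, e)
            else:
                out_c.append(cur_c), out_s.append(cur_s), out_e.append(cur_e)
                cur_c, cur_s, cur_e = c, s, e
        out_c.append(cur_c), out_s.append(cur_s), out_e.append(cur_e)
        return IntervalSet.from_arrays(out_c, out_s, out_e)

    def covered_bp(self) -> int:
        m = self.merged()
        return int(np.sum(m.ends - m.starts))

    def _merged_by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        m = self.merged()
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in np.unique(m.chroms) if len(m) else []:
            sel = m.chroms == chrom
            out[chrom] = (m.starts[sel], m.ends[sel])
        return out

    def overlaps_any(self, others: "IntervalSet") -> np.ndarray:
        """Boolean per interval of self: does it overlap >= 1 bp of ``others``?"""
        idx = others._merged_by_chrom()
        res = np.zeros(len(self), dtype=bool)
        for i in range(len(self)):
            pair = idx.get(self.chroms[i])
            if pair is None:
                continue
            starts, ends = pair
            # blocks are merged and sorted, so the only candidate overlapping
            # [s, e) is the last block starting before e
            j = np.searchsorted(starts, self.ends[i], side="left")
            if j > 0:
                res[i] = bool(ends[j - 1] > self.starts[i])
        return res

    def overlap_bp_with(self, others: "IntervalSet") -> np.ndarray:
        """Per interval of self, total bp overlapped by the union of ``others``."""
        idx = others._merged_by_chrom()
        res = np.zeros(len(self), dtype=np.int64)
        for i in range(len(self)):
            pair = idx.get(self.chroms[i])
            if pair is None:
                continue
            starts, ends = pair
            lo = np.searchsorted(ends, self.starts[i], side="right")
            hi = np.searchsorted(starts, self.ends[i], side="left")
            if hi > lo:
                ov = np.minimum(ends[lo:hi], self.ends[i]) - np.maximum(
                    starts[lo:hi], self.starts[i]
                )
                res[i] = int(np.sum(np.maximum(ov, 0)))
        return res


def covered_bp(iset: IntervalSet) -> int:
    """Total bases covered by the union of the set (overlaps merged)."""
    return iset.covered_bp()


def bin_genome(assembly: GenomeAssembly, width: int) -> IntervalSet:
    """Tile every chromosome with non-overlapping ``width`` bp windows.

    The last tile of each chromosome is truncated at the chromosome end, so
    the tiles partition the genome exactly.
    """
    if width <= 0:
        raise ValueError("bin width must be > 0")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for chrom, length in zip(assembly.chrom_names, assembly.chrom_lengths):
        edges = list(range(0, length, width)) + [length]
        for s, e in zip(edges[:-1], edges[1:]):
            chroms.append(chrom)
            starts.append(s)
            ends.append(e)
    return IntervalSet.from_arrays(chroms, starts, ends)


# ---------------------------------------------------------------------------
# readers / writers


def parse_bed(path: str | Path, expects_score: bool = False) -> IntervalSet:
    """Read a 3+ column BED file (0-based half-open) into an IntervalSet.

    Malformed lines raise :class:`BedFormatError` naming the line number.
    With ``expects_score`` a missing column 5 is an error.
    """
    chroms, starts, ends, names, scores, strands = [], [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}: line {lineno}: expected >= 3 tab-separated columns")
            try:
                s, e = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if s < 0 or s >= e:
                raise BedFormatError(
                    f"{path}: line {lineno}: invalid interval [{s}, {e}) (start must be < end)"
                )
            if expects_score and len(fields) < 5:
                raise BedFormatError(f"{path}: line {lineno}: score column required")
            chroms.append(fields[0])
            starts.append(s)
            ends.append(e)
            names.append(fields[3] if len(fields) > 3 else None)
            scores.append(_parse_score(fields[4]) if len(fields) > 4 else None)
            strands.append(fields[5] if len(fields) > 5 and fields[5] in "+-" else ".")
    return IntervalSet.from_arrays(chroms, starts, ends, strands, names, scores)


def _parse_score(tok: str) -> float | None:
    if tok in (".", ""):
        return None
    return float(tok)


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    """Write BED3 or BED6 depending on available payload."""
    six = any(n is not None for n in iset.names) or any(s != "." for s in iset.strands) or any(
        s is not None for s in iset.scores
    )
    with open(path, "w") as fh:
        for iv in iset:
            if six:
                score = "." if iv.score is None else f"{iv.score:g}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path: str | Path) -> GenomeAssembly:
    names, lengths = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedFormatError(f"{path}: line {lineno}: expected 'name<TAB>length'")
            names.append(fields[0])
            try:
                lengths.append(int(fields[1]))
            except ValueError as exc:
                raise BedFormatError(f"{path}: line {lineno}: non-integer length") from exc
    return GenomeAssembly(tuple(names), tuple(lengths))


def write_chrom_sizes(assembly: GenomeAssembly, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(assembly.chrom_names, assembly.chrom_lengths):
            fh.write(f"{name}\t{length}\n")


@dataclass
class GeneModel:
    """Gene structure parsed from GTF: span, TSS, and sub-features.

    Coordinates already converted to the 0-based half-open convention.
    """

    gene_id: str
    span: GenomicInterval
    tss: int
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in transcription order."""
        exs = sorted(self.exons, key=lambda e: e.start)
        gaps = [
            GenomicInterval(self.span.chrom, a.end, b.start, self.strand)
            for a, b in zip(exs[:-1], exs[1:])
            if b.start > a.end
        ]
        if self.strand == "-":
            gaps = gaps[::-1]
        return gaps


def read_gtf_genes(path: str | Path) -> list[GeneModel]:
    """Parse gene/exon/UTR features from a GTF file via gffutils.

    GTF is 1-based inclusive; subtracting 1 from starts converts to the
    internal half-open convention.  TSS is the 5' end of the gene span.
    """
    import gffutils

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    genes: dict[str, GeneModel] = {}
    for f in db.features_of_type("gene"):
        gid = f.attributes["gene_id"][0]
        span = GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
        tss = span.start if f.strand != "-" else span.end - 1
        genes[gid] = GeneModel(gid, span, tss, f.strand)
    for ftype, attr in (("exon", "exons"), ("five_prime_utr", "utr5"), ("three_prime_utr", "utr3")):
        for f in db.features_of_type(ftype):
            gid = f.attributes["gene_id"][0]
            if gid in genes:
                getattr(genes[gid], attr).append(
                    GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
                )
    return list(genes.values())


def write_gtf_genes(genes: Sequence[GeneModel], path: str | Path, source: str = "starrkit") -> None:
    """Write gene models as GTF (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            rows = [("gene", g.span)]
            rows += [("exon", iv) for iv in sorted(g.exons, key=lambda e: e.start)]
            rows += [("five_prime_utr", iv) for iv in g.utr5]
            rows += [("three_prime_utr", iv) for iv in g.utr3]
            for ftype, iv in rows:
                fh.write(
                    f"{iv.chrom}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    """Read a bedGraph file into (chrom, start, end, value) records."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedFormatError(f"{path}: line {lineno}: expected 4 columns")
            try:
                rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
            except ValueError as exc:
                raise BedFormatError(f"{path}: line {lineno}: malformed record") from exc
    return rows


def write_bedgraph(rows: Iterable[tuple[str, int, int, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
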