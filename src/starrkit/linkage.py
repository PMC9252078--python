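"""Enhancer-to-trait linkage through QTL overlap, TADs and Hi-C contacts.

QTL intervals longer than half their chromosome are discarded (they carry no
positional information), remaining QTLs are intersected with enhancer calls,
and each enhancer-QTL-gene triple is tested for (a) TAD co-membership of the
enhancer and the gene promoter and (b) a significant Hi-C contact between
their 40 kb bins.  Contact significance uses a distance-stratified Poisson
upper tail: the expected count for a bin pair is the chromosome-wide mean of
all pairs at the same bin distance, which absorbs the power-law distance
decay of contact frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomeAssembly, GenomicInterval, IntervalSet, overlap_bp


@dataclass(frozen=True)
class QtlRecord:
    interval: GenomicInterval
    trait: str
    source: str = ""


@dataclass
class ContactMatrix:
    """Symmetric per-chromosome contact counts at fixed resolution."""

    chrom: str
    resolution: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if np.any(m < 0):
            raise ValueError("contact counts must be non-negative")
        if not np.allclose(m, m.T):
            raise ValueError("contact matrix must be symmetric")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_of(self, pos: int) -> int:
        b = pos // self.resolution
        if not 0 <= b < self.n_bins:
            raise ValueError(f"position {pos} outside matrix bins on {self.chrom}")
        return int(b)

    def distance_means(self) -> np.ndarray:
        """Mean contact over all bin pairs at each |bin distance|."""
        n = self.n_bins
        means = np.empty(n)
        for d in range(n):
            means[d] = float(np.mean(np.diagonal(self.matrix, offset=d)))
        return means


@dataclass(frozen=True)
class TraitLink:
    """An enhancer x QTL x candidate-gene triple with linkage evidence."""

    enhancer: GenomicInterval
    qtl: QtlRecord
    gene_id: str
    same_tad: bool
    observed: float
    expected: float
    contact_p: float
    flagged: bool


def filter_qtls(qtls: Sequence[QtlRecord], assembly: GenomeAssembly) -> list[QtlRecord]:
    """Drop QTLs longer than half their chromosome (boundary length retained)."""
    lengths = assembly.lengths
    out = []
    for q in qtls:
        if q.interval.chrom not in lengths:
            raise ValueError(f"QTL on unknown chromosome {q.interval.chrom!r}")
        if q.interval.length <= 0.5 * lengths[q.interval.chrom]:
            out.append(q)
    return out


def qtl_enhancer_overlap(
    qtls: Sequence[QtlRecord],
    enhancer_intervals: Sequence[GenomicInterval],
    merge_regions: bool = False,
):
    """QTLs overlapping >= 1 bp of any enhancer, with region/trait counts.

    Non-redundant regions are exact-coordinate deduplicates by default
    (records sharing coordinates but differing in trait count once as a
    region but contribute each trait); ``merge_regions=True`` merges
    overlapping hit regions instead.
    Returns (hits: dict qtl -> list of overlapping enhancers,
    n_nonredundant_qtls, n_traits).
    """
    hits: dict[QtlRecord, list[GenomicInterval]] = {}
    for q in qtls:
        touching = [
            iv for iv in enhancer_intervals
            if overlap_bp(iv, q.interval) >= 1
        ]
        if touching:
            hits[q] = touching
    regions = {(q.interval.chrom, q.interval.start, q.interval.end) for q in hits}
    if merge_regions:
        rs = IntervalSet.from_arrays(
            [r[0] for r in regions], [r[1] for r in regions], [r[2] for r in regions]
        ) if regions else IntervalSet()
        n_regions = len(rs.merged())
    else:
        n_regions = len(regions)
    n_traits = len({q.trait for q in hits})
    return hits, n_regions, n_traits


def same_tad(a: GenomicInterval, b: GenomicInterval, tads: IntervalSet) -> bool:
    """True iff one TAD contains the midpoints of both intervals."""
    # validate: TADs non-overlapping per chromosome
    for chrom in np.unique(tads.chroms) if len(tads) else []:
        sel = tads.chroms == chrom
        s, e = tads.starts[sel], tads.ends[sel]
        if np.any(s[1:] < e[:-1]):
            raise ValueError(f"overlapping TADs on {chrom}: corrupt input")
    if a.chrom != b.chrom:
        return False
    for t in tads:
        if t.chrom == a.chrom and t.start <= a.midpoint < t.end and t.start <= b.midpoint < t.end:
            return True
    return False


def contact_significance(
    m: ContactMatrix, a: GenomicInterval, b: GenomicInterval
) -> tuple[float, float, float]:
    """(observed, expected, Poisson upper-tail p) for a bin pair.

    Expected is the mean contact over all pairs at the same bin distance on
    the chromosome; p = P(X >= observed) for X ~ Poisson(expected).
    """
    if a.chrom != m.chrom or b.chrom != m.chrom:
        raise ValueError("intervals must lie on the matrix chromosome")
    bi, bj = m.bin_of(a.midpoint), m.bin_of(b.midpoint)
    observed = float(m.matrix[bi, bj])
    expected = float(np.mean(np.diagonal(m.matrix, offset=abs(bi - bj))))
    p = float(stats.poisson.sf(np.ceil(observed) - 1, expected)) if expected > 0 else (
        1.0 if observed == 0 else 0.0
    )
    return observed, expected, p


def link_enhancers(
    enhancer_intervals: Sequence[GenomicInterval],
    qtls: Sequence[QtlRecord],
    genes,
    tads: IntervalSet,
    matrices: Mapping[str, ContactMatrix],
    alpha: float = 0.05,
) -> list[TraitLink]:
    """Emit TraitLinks for every (enhancer, QTL, QTL-overlapping gene) triple.

    ``genes`` is a sequence with ``gene_id``, ``span`` and ``tss`` attributes
    (GeneModel or GeneRecord).  A link is *flagged* as a candidate iff the
    enhancer and the gene promoter share a TAD AND their Hi-C contact is
    significant at ``alpha``.  The gene anchor is its TSS bin.
    """
    links: list[TraitLink] = []
    for q in qtls:
        q_enh = [iv for iv in enhancer_intervals if overlap_bp(iv, q.interval) >= 1]
        if not q_enh:
            continue
        q_genes = [g for g in genes if overlap_bp(g.span, q.interval) >= 1]
        for iv in q_enh:
            for g in q_genes:
                tss_iv = GenomicInterval(g.span.chrom, g.tss, g.tss + 1)
                in_tad = same_tad(iv, tss_iv, tads)
                if iv.chrom == g.span.chrom and iv.chrom in matrices:
                    obs, exp, p = contact_significance(matrices[iv.chrom], iv, tss_iv)
                else:
                    obs, exp, p = 0.0, 0.0, 1.0
                links.append(
                    TraitLink(iv, q, g.gene_id, in_tad, obs, exp, p,
                              flagged=bool(in_tad and p < alpha))
                )
    return links


# ---------------------------------------------------------------------------
# I/O


def read_qtl_table(path: str | Path) -> list[QtlRecord]:
    """Read a QTL TSV (chrom, start, end, trait, source), 1-based inclusive.

    Coordinates are converted to 0-based half-open at this boundary, the
    convention animal-QTLdb-style exports use.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected chrom, start, end, trait")
            try:
                start1, end1 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            source = fields[4] if len(fields) > 4 else ""
            out.append(QtlRecord(GenomicInterval(fields[0], start1 - 1, end1), fields[3], source))
    return out


def write_qtl_table(qtls: Sequence[QtlRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for q in qtls:
            fh.write(
                f"{q.interval.chrom}\t{q.interval.start + 1}\t{q.interval.end}\t{q.trait}\t{q.source}\n"
            )


def write_contact_matrix(m: ContactMatrix, path: str | Path) -> None:
    """Dense tab-separated text with a bin-coordinate header row."""
    with open(path, "w") as fh:
        fh.write(f"# chrom={m.chrom} resolution={m.resolution}\n")
        header = "\t".join(str(b * m.resolution) for b in range(m.n_bins))
        fh.write("bin_start\t" + header + "\n")
        for b in range(m.n_bins):
            row = "\t".join(f"{x:g}" for x in m.matrix[b])
            fh.write(f"{b * m.resolution}\t{row}\n")


def read_contact_matrix(path: str | Path) -> ContactMatrix:
    with open(path) as fh:
        meta = fh.readline().strip()
        if not meta.startswith("#"):
            raise ValueError(f"{path}: line 1: expected '# chrom=... resolution=...' header")
        kv = dict(tok.split("=") for tok in meta.lstrip("# ").split())
        fh.readline()  # column header
        rows = []
        for line in fh:
            if line.strip():
                rows.append([float(x) for x in line.split("\t")[1:]])
    return ContactMatrix(kv["chrom"], int(kv["resolution"]), np.array(rows))


def links_to_table(links: Sequence[TraitLink], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "enh_chrom\tenh_start\tenh_end\tqtl_chrom\tqtl_start\tqtl_end\ttrait\t"
            "gene\tsame_tad\tobserved\texpected\tcontact_p\tflagged\n"
        )
        for l in links:
            fh.write(
                f"{l.enhancer.chrom}\t{l.enhancer.start}\t{l.enhancer.end}\t"
                f"{l.qtl.interval.chrom}\t{l.qtl.interval.start}\t{l.qtl.interval.end}\t"
                f"{l.qtl.trait}\t{l.gene_id}\t{int(l.same_tad)}\t"
                f"{l.observed:g}\t{l.expected:g}\t{l.contact_p:.3e}\t{int(l.flagged)}\n"
            )
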