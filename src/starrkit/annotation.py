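"""Feature classification, enrichment, nearest-gene and expression binning.

Each enhancer is assigned a single genomic feature category by a priority
rule (repetitive first by default — the categories are mutually exclusive
and repeats dominate the genome under study), with the TE subclass recorded
when the repeat overlap lies in a transposable element.  Relative enrichment
normalizes the category fraction by the genomic background fraction of the
feature, so a feature's abundance cannot masquerade as preference.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .intervals import (
    GenomeAssembly,
    GenomicInterval,
    IntervalSet,
    GeneModel,
    overlap_bp,
)

TE_SUBCLASS_ORDER = ("LINE", "SINE", "LTR", "DNA")

DEFAULT_PRIORITY = (
    "repetitive",
    "tss_proximal",
    "utr5",
    "utr3",
    "first_intron",
    "other_intron",
    "exon",
)


class ExpressionBin(str, Enum):
    silent = "silent"
    low = "low"
    medium = "medium"
    high = "high"


@dataclass(frozen=True)
class GeneRecord:
    """Flat gene record: span, TSS, expression."""

    gene_id: str
    span: GenomicInterval
    tss: int
    fpkm: float = 0.0

    def __post_init__(self) -> None:
        if not self.span.start <= self.tss < self.span.end:
            raise ValueError(f"TSS {self.tss} outside span for {self.gene_id}")
        if self.fpkm < 0:
            raise ValueError("FPKM must be >= 0")


@dataclass
class FeatureCatalog:
    """Per-category interval sets with a priority order.

    ``intergenic`` is implicit: an enhancer overlapping no category falls
    through to it.
    """

    categories: dict[str, IntervalSet]
    te_subclasses: dict[str, IntervalSet]
    priority: tuple[str, ...] = DEFAULT_PRIORITY

    def __post_init__(self) -> None:
        for cat in self.priority:
            self.categories.setdefault(cat, IntervalSet())


def build_catalog(
    genes: Sequence[GeneModel],
    repeats: IntervalSet,
    tss_window: int = 2000,
    assembly: GenomeAssembly | None = None,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> FeatureCatalog:
    """Derive the feature catalog from gene models and repeat annotation.

    TSS-proximal = TSS +/- ``tss_window`` bp (clipped to the chromosome when
    an assembly is given).  First intron is the first intron in
    transcription order.
    """
    tss_c, tss_s, tss_e = [], [], []
    cats: dict[str, list[GenomicInterval]] = {
        "utr5": [], "utr3": [], "first_intron": [], "other_intron": [], "exon": []
    }
    for g in genes:
        lo = max(0, g.tss - tss_window)
        hi = g.tss + tss_window
        if assembly is not None:
            hi = min(hi, assembly.lengths[g.span.chrom])
        tss_c.append(g.span.chrom), tss_s.append(lo), tss_e.append(hi)
        cats["utr5"] += g.utr5
        cats["utr3"] += g.utr3
        cats["exon"] += g.exons
        introns = g.introns
        if introns:
            cats["first_intron"].append(introns[0])
            cats["other_intron"] += introns[1:]
    categories = {name: IntervalSet(ivs) for name, ivs in cats.items()}
    categories["tss_proximal"] = (
        IntervalSet.from_arrays(tss_c, tss_s, tss_e) if tss_c else IntervalSet()
    )
    categories["repetitive"] = repeats
    te_subclasses = {
        sub: IntervalSet([iv for iv in repeats if iv.name == sub])
        for sub in TE_SUBCLASS_ORDER
    }
    return FeatureCatalog(categories, te_subclasses, priority)


def classify_enhancer(
    enhancer: GenomicInterval, catalog: FeatureCatalog
) -> tuple[str, str | None]:
    """(category, te_subclass) for one enhancer.

    Category = highest-priority catalog category with >= 1 bp overlap,
    falling through to 'intergenic'.  When the category is repetitive and
    the enhancer overlaps a TE, the subclass with the largest overlap is
    recorded (ties broken by LINE > SINE > LTR > DNA).
    """
    one = IntervalSet([enhancer])
    category = "intergenic"
    for cat in catalog.priority:
        if len(catalog.categories[cat]) and bool(one.overlaps_any(catalog.categories[cat])[0]):
            category = cat
            break
    subclass = None
    if category == "repetitive":
        best = 0
        for sub in TE_SUBCLASS_ORDER:
            ivs = catalog.te_subclasses.get(sub)
            if ivs is None or len(ivs) == 0:
                continue
            ov = int(one.overlap_bp_with(ivs)[0])
            if ov > best:  # strict: earlier class wins ties
                best = ov
                subclass = sub
    return category, subclass


def classify_all(
    enhancers: Sequence[GenomicInterval], catalog: FeatureCatalog
) -> list[tuple[str, str | None]]:
    return [classify_enhancer(iv, catalog) for iv in enhancers]


def feature_enrichment(
    assignments: Sequence[str | None],
    feature_label: str,
    feature_set: IntervalSet,
    assembly: GenomeAssembly,
) -> float:
    """Fold change of the category fraction over the genomic background.

    ``assignments`` is the per-enhancer category (or subclass) label list;
    FC = (fraction of enhancers labelled ``feature_label``) /
    (covered_bp(feature) / genome_bp).
    """
    bg = feature_set.covered_bp() / assembly.total_bp
    if bg == 0:
        raise ValueError(f"feature {feature_label!r} covers 0 bp")
    if not assignments:
        raise ValueError("no enhancers to classify")
    frac = sum(1 for a in assignments if a == feature_label) / len(assignments)
    return frac / bg


def nearest_gene(
    enhancer: GenomicInterval, genes: Sequence[GeneRecord | GeneModel]
) -> tuple[str, int]:
    """(gene id, distance bp) of the closest gene.

    Distance is 0 when spans overlap, otherwise the gap between nearest
    edges; genes on other chromosomes are infinitely far.  Ties break to the
    lexicographically smallest gene id.
    """
    if not genes:
        raise ValueError("gene list is empty")
    best: tuple[float, str] = (float("inf"), "")
    for g in genes:
        if g.span.chrom != enhancer.chrom:
            continue
        if overlap_bp(g.span, enhancer) > 0:
            d = 0
        elif g.span.end <= enhancer.start:
            d = enhancer.start - g.span.end
        else:
            d = g.span.start - enhancer.end
        if (d, g.gene_id) < best:
            best = (d, g.gene_id)
    if best[1] == "":
        raise ValueError(f"no gene on chromosome {enhancer.chrom!r}")
    return best[1], int(best[0])


def expression_bin(fpkm: float) -> ExpressionBin:
    """Silent: FPKM = 0; low: 0 < FPKM <= 1; medium: 1 < FPKM <= 10; high: > 10."""
    if fpkm < 0:
        raise ValueError("FPKM must be >= 0")
    if fpkm == 0:
        return ExpressionBin.silent
    if fpkm <= 1:
        return ExpressionBin.low
    if fpkm <= 10:
        return ExpressionBin.medium
    return ExpressionBin.high


def read_expression_table(path) -> dict[str, float]:
    """Two-column TSV gene_id -> FPKM (header optional)."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            gid, _, val = line.partition("\t")
            if lineno == 1 and gid.lower() in ("gene", "gene_id"):
                continue
            try:
                out[gid] = float(val)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed FPKM value") from exc
    return out
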