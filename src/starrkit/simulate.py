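"""Synthetic STARR-seq study generator.

Builds a toy two-chromosome genome with repeat/TE annotation, gene models,
planted enhancers of known activity, STARR-seq fragment libraries, ATAC/ChIP
signal tracks with planted peaks, an expression table, QTLs, TADs and Hi-C
contact matrices — everything the analysis stages consume, with known ground
truth for parameter-recovery benchmarks.

Generative model of the reporter assay
--------------------------------------
The input plasmid library is a uniform random fragmentation of the genome:
midpoints uniform, lengths ~ Normal(600, 100) clipped to [200, 1200] bp
(median fragment length about 600 bp, mirroring the sequenced libraries this
generator is scaled from).  The cDNA library is a weighted resample *of the
realized input pool*: every cDNA fragment is one of the transfected input
molecules, drawn with replacement with probability proportional to the
activity of the planted enhancer containing its midpoint (weight 1
elsewhere).  Sampling from the shared pool is what the assay physically does
— transcripts can only come from transfected plasmids — and it makes the
caller's binomial null (success probability = input fraction) exact
conditional on the input counts.

Scale
-----
Default desk scale is 2 chromosomes x 2.5 Mb with 1e5 fragments per library,
which reproduces the sequencing depth that drives the caller: ~12 input
fragments per 600 bp window, matching a ~45 M-fragment library on a 2.5 Gb
genome at the ~1000x scale-down.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .calling import FragmentLibrary
from .chromatin import SignalTrack
from .intervals import (
    GenomeAssembly,
    GenomicInterval,
    IntervalSet,
    GeneModel,
    write_bed,
    write_chrom_sizes,
    write_gtf_genes,
    write_bedgraph,
)
from .linkage import ContactMatrix, QtlRecord, write_contact_matrix, write_qtl_table

TE_CLASSES = ("LINE", "SINE", "LTR", "DNA")
TRACK_MARKS = ("ATAC", "H3K4me1", "H3K4me3", "H3K27ac", "H3K9me3", "H3K27me3", "CTCF")

# fixed per-operation RNG stream codes: adding a simulator must not perturb
# the draws of existing ones
_STREAM = {
    "genome": 11,
    "fragments_input": 12,
    "fragments_cdna": 13,
    "tracks": 14,
    "hic": 15,
    "expression": 16,
    "qtls": 17,
}


@dataclass(frozen=True)
class SimConfig:
    """Study-scale configuration of the synthetic generator."""

    n_chroms: int = 2
    chrom_length: int = 2_500_000
    n_genes: int = 200
    repeat_fraction: float = 0.40
    te_class_weights: Mapping[str, float] = field(
        default_factory=lambda: {"LINE": 0.45, "SINE": 0.35, "LTR": 0.15, "DNA": 0.05}
    )
    te_fraction_of_repeats: float = 0.5
    n_enhancers: int = 20
    enhancer_length: int = 600
    activity_range: tuple[float, float] = (3.0, 6.0)
    enhancer_repeat_fraction: float = 0.5
    enhancer_grid: int | None = 600  # align planted elements to this grid
    n_input_frags: int = 100_000
    n_cdna_frags: int = 100_000
    frag_len_mean: float = 600.0
    frag_len_sd: float = 100.0
    frag_len_bounds: tuple[int, int] = (200, 1200)
    silent_fraction: float = 0.4
    open_chromatin_fraction: float = 0.2
    mark_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "H3K4me1": 0.30,
            "H3K4me3": 0.15,
            "H3K27ac": 0.25,
            "H3K9me3": 0.45,
            "H3K27me3": 0.35,
            "CTCF": 0.20,
        }
    )
    linked_gene_fraction: float = 0.25
    hic_resolution: int = 40_000
    seed: int = 1

    def __post_init__(self) -> None:
        fracs = (
            self.repeat_fraction,
            self.te_fraction_of_repeats,
            self.enhancer_repeat_fraction,
            self.silent_fraction,
            self.open_chromatin_fraction,
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if self.activity_range[0] < 1 or self.activity_range[1] < self.activity_range[0]:
            raise ValueError("activity multipliers must be >= 1 and ordered")
        if min(self.n_chroms, self.chrom_length, self.n_genes, self.n_enhancers,
               self.n_input_frags, self.n_cdna_frags) <= 0:
            raise ValueError("counts must be > 0")


@dataclass(frozen=True)
class EnhancerTruth:
    """Ground truth for one planted enhancer."""

    interval: GenomicInterval
    activity: float
    open_chromatin: bool
    marks: Mapping[str, bool]
    linked_gene: str | None = None

    @property
    def active_marks(self) -> dict[str, bool]:
        return {m: self.marks[m] for m in ("H3K4me1", "H3K4me3", "H3K27ac")}

    @property
    def repressive_marks(self) -> dict[str, bool]:
        return {m: self.marks[m] for m in ("H3K9me3", "H3K27me3")}


@dataclass
class SimGenome:
    assembly: GenomeAssembly
    repeats: IntervalSet  # name column carries the repeat class
    genes: list[GeneModel]
    truth: list[EnhancerTruth]


def _rng(config_seed: int, op: str) -> np.random.Generator:
    return np.random.default_rng([config_seed, _STREAM[op]])


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimConfig) -> SimGenome:
    """Toy genome with repeats, gene models and planted enhancers.

    Repeats are laid down as alternating exponential gaps and lognormal
    element lengths tuned to hit ``repeat_fraction`` (corrected to within
    +/- 2%); each element is a TE (class drawn from ``te_class_weights``)
    with probability ``te_fraction_of_repeats`` and a simple repeat
    otherwise.  Genes are non-overlapping with a 5'UTR / first-intron /
    internal-exon / 3'UTR structure.  Enhancers are planted in repeat or
    non-repeat windows per ``enhancer_repeat_fraction``, aligned to
    ``enhancer_grid`` when set, with activities uniform in
    ``activity_range``.
    """
    if config.repeat_fraction > 0.9:
        raise ValueError("repeat_fraction > 0.9: infeasible packing")
    rng = _rng(config.seed, "genome")
    assembly = GenomeAssembly(
        tuple(f"chr{i + 1}" for i in range(config.n_chroms)),
        tuple([config.chrom_length] * config.n_chroms),
    )
    repeats = _place_repeats(config, rng, assembly)
    genes = _place_genes(config, rng, assembly)
    truth = _place_enhancers(config, rng, assembly, repeats, genes)
    return SimGenome(assembly, repeats, genes, truth)


def _place_repeats(config: SimConfig, rng, assembly) -> IntervalSet:
    if config.repeat_fraction == 0:
        return IntervalSet()
    mean_len = 800.0
    mean_gap = mean_len * (1 - config.repeat_fraction) / config.repeat_fraction
    chroms, starts, ends, names = [], [], [], []
    for chrom, length in zip(assembly.chrom_names, assembly.chrom_lengths):
        pos = int(rng.exponential(mean_gap))
        while pos < length:
            rep_len = int(np.clip(rng.lognormal(np.log(mean_len) - 0.18, 0.6), 100, 5000))
            end = min(pos + rep_len, length)
            chroms.append(chrom)
            starts.append(pos)
            ends.append(end)
            names.append(_repeat_class(config, rng))
            pos = end + max(1, int(rng.exponential(mean_gap)))
    # correct drift: drop or extend elements until within 1.5% of target
    covered = float(np.sum(np.array(ends) - np.array(starts)))
    target = config.repeat_fraction * assembly.total_bp
    while covered > target * 1.015 and chroms:
        k = int(rng.integers(len(chroms)))
        covered -= ends[k] - starts[k]
        del chroms[k], starts[k], ends[k], names[k]
    return IntervalSet.from_arrays(chroms, starts, ends, names=names)


def _repeat_class(config: SimConfig, rng) -> str:
    if rng.random() < config.te_fraction_of_repeats:
        classes = list(config.te_class_weights)
        w = np.array([config.te_class_weights[c] for c in classes], dtype=float)
        return classes[int(rng.choice(len(classes), p=w / w.sum()))]
    return "Simple_repeat"


def _place_genes(config: SimConfig, rng, assembly) -> list[GeneModel]:
    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in assembly.chrom_names}
    total_len = assembly.total_bp
    need = config.n_genes
    attempts = 0
    while len(genes) < need:
        attempts += 1
        if attempts > 200 * need:
            raise ValueError("infeasible packing: cannot place requested genes")
        glen = int(rng.integers(2_000, 12_001))
        gpos = int(rng.integers(0, total_len - glen))
        chrom_idx = gpos // config.chrom_length
        chrom = assembly.chrom_names[min(chrom_idx, config.n_chroms - 1)]
        start = gpos % config.chrom_length
        if start + glen > config.chrom_length:
            continue
        if any(s < start + glen and start < e for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, start + glen))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(_gene_structure(f"gene_{len(genes) + 1:04d}", chrom, start, glen, strand))
    return sorted(genes, key=lambda g: (g.span.chrom, g.span.start))


def _gene_structure(gid: str, chrom: str, start: int, glen: int, strand: str) -> GeneModel:
    """Three-exon gene: 5'UTR in exon 1, first intron, internal exon, 3'UTR."""
    end = start + glen
    span = GenomicInterval(chrom, start, end, strand)
    e1, e2, e3 = 400, 200, 300
    intron1 = max(200, int(0.3 * (glen - e1 - e2 - e3)))
    b0, b1 = start, start + e1                       # exon 1 (5' on + strand)
    b2 = b1 + intron1
    b3 = b2 + e2                                     # internal exon
    b5 = end
    b4 = b5 - e3                                     # last exon
    exons = [
        GenomicInterval(chrom, b0, b1, strand),
        GenomicInterval(chrom, b2, min(b3, b4 - 1), strand),
        GenomicInterval(chrom, b4, b5, strand),
    ]
    if strand != "-":
        tss = start
        utr5 = [GenomicInterval(chrom, b0, b0 + 200, strand)]
        utr3 = [GenomicInterval(chrom, b5 - 200, b5, strand)]
    else:
        tss = end - 1
        utr5 = [GenomicInterval(chrom, b5 - 200, b5, strand)]
        utr3 = [GenomicInterval(chrom, b0, b0 + 200, strand)]
    return GeneModel(gid, span, tss, strand, exons, utr5, utr3)


def _place_enhancers(config: SimConfig, rng, assembly, repeats, genes) -> list[EnhancerTruth]:
    L, W = config.enhancer_length, config.enhancer_grid or 1
    candidates: list[GenomicInterval] = []
    for chrom, length in zip(assembly.chrom_names, assembly.chrom_lengths):
        starts = np.arange(0, length - L + 1, W)
        candidates += [GenomicInterval(chrom, int(s), int(s) + L) for s in starts]
    cand_set = IntervalSet(candidates)
    in_repeat = cand_set.overlap_bp_with(repeats) >= L // 2
    cand_sorted = list(cand_set)
    rep_idx = [k for k, f in enumerate(in_repeat) if f]
    non_idx = [k for k, f in enumerate(in_repeat) if not f]
    n_rep = round(config.enhancer_repeat_fraction * config.n_enhancers)
    n_non = config.n_enhancers - n_rep
    if len(rep_idx) < n_rep or len(non_idx) < n_non:
        raise ValueError("infeasible packing: not enough candidate windows for enhancers")
    chosen: list[int] = []
    for pool, n in ((rep_idx, n_rep), (non_idx, n_non)):
        pool = list(pool)
        while n > 0:
            k = pool[int(rng.integers(len(pool)))]
            # keep planted elements >= 2 windows apart so calls never merge
            if all(abs(k - c) > 2 or cand_sorted[k].chrom != cand_sorted[c].chrom for c in chosen):
                chosen.append(k)
                n -= 1
    chosen_ivs = [cand_sorted[k] for k in sorted(chosen)]
    activities = rng.uniform(*config.activity_range, size=config.n_enhancers)
    truth = []
    gene_ids = [g.gene_id for g in genes]
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.span.chrom, []).append(g)
    for iv, act in zip(chosen_ivs, activities):
        marks = {m: bool(rng.random() < p) for m, p in sorted(config.mark_probs.items())}
        open_chrom = bool(rng.random() < config.open_chromatin_fraction)
        linked = None
        same_chrom = genes_by_chrom.get(iv.chrom, [])
        if same_chrom and rng.random() < config.linked_gene_fraction:
            # prefer genes at looping distance (2-10 Hi-C bins at 40 kb) so a
            # planted contact is neither within-bin nor implausibly long-range
            mid = iv.midpoint
            in_range = [g for g in same_chrom if 80_000 <= abs(g.tss - mid) <= 400_000]
            pool = in_range or same_chrom
            linked = pool[int(rng.integers(len(pool)))].gene_id
        truth.append(EnhancerTruth(iv, float(act), open_chrom, marks, linked))
    return truth


# ---------------------------------------------------------------------------
# fragment libraries


def simulate_fragments(
    genome: SimGenome,
    truth: Sequence[EnhancerTruth],
    library: str,
    n: int,
    seed: int,
    pool: FragmentLibrary | None = None,
    frag_len_mean: float = 600.0,
    frag_len_sd: float = 100.0,
    frag_len_bounds: tuple[int, int] = (200, 1200),
    replicate: str = "rep1",
    cell_line: str = "cellA",
) -> FragmentLibrary:
    """Simulate one fragment library.

    ``library='input'``: fragment midpoints uniform over the genome, lengths
    Normal(mean, sd) clipped to ``frag_len_bounds`` and to the chromosome.

    ``library='cdna'``: a weighted with-replacement resample of ``pool`` (the
    input plasmid library) — each pool fragment is drawn with probability
    proportional to the activity of the truth enhancer containing its
    midpoint (1 outside enhancers); strands are re-assigned uniformly.
    Duplicates are possible by construction.
    """
    if library not in ("input", "cdna"):
        raise ValueError("library must be 'input' or 'cdna'")
    assembly = genome.assembly
    if n == 0:
        return FragmentLibrary(IntervalSet(), 0, library, replicate, cell_line)
    if library == "input":
        rng = np.random.default_rng([seed, _STREAM["fragments_input"]])
        total = assembly.total_bp
        gpos = rng.integers(0, total, size=n)
        lens = np.clip(
            np.rint(rng.normal(frag_len_mean, frag_len_sd, size=n)), *frag_len_bounds
        ).astype(np.int64)
        strands = np.where(rng.random(n) < 0.5, "+", "-").astype(object)
        bounds = np.cumsum([0] + list(assembly.chrom_lengths))
        chrom_idx = np.searchsorted(bounds, gpos, side="right") - 1
        local = gpos - bounds[chrom_idx]
        clens = np.asarray(assembly.chrom_lengths)[chrom_idx]
        starts = np.clip(local - lens // 2, 0, np.maximum(clens - lens, 0))
        ends = np.minimum(starts + lens, clens)
        chroms = np.asarray(assembly.chrom_names, dtype=object)[chrom_idx]
        frags = IntervalSet.from_arrays(chroms, starts, ends, strands)
        return FragmentLibrary(frags, n, "input", replicate, cell_line)
    # cDNA: weighted resample of the input pool
    if pool is None:
        raise ValueError("cdna simulation requires the input pool library")
    rng = np.random.default_rng([seed, _STREAM["fragments_cdna"]])
    pf = pool.fragments
    mids = (pf.starts + pf.ends) // 2
    weights = np.ones(len(pf))
    for t in truth:
        sel = (pf.chroms == t.interval.chrom) & (mids >= t.interval.start) & (mids < t.interval.end)
        weights[sel] = t.activity
    idx = rng.choice(len(pf), size=n, p=weights / weights.sum())
    strands = np.where(rng.random(n) < 0.5, "+", "-").astype(object)
    frags = IntervalSet.from_arrays(pf.chroms[idx], pf.starts[idx], pf.ends[idx], strands)
    return FragmentLibrary(frags, n, "cdna", replicate, cell_line)


# ---------------------------------------------------------------------------
# chromatin tracks


def simulate_tracks(
    genome: SimGenome,
    truth: Sequence[EnhancerTruth],
    mark: str,
    seed: int,
    bin_width: int = 100,
    peak_fold: tuple[float, float] = (4.0, 8.0),
    peak_halfwidth: int = 300,
    n_background_peaks: int = 30,
    noise_shape: float = 8.0,
) -> tuple[IntervalSet, SignalTrack]:
    """One mark's peak set and binned signal track.

    Baseline signal is Gamma noise with mean 1.  Where a truth enhancer
    carries the mark (ATAC uses the open-chromatin flag), signal over the
    enhancer +/- ``peak_halfwidth`` is multiplied by a fold drawn from
    ``peak_fold`` (>= 3 by default, guaranteeing enrichment over a matched
    INPUT track).  Background peaks of the same strength are added away from
    any planted logic to mimic genome-wide peak calls.  ``mark='INPUT'``
    yields baseline noise and no peaks.
    """
    known = TRACK_MARKS + ("INPUT",)
    if mark not in known:
        raise ValueError(f"unknown mark {mark!r}; known: {', '.join(known)}")
    rng = np.random.default_rng([seed, _STREAM["tracks"], _mark_code(mark)])
    assembly = genome.assembly
    values = {
        chrom: rng.gamma(noise_shape, 1.0 / noise_shape, size=-(-length // bin_width))
        for chrom, length in zip(assembly.chrom_names, assembly.chrom_lengths)
    }
    peaks_c, peaks_s, peaks_e = [], [], []
    if mark != "INPUT":
        for t in truth:
            flagged = t.open_chromatin if mark == "ATAC" else t.marks.get(mark, False)
            if not flagged:
                continue
            s = max(0, t.interval.start - peak_halfwidth)
            e = min(assembly.lengths[t.interval.chrom], t.interval.end + peak_halfwidth)
            _boost(values, t.interval.chrom, s, e, bin_width, float(rng.uniform(*peak_fold)))
            peaks_c.append(t.interval.chrom)
            peaks_s.append(s)
            peaks_e.append(e)
        for _ in range(n_background_peaks):
            chrom = assembly.chrom_names[int(rng.integers(len(assembly.chrom_names)))]
            width = 2 * peak_halfwidth
            s = int(rng.integers(0, assembly.lengths[chrom] - width))
            e = s + width
            _boost(values, chrom, s, e, bin_width, float(rng.uniform(*peak_fold)))
            peaks_c.append(chrom)
            peaks_s.append(s)
            peaks_e.append(e)
    peaks = (
        IntervalSet.from_arrays(peaks_c, peaks_s, peaks_e) if peaks_c else IntervalSet()
    )
    return peaks, SignalTrack(values, bin_width, mark)


def _mark_code(mark: str) -> int:
    return {m: k for k, m in enumerate(TRACK_MARKS + ("INPUT",))}[mark]


def _boost(values, chrom, start, end, bin_width, fold) -> None:
    lo, hi = start // bin_width, -(-end // bin_width)
    values[chrom][lo:hi] *= fold


# ---------------------------------------------------------------------------
# Hi-C


@dataclass
class HicStudy:
    matrices: dict[str, ContactMatrix]
    tads: IntervalSet


def simulate_hic(
    genome: SimGenome,
    links: Sequence[tuple[GenomicInterval, int]],
    resolution: int = 40_000,
    seed: int = 1,
    base_contacts: float = 100.0,
    link_boost: float = 5.0,
    tad_boost: float = 1.5,
    tad_bins: tuple[int, int] = (6, 16),
) -> HicStudy:
    """Power-law-decay Hi-C matrices with TAD blocks and boosted pairs.

    Expected contact between bins at distance d is ``base / (1 + d)``,
    multiplied by ``tad_boost`` inside a TAD block and by ``link_boost`` for
    each (enhancer interval, partner TSS position) pair in ``links``.
    Counts are Poisson; matrices are symmetric by construction.
    """
    rng = np.random.default_rng([seed, _STREAM["hic"]])
    assembly = genome.assembly
    matrices: dict[str, ContactMatrix] = {}
    tads_c, tads_s, tads_e = [], [], []
    for chrom, length in zip(assembly.chrom_names, assembly.chrom_lengths):
        n = -(-length // resolution)
        if n < 2:
            raise ValueError(f"resolution {resolution} gives < 2 bins on {chrom}")
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        lam = base_contacts / (1.0 + d)
        # TAD blocks: consecutive-bin partition with elevated intra-block
        # contact; boundaries never split a linked pair (enhancer-promoter
        # contacts are preferentially intra-TAD)
        pair_bins = [
            tuple(sorted((iv.midpoint // resolution, tss // resolution)))
            for iv, tss in links
            if iv.chrom == chrom
        ]
        b = 0
        while b < n:
            size = int(rng.integers(*tad_bins))
            hi = min(b + size, n)
            for lo_b, hi_b in pair_bins:
                if lo_b < hi <= hi_b:
                    hi = min(hi_b + 1, n)
            lam[b:hi, b:hi] *= tad_boost
            tads_c.append(chrom)
            tads_s.append(b * resolution)
            tads_e.append(min(hi * resolution, length))
            b = hi
        for iv, tss in links:
            if iv.chrom != chrom:
                continue
            bi, bj = iv.midpoint // resolution, tss // resolution
            if bi != bj:
                lam[bi, bj] *= link_boost
                lam[bj, bi] *= link_boost
        upper = np.triu(rng.poisson(lam), k=1)
        mat = upper + upper.T + np.diag(rng.poisson(np.diag(lam)))
        matrices[chrom] = ContactMatrix(chrom, resolution, mat.astype(float))
    return HicStudy(matrices, IntervalSet.from_arrays(tads_c, tads_s, tads_e))


# ---------------------------------------------------------------------------
# expression, QTLs


def simulate_expression(
    genes: Sequence[GeneModel],
    seed: int,
    silent_fraction: float = 0.4,
    log_mean: float = 0.5,
    log_sd: float = 1.5,
) -> dict[str, float]:
    """FPKM per gene: a silent fraction at exactly 0, the rest log-normal."""
    rng = np.random.default_rng([seed, _STREAM["expression"]])
    n = len(genes)
    silent = rng.random(n) < silent_fraction
    fpkm = np.where(silent, 0.0, rng.lognormal(log_mean, log_sd, size=n))
    return {g.gene_id: float(v) for g, v in zip(genes, fpkm)}


def simulate_qtls(
    genome: SimGenome,
    seed: int,
    n_qtls: int = 40,
    n_traits: int = 15,
    length_range: tuple[int, int] = (50_000, 1_200_000),
    enhancer_overlap_fraction: float = 0.5,
    n_oversized: int = 3,
) -> list[QtlRecord]:
    """QTL regions with trait labels; a fraction forced to contain a planted
    enhancer, plus a few oversized records (> half a chromosome) to exercise
    the length filter."""
    rng = np.random.default_rng([seed, _STREAM["qtls"]])
    assembly = genome.assembly
    traits = [f"trait_{k + 1:02d}" for k in range(n_traits)]
    out: list[QtlRecord] = []
    for k in range(n_qtls):
        trait = traits[int(rng.integers(n_traits))]
        qlen = int(rng.integers(*length_range))
        if out and rng.random() < enhancer_overlap_fraction and genome.truth:
            t = genome.truth[int(rng.integers(len(genome.truth)))]
            chrom = t.interval.chrom
            clen = assembly.lengths[chrom]
            qlen = min(qlen, clen)
            lo = max(0, t.interval.end - qlen)
            hi = min(t.interval.start, clen - qlen)
            start = int(rng.integers(lo, hi + 1)) if hi >= lo else 0
        else:
            chrom = assembly.chrom_names[int(rng.integers(len(assembly.chrom_names)))]
            clen = assembly.lengths[chrom]
            qlen = min(qlen, clen // 2)
            start = int(rng.integers(0, clen - qlen + 1))
        out.append(QtlRecord(GenomicInterval(chrom, start, start + qlen), trait, f"sim_{k + 1}"))
    for k in range(n_oversized):
        chrom = assembly.chrom_names[k % len(assembly.chrom_names)]
        clen = assembly.lengths[chrom]
        out.append(
            QtlRecord(
                GenomicInterval(chrom, 0, clen // 2 + 1 + k),
                traits[k % n_traits],
                f"sim_oversized_{k + 1}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# whole-study orchestration


@dataclass
class SimulatedStudy:
    """Everything one synthetic study run produces."""

    config: SimConfig
    genome: SimGenome
    libraries: dict[tuple[str, str, str], FragmentLibrary]  # (cell, rep, label)
    tracks: dict[str, tuple[IntervalSet, SignalTrack]]
    input_track: SignalTrack
    expression: dict[str, float]
    qtls: list[QtlRecord]
    hic: HicStudy


def simulate_study(
    config: SimConfig = SimConfig(),
    cell_lines: Sequence[str] = ("PK15", "ST"),
    replicates: Sequence[str] = ("rep1", "rep2"),
) -> SimulatedStudy:
    """Run every simulator with streams derived from ``config.seed``."""
    genome = simulate_genome(config)
    libraries: dict[tuple[str, str, str], FragmentLibrary] = {}
    for ci, cell in enumerate(cell_lines):
        for ri, rep in enumerate(replicates):
            sub = config.seed + 1000 * ci + 100 * ri
            inp = simulate_fragments(
                genome, genome.truth, "input", config.n_input_frags, sub,
                frag_len_mean=config.frag_len_mean, frag_len_sd=config.frag_len_sd,
                frag_len_bounds=config.frag_len_bounds, replicate=rep, cell_line=cell,
            )
            cdna = simulate_fragments(
                genome, genome.truth, "cdna", config.n_cdna_frags, sub, pool=inp,
                replicate=rep, cell_line=cell,
            )
            libraries[(cell, rep, "input")] = inp
            libraries[(cell, rep, "cdna")] = cdna
    tracks = {}
    for mark in TRACK_MARKS:
        tracks[mark] = simulate_tracks(genome, genome.truth, mark, config.seed)
    _, input_track = simulate_tracks(genome, genome.truth, "INPUT", config.seed)
    expression = simulate_expression(genome.genes, config.seed,
                                     silent_fraction=config.silent_fraction)
    qtls = simulate_qtls(genome, config.seed)
    genes_by_id = {g.gene_id: g for g in genome.genes}
    links = [
        (t.interval, genes_by_id[t.linked_gene].tss)
        for t in genome.truth
        if t.linked_gene is not None
    ]
    hic = simulate_hic(genome, links, config.hic_resolution, config.seed)
    return SimulatedStudy(config, genome, libraries, tracks, input_track,
                          expression, qtls, hic)


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write every study component in its standard text format."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_chrom_sizes(study.genome.assembly, out / "genome.chrom.sizes")
    write_bed(study.genome.repeats, out / "repeats.bed")
    write_gtf_genes(study.genome.genes, out / "genes.gtf")
    truth_set = IntervalSet.from_arrays(
        [t.interval.chrom for t in study.genome.truth],
        [t.interval.start for t in study.genome.truth],
        [t.interval.end for t in study.genome.truth],
        names=[f"truth_{k + 1:03d}" for k in range(len(study.genome.truth))],
        scores=[t.activity for t in study.genome.truth],
    )
    write_bed(truth_set, out / "enhancer_truth.bed")
    for (cell, rep, label), lib in sorted(study.libraries.items()):
        write_bed(lib.fragments, out / f"{cell}_{rep}_{label}.bed")
    for mark, (peaks, track) in sorted(study.tracks.items()):
        write_bed(peaks, out / f"{mark}_peaks.bed")
        write_bedgraph(track.to_bedgraph_rows(), out / f"{mark}_signal.bedgraph")
    write_bedgraph(study.input_track.to_bedgraph_rows(), out / "INPUT_signal.bedgraph")
    with open(out / "expression.tsv", "w") as fh:
        fh.write("gene_id\tfpkm\n")
        for gid, v in sorted(study.expression.items()):
            fh.write(f"{gid}\t{v:.6g}\n")
    write_qtl_table(study.qtls, out / "qtls.tsv")
    write_bed(study.hic.tads, out / "tads.bed")
    for chrom, m in sorted(study.hic.matrices.items()):
        write_contact_matrix(m, out / f"hic_{chrom}.tsv")
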