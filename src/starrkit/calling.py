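"""Window-based STARR-seq enhancer caller.

The caller tiles the genome with fixed-width windows (600 bp by default),
counts deduplicated fragment midpoints per window in the cDNA and input
plasmid libraries, and scores each window with

* strength (fold change): ``(c / C) / (i / I)`` where ``c``/``i`` are the
  window's cDNA/input midpoint counts and ``C``/``I`` the library totals;
* an upper-tail binomial p-value ``P(X >= c)`` for
  ``X ~ Binomial(C, i / I)`` — the input fraction is the null success
  probability, so the test asks whether the cDNA library over-samples the
  window relative to the plasmid pool;
* a Benjamini-Hochberg q-value over all informative windows.

Windows passing strength > 1.0, P < 0.001 and FDR < 0.1 (the default
thresholds) are merged into enhancer calls.  Replicate concordance and
cross-cell-line consensus/union sets complete the caller's surface.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    GenomeAssembly,
    GenomicInterval,
    IntervalSet,
    bin_genome,
    reciprocal_overlap,
)


@dataclass
class FragmentLibrary:
    """Deduplicated sequenced-fragment intervals for one library."""

    fragments: IntervalSet
    total_unique: int
    label: str  # "input" or "cdna"
    replicate: str = "rep1"
    cell_line: str = "cellA"

    def __post_init__(self) -> None:
        if self.label not in ("input", "cdna"):
            raise ValueError(f"library label must be 'input' or 'cdna', got {self.label!r}")


@dataclass(frozen=True)
class CallThresholds:
    """Significance and windowing parameters of the caller."""

    min_strength: float = 1.0
    max_p: float = 1e-3
    max_fdr: float = 0.1
    window_width: int = 600
    window_step: int | None = None  # None = non-overlapping tiles
    pseudo: int = 1

    def __post_init__(self) -> None:
        if min(self.min_strength, self.max_p, self.max_fdr, self.window_width) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class EnhancerCall:
    """A merged run of significant windows."""

    interval: GenomicInterval
    strength: float
    best_p: float
    best_q: float
    provenance: str = ""

    @property
    def length(self) -> int:
        return self.interval.length


def dedup_fragments(
    raw: IntervalSet, label: str = "input", replicate: str = "rep1", cell_line: str = "cellA"
) -> FragmentLibrary:
    """Collapse exact duplicates on (chrom, start, end, strand), as Picard
    MarkDuplicates would for identically mapped fragment pairs."""
    seen = set()
    keep = []
    for i in range(len(raw)):
        key = (raw.chroms[i], int(raw.starts[i]), int(raw.ends[i]), raw.strands[i])
        if key not in seen:
            seen.add(key)
            keep.append(i)
    keep_idx = np.array(keep, dtype=int)
    if len(raw) == 0:
        uniq = IntervalSet()
    else:
        uniq = IntervalSet.from_arrays(
            raw.chroms[keep_idx],
            raw.starts[keep_idx],
            raw.ends[keep_idx],
            raw.strands[keep_idx],
        )
    return FragmentLibrary(uniq, len(uniq), label, replicate, cell_line)


def count_midpoints(lib: FragmentLibrary, assembly: GenomeAssembly, width: int) -> np.ndarray:
    """Midpoint counts per genome tile (concatenated across chromosomes).

    A fragment belongs to the unique tile containing ``floor((start+end)/2)``;
    counts therefore sum to the library total.  Midpoints beyond a
    chromosome's end indicate corrupt input and raise.
    """
    frags = lib.fragments
    lengths = assembly.lengths
    offsets: dict[str, int] = {}
    off = 0
    nbins_per = {}
    for chrom, length in zip(assembly.chrom_names, assembly.chrom_lengths):
        nbins = -(-length // width)
        offsets[chrom] = off
        nbins_per[chrom] = nbins
        off += nbins
    counts = np.zeros(off, dtype=np.int64)
    mids = (frags.starts + frags.ends) // 2
    for chrom in np.unique(frags.chroms) if len(frags) else []:
        if chrom not in lengths:
            raise ValueError(f"fragment on unknown chromosome {chrom!r}")
        sel = frags.chroms == chrom
        m = mids[sel]
        if np.any(m >= lengths[chrom]) or np.any(m < 0):
            raise ValueError(f"fragment midpoint outside chromosome {chrom!r}")
        counts[offsets[chrom] : offsets[chrom] + nbins_per[chrom]] += np.bincount(
            m // width, minlength=nbins_per[chrom]
        )
    return counts


def window_stats(
    cdna_count,
    input_count,
    cdna_total: int,
    input_total: int,
    pseudo: int = 1,
):
    """Strength and binomial upper-tail p for one window (vectorized).

    ``pseudo`` substitutes for the input count only when it is zero, keeping
    the strength finite while staying conservative.  The p-value is the exact
    upper tail ``P(X >= c)`` with ``X ~ Binomial(C, i0 / I)``.
    """
    if cdna_total <= 0 or input_total <= 0:
        raise ValueError("library totals must be > 0")
    if pseudo < 0:
        raise ValueError("pseudo-count must be >= 0")
    c = np.asarray(cdna_count)
    i = np.asarray(input_count)
    i0 = np.where(i == 0, pseudo, i).astype(float)
    strength = (c / cdna_total) / (i0 / input_total)
    p = stats.binom.sf(c - 1, cdna_total, i0 / input_total)
    if np.ndim(cdna_count) == 0:
        return float(strength), float(p)
    return strength, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compute_window_stats(
    cdna: FragmentLibrary,
    inp: FragmentLibrary,
    assembly: GenomeAssembly,
    thr: CallThresholds = CallThresholds(),
) -> pd.DataFrame:
    """Per-window statistics table over the genome tiling.

    Columns: chrom, start, end, cdna_count, input_count, strength, p_value,
    q_value.  BH adjustment runs only over windows with at least one
    fragment in either library (empty windows carry no information and
    would dilute the step-up); empty windows get q = 1.
    """
    if thr.window_step is not None and thr.window_step != thr.window_width:
        return _compute_window_stats_sliding(cdna, inp, assembly, thr)
    bins = bin_genome(assembly, thr.window_width)
    c = count_midpoints(cdna, assembly, thr.window_width)
    i = count_midpoints(inp, assembly, thr.window_width)
    strength, p = window_stats(c, i, cdna.total_unique, inp.total_unique, thr.pseudo)
    tested = (c + i) > 0
    q = np.ones_like(p)
    if tested.any():
        q[tested] = bh_fdr(p[tested])
    return pd.DataFrame(
        {
            "chrom": bins.chroms,
            "start": bins.starts,
            "end": bins.ends,
            "cdna_count": c,
            "input_count": i,
            "strength": strength,
            "p_value": p,
            "q_value": q,
        }
    )


def _compute_window_stats_sliding(
    cdna: FragmentLibrary,
    inp: FragmentLibrary,
    assembly: GenomeAssembly,
    thr: CallThresholds,
) -> pd.DataFrame:
    """Sliding-window variant: width ``window_width``, step ``window_step``.

    Implemented as cumulative sums over a fine tiling at the step size, so a
    fragment contributes to every window containing its midpoint.
    """
    step, width = thr.window_step, thr.window_width
    if width % step != 0:
        raise ValueError("window_width must be a multiple of window_step")
    k = width // step
    rows = []
    c_fine = count_midpoints(cdna, assembly, step)
    i_fine = count_midpoints(inp, assembly, step)
    off = 0
    for chrom, length in zip(assembly.chrom_names, assembly.chrom_lengths):
        nfine = -(-length // step)
        # window starting at fine-bin s sums fine bins s..s+k-1 = full[s+k-1]
        cc = np.convolve(c_fine[off : off + nfine], np.ones(k, dtype=int), mode="full")[k - 1 :]
        ii = np.convolve(i_fine[off : off + nfine], np.ones(k, dtype=int), mode="full")[k - 1 :]
        starts = np.arange(nfine) * step
        ends = np.minimum(starts + width, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                                  "cdna_count": cc.astype(np.int64), "input_count": ii.astype(np.int64)}))
        off += nfine
    df = pd.concat(rows, ignore_index=True)
    strength, p = window_stats(
        df["cdna_count"].to_numpy(), df["input_count"].to_numpy(),
        cdna.total_unique, inp.total_unique, thr.pseudo,
    )
    df["strength"] = strength
    df["p_value"] = p
    tested = (df["cdna_count"] + df["input_count"]).to_numpy() > 0
    q = np.ones(len(df))
    if tested.any():
        q[tested] = bh_fdr(p[tested])
    df["q_value"] = q
    return df


def call_enhancers(stats_df: pd.DataFrame, thr: CallThresholds = CallThresholds(),
                   provenance: str = "") -> list[EnhancerCall]:
    """Select significant windows and merge adjacent/overlapping ones.

    A window passes when strength > min_strength (strict), p < max_p and
    q < max_fdr.  Merged call strength is the max constituent window
    strength; best_p/best_q are the minima.

    In sliding-window mode (step < width) a merged run of overlapping
    significant windows is reported at its summit — the single best
    (max-strength) window — since the run is wider than the underlying
    element by construction.  Tiled mode reports the full merged span.
    """
    summit_mode = thr.window_step is not None and thr.window_step < thr.window_width
    passing = stats_df[
        (stats_df["strength"] > thr.min_strength)
        & (stats_df["p_value"] < thr.max_p)
        & (stats_df["q_value"] < thr.max_fdr)
    ].sort_values(["chrom", "start"])
    calls: list[EnhancerCall] = []
    cur = None
    for row in passing.itertuples(index=False):
        if cur is not None and row.chrom == cur["chrom"] and row.start <= cur["end"]:
            cur["end"] = max(cur["end"], row.end)
            if row.strength > cur["strength"]:
                cur["strength"] = row.strength
                cur["summit"] = (row.start, row.end)
            cur["p"] = min(cur["p"], row.p_value)
            cur["q"] = min(cur["q"], row.q_value)
        else:
            if cur is not None:
                calls.append(_as_call(cur, provenance, summit_mode))
            cur = {"chrom": row.chrom, "start": row.start, "end": row.end,
                   "strength": row.strength, "p": row.p_value, "q": row.q_value,
                   "summit": (row.start, row.end)}
    if cur is not None:
        calls.append(_as_call(cur, provenance, summit_mode))
    return calls


def _as_call(d: dict, provenance: str, summit_mode: bool = False) -> EnhancerCall:
    if summit_mode:
        d = {**d, "start": d["summit"][0], "end": d["summit"][1]}
    return EnhancerCall(
        GenomicInterval(d["chrom"], int(d["start"]), int(d["end"])),
        float(d["strength"]),
        float(d["p"]),
        float(d["q"]),
        provenance,
    )


def replicate_concordance(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    log_scale: bool = True,
    eps: float = 0.01,
) -> float:
    """Pearson correlation of window strengths between two replicates.

    Windows with zero counts in both libraries of both replicates are
    excluded.  By default the correlation is computed on log2(FC + eps);
    ``log_scale=False`` uses raw fold changes.
    """
    if len(stats_a) != len(stats_b):
        raise ValueError("replicates must share the same window tiling")
    informative = (
        stats_a["cdna_count"].to_numpy()
        + stats_a["input_count"].to_numpy()
        + stats_b["cdna_count"].to_numpy()
        + stats_b["input_count"].to_numpy()
    ) > 0
    if informative.sum() < 2:
        raise ValueError("fewer than 2 informative windows")
    x = stats_a["strength"].to_numpy()[informative]
    y = stats_b["strength"].to_numpy()[informative]
    if log_scale:
        x, y = np.log2(x + eps), np.log2(y + eps)
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class ConsensusResult:
    """Replicate-consensus, cross-cell-line shared, and union call sets."""

    consensus_by_cell: dict[str, list[EnhancerCall]]
    shared: list[EnhancerCall]
    union: list[EnhancerCall]
    venn: dict[str, int] = field(default_factory=dict)


def _pair_consensus(
    calls_a: Sequence[EnhancerCall],
    calls_b: Sequence[EnhancerCall],
    min_reciprocal: float,
    provenance: str,
) -> list[EnhancerCall]:
    """Pairs with reciprocal overlap > min_reciprocal, collapsed to union spans."""
    out: list[EnhancerCall] = []
    used_spans = set()
    for a, b in itertools.product(calls_a, calls_b):
        if reciprocal_overlap(a.interval, b.interval, min_reciprocal):
            span = GenomicInterval(
                a.interval.chrom,
                min(a.interval.start, b.interval.start),
                max(a.interval.end, b.interval.end),
            )
            key = (span.chrom, span.start, span.end)
            if key in used_spans:
                continue
            used_spans.add(key)
            out.append(
                EnhancerCall(
                    span,
                    max(a.strength, b.strength),
                    min(a.best_p, b.best_p),
                    min(a.best_q, b.best_q),
                    provenance,
                )
            )
    return sorted(out, key=lambda c: (c.interval.chrom, c.interval.start))


def merge_calls(calls: Sequence[EnhancerCall], provenance: str = "union") -> list[EnhancerCall]:
    """Self-merge calls at > 0 bp overlap into non-redundant intervals."""
    ordered = sorted(calls, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    merged: list[EnhancerCall] = []
    for c in ordered:
        if merged and merged[-1].interval.chrom == c.interval.chrom and c.interval.start < merged[-1].interval.end:
            prev = merged[-1]
            merged[-1] = EnhancerCall(
                GenomicInterval(
                    prev.interval.chrom,
                    prev.interval.start,
                    max(prev.interval.end, c.interval.end),
                ),
                max(prev.strength, c.strength),
                min(prev.best_p, c.best_p),
                min(prev.best_q, c.best_q),
                provenance,
            )
        else:
            merged.append(replace(c, provenance=provenance))
    return merged


def consensus_and_union(
    calls_by_source: Mapping[tuple[str, str], Sequence[EnhancerCall]],
    min_reciprocal: float = 0.5,
) -> ConsensusResult:
    """Build per-cell-line replicate consensus, cross-line shared, and union sets.

    ``calls_by_source`` maps (cell_line, replicate) to that run's calls.
    Cell lines with two or more replicates get a replicate consensus
    (reciprocal-overlap pairing of the first two replicates); single-replicate
    lines use their calls directly.  The cross-line shared set pairs the two
    cell lines' consensus sets the same way.  The union self-merges all calls
    from every source at > 0 bp overlap.
    """
    by_cell: dict[str, list[Sequence[EnhancerCall]]] = {}
    for (cell, _rep), calls in sorted(calls_by_source.items()):
        by_cell.setdefault(cell, []).append(calls)
    consensus: dict[str, list[EnhancerCall]] = {}
    for cell, reps in by_cell.items():
        if len(reps) >= 2:
            consensus[cell] = _pair_consensus(reps[0], reps[1], min_reciprocal, f"{cell}:consensus")
        else:
            consensus[cell] = [replace(c, provenance=f"{cell}:consensus") for c in reps[0]]
    cells = sorted(consensus)
    shared: list[EnhancerCall] = []
    if len(cells) >= 2:
        shared = _pair_consensus(consensus[cells[0]], consensus[cells[1]], min_reciprocal, "shared")
    union = merge_calls([c for calls in calls_by_source.values() for c in calls])
    venn = {f"n_{cell}": len(consensus[cell]) for cell in cells}
    venn["n_shared"] = len(shared)
    venn["n_union"] = len(union)
    return ConsensusResult(consensus, shared, union, venn)


def calls_to_bed(calls: Sequence[EnhancerCall], path) -> None:
    """Write calls as BED6+ (name=id, score=round(100*strength), +p, q, provenance)."""
    with open(path, "w") as fh:
        for k, c in enumerate(calls, start=1):
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t"
                f"enh_{k:05d}\t{round(100 * c.strength)}\t.\t"
                f"{c.best_p:.3e}\t{c.best_q:.3e}\t{c.provenance}\n"
            )
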