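"""Chromatin-state integration for called enhancers.

Enhancers are split into *open* (overlapping an ATAC-seq accessible-chromatin
peak by >= 1 bp) and *closed* sets, scored for ChIP/INPUT fold enrichment,
profiled over +/- 5 kb flanks in 100 bp bins, compared between groups with
Wilcoxon rank-sum tests, and classified into active/repressive state classes
from histone-mark peak overlap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomeAssembly, GenomicInterval, IntervalSet

ACTIVE_MARKS = ("H3K4me1", "H3K4me3", "H3K27ac")
REPRESSIVE_MARKS = ("H3K9me3", "H3K27me3")


class StateClass(str, Enum):
    active_only = "active_only"
    repressive_only = "repressive_only"
    both = "both"
    neither = "neither"


@dataclass
class SignalTrack:
    """Fixed-width binned coverage values per chromosome (bedGraph-backed)."""

    values: dict[str, np.ndarray]
    bin_width: int
    label: str = ""

    def __post_init__(self) -> None:
        for chrom, v in self.values.items():
            if np.any(np.asarray(v) < 0):
                raise ValueError(f"negative signal values on {chrom}")

    def region_mean(self, region: GenomicInterval) -> float:
        """Mean signal over a region, weighting bins by bp of overlap."""
        if region.chrom not in self.values:
            raise ValueError(f"region chromosome {region.chrom!r} not covered by track")
        v = self.values[region.chrom]
        w = self.bin_width
        lo, hi = region.start // w, -(-region.end // w)
        if lo < 0 or hi > len(v):
            raise ValueError(f"region {region.chrom}:{region.start}-{region.end} outside track coverage")
        idx = np.arange(lo, hi)
        bin_starts = idx * w
        overlap = np.minimum(bin_starts + w, region.end) - np.maximum(bin_starts, region.start)
        return float(np.sum(v[idx] * overlap) / np.sum(overlap))

    def to_bedgraph_rows(self):
        for chrom in sorted(self.values):
            v = self.values[chrom]
            for j, x in enumerate(v):
                yield (chrom, j * self.bin_width, (j + 1) * self.bin_width, float(x))

    @classmethod
    def from_bedgraph_rows(cls, rows, bin_width: int, label: str = "") -> "SignalTrack":
        values: dict[str, dict[int, float]] = {}
        for chrom, start, end, val in rows:
            if (end - start) != bin_width and end % bin_width != 0:
                raise ValueError(f"bedGraph record [{start},{end}) does not match bin width {bin_width}")
            values.setdefault(chrom, {})[start // bin_width] = val
        out = {}
        for chrom, d in values.items():
            arr = np.zeros(max(d) + 1)
            for j, val in d.items():
                arr[j] = val
            out[chrom] = arr
        return cls(out, bin_width, label)


def classify_accessibility(
    enhancer_intervals: Sequence[GenomicInterval], atac_peaks: IntervalSet
) -> list[str]:
    """Label each enhancer 'open' (>= 1 bp ATAC-peak overlap) or 'closed'."""
    iset = IntervalSet(enhancer_intervals)
    flags = iset.overlaps_any(atac_peaks)
    # IntervalSet sorts; map flags back to the input order
    order = sorted(range(len(enhancer_intervals)),
                   key=lambda k: (enhancer_intervals[k].chrom,
                                  enhancer_intervals[k].start,
                                  enhancer_intervals[k].end))
    out = [""] * len(enhancer_intervals)
    for sorted_pos, orig in enumerate(order):
        out[orig] = "open" if flags[sorted_pos] else "closed"
    return out


def fold_enrichment(
    chip: SignalTrack, inp: SignalTrack, region: GenomicInterval, pseudo: float = 0.1
) -> float:
    """(mean ChIP + pseudo) / (mean INPUT + pseudo) over a region."""
    if chip.bin_width != inp.bin_width:
        raise ValueError("ChIP and INPUT tracks must share binning")
    return (chip.region_mean(region) + pseudo) / (inp.region_mean(region) + pseudo)


@dataclass
class ChromatinProfile:
    """Per-enhancer fold-enrichment matrix over flanking bins.

    Rows are enhancers (those whose window fits in the chromosome), columns
    the ``2 * flank / bin`` bins centred on the enhancer midpoint.
    """

    matrix: np.ndarray
    n_dropped: int
    flank: int
    bin_width: int

    @property
    def mean_profile(self) -> np.ndarray:
        return self.matrix.mean(axis=0) if len(self.matrix) else np.zeros(self.matrix.shape[1])


def profile_matrix(
    enhancer_intervals: Sequence[GenomicInterval],
    chip: SignalTrack,
    inp: SignalTrack,
    assembly: GenomeAssembly,
    flank: int = 5000,
    bin_width: int = 100,
    pseudo: float = 0.1,
) -> ChromatinProfile:
    """Midpoint-anchored ChIP/INPUT fold-enrichment profile over +/- flank.

    Enhancers whose profile window would cross a chromosome edge are dropped
    and counted in ``n_dropped``.
    """
    if flank % bin_width != 0:
        raise ValueError("flank must be divisible by bin width")
    ncols = 2 * flank // bin_width
    rows = []
    dropped = 0
    lengths = assembly.lengths
    for iv in enhancer_intervals:
        m = iv.midpoint
        left = m - flank
        if left < 0 or m + flank > lengths[iv.chrom]:
            dropped += 1
            continue
        row = np.empty(ncols)
        for j in range(ncols):
            seg = GenomicInterval(iv.chrom, left + j * bin_width, left + (j + 1) * bin_width)
            row[j] = fold_enrichment(chip, inp, seg, pseudo)
        rows.append(row)
    matrix = np.array(rows) if rows else np.empty((0, ncols))
    return ChromatinProfile(matrix, dropped, flank, bin_width)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for sample x, counting ties as 1/2."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def rank_sum_test(x, y, exact_limit: int = 12) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    For ``n1 + n2 <= exact_limit`` the p-value is exact: every
    ``C(n1+n2, n1)`` relabelling of the pooled values is enumerated and
    arrangements at least as extreme as observed (|U - n1 n2 / 2|) in either
    tail are counted.  Larger samples use the normal approximation with tie
    and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    u_obs = _u_statistic(x, y)
    if n1 + n2 <= exact_limit:
        pooled = np.concatenate([x, y])
        centre = n1 * n2 / 2
        dev = abs(u_obs - centre)
        hits = total = 0
        for comb in itertools.combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - centre) >= dev - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def state_class(
    enhancer: GenomicInterval, mark_peaks: Mapping[str, IntervalSet]
) -> StateClass:
    """Classify an enhancer by active/repressive histone-mark peak overlap."""
    for mark in ACTIVE_MARKS + REPRESSIVE_MARKS:
        if mark not in mark_peaks:
            raise ValueError(f"missing peak set for mark {mark!r}")
    one = IntervalSet([enhancer])
    active = any(bool(one.overlaps_any(mark_peaks[m])[0]) for m in ACTIVE_MARKS)
    repressive = any(bool(one.overlaps_any(mark_peaks[m])[0]) for m in REPRESSIVE_MARKS)
    if active and repressive:
        return StateClass.both
    if active:
        return StateClass.active_only
    if repressive:
        return StateClass.repressive_only
    return StateClass.neither


def compare_open_closed(
    enhancer_intervals: Sequence[GenomicInterval],
    accessibility: Sequence[str],
    chip_tracks: Mapping[str, SignalTrack],
    input_track: SignalTrack,
    pseudo: float = 0.1,
    statistic: str = "mean",
):
    """Per-mark open-vs-closed comparison of per-enhancer fold enrichments.

    Returns a list of dict rows: mark, n_open, n_closed, U, p, and the group
    mean fold enrichments.  ``statistic`` selects the per-enhancer summary
    over the call span ('mean' of the binned fold enrichment; 'max' of the
    per-bin fold within the span).
    """
    import pandas as pd

    rows = []
    open_idx = [k for k, a in enumerate(accessibility) if a == "open"]
    closed_idx = [k for k, a in enumerate(accessibility) if a == "closed"]
    for mark, track in sorted(chip_tracks.items()):
        folds = np.array([
            _enhancer_fold(track, input_track, iv, pseudo, statistic)
            for iv in enhancer_intervals
        ])
        fo, fc = folds[open_idx], folds[closed_idx]
        if len(fo) and len(fc):
            u, p = rank_sum_test(fo, fc)
        else:
            u, p = float("nan"), float("nan")
        rows.append(
            {"mark": mark, "n_open": len(fo), "n_closed": len(fc), "U": u, "p": p,
             "mean_fold_open": float(np.mean(fo)) if len(fo) else float("nan"),
             "mean_fold_closed": float(np.mean(fc)) if len(fc) else float("nan")}
        )
    return pd.DataFrame(rows)


def _enhancer_fold(chip, inp, iv, pseudo, statistic):
    if statistic == "mean":
        return fold_enrichment(chip, inp, iv, pseudo)
    if statistic == "max":
        w = chip.bin_width
        folds = []
        for s in range(iv.start - iv.start % w, iv.end, w):
            seg = GenomicInterval(iv.chrom, max(s, iv.start), min(s + w, iv.end))
            folds.append(fold_enrichment(chip, inp, seg, pseudo))
        return max(folds)
    raise ValueError(f"unknown per-enhancer statistic {statistic!r}")
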