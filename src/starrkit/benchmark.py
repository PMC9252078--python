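"""Ground-truth benchmarks of the caller on synthetic studies.

Sensitivity counts a planted enhancer as recovered when some call matches it
at > 50% reciprocal overlap; empirical FDR is the fraction of calls matching
no planted enhancer.  The same matching rule the consensus stage uses for
"shared" enhancers, applied here to truth.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .calling import CallThresholds, EnhancerCall, call_enhancers, compute_window_stats
from .intervals import GenomicInterval, reciprocal_overlap
from .simulate import SimConfig, simulate_fragments, simulate_genome


def match_calls_to_truth(
    calls: Sequence[EnhancerCall],
    truth_intervals: Sequence[GenomicInterval],
    min_reciprocal: float = 0.5,
) -> tuple[int, int]:
    """(n_truth_recovered, n_false_calls) under reciprocal-overlap matching."""
    recovered = sum(
        any(reciprocal_overlap(t, c.interval, min_reciprocal) for c in calls)
        for t in truth_intervals
    )
    false_calls = sum(
        not any(reciprocal_overlap(c.interval, t, min_reciprocal) for t in truth_intervals)
        for c in calls
    )
    return recovered, false_calls


def run_one_recovery(
    config: SimConfig, thresholds: CallThresholds = CallThresholds()
) -> dict:
    """Simulate one study at ``config`` and call enhancers against truth."""
    genome = simulate_genome(config)
    inp = simulate_fragments(
        genome, genome.truth, "input", config.n_input_frags, config.seed,
        frag_len_mean=config.frag_len_mean, frag_len_sd=config.frag_len_sd,
        frag_len_bounds=config.frag_len_bounds,
    )
    cdna = simulate_fragments(
        genome, genome.truth, "cdna", config.n_cdna_frags, config.seed, pool=inp
    )
    stats = compute_window_stats(cdna, inp, genome.assembly, thresholds)
    calls = call_enhancers(stats, thresholds)
    truth_ivs = [t.interval for t in genome.truth]
    recovered, false_calls = match_calls_to_truth(calls, truth_ivs)
    n_windows_tested = int(((stats["cdna_count"] + stats["input_count"]) > 0).sum())
    n_pass_strength = int((stats["strength"] > thresholds.min_strength).sum())
    return {
        "n_truth": len(truth_ivs),
        "n_calls": len(calls),
        "recovered": recovered,
        "false_calls": false_calls,
        "sensitivity": recovered / len(truth_ivs) if truth_ivs else float("nan"),
        "empirical_fdr": false_calls / len(calls) if calls else 0.0,
        "n_windows_tested": n_windows_tested,
        "n_pass_strength": n_pass_strength,
    }


def recovery_metrics(
    base_config: SimConfig = SimConfig(),
    seeds: Sequence[int] = tuple(range(1, 11)),
    thresholds: CallThresholds = CallThresholds(),
) -> dict:
    """Mean sensitivity and empirical FDR of the caller over seeds."""
    runs = [run_one_recovery(replace(base_config, seed=s), thresholds) for s in seeds]
    return {
        "sensitivity": float(np.mean([r["sensitivity"] for r in runs])),
        "empirical_fdr": float(np.mean([r["empirical_fdr"] for r in runs])),
        "runs": runs,
    }


def null_calibration(
    base_config: SimConfig = SimConfig(),
    seeds: Sequence[int] = tuple(range(1, 21)),
    thresholds: CallThresholds = CallThresholds(),
) -> dict:
    """Call counts when every planted activity is 1 (no real signal).

    The FDR bound implies expected calls <= max_fdr x (windows passing the
    strength filter); the per-seed bound and call counts are returned.
    """
    null_cfg = replace(base_config, activity_range=(1.0, 1.0))
    runs = [run_one_recovery(replace(null_cfg, seed=s), thresholds) for s in seeds]
    return {
        "mean_calls": float(np.mean([r["n_calls"] for r in runs])),
        "mean_bound": float(np.mean(
            [thresholds.max_fdr * r["n_pass_strength"] for r in runs]
        )),
        "runs": runs,
    }
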