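"""Experiment orchestration: the sampling-interval and read-depth grids.

Stage order is fixed: pairs are identified on the *unrarefied* table, then
all samples are rarefied, then the four taxon-level change measures and
the global dissimilarities are computed on the rarefied table and
summarized by abundance bin.  Because pairing precedes rarefaction, depth
comparisons across rarefaction modes are paired: every mode sees exactly
the same sample pairs.

Three standard experiments:

* :func:`run_interval_experiment` — the four sampling intervals at the
  conventional rarefaction depth (100% of the minimum read count).
* :func:`run_depth_experiment` — weekly (7±1 day) pairing under four
  rarefaction conditions (none, 100%, 80%, 60% of the minimum).
* :func:`run_residual_depth_experiment` — weekly pairing, conventional
  rarefaction, summaries by quartile of the pairs' original read depths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from skbio import TreeNode

from .changes import compute_changes
from .core import LongitudinalMicrobiomeTable
from .dissimilarity import pairwise_dissimilarities
from .pairing import PairingSpec, default_specs, enumerate_pairs
from .rarefaction import RarefactionPlan, rarefy_table
from .summaries import (
    AbundanceBinning,
    add_abundance_bins,
    depth_quartile_analysis,
    qualitative_curve,
    summarize_changes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentResult",
    "run_interval_experiment",
    "run_depth_experiment",
    "run_residual_depth_experiment",
    "WEEKLY_SPEC",
    "DEPTH_MODES",
]

WEEKLY_SPEC = PairingSpec(7.0, 1.0, 1.0)
DEPTH_MODES = ("none", "pct100", "pct80", "pct60")


@dataclass
class ExperimentResult:
    """Summaries plus enough provenance to trace every row.

    ``summaries`` carries one row per stratum with the condition keys;
    ``dissimilarities`` one row per (condition, pair, metric); ``curves``
    maps a condition label to its qualitative-change LOESS curve; ``log``
    records resolved depths, pair counts and seeds.
    """

    summaries: pd.DataFrame
    dissimilarities: pd.DataFrame
    curves: Dict[str, pd.DataFrame] = field(default_factory=dict)
    changes: Dict[str, pd.DataFrame] = field(default_factory=dict)
    log: Dict[str, object] = field(default_factory=dict)


def run_interval_experiment(
    table: LongitudinalMicrobiomeTable,
    specs: Optional[Sequence[PairingSpec]] = None,
    floor_depth: Optional[int] = None,
    policy: str = "all_within_window",
    binning: AbundanceBinning = AbundanceBinning(),
    metrics: Sequence[str] = ("bray_curtis",),
    tree: Optional[TreeNode] = None,
    pseudocount: float = 1.0,
    seed: int = 0,
    keep_changes: bool = False,
) -> ExperimentResult:
    """Volatility summaries for each sampling interval at 100% rarefaction."""
    specs = list(specs) if specs is not None else default_specs()
    plan = RarefactionPlan(mode="pct100", floor_depth=floor_depth)
    rarefied = rarefy_table(table, plan, seed)
    run_log: Dict[str, object] = {
        "seed": seed,
        "rarefaction_target": plan.resolve_target(table),
        "pair_counts": {},
    }
    summary_frames: List[pd.DataFrame] = []
    diss_frames: List[pd.DataFrame] = []
    changes_by_lag: Dict[str, pd.DataFrame] = {}
    for spec in specs:
        pairs = enumerate_pairs(table, spec, policy)
        run_log["pair_counts"][spec.label] = len(pairs)
        if not pairs:
            warnings.warn(
                f"no sample pairs for interval {spec.label}; emitting empty summary"
            )
            empty = pd.DataFrame(
                [{"lag_spec": spec.label, "target_lag_days": spec.target_lag_days,
                  "n_records": 0}]
            )
            summary_frames.append(empty)
            continue
        changes = add_abundance_bins(
            compute_changes(rarefied, pairs, pseudocount), binning
        )
        summary = summarize_changes(changes, ["abundance_bin"])
        summary.insert(0, "lag_spec", spec.label)
        summary.insert(1, "target_lag_days", spec.target_lag_days)
        summary_frames.append(summary)
        if keep_changes:
            changes_by_lag[spec.label] = changes
        for metric in metrics:
            diss = pairwise_dissimilarities(rarefied, pairs, metric, tree=tree)
            diss.insert(0, "lag_spec", spec.label)
            diss.insert(1, "target_lag_days", spec.target_lag_days)
            diss_frames.append(diss)
    summaries = pd.concat(summary_frames, ignore_index=True)
    dissimilarities = (
        pd.concat(diss_frames, ignore_index=True) if diss_frames else pd.DataFrame()
    )
    logger.info("interval experiment: %s", run_log)
    return ExperimentResult(summaries, dissimilarities, {}, changes_by_lag, run_log)


def run_depth_experiment(
    table: LongitudinalMicrobiomeTable,
    spec: PairingSpec = WEEKLY_SPEC,
    modes: Sequence[str] = DEPTH_MODES,
    floor_depth: Optional[int] = None,
    policy: str = "all_within_window",
    binning: AbundanceBinning = AbundanceBinning(),
    metrics: Sequence[str] = ("bray_curtis",),
    tree: Optional[TreeNode] = None,
    pseudocount: float = 1.0,
    loess_span: float = 0.75,
    seed: int = 0,
    keep_changes: bool = False,
) -> ExperimentResult:
    """Volatility summaries under each rarefaction condition at weekly lag.

    Pairs are computed once on the unrarefied table and reused for every
    mode, so mode comparisons are over identical pair sets.
    """
    pairs = enumerate_pairs(table, spec, policy)
    run_log: Dict[str, object] = {
        "seed": seed,
        "lag_spec": spec.label,
        "n_pairs": len(pairs),
        "rarefaction_targets": {},
    }
    if not pairs:
        warnings.warn(f"no sample pairs for interval {spec.label}")
    summary_frames: List[pd.DataFrame] = []
    diss_frames: List[pd.DataFrame] = []
    curves: Dict[str, pd.DataFrame] = {}
    changes_by_mode: Dict[str, pd.DataFrame] = {}
    for mode in modes:
        plan = RarefactionPlan(mode=mode, floor_depth=floor_depth)
        rarefied = rarefy_table(table, plan, seed)
        run_log["rarefaction_targets"][mode] = plan.resolve_target(table)
        mode_pairs = [
            p
            for p in pairs
            if p.sample_earlier in rarefied.counts.columns
            and p.sample_later in rarefied.counts.columns
        ]
        if not mode_pairs:
            continue
        changes = add_abundance_bins(
            compute_changes(rarefied, mode_pairs, pseudocount), binning
        )
        summary = summarize_changes(changes, ["abundance_bin"])
        summary.insert(0, "rarefaction_mode", mode)
        summary_frames.append(summary)
        curves[mode], _ = qualitative_curve(changes, span=loess_span)
        if keep_changes:
            changes_by_mode[mode] = changes
        for metric in metrics:
            diss = pairwise_dissimilarities(rarefied, mode_pairs, metric, tree=tree)
            diss.insert(0, "rarefaction_mode", mode)
            diss_frames.append(diss)
    summaries = pd.concat(summary_frames, ignore_index=True)
    dissimilarities = (
        pd.concat(diss_frames, ignore_index=True) if diss_frames else pd.DataFrame()
    )
    logger.info("depth experiment: %s", run_log)
    return ExperimentResult(summaries, dissimilarities, curves, changes_by_mode, run_log)


def run_residual_depth_experiment(
    table: LongitudinalMicrobiomeTable,
    spec: PairingSpec = WEEKLY_SPEC,
    floor_depth: Optional[int] = None,
    policy: str = "all_within_window",
    binning: AbundanceBinning = AbundanceBinning(),
    pseudocount: float = 1.0,
    seed: int = 0,
) -> ExperimentResult:
    """Residual read-depth analysis: weekly lag, 100% rarefaction, then
    summaries stratified by quartile of the pairs' mean original depth."""
    pairs = enumerate_pairs(table, spec, policy)
    if not pairs:
        warnings.warn(f"no sample pairs for interval {spec.label}")
        return ExperimentResult(pd.DataFrame(), pd.DataFrame())
    plan = RarefactionPlan(mode="pct100", floor_depth=floor_depth)
    rarefied = rarefy_table(table, plan, seed)
    changes = compute_changes(rarefied, pairs, pseudocount)
    summaries = depth_quartile_analysis(changes, binning)
    run_log = {
        "seed": seed,
        "lag_spec": spec.label,
        "n_pairs": len(pairs),
        "rarefaction_target": plan.resolve_target(table),
    }
    logger.info("residual depth experiment: %s", run_log)
    return ExperimentResult(summaries, pd.DataFrame(), {}, {}, run_log)
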