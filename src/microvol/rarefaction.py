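"""Rarefaction: subsampling reads without replacement to a common depth.

Rarefying draws a uniform random subset of a sample's reads (multivariate
hypergeometric), so each rarefied column sums exactly to the target depth
and no taxon can appear that was absent before.  The plan supports the four
standard study conditions — no rarefaction, and rarefaction to 100%, 80% or
60% of the minimum read count — plus a floor on the "minimum" for studies
whose true minimum is unusably small, in which case samples below the floor
may be kept unrarefied or dropped.

Each sample gets its own random substream derived from (seed, sample_id),
so results do not depend on column order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import LongitudinalMicrobiomeTable

__all__ = ["RarefactionPlan", "min_read_count", "rarefy_sample", "rarefy_table"]

_MODES = ("none", "pct100", "pct80", "pct60", "fixed")
_PCT = {"pct100": 1.0, "pct80": 0.8, "pct60": 0.6}


@dataclass(frozen=True)
class RarefactionPlan:
    """How to rarefy a table.

    mode
        ``none`` leaves the table untouched; ``pct100``/``pct80``/``pct60``
        rarefy to the given percentage of the (floored) minimum read count,
        rounded to the nearest integer; ``fixed`` uses ``fixed_depth``.
    floor_depth
        If given, the minimum read count used by the pct modes is at least
        this value (the convention for studies with a handful of very
        shallow samples).
    below_target_policy
        What to do with samples shallower than the target: keep them with
        their original counts (``keep_unrarefied``) or remove them
        (``drop``).
    """

    mode: str = "pct100"
    fixed_depth: Optional[int] = None
    floor_depth: Optional[int] = None
    below_target_policy: str = "keep_unrarefied"

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode {self.mode!r}; choose from {_MODES}")
        if self.mode == "fixed":
            if self.fixed_depth is None or self.fixed_depth < 1:
                raise ValueError("mode 'fixed' requires fixed_depth >= 1")
        if self.floor_depth is not None and self.floor_depth < 1:
            raise ValueError("floor_depth must be >= 1")
        if self.below_target_policy not in ("keep_unrarefied", "drop"):
            raise ValueError("below_target_policy must be keep_unrarefied or drop")

    def resolve_target(self, table: LongitudinalMicrobiomeTable) -> Optional[int]:
        """Target depth for this plan on this table (None for mode 'none')."""
        if self.mode == "none":
            return None
        if self.mode == "fixed":
            return int(self.fixed_depth)
        target = int(round(_PCT[self.mode] * min_read_count(table, self.floor_depth)))
        if target < 1:
            raise ValueError(f"resolved rarefaction depth {target} < 1")
        return target


def min_read_count(
    table: LongitudinalMicrobiomeTable, floor_depth: Optional[int] = None
) -> int:
    """Minimum current column sum, floored at ``floor_depth`` when given."""
    if table.n_samples == 0:
        raise ValueError("table has no samples")
    minimum = int(table.sample_depths().min())
    if floor_depth is not None:
        minimum = max(minimum, int(floor_depth))
    return minimum


def rarefy_sample(
    counts: np.ndarray,
    depth: int,
    seed: Union[int, np.random.Generator],
) -> np.ndarray:
    """Draw ``depth`` reads without replacement from one sample's counts.

    The draw is multivariate hypergeometric: a uniform random subset of the
    reads.  Output sums to exactly ``depth`` and never exceeds the input in
    any taxon.
    """
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"cannot rarefy to {depth} reads from a total of {total}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts.astype(np.int64), int(depth))


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # stable per-sample substream: blake2b is deterministic across runs
    digest = hashlib.blake2b(str(sample_id).encode("utf-8"), digest_size=8).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int.from_bytes(digest, "big")])
    )


def rarefy_table(
    table: LongitudinalMicrobiomeTable,
    plan: RarefactionPlan,
    seed: int,
) -> LongitudinalMicrobiomeTable:
    """Apply a rarefaction plan to every sample of a table.

    Samples at or above the target are subsampled to it; samples below it
    are kept unrarefied or dropped per the plan.  ``original_read_depth``
    metadata is preserved unchanged.
    """
    if plan.mode == "none":
        return table.with_counts(table.counts)
    target = plan.resolve_target(table)
    depths = table.sample_depths()
    new_cols = {}
    dropped = []
    for sample_id in table.sample_ids:
        col = table.counts[sample_id].to_numpy()
        if depths[sample_id] < target:
            if plan.below_target_policy == "drop":
                dropped.append(sample_id)
            else:
                new_cols[sample_id] = col
        else:
            new_cols[sample_id] = rarefy_sample(
                col, target, _sample_rng(seed, sample_id)
            )
    counts = pd.DataFrame(new_cols, index=table.counts.index)
    counts = counts[[s for s in table.sample_ids if s not in set(dropped)]]
    return LongitudinalMicrobiomeTable(counts, table.metadata.loc[counts.columns])
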