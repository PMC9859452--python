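"""Pairing of intra-subject samples at a target sampling interval.

Longitudinal microbiome studies rarely achieve perfectly regular sampling,
so a "7-day" analysis really means: all ordered pairs of samples from the
same subject whose observed lag falls in a tolerance window around 7 days.
The window is kept within 15% of the target on either side so that the
nominal interval remains meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence, Union

import pandas as pd

from .core import LongitudinalMicrobiomeTable

__all__ = ["PairingSpec", "SamplePair", "default_specs", "enumerate_pairs", "pairs_to_frame", "write_pairs"]

#: maximum window half-width as a fraction of the target lag
TOLERANCE_CAP = 0.15

_POLICIES = ("consecutive_disjoint", "all_within_window")


@dataclass(frozen=True)
class PairingSpec:
    """Target sampling interval with an asymmetric tolerance window.

    A lag L is accepted iff target - lower_tol <= L <= target + upper_tol
    (both ends inclusive).  Tolerances beyond 15% of the target must be
    requested explicitly with ``allow_wide=True``.
    """

    target_lag_days: float
    lower_tol_days: float = 0.0
    upper_tol_days: float = 0.0
    allow_wide: bool = False

    def __post_init__(self) -> None:
        if self.target_lag_days <= 0:
            raise ValueError("target lag must be positive")
        if self.lower_tol_days < 0 or self.upper_tol_days < 0:
            raise ValueError("tolerances must be non-negative")
        if self.lower_tol_days >= self.target_lag_days:
            raise ValueError("window must not reach down to zero lag")
        if not self.allow_wide:
            cap = TOLERANCE_CAP * self.target_lag_days + 1e-12
            if self.lower_tol_days > cap or self.upper_tol_days > cap:
                raise ValueError(
                    f"tolerance exceeds {TOLERANCE_CAP:.0%} of the target lag; "
                    "pass allow_wide=True to override"
                )

    @property
    def window(self) -> tuple:
        return (
            self.target_lag_days - self.lower_tol_days,
            self.target_lag_days + self.upper_tol_days,
        )

    def accepts(self, lag: float) -> bool:
        lo, hi = self.window
        return lo <= lag <= hi

    @property
    def label(self) -> str:
        if self.lower_tol_days == 0 and self.upper_tol_days == 0:
            return f"{self.target_lag_days:g}d"
        return f"{self.target_lag_days:g}d±{max(self.lower_tol_days, self.upper_tol_days):g}"


@dataclass(frozen=True)
class SamplePair:
    """One ordered intra-subject pair of samples at an accepted lag."""

    subject: str
    sample_earlier: str
    sample_later: str
    observed_lag_days: float
    mean_original_depth: float

    @property
    def pair_id(self) -> str:
        return f"{self.sample_earlier}|{self.sample_later}"


def default_specs() -> List[PairingSpec]:
    """The four standard sampling intervals: 1, 3, 7±1 and 28±4 days."""
    return [
        PairingSpec(1.0),
        PairingSpec(3.0),
        PairingSpec(7.0, 1.0, 1.0),
        PairingSpec(28.0, 4.0, 4.0),
    ]


def enumerate_pairs(
    table: LongitudinalMicrobiomeTable,
    spec: PairingSpec,
    policy: str = "all_within_window",
) -> List[SamplePair]:
    """Enumerate intra-subject sample pairs whose lag falls in the window.

    ``all_within_window`` takes every ordered pair in the window (samples may
    appear in several pairs); ``consecutive_disjoint`` walks each subject's
    series greedily left to right, pairing the current anchor with the
    earliest later sample in the window and never reusing a sample.  Output
    order is deterministic: subjects sorted, pairs by (earlier, later) time.
    """
    if policy not in _POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {_POLICIES}")
    depth = table.metadata["original_read_depth"]
    pairs: List[SamplePair] = []
    for subject in table.subjects():
        sub = table.samples_for_subject(subject)
        ids = list(sub.index)
        times = sub["time_days"].to_numpy()
        n = len(ids)
        if policy == "all_within_window":
            for a in range(n):
                for b in range(a + 1, n):
                    if spec.accepts(times[b] - times[a]):
                        pairs.append(
                            _make_pair(subject, ids[a], ids[b], times, a, b, depth)
                        )
        else:  # consecutive_disjoint
            a = 0
            while a < n:
                matched = False
                for b in range(a + 1, n):
                    if spec.accepts(times[b] - times[a]):
                        pairs.append(
                            _make_pair(subject, ids[a], ids[b], times, a, b, depth)
                        )
                        a = b + 1
                        matched = True
                        break
                if not matched:
                    a += 1
    return pairs


def _make_pair(subject, id_a, id_b, times, a, b, depth) -> SamplePair:
    return SamplePair(
        subject=subject,
        sample_earlier=id_a,
        sample_later=id_b,
        observed_lag_days=float(times[b] - times[a]),
        mean_original_depth=float((depth[id_a] + depth[id_b]) / 2.0),
    )


def pairs_to_frame(pairs: Iterable[SamplePair]) -> pd.DataFrame:
    """Tabulate pairs: subject, sample ids, observed lag, mean depth."""
    return pd.DataFrame(
        [
            {
                "subject": p.subject,
                "sample_earlier": p.sample_earlier,
                "sample_later": p.sample_later,
                "observed_lag_days": p.observed_lag_days,
                "mean_original_depth": p.mean_original_depth,
            }
            for p in pairs
        ],
        columns=[
            "subject",
            "sample_earlier",
            "sample_later",
            "observed_lag_days",
            "mean_original_depth",
        ],
    )


def write_pairs(pairs: Sequence[SamplePair], path: Union[str, Path]) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)
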