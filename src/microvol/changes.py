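"""Taxon-level measures of change between paired time points.

For a taxon j of subject i observed at times t_{k-1} and t_k with relative
abundances p (and pseudocount-adjusted abundances p~), four measures of
change are computed:

* additive          d^a = p_curr - p_prev                         in [-1, 1]
* multiplicative    d^m = log(p_curr / p_prev), only if both p > 0
* CLR-based         d^c = CLR(p~_curr) - CLR(p~_prev)
* qualitative       d^q = 1{count_curr > 0} - 1{count_prev > 0}   in {-1,0,1}

with CLR(x)_j = log(x_j / GM(x)) the centered log-ratio transform.  The CLR
measure relates to the multiplicative one through a ratio of geometric
means,

    d^c_j = log(p~_curr,j / p~_prev,j) - log(GM(p~_curr) / GM(p~_prev)),

so all taxa absent at both time points of an equal-depth pair share one
d^c value (the negated log GM ratio): zero-replacement lets absent taxa
carry multiplicative information, at the price of a common offset.

Undefined multiplicative changes are carried as NaN and excluded from
downstream standard deviations — never coerced to 0.

Natural logarithms throughout.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np
import pandas as pd

from .core import (
    LongitudinalMicrobiomeTable,
    mean_taxon_abundance,
    pseudocount_relative_abundances,
    relative_abundances,
)
from .pairing import SamplePair

__all__ = [
    "additive_change",
    "multiplicative_change",
    "clr_transform",
    "clr_change",
    "qualitative_change",
    "compute_changes",
]


def additive_change(p_prev, p_curr):
    """Difference in relative abundance, p_curr - p_prev."""
    return np.asarray(p_curr) - np.asarray(p_prev)


def multiplicative_change(p_prev, p_curr):
    """Log fold change log(p_curr / p_prev); NaN unless both are positive."""
    p_prev = np.asarray(p_prev, dtype=float)
    p_curr = np.asarray(p_curr, dtype=float)
    defined = (p_prev > 0) & (p_curr > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(defined, np.log(np.where(defined, p_curr, 1.0) /
                                       np.where(defined, p_prev, 1.0)), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def clr_transform(composition) -> np.ndarray:
    """Centered log-ratio transform of a strictly positive composition.

    CLR(x)_j = log x_j - mean_k log x_k; components sum to zero.
    """
    x = np.asarray(composition, dtype=float)
    if (x <= 0).any():
        raise ValueError("CLR requires strictly positive entries")
    logs = np.log(x)
    return logs - logs.mean(axis=0, keepdims=x.ndim > 1)


def clr_change(ptilde_prev, ptilde_curr) -> np.ndarray:
    """CLR(p~_curr) - CLR(p~_prev), per taxon."""
    return clr_transform(ptilde_curr) - clr_transform(ptilde_prev)


def qualitative_change(count_prev, count_curr):
    """Presence flip indicator: 1{curr>0} - 1{prev>0} in {-1, 0, 1}."""
    prev = np.asarray(count_prev)
    curr = np.asarray(count_curr)
    out = (curr > 0).astype(np.int8) - (prev > 0).astype(np.int8)
    if out.ndim == 0:
        return int(out)
    return out


def compute_changes(
    table: LongitudinalMicrobiomeTable,
    pairs: Sequence[SamplePair],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """All four change measures for every (pair, taxon).

    Returns a long DataFrame with one row per (pair, taxon): pair
    identifiers and lag, d_additive, d_multiplicative (NaN when undefined),
    d_clr, d_qualitative, and the taxon's study-wide mean relative
    abundance on this table (used downstream for abundance binning).
    """
    pairs = list(pairs)
    if not pairs:
        return pd.DataFrame(
            columns=[
                "subject", "pair_id", "sample_earlier", "sample_later",
                "observed_lag_days", "mean_original_depth", "taxon",
                "d_additive", "d_multiplicative", "d_clr", "d_qualitative",
                "mean_abundance",
            ]
        )
    col_index = {s: k for k, s in enumerate(table.sample_ids)}
    missing = [
        s
        for p in pairs
        for s in (p.sample_earlier, p.sample_later)
        if s not in col_index
    ]
    if missing:
        raise ValueError(f"pair references sample absent from table: {missing[0]!r}")

    idx_prev = np.array([col_index[p.sample_earlier] for p in pairs])
    idx_curr = np.array([col_index[p.sample_later] for p in pairs])

    counts = table.counts.to_numpy()
    p = relative_abundances(table).to_numpy()
    ptilde = pseudocount_relative_abundances(table, pseudocount).to_numpy()
    clr = clr_transform(ptilde)
    mean_ab = mean_taxon_abundance(table).to_numpy()

    d_a = p[:, idx_curr] - p[:, idx_prev]
    d_m = multiplicative_change(p[:, idx_prev], p[:, idx_curr])
    d_c = clr[:, idx_curr] - clr[:, idx_prev]
    d_q = qualitative_change(counts[:, idx_prev], counts[:, idx_curr])

    n_taxa, n_pairs = d_a.shape
    taxa = np.asarray(table.taxon_ids)
    frame = pd.DataFrame(
        {
            "subject": np.repeat([p.subject for p in pairs], n_taxa),
            "pair_id": np.repeat([p.pair_id for p in pairs], n_taxa),
            "sample_earlier": np.repeat([p.sample_earlier for p in pairs], n_taxa),
            "sample_later": np.repeat([p.sample_later for p in pairs], n_taxa),
            "observed_lag_days": np.repeat(
                [p.observed_lag_days for p in pairs], n_taxa
            ),
            "mean_original_depth": np.repeat(
                [p.mean_original_depth for p in pairs], n_taxa
            ),
            "taxon": np.tile(taxa, n_pairs),
            "d_additive": d_a.T.ravel(),
            "d_multiplicative": d_m.T.ravel(),
            "d_clr": d_c.T.ravel(),
            "d_qualitative": d_q.T.ravel(),
            "mean_abundance": np.tile(mean_ab, n_pairs),
        }
    )
    return frame


def write_changes(changes: pd.DataFrame, path) -> None:
    """Tab-delimited long export; undefined d_m cells are left empty."""
    changes.to_csv(path, sep="\t", index=False)
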