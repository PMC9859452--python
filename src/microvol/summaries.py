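"""Stratified summaries of volatility: SDs, qualitative proportions, curves.

The quantitative change measures are symmetric around zero in a stationary
community, so volatility is summarized by spread: the sample standard
deviation (n-1 denominator) of d^a, d^m (over defined values only) and
d^c within a stratum, together with the proportion of (pair, taxon)
records whose qualitative change d^q is non-zero.  Strata are any
combination of sampling-interval spec, rarefaction condition, taxon
abundance bin and original-read-depth quartile.

Abundance bins are decade bins on the study-wide mean relative abundance,
right-closed, with the lowest bin absorbing zero.  The qualitative-change
proportion as a function of log10 mean abundance is smoothed with LOESS
(statsmodels lowess, local-linear), with bootstrap pointwise standard
errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "AbundanceBinning",
    "DEFAULT_BIN_EDGES",
    "assign_abundance_bins",
    "add_abundance_bins",
    "summarize_changes",
    "qualitative_curve",
    "curve_peak_abundance",
    "depth_quartile_analysis",
    "assign_depth_quartiles",
]

#: default decade bin edges on mean relative abundance; right-closed, the
#: lowest bin includes 0
DEFAULT_BIN_EDGES = (0.0, 1e-5, 1e-4, 1e-3, 1e-2, 1.0)


@dataclass(frozen=True)
class AbundanceBinning:
    """Right-closed abundance bins on [0, 1]; topmost edge must be 1."""

    bin_edges: Tuple[float, ...] = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.bin_edges)
        if len(edges) < 2:
            raise ValueError("need at least two bin edges")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly increasing")
        if edges[0] != 0.0 or edges[-1] != 1.0:
            raise ValueError("bin edges must start at 0 and end at 1")
        object.__setattr__(self, "bin_edges", edges)

    @property
    def labels(self) -> List[str]:
        edges = self.bin_edges
        out = [f"[{edges[0]:g}, {edges[1]:g}]"]
        out += [f"({a:g}, {b:g}]" for a, b in zip(edges[1:-1], edges[2:])]
        return out


def assign_abundance_bins(
    mean_abundances, binning: AbundanceBinning = AbundanceBinning()
) -> pd.Categorical:
    """Map each taxon's mean abundance to its bin label."""
    x = np.asarray(mean_abundances, dtype=float)
    if ((x < 0) | (x > 1)).any():
        raise ValueError("mean abundances must lie in [0, 1]")
    return pd.cut(
        x,
        bins=list(binning.bin_edges),
        labels=binning.labels,
        include_lowest=True,
        right=True,
    )


def add_abundance_bins(
    changes: pd.DataFrame, binning: AbundanceBinning = AbundanceBinning()
) -> pd.DataFrame:
    """Return a copy of a change table with an ``abundance_bin`` column."""
    out = changes.copy()
    out["abundance_bin"] = assign_abundance_bins(
        out["mean_abundance"].to_numpy(), binning
    )
    return out


def summarize_changes(
    changes: pd.DataFrame, group_by: Sequence[str] = ()
) -> pd.DataFrame:
    """Per-stratum SDs of the quantitative measures and qualitative proportion.

    SDs use the n-1 denominator and are NaN for strata with fewer than two
    contributing records; undefined multiplicative changes are excluded,
    with the count of defined values reported.
    """
    if changes.empty:
        raise ValueError("no change records to summarize")
    group_by = list(group_by)

    def _one(group: pd.DataFrame) -> pd.Series:
        d_m = group["d_multiplicative"].dropna()
        return pd.Series(
            {
                "sd_additive": _sample_sd(group["d_additive"]),
                "sd_multiplicative": _sample_sd(d_m),
                "sd_clr": _sample_sd(group["d_clr"]),
                "prop_qualitative": float((group["d_qualitative"] != 0).mean()),
                "n_records": len(group),
                "n_defined_multiplicative": len(d_m),
            }
        )

    if not group_by:
        return _one(changes).to_frame().T.astype(
            {"n_records": int, "n_defined_multiplicative": int}
        )
    grouped = changes.groupby(group_by, observed=True, sort=True)
    out = grouped.apply(_one, include_groups=False).reset_index()
    return out.astype({"n_records": int, "n_defined_multiplicative": int})


def _sample_sd(values: pd.Series) -> float:
    values = values.dropna()
    if len(values) < 2:
        return float("nan")
    return float(values.std(ddof=1))


def qualitative_curve(
    changes: pd.DataFrame,
    span: float = 0.75,
    n_boot: int = 40,
    boot_seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """LOESS curve of P(d^q != 0) against log10 mean abundance.

    Records are first collapsed per taxon to its qualitative-change
    proportion and mean abundance; taxa with zero mean abundance have no
    place on the log axis and are returned separately.  The curve is
    evaluated at the observed taxa; pointwise standard errors come from
    ``n_boot`` bootstrap resamples of taxa (seeded, hence deterministic).

    Returns ``(curve, excluded)``: the curve frame has columns
    log10_abundance, proportion (raw per-taxon), fitted and se.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    per_taxon = (
        changes.groupby("taxon", observed=True)
        .agg(
            proportion=("d_qualitative", lambda q: float((q != 0).mean())),
            mean_abundance=("mean_abundance", "first"),
        )
        .reset_index()
    )
    excluded = per_taxon[per_taxon["mean_abundance"] == 0.0]
    kept = per_taxon[per_taxon["mean_abundance"] > 0.0].copy()
    if len(kept) < 3:
        raise ValueError("need at least three taxa with positive abundance")
    kept["log10_abundance"] = np.log10(kept["mean_abundance"])
    kept = kept.sort_values("log10_abundance").reset_index(drop=True)
    x = kept["log10_abundance"].to_numpy()
    y = kept["proportion"].to_numpy()
    fitted = lowess(y, x, frac=span, return_sorted=False)

    rng = np.random.default_rng(boot_seed)
    boots = np.full((n_boot, len(x)), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, len(x), size=len(x))
        boots[b] = _lowess_at(x[idx], y[idx], x, span)
    se = np.nanstd(boots, axis=0, ddof=1)

    curve = kept[["taxon", "log10_abundance", "proportion"]].copy()
    curve["fitted"] = fitted
    curve["se"] = se
    return curve, excluded[["taxon", "proportion"]]


def _lowess_at(xs: np.ndarray, ys: np.ndarray, grid: np.ndarray, span: float):
    fit = lowess(ys, xs, frac=span, return_sorted=True)
    return np.interp(grid, fit[:, 0], fit[:, 1])


def curve_peak_abundance(curve: pd.DataFrame) -> float:
    """log10 abundance at which the fitted qualitative curve is maximal."""
    k = int(np.argmax(curve["fitted"].to_numpy()))
    return float(curve["log10_abundance"].iloc[k])


def assign_depth_quartiles(depths) -> pd.Categorical:
    """Quartile labels Q1..Q4 from the empirical quartiles (type-7 linear
    interpolation); values exactly at a cut point go to the lower group."""
    depths = np.asarray(depths, dtype=float)
    cuts = np.quantile(depths, [0.25, 0.5, 0.75], method="linear")
    labels = np.array(["Q1", "Q2", "Q3", "Q4"])
    idx = np.searchsorted(cuts, depths, side="left")
    return pd.Categorical(labels[idx], categories=list(labels), ordered=True)


def depth_quartile_analysis(
    changes: pd.DataFrame,
    binning: AbundanceBinning = AbundanceBinning(),
    extra_group_by: Sequence[str] = (),
) -> pd.DataFrame:
    """Summaries by original-read-depth quartile x abundance bin.

    Quartiles of ``mean_original_depth`` are computed over *pairs* (each
    pair counted once), then every change record inherits its pair's
    quartile and summaries are formed within quartile x abundance bin.
    """
    pair_depths = changes.drop_duplicates("pair_id")[["pair_id", "mean_original_depth"]]
    quartiles = assign_depth_quartiles(pair_depths["mean_original_depth"].to_numpy())
    mapping = dict(zip(pair_depths["pair_id"], quartiles))
    out = add_abundance_bins(changes, binning)
    out["depth_quartile"] = pd.Categorical(
        [mapping[p] for p in out["pair_id"]],
        categories=["Q1", "Q2", "Q3", "Q4"],
        ordered=True,
    )
    return summarize_changes(
        out, ["depth_quartile", "abundance_bin", *extra_group_by]
    )
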