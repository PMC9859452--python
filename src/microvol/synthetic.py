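"""Synthetic longitudinal microbiome studies with known ground truth.

The generator emulates the structure of real gut and vaginal time series:
dense or sparse sampling grids with missing time points, diverse gut-like
versus dominance-structured vaginal-like communities, per-sample read
depths that vary over an order of magnitude, and per-taxon temporal
dynamics with a controllable volatility.

The model: each taxon j carries a baseline log abundance mu_j; within a
subject its latent log abundance follows either a random walk
(increments Normal(0, sigma^2 * dt), so the variance of a lag-L change is
sigma^2 * L) or a stationary AR(1)-type process with autocorrelation
phi^dt and stationary SD sigma.  The community composition at a time
point is the softmax of the latent log abundances over the taxa present
in that subject; a configurable fraction of taxa is structurally absent
per subject, so every zero in the output is labeled in ground truth as
structural (biological absence) or sampling (missed by the finite read
depth).  Read depths are log-normal; counts are multinomial given depth
and composition (optionally Dirichlet-multinomial for overdispersion).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import LongitudinalMicrobiomeTable

__all__ = [
    "SyntheticConfig",
    "LatentSeries",
    "GroundTruth",
    "simulate_latent_series",
    "simulate_counts",
    "simulate_study",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of a simulated study.

    Defaults describe a gut-like cohort: 20 subjects sampled daily for 100
    days with occasional missed samples, 100 taxa whose baseline log
    abundances spread over several decades, random-walk dynamics with a
    per-sqrt-day innovation SD of 0.3, and log-normal read depths with
    median 5,000 and log-SD 0.7 (roughly an order-of-magnitude range
    across samples, as seen in real studies).
    """

    n_subjects: int = 20
    time_grid_days: Tuple[float, ...] = tuple(float(t) for t in range(100))
    missing_prob: float = 0.05
    n_taxa: int = 100
    community_style: str = "gut_like"  # or "vaginal_like"
    base_logmean_spread: float = 3.0
    dominant_share: float = 0.9  # vaginal_like: dominant taxon mean share
    dynamics: str = "random_walk"  # or "ar1"
    sigma_volatility: float = 0.3
    ar1_phi: float = 0.9
    depth_median: float = 5000.0
    depth_log_sd: float = 0.7
    structural_zero_prob: float = 0.1
    overdispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_taxa < 2:
            raise ValueError("need at least one subject and two taxa")
        if not 0 <= self.missing_prob < 1:
            raise ValueError("missing_prob must be in [0, 1)")
        if self.community_style not in ("gut_like", "vaginal_like"):
            raise ValueError("community_style must be gut_like or vaginal_like")
        if self.dynamics not in ("random_walk", "ar1"):
            raise ValueError("dynamics must be random_walk or ar1")
        if self.sigma_volatility < 0:
            raise ValueError("sigma_volatility must be >= 0")
        if not 0 <= self.ar1_phi <= 1:
            raise ValueError("ar1_phi must be in [0, 1]")
        if sorted(self.time_grid_days) != list(self.time_grid_days):
            raise ValueError("time_grid_days must be sorted")
        if not 0 <= self.structural_zero_prob < 1:
            raise ValueError("structural_zero_prob must be in [0, 1)")
        object.__setattr__(
            self, "time_grid_days", tuple(float(t) for t in self.time_grid_days)
        )


@dataclass
class LatentSeries:
    """Latent log abundances and compositions per subject and time point."""

    times: np.ndarray  # (n_times,)
    log_abundance: np.ndarray  # (n_subjects, n_times, n_taxa)
    composition: np.ndarray  # (n_subjects, n_times, n_taxa); rows sum to 1
    structural_absent: np.ndarray  # (n_subjects, n_taxa) bool
    baseline: np.ndarray  # (n_taxa,)
    config: SyntheticConfig


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must estimate."""

    latent: LatentSeries
    sample_truth: pd.DataFrame  # sample_id -> subject index, time index, depth
    sigma_volatility: float
    config: SyntheticConfig


def _rng_streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_latent_series(config: SyntheticConfig) -> LatentSeries:
    """Simulate per-subject latent log-abundance trajectories."""
    rng_base, rng_struct, rng_dyn, _, _ = _rng_streams(config.seed, 5)
    n_sub, n_taxa = config.n_subjects, config.n_taxa
    times = np.asarray(config.time_grid_days)
    n_times = len(times)

    baseline = rng_base.normal(0.0, config.base_logmean_spread, size=n_taxa)
    if config.community_style == "vaginal_like":
        # one dominant taxon pinned at ~dominant_share of the mean community
        share = config.dominant_share
        baseline[0] = np.log(share / (1 - share) * np.exp(baseline[1:]).sum())

    structural = rng_struct.random((n_sub, n_taxa)) < config.structural_zero_prob
    if config.community_style == "vaginal_like":
        structural[:, 0] = False
    # every subject keeps at least two taxa
    for i in range(n_sub):
        if structural[i].sum() > n_taxa - 2:
            structural[i, :2] = False

    sigma = config.sigma_volatility
    dt = np.diff(times)
    z = np.zeros((n_sub, n_times, n_taxa))
    if config.dynamics == "random_walk":
        for k, d in enumerate(dt):
            z[:, k + 1] = z[:, k] + rng_dyn.normal(
                0.0, sigma * np.sqrt(d), size=(n_sub, n_taxa)
            )
    else:  # ar1, stationary SD = sigma, autocorrelation phi^dt
        phi = config.ar1_phi
        z[:, 0] = rng_dyn.normal(0.0, sigma, size=(n_sub, n_taxa))
        for k, d in enumerate(dt):
            rho = phi**d
            innov_sd = sigma * np.sqrt(max(0.0, 1.0 - rho**2))
            z[:, k + 1] = rho * z[:, k] + rng_dyn.normal(
                0.0, innov_sd, size=(n_sub, n_taxa)
            )

    log_ab = baseline[None, None, :] + z
    comp = np.exp(log_ab - log_ab.max(axis=2, keepdims=True))
    comp[np.broadcast_to(structural[:, None, :], comp.shape)] = 0.0
    comp = comp / comp.sum(axis=2, keepdims=True)
    return LatentSeries(times, log_ab, comp, structural, baseline, config)


def simulate_counts(
    latent: LatentSeries, config: Optional[SyntheticConfig] = None
) -> Tuple[LongitudinalMicrobiomeTable, pd.DataFrame]:
    """Draw observed read counts from latent compositions.

    Per sample: a log-normal read depth, an independent Bernoulli missing
    indicator, and a multinomial count vector (Dirichlet-multinomial when
    ``overdispersion`` > 0).  Returns the observed table and a per-sample
    truth frame (subject/time indices and drawn depth).
    """
    config = config or latent.config
    _, _, _, rng_depth, rng_counts = _rng_streams(config.seed, 5)
    n_sub, n_times, n_taxa = latent.composition.shape
    taxa = [f"taxon{j:04d}" for j in range(n_taxa)]

    columns: Dict[str, np.ndarray] = {}
    meta_rows = []
    truth_rows = []
    for i in range(n_sub):
        subject = f"subj{i:02d}"
        for k in range(n_times):
            missing = rng_depth.random() < config.missing_prob
            depth = max(
                1,
                int(
                    round(
                        np.exp(
                            rng_depth.normal(
                                np.log(config.depth_median), config.depth_log_sd
                            )
                        )
                    )
                ),
            )
            if missing:
                continue
            comp = latent.composition[i, k]
            if config.overdispersion > 0:
                present = comp > 0
                alpha = comp[present] / config.overdispersion
                draw = np.zeros_like(comp)
                draw[present] = rng_counts.dirichlet(alpha)
                comp = draw
            counts = rng_counts.multinomial(depth, comp)
            sample_id = f"S{i:02d}T{latent.times[k]:07.2f}"
            columns[sample_id] = counts
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "subject": subject,
                    "time_days": float(latent.times[k]),
                    "original_read_depth": depth,
                }
            )
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "subject_index": i,
                    "time_index": k,
                    "depth": depth,
                }
            )
    if not columns:
        raise ValueError("all samples came out missing; lower missing_prob")
    counts_df = pd.DataFrame(columns, index=taxa)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    table = LongitudinalMicrobiomeTable(counts_df, meta)
    return table, pd.DataFrame(truth_rows).set_index("sample_id")


def simulate_study(
    config: SyntheticConfig,
) -> Tuple[LongitudinalMicrobiomeTable, GroundTruth]:
    """Simulate a full study: latent dynamics, then observed counts."""
    latent = simulate_latent_series(config)
    table, sample_truth = simulate_counts(latent, config)
    truth = GroundTruth(
        latent=latent,
        sample_truth=sample_truth,
        sigma_volatility=config.sigma_volatility,
        config=config,
    )
    return table, truth
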