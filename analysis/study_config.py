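"""Shared configuration for the analysis drivers.

One reference synthetic cohort is used throughout: 20 subjects sampled
daily for 100 days (5% of samples missing), 100 taxa with gut-like
abundance structure, random-walk volatility sigma = 0.3 per sqrt(day),
and log-normal read depths with median 5,000.
"""

from pathlib import Path

from microvol.synthetic import SyntheticConfig, simulate_study

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

CONFIG = SyntheticConfig(seed=SEED)


def get_study():
    return simulate_study(CONFIG)
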