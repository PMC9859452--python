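# Methods

## Pipeline and stage order

The analysis of one condition proceeds: **pair → rarefy → measure →
summarize**. Intra-subject sample pairs are identified on the *unrarefied*
table; then every sample is rarefied (one draw per sample); then the four
taxon-level change measures and the global dissimilarities are computed on
the rarefied table; finally summaries are stratified. Because pairing comes
first, comparisons across rarefaction conditions are over identical pair
sets, and swapping the order is deliberately not exposed.

## Temporal pairing

A pairing spec is a target lag with an asymmetric tolerance window,
inclusive at both ends; half-widths are capped at 15% of the target unless
explicitly overridden. The default grid is 1 day (±0), 3 days (±0), 7 days
(±1) and 28 days (±4). Two policies are provided because a convention for
sample reuse is genuinely open: `all_within_window` (every ordered pair in
the window; the default, since summaries are over pairs rather than
subjects and this maximizes the number of pairs) and `consecutive_disjoint`
(greedy left-to-right walk, no sample reused). Times are real-valued days;
lags are never rounded.

## Rarefaction

Rarefying draws a uniform random subset of a sample's reads *without
replacement* (multivariate hypergeometric, via numpy), the standard
convention: each rarefied column sums exactly to the target and no absent
taxon can reappear. Percent modes target round(pct × minimum read count);
an optional floor replaces an unusably small study minimum (samples below
the target are kept unrarefied by default, or dropped). Each sample's draw
comes from a substream seeded by a stable hash of (seed, sample_id), so
results are independent of column order. One draw per sample is used per
condition; replicate draws are available by varying the seed. The
alternative — multinomial resampling — differs measurably (it can inflate
within-sample variance) and is not offered.

## Change measures

Natural logarithms throughout. `d_m` uses *raw* proportions and is
undefined (NaN, never 0) unless both are positive; undefined values are
excluded from SDs, with the count of defined values reported alongside.
`d_c` uses pseudocount-adjusted proportions (default pseudocount 1, a
parameter), so it is always defined. The CLR identity
`d_c = log p̃-ratio − log GM-ratio` is enforced by construction and verified
numerically in tests; within a pair, additive and CLR changes each sum to
zero over taxa (compositional closure). The per-taxon `mean_abundance` used
for binning is computed on the same (rarefied) table as the changes, so
binning reflects the analyzed condition.

## Dissimilarities

Bray–Curtis is `1 − 2·Σmin/(Σx+Σy)`. Unweighted UniFrac delegates to
scikit-bio on presence vectors. Weighted and generalized UniFrac are
computed by an explicit post-order branch traversal: for each non-root
branch b with length l_b, A_b and B_b are the relative abundances of the
subtree below b; weighted = Σ l_b·|A_b − B_b| (normalized by Σ l_b·(A_b+B_b)
to lie in [0,1] — the default, for comparability across pairs; the raw form
is available since either convention is defensible), and generalized =
Σ l_b (A_b+B_b)^α |A_b−B_b|/(A_b+B_b) over branches with A_b+B_b > 0,
divided by Σ l_b (A_b+B_b)^α. At α = 1 generalized equals normalized
weighted, which is cross-checked against scikit-bio's independent
implementation in the tests. The traversal handles fractional abundance
vectors exactly (scikit-bio's weighted form truncates them to integers).
A branch length on the root is ignored: the root subtree carries both
samples entirely, so it contributes no signal. Dissimilarities use
relative abundances without pseudocounts — zeros are unproblematic for
distances. UniFrac metrics raise a clear error when no tree is supplied.

## Summaries

SDs are sample SDs (n−1); strata with fewer than two contributing records
report a missing SD. The qualitative proportion is P(d_q ≠ 0), symmetric in
flip direction. Abundance bins are right-closed decade bins on mean
relative abundance — [0, 1e−5], (1e−5, 1e−4], …, (1e−2, 1] — chosen to
preserve the coarse rare/common contrast at 1e−3 while giving resolution
below it; edges are configurable. The qualitative-change curve is a LOESS
fit (statsmodels lowess, local-linear, default span 0.75 — span is
configurable, and local-linear is the smoother this package standardizes
on) of per-taxon flip proportions against log10 mean abundance;
zero-abundance taxa have no place on the log axis and are reported
separately. Pointwise standard errors come from 40 seeded bootstrap
resamples of taxa, so curves are deterministic. Depth quartiles are type-7
(linear-interpolation) empirical quartiles of the *pairs'* mean original
read depth, each pair counted once, with values exactly at a cut point
assigned to the lower quartile.

## Synthetic cohorts

The generator produces the study conditions every test and experiment runs
on. Each taxon has a baseline log abundance drawn with SD
`base_logmean_spread` (default 3, giving mean abundances spanning roughly
six decades, as in diverse gut communities); `vaginal_like` instead pins one
dominant taxon at ~90% mean share. Within a subject, latent log abundances
follow a random walk (increments N(0, σ²Δt), so a lag-L change has variance
σ²L) or a stationary AR(1)-type process (autocorrelation φ^Δt, stationary SD
σ). Composition is the softmax over the taxa present in that subject; a
fraction of taxa (default 10%) is structurally absent per subject, so every
zero is labeled in ground truth as structural (biological absence) versus
sampling (missed at finite depth). Read depths are log-normal (default
median 5,000, log-SD 0.7 — about an order of magnitude across samples,
matching the within-study ranges seen in real 16S cohorts); counts are
multinomial given depth, with an optional Dirichlet-multinomial
overdispersion parameter (multinomial is the default because rarefaction
and sampling zeros then behave analytically). The default cohort is 20
subjects × 100 daily time points with 5% missingness, 100 taxa, σ = 0.3 —
large enough that stratum SDs are stable, small enough that the full
experiment grid runs in seconds on one core.

What the generator does **not** emulate: compositional interactions between
taxa (taxa move independently on the latent scale), regime shifts or
clinical covariates (e.g. menses, antibiotics), taxon correlation induced
by phylogeny, and batch effects. Passing pattern checks on these cohorts
therefore demonstrates that the *pipeline* behaves correctly under known
dynamics — not that any particular real community follows a random walk.

## Numerical notes

- Compositional closure of `d_a`/`d_c` holds to ~1e−13 for 100-taxa tables;
  tests assert 1e−10.
- CLR is computed as log-count minus mean log-count, so the
  log(GM)-cancellation is exact in floating point up to ~1e−15.
- Rarefaction percent targets are rounded to the nearest integer (depth
  differences of ±1 read are immaterial at the scales involved).
- Ties in depth quartiles and right-closed bin boundaries are fixed
  conventions, chosen for determinism rather than statistical necessity.

## Known limitations

- The qualitative-curve SE is a taxon-resampling bootstrap; it ignores
  dependence between pairs sharing a sample, so it understates uncertainty
  for heavily overlapping pair sets.
- `all_within_window` reuses samples across pairs, making records
  correlated; summaries are descriptive spreads, not inferential estimates,
  and no test statistics are attached deliberately.
- Aggregation of OTU tables to genus level, taxonomy handling, and
  model-based alternatives to rarefaction are out of scope; inputs are
  assumed to be ready count tables.
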