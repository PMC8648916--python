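# Methods

This note records the statistical model behind each stage of `rknet`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a user extending the package
should know about.

## Study design assumptions

The package targets crossover selection experiments: microcosms belong to
a selection group (RK = r-selection first, KR = K-selection first) and a
resource-supply level (H/L), with three replicate microcosms per
combination and the regime switched strictly between days 28 and 29. The
*current regime* of a sample is therefore a pure function of its selection
group and day, with day 28 the last day under the initial regime. Sample
and OTU identifiers are the only join keys anywhere; tables are stored
samples-as-rows and file orientation is always declared by the caller,
never guessed, because silent transposition is the classic OTU-table bug.
Incomplete designs (missing microcosm × day combinations) load without
error; replicate averaging simply uses whatever replicates are present.

## Synthetic generator

`generate_experiment` plants the structure the analysis is supposed to
find. Latent log-abundance of OTU *k* on day *i* in microcosm *j* is

    baseline_k + guild_effect · favoured(k, regime(i, j)) + e[i, j, k]

with `favoured` = +1 under the guild's preferred regime, −1 under the
opposing one and 0 for neutral OTUs. Parameters, units and defaults:

| parameter | default | meaning |
|---|---|---|
| `n_k_otus` / `n_r_otus` / `n_neutral_otus` | 30 / 30 / 20 | guild sizes |
| `guild_effect` | 2.0 | log-scale shift under the favoured regime |
| `noise_sd` | 0.6 | marginal SD of AR(1) temporal noise (log scale) |
| `ar_coef` | 0.5 | AR(1) lag coefficient (log scale) |
| `baseline_sd` | 1.5 | SD of lognormal OTU baselines |
| `depth` | 60 000 | expected reads per sample |
| `depth_log_sd` | 0.3 | SD of lognormal library-size variation |
| `density_base` | 10⁷ | expected total cells per mL |
| `days` | 17 days in 1..50 | switch falls between 28 and 29 |

The AR(1) coefficient of 0.5 produces smooth but mixing trajectories
without long-memory artefacts; the stationary parameterisation (innovation
SD = `noise_sd`·√(1 − φ²)) keeps the marginal noise level independent of
φ. Baselines are lognormal with SD 1.5 so the rank-abundance curve is
realistic and a handful of OTUs fall below the filtering thresholds by
construction, giving the filters real work. Read counts are multinomial
given the latent composition and a lognormal library size (SD 0.3 log
units, matching the large depth variability of real amplicon runs, where
exact depth is not a target). The density estimate is
`density_base` × (summed latent abundance, normalised to mean 1), i.e. a
noiseless function of the latent state — real flow-cytometry estimates
carry gating and counting error that is *not* modelled.

Also not modelled: sequencing error, chimeras, copy-number variation,
taxon-specific amplification bias, and true ecological interactions
(cross-feeding, inhibition). The planted structure is pure habitat
preference, so a perfect recovery by the pipeline shows that the chain
detects coordinated niche responses — it says nothing about detecting
direct interactions in real data, where compositional effects and
unmodelled covariates are harsher.

Because the design is a balanced crossover, swapping the RK/KR labels
while swapping the guild labels leaves the generating distribution
invariant. Its sharp finite-sample consequence — that the two guilds'
favoured-vs-opposed log-gains sum to 4·`guild_effect`, the community-total
term cancelling — is what the test suite checks, since a single
realisation never exhibits the label symmetry exactly.

An optional `disturbance_pulse` flag adds one extra noise pulse at the
first sampling day and the first day after the switch, emulating the
transient instability expected at inoculation and after the crossover; it
is off by default so that the planted structure stays the only signal.

## Preprocessing

Counts are divided by library size (no further depth correction — the aim
is an accurate per-sample composition, not variance equalisation), OTUs
are filtered on their *maximum* relative abundance across samples (named
thresholds: high 5·10⁻³, medium 10⁻³, low 5·10⁻⁴), and optionally scaled
by total density to absolute abundances. The errthresh prevalence rule
excludes an OTU from association testing when its zero-count strictly
exceeds n·10^(−4/n); "more than" is read strictly, so a zero-count exactly
at the cutoff is kept. The rule is applied to the working table at
association time (after abundance-type selection), and the summed
per-sample mass of excluded OTUs is retained as the renormalization pool.

## ReBoot

For every unordered OTU pair the bootstrap distribution (resample samples
with replacement, recompute the similarity) is compared with a permutation
null (permute each OTU's values across samples independently). With
renormalization on — relative abundances only — each permuted sample is
re-divided by its new total including the residual pool, restoring the
sum-to-constant constraint so that the null preserves compositional
coupling. Gaussian noise of SD γ = s·x_min (x_min = smallest nonzero
relative abundance; named levels s = 0/1/10/100) is drawn fresh inside
every iteration, wrapped around the measure itself. For efficiency all
pairs share one noise draw and one resampling per iteration; pairs are
never noised independently, which leaves each pair's marginal distribution
unchanged. Spearman uses average ranks for ties (required for the type-I
calibration below to hold under resampling ties).

**Z-statistic.** The two distributions are compared as
z = (mean_boot − mean_perm)/SD_perm, p = 2·Φ(−|z|). Under a global null
mean_boot ≈ the observed correlation and SD_perm ≈ its null sampling SD,
so z is approximately standard normal and the nominal type-I error holds
(measured 0.047–0.050 at α = 0.05 in the acceptance runs). The
alternative pooled form, z = Δ/√(SD_boot² + SD_perm²), is exposed via
`z_variant="pooled"`; because SD_boot ≈ SD_perm under the null it deflates
z by ≈ √2 and is conservative (measured type-I ≈ 0.01). The default is
the calibrated form; published descriptions of the test do not pin the
denominator down, so both are kept available.

Bootstrap and permutation phases use independent draws (default 1000
each). Pairs with undefined similarity (constant vector) or zero pooled
variance are excluded from the output *and* from the multiple-testing
family. q-values use Benjamini–Yekutieli (step-up with
c(m) = Σ 1/k), valid under the strong dependence among overlapping pairs.
Networks from different similarity measures are never merged; associations
are always computed across all samples, regardless of group or supply.

## Network

Edges are the k most significant associations (smallest q, ties broken by
larger |z| then lexicographic pair; default k = 500) or all with
q ≤ 0.05. Edge sign is the sign of z. Walktrap (walk length 20) runs
unweighted on the positive-edge subgraph — negative edges carry no
random-walk meaning — and nodes attached only by negative edges stay
unassigned; a |z|-weighted variant sits behind a flag. Module ids are
relabelled in decreasing order of module size so "module 1" is stable
across runs. Node exports carry both mean relative and (when available)
mean absolute abundance, since logarithmic node sizing can reasonably use
either.

## Temporal decomposition

Day means average the available replicates; the series SD uses the
population (1/N) form, so per OTU the z-scores have mean 0 and population
SD exactly 1, giving the identity
(1/N) Σᵢ z_{i,k} z_{i,l} = Pearson correlation of the two day-mean series
(verified to 10⁻¹⁰ in tests). For Spearman-based networks the same
machinery runs on ranks, computed per OTU *across the facet's sampling
days within each microcosm* (not across OTUs within a sample): this is
the choice under which the identity reduces exactly to the Spearman
correlation when there is a single replicate, and it makes all rank-basis
outputs invariant to monotone transforms of the abundances. Styling
cuts: node black/orange outside z = ±1 (boundary grey, inclusive), edge
red/blue outside a z-product of ±0.3 (boundary grey, inclusive); sizes
a + b·|z| with display-unit defaults a = b = 2 (cosmetic, configurable).
Flagged values (constant series, missing days) render grey at base size.

## Ordination and PERMANOVA

PCoA is classical scaling implemented directly (Gower double-centring +
symmetric eigendecomposition): Bray–Curtis matrices are routinely
non-Euclidean, and the implementation must drop the negative-eigenvalue
axes with a warning and exclude them from the proportion-explained
denominator rather than silently zeroing them. No Cailliez/Lingoes
correction is applied. Coordinates reproduce Euclidean inputs to 10⁻⁸.

The sequential PERMANOVA follows McArdle–Anderson: with G the
Gower-centred matrix and H_t the hat matrix of the cumulative design
through term t, SS_t = tr((H_t − H_{t−1})G), pseudo-F_t =
(SS_t/df_t)/(SS_res/df_res), and p-values from free permutation of sample
identities, p = (#{F* ≥ F} + 1)/(perms + 1). Restricted (within-microcosm)
permutation schemes are not implemented; with strong regime effects the
free-permutation p-values for the regime term are anti-conservative
against microcosm autocorrelation, which matters for borderline effects.
Term order is fixed by the caller (study design: selection group first,
current regime second, on the day-28 and day-50 samples). The default
9 999 permutations keeps the Monte-Carlo SE of a p ≈ 0.05 below 0.003;
the 10⁶ used for final published-style numbers is supported but
unnecessary for routine work. The dependent dissimilarity for the study
design is 1 − Spearman correlation of sample profiles, which is not a
metric and may be non-Euclidean — PERMANOVA only needs the Gower form, so
negative term SS (and slightly negative R²) can occur and are reported
as computed.

## Problem sizes in tests and acceptance runs

The validation suite works at the generator's default scale — 12
microcosms × 17 days = 204 samples and 60–80 OTUs, with 500–1000 ReBoot
iterations — and uses 50 replicate datasets for the type-I and power
Monte-Carlos and 200 datasets × 999 permutations for the PERMANOVA null
calibration. These sizes give Monte-Carlo SEs comfortably below the
asserted margins while keeping a full run in the minutes range on one
core.

## Known limitations

- The similarity measures are correlation-based; no compositionality-aware
  estimator (SparCC-style) and no indirect-edge removal is attempted, so
  edges are associations, not interactions.
- The generator's planted guilds create associations through shared niche
  response only; methods that fail on real data for compositional or
  confounding reasons can still pass here.
- PERMANOVA uses free permutations (see above).
- The errthresh rule is applied to the working table at association time;
  pipelines that filter on raw counts before normalisation would count
  zeros on a different table.
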