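# Methods

This note documents the models, defaults and numerical choices behind
`binflux`, and what the synthetic-data generator does and does not
emulate.

## Quantification model

Input depths are mean per-base coverage per scaffold per sample (the
output of `bedtools genomecov`-style callers, or the bundled interval
adapter, which computes exactly Σ depth·len / scaffold length with
uncovered positions as zero). The chain is:

1. **Length filter.** Scaffolds must be strictly longer than
   `min_scaffold_length` (default 500 bp). The inequality is strict: a
   500 bp scaffold is dropped, a 501 bp scaffold kept. Short contigs
   have unreliable mapping and inflate binning noise.
2. **Read-count normalization.** Sample *s* is scaled by R_min/R_s
   where R_s is its aligned-read count and R_min the minimum over
   *all* samples of the run (both experimental sets jointly, before
   any subsetting). The least-sequenced sample is therefore the
   reference with scaling factor exactly 1. This removes sequencing-
   depth differences while keeping depths on the scale of the
   shallowest library.
3. **Aggregation.** Bin abundance is the length-weighted mean scaffold
   depth — equal to total aligned bases assigned to the bin divided by
   the bin's assembled length, the standard coverage notion. Scaling
   commutes with this weighted mean, so normalizing before or after
   aggregation is equivalent (asserted by a property test).

Relative abundance divides each sample column by its sum (over all
bins by default; restricting to a subset such as the responsive bins
is possible by passing that subset). Fold changes are
log₂(mean_a+ε) − log₂(mean_b+ε) with arithmetic group means; the log
difference (rather than log of the quotient) makes swap-antisymmetry
exact in floating point. The default pseudocount ε is 1% of the
smallest nonzero abundance in the matrix — scale-aware, so results are
invariant under global rescaling of the data.

The inoculum comparison operationalizes "inoculum abundance" as the
mean over period-I samples of each experimental set: inocula were
sampled at steady state before the pulse and period I is exactly that
state.

## Response-group classification

Bins are classified per experimental set from period means (arithmetic
over all samples of the period — every reactor, replicate and sampling
day; a pulse-window mean, not the nadir day only). The rule on
log-ratios u₂, u₃ against period I (see README for the formula) is
total and deterministic: exactly one of {A, B, C, D, NONE} applies.
Choices worth noting:

* **Threshold θ = 2-fold** by default. No quantitative criterion for a
  "distinct" response is forced by the data; 2-fold is the
  conventional choice and θ is exposed everywhere. The bundled
  generator plants 4-fold effects, so recovery does not hinge on the
  threshold's exact value.
* **Discordant patterns** (e.g. up beyond θ in period II but down
  beyond θ in period III) map to NONE rather than being forced into A
  or C; the log-ratios are retained in the output so such bins can be
  inspected.
* The rule is scale-invariant (profiles multiplied by any c > 0 keep
  their label) provided the pseudocount scales along, which the
  automatic pseudocount does.

**Clustering** for heatmap ordering is agglomerative average linkage
on d = 1 − Pearson r between log₂(abundance+ε) profiles. Zero-variance
profiles, whose correlation is undefined, sit at distance 1 from
everything (neutral). Bins are canonicalized to lexicographic order
before linkage, which makes the leaf order invariant to input
permutation and resolves merge-height ties deterministically.

## Hypergeometric enrichment

For each (bin, category) pair with k ≥ 1 the upper tail P(X ≥ k) is
summed in log space (log-binomials via `gammaln`, combined with
log-sum-exp), accurate for community scales of 10⁵–10⁶ genes; an exact
rational mode (integer binomials) exists for validation at small g.
Querying k below the guaranteed overlap n−(g−f) returns exactly 1 (the
degenerate bin-holds-everything case). Counting rule: a gene mapped to
several categories contributes to each category's k and f but counts
once in the bin total n and the community total g. Adjustment is
Benjamini–Hochberg across all tested pairs by default (none and
Bonferroni available); no particular significance convention is
asserted beyond the configurable α = 0.05.

## General linear model

A from-scratch OLS engine (thin QR; coefficients, SEs, t/p; Type-III-
style F per effect by refitting without that effect's columns) with:

* treatment coding, reference level = first sorted label — lsmeans are
  coding-invariant, so this choice does not affect reported
  quantities;
* least-squares means: prediction at the target level with other
  categorical effects averaged at equal weight (each dummy at 1/L) and
  numeric covariates at their grand mean; pairwise comparisons by
  Student's t using the contrast SE and residual df;
* one bin-abundance covariate at a time in the covariate scan; the
  slope's sign reports "directly"/"inversely" correlated. A bin whose
  abundance column is aliased with the fixed effects (e.g. constant)
  is reported with a rank-deficiency note and the scan continues.

Observations are reactor-day records joined to samples by
(reactor, day) and treated as independent: no repeated-measures or
autocorrelation structure is modelled. This is a fidelity choice and a
known limitation — p-values are anti-conservative if within-reactor
correlation is strong. The Ac/Pr trait drops (and counts) records with
zero propionate.

## Synthetic-data generator

The generator emulates the *derived structure* of an LCFA-pulse
metagenome study, not its raw reads:

* **Community:** 106 bins, 45 responsive, allocated near-evenly to
  groups A–D (floors of configurable proportions, remainder in A,B,C,D
  order). Scaffold lengths are log-normal (median ≈ 4.9 kb, floor
  501 bp) with ~10% sub-500 bp decoy scaffolds whose only purpose is
  to exercise the length filter. Baseline abundances are log-normal;
  group A/B bins get 2× higher baselines in the acclimatized set and
  group D in the non-acclimatized set, mirroring the expected inoculum
  specialization.
* **Trajectories:** multiplicative period effects (default 4-fold): A
  up in II; B up in II and III; C down in III; D down in II and III.
* **Coverage:** scaffold depth = bin abundance × log-normal noise
  (mean 1, CV = `noise_cv`, default 0.2) × R_s/R_min, with
  aligned-read counts drawn in 16–20 M so normalization genuinely has
  work to do and inverts the depth factor exactly at zero noise.
* **Design:** 2 sets × doses {2, 3 g/L-reactor} × 2 biological
  replicates; periods I/II/III spanning days 1–4/5–14/15–24; 2
  sampling days per period, evenly placed (the study marks DNA days
  only graphically, so these are configurable).
* **Annotations:** per-gene categories multinomial over 20 background
  categories plus planted ones; in targeted bins a planted category's
  per-gene probability is its uniform baseline × the planted fold
  (default: two motility-like categories at 5× in A/B bins), the
  remaining mass spread evenly. ~5% of genes carry a second category
  to exercise the counting rule.
* **Process curves:** deterministic templates + additive Gaussian
  noise, not a mechanistic digestion model — the artifact tests
  statistics, not kinetics. Methane yield: 260 mL CH₄/gVS through
  period I; a linear drop to 260×(1−depth) at the per-(set, dose)
  nadir day with depths {0.95, 0.67} (non-acclimatized, 3/2 g) and
  {0.62, 0.31} (acclimatized); then a damped-cosine recovery whose
  overshoot reproduces the transient productivity peak; an exact
  265 mL CH₄/gVS plateau in period III. Total VFA is flat (2.5 g/L)
  while the acetate/propionate split follows a log-linear Ac/Pr
  trajectory from 6.0 (non-acclimatized) or 4.7 (acclimatized) down to
  0.3 / 0.3 and 0.5 / 0.4 respectively on the final day. Nadir days
  default to 8 (non-acclimatized, 3 g) and 7 otherwise. Process
  records are daily so any sampling day joins to a record.
* **Determinism:** one `SeedSequence` per dataset, child seeds per
  component; identical seeds give byte-identical files. A truth
  manifest (true groups, planted enrichments, decoy list) accompanies
  every dataset.

What it does **not** emulate: read-level artifacts (mapping bias,
chimeric bins, strain mixtures), compositional closure effects,
taxon-specific biology, or autocorrelated process noise. Passing tests
therefore demonstrate that the statistical machinery recovers planted
structure under idealized sampling noise — not that the pipeline is
robust to assembly or binning failure modes.

## Numerical choices and degenerate inputs

* Missing coverage cells read as 0 with one logged warning per file
  (absence is a biological zero); malformed numerics are hard errors.
* All-zero samples, empty periods, zero-length bins, zero aligned
  reads, overlapping depth intervals: hard errors naming the offender.
* Report floats render at 6 significant digits; row order sorts by the
  leading columns, so reports are diffable and reruns byte-identical.
* Pipeline manifests record config hash, input checksums and row
  counts but no timestamps, keeping reruns bit-identical.
* Problem sizes in the test and acceptance runs (default 106-bin
  community, 200-bin enrichment calibration, 500 GLM replicates) were
  chosen so the full suite completes in well under a minute while
  keeping binomial error on the calibration checks small.

## Known limitations

* The 45-of-106 responsive count is a generator parameter, not an
  inference target: with real data the responsive count depends on θ.
* GLM inference ignores repeated measures (above).
* Enrichment treats genes as exchangeable draws; operon structure and
  annotation errors violate that in real data.
* The length filter and normalization follow one published convention;
  other studies normalize per million reads or use TPM-like scalings,
  which are intentionally out of scope.
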