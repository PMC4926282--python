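# binflux

Genome-bin abundance dynamics in anaerobic digesters under long-chain
fatty acid (LCFA) shock loads.

When a biogas reactor receives a pulse of LCFA (e.g. sodium oleate),
methane production collapses and recovers over days while the microbial
community reorganizes. Shotgun metagenomics tracks this at the genome
level: reads mapped to assembled scaffolds give per-scaffold coverage,
scaffolds are grouped into genome bins (GBs, one per recovered genome),
and bin coverage over time is a proxy for each organism's abundance.
`binflux` is the analysis layer for such experiments: it turns scaffold
coverage tables into normalized bin abundances, classifies each bin's
temporal response to the pulse, tests functional categories for
over-representation within bins, compares acclimatized vs
non-acclimatized inocula, and relates reactor performance traits to bin
abundances with a general linear model. A synthetic-data generator
reproduces the structure of such a study end to end, so the whole
pipeline is testable without any sequencing data.

It is aimed at microbiome/bioprocess researchers who already have
coverage, binning and annotation tables (from e.g. `bowtie2` +
`bedtools genomecov` + a binning workflow) and want a reproducible,
scripted version of this analysis.

## Methods at a glance

**Quantification.** Scaffolds ≤ 500 bp are removed (reads are only
trusted on longer scaffolds). Depths are rescaled per sample by aligned
read counts, with the least-sequenced sample as reference: column *s*
is multiplied by R_min/R_s. Bin abundance is the length-weighted mean
depth

  A(b, s) = Σᵢ Lᵢ·dᵢₛ / Σᵢ Lᵢ  over scaffolds i ∈ bin b,

i.e. total aligned bases attributed to the bin divided by bin size.

**Response groups.** With period means m_I, m_II, m_III (before /
during / after the pulse), u₂ = log₂((m_II+ε)/(m_I+ε)) and u₃ defined
analogously, and t = log₂ θ (θ = 2 by default), each bin is labelled
A (u₂ ≥ t, |u₃| < t: up during the pulse only), B (u₂ ≥ t, u₃ ≥ t),
C (|u₂| < t, u₃ ≤ −t), D (u₂ ≤ −t, u₃ ≤ −t), or NONE.

**Enrichment.** For a bin of n genes holding k of a category's f genes
out of g community-wide, the statistic is the hypergeometric upper
tail

  P(X ≥ k) = Σ_{j=k}^{min(n,f)} C(f,j)·C(g−f,n−j) / C(g,n),

computed in log space, with Benjamini–Hochberg adjustment across all
(bin, category) tests.

**Association.** Each trait (methane yield, total/individual VFA,
Ac/Pr ratio) is fit by OLS against inoculum (2 levels), period
(3 levels) and LCFA dose, plus — one bin at a time to avoid
confounding — that bin's abundance as a linear covariate.
Least-squares means per factor level are compared by Student's t; the
covariate's slope sign reports whether a bin is directly or inversely
correlated with the trait.

## Worked example

Run the full pipeline on the default synthetic study (106 bins, 45
with a planted pulse response, two inocula × doses 2 and 3 g/L-reactor
× 2 replicates, three periods, 20% coverage noise):

```sh
binflux run --config run.yaml
```

with `run.yaml`:

```yaml
output_dir: demo
seed: 42
simulate: {}
enrich_groups: null   # test all bins
traits: [methane_yield, acetate]
```

The manifest reports, per stage:

```
classify: {'A': 24, 'B': 22, 'C': 22, 'D': 22, 'NONE': 122, 'responsive': 45}
enrich:   {'pairs_tested': 2326, 'enriched': 46}
```

45 of 106 bins are called responsive — here label recovery is exact
because the planted 4-fold effects sit well above the 2-fold threshold
(counts are per bin × experimental set, hence 212 labels). The 46
enriched (bin, category) pairs are precisely the planted ones: the two
motility-like categories seeded at 5-fold in the positively responding
(A/B) bins. The top of `demo/enrichment.tsv`:

```
bin_id  category_id      k    n    f     g      p_value      adjusted_p
GB098   flagellar_like   43   128  1373  15935  1.44128e-15  3.35241e-12
GB003   flagellar_like   50   177  1373  15935  1.92626e-14  2.24024e-11
GB072   chemotaxis_like  47   164  1346  15935  3.10522e-14  2.40758e-11
```

reading: bin GB098 carries k=43 of its n=128 genes in
"flagellar_like" against a community background of f=1373 in g=15935 —
a ~4.9× over-representation. `demo/foldchange_inoculum.tsv` compares
pre-pulse (period I) abundances between the two inocula; group-A bins
average log₂ fold change ≈ 1.01, recovering the planted 2× enrichment
of pulse-degraders in the acclimatized inoculum.
`demo/association_*.tsv` hold the per-bin covariate scans (slope,
direction, p-value) for each requested trait.

Every stage is also exposed separately (`binflux simulate`,
`abundance`, `classify`, `cluster`, `enrich`, `foldchange`,
`associate`); see `binflux --help`.

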