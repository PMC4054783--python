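# esekit

Comparative analysis of **exonic splice enhancer (ESE) hexamer
catalogues** for molecular evolution work.

Exonic splice enhancers are short exonic motifs, conventionally 6-mers,
that promote recognition of nearby splice sites (largely via SR-protein
binding). Several systematic screens have each nominated a catalogue of
candidate ESE hexamers, and the catalogues disagree substantially. This
package provides the statistical toolkit for asking, with any such
catalogues in hand:

* **Concordance** — do catalogues share more motifs than expected?
  For two uniform random catalogues of sizes *n₁*, *n₂* drawn without
  replacement from the *N* = 4,096 hexamers, the overlap is
  hypergeometric with mean *n₁n₂/N*; *k* independent catalogues share
  *N·∏(nᵢ/N)* motifs on average. Monte Carlo simulation supplies Z-scores
  and empirical P values, against the uniform universe, a nominated pool,
  or a hypothetical true pool.
* **True-pool estimation** — capture-recapture logic: the pool size *N*
  whose expected *k*-way intersection matches the observed one, found by
  integer search with analytic initialisation *N = (∏nᵢ/target)^(1/(k−1))*.
* **Positional profiling** — ESE coverage (fraction of positions covered
  by ≥1 motif) across a merged intron|exon|intron layout, with unpaired
  and matched flank-vs-core contrasts and purine splits.
* **Codon-usage concordance** — the hexamer preference index
  HPI(c) = (obs_c − μ_c)/σ_c, the Z-score of codon *c*'s share of a
  catalogue's frame codons against 10,000 codon-usage-weighted random
  catalogues; per-codon slopes of within-family usage on distance from
  the exon boundary; and, over all 87 synonymous codon pairs, a binomial
  sign test plus Spearman correlation combined with Fisher's method.
* **Selection tests** — substitution proportions at four-fold degenerate
  third positions (human–mouse) and SNP-bearing site proportions, in
  versus out of the ESE mask as a function of distance from the exon
  boundary, with composition-matched pseudoESE control sets and paired
  (by distance) Wilcoxon tests; plus the net estimate of how much ESEs
  depress the synonymous substitution rate.
* **Associations** — Spearman (and partial Spearman) correlations of
  flank ESE density with splice-site strength, flanking intron length,
  exon class labels and expression summaries (breadth, tau).

Every pipeline stage is exercisable without external downloads through
the built-in synthetic-data generator (`esekit.synthetic_data`), which
emulates exons, ortholog pairs, SNPs, splice scores and codon-usage
gradients with controlled ground truth.

## Worked example

```python
import esekit as ek
from esekit.motif_sets import HexamerSet
from esekit.synthetic_data import SyntheticSpec, gen_genome, gen_ortholog_pairs

# Two catalogues of 238 hexamers sharing 75 motifs, against the uniform null
null = ek.OverlapNull(universe_size=4096, reps=10_000, seed=1)
res = ek.simulate_overlap([238, 238], null, observed=75)
print(f"O={res.observed} E={res.expected_mean:.1f} F={res.fold:.2f} "
      f"Z={res.z:.1f} P{res.p_label}")
# O=75 E=13.8 F=5.42 Z=17.6 P<0.0001

# Divergence deficit inside enhancers, on a synthetic genome whose true
# in-ESE rate multiplier is 0.85 (i.e. a 15% deficit)
spec = SyntheticSpec(seed=1, n_exons=2000)
exons, truth = gen_genome(spec)
pool = HexamerSet.from_iterable("pool", truth["params"]["pool"])
pairs = gen_ortholog_pairs(exons, pool, seed=2, spec=spec)
profile = ek.divergence_by_distance(pairs, pool, max_distance=100)
print(ek.summarize_profile(profile, min_sites=50))
# {'n_distances': 61, 'median_ese': 0.2955..., 'median_non': 0.3542...,
#  'pct_difference': -16.6, 'p_paired': 3.12e-08}

print(ek.net_selection_estimate(0.15, 0.30, 0.80))
# {'local_reduction_pct': 5, 'net_reduction_pct': 4}
```

The first block reproduces the familiar enrichment arithmetic: 75
shared motifs against an expectation of 13.8 is a 5.4-fold excess, 17.6
null standard deviations out. The second recovers the imposed ~15%
in-enhancer rate deficit from the simulated ortholog pairs
(−16.6% here; the paired-by-distance Wilcoxon P is the significance of
the deficit). The last line chains a 15% rate deficit at 30% enhancer
coverage over 80% of near-boundary sequence into a net ~4% reduction in
the synonymous substitution rate.

A command-line interface mirrors the library:

```sh
ese simulate --seed 9 --n-exons 2000 --out sim/
ese overlap --sets a.txt --sets b.txt --reps 10000 --seed 1 --out overlap.tsv
ese hpi --set a.txt --reps 10000 --seed 7 --out hpi.tsv
ese divergence --pairs sim/pairs.tsv --set sim/pool.txt --out div.tsv
```

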