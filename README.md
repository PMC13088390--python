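# olivepedigree

Parentage inference and pedigree-atlas construction for clonally propagated
crops genotyped with small SNP panels — built around the olive use case:
a germplasm-bank panel of ~96 biallelic EST-SNPs (dosage-coded 0/1/2),
cultivar metadata (region of cultivation, chloroplast haplotype, stigmatic
self-incompatibility group G1/G2, andro-sterility, admixture Q-vectors), and
the question *who are the parents of whom* across hundreds of cultivars.

## What it computes

**Duos (parent–offspring pairs), two independent ways.**

1. *Kinship screen* — the allele-frequency-free KING-robust estimator over
   jointly typed loci,

   φ = (N<sub>Aa,Aa</sub> − 2·N<sub>AA,aa</sub>) / (N<sub>Aa</sub>(i) + N<sub>Aa</sub>(j)),

   retaining a pair when no locus shows opposite homozygotes (the zero-IBS
   condition, R0 = 0) and 0.177 < φ < 0.354.
2. *Likelihood* — a summed log-likelihood ratio (LOD) of parentage vs
   unrelatedness per pair, with a genotyping-error model (with probability
   *e* an observed genotype is an independent Hardy–Weinberg draw). Strict
   confidence cutoffs for LOD<sub>p</sub> (duo) and LOD<sub>pp</sub>
   (parent pair) are calibrated by simulated parentage analysis
   (10,000 offspring, 200 candidate parents, 30% of parents sampled, 80% of
   loci typed, *e* = 0.01) at the 95% level.

**Trios and robust selection.** Parent pairs are scored for every
duo-supported offspring; pairs need LOD<sub>pp</sub> above the calibrated
cutoff, at most two Mendelian-impossible loci, and both parents supported by
the duo analysis. One robust trio per offspring is selected by highest
LOD<sub>pp</sub> with a deterministic tie cascade (fewest mismatches → most
duo-supported parents → regional consistency → lexicographic); offspring
with more than 20 supported pairs are treated as acting parents and receive
no trio; contradictory trios are resolved by LOD<sub>pp</sub>.

**Biological validation and deduction.** Self-incompatibility (parents must
belong to opposite G1/G2 groups), maternal chlorotype inheritance, and
andro-sterility (a male-sterile tree cannot donate pollen) validate
complete trios and, on partial metadata, run deductively to a fixpoint:
complementary SI groups, offspring chlorotypes from agreeing parents, and
mother/father roles, each with provenance.

**Pedigree network.** Robust trios become a directed parent→offspring graph
with node roles (offspring / genitor / both), connected components, founder
rankings by duo degree and trio out-degree, and GraphML/DOT/CSV exports.

**Synthetic panels with truth.** Because parentage pipelines are hard to
test on real collections, `olivepedigree.simulate` generates founder
genotypes under Hardy–Weinberg, multi-generation SI-constrained pedigrees
with maternal cytoplasm and CMS, validation seedlings from known crosses,
and per-call noise — together with complete truth tables.

## Worked example

```
$ cat cfg.yaml
simulation:
  n_founders: 60
  n_generations: 2
  crosses_per_generation: 15
  seed: 42
calibration:
  n_offspring: 5000
  seed: 43

$ olive-atlas simulate --config cfg.yaml --out sim
simulated 120 individuals x 96 loci -> sim

$ olive-atlas run --genotypes sim/genotypes.csv --metadata sim/metadata.csv \
    --config cfg.yaml --out atlas
INFO olivepedigree.pipeline: kinship_duos: 7140 pairs scored, 116 pass
INFO olivepedigree.likelihood: calibrated thresholds: LOD_p > 6.737, LOD_pp > 16.889
INFO olivepedigree.pipeline: likelihood_duos: 7140 pairs scored, 117 pass
INFO olivepedigree.pipeline: consensus: 93 duos validated by both approaches
INFO olivepedigree.pipeline: trio_candidates: 18050 scored, 76 pass
INFO olivepedigree.pipeline: robust_selection: 57 robust trios, 6 offspring excluded
INFO olivepedigree.pipeline: network: 91 nodes, 114 edges, main component 69
wrote artifacts to atlas (57 robust trios)
```

Reading the numbers: of 7,140 possible pairs among 120 individuals, 116
passed the kinship screen and 117 the likelihood criteria; 93 duos were
validated by both approaches. The calibrated strict cutoffs for this panel
were LOD<sub>p</sub> > 6.74 and LOD<sub>pp</sub> > 16.89. 76 candidate
trios met all trio criteria, from which the rule cascade kept one robust
trio for each of 57 offspring (6 offspring were excluded, e.g. as acting
parents or conflict losers). The pedigree network has 91 nodes in a main
component of 69 cultivars plus 4 smaller subnetworks. Per-stage CSV
artifacts (`duos_*.csv`, `trios_robust.csv`, `founder_ranking.csv`,
`network.graphml`, `report.json`, …) land in `atlas/`.

The library surface mirrors the stages: `sambar_duo_search`,
`calibrate_thresholds`, `cervus_duo_search`, `trio_search`,
`intersect_duos`, `select_robust_trios`, `sensitivity_scenarios`,
`deduce_attributes`, `build_network`, all composable from Python with
pandas inputs and outputs.

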