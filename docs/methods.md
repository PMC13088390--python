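# Methods

This note documents the statistical model, the simulation design, the
numerical choices, and the known limitations of `olivepedigree`.

## Genotype model and notation

Loci are biallelic SNPs; a genotype is the dosage of the reference allele
(0, 1, 2), missing allowed. For a locus with reference-allele frequency
`p` (and `q = 1 − p`), Hardy–Weinberg genotype frequencies are
`f = (q², 2pq, p²)`. Marker descriptives follow the standard definitions
for biallelic loci: `MAF = min(p, q)`, expected heterozygosity
`He = 2pq`, polymorphic information content
`PIC = 1 − (p² + q²) − 2p²q²`. Allele frequencies for the likelihood
machinery are estimated from the full input matrix by default (an external
frequency table can be supplied instead); loci with missing rate above 0.5
are dropped before parentage analysis, and loci that are monomorphic in the
sample contribute zero LOD but still participate in mismatch counting,
which is frequency-free.

## Kinship duo screen

The KING-robust estimator uses only heterozygote and opposite-homozygote
counts over the loci typed in both members of a pair:

    phi = (N_het,het − 2 · N_opphom) / (N_het(i) + N_het(j))

It requires no allele frequencies and is exactly symmetric. A pair is
retained as a putative parent–offspring duo iff (a) no locus shows opposite
homozygotes — a Mendelian necessity for true parent–offspring at zero
error — and (b) phi lies strictly inside (0.177, 0.354), the standard
first-degree window whose midpoint 0.25 is the parent–offspring
expectation. The window endpoints are exclusive and configurable. R0 is
carried as `n_opposite_hom / n_compared`; the filter tests the numerator,
so any denominator convention is filter-equivalent. Pairs with fewer than
20 jointly typed loci (configurable) are flagged low-confidence and never
pass.

A sampling property worth knowing: at 96 loci the per-pair phi of a true
parent–offspring pair has a standard deviation of about 0.04, so roughly
5% of true pairs fall outside the window even without genotyping error.
The kinship screen is therefore deliberately conservative; the pipeline
compensates by feeding the *union* of both duo approaches into the trio
search while reserving the *intersection* (consensus) for reporting and
tie-breaking.

## Likelihood engine

Per locus, the parentage hypothesis is scored against unrelatedness:

- single parent: `T1(g_o | g_p)` is the probability of the observed
  offspring genotype given the observed parent genotype, marginalizing over
  true genotypes — Mendelian transmission from the parent with the
  untransmitted allele drawn from the population at frequency `p`;
- parent pair: `T2(g_o | g_a, g_b)` with Mendelian transmission from both;
- unrelated: the Hardy–Weinberg probability `f(g_o)`.

`LOD = Σ ln(T / f(g_o))` over jointly typed loci. The genotyping-error
model treats each observed genotype independently as a random
Hardy–Weinberg draw with probability `e` (default 0.01, matching the
"proportion of loci mistyped" setting) and the true genotype otherwise.
Because the marginal of an observation equals Hardy–Weinberg for every `e`,
posteriors over true genotypes have a closed form and the transition tables
(per locus, 3×3 for duos, 3×3×3 for trios) are exact. `T` is a proper
conditional distribution — it sums to one over offspring genotypes for
every parent configuration and every `e` — and is finite whenever `e > 0`,
so Mendelian-impossible configurations are penalized (≈ −4 per locus at
intermediate frequencies) rather than fatal. Mismatches are counted
frequency-free at `e = 0`: opposite homozygotes for duos, offspring
genotypes impossible under the pair for trios. The duo LOD is
role-symmetric (the joint parent–offspring likelihood is symmetric in the
two individuals), so duos are unordered; orientation comes later from
biology.

Scoring is vectorized: genotypes are one-hot encoded on four states
(0/1/2/missing, missing contributing zero LOD and zero comparisons) and
all-pairs LOD matrices are computed as matrix products against the
per-locus tables.

## Confidence calibration

Strict LOD cutoffs are calibrated by simulated parentage analysis at the
panel's own allele frequencies, with the standard recommended settings as
defaults: 10,000 simulated offspring, 200 candidate parents, probability
0.3 that each true parent is present among the candidates, 80% of loci
typed, `e = 0.01`. For each simulated offspring the duo assignment is the
top-LOD candidate, and the pair assignment the top-LOD_pp pair among the
10 best single-parent candidates (a pruning that loses nothing, because
relatives dominate the single-parent ranking). The strict threshold is the
lowest cutoff such that at least 95% of assignments strictly above it are
correct; the Δ statistic (top minus second score) is computed and logged
but not used for filtering. Calibration is seed-reproducible and reports
the fraction of assignments retained plus separability flags.

Empirically the LOD_pp cutoff grows with panel size (more loci, more
separation), while the duo cutoff tracks the upper tail of
best-unrelated-candidate scores, which *shrinks* with more loci — the two
cutoffs are not jointly monotone in locus count. At 96 loci with
intermediate frequencies the calibration lands near `LOD_p ≈ 6.7` and
`LOD_pp ≈ 17–19`; the exact values are a property of the panel's
frequencies and are recomputed per dataset, never hard-coded.

## Trio search and robust selection

Offspring eligible for the pair search are the individuals appearing in at
least one passing duo; candidate parents are likewise all duo members
(not only the offspring's own partners — a single damaged duo must not
veto a pair whose joint likelihood is decisive). Scored pairs per
offspring are pruned to its top-20 candidates by single-parent LOD. A
candidate trio passes with `LOD_pp` above the strict cutoff and at most
two mismatching loci.

Robust selection keeps at most one trio per offspring:

1. highest `LOD_pp`; exact ties cascade through
2. (i) fewest trio mismatching loci,
3. (ii) most parents appearing in a consensus duo with the offspring,
4. (iii) most parents whose region of cultivation equals the offspring's
   (skipped with a logged notice when regions are unknown), then
5. lexicographic parent-pair order, making the selection total and
   deterministic.

Offspring with more than 20 statistically supported parental pairs receive
no trio — that pattern identifies an individual acting predominantly as a
parent (typically a founder), not a descendant. Direct contradictions
(X offspring of (A, B) while X parent of A) are resolved by keeping the
higher-`LOD_pp` trio; longer cycles in the parent→offspring graph are
detected and broken the same way, and all resolutions are reported.

Sensitivity scenarios re-run the trio inference for designated validation
offspring with the same thresholds: scenario 1 unmodified, scenario 2 with
one known parent removed from that offspring's candidate set (the father
when known, else the mother), scenario 3 with both removed. The report
records, per offspring and scenario, the selected trio, its support, and
whether it matches the declared truth.

## Biological rules

Three systems constrain a trio: the diallelic self-incompatibility system
(parents must belong to opposite stigmatic groups G1/G2), maternal
inheritance of the chloroplast haplotype, and andro-sterility (a
male-sterile tree cannot be a pollen donor; in this germplasm CMS
co-segregates with the E3.1 chlorotype lineage). With complete metadata
these act as validation filters; with partial metadata the same rules run
deductively: SI complement across a parental pair (DED-a), offspring
chlorotype from two agreeing parents (DED-b), mother/father roles from
chlorotype matching or andro-sterility and maternal chlorotype propagation
once roles are known (DED-c/DED-d). Deduction sweeps trios in lexicographic
order and iterates to a fixpoint; attribute states only move
unknown → known → frozen, bounding the iteration. Observations always beat
deductions (a contradicted deduction is discarded and the trio flagged
inconsistent); contradictory deductions freeze the attribute and log both
sources. When both parents share the offspring's chlorotype the parental
roles are genuinely indeterminate and are left unknown rather than guessed.

Admixture handling is intentionally thin: the package consumes a
precomputed Q-matrix (three clusters), assigns a cultivar to a cluster only
when its largest membership strictly exceeds 0.75 (else admixed), and
cross-tabulates consensus duos by cluster with row-percentage
normalization, counting each unordered duo in both orientations.

## Synthetic data generator

The generator emulates the panel the pipeline targets, with every default a
stated study condition: 96 loci with minor-allele frequencies uniform on
[0.05, 0.5] (which yields the intermediate frequencies and ≈0.46 mean He
such panels are selected for), per-call error 0.01, per-call missingness
0.0028, founders split evenly between SI groups, chlorotype frequencies
E1.1 0.70 / E1.2 0.15 / E2 0.05 / E3.1 0.10 (one dominant maternal lineage
plus a CMS-carrying lineage), andro-sterility exactly in E3.1 carriers.
Where the study conditions name no value we fixed a realistic one once:
40 crosses per bred generation with 2 offspring each; founder regions
uniform over EM/CM/WM; founder Q-vectors Dirichlet-concentrated on the
region-matched cluster (α = 12 vs 1.5, giving mostly assigned founders and
a realistic admixed fraction); offspring region and chlorotype follow the
mother and offspring Q is the parental mean. Offspring SI group is drawn
uniformly — the genetic architecture of olive SI is not modelled, and only
parental complementarity is consumed downstream. "Mistyped" calls are
redrawn from the locus's Hardy–Weinberg distribution, deliberately matching
the likelihood engine's error model; the returned error mask marks every
redrawn cell whether or not the redraw coincided with the original call.
Validation seedlings (13 by convention) are bred from compatible founder
pairs, the last one emulating an open-pollination cross whose pollen donor
is nonetheless present in the panel.

What the generator does **not** emulate: linkage and recombination maps
(loci are independent), selection, population structure beyond the founder
Q-vectors and regions, genotyping batch effects, null alleles, and cultivar
synonymy (ids are pre-deduplicated). Passing tests therefore demonstrate
correctness of the inference machinery under an idealized panel, not
robustness to structured real-world artefacts.

## Problem sizes and measured behaviour

The end-to-end checks run a panel of 150 founders plus two bred generations
(about 320 individuals, 96 loci) with the default noise, a size at which
the full pipeline including calibration completes in a few seconds on one
core. Under those conditions the pipeline recovers the true parental pair
for 95–99% of offspring whose parents are both present (across seeds), all
or all-but-one of the 13 validation seedlings at baseline, and selects no
surviving high-confidence trio for any validation seedling once both true
parents are removed from its candidate set. All such figures are computed
by the test suite and `scripts/acceptance.py` at run time.

## Numerical and degenerate-input choices

- Allele frequencies are clipped to [1e−9, 1 − 1e−9] inside table
  construction; loci degenerate in the sample are marked uninformative
  (zero LOD) rather than erroring, while the scalar `transition_prob`
  rejects degenerate `p` explicitly.
- Pairs with no jointly typed loci or no heterozygous loci have undefined
  phi (NaN) and never pass the window.
- Fully missing loci carry an `undefined` flag in marker statistics instead
  of raising.
- Threshold extraction from the calibration scores takes the midpoint
  between adjacent order statistics (or the next-representable value below
  on exact ties), so the strict `>` comparison reproduces the intended set.
- All randomness flows through explicit seeds (simulation and calibration
  seeds are separate config fields); identical configuration reproduces
  byte-identical artifacts.

## Known limitations

- Duo/trio confidence uses plain LOD cutoffs; the Δ-based confidence of
  interactive parentage software is logged but not applied.
- The kinship screen misses a few percent of true pairs at 96 loci by
  construction (see above); consensus counts inherit that.
- Sibship reconstruction, half-sib categories, multi-generation joint
  likelihood, and Bayesian pedigree reconstruction are out of scope.
- Region consistency is operationalized as exact region equality; no
  geographic adjacency model is attempted.
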