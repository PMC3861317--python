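# Methods

## The statistical problem

A variant that disrupts a basic cellular mechanism (coagulation, DNA
repair, chromatid segregation) can present as any of many clinical
diagnoses. Single-diagnosis association tests dilute such pleiotropic
effects; a mechanistic phenotype pools the constituent diagnoses into one
case definition. For low-MAF nsSNPs the interesting contrast is between
the two homozygote classes: a recessive-acting allele concentrates its
effect in the minor-allele homozygotes (HZMA), and heterozygote carriers
of an additive allele would blur the comparison, so the reverse-genetics
statistics drop heterozygotes entirely.

## Models

**Forward models.** Per SNP and phenotype, logistic regression of case
status on genotype (additive 0/1/2 or recessive HZMA-indicator coding)
with age (continuous years), gender and source dataset (dummy-coded;
single-level columns dropped) as covariates. The genotype term's Wald
statistic supplies `OR = exp(β̂)`, 95% CI and p — the same quantities
standard GWAS toolchains report, so output is directly comparable.
Separation (common in recessive fits with ≈10 homozygotes) is detected
by unbounded estimates/standard errors and flagged with a missing p by
default; `firth=True` switches to a Jeffreys-prior penalised fit (Newton
iterations on the Firth-modified score with step-halving), which keeps
estimates finite under complete separation. Only OR > 1 results (risk
direction, strict inequality) feed enrichment.

**Reverse-genetics models.** For a SNP with homozygote split
(HZMA, HZCA):

* qualifying diagnoses, model 1: constituent groups carried by
  ≥ `min_count` distinct HZMA subjects (default 2, i.e. "occurring more
  than once"; the ≥ 3-carrier variant discussed below is available via
  `min_count=3`);
* qualifying diagnoses, model 2: model-1 groups additionally showing
  HZMA excess at one-sided Fisher exact p < 0.1 vs HZCA (the lenient
  threshold deliberately keeps sub-significant excesses while discarding
  groups at chance levels; setting it to a genome-wide threshold would
  collapse the model onto a standard PheWAS test);
* statistic: T = number of HZMA subjects carrying ≥ 1 qualifying group.

Because the qualifying set is chosen by looking at the observed HZMA
subjects, the null distribution must undergo the same optimisation:
genotype vectors are reassigned among subjects within strata
(dataset × age decade × gender by default; `age_bin` configurable since
no theory fixes it), the qualifying set is re-derived for every
reassignment, and p = #{T_perm ≥ T_obs}/B ("plain", the literal
definition, which can return 0) or (count+1)/(B+1) ("anchored",
recommended for ranking). B defaults to 10,000. Within-stratum
reassignment preserves per-stratum genotype counts, hence the MAF, and
minor-allele homozygotes can never migrate across strata. Permutation
RNG streams are seeded per SNP from (seed, snp_index), so results are
reproducible and independent of execution order or parallelisation.

**The ≥2 vs ≥3 carrier threshold.** Sources describing this model family
state the multiply-occurring rule both as "more than once" (≥ 2 carriers)
and as "> 2 affected subjects" (≥ 3), in different places. The package
default is `min_count=2`; the ROC acceptance checks for the published
scenario-1 AUC magnitudes use `min_count=3`, which is the definition the
published ROC summary states for those numbers and the only one that
reproduces them, while the model-ordering checks use the default. Both
variants are first-class.

## Enrichment scan

Genes are ranked by their best (minimum) association p over their nsSNPs
(most genes carry a single nsSNP, so the min convention is essentially a
per-gene p). Pooled mode takes each gene's best p across phenotypes and
dedupes (the pair-universe alternative, one entry per gene × phenotype,
is available as `pooled_pairs`). For k = 1..K, where K counts genes with
p < 0.05 (or a fixed top-n in GWAS mode), each ontology term is tested
with a one-sided hypergeometric tail against the full ranked universe;
k only advances at strict p increases, so rank ties enter together.
Each term reports its scan minimum Fisher p, the attaining k and
association-p threshold, and a BH step-up q over all m terms annotating
the universe (terms never annotated by a selected gene enter at p = 1;
BH with m larger than the list is computed by padding with ones).
Significance requires q < 0.05 *and* ≥ 2 annotated selected genes.

The scan minimum is a minimum over nested tests and therefore
anti-conservative as a standalone p-value; the whole-universe FDR and
two-gene rule temper but do not remove this. An optional rank-shuffling
calibration (`scan_minp_permutation_calibration`) estimates how often a
random ranking achieves an equal or smaller scan minimum; it is off by
default and not part of the significance rule.

Ontology terms are flat labels; no GO-graph propagation is applied
(annotations are read as exported).

## Synthetic cohorts

The generator emulates the published cohort margins: subject covariates
(age ~ N(52.3, 17.7²) clipped to [18, 90], gender 64% female for the
thrombosis profile, two source datasets 40/60), a low-MAF SNP panel
(MAF ~ U(0.05, 0.10), Hardy–Weinberg Binomial(2, MAF) dosages,
independent of phenotype — null by construction), and constituent-group
indicators with the Table-style prevalences (thrombosis: anticoagulation
10.8%, stroke 10.0%, myocardial infarction 9.0%, venous 7.0%, pulmonary
2.8%, other 2.7%, arterial 2.2%, spontaneous abortion 1.9%; any 27.4%).

Co-occurrence uses a shared logistic frailty: subject i draws
u_i ~ N(0, 1) and carries group g with probability
expit(α_g + σ·u_i). Given σ, each α_g is solved (Gauss–Hermite
quadrature + Brent root-finding) so the group marginal matches its
target; σ itself is then solved so the induced any-phenotype prevalence
matches the published aggregate. The aggregate is far below the
independence bound (38.4% for the thrombosis margins), so a single
positive σ is pinned by the published numbers rather than chosen.

What the generator does **not** emulate: code-level ICD-9 structure
(generation is at constituent-group level, with a trivial one-code-per-
group map emitted for pipeline completeness); the real data's finer
grouping (21 thrombosis groups vs the 8 published category margins);
age/gender-dependent diagnosis risk; and any true genotype–phenotype
association unless `plant_effect` adds one. Passing tests therefore
certify the statistical machinery under realistic margins and
co-occurrence, not performance on real EMR data.

`plant_effect` gives each minor-allele homozygote of a chosen SNP a
target-group diagnosis independently with a stated penetrance
(single/multi/random-diagnosis modes), enabling recovery experiments.

## Simulation studies

Both operating-characteristics studies run with a single collapsed
permutation stratum: under the null, genotypes are exchangeable across
subjects, so a global shuffle induces the same tally distribution as a
stratified one, and the homozygote sets of a shuffled genotype are
uniformly random subject subsets. The engine samples those subsets
directly (with-replacement draws plus duplicate rejection) and computes
tallies with vectorised carrier-count algebra; for model 2 the
common-homozygote carrier comparison is sampled from its exact
conditional hypergeometric law, with the Fisher cut-off precomputed as a
monotone threshold on the common-homozygote carrier count. Equivalence
with the general stratified-permutation path and with exhaustive
enumeration is covered by tests.

*Type-I error*: genotype labels of the QC-retained panel are shuffled
(preserving the MAF spectrum) to form ≥ 50,000 null SNPs, each scored
with a B = 1,000 permutation p; rate(α) is the fraction with p < α
(strict, matching the definition of the cut-off).

*ROC*: paired draws of 13 subjects (a typical minor-homozygote count for
the panel) act as HZMA with the rest of the cohort as HZCA; a spiked
copy assigns k added cases under four scenarios — uniform-random
constituent group, carrier-frequency-weighted, a group already present
in the sample (infeasible samples are redrawn and counted), or one
random group given to all k. Added diagnoses are always groups the
subject does not already carry, and existing diagnoses are retained.
AUC is the Mann–Whitney probability that a spiked sample's p undercuts
a null sample's p, with midrank ties.

## Numerical choices and degenerate inputs

* Exact tests (diagnosis Fisher, ontology Fisher) use hypergeometric
  tail sums (`scipy.stats.hypergeom`); the HWE test is the exact
  conditional test computed by enumeration over heterozygote counts in
  log-space (monomorphic SNPs return p = 1).
* Minor-allele polarity is decided per SNP by in-cohort frequency, a
  50/50 tie going to the lexicographically larger allele; dosage
  re-polarisation makes PED/MAP and dosage-TSV inputs equivalent.
* All-missing SNPs are dropped with a warning; missing dosages are
  handled complete-case per SNP, and missing labels ride through
  permutations unchanged.
* SNPs with zero minor-allele homozygotes have an undefined tally and
  are skipped with a recorded reason.
* Result TSVs are written with shortest round-tripping float repr and a
  documented sort (enrichment: FDR q, then Fisher p, then term id), so
  identical inputs give bit-identical outputs.
* HWE failures are flagged, not removed, by default (`hwe_exclude`
  available): the selection criteria this mirrors reported HWE failures
  without stating removal, and both behaviours are supported.

## Known limitations

* **Discrete tallies make small-α permutation rates conservative.** T is
  an integer on a short range, so its survival ladder is coarse; for an
  exchangeable null and the plain estimator, P(p < k/B) ≤ k/(B+1) at
  every B, and the rung structure pushes the empirical type-I rate at
  α = 0.001 several-fold below nominal under the default generator
  (≈ 4–5 × 10⁻⁴; the effect persists at B = 10,000 and with finer group
  subdivisions). Rates at looser cut-offs are likewise conservative,
  never anti-conservative — the direction that matters for validity.
* **Recovery power is condition-limited.** At penetrance 0.4 among ~13
  homozygotes, the Binomial lower tail leaves ≈ 1 in 6 replicates with
  ≤ 3 planted carriers, and the 8-group profile's high null tallies cap
  single-SNP recovery below the 5th-percentile null cut at roughly 70%
  of replicates.
* The enrichment scan's min-p is anti-conservative by construction (see
  above); interpret reported Fisher p-values through the FDR/two-gene
  rule or the optional calibration.
* Exact logistic regression, PC covariates, relatedness/ancestry QC and
  GO-graph semantics are out of scope.
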