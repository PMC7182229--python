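# Methods

This note documents the statistical procedures implemented in `snpqc`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## Diploidized genotype coding

Commercial reduced-representation genotyping of an autohexaploid at
~25–30× allele depth cannot call allele dosage (0–6 copies) reliably, so
the five heterozygous dosage classes are collapsed into a single
heterozygote: every call is one of homozygous-reference, homozygous-
alternative, heterozygous, or missing (file codes `0`, `1`, `2`, `-`).
Internally the four states are an enum; the file codes are purely a
serialization, because code `1` = BB and `2` = AB are not dosages and
must never enter arithmetic. Dosage conversion (REF→0, HET→1, ALT→2 on a
diploid scale) is explicit and used only where a statistic is defined on
dosages (LD, the ASD equivalence).

**Consequence for every estimator.** All statistics treat the collapsed
codes as diploid genotypes. For a truly hexaploid locus at allele
frequency p the collapsed heterozygote fraction is
1 − p⁶ − (1−p)⁶, far above the diploid 2p(1−p); allele frequencies
estimated from the collapsed codes are pulled toward 0.5. Under
hexaploid sampling this makes Nei F_IS strongly negative (≈ −0.7 in the
default simulation, with no inbreeding present at all) and attenuates
Weir–Cockerham θ relative to the generator's target (≈ 0.03 observed at
target 0.07 in the default design). The bias is a property of the data
representation, not an estimator bug; it is left uncorrected because the
dosage information needed to correct it is absent from the inputs.
Estimator-validation tests therefore run the generator at `ploidy=2`,
where the diploid model holds and the estimators are unbiased; the
hexaploid default is retained everywhere the *pipeline behaviour* (rather
than estimator calibration) is under test. Real diploidized data carry
the same distortion, so cross-dataset comparisons of F-statistics should
only ever be made between matrices coded the same way.

## Locus quality and filtering

For each locus, with n_called genotyped samples of which n_AA, n_BB,
n_AB are the three classes:

- alternative-allele frequency p̂ = (2·n_BB + n_AB) / (2·n_called);
- MAF = min(p̂, 1−p̂);
- PIC = 1 − p̂² − (1−p̂)² (gene-diversity form, maximum 0.5 — chosen over
  Botstein's three-term PIC, which caps at 0.375, to match the 0–0.5
  scale platform exports use);
- AvgPIC = the same diversity computed from each allele's *presence*
  frequency among called genotypes (fraction of genotypes carrying the
  allele), averaged over the two alleles.

A locus with zero called samples gets call rate 0 and NaN metrics; it is
flagged, never an exception. Filtering keeps a locus only if it passes
every active criterion (missingness ≤ t, PIC ≥ t, MAF ≥ t, call rate ≥ t,
and optionally a real chromosome assignment, with `Chr00` counting as
unplaced). Missingness and call rate are one quantity with two spellings.
Two ready-made recipes are provided: the parent recipe (missingness ≤
0.25, PIC ≥ 0.25, MAF ≥ 0.10) and the stricter progeny recipe (PIC ≥
0.25, MAF ≥ 0.20, call rate ≥ 0.90, placed loci only). Sequencing-depth
criteria cannot be evaluated from a genotype matrix and are recorded in
the report as not evaluated. Filtering is idempotent and the report
tallies failures both per criterion and by first failing criterion.

## Allele-sharing distance

Per locus, two called genotypes are at distance 0 if identical, 1 if
opposite homozygotes, 0.5 if exactly one is heterozygous; the pairwise
ASD is the mean over loci where both samples are called (pairwise
deletion). This equals the mean half-absolute-difference of diploid
dosages, which the test suite uses as an independent oracle. ASD assumes
neither Hardy–Weinberg nor linkage equilibrium, which is why it is the
distance of choice for diploidized polyploid data. Pairs sharing fewer
than `min_overlap` loci (default 20) are flagged; a pair with *no*
shared locus raises by default, or takes the matrix-wide mean under the
`zero_overlap="mean"` policy.

## Neighbor joining and tree comparison

NJ is the classic Saitou–Nei agglomeration on the Q criterion with two
determinism rules: ties in Q break toward the lexicographically lowest
pair of cluster representatives (a cluster is represented by its
smallest leaf label), and a negative branch length is clamped to zero
with the deficit moved to its sibling so the joined pair's total is
preserved. On additive matrices the output reproduces the input path
lengths exactly (tested to 1e-9); the topology agrees with dendropy's
independent NJ implementation.

"Strict" tree comparison counts exactly-matching internal-edge
bipartitions (splits), ignoring branch lengths and newick rotation:
dissimilarity % = 100 · (1 − shared / max(n₁, n₂)). The normalization is
an interpretation of tree-comparison tools that report a single
"difference" percentage; since alternatives exist, `min` and `avg`
normalizations are exposed as options rather than guessed at.

## F-statistics

- **Nei F_IS** per population: 1 − H_obs/H_exp where both are unweighted
  means over loci polymorphic *within that population* (ratio of
  averages, which is stable when some loci have tiny H_exp); H_exp =
  2p̂(1−p̂). Monomorphic populations yield NaN, flagged not raised.
- **Weir–Cockerham (1984)**: per-locus variance components a (among
  populations), b (among individuals within populations), c (within
  individuals), computed from per-population sample sizes, allele
  frequencies and heterozygote fractions, then *summed over loci* before
  forming θ = Σa/Σ(a+b+c), F = 1 − Σc/Σ(a+b+c), f = 1 − Σc/Σ(b+c) — the
  estimator's recommended multi-locus form. The identity
  (1−F) = (1−θ)(1−f) then holds by construction and is asserted to 1e-9.
  Populations with fewer than two samples are excluded with a warning;
  loci informative in fewer than two populations get NaN components.
  Pairwise θ applies the same estimator to each population pair. A
  scalar brute-force transcription of the published formulas serves as
  the test oracle for the components.
- **LD r²**: squared Pearson correlation of dosage vectors over samples
  called at both loci (phase-free, genotype-level), within chromosomes
  by default. Pairs monomorphic in the shared samples are excluded and
  counted. This screens marker redundancy/distribution; it is not an LD
  decay analysis, which would need dosage, phase and far higher density.

## Mantel tests

The statistic is the Pearson correlation of strictly-lower-triangle
entries after aligning the second matrix to the first's label order. The
permutation null relabels the second matrix's rows and columns jointly;
the test is one-sided upper with p = (1 + #{r_perm ≥ r_obs})/(n_perm+1),
seeded and reproducible. Calibration under independence (false-rejection
rate at the 1% level over 100 seeded repeats) is part of the acceptance
suite, and r/p agree with scikit-bio's implementation in tests.

## Replicate concordance

Clones replicated across propagation stages should cluster together.
Default rule `tree_clade`: the clone's replicate set must be one side of
an edge bipartition of the NJ tree over all samples (the formalization
of "forms its own clade on the tree"); alternative rule
`exclusive_cluster`: max within-replicate ASD strictly below the min
replicate-to-outsider ASD. Single-replicate clones are untestable and
excluded. A clone whose replicates agree among themselves (within the
resolvability floor, default ASD 0.01) but that fails only because a
*distinct* clone sits within that floor is a near-duplicate — flagged
"unresolvable" and excluded from both numerator and denominator of the
mislabeling rate, since no marker panel can separate identical
genotypes. The mislabeling rate is 100 · discordant / tested.

Stage-to-stage agreement: one genotype-labelled ASD matrix per stage
(complete cases only — clones with exactly one sample in every stage),
Mantel r per stage pair, and a companion discordance rate 100·(1−r)
which reads r as fractional agreement.

## Panel selection

The intermediate set is the intersection rule: markers passing the
parent filter that are also present and segregating in the progeny,
ranked by parent PIC. The diagnostic panel takes k markers per
chromosome (default 2, giving 30 for a 15-chromosome genome) maximizing
the minimum pairwise physical distance — for k = 2, the most widely
separated pair; "genetic distance" is implemented as base-pair
separation since genetic maps are typically unavailable for the
candidate markers. Ties break toward higher PIC, then lower AlleleID, so
selection is fully deterministic. A chromosome short of candidates is
topped up from a fallback set (e.g. the full filtered parent set) by
maximal distance to what is already selected, with each rescue recorded;
a chromosome absent from both sets is a reported deficit, never an
exception. Trait-associated markers are appended as-is (distinct role,
no deduplication beyond an identity warning). Panel evaluation reports
strict tree dissimilarity against the full set, per-population F_IS on
both sets with a rank-preservation check, and — when a replicate map is
supplied — the mislabeling rate through the panel versus the full set.

## Synthetic data

The generator is an *emulator* of the data the pipeline consumes, not a
model fitted to any real dataset. Ancestral allele frequencies are
uniform on [0.10, 0.50]; each population's frequency follows the
Balding–Nichols model, Beta(p(1−F)/F, (1−p)(1−F)/F) with F the target
F_ST, whose mean is p and variance F·p(1−p) (verified at 2,010 loci to
±0.02). Individual alt-allele counts are Binomial(ploidy, p_pop), or
beta-binomial with correlation f when within-population inbreeding is
requested; counts are diploidized and calls masked at the missing rate.
Defaults fix the emulated study design once: four populations of
331/126/144/61 samples (Peru, Uganda, Mozambique, Ghana), 15 chromosomes
× 14 loci (≈ the ~205-marker scale of a stringently filtered parent
set), target F_ST 0.07, ploidy 6, 5% missingness.

The replicate generator copies each genotype once per stage (in-vitro,
screenhouse, field), perturbs each copy at the genotype error rate
(homozygote→heterozygote, or heterozygote→a homozygote drawn from the
locus allele frequency — crossing the hom/het boundary only, as a
mis-clustered sequencing call would), and swaps one randomly chosen
stage's copies between pairs of clones until the requested mislabel
fraction is reached (rounded down to an even count; the default progeny
preset uses 94 clones and fraction 0.28, i.e. 26 mislabeled clones).
Every swap and error count is recorded in the ground truth.

Not emulated: linkage along chromosomes (loci are exchangeable;
positions matter only to panel selection), family/pedigree structure in
the progeny (clones are independent draws rather than full-sib
families), platform-specific error profiles, and read-level data.
Passing tests therefore demonstrate correctness of the estimators and
decision rules under the stated sampling model — not robustness to
pedigree structure or platform artifacts.

## Numerical and design choices

- Problem sizes in the test and acceptance runs (e.g. 4×100 samples ×
  300 loci × 10 seeds for θ recovery; 94×3 replicates; 50 random trees
  of 5–8 leaves) were chosen as the smallest designs at which the
  binomial/sampling error bands quoted in the tests are meaningful.
- NJ tie tolerance is 1e-12 on the Q criterion; bipartition comparison
  is exact (set equality on label sets).
- Mantel requires ≥ 99 permutations; p is never 0 by construction.
- Degenerate inputs are flagged, not raised, wherever a partial result
  is scientifically meaningful (all-missing loci, monomorphic
  populations, chromosomes with one locus); hard errors are reserved for
  structural problems (duplicate IDs, label mismatches, zero-overlap
  pairs under the default policy).
- Seeds: every stochastic routine takes an explicit seed; the CLI and
  the acceptance script derive all randomness from a single `--seed`.

## Known limitations

- All heterozygosity-based statistics inherit the diploidization bias
  discussed above; absolute F_IS/θ values from diploidized hexaploid
  data are not comparable to dosage-based estimates.
- The exclusive-cluster rule is conservative for clones with high
  genotyping error (replicates drift apart); the tree-clade rule is the
  default because clustering on a tree is how such verdicts are made in
  practice.
- The strict tree-comparison percentage depends on the chosen
  normalization when the two trees resolve different numbers of splits.
- Two-row platform exports, dosage genotypes (0–6) and VCF import are
  out of scope (the one-row diploidized export and the simple dialect
  cover the intended inputs); no Hardy–Weinberg tests are provided, by
  design.
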