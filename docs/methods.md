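# Methods

This note documents the model, the numerical choices and the design
decisions behind `layersim`, and states precisely what the bundled
tests and the acceptance script do and do not demonstrate.

## Genome and inheritance

The simulated genome is 10 autosomes of 1 Morgan each carrying 50,000
biallelic SNPs at uniform-random map positions (both counts scale with
the global scale factor).  Only total map length and marker density
matter for the statistics studied here, so no real-array coordinates
are used.  Founder allele frequencies are drawn once per locus from
Uniform(0.05, 0.95); near-monomorphic loci are avoided because they
destabilize the scaling of the genomic relationship matrix.  Founder
haplotypes are Bernoulli draws per locus; there is no initial linkage
disequilibrium beyond what the 10-generation burn-in (random mating
among 200 males and 1,000 females, expanded to 800 males and 5,500
females in the final round) builds up.

Meiosis follows the Haldane model: per chromosome, a
Poisson(length-in-Morgan) number of crossovers at uniform positions,
no interference, no mutation, fair choice of the starting homologue,
autosomes only.  A zero-length chromosome is transmitted as an
unrecombined copy of one homologue.

Inbreeding is genomic identity-by-descent, computed exactly from
recombination breakpoints rather than on a marker grid: every founder
gamete carries one globally unique origin label, gametes store origin
as piecewise-constant segments on the genetic map, and F is the
genetic-length fraction of the genome where the paternal and maternal
labels agree.  Founders are unrelated by construction, so F is
measured relative to the founder generation.

## Traits and phenotypes

Nine traits with heritabilities (0.35, 0.10, 0.12, 0.20, 0.75, 0.50,
0.35, 0.26, 0.03), phenotypic SDs (22.7, 4.8, 7.0, 7.3, 3.8, 10.0,
7.0, 5.8, 0.2) in trait units, economic weights (3, 6, 6, 9, 18, −12,
7, 22, −3) per unit, and dense genetic/phenotypic correlation
matrices.  One shared set of 1,000 QTL drives all nine traits
(pleiotropy); per-QTL effect vectors are independent standard normals
mixed by the lower Cholesky factor of the genetic correlation matrix,
and each trait column is then rescaled so the realized additive
variance across the base population equals h²·σ²_P exactly (the
intercept centres the base mean at 0).  The QTL remain part of the
marker panel used in genomic evaluation.

Hens record at 51 and 72 weeks of age: laying performance 1–2 only at
51, laying performance 3–4 only at 72, the other five traits at both
ages.  Residual correlations are derived as
rE = (rP − rG·√(h²h²')) / √((1−h²)(1−h²')), projected to the nearest
positive semi-definite correlation matrix by eigenvalue clipping at
1e−8 with diagonal renormalization if needed (with the default tables
no repair is necessary; minimum eigenvalue ≈ 0.55).  Residuals of the
two recording ages are independent — no permanent environmental
effect — so repeated records of a trait share only the genetic part.
Mortality is an ordinary Gaussian trait; no birds are removed.
Cocks have no phenotypes.

## Breeding value estimation

Single-trait animal-model mixed model equations with known
heritabilities, an overall mean as the only fixed effect, repeated
records through a record-to-animal incidence matrix, and variance
ratio λ = (1−h²)/h² (phenotypes are simulated on the phenotypic-SD
scale, so no further adjustment is needed).  The per-trait EBVs are
combined by the selection index, not by a multivariate MME: with known
variance components and the index described below this is
well-defined and much cheaper.

Relationship structures:

* **A** — tabular method over the recorded pedigree.  The pedigree
  starts at the base breeding population; burn-in ancestry is treated
  as unknown (the conventional situation for a newly recorded
  nucleus), while IBD inbreeding still uses the true founder labels.
  Evaluations use A over the ancestor closure of the animals in the
  training window.
* **G** — VanRaden's first method: dosages centred by 2p and
  cross-products divided by 2Σp(1−p), allele frequencies computed
  from the currently genotyped set.  Before use, G is rescaled so its
  mean diagonal and mean off-diagonal match the pedigree block A₂₂,
  then blended 0.95·G + 0.05·A₂₂ to guarantee invertibility.
* **H⁻¹** — single-step: A⁻¹ plus the genotyped-block increment
  G_b⁻¹ − A₂₂⁻¹, with τ = ω = 1 and the same blending.

Systems are solved by dense symmetric factorization; at the problem
sizes this package targets (scale ≤ 0.2, a few thousand equations)
this is faster and more robust than an iterative solve.

The training window of every evaluation is all cohorts born within
three female generation intervals before the birth event — i.e. the
candidate cohorts plus the two (equal intervals) or five (male-only
shortening) preceding half-cycle cohorts.  This reproduces the
full-scale bookkeeping of 18,900 genotyped animals per evaluation when
every candidate is genotyped.  Records are visible only if their
recording week precedes the selection week; hens genotyped *after*
selection contribute genotypes from the following cycle.

## Selection, OCS and mating

Index weights b = (R·C·R + D)⁻¹·R·C·w with C the additive genetic
covariance matrix, w the economic weights, R = diag(√r²) and
D = diag((1−r²ᵢ)·Cᵢᵢ).  Reliabilities r² are squared correlations of
EBV and true breeding value within each candidate cohort (a
simulation shortcut replacing prediction-error variances; with
uncorrelated traits and equal reliabilities b reduces to w).
Phenotypic selection of hens applies the same formula with
reliabilities h² on the seven traits recorded at 51 weeks and scores
the cohort-mean-centred phenotype deviations; at the 31.5-week
interval hens are 19.5 weeks old at selection and have no phenotypes,
so phenotypic selection does not occur there.

Truncation keeps the top 60 of 800 males and 600 of 5,500 females
(ties broken by id).  With OCS, the quadratic program
min c'Kc, per-sex sums ½, 0 ≤ cᵢ ≤ 4/(2n_sex) — the minimum-kinship
("min.sKin") flavour with a cap preventing single-parent dominance —
reweights contributions *within* the truncation-selected set, using
the pedigree kinship A/2.  An alternative reading (OCS replacing
truncation over all candidates) exists; reweighting the selected set
was chosen because the study design reports identical selected-count
structures with and without OCS.  The QP is solved with SLSQP; a
uniform-contribution fallback guarantees the solution is never worse
than equal contributions.  Contributions become integer gamete quotas
by largest-remainder rounding.

Matings never pair full or half siblings.  Without OCS, sire/dam
pairs are drawn uniformly over the permissible pairs (equivalent to
uniform draws with rejection); with OCS, shuffled quota slots are
paired with swap repair.  If a heavily scaled-down run produces a
selected set in which *every* cross is a sib cross, the scheduler
relaxes the ban stepwise (full+half → full only → none) with a
warning rather than dead-locking; at scale ≥ 0.1 this is never
triggered by the default designs.

## Calendar

Cohorts are born at multiples of the cycle length; selection happens
at candidate age 51 weeks (63-week interval) or 19.5 weeks (31.5-week
interval), 12 weeks before the next birth.  The 12-week
selection-to-hatch lag is an assumption affecting only bookkeeping.
In the two-subpopulation design the two halves (400 male + 2,750
female candidates each) are offset by 31.5 weeks; each birth event
mates the subpopulation's own 51-week-old selected hens to 30
newly-selected 19.5-week-old males from the *other* subpopulation, so
the male generation interval is halved while hens keep the 63-week
cycle, and a subpopulation's female phenotypes can never inform the
selection of its own male candidates.  Training pools both
subpopulations.

At the 630-week horizon the equal-interval designs complete 10 (63
weeks) or 20 (31.5 weeks) generations.  ΔG and ΔF are changes in
cohort means from the generation born at week 63 (the second
generation of the short-interval designs, so all designs span the
same wall-clock window) to the last generation born by week 630; ΔG
is measured on the economic-weight index of *true* breeding values
and is exactly linear in the weights, so relative design contrasts
are weight-scale-free.  Accuracies are reported for the selection
event 12 weeks before the horizon (generation 9 of the long-interval
designs and the time-matched cycle of the others) as the correlation
of index-weighted true values with the index-weighted criterion over
the candidate cohort.  Welch's two-sample t-test compares replicates
between scenarios; two-dimensional boxplots use type-7 quantiles and
whiskers at mean ± 2.5 SD clipped to the data range.

## Scale factor, problem sizes, and what the tests show

A single global scale factor multiplies every cohort size and the
locus/QTL counts (rounded, minimum 2 per sex).  Replicates are
seeded from one master seed; scenarios can share the burn-in within a
replicate (common random numbers) to sharpen contrasts.  Runs are bit
reproducible given (seed, scenario, scale).

The bundled test suite and the acceptance script run at scales 0.05
and 0.1 (315/630 birds per generation instead of 6,300).  Small
populations drift roughly 10–20× faster than the commercial-size
program, which has two systematic consequences worth stating plainly:

* **Inbreeding levels are inflated** (ΔF of 0.3–0.5 over the horizon
  instead of a few percent), so ΔF is interpreted only *relatively*
  between designs sharing a scale.
* **Long-horizon gain contrasts compress or even invert** when a
  design's advantage rests on accuracy while its inbreeding cost is
  amplified.  The clearest case: selecting hens on pedigree EBVs
  instead of phenotypes raises accuracy and, at full population size,
  raises cumulative gain; at scale ≤ 0.1 the family co-selection
  destroys genetic variance so fast that the gain advantage
  disappears while the inbreeding penalty remains.  The tests
  therefore assert the contrasts that are robust to scale-down: the
  inbreeding penalty of pedigree selection of hens, the stepwise rise
  of male accuracy with genomic information (cycle-averaged to reduce
  single-cohort noise), the gain advantage of halving the male
  interval, and the OCS inbreeding reduction at near-constant gain —
  each as a comparison of replicate means over a fixed seed set.
  Full-size reproduction of the printed accuracies and percentage
  contrasts is an overnight batch, not part of the test suite.

One quantitative anchor is scale-free: the phenotypic index accuracy
of an unselected cohort, which has the closed form
b'C_m b / √(b'P_m b · b'Cb) (C, P restricted to the recorded traits);
the simulated base cohort reproduces it to within sampling error.

The synthetic genome emulates marker density, map length, pleiotropic
trait architecture and the recording calendar of a commercial layer
nucleus.  It does not emulate real-array LD structure, mutation, sex
chromosomes, genotype-by-environment interaction, dominance/epistasis,
inbreeding depression, or actual mortality culling — so passing tests
demonstrate correct implementation of the stated model and the
relative behaviour of the designs under it, not predictions for any
specific commercial line.

## Known limitations

* Dense linear algebra bounds practical population scale (roughly
  0.2–0.3 of commercial size on one CPU); full-scale runs want an
  iterative solver or APY-type approximations, which are out of scope.
* Reliabilities from TBV–EBV correlations are a simulation-only
  device; field implementations would use prediction error variances.
* The OCS variant maximizing gain under an inbreeding constraint is
  not implemented.
* Economic weights and phenotypic SDs are config-overridable; all
  scenario contrasts are invariant to the overall weight scale.
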