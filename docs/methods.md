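# Methods

## Model

A full-sib family is the progeny of one cross between two outbred
diploid parents.  At each biallelic locus, ordered along a chromosome
with the order taken as known, progeny *i* carries a latent inheritance
vector S_ij = (s¹_ij, s⁰_ij): one bit per parent, 0 if the allele
transmitted by that parent came from the parent's own maternal
chromosome and 1 if from its paternal chromosome.  The four states are
indexed 2·s¹ + s⁰.  Between adjacent loci the two bits evolve
independently (no crossover interference), each flipping with that
parent's interval recombination fraction; the initial distribution is
uniform (¼), i.e. the first locus descends from either grandparental
chromosome with equal probability.

The phase of the parents at locus *j* is the ordered parental genotype
pair (OPGP): the quadruple (Z11, Z10, Z01, Z00) of alleles on the
paternal parent's two chromosomes followed by the maternal parent's,
encoded as an integer 1–16.  The codes group into blocks by segregation
type (ST) — which parents are heterozygous: both-informative BI
(codes 1–4), paternal-informative PI_A/PI_B (5–6/7–8),
maternal-informative MI_A/MI_B (9–10/11–12), uninformative U (13–16),
with the A/B subscript naming the homozygous parent's allele and
crosses written maternal × paternal.  Given a state and an OPGP, the
progeny genotype is the concatenation of the selected parental alleles.

Two observation models share this chain:

* **genotype model** — genotypes observed without error: emission 1 if
  the state-implied genotype matches the call, else 0; missing calls
  emit 1 for every state.  A call impossible under the locus's ST
  (Mendelian error) makes an all-zero emission row; the package raises
  a dedicated error rather than returning −∞ silently.
* **sequencing model** — the observation is the reference-allele read
  count a out of total depth d.  Reads sample the true genotype's two
  alleles with replacement, and each read is miscalled with probability
  ε, giving binomial emissions: Binomial(d, 1−ε) for AA, Binomial(d, ½)
  for AB, Binomial(d, ε) for BB; d = 0 is missing (emission 1).  This
  single mechanism captures both allelic dropout (an AB covered by d
  reads shows one allele with probability 2^(1−d)) and miscalls, the
  two error types that otherwise inflate maps.

Progeny are conditionally independent given the OPGPs, so the
likelihood is a product over individuals and families of per-individual
forward sums.

## Estimation

Likelihoods use the forward recursion with per-locus renormalization
(log scale factors accumulated), since raw products underflow for maps
of realistic length.  Binomial coefficients are computed once per
dataset in log space.

Maximum likelihood is by EM.  The E-step is the scaled forward–backward
pass; the M-steps are closed form:

* each estimable recombination fraction ← (expected number of
  recombination events in its meioses, summed over progeny and
  families) / (number of meioses), clipped to the admissible interval —
  a constrained M-step, which preserves monotone ascent; with shared
  (non-sex-specific) fractions the paternal and maternal expectations
  are pooled over 2N meioses;
* ε ← Σ[w_AA(d−a) + w_BB·a] / Σ[(w_AA+w_BB)·d], where w_g is the
  posterior weight of genotype g obtained by collapsing state
  posteriors through the OPGP.  Heterozygote-weighted reads are
  excluded: they carry no information about ε since miscalls do not
  change the read distribution of an AB genotype.

Both updates maximize the expected complete-data log-likelihood, so the
observed log-likelihood never decreases; the test suite asserts this in
every fit.  Convergence is declared when the log-likelihood changes by
less than 1e−6 (default; max 1000 iterations).  Initial values are
r = 0.1 and ε = 0.005 unless supplied.  r̂ = 0 is a legitimate boundary
fixed point (cosegregating loci).  ε is allowed in [0, 1) although
values above 0.5 indicate a label-swap regime and are not meaningful.

**Estimable intervals.**  If one parent is homozygous at every locus up
to an interval, or at the locus just after it, in every family, that
parent's fraction for the interval cannot be estimated.  It is fixed at
0, which exactly reparametrizes the next estimable fraction as the
recombination probability to the previous locus segregating in that
parent (the uninformative locus's emission does not read that parent's
bit, so the zero-r transition composes transparently).  With shared
fractions an interval is excluded only if neither parent informs it.

**Haldane distances.**  d = −50·ln(1−2r) centimorgans per interval;
interval distances use the mean of the estimable parental fractions
(they coincide in the shared-r fits used for map totals).

**Two-point estimates.**  For a locus pair, the 2-locus likelihood with
a single shared r ∈ [0, ½] and fixed ε is maximized under each
admissible relative phase (flip / no flip per parent heterozygous at
both loci); the phase with the larger likelihood wins and the matrix of
pairwise r̂ serves as an ordering diagnostic (heatmaps).  For a BI–BI
pair under a tied r, which parent carries a single flip is not
identifiable — both assignments give identical likelihood and r̂ — so
ties are broken toward coupling, paternal before maternal.  The r̂
itself is unaffected.

## Phase inference

OPGPs are unknown in practice; STs are known from the parents'
genotypes.  Each family is phased independently: every locus is fixed
at the lowest-numbered OPGP of its ST block — the baseline quadruples
(A,B,A,B), (A,B,A,A), (A,B,B,B), (A,A,A,B), (B,B,A,B), (A,A,A,A) — and
the likelihood is maximized with the recombination fractions relaxed to
[0, 1].  A relaxed estimate above ½ means the default phase is wrong
relative to the previous locus segregating in that parent; walking the
loci left to right and toggling a per-parent flip parity at each such
interval yields the OPGP sequence.  The parity is carried across loci
where a parent is homozygous (the relaxed fraction is defined between
consecutive segregating loci).  Uninformative loci take their code
(13–16) from the parental genotype calls; they carry no phase content.
ε is estimated jointly during the relaxed fit unless fixed by the
caller.

Numerical choices made here, where the design was genuinely open:

* the relaxed fit starts at r = 0.5 (not the mapping default 0.1): the
  first M-step then reads each interval's flip direction from
  emission-only posteriors.  A no-flip-biased start can strand two
  adjacent intervals on a likelihood saddle near (½, ½) at mean depth
  ≈ 2, producing occasional phase errors that the symmetric start
  eliminates;
* the start is made slightly asymmetric between parents (0.49
  paternal / 0.51 maternal) because a family whose loci are *all* BI
  identifies phase only up to exchanging the two parents (swapping the
  state bits maps OPGP 2 ↔ 3 and r¹ ↔ r⁰ without changing the
  likelihood); the deterministic tilt lets EM leave that exchange
  saddle reproducibly.  Layouts mixing PI or MI loci anchor parent
  identity and are unaffected;
* a relaxed estimate within 0.01 of ½ carries no phase signal: the
  interval is flagged ambiguous, a warning is emitted, and the default
  (no flip) is retained.

Phase is only defined modulo the 4-fold symmetry of globally
relabelling either parent's chromosomes; comparisons (and the
phase-recovery statistics below) are made modulo that group.

## Filtering pipeline

Mirrors a typical genotyping-by-sequencing workflow, in order, each
removal audited by rule:

1. minor allele frequency < 0.05, computed from pooled progeny read
   fractions rather than genotype calls (read-fraction MAF avoids the
   depth bias of calls made from one or two reads);
2. ≥ 20% of progeny with zero depth;
3. ST inference from parental counts, requiring both parents' depth
   strictly above 5; heterozygous iff both alleles observed, no error
   correction (downstream, miscalls at this step are absorbed by the
   HMM's ε; loci with undeterminable ST are dropped);
4. a depth-adjusted segregation chi-square test at α = 0.05 (below);
5. binning of adjacent SNPs closer than 180 bp (so a read contributes
   at most one variant), keeping one seeded-random representative per
   bin — the seed is part of the configuration and logged.

**Depth-adjusted segregation test.**  Each progeny with d > 0 is
assigned a read-based call category (all-reference / mixed /
all-alternate).  Under the locus's ST, the expected probability of each
category for individual i mixes the Mendelian genotype frequencies with
the read model at depth d_i (ε defaults to 0 at this pre-estimation
stage), so a heterozygote's dropout mass is routed to the homozygous
categories instead of being counted as distortion.  Observed and
expected category counts are compared by Pearson chi-square over the
categories with positive expectation, with df = (number of such
categories) − 1; as d → ∞ the dropout categories vanish and the df
collapses to (Mendelian genotype classes) − 1.  We use this standard
Pearson df because fixing df at (genotype classes − 1) while observing
three categories makes low-depth null p-values anticonservative (~12%
rejection at α = 0.05 in simulation, vs ~5% with the standard df).
This adjustment is the package's own reconstruction of a low-depth
segregation test and is labelled as such.

## Simulator

Generates data exactly under the model, in the order the method runs:
inheritance bits (fair coin at locus 1, interval-specific flip
probabilities after), genotypes through the OPGP quadruples, depths
from a negative binomial with mean μ_d and dispersion δ sampled through
its gamma–Poisson mixture (variance μ + μ²/δ; δ defaults to 2, a
realistic overdispersion for pooled GBS libraries), and reads as a
two-stage draw — allele sampling with replacement, then per-read
miscalls — so the mechanism, not just the marginal binomial, matches
the model.  Parents are emitted at twice the progeny mean depth
(parents are typically sequenced repeatedly).  Datasets are written as
minimal VCF (per-sample AD counts) and tab-delimited matrices;
everything flows from one explicit seed and is bitwise reproducible.

The built-in 12-locus single-family study layout (3 BI, 4 PI, 5 MI,
with a PI locus between two MI loci at positions 4–6, several loci
phase-flipped from the block defaults) is **synthetic**: a
representative mixed-informativeness configuration chosen once as the
package default — in particular it stresses phasing and estimation
across stretches where one parent is uninformative — and it can be
overridden.
Study conditions are N = 100 progeny, r = 0.01 in both parents
(true map 11.11 cM), mean depths {2, 10, 20} × error rates
{0, 0.002, 0.01} for the depth × error grid, and a fixed sequencing
effort N·M·μ = 10,000 at ε = 0.002 with mean depths {1, 2, 3, 4, 6, 8,
12} (N from 833 down to 69) for the optimal-depth study, fitted with
the true phase.

What the simulator does **not** emulate: locus dropout/ascertainment,
depth correlation across loci or individuals, locus-specific or
allele-biased error rates, segregation distortion, and genotyping of
the parents beyond independent reads.  Passing tests therefore
demonstrate correctness and calibration *under the model's own
assumptions*, not robustness to the ways real libraries violate them.

## Statistical acceptance checks

The dedicated suite verifies, at 100 replicates per condition with a
fixed seed: forward likelihood ≡ brute-force path enumeration (rel.
1e−10); emission normalization; mean map length and per-interval mean
r̂ within 3 Monte-Carlo SE of truth across the full grid; mean ε̂
within 3 MC SE at depths 10/20 and |bias| < 0.002 at depth 2 (error
estimates at depth 2 are highly variable and slightly biased); 100%
phase recovery in all nine scenarios; the fixed-effort MSE-minimizing
depth in {3, 4}; and monotone EM ascent everywhere.  Replicate counts
(100 for the grid, 250 for the fixed-effort design) keep the suite in
the minutes range; the
fixed-effort MSE curve has a shallow valley around depths 2–4, so its
argmin needs the larger replicate count to be resolved above the
Monte-Carlo noise.

A calibration caveat at mean depth 2: the maximum-likelihood estimates
carry small finite-sample biases of order ±0.002 per interval (end
intervals pushed up by the r ≥ 0 boundary, some interior intervals
informed by a single meiosis pushed down).  With 108 separate 3-SE
comparisons in the grid check, an exceedance at one interval for one
seed stream is possible without any defect; independent seed streams
localize such events to sampling noise (deterministic causes are
excluded by the exact brute-force agreement and the
tolerance-insensitivity of the EM fixed point).

## Known limitations

* Locus order is assumed known; no ordering/optimization is provided
  (two-point heatmaps are diagnostics only).
* No standard errors or confidence intervals for r̂ and ε̂.
* One global ε: constant across loci, individuals, and alleles.
* Autosomal biallelic loci in diploids only; no allosomal or
  multiallelic support.
* Phase inference is per family; no joint multi-family phase
  likelihood and no use of grandparental genotypes.
* The EM fallback without numba is ~5× slower; results are identical.
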