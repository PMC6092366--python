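# Methods

This note documents the models implemented in `palettefit`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices made
where the design was genuinely open.

## 1. The palette-fit model

### Copying palettes

Under an all-vs-all chromosome painting, each individual (recipient) is
modelled as an imperfect mosaic of all other individuals' haplotypes
(donors). The *palette* of a recipient is the vector of expected genome
fractions copied from each donor group; stacking recipients gives the
N×P palette matrix **C** (rows sum to 1).

### Ancestral palettes by least squares

Given the N×K admixture-proportion matrix **A**, the admixture model
implies that palettes of admixed individuals are mixtures of K ancestral
palettes **X** (K×P):

    A X = C,    X̂ = argmin ‖A X − C‖²_F = (AᵀA)⁻¹ AᵀC.

We solve by SVD-based least squares rather than forming (AᵀA)⁻¹
explicitly; the solution is identical but conditioning is better. Rank
is decided at a relative singular-value tolerance of 1e-10; a
rank-deficient design raises an error (the components are collinear —
this normally means K is too large) rather than returning one of many
minimizers. The condition number of AᵀA is reported with every fit.

Properties that follow algebraically, and that the test suite asserts:

- *exact recovery*: for full-column-rank A, fit(A, A·X_true) returns
  X_true (to 1e-10);
- *residual row conservation*: if A and C are row-stochastic and A has
  full column rank, predicted rows sum to 1 and residual rows to 0
  (1_N lies in the column span of A);
- *projection idempotence*: refitting on the predictions returns the
  same X̂.

Negative entries in X̂ are legal output and are flagged, never clipped:
they are themselves evidence that the admixture description fails. An
opt-in non-negative fit (`fit_ancestral_palettes_constrained`) solves
each palette column as an independent NNLS problem; it coincides with
the unconstrained solution whenever that is already non-negative.

### Residual diagnostics

`residual_summary` reports per-group mean residuals per donor column,
each group's mean self-column residual, and a *block score*: on the G×P
group-mean residual matrix, mean |diagonal entry| (each group against
its own donor column) minus mean |off-diagonal entry|. The score is
computed on group means rather than per-individual residuals because
self-copying is intrinsically noisier at the individual level
(finite-panel sampling); averaging within groups isolates systematic
structure from heteroskedastic noise. Near-zero scores indicate an
adequate fit; positive scores indicate unmodelled drift or ghost
ancestry.

### Drift correction

Recent group-specific drift inflates self-copying uniformly within a
group, which no admixture mixture can express. The correction refits
**X** with each individual's own-group palette entry masked out of the
objective: the column for donor group *g* is fitted using only
individuals not labelled *g*. Corrected palettes substitute the masked
prediction for the self-group entry and renormalize rows; the positive
part of (observed − predicted) self-copying is returned as the
unexplained excess. The masked-refit definition is this package's own;
analytically, injecting an excess δ into drift-free palettes (rows
renormalized) yields recovered excess δ/(1+δ) exactly and restores the
original palettes, which the tests verify. A column is unidentifiable
if masking its group makes the design rank deficient; this raises an
error naming the group. The more stringent alternative — excluding
same-label donors from the painting panel altogether — is available as
`paint_all(..., exclude_same_label=True)`.

## 2. The painting engine

The linked model is a Li–Stephens haplotype-copying HMM with the
uniform-prior jump simplification: hidden state = donor haplotype
(uniform initial distribution); between adjacent sites at genetic
distance g cM the chain stays with probability exp(−n·g) and otherwise
jumps to a uniformly drawn donor; emissions are 1−M on allele match and
M on mismatch. Defaults M = 0.01, n = 1 per cM. These are sensible
copying-model defaults, not claimed to equal any external program's;
both are overridable.

Forward–backward is run per chromosome with per-site scaling (no
underflow for any realistic L). Posteriors aggregate into:

- *genome fractions*: site l carries weight (g_{l−1}+g_l)/2, end sites
  the half-interval toward their single neighbour (an unbiased tiling of
  the genetic map); fractions sum to 1 per recipient haplotype;
- *chunk counts*: expected entries into each donor state plus the
  initial-state indicator, per chromosome.

Correctness is established against an independent exhaustive-path
oracle (all D^L donor paths, D ≤ 4, L ≤ 6) to 1e-10, for both
aggregations.

The unlinked model treats sites independently (posterior ∝ emission)
and reports expected matching counts; it is the g→∞ limit of the linked
model, which the tests check. Linked palettes depend on site order
through the map; unlinked palettes do not.

`paint_all` excludes both haplotypes of the recipient individual from
the panel by default (`self_exclusion="individual"`), mirroring
all-vs-all practice and avoiding trivial self-copying; diploid
recipients average their two haplotypes, donor haplotypes aggregate by
group label, rows are normalized. Unphased genotypes are refused in
linked mode rather than approximated.

## 3. The scenario simulator

Three demographies, chosen because they produce nearly indistinguishable
admixture bar plots:

- **recent_admixture** — P2 genomes are explicit mosaics of P1/P3/P4
  donor chromosomes, mixed 50/35/15 by an instantaneous event λ = 15
  generations ago;
- **ghost_admixture** — P2 receives ~50% ancestry from an unsampled
  population most closely related to P3, by continuous migration
  (per-generation rate set so the cumulative fraction over the window
  equals the target);
- **recent_bottleneck** — P1 splits from P2 recently (20 generations)
  and immediately undergoes a strong bottleneck. Source texts differ on
  which sister population is bottlenecked; here it is P1 by default
  (matching the residual narrative the scenarios illustrate) and
  configurable via `bottleneck_population`.

### Mixing algorithm and tract bookkeeping

Each admixed chromosome is tiled left to right: draw x ~
Exponential(rate λ/100 per cM), copy the next x cM from a donor
chromosome whose source population is drawn from the mixing proportions,
repeat until the chromosome is covered. Donor haplotypes are sampled
*without replacement within a chromosome* (reuse would create artificial
identical-by-descent tracts between the recipient's segments); a source
whose pool empties raises an explicit exhaustion error. Donors come
from "excess" individuals — simulated but not included in the analysis
sample — with 20 donor individuals per source and 35 admixed diploids
(70 haploid genomes of 20 chromosomes) by default. Every copied segment
is recorded in a `TractMap` (half-open cM intervals tiling each
chromosome exactly, validated to 1e-9).

Two tract-length estimands must not be conflated: the *draw law* and
the *tiled segments*. Segments abutting a chromosome end are
right-censored draws, so a naive 1/mean over segments is biased upward
(~7% at 100 cM chromosomes). `estimate_tract_rate` therefore uses the
censored exponential MLE — (#complete tracts)/(total length) — which is
unbiased for λ/100 at any chromosome length, and `TractMap` preserves
the raw draws (`raw_draw_lengths`) for distributional tests.

### Divergence backend

Population structure is produced by a discrete-generation Wright–Fisher
simulator: random mating; Haldane-map recombination (per-interval
switch probability ½(1−e^{−2d/100}), independent assortment across
chromosomes); symmetric per-site mutation; founder haplotypes drawn in
linkage equilibrium from shared ancestral frequencies Uniform(0.1, 0.9).
Populations split by copying the parent pool and drifting independently;
a bottleneck is a reduced diploid size over its window, with the
present-day sample drawn as one final offspring generation when the
census is smaller than the sample. A uniform 1 cM/Mb map converts
genetic to physical coordinates.

Sizes are scaled down for desk-scale running (default diploid N = 100
per population). Scaling sizes without scaling mutation would fix all
loci over deep histories, so the per-site mutation rate default (1e-3
per transmission at N = 100, i.e. θ = 4Nμ = 0.4) follows the standard
rescaling argument that keeps population-scaled diversity of order one.
Consequently the nominal deep split times (e.g. 1700 generations for
the ghost scenario's P1/P2 split) correspond to effectively complete
drift at N = 100; the desk-scale configuration used by the analyses
(`desk_scenario_config`) additionally rescales the deep split times
(P1/P2 at 80 generations, ghost–P3 at 40, with N = 50) so that
*relative* relatedness — P1 closest to P2, ghost closest to P3 —
is preserved in coalescent units.

What the generator does *not* emulate: mutation at sequence level (sites
are pre-ascertained biallelic SNPs), realistic human recombination maps,
phasing error, genotyping error or missingness, and the full 13-
population world model behind the original scenarios (outgroups here
are generic). Passing tests therefore demonstrate the method's
behaviour under its own assumptions — clean phased haplotypes and known
truth — not robustness to real-data artefacts.

### Determinism

One master seed; divergence and mixing draw from deterministically
spawned child streams. Identical configurations produce bit-identical
datasets, which the tests assert, and the CLI writes a manifest
sufficient to reproduce a run byte for byte.

## 4. Supporting estimators

- **LD pruning** — greedy left-to-right scan; a site is dropped if its
  r² (Pearson, on 0/1/2 dosages) with any already-retained site within
  250 kb (closed interval) exceeds 0.1; the earlier site of an offending
  pair is kept (deterministic and order-stable). Monomorphic sites have
  undefined r²: they are retained and never trigger removal. The
  retained set provably contains no offending pair, verified
  exhaustively in tests; pruning is idempotent.
- **Supervised admixture proportions** — EM for the binomial admixture
  likelihood ∏_l Bin(g_l; 2, Σ_k q_k f_kl) with fixed source
  frequencies (clamped to [1e-6, 1−1e-6]); allele copies are treated as
  independent mixture draws. Convergence at max|Δq| < 1e-7 or 2000
  iterations (a flag reports non-convergence); the log-likelihood is
  non-decreasing across iterations and the iterate never leaves the
  simplex. This estimator stands in for a full unsupervised analysis,
  whose output the method treats as *input*.
- **Coancestry probability** — Σ_k q1_k·q2_k, the chance two
  individuals draw the same ancestral source at a locus; symmetric,
  ≤ 1 with equality only at simplex vertices.

## 5. Problem sizes used by tests and acceptance runs

Tract-based quantities use the full default mixing configuration
(35 diploids × 20 chromosomes × 100 cM, λ = 15, 50/35/15, 20 donors per
source; ≥10⁴ tracts pooled for rate estimation). Painting-based
scenario analyses use the desk-scale configuration: 4 populations,
diploid N = 50, analysis samples 12/10/14/10, 10 admixed diploids, 10
donors per source, 2 chromosomes × 60 cM × 180 SNPs, supervised Q
against P1/P3/P4 frequencies, K = 3, P = 4. At these sizes the full
suite runs in about half a minute while reproducing the qualitative
contrast between scenarios on every seed tried (block score ≈ 0 for
recent admixture; ≈ +0.06–0.08 with strongly positive P2 self-residuals
for ghost and bottleneck).

## 6. Known limitations

- The drift correction is this package's definition (masked refit); the
  original procedure it is inspired by is not specified to numerical
  precision in the literature it follows.
- The block score compares each group against the palette column of the
  same name; without labels (or with labels that do not match donor
  groups) the fit still runs but group diagnostics are unavailable.
- The painting transition kernel is the uniform-jump simplification;
  donor-specific copying priors and unequal panel weighting are not
  implemented.
- Residuals are reported as palette-fraction differences (dimensionless,
  per entry); no significance calibration is built in beyond the
  permutation comparison used in the tests.
- The supervised Q estimator assumes the source frequencies are known
  without error; with small reference panels its estimates inherit that
  sampling noise.
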