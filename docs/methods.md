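# Methods

This note documents the models, parameter choices and numerical decisions
behind `actnet`, and what the synthetic benchmarks do and do not demonstrate.

## Longitudinal model

Each feature (protein or transcript) is modeled across both arms jointly:

    y = (b0_C + b0_TvsC·D) + (b1_C + b1_TvsC·D)·t + (b2_C + b2_TvsC·D)·t² + ε,

with D = 1 for treated samples, t in raw hours, ε ~ N(0, σ²). The design is
7 time points (2, 8, 24, 72, 168, 240, 336 h) × 3 replicates × 2 conditions.
Numerically the solver column-scales the Vandermonde-like design and uses a
QR factorization; estimates are rescaled back, so the reported coefficients
and their two-sided t-test p-values live in the raw-hour parameterization
(raw powers of t up to ~1.1·10⁵ would otherwise make the normal equations
ill-conditioned). The treatment-effect p-value is the F-test of the full
model against the control-shape-only reduction (all three TvsC terms zero).
The per-coefficient p-values feed the network scoring; they come from full-
model t-tests rather than a stepwise per-coefficient selection — a
deliberate simplification of the two-step selection some longitudinal
packages perform, chosen because the downstream score sums all three
coefficients' p-values regardless of which survive a stepwise pass.

Decision rules: a feature is *dynamic* when BH q(global p) ≤ 0.05 within its
(drug, dose, layer) stratum, R² ≥ 0.7, and ≥ 10 observations were used.
Missing values are dropped listwise; a feature with fewer than 6 usable
observations is marked failed and excluded (not an exception, so one bad
feature cannot abort a 10⁴-feature stratum). Constant features get R² = 0
and global p = 1 by definition. All p-values are floored at 1e−300 so that
−log₁₀ p stays finite. Whether proteome and transcriptome should share one
BH family is not determined by the design; each stratum is corrected
separately here, which is the more conservative bookkeeping when layers
have very different feature counts.

Proteome normalization shifts each control sample so its median over the
proteins present in *all* controls equals the median of those medians, then,
per time point, shifts each treated sample onto the median-of-medians of
the (normalized) controls computed on the proteins common to both groups at
that time point. Features absent from the reference group are still carried
through (shifted with their sample).

## Node scoring and propagation

Scores are Sᵢ = −Σⱼ log₁₀ pⱼ for dynamic features, 0 otherwise, and layers
integrate by summation (a protein measured in only one layer keeps that
layer's score). The walk matrix is column-stochastic (W[i,j] = 1/deg(j) on
edges); isolated nodes are removed first. The diffusion kernel
F = β(I − (1−β)W)⁻¹ conserves heat exactly (1ᵀF = 1ᵀ), so column j of
E = F·diag(S) redistributes exactly score Sⱼ. β defaults to 0.4, the value
commonly recommended for protein interaction networks in restart-walk
propagation; it controls locality (heat at graph distance d from the only
source decays at least like (1−β)^d). The linear system is solved densely
up to 2000 nodes and by sparse LU above; the two paths agree to < 1e−8 and
are cross-checked in the tests.

Subnetworks: for a threshold δ, keep directed edges j→i where E[i,j] > δ,
take strongly connected components with ≥ 3 nodes (the component floor is a
package default; 2-node components are almost always reciprocal noise).
Four δ candidates are the 0.95/0.99/0.995/0.999 quantiles of the positive
off-diagonal heat — the procedure that selects among four subnetworks
always takes the minimal δ, so the quantile grid only needs to bracket the
interesting range from "permissive" to "strict". Because raising δ can only
remove edges, the SCC partition refines and retained node sets shrink
weakly; this monotonicity is asserted on random instances. When a drug has
no dynamic features at all, E has no positive off-diagonal and the
subnetwork is empty (logged, not an error).

Consensus: undirect each drug's edges; keep nodes occurring in ≥ 2 of the
subnetworks, and edges occurring in ≥ 2 whose endpoints are both kept. Both
the node and the edge occurrence rule are enforced — "nodes and their
interactions" — which is the stricter of the two readings of the rule.

## Set statistics

Over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k) with BH across the collection and fold enrichment (k/n)/(K/N).
The background universe is a mandatory explicit argument: in the pipeline
it defaults to the interactome's node set (configurable to the measured
subset), because enrichment q-values can shift by orders of magnitude with
the background and silently defaulting would hide the single most
consequential analysis choice.

## Metagene methylation profile

Genes are mapped to 75 bins: 20 equal bins over the 5 kb promoter, one TSS
bin, 4 bins over the first kilobase of the body, 50 over the remainder. The
single TSS bin has no canonical width; here it covers the first 200 bp of
the gene and the 4 early-body bins cover the remaining 800 bp of the first
kilobase, so the 75 bins tile the locus exactly without overlap. Window
percentages contribute to bins by bp-weighted coverage; per gene the profile
is averaged over time points, then over the genes of each expression class
(six near-equal quantile classes of median abundance, ties broken by gene
id so that any monotone transformation of abundances gives identical
classes). Genes shorter than 1 kb past the TSS cannot host the layout and
are skipped with a logged count. Coordinates are 0-based half-open
throughout; all synthetic genes are on the + strand, so strand mirroring is
not exercised.

TFBS-in-DMR enrichment is the observed site count over the bp-fraction
expectation n·(DMR bp / universe bp); a site falls in a DMR when its
midpoint does (sites are counted, not bp; any-overlap is available via
`overlap_rule="any"`). The permutation p re-places midpoints uniformly in
the universe (enrichment-sided, add-one corrected). Whether the expectation
should be bp-fraction or region-count based is ambiguous; bp-fraction is
implemented because it is exact under uniform placement, and the generator
plants sites by the inverse of the same rule, making the estimator unbiased
(checked over 200 draws).

## Mitochondrial model

The 181-protein biophysical model this analysis step would normally consume
is not reimplemented; instead a reduced 11-reaction mass-action scheme
preserves the three-subsystem structure (TCA: R0–R1; ETC: R2–R6, R10; ROS:
R7–R9) with the membrane potential ΔΨ as an explicit state (see the module
docstring for the full scheme). Three modeling devices keep the reduced
scheme bounded and responsive:

* substrate supply saturates as S accumulates (v₀ = k₀(1 − S/S_max)), so
  slowing TCA/ETC rate constants genuinely lowers throughput instead of
  only shifting intermediate pools;
* proton-pumping rates carry e^(−ΔΨ/ψ₀) damping and ROS production
  e^(+ΔΨ/ψ₁) growth (ψ₀ = ψ₁ = 400 mV), the usual thermodynamic back-
  pressure shape;
* ATP synthase flux saturates in ΔΨ with K_ψ = 200 mV.

Defaults (rate constants in the module) give a stable positive steady state
with ATP/A_tot ≈ 0.76 and ΔΨ ≈ 180 mV, independent of the starting point
within the positive orthant; NAD(H), Q(H₂), cytochrome c and adenine-
nucleotide totals are conserved exactly by construction and to ≤ 1e−8 by
the integrator. Integration uses stiff BDF with rtol 1e−9/atol 1e−12 in
chunks, declaring steady state when every |dy/dt|/|y| < 1e−9; the outer cap
is 50 000 × 60 s of simulated time. Readout precision sets a noise floor of
roughly 1e−4 on the 1%-perturbation sensitivities, which is why the local
sensitivity re-anchors its reference through the same warm-start protocol
as the perturbed runs.

Drug action multiplies rate constants by the geometric mean of the mapped
proteins' fold changes (arithmetic mean available); geometric aggregation
is the natural choice for multiplicative abundance ratios. Exposure series
apply each day's fold changes, re-settle, and report ATP and ΔΨ relative to
day 0. The macroscopic sensitivity re-solves with all drug scalings except
one reaction held at reference and reports ATP(all-but-r) − ATP(all),
ranked by magnitude next to the applied fold change — large abundance
changes on low-impact reactions (e.g. peroxide clearance) rank below modest
changes on critical ones (substrate oxidation, synthase), which is the
comparison the rank-vs-fold-change table exists to expose.

## Synthetic data: what it emulates and what it does not

The generators reproduce the study design: 7 time points over 14 days,
3 replicates, treated vs time-matched control, 4 drugs × doses, proteome +
transcriptome, missing proteome values, a 15-patient cohort (7 exposed, 8
control). Defaults chosen where the design leaves them open, fixed once:

* terminal treatment effect 2.0 log2 units (a 4-fold change, typical of a
  strong proteomic drug response) reached as a linear ramp over 336 h, sign
  random per feature; with noise SD 0.25 log2 units this is an 8-SD
  terminal effect — comfortably inside the "strong effect" regime (≥ 5 SD)
  used for recovery benchmarks;
* proteome missingness 0.1, completely at random. Real LC–MS missingness is
  partly intensity-dependent; MCAR is used because the upstream mechanism
  is not identified, so recovery results say nothing about
  informative-missingness robustness;
* baseline profiles are smooth per-feature quadratics (drift SD 0.3 log2
  units over the course) — nontrivial but not confounded with the effect
  shape;
* cohort LVEF ~ N(35, 8) %, clipped to [5, 80]; signal proteins are drawn
  jointly bivariate-normal with LVEF using the *population* standardization
  so that planted correlations are exact in distribution and Fisher-z
  intervals attain nominal coverage.

Passing benchmarks on these data demonstrates the statistical machinery
(calibration of the F-test and BH thresholds, heat conservation, module
recovery under clean planted signal). They do not demonstrate robustness to
batch effects, heteroscedastic or intensity-dependent noise, network
mis-specification, or modules that only partially respond.

## Problem sizes

The default benchmark sizes — 300-node networks with one 15-node module for
recovery (10 seeds), 2000 features for null calibration, 5000 sites for the
odds-ratio check, 300 cohorts for correlation coverage — are chosen so the
whole suite runs in about a minute while keeping Monte-Carlo error well
below the decision margins (e.g. binomial SD of the null call rate at
n = 2000 is 0.005 against a 0.02 margin).

## Known limitations

* The per-coefficient p-values are full-model t-tests, not a stepwise
  selection; features whose treatment effect is purely quadratic get the
  same three-term score as a stepwise procedure would, but individual
  p-values can differ.
* The δ grid is quantile-derived from each drug's own heat matrix, so δ is
  not comparable across drugs in absolute terms; only the selection rule
  (minimal of four) is shared.
* The reduced mitochondrial scheme is property-faithful (conservation,
  stability, subsystem structure, qualitative dose ordering), not
  curve-faithful: absolute ATP/ΔΨ trajectories are not comparable to any
  specific full-scale model.
* Strand handling in the metagene profile is implemented for + strand only,
  matching the synthetic chromosome.
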