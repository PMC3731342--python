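# Methods

This note documents the models, conventions and numerical choices behind
caprachron, in the package's own terms.

## Codon alignment construction

Protein-coding genes are supplied as column intervals (0-based, half-open)
on a nucleotide concatenation. Per gene, columns listed in inter-gene
overlap exclusions are removed from *both* overlapping genes, the remainder
must be divisible by 3, and the first (initiation) and last (termination)
codons are stripped. Cells are codon states over the 60 sense codons of the
vertebrate mitochondrial code (table 2: TAA/TAG/AGA/AGG stop, ATA = Met,
TGA = Trp); any N or gap in a triplet voids the whole codon (codon models
need complete states). An internal stop codon aborts construction and names
the sequence, gene and codon index: in mitochondrial data this is the
signature of a nuclear pseudogene (numt) or a frameshifted assembly, not a
biological state.

Two data sets are derived from one matrix: the *smaller* set drops
sequences containing missing codons, then any residual incomplete column;
the *larger* set keeps missing data (treated as fully ambiguous states in
likelihoods). Identical haplotypes are collapsed to one representative in
both, with the mapping recorded.

## Distances, NJ, haplogroup assignment

Pairwise distances use the gamma-corrected Kimura two-parameter form

    d = (α/2)[(1 − 2P − Q)^(−1/α) − 1] + (α/4)[(1 − 2Q)^(−1/α) − 1],

with transition/transversion proportions P, Q over pairwise-complete
columns. The control-region shape default is α = 0.22 (an externally
estimated value for the fast-evolving D-loop); saturated pairs (non-positive
power argument) are flagged undefined rather than silently clamped.

Neighbor joining is the standard agglomerative algorithm with two
determinism rules: ties in the Q criterion resolve to the lexicographically
smallest pair of cluster ids (a cluster's id is its smallest member leaf
name), and negative branch lengths are clamped to zero with the deficit
moved to the sister branch (the pair sum d_ij is preserved). Bootstrap
supports are percentages of column-resampled NJ replicates containing each
original bipartition.

Queries are assigned to haplogroups on a joint NJ tree with labelled
reference haplotypes: each query takes the label of the smallest clade
containing it and at least one reference (majority vote with a warning if
references conflict; `unassigned` on an unresolvable tie).

## Branch stratification

On the outgroup-rooted tree (root placed at the midpoint of the outgroup
stem; any point on that branch gives the same ingroup categorization), with
every haplogroup required to be monophyletic:

* **shallow** — branches strictly inside a haplogroup's MRCA subtree,
  tagged with the haplogroup;
* **deep** — remaining ingroup branches between the all-ingroup MRCA and
  the haplogroup MRCAs, *including* each haplogroup's stem. In the
  four-haplogroup layout (C,(B,(D,A))) this yields exactly six deep
  branches: the four stems a–d plus the A+D ("x") and A+D+B ("y") backbone
  branches;
* **inter-species** — branches connecting the outgroup to the ingroup MRCA
  (plus outgroup-internal branches when the outgroup has several leaves).

A single-member haplogroup has one pendant branch that is simultaneously
its stem and its terminal branch; the package classifies it as shallow
(the terminal-branch reading). This convention is irrelevant for the study
topology, where every haplogroup has at least two members.

## Branch-ω codon model

The substitution process is a GY94-style reversible 60-state codon model:
single-nucleotide steps only, target-codon frequency π_j, transition factor
κ, non-synonymous factor ω. ω is shared within branch *classes*; a model
specification is a partition of the class keys (`interspecies`,
`deep:a`…`deep:y`, `shallow:A`…`shallow:D`) into groups sharing one free ω.
The shallow ladder is 1ω, 2ω (inter- vs intra-species), 3ω (… ≠ deep ≠
shallow), 4ω1 (A apart), 4ω2 (B apart), 4ω3 (A=B vs C=D), 5ω, 6ω; the deep
ladder is 3ω, 4ω1…4ω6 (each deep branch singled out), 5ω (b and y apart).
Each ladder row reports lnL, #p, AIC = −2lnL + 2#p (an exact identity on
the results object) and the χ² LRT against its designated nested partner.

Conventions:

* **Frequencies** — F3×4 by default (position-specific nucleotide
  frequencies, restricted to sense codons and renormalized), selectable
  F61/equal. Frequencies are empirical, not ML-optimized.
* **Scaling** — each class generator is normalized to one expected
  substitution per codon per unit branch length *under that class's own ω*,
  so branch lengths read as substitutions per codon regardless of class.
  This matches the branch-model convention of mainstream codon-model
  software; it affects branch-length interpretation, not likelihood ranks.
* **Parameter count** — #p = branch lengths + κ + free ω's + frequency
  parameters (9 for F3×4, 59 for F61). Published ladders of this design
  count 59-frequency bookkeeping; only the deltas (one per extra ω) matter
  for the LRTs, and those are invariant to the choice.
* **ω bounds** — [1e-4, 999]; fits against data generated with vanishing ω
  report the 1e-4 boundary.

Likelihood is Felsenstein pruning over compressed site patterns with
per-node rescaling. Transition matrices come from the eigendecomposition of
the symmetrized generator (B = D^{1/2} Q D^{−1/2}, D = diag π), so
P(t) = X e^{Λt} Y with X, Y cached per class. Gradients are analytic:
branch-length derivatives are diagonal in the eigenbasis
(∂P/∂t = X Λe^{Λt} Y), and κ/ω derivatives use first-order perturbation of
the matrix exponential (the divided-difference kernel
G_ij = (e^{λ_i t} − e^{λ_j t})/(λ_i − λ_j), with the t e^{λt} limit on
near-degenerate eigenvalue pairs). Derivative ratios are computed per
branch so scaling constants cancel.

Optimization is L-BFGS-B over log-transformed branch lengths, κ and ω
(multiplicative parameters; log-scale markedly improves conditioning), with
multi-start over {1.0, 0.5, 0.1}×ω₀ (short exploratory stage, then the best
start polished; convergence tolerance |ΔlnL| ≤ 1e-6). Two robustness
guards: implausible initial branch-length totals (e.g. a tree whose lengths
are in years) are renormalized to a generic starting point, and the
gradient norm is capped (near-zero branches can produce almost
discontinuous derivatives that break the line search). Ladder runs
warm-start each model from its comparison partner's branch lengths, κ and
mean ω.

## McDonald–Kreitman and Tajima's D

Only codon columns complete in every used sequence of both groups enter a
pair's table (this is why "codons analyzed" differs across pairs when
different individuals lack different genes). A column is *fixed* when both
groups are internally monomorphic with disjoint alleles, *polymorphic* when
either group varies internally. Each single-nucleotide change is classified
synonymous/non-synonymous under the mitochondrial code; multi-position
codon pairs are decomposed change-by-change only when every mutational
order gives the same classification without crossing a stop codon, and are
otherwise excluded and counted. Within a polymorphic group, changes are
counted star-wise against a deterministic reference allele (smallest codon
index).

Statistics: NI = (Pn/Ps)/(Dn/Ds) and α = 1 − NI (flagged undefined on zero
denominators, never NaN); Fisher's two-tailed exact p by the
sum-of-point-probabilities convention (verified against exhaustive
enumeration); the likelihood-ratio G statistic with Williams' correction
q = 1 + (N/r₁ + N/r₂ − 1)(N/c₁ + N/c₂ − 1)/(6N). The "Yates" variant is
computed as G on counts shifted 0.5 toward expectation; continuity-corrected
G has no single standard form, so this column is convention-sensitive and
is reported as such rather than claimed to match any particular published
variant.

Tajima's D uses the canonical 1989 constants on gap-free columns, with π
the mean number of pairwise differences; D is undefined at S = 0.

## Strict-clock dating

On a codon-position view (default 3rd positions, where most change is
synonymous and hence closest to neutral), a GTR+Γ₄ model (empirical base
frequencies; discrete-gamma category means; exchangeabilities free with
s_GT = 1) is fitted either with free branch lengths or clock-constrained
node heights (root height plus per-node height fractions in (0,1), the
standard multiplicative parameterization). The clock LRT has
df = (2n − 3) − (n − 1) = n − 2. Because the clock solution is a feasible
point of the free model, the free fit is additionally warm-started from it,
guaranteeing lnL_free ≥ lnL_clock up to optimizer tolerance; the free fit
is also multi-started over branch-length rescalings.

Dating rescales heights so one calibrated node (the goat/markhor split,
3.4 Ma, by default — taken as an external constant) matches its age
exactly; the per-site per-year rate is height/age. Standard errors come
from the observed information (central-difference Hessian of the height
likelihood at the MLE, other parameters fixed; eigenvalue-floored before
inversion), propagated through the calibration rescaling by the delta
method; the calibrated node has SE 0 by construction. Node ages are exactly
equivariant in the calibration age. The helper
`rate_from_calibrated_node` converts any fitted node height plus an assumed
age into a rate (the D-loop fast-clock construction: height ≈ 0.0248 at an
assumed 91 ka MRCA gives ≈ 2.7e-7 subs/site/yr).

## Synthetic data generator

`simgen` draws within-haplogroup genealogies from a Kingman coalescent with
backward-exponential population decline N(t) = N₀e^{−rt} (exact inversion
sampling of the inhomogeneous waiting times; strong growth yields the
star-like genealogies characteristic of expansion), grafts the group MRCAs
onto a fixed deep topology at configured split times, and attaches the
outgroup at the calibration depth. All node times are years, converted via
an explicit generation time (default 2.5 y, sexual maturity at 2–3 y).
Defaults mirror the study card: samples A:16, B:13, C:2, D:3 plus one
outgroup; splits C 840 ka, B vs A+D 350 ka, A vs D 200 ka (the A/D split is
not published; 200 ka sits between the A TMRCA and the B split); haplogroup
TMRCAs pinned by rescaling to 90.95/41.93/77.35/32.3 ka; within-group
N₀ = 1e5 with growth 5e-4 per generation (tuning choices recorded in the
parameter card, not estimates).

Sequences evolve by sampling states down the tree from spectral
P = e^{Qt}; codon mode uses the branch-category ω map (defaults are the
study's per-branch point estimates) and cannot emit stop codons because the
state space is the 60 sense codons. The overall coding rate default is
1.2e-8 subs/site/yr (≈8% goat–markhor coding divergence at 3.4 Ma; codon
branch lengths are 3 × rate × years); the D-loop-like fragment uses
K80+Γ(0.22) at 2.73e-7 subs/site/yr.

What the generator does *not* emulate: recombination (absent in mtDNA),
migration or incomplete lineage sorting between haplogroups (group
monophyly is imposed), selection acting on the genealogy shape (ω only
rescales the mutation process), rate variation among genes, sequencing
error and numts. Passing recovery tests therefore demonstrates estimator
correctness under the model's own assumptions, not robustness to real-data
artifacts.

## Test problem sizes and known limitations

The suite exercises full study scale where the claim requires it (3,500
codons, 30–35 taxa for the ω-recovery and stratification checks) and
reduced sizes (300–2,000 codons, 12–20 taxa) for pipeline smoke tests,
ladder behavior and clock properties; exhaustive-enumeration oracles run on
≤3-leaf, ≤6-codon instances where they are exact.

Known limitations:

* Branch-category ω estimates from a single study-sized data set carry a
  per-seed coefficient of variation of roughly 20–30% — the deep branches
  hold only a few hundred substitutions, a few dozen of them
  non-synonymous, and no estimator can beat that counting noise. The
  estimator is unbiased across seeds; single-data-set point estimates
  should be read with that spread in mind.
* The published ladder lnL values are not bit-reproducible without the
  original sequences and the original tool's unstated settings (κ,
  frequency model); the package reproduces the ladder *arithmetic* (AIC,
  LRT) exactly and the fitting behavior on simulated data.
* Height SEs are curvature-based; for nodes with near-zero height the
  observed information is nearly singular and SEs become large (honest
  uncertainty, but not useful intervals). Bootstrap SEs are not
  implemented.
* The clock LRT assumes the χ² asymptotics of nested hypotheses; with few
  taxa the null distribution is only approximate.
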