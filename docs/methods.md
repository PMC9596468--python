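# Methods

This note records the models implemented, the defaults and why, the
numerical choices, and what the synthetic-data generators do and do
not emulate.

## Data model and conventions

Node ages are Ma before present and increase into the past; extant
tips sit at age 0.  Trees must be rooted and strictly bifurcating —
polytomies are rejected rather than arbitrarily resolved, because both
the cladogenetic range models and the event classification assume one
split per node.  Age credibility intervals (95% HPDs) are accepted as
BEAST-style node comments `[&95%HPD={lo,hi}]` or as a sidecar TSV
keyed by each clade's sorted tip set; the sidecar wins on conflict,
since comment dialects vary across dating programs.  Sequences are
upper-cased with `?` normalised to `N`.

## Supermatrix construction

**Species merging.**  Per alignment column, gaps and `N` are ignored;
if the remaining conspecific bases agree the base is kept, and
genuine conflicts collapse to the minimal IUPAC code covering the
observed bases.  This preserves information while flagging
within-species polymorphism as ambiguity, which the downstream
ambiguity filter then sees.  A species with no data in a gene gets an
all-`N` row; genes where no species has data are dropped.

**Filters.**  A gene is retained iff ambiguous < 0.1% **and**
missing < 60% (individual level) or < 40% (species level) **and**
coverage ≥ 95% (individual) or = 100% (species).  The fraction
thresholds are strict `<` and the coverage threshold inclusive `≥`,
matching the wording they implement.  *Missing* counts both `-` and
`N` (consensus callers use them interchangeably for no-coverage);
*ambiguous* counts IUPAC codes other than A/C/G/T, excluding gap and
`N`.  A taxon counts as covered when it has at least one non-missing
site.

**Rate proxy.**  Genes are ranked by mean pairwise p-distance over
sites where both sequences carry an unambiguous base — deterministic
and tree-free, where a tree-based rate would drag in an inference the
pipeline is supposed to consume, not produce.  Binning sorts genes by
(rate, id) and cuts contiguous slices whose sizes differ by at most
one; genes with fewer than two comparable sequences go to the median
bin with a warning.  Gene order in the supermatrix is lexicographic by
id, for reproducibility.

## Range evolution (DEC / DIVALIKE, ±J)

States are the non-empty subsets of an ordered area set (≤ 5 areas),
optionally capped by a maximum range size; the empty range is not
modelled.  Anagenesis: an unoccupied area is gained at rate *d* per
addable area and an occupied area lost at rate *e*, with losses that
would empty the range forbidden.  The gain rate is per addable area,
independent of how many areas are already occupied (the classic
formulation scales gains with the number of occupied source areas;
without distance multipliers the two differ only by that factor).
No dispersal multipliers and no time stratification are implemented.

Cladogenesis enumerates daughter-range pairs per ancestral state:

* singleton ancestor — narrow sympatry (s, s);
* DEC, widespread ancestor — subset sympatry (s, {a}) and ({a}, s)
  for each occupied a, plus each ordered bipartition of s with a
  singleton daughter (vicariance), enumerated once;
* DIVALIKE, widespread ancestor — every ordered bipartition of s into
  two non-empty ranges (no subset sympatry);
* +J — (s, {b}) and ({b}, s) for each unoccupied b.

Each sympatry/vicariance pair carries weight (3 − *j*)/3 and each jump
pair weight *j*, normalised per ancestral state; *j* ∈ [0, 3), and
*j* = 0 reproduces the base model exactly (verified to 1e-9).

The likelihood is Felsenstein pruning with branch propagators
exp(*Q t*) (eigendecomposition shared across branches, with a
scipy `expm` fallback when the eigenbasis is ill-conditioned) and
per-node rescaling against underflow.  The root prior is uniform over
allowed states — explicit and testable, though reference
implementations differ subtly here, so node probabilities near the
root may not match other software digit-for-digit.  Marginal
ancestral ranges come from a standard up/down pass and equal the
brute-force enumeration posterior on small instances.

Fitting maximises lnL over log₁₀ *d*, log₁₀ *e* ∈ [−6, 1] (and *j* ∈
[0, 2.99999] when enabled) by Nelder–Mead from a fixed 3×3(×3) start
grid — deterministic without seeds.  AIC = 2k − 2 lnL with k = 2 or
3; nested base/+J pairs also get a χ²(1) likelihood-ratio p-value.
A caution from the simulations: with few widespread tips the loss
rate *e* is weakly identified and its MLE can run to a bound, so
means of *e* over replicates have a heavy right tail; *d* is well
behaved.

One subtlety the simulations exposed: with *d* = *e* = 0 ranges are
anagenetically frozen, but a widespread root can still split
vicariantly, so "no events possible" intuitions only hold on the
singleton-only state space.

## Event classification and rate curves

Each node is hardened to its modal marginal range (ties broken toward
the smaller range, then lexicographically) and classified as
focal-only, outside-only, or both; "distributed in the focal region"
includes the `both` class.  *In situ diversification* is a node event
— recorded once per internal node in the focal region with at least
one daughter lineage remaining in it — because a speciation event
happens once at a split.  *Colonization* is a branch event: parent
outside, child inside.  Event counts are integers, so modal hardening
is used rather than probability-weighted counts.

Event timing uses the dating uncertainty: an in-situ event takes its
parent node's HPD (point age as fallback); a colonization happened
somewhere along its branch, so it takes [child HPD low, parent HPD
high].  Rate curves count, per half-open window [t, t + 0.1 Ma), the
events whose closed plausible interval intersects it, separately by
type (MDivE / MColE), with an optional centred 3-window moving
average for the smoothed curves (kernel choice is a display decision,
not an inference).

## Brownian ancestral traits

Tip values are multivariate normal with covariance σ²C, C the shared
path-length matrix.  The root estimate is the GLS mean
(1ᵀC⁻¹x)/(1ᵀC⁻¹1); each internal node's estimate re-roots the tree at
that node and takes the same GLS mean there, which equals the
conditional ML value (and the joint mode — verified against a direct
tree-Laplacian solve).  σ̂² is the ML (1/n) estimator; reported
per-node variances are conditional ML variances σ̂²/(1ᵀC_v⁻¹1), not
confidence intervals.  Zero-length branches are nudged by 1e-8 before
inversion.  Species elevations are taken as the midpoint of an
elevational range when a range is given.  Elevation bands used in
presentations (e.g. 1000–2000 m) are display binning; inference is on
the continuous values.

## Patterson's D survey

A site enters the tally iff all four taxa carry an unambiguous
A/C/G/T and exactly two distinct bases occur among them; the outgroup
base is ancestral.  D = (nABBA − nBABA)/(nABBA + nBABA); significance
is a χ²(1) goodness-of-fit test on the two counts at α = 0.01, the
cutoff conventional for this survey design.  Quartets with
nABBA + nBABA = 0 report D = 0; quartets with fewer than
`min_sites = 10` usable sites are flagged undetermined and never
significant, guarding degenerate comparisons.  Undetermined quartets
are reported separately so percentages can be computed with either
denominator convention.  The survey runs on the concatenated
species-level matrix, enumerating P1 × P2 × P3 with a fixed outgroup
in lexicographic order; a significant D > 0 is attributed to P2–P3
flow and D < 0 to P1–P3 flow.  Sub-group restrictions (e.g. a single
species-rich genus as P1) recompute percentages on the restricted
denominator.

## Synthetic data: what it emulates, what it does not

* **Trees** — pure-birth, so no extinction and no diversification
  rate shifts; pseudo-HPDs of ±10% of each node age stand in for
  dating uncertainty without a dating engine.
* **Quartet alignments** — per-site multinomial mixture over ABBA /
  BABA / other-biallelic / invariant classes, realised as bases with
  a uniformly drawn ancestral/derived pair.  This gives a closed-form
  true D for exact oracles; it deliberately omits coalescent
  genealogies, linkage, mutation-model structure and indels, which
  the estimator does not use.  A site-pattern mask and its complement
  are observationally identical, so the complement masks of
  ABBA/BABA are excluded from the "other" class.
* **Introgressed supermatrices** — group-level site classes
  (pABBA = p₀ + γ·p_flow, pBABA = p₀) plus independent per-taxon
  noise.  All quartets share the planted signal, so detection
  saturates at large γ; the generator calibrates direction and
  type-I behaviour, not realistic between-quartet heterogeneity.
* **Range histories** — forward Gillespie simulation exactly matching
  the anagenetic generator plus draws from the model's cladogenesis
  table; true ranges are recorded at every node and the planted event
  list is derived by independent inline logic.
* **Orthogroup fixtures** — missing/ambiguous cells and absent taxa
  are planted by exact count, and the realised per-gene fractions are
  recorded as the construction oracle; optionally conspecific samples
  share a base sequence with a small per-site divergence
  (default 0.1% in the drivers), mimicking consensus sequences.

Passing tests on these generators demonstrates estimator correctness
under each model's own assumptions — not robustness to model
violations in real capture data (alignment error, paralogy,
base-composition bias, coalescent variance).

## Study-scale defaults in the drivers

The `analysis/` drivers simulate 30 species (42 samples), 60 genes of
300 nt, a ~10–12 Ma pure-birth tree (birth rate 0.28/Ma), four areas
with *d* = 0.05, *e* = 0.02 /Ma, Brownian elevation with σ² = 4×10⁴
m²/Ma from a 1500 m root, and a gene-flow survey over an 8 × 6 × 8
scheme — sizes at which every stage runs in seconds while preserving
the structure of a real montane-radiation dataset.  The acceptance
script uses 50-tip trees and 20 replicates for rate recovery, 10,000
quartets for calibration and 10⁵ sites for D consistency.
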