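# Methods

## The exposure metric

Half-sphere exposure counts, for a residue, the alpha carbons of other
residues inside a hemisphere of fixed radius oriented along the side chain;
a high count means a buried residue. `structptm` generalizes this in two
ways to suit *predicted* structures.

First, the hemisphere becomes a cone of configurable opening angle α about
the side-chain direction u = (CB − CA)/‖CB − CA‖. α = 90° recovers the
half-sphere; α = 180° is the full sphere and makes the count independent of
side-chain orientation (this is asserted by test, not assumed). Glycine has
no CB, so a pseudo-CB is constructed from the backbone frame by the ideal
tetrahedral geometry (b = CA − N, c = C − CA, a = b × c, CB = CA − 0.58273431·a
+ 0.56802827·b − 0.54067466·c), the standard construction in HSE-β-style
metrics. The same construction is used whenever a CB atom is absent.

Second, each candidate distance is inflated by the pair's predicted aligned
error before the radius test: residue j is a neighbor of i iff

    ‖CA_j − CA_i‖ + max(PAE[i,j], PAE[j,i]) ≤ r   and   ∠(u_i, CA_j − CA_i) ≤ α.

PAE matrices are slightly asymmetric; we symmetrize by the maximum, the
conservative choice — a residue pair is only a contact if the predictor is
confident about the pair in both directions. The minimum or the directional
entry would count more neighbors in half-confident regions. Both the radius
and angle boundaries are inclusive, consistent with the inclusive
conventions of the downstream thresholds (pPSE ≤ 5, smoothed pPSE ≤ 34.27).
Distances are CA–CA throughout; only the cone angle encodes side-chain
geometry.

Two parameterizations matter downstream:

| purpose | radius | angle | post-processing | threshold |
|---|---|---|---|---|
| side-chain exposure | 12 Å | 70° | none | ≤ 5 → "high" exposure |
| disorder calling | 24 Å | 180° | ±10-residue mean | ≤ 34.27 → IDR |

The 12 Å / 70° pair reflects the ~3.5 Å scale of a residue and the
flexibility of side chains about the CB direction; 24 Å / full-sphere with
PAE was the best-performing configuration for disorder prediction in the
benchmark that produced the 34.27 threshold (85% true-positive rate at 5%
false positives). The smoothing window is exposed as configuration because
the threshold is only meaningful together with its window; the window-size
family screened in that benchmark was {5, 10, 15, 20, 25} and this package
interprets "window size w" as a half-window (±w residues, truncated at the
termini), with 10 as the documented default.

## Regions

IDR flags are per-residue booleans from the smoothed full-sphere pPSE. A
**short IDR** is a maximal disordered run of at most 20 residues whose
neighboring structured runs each span at least 80 residues; runs touching a
terminus have no flank on that side and never qualify. Because smoothing
drags the flanking domains' high counts into a short linker, often only the
linker core crosses the disorder threshold; the **extended region** widens
each short IDR by 5 residues per side (clipped to the chain) to recover the
residues at the flexible/structured boundary, where a modification can
still gate the linker's conformation.

## PTM tables and the structural join

Site tables keep only the common acceptor residues per modification type
(phosphorylation S/T/Y; ubiquitination, sumoylation, acetylation K;
methylation K/R with all subtypes m1/m2/m3/me… grouped as `m`;
O-glycosylations S/T). Duplicate (protein, position, type) rows merge with
the regulatory flag as the union; regulatory sites missing from their
type's list are added to it. Filtering is order-independent (sorted before
merging) and every dropped row is counted in a machine-readable report.

The join attaches exposure, exposure class, IDR/short-IDR membership, and
`eligible_for_proximity` = outside any IDR, or inside a short IDR. Long
IDRs are excluded from 3D analyses because their predicted coordinates are
not positions, only placeholders; short IDRs are kept because their
geometry is constrained by the flanking domains.

## Enrichment statistics

Every design is a 2×2 table (category membership × modified status) over a
universe of acceptor residues: all acceptors (IDR design), structured-only
acceptors (exposure design), IDR-only acceptors (short-IDR vs other IDR),
or motif centers. The test is the two-sided Fisher exact test implemented
by hypergeometric enumeration over the support, including every
same-margin table whose probability is at most that of the observed table
times (1 + 1e-7); tables with total ≤ 1000 are enumerated in exact integer
arithmetic, larger ones in log space over the same support. The reported
odds ratio is the sample OR (a·d)/(b·c), reported as +∞ or 0 for zero
cells (no continuity correction) and NaN for 0/0. Families — all PTM types
of one design, or all proteins of a per-protein scan — are corrected with
Benjamini–Hochberg (via statsmodels, cross-checked against the closed
form). For the functional-score sweep of the short-IDR design the
comparison set at a cutoff is ambiguous (scores below the cutoff vs all
sites); the `restrict` row-filter makes either choice explicit at the call
site.

## 3D proximity

All distances are ‖CA_i − CA_j‖ + max(PAE[i,j], PAE[j,i]). The global
profile bins, for every modified source residue, every eligible
target-acceptor in the same protein by that distance (right-closed bins;
self-proximity bins start at 1 Å and exclude the source residue itself;
colocalization bins start at 0 Å so two PTM types competing for the same
residue land in the leading bin) and reports the fraction of binned
acceptors that are modified. The background redistributes each protein's
observed modification count uniformly over that protein's eligible
acceptors — per protein, not pooled, so protein length and composition are
preserved; for self-proximity the randomized set serves as both sources and
targets. The profile reports the randomization mean, sd (ddof = 1),
z = (observed − mean)/sd, and a significance flag |z| ≥ 1.96 (the flag's
criterion is explicit configuration, and raw z is always reported
alongside). With the historical default of 5 randomizations the sd estimate
is itself noisy — z behaves like a t(4) variable under the null — so
calibration checks in this package use 50 randomizations, where z is
effectively normal; the default stays at 5 for compatibility with the
published profile layout.

The per-protein cluster test takes the k ≥ 3 modified eligible acceptors of
one type, computes their mean pairwise distance, and compares it against
draws of k acceptors sampled uniformly without replacement from the same
protein's eligible acceptors of the same type (restricting the null to the
same acceptor class keeps amino-acid composition fixed). The empirical
p-value uses the (1 + m)/(1 + N) estimator — never zero, slightly
conservative — with N = 10,000 permutations by default and BH correction
across proteins.

## Synthetic data

The generator produces the geometry classes the statistics care about, not
protein physics:

* **helix** — ideal α-helix CA trace (2.3 Å radius, 1.5 Å rise, 100°/residue);
* **coil** — extended chain, exact 3.8 Å steps with Gaussian direction
  jitter (σ = 0.15 transverse), emulating a disordered linker;
* **globule** — CA positions on a jittered 3.8 Å boustrophedon grid curve
  inside a sphere sized to hold the chain, which guarantees folded-core
  neighbor counts without simulation. Consecutive CA–CA distances are exact
  only within rows of the curve; the occasional longer step at a row
  boundary is irrelevant to neighbor counting.

Segments are laid out disjointly along +x with a 3.8 Å gap. N and C atoms
are synthesized along the chain direction (1.46 / 1.52 Å with a small
transverse wobble to avoid exact collinearity) and CBs placed by the ideal
tetrahedral construction; glycines get no CB. Sequences are uniform over
the 20 canonical residues, so acceptor frequencies are 0.15 (S/T/Y), 0.05
(K), 0.10 (K/R). PAE is block-structured: `intra_pae` within a segment and
the larger of the two segments' `inter_pae` across segments. Defaults are
2 Å inside folded domains, 25 Å across segments, and 15 Å *within* coil
segments of the standard chimera — predictors assign high PAE inside
disordered regions, and this is load-bearing: without it a 15-residue
linker between two compact domains cannot drop below the smoothed disorder
threshold, because the ±10 smoothing window mixes in the domains' ~100-count
neighbors. pLDDT is constant per segment (92 folded, 45 coil) and is carried
through but not used by any statistic.

The PTM simulator modifies each acceptor independently with an
exposure-dependent probability (pPSE ≤ 5 → `p_modify_exposed`, else
`p_modify_buried`), with an optional 3D hotspot: acceptors within
`cluster_radius` of a chosen acceptor get the exposed-rate regardless of
exposure. A single explicitly seeded RNG stream drives each call.

What the fixtures do **not** emulate — and hence what passing tests do not
show about real data: realistic packing density and secondary-structure
mixtures (the globule is denser and more uniform than a real fold), real
PAE textures (real matrices are not block-constant), sequence composition
bias, fragment files for very long proteins (rejected, not repaired), and
catalog-level artifacts of PTM databases. The calibration results
demonstrate the statistics behave correctly given their inputs, not that
the biological effect sizes of any particular catalog will be reproduced.

## Verification problem sizes

The acceptance script and the deepest tests use: 50 random structures
(≤ 200 residues, random asymmetric PAE in [0, 20] Å) × 12 parameter
combinations for exact oracle agreement; every 2×2 table with total ≤ 60
(635,375 tables) for Fisher exactness; 200 replicate proteomes of 10
two-domain/long-coil chimeras (~320 residues each, modification rate 0.4)
for enrichment type-I error and power; 500 150-residue globules with 4–8
uniform sites and 1,000 permutations for cluster-test null uniformity;
40 seeds × 5-site 8 Å pockets in 200-residue globules at 10,000
permutations for recovery; and 100 replicate 3-globule proteomes at 50
randomizations for profile z calibration. These sizes give the calibration
estimates standard errors comfortably inside the asserted bands.

## Numerical choices and edge cases

* Radius/angle comparisons are on raw doubles (inclusive ≤); the angle test
  compares cosines, avoiding arccos round-off near the boundary.
* Fisher's tie tolerance (1 + 1e-7) is applied in exact integer arithmetic
  for small tables, so "equally probable" tables are included exactly as
  the convention dictates.
* The cluster test compares null means against the observed mean with a
  1e-12 relative tolerance so the degenerate all-acceptors-modified case
  (every permutation reproduces the observed set up to summation order)
  yields p = 1 exactly.
* Empty bins report NaN fractions and NaN z; bins with zero randomization
  sd report NaN z and are never flagged significant.
* A structure with a single residue has pPSE 0; a profile smoothed with a
  window larger than the chain reduces to the global mean.
* PAE parsing accepts both the dense and the triplet JSON dialects, clamps
  the diagonal to zero, and rejects negative, non-finite, non-square, or
  size-mismatched matrices. Author residue numbering is preserved as
  metadata but all internal positions are re-based to 1..n; multi-chain
  files and fragmented entries are rejected rather than repaired.

## Known limitations

* The disorder threshold 34.27 is tied to an external benchmark's ground
  truth and to the (unpublished) smoothing window of that benchmark; on
  synthetic data it cleanly separates coils from globules, but real
  proteomes may warrant re-tuning threshold and window together.
* The log-odds PSSM uses a background-proportional pseudocount (default 1);
  the external motif-discovery service it stands in for does not publish
  its exact normalization, so absolute score values are comparable within
  this package only.
* Global-profile significance marks |z| ≥ 1.96 against a small-sample sd;
  treat the flag as descriptive at the default 5 randomizations and raise
  the randomization count where calibrated inference matters.
* Cross-protein (complex-level) proximity, ubiquitin linkage types, and
  ensemble structures are out of scope.
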