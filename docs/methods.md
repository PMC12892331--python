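# Methods

This note documents the model behind `sitevec`, the numerical and design
choices that were genuinely open, and what the synthetic test bed does and
does not establish about real structures.

## Scaffold geometry

Directions come from a class-I geodesic subdivision of the icosahedron at
integer edge frequency *f*: each face corner triple (A, B, C) is sampled on
the barycentric lattice (iA + jB + kC)/f with i + j + k = f, every lattice
point is projected radially onto the unit sphere, and vertices shared by
neighbouring faces are deduplicated by rounding coordinates to 1e-8 before
hashing.  The full sphere then carries exactly 10·f² + 2 directions; the
package default f = 7 gives 492.  Class-I subdivision is required here:
recursive edge bisection can only reach 12, 42, 162, 642, … vertices and has
no member near 492.

Directions are sorted canonically (descending z, then azimuth), so a given
frequency always yields the same ordered list and descriptor index k means
the same spatial direction for every structure.

**Icosahedron orientation.**  The package uses the golden-ratio vertex set —
the twelve permutations of (0, ±1, ±φ), normalized — which places an edge
midpoint, not a vertex, on the +z axis.  This choice is load-bearing: at
f = 7 it puts 28 subdivided vertices *exactly on the equator*, so the
inclusive hemisphere rule below retains 232 + 28 = 260 of 492 directions.
With a vertex on +z the near-equator rings come in bands of 10 and no
dot-product threshold can retain exactly 260 (the achievable counts are
246, 256, 266, …).  The orientation is therefore fixed, documented, and not
configurable.

**Hemisphere rule.**  `restrict_hemisphere` keeps directions with
u·n ≥ −ε relative to the anchor-plane normal n, with ε = 1e-9 — i.e. the
open hemisphere plus the equator, the equator membership being exact in this
orientation.  A strict rule (u·n > ε) and a keep-all rule are exposed.
Restriction only sets a mask; the full-sphere indexing never changes, so
masked descriptors from different structures stay comparable.

## Structures, radii, charges, reference frame

PDB parsing is delegated to biotite; waters and common ions can be dropped
on read.  Radii come from a packaged Bondi-type element table (C 1.70, N
1.55, O 1.52, S 1.80, Fe 2.00 Å, …), charges from a packaged simplified
force-field-like (residue, atom) table covering the backbone amide dipole
and charged/polar side-chain termini, with 0 e as the fallback for apolar
atoms.  Both tables are overridable from 2- and 3-column TSV files.  Only
*consistency* of radii and charges across the structures being compared
matters to the metrics; the packaged values are documented defaults, not a
redistribution of any particular force field.

The reference frame maps the anchor atom (default HEM/HEC iron) to the
origin and the least-squares plane of the plane-defining atoms (default: the
four pyrrole nitrogens; fallback: all heavy heme atoms) into the xy-plane.
The +z side is chosen by an optional "above" selection, defaulting to the
side containing the structure centroid.  The remaining in-plane rotational
freedom is fixed by placing the first plane atom at azimuth 0, which makes
the frame a deterministic, idempotent function of the structure.
Superposition uses the Kabsch algorithm (SVD with determinant correction,
proper rotations only) over matched selections, default backbone N/CA/C/O.
Alignment of trajectory frames on a stable residue subset is supported by
passing an explicit residue-restricted selection; the package does not
assign secondary structure itself.

## Ray tracing

For a ray with unit direction u from origin o and an atom at center c with
radius r: b = (c − o)·u, y² = |c − o|² − b², and when y ≤ r the
entry/exit distances are b ∓ √(r² − y²).  Site tracing takes, per direction,
the smallest *positive* entry distance ≤ R over all non-excluded atoms;
ligand tracing takes the largest exit distance (clamped to R).  Degenerate
cases are resolved as follows, all deterministic:

* atoms whose entry distance is ≤ 0 (behind, or containing, the anchor) are
  skipped for site tracing — a surface behind the origin is not a pocket
  wall, and an atom overlapping the anchor would yield nonphysical lengths;
* exact ties on the entry distance go to the lowest atom index;
* hits beyond the scaffold radius R are misses: length R, charge 0;
* the default exclusion set is {HEM, HEC} plus waters and ions, so the
  anchor cofactor itself cannot produce near-zero vectors.

## Metrics and normalization

The shape and charge metrics are per-index root-mean-square differences over
all N retained vectors, including no-hit vectors (length R, charge 0) — no
exclusion rule is applied, so N is constant across comparisons.  The
combined metric normalizes by σ_l and σ_q, the **population** (ddof = 0)
standard deviations pooled over all vectors of all descriptors in the
comparison set; the pooled means cancel in the difference and are computed
for reporting only.  Published dataset-specific constants can be supplied
directly instead of pooled values.  Weights w_s = 2/(2+d),
w_c = 2(1+d)/(2+d) keep (w_s + w_c)/2 = 1; the domain is restricted to
d > −1 so both weights stay positive.  At d = 0 the weighted form reduces
exactly to the unweighted normalized sum (verified to 1e-12 in tests).

Ensemble comparison multiplies each exemplar-pair RMSD by the product of
frame fractions (n_i/N_A)(n_j/N_B) and sums over all pairs; it is symmetric
and invariant to splitting an exemplar's weight across duplicates.

## Clustering

Affinity Propagation (scikit-learn, `affinity="precomputed"`) runs on the
negated distance matrix with damping 0.9, max 1000 iterations and a fixed
random state (default 0).  Two numerical choices deviate from the obvious
defaults and are deliberate:

* **Preference.**  The default preference is the **mean off-diagonal
  similarity**.  scikit-learn's own default (median of the full matrix)
  includes the zero self-similarity diagonal, which drags the preference
  upward on negated-distance inputs and oversplits tight, well-separated
  groups; the minimum similarity, at the other extreme, merges small pooled
  exemplar sets.  The off-diagonal mean is scale-aware and behaves well from
  a handful of pooled exemplars up to full ensembles.  Any explicit value
  can be passed.
* **Exact duplicates.**  Items at exactly zero distance are collapsed to one
  representative before message passing and re-expanded afterwards.  AP's
  update rules are ill-defined under exact ties — every duplicate otherwise
  ends up its own exemplar.

Non-convergence produces a logged warning and the best-iterate assignment
flagged `converged=False`; a fully degenerate outcome falls back to a single
cluster at the medoid.

The second, joint round pools the exemplars of all systems, clusters them on
the chosen metric, and sums each system's first-round frame weights per
joint cluster; rows of the resulting population table are normalized by each
system's total frame count and sum to 1 by construction.

Average-linkage trees are built with `scipy.cluster.hierarchy.linkage` on
the condensed distance matrix and exported as Newick with branch lengths
taken as differences of merge heights, so an ultrametric input is reproduced
exactly by the cophenetic distances.

## Ligand criterion

A pose is tested only on rays that intersect the ligand (the denominator is
the ligand's own ray count, not all 260).  The two thresholds are
conjunctive: every protrusion must be ≤ slack (default 1 Å) *and* the
protruding fraction must be ≤ max_violation_fraction (default 10%).  The
alternative reading — a budget of 1 Å of *total* protrusion — was rejected
because a single deep clash should always reject regardless of how many rays
are clean.  Ligand-vector charges are recorded and reported as a
complementarity diagnostic but do not affect accept/reject.

## Synthetic test bed

`make_cavity` tiles a hemispherical shell of radius ρ (extended one atom
radius below the equator so equatorial rays are covered) with atoms of
radius r on a Fibonacci lattice; every upward ray's true first-surface
distance is ρ − r up to the tiling granularity.  The granularity is
*measured*, not estimated: the generator traces ~8× as many probe rays as
shell atoms against their nearest neighbours (cKDTree) and reports the worst
deviation from ρ − r with a 25% margin, so tests derive tolerances from the
realized lattice rather than an idealized spacing formula.
`make_two_state_ensemble` mixes two such shells with seeded coordinate
jitter and returns ground-truth labels; `make_charged_patch` charges a polar
cap of chosen solid angle, giving the closed form
RMSD<sup>c</sup> = |q|·√(patch fraction) against the neutral shell.  All
generators are pure functions of their arguments, including the seed.

These fixtures exercise the geometry, metrics and clustering machinery with
known answers.  They do **not** emulate real protein features: no
side-chain-scale surface texture, no charge distributions beyond the patch,
no correlated backbone motions, and no heme chemistry.  Passing tests
establish the correctness of the computations, not the biological
discriminative power of the descriptor on real ensembles.

## Problem sizes and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| frequency f | 7 | – | 492 directions; finest icosphere below 1k rays |
| max_length R | 20 | Å | upper bound on pocket depth from the anchor |
| hemisphere rule | inclusive (ε = 1e-9) | – | retains 260 incl. the exact equator |
| shell_density | 2.0 | atoms/Å² | closes a 1 Å-atom shell with ~0.14 Å granularity |
| two-state ensemble | 30 frames, radii 6/10 Å, noise 0.05 Å | – | clearly separated states, realistic thermal jitter |
| AP damping / max_iter / seed | 0.9 / 1000 / 0 | – | conservative damping, deterministic |
| d | 0 | – | equal shape/charge weighting |
| slack / violation fraction | 1.0 Å / 0.10 | – | tolerant of tiling-scale contact |

Test and example ensembles use tens of frames and ~1–2·10³ shell atoms,
sizes at which every pipeline stage (tracing, matrices, AP, trees) is exact
or fully converged; the machinery is linear in frames for tracing and
quadratic for pairwise matrices, so scaling to MD-sized ensembles is a
matter of runtime only.

## Known limitations

* Single anchor point per site; pockets not star-shaped around the anchor
  are partially shadowed.
* Hard-sphere vdW surfaces only — no probe-rolling or solvent-accessible
  surface, by design.
* The packaged charge table is a simplified stand-in sufficient for
  consistent per-atom charges; users comparing against published constants
  should load their own force-field table.
* AP cluster counts depend on the preference heuristic; the number of joint
  clusters on real data is data-dependent and not a calibrated quantity.
* mmCIF input, residue reconstruction and protonation are out of scope.
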