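# Methods

This note documents the models and numerical choices behind chromolink: how
each stage of the open-chain link analysis is computed, which parameters
matter, what the synthetic generators do and do not emulate, and where the
design was genuinely open.

## Gauss linking number of polygonal chains

The GLN of two polylines is the Gauss double integral evaluated exactly as
a sum over segment pairs: for two straight segments the integral equals
1/(4π) times the signed solid angle of the quadrilateral spanned by the
four endpoints, computed from the four unit normals of the tetrahedral
faces (arcsin form) with the sign taken from the triple product
(r₃₄ × r₁₂) · r₁₃. Coplanar segment pairs contribute exactly zero; the
normals' norms are guarded so the formula degrades to zero rather than NaN.
Segment pairs that touch (distance ≤ 1e−9 nm) raise a degeneracy error in
the scalar API; the bulk path assumes disjoint chains, as chromosome models
are.

Whole-chain GLN is the sum over all segment pairs, O(n·m), vectorized in
row blocks so two 2,000-bead chromosomes take a few hundred ms. The
per-pair contributions are kept and prefix-summed (`FragmentGLNTable`), so
the GLN of any fragment pair is four array lookups. Closed chains include
the wrap-around segment; a fragment query covering a whole closed chain
includes it too.

**Localization.** The linking region is the shortest fragment pair whose
GLN stays within a tolerance of the whole-chain value G. The search is a
two-sided greedy shrink: from full intervals, repeatedly trim whichever of
the four ends keeps |g − G| ≤ tolerance and leaves g closest to G; stop
when no trim is feasible. This is O((n+m) ) queries rather than the O(n²m²)
exhaustive scan, matches the "shortest but similar" intent, and the result
is guaranteed feasible and locally minimal (no single-end trim remains).
The default tolerance is 0.2·|G|, mirroring the ±0.2 GLN drift allowance
used for link stability; it is exposed as a parameter because no canonical
value exists. Localization refuses effectively unlinked pairs (tolerance
≥ |G|), where the criterion would be satisfied by arbitrary fragments.

## Closures

Open chains must be closed before any polynomial invariant applies. Three
constructions are provided. *Direct*: the endpoint chord (implicit closing
segment). *Center-of-mass*: endpoints extended radially from the chain's
center of mass to a sphere of radius `sphere_radius_factor` (default 10)
times the maximal bead distance, joined by the shorter great-circle arc
discretized at ≤ 5° steps; antipodal sphere points route through a fixed
perpendicular waypoint. *Random*: both endpoints joined straight to one
point drawn uniformly on a sphere around the **whole system** of chains
under analysis (bounding-sphere center, radius factor 10), so simultaneous
closures of a pair live on one sphere and closure legs of different chains
cannot interleave inside the data region. Each chain of a pair receives its
own independent random point; whether the original study shared one point
per pair is not documented, and independent points are the literal reading
of "for each chromosome we choose randomly one point". All closures only
append vertices; the original coordinates are untouched.

Consensus typing performs `n_random` = 100 closures, types each closed
system, and reports frequencies. The center-of-mass method is the default
for single-chain knot typing (one deterministic answer); random closure is
the default for pairs.

## KMT reduction

Before computing polynomials, chains are shortened by removing any interior
vertex v whose triangle (u, v, w) is intersected by no other segment — of
the chain itself **or of any other chain in the system**. The obstacle
check is essential for link analysis: without it a triangle move can pass
one chromosome through another and silently change the link type, even
though the cited single-chain literature does not need it. Sweeps run in
ascending vertex order and restart until a pass removes nothing, making the
output deterministic. The triangle is treated as closed with ε = 1e−9 nm
(boundary contact counts as intersection — conservative, so an entangled
vertex is never removed); the two segments adjacent to the triangle, which
always touch it at the shared vertex, are tested with that endpoint trimmed
by 1e−4 of their length so only genuine piercing blocks removal.

One mathematical point the tests document explicitly: a triangle move
leaves the GLN against a partner invariant **exactly** only when the
partner is a closed curve (the move's effect on the Gauss integral is the
triangle-boundary loop integrated against the partner, which vanishes only
for closed partners). Against an open partner the open-chain GLN genuinely
changes. The pipeline therefore reduces chains only after closure, and the
conservation tests use closed obstacles, where the drift is < 1e−11.

## HOMFLY-PT engine

Closed chains are projected along a direction sampled uniformly on the
sphere; all pairwise segment crossings in the projection plane are recorded
with over/under from depth and sign by the right-hand rule. Projections are
rejected (and resampled, up to 50 times) when segments are near-parallel at
a crossing, a crossing falls within 1e−9 of a vertex or of another
crossing, or the two strands' depths differ by less than 1e−9 of the system
size. Crossing-sign consistency is pinned by the invariant that half the
inter-component sign sum equals the pair's GLN, which the tests check on
Hopf and Solomon geometries.

The polynomial is computed on the Gauss-code diagram by skein recursion
toward descending diagrams, under the convention l·P(L₊) + l⁻¹·P(L₋) +
m·P(L₀) = 0 with P(unknot) = 1: the first crossing met on its under-strand
is switched and smoothed, the switched diagram moving closer to descending
(an unlink, worth δ^(c−1), δ = −(l+l⁻¹)/m) and the smoothed one losing a
crossing. Reidemeister I/II reductions run at every node; diagrams that
split into crossing-disjoint groups factorize with a δ per split;
subresults are memoized on a canonical code (crossings relabeled by first
appearance). Polynomials are exact integer Laurent polynomials in (l, m).
Diagrams still above 15 crossings after simplification are reported as
"too complex" and classified *Other* — the skein tree is exponential, and
complex links are binned rather than mistyped.

**Self-generated classification table.** Names are assigned by looking up
the computed polynomial (plus component count) in a table the engine
builds from canonical geometric constructions: braid words realized as 3D
curves (strands along +y, crossing bridges at z = ±½, nested rectangular
closure arcs) and pushed through the same projection/skein pipeline. Base
entries: torus knots 3_1, 5_1, 7_1; twist/other knots 4_1, 5_2, 6_1, 6_2,
6_3; the links Hopf, Solomon, Whitehead, and the (2,6) torus link 6²_1 —
each in both chiralities where chiral. Composites are derived
algebraically: P multiplies over connected sums and gains a δ per split
union, enumerated up to 9 total crossings. Mirror pairs share one unsigned
name, following the field's convention for chromosome work. Building the
table takes about a second; a prebuilt JSON ships with the package and
`chromolink table-build` regenerates it. A collision between two names for
one polynomial aborts the build (none occur at this scope). The prime-knot
catalog stops at the named repertoire above — 7_2 through 7_7 are omitted
because no construction of certain identity was available to the builder;
anything outside the table is *Other*.

## Genome survey

`survey` computes GLN for all C(n,2) chromosome pairs, calls a pair linked
at |GLN| ≥ 0.7 (the boundary is inclusive; the threshold is a parameter),
localizes linked pairs, and optionally types them by consensus (typing only
linked pairs keeps the HOMFLY cost proportional to the few percent of pairs
that matter). Records sort by |GLN| descending. The histogram helper
reports per-bin counts, cumulative fractions, and the shares of pairs below
0.5 and at/above threshold.

Multiple links are connected components of ≥ 3 chromosomes in the graph
whose edges are linked pairs. Component membership — rather than requiring
every member to have two linked partners — is deliberate: chain-like
examples such as c−n−d−h contain degree-1 nodes, and the component reading
is the one consistent with them. Cross-model conservation counts, per pair,
the number of a cell's models in which it is linked; a pair linked in all
models is flagged stable.

The closure-preservation estimate p₁·p₂·(1 − f_cross)² quantifies why a
consensus probability of ~40% for the dominant type is expected rather than
alarming: both chains' closures must individually preserve their knot type
(p₁·p₂) and neither may cross the partner (squared because the closures are
independent).

## Structure-based relaxation

The potential is the structure-based (Gō-like) form given in the README
with all reference values — bond lengths, angle cosines, dihedral phases,
contact distances — taken from the input structure, which is therefore a
minimum of the bonded terms. One printed-sign subtlety: the dihedral term
is implemented as k_d¹(1 − cos(φ−φ₀)) + k_d³(1 − cos 3(φ−φ₀)), the phase
convention under which the native structure minimizes the term (the
1 + cos form is its maximum there, contradicting the structure-based
definition); the tests assert bond, angle and dihedral terms vanish exactly
on the input.

Contacts are non-chain-neighbour pairs (same-chain |i−j| ≤ 3 excluded —
those pairs are governed by the bonded terms) at initial separation within
[r_min, r_coff] = [0.6, 2.0] nm, with per-contact σ = r₀·2^(−1/6) so each
Lennard-Jones minimum sits at the native distance and depth α·ε = 0.2 ε.
Pairs initially closer than r_min do not interact at all (no overlap
penalty); all remaining pairs are repulsive-only 4ε(σ_rep/r)¹² with
σ_rep = 0.6 nm — r_min being the only repulsion-scale length in the model.
Beads within 0.6 nm of the last kept predecessor are pruned first (strict
"within", single forward pass).

Dynamics are BAOAB Langevin with unit masses, friction 1.0 and
dt = 0.0005 in reduced units; k_BT = T̃·ε·k̃_B with k̃_B = 0.00831451, so
T̃ = 120 gives k_BT ≈ 1 ε. With γ = 0 the integrator degenerates to
velocity Verlet (the no-thermostat energy-conservation test uses this).
Dihedrals whose native geometry is nearly collinear (sin² of either bending
angle < 1e−3) carry no dihedral term — their reference phase is undefined —
and instantaneously near-collinear dihedrals have their torque dropped for
that step, because the torque arm diverges as 1/|sinθ| while the potential
stays bounded; without this guard a straight chain segment destabilizes the
integrator at the first thermal kick. The same seed yields bitwise
identical trajectories.

**Stability criteria.** Per recorded frame the pair's open-chain GLN is
computed. *Strict*: linked (|GLN| ≥ 0.7) in ≥ 90% of frames and GLN within
±0.2 of the reference (first frame unless given) throughout. *
Non-decreasing*: |GLN| never falls below the reference magnitude minus
0.05. The temperature-scan helper reports the linked fraction per
temperature without enforcing monotonicity.

## Synthetic data

The generators provide, with seeded reproducibility: parametric (2,q) torus
knots and (2,2k) torus links (|GLN| = k by construction, within 1e−3 at
≥ 100 beads/component), the figure-eight knot, the Whitehead link from its
braid closure (GLN = 0 yet nontrivially linked — the survey's documented
blind spot, which the tests exercise by asserting the survey misses it
while forced-closure typing names it), opened variants (gap arc deletion,
straight tails, Gaussian jitter), local connected-sum insertion (a small
trefoil spliced into one edge), a deeply threaded pair (helix wound three
times around a rod, |GLN| ≈ 3 — the geometry of the stable deeply wound
chromosome pairs, and stable by construction on short runs because
unthreading requires sliding the whole helix off the rod), and toy genomes:
confined random walks in disjoint cubic-grid territories with planted
open-Hopf pairs and returned ground truth.

What the toy genomes do **not** emulate: realistic chromatin statistics
(territory shapes, loop extrusion, contact-frequency structure), chromosome
length heterogeneity, or links of the marginal |GLN| ≈ 0.7–0.9 kind that
real models produce. Passing the planted-recovery tests therefore shows the
detection machinery is correct, not that the 0.7 threshold has any
particular sensitivity/specificity on real nuclei. Likewise the threaded
pair shows the stability criterion accepts a construct that cannot unlink
on the simulated timescale; it says nothing about marginal links, whose
fate is temperature- and criterion-dependent by design.

## Problem sizes and determinism

Default analysis sizes: 100 random closures per pair; 15-crossing budget
after simplification; relaxation protocol 200,000 × dt 0.0005 (tests and
the acceptance script use 20,000 steps on ≤ 100-bead constructs, which
already spans several Langevin relaxation times at γ = 1). All randomness —
closure points, projection directions, synthetic geometry, thermostat
noise — flows from explicit seeds; the CLI derives independent named
substreams (closures, simulation, synthesis) from its single `--seed`.

## Known limitations

- Link typing by HOMFLY covers pairs; systems of ≥ 3 chromosomes are
  described through the GLN link graph, not a multi-component polynomial.
- The classification table stops at the named repertoire (knots ≤ 7
  crossings less 7_2–7_7, prime 2-component links to 6 crossings plus
  Whitehead, composites to 9); everything else is *Other*, as is anything
  beyond the crossing budget.
- Open-chain GLN is a geometric, not topological, quantity: it changes
  under deformation even when the entanglement does not, which is precisely
  why the stability analysis tracks it with a drift allowance instead of
  demanding constancy.
- The relaxation model is a minimal structure-based field: no
  excluded-volume calibration against chromatin, no hydrodynamics, and a
  single global ε; temperatures are meaningful relative to ε only.
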