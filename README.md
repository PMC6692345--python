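# chromolink

Detection, classification, localization and stability testing of
**topological links between open 3D chains**, built for coarse-grained
chromosome models (one bead ≈ 100 kb, coordinates in nm) but applicable to
any bead-chain polymers.

Interphase chromosomes are open curves, so the classical machinery of link
theory — which needs closed loops — does not apply directly. This package
implements the combined workflow used to map chromosome entanglement in
single-cell genome structures:

- **Gauss linking number (GLN)** of open chains,

  GLN = 1/(4π) ∮₁ ∮₂ (r⁽¹⁾ − r⁽²⁾) · (dr⁽¹⁾ × dr⁽²⁾) / |r⁽¹⁾ − r⁽²⁾|³,

  evaluated exactly per segment pair by the solid-angle closed form. For
  closed curves GLN is the integer linking number; for open chains it is
  real-valued, with |GLN| ≈ 1 indicating Hopf-like and |GLN| ≈ 2
  Solomon-like winding. A pair of chromosomes is called *linked* when
  |GLN| ≥ 0.7.
- **Closures**: direct (endpoint chord), center-of-mass (radial arcs
  through a far sphere) and random one-point closures on a huge sphere.
- **KMT reduction** (Koniaris–Muthukumar–Taylor): obstacle-aware triangle
  moves that shrink chains without changing their entanglement.
- **HOMFLY-PT polynomials** by skein recursion (l·P(L₊) + l⁻¹·P(L₋) +
  m·P(L₀) = 0) over projected diagrams, with Reidemeister simplification,
  split-diagram factorization (δ = −(l+l⁻¹)/m per split) and memoization.
  Link names (3_1, 4_1, Hopf, Solomon, Whitehead, composites like
  `3_1 # 3_1 # Hopf`, split unions like `3_1 U 3_1`) come from a lookup
  table the engine generates itself from canonical geometric constructions,
  so no external variable convention can disagree with the classifier.
- **Random-closure consensus**: 100 independent closures per pair, each
  typed after KMT reduction; the type frequencies are the result.
- **Linking-region localization**: prefix-summed fragment GLN tables give
  the GLN of any fragment pair in O(1); the shortest fragment pair that
  retains the whole-chain GLN is the physical location of the link.
- **Structure-based relaxation**: a Gō-like potential whose bonds, angles,
  dihedrals and Lennard-Jones contacts are referenced to the input
  structure (k_b = 20000 ε/nm², k_a = 20 ε, k_d¹ = 1 ε, k_d³ = 0.5 ε,
  α = 0.2, contacts in [0.6, 2.0] nm), integrated by Langevin dynamics at
  reduced temperature T̃ = k_BT/(ε·k̃_B) (default 120). A link is *stable*
  when it is present in ≥ 90% of the recorded trajectory with GLN drift
  ≤ ±0.2, or (laxer) when |GLN| never decreases.
- **Synthetic generators** for every pipeline stage: parametric torus
  knots/links, figure-eight, the Whitehead link (the GLN = 0 blind spot),
  opened/noisy variants, deeply threaded stable pairs and toy genomes with
  planted links and known ground truth.

## Worked example

Generate an open Hopf pair (120 beads per ring, one-bead gap), measure its
GLN, type it by random-closure consensus, and localize the linking region:

```
$ chromolink synth --kind hopf --beads 120 --gap 0.0084 --out hopf.xyz
$ chromolink gln hopf.xyz
0.939063
$ chromolink linktype hopf.xyz --closures 100 --seed 1
Hopf    0.940
U       0.050
Other   0.010
# dominant: Hopf (100 closures)
$ chromolink localize hopf.xyz
a       [0, 119)        b       [63, 116)       gln=0.9391
```

The open-chain GLN of 0.94 (just below the closed-curve value 1) already
signals a Hopf-like link; 94 of 100 random closures confirm the Hopf type,
while the few discordant closures show why a single closure is not trusted.
The localization line reports 0-based half-open bead intervals: the link
involves essentially all of chain *a* and beads 63–115 of chain *b*.

Genome-scale commands follow the same pattern: `survey` computes GLN for
all C(n,2) chromosome pairs of a model, `multilinks` reports connected
groups of ≥ 3 linked chromosomes, `conservation` counts in how many models
of a cell each pair stays linked, and `relax`/`stability` run the
structure-based dynamics and apply the stability criteria.

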