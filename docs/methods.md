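# Methods

`torsionfold` builds protein models by minimizing a composite energy over
the backbone dihedral angles. This note documents the model, its
parameters, the numerical choices, and what the synthetic test bed does
and does not demonstrate.

## Conformational model

A chain of L residues is represented by seven sites per residue — N,
amide H, Cα, C, carbonyl O, Cβ and a side-chain center (SC) — with every
bond length and bond angle fixed at ideal (Engh–Huber-style) values:
N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å, N–H 1.010 Å,
Cα–Cβ 1.521 Å; N–Cα–C 111.2°, Cα–C–N 116.2°, C–N–Cα 121.7°. The peptide
bond ω is held trans (180°). The only degrees of freedom are the 2L−2
defined dihedrals x = (φ₂…φ_L, ψ₁…ψ_{L−1}), in radians internally and
degrees at every interface, IUPAC sign convention (validated against
mdtraj). Coordinates are built by sequential internal-to-Cartesian (NeRF)
placement in a canonical frame — N₁ at the origin, Cα₁ on +x, C₁ in the
xy-plane — so the model has no rigid-body degrees of freedom; every
energy term depends only on internal coordinates, which the tests assert
directly.

Cβ is placed at the ideal tetrahedral position (N–Cα–Cβ 110.4°, improper
dihedral C–N–Cα–Cβ −122.6°, the L-configuration). Glycine carries
Cβ = Cα and SC = Cα, so Cβ-based terms fall back to Cα for glycine. SC
lies on the Cα→Cβ axis at a residue-specific distance (a shipped
20-entry table of approximate side-chain-centroid offsets, 0 Å for Gly
to 4.10 Å for Arg). The SC placement is a deliberate simplification: the
reduced model carries no side-chain torsions, so a collinear offset is
the only rotation-free choice.

## Restraints and their potentials

Restraints arrive as per-pair probability histograms in seven channels:

| channel | geometry | bins |
|---|---|---|
| cb_distance | Cβᵢ–Cβⱼ distance | 38 (one <2 Å, 36 × 0.5 Å on [2,20), one ≥20 Å) |
| ca_distance | Cαᵢ–Cαⱼ distance | 38 |
| omega | Cαᵢ–Cβᵢ–Cβⱼ–Cαⱼ dihedral | 24 × 15° + no-interaction |
| theta | Nᵢ–Cαᵢ–Cβᵢ–Cβⱼ dihedral (asymmetric) | 24 × 15° + no-interaction |
| phi_angle | Cαᵢ–Cβᵢ–Cβⱼ planar angle (asymmetric) | 12 × 15° + no-interaction |
| cb_contact / ca_contact | indicator < 8 Å | single probability |

The θ/φ/ω atom definitions follow the convention common to
orientation-restraint folding pipelines; the no-interaction bin encodes
"Cβ–Cβ distance ≥ 20 Å".

Histograms become energies by a negative log-ratio against a reference
bin, E_b = −log((p_b + ε)/(p_ref + ε)) with ε = 1e−4; the reference is
the ≥20 Å bin for distances and the no-interaction bin for orientations.
Shifting all bin energies of a pair by a constant leaves every gradient
unchanged (asserted numerically), so the choice of reference only fixes
the zero of energy per pair.

Bin energies are interpolated with cubic splines over knots at bin
centers: natural splines for distances and the planar angle, periodic
splines for the dihedrals (value and derivative match at ±180°). Outside
the distance knots the potential continues C¹: below the first knot a
repulsive quadratic (curvature 50 Å⁻², slope magnitude exceeding
10 energy units/Å within 0.1 Å); above the last knot a ramp whose slope
decays linearly to zero over 1.75 Å, leaving the potential flat beyond
22 Å. Contacts use a smooth flat-bottom well, −p·S(d), S = 1 for
d ≤ 8 Å switching cubically to 0 over [8, 9] Å; the well depth is the
predicted contact probability.

Restraint selection supports the probability-cutoff policy (keep pairs
whose sub-20-Å mass exceeds c; default c = 0.55) and top-n·L selection
by that confidence within a sequence-separation class (short
1<|i−j|≤11, medium 11<|i−j|≤23, long |i−j|>23; ties broken by pair
order; n·L clamped to the available pairs). Orientation channels are
evaluated only where the no-interaction probability is below 0.5,
intersected with the Cβ-distance mask, and never for glycine pairs
(degenerate Cβ frame).

## The composite energy

E = Σ_t Σ_r w_{t,r} E_{t,r} + w_hb E_hb + w_vdw E_vdw + w_tor E_tor

with t over the seven restraint channels and r over the three separation
classes — 24 weights in total, each constrained to [0, 25]. The three
generic terms are the package's own smooth stand-ins:

- **E_hb** — backbone hydrogen bonds: for donor H_i/N_i and acceptor O_j
  (|i−j| > 2), −f_d(d_HO)·f_a(θ_NHO), where f_d is a cubic-smoothstep
  bump supported on [1.2, 3.0] Å (full strength on [1.5, 2.6]) and f_a
  switches on over 120–150°. The ideal (−57°, −47°) helix scores ~1 unit
  per i,i+4 bond (H…O 2.10 Å, angle 165°).
- **E_vdw** — soft clash penalty: Σ (r_clash − d)² for d < r_clash =
  0.85·(R_a + R_b) over non-bonded heavy-site pairs (radii N 1.55, C/Cα
  1.70, O 1.52, Cβ 1.80, SC 2.00 Å). Pairs within two covalent bonds are
  excluded, as are same-residue pairs among {N, Cα, C, Cβ, SC}, whose
  distances are rigid under ideal geometry and carry no signal.
- **E_tor** — a statistical backbone-torsion surface: 24×24 −log p grids
  (15° cells) for general, glycine and proline residues, built from
  wrapped-Gaussian mixtures over the allowed Ramachandran basins and
  interpolated with periodic Catmull-Rom bicubics (C¹, interpolating at
  knots).

Every gate and switch is C¹ by construction, because the optimizer
requires a continuously differentiable energy.

**Gradients.** Each term first accumulates its Cartesian gradient
∂E/∂x_a over all sites; the chain rule to torsion space then uses the
rigid-rotation identity ∂x_a/∂χ = ê × (x_a − p) for every atom a
downstream of the rotating bond (axis ê through pivot p), plus the
same-residue special cases (φ also rotates C, O, Cβ, SC of its own
residue; ψ rotates the carbonyl O). Dihedral and planar-angle
derivatives with respect to atom positions use the standard analytic
forms. Agreement with central finite differences to better than 1e−4
relative error, with all terms active, is an acceptance-level test.

**Default weights.** Distance channels carry the largest weights
(Cβ 2–3, Cα 1–1.5, rising with separation class), orientations 0.5–1,
contacts 0.25–0.5, hb 0.5, vdw 1.0, tor 0.2. They were calibrated on the
synthetic fixture suite; the full coordinate-descent weight search
(`optimize_weights`, implemented per the printed schedule: one 0.25-step
pass over [0, 25] from zero, three 0.1-step passes, a final ±2 pass at
0.02) is exercised on closed-form objectives in the tests because a
folding-objective search would require tens of thousands of folds.

## Optimization

Minimization uses limited-memory BFGS with the two-loop recursion
(history m = 256, initial inverse Hessian γI with the standard
most-recent-pair scaling, curvature pairs with yᵀs ≤ 1e−12 discarded)
and Armijo backtracking line search (c = 1e−4, halving from α₀ = 1, at
most 30 backtracks). A folding run performs up to 10 restart rounds of
at most 2000 steps; the history is cleared between rounds while the
conformation carries over; torsions are wrapped into (−π, π] after each
step (the stored s_k uses the unwrapped step). A round converges when
|ΔE| < 1e−6 for 5 consecutive accepted steps, when ‖∇E‖∞ < 1e−6, or
when the line search fails; the run stops early when a round converges
within its first few steps. The returned model is the lowest-energy
conformation over all accepted steps. Runs are fully deterministic given
the seed — byte-identical outputs are an acceptance-level test.

Initial torsions come from one of four modes: `provided` (a file),
`extended` (−120°, 120°), `ss_guess` (seeded draws around helix/strand
means under an H/E/C string — the package's replacement for a learned
initial-torsion predictor), and `random` (uniform draws within the four
allowed Ramachandran basins, including left-handed α for turns).
Gradient-based minimization is local: with sparse or
chirality-insensitive restraints, a trajectory can settle into a
mirror-topology basin, which is why orientation restraints and a sound
initialization matter (see the synergy study below).

## Synthetic test bed

`synthetic` builds toy natives from ideal torsions — α-helix
(−57°, −47°); β-hairpin with strands (−120°, 120°) and a four-residue
turn; a two-helix bundle joined by a four-residue loop; a mixed
helix+hairpin topology. The turn/loop/junction torsions are fixed
constants chosen by a geometric search for clash-free, compact packings
(an interpenetrating native would make its own restraints fight the
clash term). Optional seeded jitter ≤ 5° roughens the ideal geometry.

`restraints_from_structure` emulates a predictor's output: distance
histograms are Gaussians of width σ (default 0.5 Å) around the true
distance, discretized onto the 38-bin schema with tail mass routed into
the end bins; orientation histograms are wrapped Gaussians (width 10°)
scaled by 1 − p_no-interaction; contacts are cdf-smoothed indicators. A
seeded fraction η of pairs is replaced by uniform histograms (noise) and
a fraction 1 − κ is blanked to the no-interaction pattern (coverage).
The emulation is unimodal and unbiased by construction; real predicted
restraints are multimodal, correlated across pairs and systematically
biased, so passing the recovery tests demonstrates that the engine
solves the optimization problem the restraints pose — not that it would
reach any particular accuracy on real proteins.

## Study designs and problem sizes

The shipped studies run at desk scale; sizes are package choices:

- **Fold recovery** — the 10-fixture suite (lengths 30–60, σ = 0.5 Å,
  η = 0, κ = 1, seed 0), default pipeline, ss_guess initialization;
  TM-score ≥ 0.8 against the native counts as recovered; ≥ 8/10 must
  recover.
- **Restraint count** — 6 fixtures (L = 30–48), top-n·L selection over
  the full channel set for n ∈ {1, 5, 10, 20, all}, lowest-energy of
  three seeded trajectories per point, 2 rounds × 500 steps. Mean
  TM-score must be non-decreasing up to a 0.02 tie margin (TM
  differences below 0.02 are conventionally ties; the curve saturates
  above n = 5).
- **Orientation synergy** — six β-hairpins (L = 20–38) folded with and
  without the three orientation channels, lowest-energy of three
  trajectories. Orientations break the mirror degeneracy that
  distance-only energies cannot rank, so the with-orientation median
  TM-score must be at least the distance-only median.

Lowest-energy model selection across a small trajectory ensemble is the
same selection rule the single-trajectory pipeline applies across its
own steps; it is used in the comparative studies to keep medians stable
at these suite sizes.

## Known limitations

- Restraint quality is the whole game: with η → 1 or κ → 0 the engine
  degrades to the generic terms, which cannot fold anything on their
  own (gradient search on a rough knowledge-based landscape stalls).
- The torsion surface, H-bond and clash terms are coarse stand-ins;
  models are ideal-geometry backbones with pseudo-side-chains, not
  all-atom structures.
- TM-score here is sequence-dependent (fixed correspondence); it does
  not align different sequences.
- The clash counter reports raw pair counts at 0.6·(R_a+R_b) over the
  reduced representation; it is an internal quality signal, not
  comparable to all-atom clash scores.
- Tight β-topologies remain the hardest case: a single trajectory from
  an uninformative initialization can fold to the mirror image when
  orientation restraints are absent or weak.
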