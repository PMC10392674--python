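# Methods

This note documents the models, the numerical choices, and what the
synthetic test surfaces do and do not demonstrate. Units throughout:
kcal/mol, Å, degrees, elementary charges; coordinates are right-handed
with the membrane normal along +z; residue indices are 1-based.

## Molecular model and ideal helices

Structures are plain containers (atoms → residues → helices → bundles).
The ideal α-helix builder parametrizes the Cα trace by rise (default
1.5 Å/residue) and twist (default 100°/residue) on a cylinder of radius
2.278 Å; backbone N/C/O, the amide hydrogen and Cβ are placed from fixed
cylindrical offsets derived once from an internal-coordinate helix built
at φ = −57°, ψ = −47° and frozen in `core.py`. The trace is exactly
parametric (axial extent = (n−1)·rise), so bond geometry is ideal only
near the default rise/twist; this is deliberate — the builder is a
geometric primitive, not a refinement target. Side chains are grown from
internal-coordinate templates (NeRF) for a 14-type alphabet
(A, G, S, T, V, L, I, F, Y, W, D, E, K, M); other residue types are
rejected loudly rather than approximated.

Helix axes are least-squares lines through sliding-window (4-residue)
Cα centroids. Orientation changes compose in a fixed, documented order:
axial rotation χ about the helix's own axis first, then the tilt θ about
an in-membrane-plane axis through the hinge Cα whose direction is set by
the azimuth φ. The hinge defaults to the middle residue; neither the
hinge nor the composition order is standardized in the field, so both
are explicit package conventions.

Ballesteros–Weinstein numbering resolves "h.x" labels as
`anchor_index + (x − 50)` from per-helix anchors (the x.50 position);
inverse lookup uses optional per-helix residue ranges.

Structure I/O is a deliberately narrow fixed-column PDB dialect:
ATOM/HETATM/TER/MODEL/ENDMDL/END records, alternate locations collapse to
conformer "A", insertion codes are rejected, malformed records are
reported with their line number. Multi-model files carry frame series.
Partial charges and van der Waals classes are re-assigned on read from
the name-based tables (PDB cannot carry them).

## Energy model

Three pairwise terms:

* Lennard-Jones 12-6 with Lorentz–Berthelot combination over five
  element classes (C, N, O, S, H); per-class (r_min/2, ε) values are a
  small self-contained table.
* Screened Coulomb q₁q₂·332.06/(ε(r)·r) with a distance-dependent
  dielectric ε(r) = ε₀·r, ε₀ = 4 by default (a common implicit-screening
  choice for membrane-protein scoring); a constant-dielectric mode is
  available.
* A directional hydrogen bond: a 12-10 well with depth `hb_eps`
  (4.0 kcal/mol) at `hb_rmin` (2.9 Å, donor–acceptor heavy distance),
  scaled by cos² of the D–H···A deviation from linearity and zero below
  90°.

All terms switch smoothly to zero over the last 1 Å before the 10 Å
cutoff (cubic smoothstep), making the energy continuous there. Partial
charges are CHARMM-flavoured but simplified so every residue carries an
integer net charge; charged side chains (Asp/Glu −1, Lys +1) concentrate
their charge on the terminal group. The parametrization is designed for
*recognition*: polar/ionic anchors dominate the dispersive background,
which is what the planted-truth recovery tests exercise. Absolute
energies are not comparable to any published force field, by design.

Per-residue ligand decompositions are exact partitions: the rows of the
receptor-residue table sum to the total breakdown.

## Side-chain placement

Rotamers are a Cartesian grid over the side-chain χ torsions (default
60° steps) on rigid ideal internal geometry; intra-side-chain strain is
ignored (each rotamer is a rigid template). Placement initializes every
mutable residue at its best self-energy rotamer and runs deterministic
single-residue best-response sweeps in ascending residue order until a
sweep changes nothing; ties break toward the lowest rotamer index. The
self/pair energy tables are precomputed vectorized; rotamers more than
25 kcal/mol above the best self energy are pruned (disable with
`prune_margin=None` for strict equivalence with exhaustive enumeration).
A residue's environment excludes its own Cα/Cβ (the 1-2/1-3 neighbours);
1-4 contacts are kept.

During placement the per-pair repulsion is capped at +10 kcal/mol so a
single overlap cannot dominate the combinatorics; the Coulomb term is
clipped to the same ±cap whenever the cap is active, because otherwise an
overlapping +/− atom pair would gain unbounded attraction against a
bounded repulsion and side chains would collapse onto acceptors.

Alanization truncates the six bulky hydrophobic types (I, L, V, F, Y, W)
to Cβ, renames them ALA for bookkeeping and records the original type for
restoration; it is idempotent and leaves other types untouched.

## Orientation sampling

The coarse grid is 12 axial rotations (30° steps) per helix; the fine
grid is θ ∈ {−10, 0, 10}, φ ∈ {−30, −15, 0, 15, 30},
χ ∈ {−30, −15, 0, 15, 30} (75 per helix). Pair tables are computed with
the two helices in isolation and side chains kept at their input
conformation; the pairwise-additive total is then ranked **exactly**:
dense enumeration for product spaces up to 2×10⁶, otherwise best-first
(A*) search over per-helix assignments with an admissible lower bound
(the minimum of each unresolved pair table, row/column-restricted once
one endpoint is assigned). Completed assignments pop off the frontier in
nondecreasing true energy, so the top-N list is exact, never heuristic.

Rebuilding applies the winning orientations and repacks side chains in
**clash-relief** scope by default: only residues whose side-chain vdW
repulsion against the reoriented bundle exceeds 5 kcal/mol are repacked
("all" and "none" scopes are available). Full re-derivation was rejected
as the default because a long charged side chain can re-form an
equivalent salt bridge from a rotated backbone, erasing exactly the
orientational signal this stage is supposed to rank; clash relief keeps
informative input rotamers and still removes steric impossibilities.

"Energy and diversity" ensemble selection is greedy maximin: accept the
best-energy structure, then repeatedly the lowest-energy structure at
backbone-Cα RMSD ≥ 2 Å (default) from everything accepted, considering
structures within a 20 kcal/mol window of the best; the threshold halves
when stuck, with a floor that prevents duplicates from ever being
returned twice.

## Docking

Pose generation uses uniform random rotations (normalized 4-normal
quaternions), translations uniform in the site sphere (cube-root radial
sampling), and independent ±60° perturbations of every rotatable torsion;
all streams derive from one seed. Stage 1 scores each pose's
receptor–ligand interaction energy against the alanized receptor, drops
poses above a +50 kcal/mol clash ceiling, and keeps the exact top 100.
Stage 2 restores the truncated hydrophobics independently per pose,
repacks them with the ligand present, rescoring each pose in its own
side-chain environment. The 25 best rescored poses are then settled into
their local minima by deterministic Nelder-Mead over rigid-body motion
plus substituent torsions, the leading three more deeply, and the list is
re-ranked. The refinement step is this package's own addition: ranking
unrefined raw poses compares sampling noise rather than basins.
Interaction-only (not total) energy is used for ranking throughout.

Matched-core initialization superposes mapped core atoms by Kabsch
(SVD) superposition, rejecting fewer than three or collinear mapped
atoms in either set. Substituent annealing runs Metropolis Monte Carlo
on single random torsions (±30° moves) over geometric temperature ramps
(10 cycles, 50→600 K by default) and returns the best pose seen, so the
returned energy never exceeds the input's.

## Interaction analysis

Hydrogen bonds: donor–acceptor heavy distance ≤ 3.5 Å and D–H···A angle
≥ 120°, one record per donor/acceptor atom pair (best angle); salt
bridges: charged-group nitrogen (Lys NZ, Arg NH1/NH2/NE, flagged-His
ND1/NE2, ligand formal +) to carboxylate/phosphate oxygen (or ligand
formal −) within 4.0 Å, one record per residue pair at the minimum N–O
distance. Neither cutoff is standardized; both are configurable and
recorded in report headers. Histidine protonation is never inferred.
Hydrogen-bond networks expand breadth-first from a seed residue; with
water mediation enabled, residue–water–residue chains appear as single
water-mediated edges (distance-only legs when the water carries no
hydrogens). Persistence evaluates a named interaction per frame and
reports the mean presence. Anchor reports list SB/HB records crossing
named group boundaries with distances and, given frames, persistence
fractions.

## Toy metadynamics

Overdamped Langevin dynamics (no inertia — the simplest dynamics with
the correct stationary distribution): s ← s + (F/γ)Δt + √(2k_BTΔt/γ)·ξ
with reflecting walls at the potential bounds. Well-tempered hills of
initial height h₀ = 0.3 kcal/mol, width σ = 0.2, bias factor γ = 10 and
stride 200 steps; heights decay as exp(−V_bias/(k_BΔT)) with
ΔT = (γ−1)T, recovering standard metadynamics as γ → ∞. The free energy
is F(s) = −(γ/(γ−1))·V_bias(s), shifted to zero at its minimum. On the
symmetric double well (3 kcal/mol barrier), 2×10⁵ steps at 300 K with
friction 1.0 and Δt = 0.01 recover the profile below the barrier to
≲0.2 kcal/mol RMSE.

## Synthetic fixtures: what they emulate, and what they do not

`make_bundle` plants one axial-rotation combination in a ring of three
(or more) helices: every ring-adjacent pair gets a Lys on one helix
aimed at an Asp on the next, and the inter-axis translations are refined
numerically (Nelder-Mead) with an objective that binds the planted
rotations and keeps the off-by-one rotations weakly bound but not
clashing (a clash would later invite repacking into an alternative
contact). The generator then *verifies* its own contract: the planted
combination must be the exact mean-field global minimum with a gap of at
least 5 kcal/mol (measured gaps ≈ 7–8) **and** must survive the rebuild
stage; chi draws that admit no good ring geometry are redrawn
deterministically from the seed stream.

`make_complex` builds a six-helix cage holding an Asp anchor, a Lys
anchor across the pocket, and three alanizable hydrophobics (F, Y, L).
The toy ligand is a zwitterion — a six-carbon ring with a protonated
amine arm (formal +1) and a para alkoxide-like oxygen (formal −1) — so
the bound orientation is pinned by two complementary salt bridges and
the end-to-end flip is doubly repulsive. Neutral-hydroxyl variants were
rejected during design: their landscapes held several near-degenerate
single-salt-bridge modes and independent searches did not reproduce one
pose. The planted pose is the medoid of three internally seeded full
pipeline searches run under a site definition frozen beforehand, so the
ground truth is the scoring function's actual optimum and is
reproducible by further searches (observed: 5/5 independent 5000-pose
runs within 2 Å). The `seed` argument does not alter this construction;
the complex is a deterministic reference fixture.

`make_frames` schedules an interaction on in exactly
`round(on_fraction·n_frames)` frames (seeded random schedule), displacing
one partner by 10 Å in off frames and adding 0.05 Å Gaussian noise
everywhere — large margins relative to the 3.5/4.0 Å criteria, so the
detector count is exact by construction.

Passing these tests shows the machinery is correct on landscapes whose
optimum is engineered to be unique and strongly separated. It does not
show that the simplified energy model ranks real receptor conformations
or real ligand poses correctly; real data have flexible backbones, water,
and force-field subtleties entirely outside this package's scope.

## Problem sizes

Desk-scale defaults used by the test suite and the acceptance script:
3-helix bundles of 16 residues on the coarse 12³ grid (top-20 ranked,
top-10 rebuilt, 5 selected); the docking fixture with 5000 poses per
seed, 100 kept, 25 refined; metadynamics runs of 2×10⁵ steps. These
sizes keep every stage exhaustively checkable against enumeration while
exercising the same code paths as the full-size grids, whose 12⁷ and 75⁷
product spaces are only ever ranked through the pair tables, never
materialized.

## Known limitations

* The residue alphabet omits Arg, His, Asn, Gln, Cys, Pro and Met
  variants beyond the 14 supported types; His charge states must be
  flagged by the caller.
* Rotamer internal strain and backbone flexibility are ignored.
* The mean-field estimate neglects many-body context at scan stage (the
  two helices are scanned in isolation), exactly as the staged protocol
  assumes.
* Greedy side-chain placement is not globally optimal in general; it is
  verified against exhaustive enumeration on the fixture sizes where
  enumeration is feasible.
* The pose-generation cloud is isotropic; no shape-guided sampling.
* Metadynamics convergence is asserted only for the 1D double well at
  the stated schedule.
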