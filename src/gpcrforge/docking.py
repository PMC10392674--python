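"""Two-stage ligand docking against an alanized pocket.

Stage 1 throws a large cloud of rigid-body + torsion-perturbed poses into
the (alanized) binding site and keeps the best ``keep`` by receptor-ligand
interaction energy. Stage 2 restores the truncated hydrophobic side chains
independently for every surviving pose, repacks them around the ligand and
rescores, so each pose sees its own side-chain environment. Helpers cover
matched-core initialization of a bulky analog from a reference pose
(Kabsch superposition of mapped core atoms) and simulated annealing of
substituent torsions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .forcefield import AtomArrays, ForceFieldParams, LigandScorer
from .geometry import (kabsch, quaternion_to_matrix, random_unit_quaternion,
                       rotation_about_axis)
from .repack import dealanize

__all__ = ["Ligand", "LigandPose", "SiteRegion", "generate_poses",
           "stage1_select", "stage2_dealanize_rescore", "matched_core_init",
           "anneal_substituents", "refine_pose", "rotate_torsion",
           "load_ligand", "save_ligand"]

logger = logging.getLogger(__name__)

KB = 0.0019872041  # kcal/(mol*K)


@dataclass
class Ligand:
    """A small molecule: atoms, bond graph, and rotatable torsions."""
    atoms: list
    bonds: list                       # (i, j) atom-index pairs
    rotatable_torsions: list = field(default_factory=list)  # 4-index tuples
    name: str = "LIG"

    def __post_init__(self):
        g = self.graph()
        if len(self.atoms) and not nx.is_connected(g):
            raise ValueError(f"ligand {self.name}: bond graph not connected")
        bond_set = {frozenset(b) for b in self.bonds}
        for tors in self.rotatable_torsions:
            for a, b in zip(tors, tors[1:]):
                if frozenset((a, b)) not in bond_set:
                    raise ValueError(
                        f"torsion {tors}: atoms {a},{b} are not bonded")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from(self.bonds)
        return g

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])

    def donor_pairs(self):
        """(heavy, hydrogen) index pairs for H bonded to N or O."""
        adj = {i: set() for i in range(len(self.atoms))}
        for a, b in self.bonds:
            adj[a].add(b)
            adj[b].add(a)
        pairs = []
        for i, at in enumerate(self.atoms):
            if at.element == "H":
                for j in adj[i]:
                    if self.atoms[j].element in ("N", "O"):
                        pairs.append((j, i))
        return pairs

    def acceptor_indices(self):
        """O atoms, plus neutral N atoms with no attached hydrogen."""
        donors = {h for _, h in self.donor_pairs()}
        heavy_with_h = {d for d, _ in self.donor_pairs()}
        out = []
        for i, at in enumerate(self.atoms):
            if at.element == "O":
                out.append(i)
            elif (at.element == "N" and at.formal_charge == 0
                  and i not in heavy_with_h):
                out.append(i)
        return out

    def heavy_indices(self):
        return [i for i, a in enumerate(self.atoms) if a.element != "H"]

    def as_residue(self, coords=None, index: int = 1):
        """Pack the ligand (optionally at pose coordinates) as a residue."""
        from .core import Atom as CoreAtom, Residue
        coords = self.coords() if coords is None else np.asarray(coords)
        atoms = [CoreAtom(a.name, a.element, coords[i],
                          partial_charge=a.partial_charge,
                          formal_charge=a.formal_charge)
                 for i, a in enumerate(self.atoms)]
        return Residue(index=index, name="LIG", chain="L", atoms=atoms)


def save_ligand(ligand: Ligand, path) -> None:
    """Write a ligand as structured text (YAML)."""
    import yaml
    data = {
        "name": ligand.name,
        "atoms": [{"name": a.name, "element": a.element,
                   "coord": [float(x) for x in a.coord],
                   "partial_charge": float(a.partial_charge),
                   "formal_charge": int(a.formal_charge)}
                  for a in ligand.atoms],
        "bonds": [[int(i), int(j)] for i, j in ligand.bonds],
        "rotatable_torsions": [[int(x) for x in t]
                               for t in ligand.rotatable_torsions],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_ligand(path) -> Ligand:
    """Read a ligand from the structured-text (YAML) format."""
    import yaml
    from .core import Atom as CoreAtom
    with open(path) as fh:
        data = yaml.safe_load(fh)
    atoms = [CoreAtom(d["name"], d["element"], np.array(d["coord"]),
                      partial_charge=float(d.get("partial_charge", 0.0)),
                      formal_charge=int(d.get("formal_charge", 0)))
             for d in data["atoms"]]
    return Ligand(atoms=atoms,
                  bonds=[tuple(b) for b in data["bonds"]],
                  rotatable_torsions=[tuple(t) for t in
                                      data.get("rotatable_torsions", [])],
                  name=data.get("name", "LIG"))


@dataclass
class LigandPose:
    ligand: Ligand
    coords: np.ndarray
    score: object | None = None          # EnergyBreakdown once scored
    stage: str = "generated"
    per_residue: object | None = None    # decomposition table (stage >= 1)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.ligand.atoms), 3):
            raise ValueError("pose coordinate count does not match ligand")

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def copy(self) -> "LigandPose":
        return LigandPose(self.ligand, self.coords.copy(),
                          score=self.score, stage=self.stage)


@dataclass
class SiteRegion:
    centre: np.ndarray
    radius: float

    def __post_init__(self):
        self.centre = np.asarray(self.centre, dtype=float)
        if self.radius <= 0:
            raise ValueError("site radius must be positive")


def rotate_torsion(coords: np.ndarray, ligand: Ligand, torsion, angle: float
                   ) -> np.ndarray:
    """Rotate the distal side of torsion (a,b,c,d) by ``angle`` about b-c."""
    a, b, c, d = torsion
    g = ligand.graph()
    g.remove_edge(b, c)
    moving = nx.node_connected_component(g, c)
    R = rotation_about_axis(coords[c] - coords[b], angle)
    out = coords.copy()
    idx = sorted(moving)
    out[idx] = (coords[idx] - coords[b]) @ R.T + coords[b]
    return out


# ---------------------------------------------------------------------------

def generate_poses(ligand: Ligand, site: SiteRegion, n: int, seed: int,
                   torsion_perturbation: float = 60.0):
    """``n`` random poses in the site sphere, reproducible from ``seed``.

    Each pose: a uniform random rotation (quaternion method) about the
    ligand centroid, a translation uniform in the site sphere, and an
    independent uniform perturbation of +-``torsion_perturbation`` degrees
    on every rotatable torsion.
    """
    if n < 1:
        raise ValueError("need n >= 1 poses")
    rng = np.random.default_rng(seed)
    base = ligand.coords()
    poses = []
    for _ in range(n):
        coords = base.copy()
        for tors in ligand.rotatable_torsions:
            delta = rng.uniform(-torsion_perturbation, torsion_perturbation)
            coords = rotate_torsion(coords, ligand, tors, delta)
        R = quaternion_to_matrix(random_unit_quaternion(rng))
        coords = (coords - coords.mean(axis=0)) @ R.T
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = site.radius * rng.uniform() ** (1.0 / 3.0)
        coords = coords + site.centre + radius * direction
        poses.append(LigandPose(ligand, coords, stage="generated"))
    return poses


def stage1_select(poses, receptor_alanized, p: ForceFieldParams | None = None,
                  keep: int = 100, clash_ceiling: float = 50.0):
    """Score all poses against the alanized receptor; keep the best ``keep``.

    Poses whose receptor-ligand interaction energy exceeds
    ``clash_ceiling`` kcal/mol are discarded before ranking. The survivors
    are the exact minimum-``keep`` of the score list.
    """
    p = p or ForceFieldParams()
    scorer = LigandScorer(receptor_alanized, p)
    scored = []
    for pose in poses:
        bd = scorer.score(pose.ligand, pose.coords)
        if bd.total > clash_ceiling:
            continue
        new = pose.copy()
        new.score = bd
        new.stage = "stage1"
        scored.append(new)
    if len(scored) < keep:
        logger.warning("stage1: only %d/%d poses below the clash ceiling",
                       len(scored), keep)
    scored.sort(key=lambda q: q.score.total)
    return scored[:keep]


def refine_pose(pose: LigandPose, receptor,
                p: ForceFieldParams | None = None,
                maxiter: int = 300) -> LigandPose:
    """Local rigid-body + torsion minimization of a pose (Nelder-Mead).

    Deterministic; returns a new pose with an updated score. Used to settle
    shortlisted poses into their local energy minima before final ranking.
    """
    p = p or ForceFieldParams()
    scorer = LigandScorer(receptor, p)
    ligand = pose.ligand
    base = pose.coords.copy()
    centroid = base.mean(axis=0)
    ntors = len(ligand.rotatable_torsions)

    def build(x):
        c = base - centroid
        ang = np.linalg.norm(x[3:6])
        if ang > 1e-9:
            c = c @ rotation_about_axis(x[3:6] / ang, np.rad2deg(ang)).T
        c = c + centroid + x[:3]
        for t, tors in enumerate(ligand.rotatable_torsions):
            c = rotate_torsion(c, ligand, tors, x[6 + t])
        return c

    from scipy.optimize import minimize
    res = minimize(lambda x: scorer.score(ligand, build(x)).total,
                   np.zeros(6 + ntors), method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-3,
                            "fatol": 1e-3})
    coords = build(res.x)
    out = LigandPose(ligand, coords, stage=pose.stage)
    out.score = scorer.score(ligand, coords)
    return out


def stage2_dealanize_rescore(poses, receptor_alanized,
                             p: ForceFieldParams | None = None,
                             refine_top: int = 25,
                             refine_maxiter: int = 300):
    """Per-pose de-alanization, repacking, rescoring and local refinement.

    For every stage-1 pose the truncated hydrophobics of
    ``receptor_alanized`` are restored and repacked with the ligand present
    (each pose independently), then the pose is rescored in its own
    receptor environment. The best ``refine_top`` poses are then settled
    into their local minima (rigid body + substituent torsions) and
    re-ranked; ``refine_top=0`` disables refinement. Returns
    ``(final_poses, receptors)`` ranked by final interaction energy.
    """
    p = p or ForceFieldParams()
    out = []
    for pose in poses:
        lig_arrays = AtomArrays.from_ligand(pose.ligand, pose.coords, p)
        receptor, restored = dealanize(receptor_alanized, p, repack=True,
                                       extra_context=lig_arrays)
        bd, table = LigandScorer(receptor, p).score(
            pose.ligand, pose.coords, per_residue=True)
        new = pose.copy()
        new.score = bd
        new.stage = "final"
        new.per_residue = table
        out.append((new, receptor))
    out.sort(key=lambda t: t[0].score.total)
    if refine_top:
        refined = []
        for pose, receptor in out[:refine_top]:
            better = refine_pose(pose, receptor, p, maxiter=refine_maxiter)
            refined.append((better, receptor))
        out = refined + out[refine_top:]
        out.sort(key=lambda t: t[0].score.total)
        # deep-refine the leaders so the final ranking compares converged
        # minima rather than refinement budgets
        deep = []
        for pose, receptor in out[:3]:
            better = refine_pose(pose, receptor, p,
                                 maxiter=3 * refine_maxiter)
            _, better.per_residue = LigandScorer(receptor, p).score(
                better.ligand, better.coords, per_residue=True)
            deep.append((better, receptor))
        out = deep + out[3:]
        out.sort(key=lambda t: t[0].score.total)
    return [t[0] for t in out], [t[1] for t in out]


def matched_core_init(reference_pose: LigandPose, new_ligand: Ligand,
                      core_map) -> tuple:
    """Place a new ligand by superposing mapped core atoms onto a reference.

    ``core_map`` is a list of (new_ligand_index, reference_index) pairs
    (>= 3, non-collinear). Returns ``(pose, core_rmsd)``.
    """
    core_map = list(core_map)
    if len(core_map) < 3:
        raise ValueError("core map needs at least 3 atom pairs")
    new_idx = [a for a, _ in core_map]
    ref_idx = [b for _, b in core_map]
    mobile = new_ligand.coords()[new_idx]
    target = reference_pose.coords[ref_idx]
    R, t, core_rmsd = kabsch(mobile, target)
    coords = new_ligand.coords() @ R.T + t
    return LigandPose(new_ligand, coords, stage="generated"), core_rmsd


def anneal_substituents(pose: LigandPose, receptor,
                        p: ForceFieldParams | None = None,
                        cycles: int = 10, t_start: float = 50.0,
                        t_end: float = 600.0, steps_per_cycle: int = 100,
                        seed: int = 0, move_size: float = 30.0,
                        torsions=None):
    """Simulated annealing of substituent torsions, core frozen.

    Runs ``cycles`` cycles, each a geometric temperature ramp from
    ``t_start`` to ``t_end`` K with Metropolis-accepted random single-torsion
    moves of uniform +-``move_size`` degrees. ``torsions`` restricts the
    move set (default: all rotatable torsions). The best pose seen is
    tracked and returned, so the returned energy never exceeds the input's.
    """
    p = p or ForceFieldParams()
    torsions = list(torsions if torsions is not None
                    else pose.ligand.rotatable_torsions)
    scorer = LigandScorer(receptor, p)

    def energy(coords):
        return scorer.score(pose.ligand, coords).total

    if not torsions:
        out = pose.copy()
        out.score = scorer.score(pose.ligand, pose.coords)
        return out

    rng = np.random.default_rng(seed)
    current = pose.coords.copy()
    e_current = energy(current)
    best, e_best = current.copy(), e_current
    for _ in range(cycles):
        for step in range(steps_per_cycle):
            frac = step / max(steps_per_cycle - 1, 1)
            temp = t_start * (t_end / t_start) ** frac
            tors = torsions[rng.integers(len(torsions))]
            delta = rng.uniform(-move_size, move_size)
            trial = rotate_torsion(current, pose.ligand, tors, delta)
            e_trial = energy(trial)
            if (e_trial <= e_current
                    or rng.uniform() < np.exp(-(e_trial - e_current)
                                              / (KB * temp))):
                current, e_current = trial, e_trial
                if e_current < e_best:
                    best, e_best = current.copy(), e_current
    out = LigandPose(pose.ligand, best, stage=pose.stage)
    out.score = scorer.score(pose.ligand, best)
    return out
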