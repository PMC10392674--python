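"""Simplified all-atom interaction energy.

Three terms, in kcal/mol: a 12-6 Lennard-Jones with Lorentz-Berthelot
combination, a screened Coulomb term q1*q2*332.06/(eps(r)*r) with either a
constant or a distance-dependent dielectric eps(r) = eps0*r, and a
directional 12-10 hydrogen-bond well scaled by cos^2 of the D-H...A
deviation from linearity. All terms are switched smoothly to zero over the
last ``switch_width`` Angstrom before the nonbonded cutoff.

This is a self-contained scoring function for ranking synthetic helix
bundles and toy ligand poses, not a transferable force field; absolute
energies are not comparable to any published potential.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import residues as rt

__all__ = [
    "ForceFieldParams", "EnergyBreakdown", "pair_atom_energy", "hbond_energy",
    "interhelical_energy", "bundle_energy", "ligand_site_energy", "LigandScorer",
]

COULOMB_CONSTANT = 332.06  # kcal*A/(mol*e^2)

#: per-class (rmin_half [A], epsilon [kcal/mol]); classes keyed by element
DEFAULT_LJ = {
    "C": (1.95, 0.070),
    "N": (1.85, 0.170),
    "O": (1.70, 0.210),
    "S": (2.00, 0.250),
    "H": (0.75, 0.030),
}


@dataclass
class ForceFieldParams:
    lj: dict = field(default_factory=lambda: dict(DEFAULT_LJ))
    hb_rmin: float = 2.9
    hb_eps: float = 4.0
    dielectric_model: str = "distance"   # "distance": eps(r)=eps0*r, or "constant"
    eps0: float = 4.0
    nonbond_cutoff: float = 10.0
    switch_width: float = 1.0
    clash_cap: float | None = None       # per-pair LJ cap (used during repacking)

    def __post_init__(self):
        if self.nonbond_cutoff <= 0:
            raise ValueError("cutoff must be positive")
        for cls, (rh, eps) in self.lj.items():
            if eps < 0:
                raise ValueError(f"negative epsilon for class {cls!r}")

    def lj_params(self, vdw_class: str):
        try:
            return self.lj[vdw_class]
        except KeyError:
            raise KeyError(f"unknown vdw class {vdw_class!r}") from None

    @classmethod
    def from_file(cls, path) -> "ForceFieldParams":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {}
        if "lj" in data:
            kwargs["lj"] = {k: tuple(v) for k, v in data["lj"].items()}
        for key in ("hb_rmin", "hb_eps", "dielectric_model", "eps0",
                    "nonbond_cutoff", "switch_width", "clash_cap"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)


@dataclass
class EnergyBreakdown:
    vdw: float = 0.0
    coulomb: float = 0.0
    hbond: float = 0.0

    @property
    def total(self) -> float:
        return self.vdw + self.coulomb + self.hbond

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(self.vdw + other.vdw,
                               self.coulomb + other.coulomb,
                               self.hbond + other.hbond)


# ---------------------------------------------------------------------------
# flattened atom arrays

class AtomArrays:
    """Structure-of-arrays view over a residue list or a ligand."""

    def __init__(self, coords, charges, rmin_half, eps, labels,
                 donors, acceptors):
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(charges, dtype=float)
        self.rmin_half = np.asarray(rmin_half, dtype=float)
        self.eps = np.asarray(eps, dtype=float)
        self.labels = labels                     # list of (residue key, atom name)
        self.donors = donors                     # list of (heavy_idx, h_idx)
        self.acceptors = np.asarray(acceptors, dtype=int)

    def __len__(self):
        return len(self.coords)

    @classmethod
    def from_residues(cls, residues, params: ForceFieldParams,
                      atom_filter=None) -> "AtomArrays":
        coords, charges, rh, ep, labels = [], [], [], [], []
        donors, acceptors = [], []
        heavy_index = {}
        for res in residues:
            key = (res.chain, res.index)
            for a in res.atoms:
                if atom_filter is not None and not atom_filter(res, a):
                    continue
                i = len(coords)
                coords.append(a.coord)
                charges.append(a.partial_charge)
                r_, e_ = params.lj_params(a.vdw_class)
                rh.append(r_)
                ep.append(e_)
                labels.append((key, a.name))
                heavy_index[(key, a.name)] = i
                if a.name in rt.ACCEPTOR_NAMES and a.element == "O":
                    acceptors.append(i)
                if a.name in rt.DONOR_OF_HYDROGEN:
                    heavy_name = rt.DONOR_OF_HYDROGEN[a.name]
                    j = heavy_index.get((key, heavy_name))
                    if j is not None:
                        donors.append((j, i))
        return cls(coords, charges, rh, ep, labels, donors, acceptors)

    @classmethod
    def from_ligand(cls, ligand, coords, params: ForceFieldParams) -> "AtomArrays":
        coords = np.asarray(coords, dtype=float)
        charges = [a.partial_charge for a in ligand.atoms]
        rh, ep = [], []
        for a in ligand.atoms:
            r_, e_ = params.lj_params(a.vdw_class)
            rh.append(r_)
            ep.append(e_)
        labels = [(("LIG", 1), a.name) for a in ligand.atoms]
        return cls(coords, charges, rh, ep, labels,
                   ligand.donor_pairs(), ligand.acceptor_indices())


# ---------------------------------------------------------------------------
# pairwise terms

def _switch(r: np.ndarray, cutoff: float, width: float) -> np.ndarray:
    """Smoothstep from 1 at (cutoff - width) to 0 at cutoff."""
    s = np.clip((cutoff - r) / width, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def _nonbonded_matrices(r, qq, rmin, eps, p: ForceFieldParams, cap=None):
    r = np.maximum(r, 0.05)
    in_range = r < p.nonbond_cutoff
    sw = _switch(r, p.nonbond_cutoff, p.switch_width) * in_range
    x = (rmin / r) ** 6
    lj = eps * (x * x - 2.0 * x)
    if p.dielectric_model == "distance":
        coul = COULOMB_CONSTANT * qq / (p.eps0 * r * r)
    else:
        coul = COULOMB_CONSTANT * qq / (p.eps0 * r)
    if cap is not None:
        # keep a capped repulsion from being outweighed by the diverging
        # attraction of an overlapping +/- pair during placement
        lj = np.minimum(lj, cap)
        coul = np.clip(coul, -cap, cap)
    return lj * sw, coul * sw


def nonbonded_energy(a: AtomArrays, b: AtomArrays, p: ForceFieldParams,
                     cap=None):
    """Summed (vdw, coulomb) between two disjoint atom sets."""
    if len(a) == 0 or len(b) == 0:
        return 0.0, 0.0
    r = cdist(a.coords, b.coords)
    qq = np.outer(a.charges, b.charges)
    rmin = a.rmin_half[:, None] + b.rmin_half[None, :]
    eps = np.sqrt(np.outer(a.eps, b.eps))
    cap = cap if cap is not None else p.clash_cap
    lj, coul = _nonbonded_matrices(r, qq, rmin, eps, p, cap)
    return float(lj.sum()), float(coul.sum())


def _hb_one_direction(donor_arrays: AtomArrays, acceptor_arrays: AtomArrays,
                      p: ForceFieldParams, cap=None) -> float:
    acc = acceptor_arrays.acceptors
    if len(acc) == 0 or not donor_arrays.donors:
        return 0.0
    acc_coords = acceptor_arrays.coords[acc]
    total = 0.0
    for heavy_i, h_i in donor_arrays.donors:
        d = donor_arrays.coords[heavy_i]
        h = donor_arrays.coords[h_i]
        r = np.linalg.norm(acc_coords - d, axis=1)
        mask = r < p.nonbond_cutoff
        if not mask.any():
            continue
        hd = d - h
        ha = acc_coords[mask] - h
        cosang = (ha @ hd) / (np.linalg.norm(ha, axis=1) * np.linalg.norm(hd) + 1e-12)
        # D-H...A angle at the hydrogen; 180 degrees is linear
        ang = np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ok = ang >= 90.0
        if not ok.any():
            continue
        rr = np.maximum(r[mask][ok], 0.5)
        x10 = (p.hb_rmin / rr) ** 10
        x12 = (p.hb_rmin / rr) ** 12
        well = p.hb_eps * (5.0 * x12 - 6.0 * x10)
        if cap is not None:
            well = np.minimum(well, cap)
        dev = np.deg2rad(180.0 - ang[ok])
        total += float(np.sum(well * np.cos(dev) ** 2
                              * _switch(rr, p.nonbond_cutoff, p.switch_width)))
    return total


def hbond_pair_energy(a: AtomArrays, b: AtomArrays, p: ForceFieldParams,
                      cap=None) -> float:
    """Hydrogen-bond energy, donors of each side against acceptors of the other."""
    cap = cap if cap is not None else p.clash_cap
    return (_hb_one_direction(a, b, p, cap) + _hb_one_direction(b, a, p, cap))


# scalar convenience forms -------------------------------------------------

def pair_atom_energy(a1, a2, p: ForceFieldParams) -> EnergyBreakdown:
    """LJ + Coulomb between two atoms (no hydrogen-bond term)."""
    r = float(np.linalg.norm(a1.coord - a2.coord))
    rh1, e1 = p.lj_params(a1.vdw_class)
    rh2, e2 = p.lj_params(a2.vdw_class)
    lj, coul = _nonbonded_matrices(
        np.array([[r]]), np.array([[a1.partial_charge * a2.partial_charge]]),
        np.array([[rh1 + rh2]]), np.array([[np.sqrt(e1 * e2)]]), p)
    return EnergyBreakdown(vdw=float(lj[0, 0]), coulomb=float(coul[0, 0]))


def hbond_energy(donor, hydrogen, acceptor, p: ForceFieldParams) -> float:
    """Directional hydrogen-bond energy for one D-H...A triple."""
    r = float(np.linalg.norm(acceptor.coord - donor.coord))
    if r > p.nonbond_cutoff:
        return 0.0
    hd = donor.coord - hydrogen.coord
    ha = acceptor.coord - hydrogen.coord
    cosang = np.dot(ha, hd) / (np.linalg.norm(ha) * np.linalg.norm(hd))
    ang = float(np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0))))
    if ang < 90.0:
        return 0.0
    x10 = (p.hb_rmin / r) ** 10
    x12 = (p.hb_rmin / r) ** 12
    well = p.hb_eps * (5.0 * x12 - 6.0 * x10)
    dev = np.deg2rad(180.0 - ang)
    return float(well * np.cos(dev) ** 2
                 * _switch(np.array(r), p.nonbond_cutoff, p.switch_width))


# ---------------------------------------------------------------------------
# structure-level sums

def interhelical_energy(bundle, i: int, j: int,
                        p: ForceFieldParams | None = None) -> EnergyBreakdown:
    """Interaction energy between helices ``i`` and ``j`` of a bundle."""
    p = p or ForceFieldParams()
    if i == j:
        raise ValueError("need two distinct helices")
    ha = AtomArrays.from_residues(bundle.helix(i).residues, p)
    hb = AtomArrays.from_residues(bundle.helix(j).residues, p)
    return _interaction(ha, hb, p)


def _interaction(a: AtomArrays, b: AtomArrays, p: ForceFieldParams,
                 cap=None) -> EnergyBreakdown:
    vdw, coul = nonbonded_energy(a, b, p, cap=cap)
    hbond = hbond_pair_energy(a, b, p, cap=cap)
    return EnergyBreakdown(vdw=vdw, coulomb=coul, hbond=hbond)


_SIDECHAIN_EXCLUDE = {"N", "CA", "C", "O", "H"}


def bundle_energy(bundle, p: ForceFieldParams | None = None) -> EnergyBreakdown:
    """Sum of all inter-helical energies plus intra-helix side-chain clashes."""
    p = p or ForceFieldParams()
    total = EnergyBreakdown()
    ids = [h.helix_id for h in bundle.helices]
    for ai in range(len(ids)):
        for aj in range(ai + 1, len(ids)):
            total = total + interhelical_energy(bundle, ids[ai], ids[aj], p)
    sc_filter = lambda res, atom: atom.name not in _SIDECHAIN_EXCLUDE
    for h in bundle.helices:
        per_res = [AtomArrays.from_residues([r], p, atom_filter=sc_filter)
                   for r in h.residues]
        for ri in range(len(per_res)):
            for rj in range(ri + 1, len(per_res)):
                if len(per_res[ri]) and len(per_res[rj]):
                    total = total + _interaction(per_res[ri], per_res[rj], p)
    return total


class LigandScorer:
    """Receptor-ligand interaction energy with per-residue decomposition.

    The receptor side is flattened once; poses are then scored by swapping
    in new ligand coordinates, which keeps mass pose scoring cheap.
    """

    def __init__(self, receptor, p: ForceFieldParams | None = None):
        self.params = p or ForceFieldParams()
        self.residues = list(getattr(receptor, "residues", receptor))
        self.arrays = AtomArrays.from_residues(self.residues, self.params)
        # residue slice bookkeeping for the decomposition
        self._res_of_atom = np.empty(len(self.arrays), dtype=int)
        pos = 0
        self._res_keys = []
        for ri, res in enumerate(self.residues):
            n = len(res.atoms)
            self._res_of_atom[pos:pos + n] = ri
            self._res_keys.append((res.chain, res.index, res.name))
            pos += n

    def score(self, ligand, coords, per_residue: bool = False, cap=None):
        p = self.params
        lig = AtomArrays.from_ligand(ligand, coords, p)
        rec = self.arrays
        if len(rec) == 0 or len(lig) == 0:
            empty = pd.DataFrame(
                columns=["chain", "residue", "name", "vdw", "coulomb",
                         "hbond", "total"])
            return (EnergyBreakdown(), empty) if per_residue else EnergyBreakdown()
        r = cdist(rec.coords, lig.coords)
        qq = np.outer(rec.charges, lig.charges)
        rmin = rec.rmin_half[:, None] + lig.rmin_half[None, :]
        eps = np.sqrt(np.outer(rec.eps, lig.eps))
        cap = cap if cap is not None else p.clash_cap
        lj, coul = _nonbonded_matrices(r, qq, rmin, eps, p, cap)
        if not per_residue:
            return EnergyBreakdown(
                vdw=float(lj.sum()), coulomb=float(coul.sum()),
                hbond=hbond_pair_energy(rec, lig, p, cap=cap))
        vdw_per_res = np.bincount(self._res_of_atom, weights=lj.sum(axis=1),
                                  minlength=len(self._res_keys))
        coul_per_res = np.bincount(self._res_of_atom, weights=coul.sum(axis=1),
                                   minlength=len(self._res_keys))
        # hydrogen bonds, attributed per receptor residue
        hb_per_res = np.zeros(len(self._res_keys))
        for ri, res in enumerate(self.residues):
            res_arr = AtomArrays.from_residues([res], p)
            if np.min(cdist(res_arr.coords, lig.coords)) > p.nonbond_cutoff:
                continue
            hb_per_res[ri] = hbond_pair_energy(res_arr, lig, p, cap=cap)
        breakdown = EnergyBreakdown(vdw=float(vdw_per_res.sum()),
                                    coulomb=float(coul_per_res.sum()),
                                    hbond=float(hb_per_res.sum()))
        rows = []
        for ri, (chain, idx, name) in enumerate(self._res_keys):
            tot = vdw_per_res[ri] + coul_per_res[ri] + hb_per_res[ri]
            if tot != 0.0:
                rows.append((chain, idx, name, vdw_per_res[ri],
                             coul_per_res[ri], hb_per_res[ri], tot))
        table = pd.DataFrame(
            rows, columns=["chain", "residue", "name", "vdw", "coulomb",
                           "hbond", "total"])
        return breakdown, table


def ligand_site_energy(receptor, ligand_pose, p: ForceFieldParams | None = None):
    """Total receptor-ligand energy and its per-residue table.

    ``ligand_pose`` must carry ``.ligand`` and ``.coords``. The sum of the
    per-residue rows equals the total breakdown by construction.
    """
    scorer = LigandScorer(receptor, p)
    return scorer.score(ligand_pose.ligand, ligand_pose.coords,
                        per_residue=True)
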