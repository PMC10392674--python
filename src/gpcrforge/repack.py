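"""Rotamer-based side-chain placement and pocket alanization.

Rotamers are a Cartesian grid over the side-chain torsions (default 60
degree step) built on rigid ideal internal geometry. Placement initializes
every mutable residue at its best self-energy rotamer, then runs
deterministic single-residue relaxation sweeps in ascending residue order
until a sweep changes nothing. Rotamer-rotamer and rotamer-environment
energies are precomputed as tables (vectorized over whole rotamer stacks),
rotamers far above the best self energy are pruned, and the per-pair
repulsion is capped at ``CLASH_CAP`` kcal/mol so a single overlap cannot
dominate the combinatorics.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from . import residues as rt
from .core import Residue, build_side_chain
from .forcefield import (AtomArrays, ForceFieldParams, _nonbonded_matrices,
                         _switch)

__all__ = ["Rotamer", "PlacementResult", "generate_rotamers",
           "place_side_chains", "placement_energy", "alanize", "dealanize",
           "rotamer_energy_tables"]

#: per-atom-pair cap on repulsive energy during placement (kcal/mol)
CLASH_CAP = 10.0
#: rotamers with self energy above best + this margin are dropped (kcal/mol)
PRUNE_MARGIN = 25.0

_BACKBONE = ("N", "CA", "C", "O", "H", "OXT")


@dataclass
class Rotamer:
    residue_type: str
    chi_angles: list
    self_energy: float | None = None


@dataclass
class PlacementResult:
    structure: object
    chosen: dict                 # residue key -> Rotamer
    final_energy: float
    sweeps_used: int


def generate_rotamers(residue_type: str, chi_step: float = 60.0):
    """All chi-grid rotamers for a residue type (Ala/Gly: one, chi-less)."""
    if 360.0 % chi_step != 0.0:
        raise ValueError(f"chi_step {chi_step} does not divide 360")
    nchi = rt.n_chi(residue_type)      # raises for unknown types
    if nchi == 0:
        return [Rotamer(residue_type, [])]
    values = np.arange(0.0, 360.0, chi_step)
    grids = np.meshgrid(*([values] * nchi), indexing="ij")
    combos = np.stack([g.ravel() for g in grids], axis=-1)
    return [Rotamer(residue_type, list(c)) for c in combos]


def _residue_key(res) -> tuple:
    return (res.chain, res.index)


def _resolve_mutable(residues, mutable):
    """Map a mixed mutable spec (keys, indices, Residue objects) to keys."""
    keys = []
    for m in mutable:
        if isinstance(m, Residue):
            keys.append(_residue_key(m))
        elif isinstance(m, tuple):
            keys.append(m)
        else:
            matches = [r for r in residues if r.index == int(m)]
            if not matches:
                raise KeyError(f"no residue with index {m}")
            keys.append(_residue_key(matches[0]))
    return keys


class _RotamerStack:
    """All rotamer side-chain conformations of one residue, as arrays."""

    def __init__(self, res, rotamers, p: ForceFieldParams):
        template = rt.SIDE_CHAIN_TEMPLATES[res.name]
        names = [row[0] for row in template]
        self.rotamers = rotamers
        coords = np.empty((len(rotamers), len(names), 3))
        for ri, rot in enumerate(rotamers):
            tmp = copy.deepcopy(res)
            build_side_chain(tmp, rot.chi_angles)
            atom_map = {a.name: a for a in tmp.atoms}
            for ai, name in enumerate(names):
                coords[ri, ai] = atom_map[name].coord
        self.coords = coords
        self.names = names
        self.charges = np.array([rt.charge_of(res.name, n) for n in names])
        element_of = {row[0]: row[1] for row in template}
        lj = [p.lj_params(element_of[n]) for n in names]
        self.rmin_half = np.array([v[0] for v in lj])
        self.eps = np.array([v[1] for v in lj])
        name_idx = {n: i for i, n in enumerate(names)}
        self.donors = [(name_idx[rt.DONOR_OF_HYDROGEN[n]], name_idx[n])
                       for n in names
                       if n in rt.DONOR_OF_HYDROGEN
                       and rt.DONOR_OF_HYDROGEN[n] in name_idx]
        self.acceptors = [i for i, n in enumerate(names)
                          if n in rt.ACCEPTOR_NAMES]

    def subset(self, keep: np.ndarray) -> "_RotamerStack":
        out = copy.copy(self)
        out.coords = self.coords[keep]
        out.rotamers = [self.rotamers[i] for i in np.flatnonzero(keep)]
        return out

    @property
    def n_rot(self):
        return len(self.coords)


def _hb_terms(d_coords, h_coords, a_coords, p, cap):
    """Vectorized hydrogen-bond energy; inputs broadcast to (..., 3)."""
    r = np.linalg.norm(a_coords - d_coords, axis=-1)
    hd = d_coords - h_coords
    ha = a_coords - h_coords
    denom = (np.linalg.norm(ha, axis=-1) * np.linalg.norm(hd, axis=-1) + 1e-12)
    cosang = np.sum(ha * hd, axis=-1) / denom
    ang = np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0)))
    rr = np.maximum(r, 0.5)
    x10 = (p.hb_rmin / rr) ** 10
    x12 = (p.hb_rmin / rr) ** 12
    well = p.hb_eps * (5.0 * x12 - 6.0 * x10)
    if cap is not None:
        well = np.minimum(well, cap)
    dev = np.deg2rad(180.0 - ang)
    e = well * np.cos(dev) ** 2 * _switch(rr, p.nonbond_cutoff, p.switch_width)
    return np.where((ang >= 90.0) & (r < p.nonbond_cutoff), e, 0.0)


def _stack_env_energy(stack: _RotamerStack, env: AtomArrays,
                      p: ForceFieldParams, cap=CLASH_CAP) -> np.ndarray:
    """Energy of each rotamer against a fixed environment, shape (R,)."""
    R, n = stack.coords.shape[:2]
    if n == 0 or len(env) == 0:
        return np.zeros(R)
    flat = stack.coords.reshape(R * n, 3)
    r = cdist(flat, env.coords)
    qq = np.outer(np.tile(stack.charges, R), env.charges)
    rmin = np.tile(stack.rmin_half, R)[:, None] + env.rmin_half[None, :]
    eps = np.sqrt(np.outer(np.tile(stack.eps, R), env.eps))
    lj, coul = _nonbonded_matrices(r, qq, rmin, eps, p, cap)
    out = (lj + coul).reshape(R, n * len(env)).sum(axis=1)
    # rotamer donors -> environment acceptors
    if len(env.acceptors):
        acc = env.coords[env.acceptors]                     # (m, 3)
        for d, h in stack.donors:
            e = _hb_terms(stack.coords[:, d, None, :],
                          stack.coords[:, h, None, :],
                          acc[None, :, :], p, cap)
            out += e.sum(axis=1)
    # environment donors -> rotamer acceptors
    if stack.acceptors:
        acc = stack.coords[:, stack.acceptors, :]           # (R, m, 3)
        for d, h in env.donors:
            e = _hb_terms(env.coords[d][None, None, :],
                          env.coords[h][None, None, :], acc, p, cap)
            out += e.sum(axis=1)
    return out


def _stack_pair_energy(sa: _RotamerStack, sb: _RotamerStack,
                       p: ForceFieldParams, cap=CLASH_CAP) -> np.ndarray:
    """Rotamer-rotamer interaction matrix, shape (Ra, Rb); chunked."""
    Ra, na = sa.coords.shape[:2]
    Rb, nb = sb.coords.shape[:2]
    if na == 0 or nb == 0:
        return np.zeros((Ra, Rb))
    out = np.zeros((Ra, Rb))
    qq = np.outer(sa.charges, sb.charges)[None, None, :, :]
    rmin = (sa.rmin_half[:, None] + sb.rmin_half[None, :])[None, None, :, :]
    eps = np.sqrt(np.outer(sa.eps, sb.eps))[None, None, :, :]
    chunk = max(1, int(4e6 / (Rb * na * nb)))
    for lo in range(0, Ra, chunk):
        hi = min(lo + chunk, Ra)
        diff = (sa.coords[lo:hi, None, :, None, :]
                - sb.coords[None, :, None, :, :])
        r = np.linalg.norm(diff, axis=-1)
        lj, coul = _nonbonded_matrices(r, qq, rmin, eps, p, cap)
        out[lo:hi] = (lj + coul).sum(axis=(2, 3))
    for d, h in sa.donors:
        if sb.acceptors:
            e = _hb_terms(sa.coords[:, None, d, None, :],
                          sa.coords[:, None, h, None, :],
                          sb.coords[None, :, sb.acceptors, :], p, cap)
            out += e.sum(axis=2)
    for d, h in sb.donors:
        if sa.acceptors:
            e = _hb_terms(sb.coords[None, :, d, None, :],
                          sb.coords[None, :, h, None, :],
                          sa.coords[:, None, sa.acceptors, :], p, cap)
            out += e.sum(axis=2)
    return out


def _environment_arrays(residues, keys, p):
    """Everything except the mutable side chains (their backbones stay)."""
    env_residues = []
    for r in residues:
        if _residue_key(r) in keys:
            bb = copy.deepcopy(r)
            bb.atoms = [a for a in bb.atoms
                        if a.name in _BACKBONE or a.name == "CB"]
            env_residues.append(bb)
        else:
            env_residues.append(r)
    return AtomArrays.from_residues(env_residues, p)


def _env_without_own(env: AtomArrays, key):
    """Environment minus the residue's own CA/CB (1-2/1-3 neighbours)."""
    mask = np.array([not (lab[0] == key and lab[1] in ("CA", "CB"))
                     for lab in env.labels])
    new_index = np.cumsum(mask) - 1
    donors = [(int(new_index[d]), int(new_index[h])) for d, h in env.donors
              if mask[d] and mask[h]]
    acceptors = [int(new_index[a]) for a in env.acceptors if mask[a]]
    return AtomArrays(env.coords[mask], env.charges[mask],
                      env.rmin_half[mask], env.eps[mask],
                      [lab for lab, m in zip(env.labels, mask) if m],
                      donors, acceptors)


def rotamer_energy_tables(structure, mutable, p: ForceFieldParams | None = None,
                          chi_step: float = 60.0, extra_context=None,
                          prune_margin: float | None = PRUNE_MARGIN):
    """Precompute self and pairwise rotamer energies for ``mutable`` residues.

    Returns ``(keys, rotamers, self_E, pair_E)``: per-residue rotamer lists
    (pruned to self energy within ``prune_margin`` of the best unless
    ``prune_margin`` is None), self-energy arrays, and pair matrices for
    residue pairs within interaction range. ``extra_context`` (an
    AtomArrays, e.g. a ligand) contributes to every self energy.
    """
    p = p or ForceFieldParams()
    pcap = replace(p, clash_cap=CLASH_CAP)
    residues = list(getattr(structure, "residues", structure))
    keys = _resolve_mutable(residues, mutable)
    by_key = {_residue_key(r): r for r in residues}
    for k in keys:
        res = by_key[k]
        if not res.backbone_complete():
            raise ValueError(
                f"residue {res.name}{res.index} has incomplete backbone")
    env = _environment_arrays(residues, keys, pcap)

    stacks, rotamers, self_E = {}, {}, {}
    for k in keys:
        res = by_key[k]
        stack = _RotamerStack(res, generate_rotamers(res.name, chi_step), pcap)
        energies = _stack_env_energy(stack, _env_without_own(env, k), pcap)
        if extra_context is not None:
            energies = energies + _stack_env_energy(stack, extra_context, pcap)
        if prune_margin is not None and stack.n_rot > 1:
            keep = energies <= energies.min() + prune_margin
            stack = stack.subset(keep)
            energies = energies[keep]
        stacks[k] = stack
        rotamers[k] = stack.rotamers
        self_E[k] = energies

    pair_E = {}
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            ki, kj = keys[i], keys[j]
            ca_i = by_key[ki].atom("CA").coord
            ca_j = by_key[kj].atom("CA").coord
            if np.linalg.norm(ca_i - ca_j) > p.nonbond_cutoff + 14.0:
                continue
            pair_E[(ki, kj)] = _stack_pair_energy(stacks[ki], stacks[kj], pcap)
    return keys, rotamers, self_E, pair_E


def place_side_chains(structure, mutable, p: ForceFieldParams | None = None,
                      max_sweeps: int = 20, chi_step: float = 60.0,
                      extra_context=None,
                      prune_margin: float | None = PRUNE_MARGIN
                      ) -> PlacementResult:
    """Combinatorial side-chain placement over ``mutable`` residues.

    Deterministic: best-self-energy initialization, then greedy
    single-residue sweeps in ascending (chain, index) order; rotamer-energy
    ties break toward the lowest rotamer index.
    """
    p = p or ForceFieldParams()
    out = structure.copy() if hasattr(structure, "copy") else copy.deepcopy(structure)
    keys, rotamers, self_E, pair_E = rotamer_energy_tables(
        out, mutable, p, chi_step, extra_context, prune_margin)
    order = sorted(range(len(keys)), key=lambda i: keys[i])
    current = {k: int(np.argmin(self_E[k])) for k in keys}

    def local_energies(k):
        e = self_E[k].copy()
        for (ka, kb), mat in pair_E.items():
            if ka == k:
                e += mat[:, current[kb]]
            elif kb == k:
                e += mat[current[ka], :]
        return e

    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        changed = False
        for i in order:
            k = keys[i]
            best = int(np.argmin(local_energies(k)))
            if best != current[k]:
                current[k] = best
                changed = True
        if not changed:
            break

    total = sum(self_E[k][current[k]] for k in keys)
    total += sum(mat[current[ka], current[kb]]
                 for (ka, kb), mat in pair_E.items())
    chosen = {}
    residues = list(getattr(out, "residues", out))
    by_key = {_residue_key(r): r for r in residues}
    for k in keys:
        rot = rotamers[k][current[k]]
        rot = Rotamer(rot.residue_type, list(rot.chi_angles),
                      self_energy=float(self_E[k][current[k]]))
        chosen[k] = rot
        build_side_chain(by_key[k], rot.chi_angles)
    return PlacementResult(structure=out, chosen=chosen,
                           final_energy=float(total), sweeps_used=sweeps)


def placement_energy(structure, mutable, p: ForceFieldParams | None = None,
                     extra_context=None) -> float:
    """Recompute the placement objective from built coordinates.

    Sums the current side-chain conformations' self and pairwise energies
    with the same clash cap as placement; used to verify that a
    :class:`PlacementResult`'s reported energy matches its structure.
    """
    p = p or ForceFieldParams()
    pcap = replace(p, clash_cap=CLASH_CAP)
    residues = list(getattr(structure, "residues", structure))
    keys = _resolve_mutable(residues, mutable)
    by_key = {_residue_key(r): r for r in residues}
    env = _environment_arrays(residues, keys, pcap)
    stacks = {}
    for k in keys:
        res = by_key[k]
        chis = [_current_chi(res, i + 1) for i in range(rt.n_chi(res.name))]
        stacks[k] = _RotamerStack(res, [Rotamer(res.name, chis)], pcap)
    total = 0.0
    for k in keys:
        total += float(_stack_env_energy(stacks[k], _env_without_own(env, k),
                                         pcap)[0])
        if extra_context is not None:
            total += float(_stack_env_energy(stacks[k], extra_context, pcap)[0])
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            total += float(_stack_pair_energy(stacks[keys[i]],
                                              stacks[keys[j]], pcap)[0, 0])
    return total


def _current_chi(res, k):
    from .geometry import dihedral
    names = rt.CHI_ATOMS[res.name][k - 1]
    return dihedral(*(res.atom(n).coord for n in names))


# ---------------------------------------------------------------------------
# alanization

def alanize(structure, site_residues):
    """Truncate bulky hydrophobic side chains (I/L/V/F/Y/W) in a site to Ala.

    Truncated residues are renamed ALA for bookkeeping; the original type is
    kept on ``alanized_from`` so :func:`dealanize` can restore it.
    Idempotent; non-hydrophobic site residues are untouched.
    """
    out = structure.copy() if hasattr(structure, "copy") else copy.deepcopy(structure)
    residues = list(getattr(out, "residues", out))
    keys = set(_resolve_mutable(residues, site_residues))
    for r in residues:
        if _residue_key(r) in keys and r.name in rt.ALANIZABLE:
            r.alanized_from = r.name
            r.name = "ALA"
            keep = set(_BACKBONE) | {"CB"}
            r.atoms = [a for a in r.atoms if a.name in keep]
            for a in r.atoms:
                a.partial_charge = rt.charge_of("ALA", a.name)
    return out


def dealanize(structure, p: ForceFieldParams | None = None,
              repack: bool = True, extra_context=None):
    """Restore previously alanized residues (and optionally repack them).

    Returns ``(structure, restored_keys)``; with ``repack`` the restored
    side chains are placed with :func:`place_side_chains` in the context of
    ``extra_context`` (e.g. a bound ligand pose).
    """
    out = structure.copy() if hasattr(structure, "copy") else copy.deepcopy(structure)
    residues = list(getattr(out, "residues", out))
    restored = []
    for r in residues:
        if r.alanized_from:
            r.name = r.alanized_from
            r.alanized_from = None
            build_side_chain(r)   # extended; refined below
            for a in r.atoms:
                a.partial_charge = rt.charge_of(r.name, a.name)
            restored.append(_residue_key(r))
    if repack and restored:
        result = place_side_chains(out, restored, p,
                                   extra_context=extra_context)
        return result.structure, restored
    return out, restored
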