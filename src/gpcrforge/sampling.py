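"""Combinatorial helix-orientation sampling.

The two standard grids mirror the field's two-stage protocol for GPCR
bundle prediction: a coarse axial-rotation stage (12 chi values per helix,
12^7 = 35,831,808 combinations for a 7-helix bundle) and a fine
tilt-plus-rotation stage (3 theta x 5 phi x 5 chi = 75 per helix,
75^7 ~ 1.3e13). Full product spaces are never materialized: each contacting
helix pair is scanned in isolation into a pair-energy table, the product
space is ranked exactly under the pairwise-additive (mean-field) energy by
best-first search, and only the top combinations are rebuilt with
side-chain repacking and full bundle energies. The final ensemble balances
energy and conformational diversity by greedy maximin selection.
"""
from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np

from .core import HelixOrientation, apply_orientation, apply_combo, helix_axis
from .forcefield import ForceFieldParams, interhelical_energy, bundle_energy
from .geometry import rmsd
from .repack import place_side_chains

__all__ = [
    "OrientationGrid", "PairEnergyTable", "RankedCombo",
    "default_bihelix_grid", "default_superbihelix_grid", "grid_combinations",
    "contact_pairs", "pair_energy_scan", "mean_field_rank",
    "rebuild_and_rescore", "diversity_select", "superbihelix_protocol",
]


@dataclass
class OrientationGrid:
    """Per-helix lists of theta, phi and chi values (degrees)."""
    axes: dict  # helix_id -> (thetas, phis, chis)

    def __post_init__(self):
        for h, (thetas, phis, chis) in self.axes.items():
            if not (len(thetas) and len(phis) and len(chis)):
                raise ValueError(f"helix {h}: empty orientation axis")

    @classmethod
    def uniform(cls, helix_ids, thetas, phis, chis) -> "OrientationGrid":
        axes = {h: (list(thetas), list(phis), list(chis)) for h in helix_ids}
        return cls(axes=axes)

    def size(self, helix_id: int) -> int:
        t, p, c = self.axes[helix_id]
        return len(t) * len(p) * len(c)

    def orientations(self, helix_id: int):
        """Ordered orientations: theta slowest, chi fastest."""
        t, p, c = self.axes[helix_id]
        return [HelixOrientation(theta=th, phi=ph, chi=ch)
                for th, ph, ch in itertools.product(t, p, c)]

    @property
    def helix_ids(self):
        return sorted(self.axes)


def default_bihelix_grid(helix_ids=range(1, 8)) -> OrientationGrid:
    """Coarse stage: coupled 30-degree axial rotations, 12 per helix."""
    return OrientationGrid.uniform(helix_ids, [0.0], [0.0],
                                   [30.0 * k for k in range(12)])


def default_superbihelix_grid(helix_ids=range(1, 8)) -> OrientationGrid:
    """Fine stage: theta +-10, phi +-15/+-30, chi +-15/+-30 (75 per helix)."""
    return OrientationGrid.uniform(
        helix_ids, [-10.0, 0.0, 10.0],
        [-30.0, -15.0, 0.0, 15.0, 30.0],
        [-30.0, -15.0, 0.0, 15.0, 30.0])


def grid_combinations(grid: OrientationGrid, n_helices: int | None = None) -> int:
    """Exact size of the orientation product space."""
    ids = grid.helix_ids
    if n_helices is not None:
        ids = ids[:n_helices]
        if len(ids) != n_helices:
            raise ValueError("grid covers fewer helices than requested")
    total = 1
    for h in ids:
        total *= grid.size(h)
    return total


@dataclass
class PairEnergyTable:
    pair: tuple               # (helix_i, helix_j)
    energies: np.ndarray      # (n_orient_i, n_orient_j), kcal/mol

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        if not np.all(np.isfinite(self.energies)):
            raise ValueError(f"non-finite pair energies for {self.pair}")


@dataclass
class RankedCombo:
    indices: dict             # helix_id -> orientation index
    estimated_energy: float
    rebuilt_energy: float | None = None


# ---------------------------------------------------------------------------

def contact_pairs(bundle, cutoff: float = 14.0):
    """Helix pairs whose minimum inter-axial distance is within ``cutoff``.

    Axes are sampled at each residue's projection onto the fitted axis.
    Output is sorted, each pair reported once as (i, j) with i < j.
    """
    samples = {}
    for h in bundle.helices:
        point, direction = helix_axis(h)
        t = (h.ca_coords() - point) @ direction
        samples[h.helix_id] = point + np.outer(t, direction)
    ids = sorted(samples)
    pairs = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            d = np.linalg.norm(
                samples[ids[a]][:, None, :] - samples[ids[b]][None, :, :],
                axis=-1).min()
            if d <= cutoff:
                pairs.append((ids[a], ids[b]))
    return pairs


def pair_energy_scan(bundle, pair, grid: OrientationGrid,
                     p: ForceFieldParams | None = None) -> PairEnergyTable:
    """Scan one helix pair over the orientation grid, helices in isolation.

    Side chains are kept at their input conformation (no repacking at scan
    stage); all other helices are absent.
    """
    p = p or ForceFieldParams()
    i, j = pair
    hi, hj = bundle.helix(i), bundle.helix(j)
    oris_i = grid.orientations(i)
    oris_j = grid.orientations(j)
    transformed_i = [apply_orientation(hi, o) for o in oris_i]
    transformed_j = [apply_orientation(hj, o) for o in oris_j]

    class _TwoHelix:
        def __init__(self, a, b):
            self.helices = [a, b]

        def helix(self, hid):
            for h in self.helices:
                if h.helix_id == hid:
                    return h
            raise KeyError(hid)

    table = np.empty((len(oris_i), len(oris_j)))
    for a, ha in enumerate(transformed_i):
        for b, hb in enumerate(transformed_j):
            table[a, b] = interhelical_energy(_TwoHelix(ha, hb), i, j, p).total
    return PairEnergyTable(pair=(i, j), energies=table)


# ---------------------------------------------------------------------------
# exact mean-field ranking

def _check_connected(tables, helix_ids):
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(helix_ids)
    g.add_edges_from(t.pair for t in tables)
    if not nx.is_connected(g):
        raise ValueError("pair tables do not cover a connected contact graph")


def mean_field_rank(tables, grid: OrientationGrid, top_n: int):
    """Exact top-``top_n`` combinations under the pairwise-additive energy.

    E(c) = sum over tabulated pairs (i,j) of T_ij[c_i, c_j]. Small spaces
    are ranked by dense enumeration; large ones by best-first (A*) search
    with an admissible per-pair lower bound, which yields complete
    assignments in exact nondecreasing energy order. Ranking ties break
    lexicographically on orientation indices.
    """
    ids = grid.helix_ids
    _check_connected(tables, ids)
    sizes = [grid.size(h) for h in ids]
    space = 1
    for s in sizes:
        space *= s
    top_n = min(top_n, space)
    if space <= 2_000_000:
        combos, energies = _dense_rank(tables, ids, sizes, top_n)
    else:
        combos, energies = _astar_rank(tables, ids, sizes, top_n)
    return [RankedCombo(indices=dict(zip(ids, c)), estimated_energy=float(e))
            for c, e in zip(combos, energies)]


def _dense_rank(tables, ids, sizes, top_n):
    pos = {h: k for k, h in enumerate(ids)}
    E = np.zeros(sizes)
    for t in tables:
        i, j = t.pair
        shape = [1] * len(ids)
        shape[pos[i]] = sizes[pos[i]]
        shape[pos[j]] = sizes[pos[j]]
        # broadcast the pair table across the remaining axes
        arr = t.energies
        if pos[i] > pos[j]:
            arr = arr.T
        E = E + arr.reshape(shape)
    flat = E.ravel()
    # stable ordering: energy, then lexicographic flat index
    order = np.lexsort((np.arange(flat.size), flat))[:top_n]
    combos = [np.unravel_index(k, sizes) for k in order]
    return combos, flat[order]


def _astar_rank(tables, ids, sizes, top_n):
    pos = {h: k for k, h in enumerate(ids)}
    pair_list = [(pos[t.pair[0]], pos[t.pair[1]], t.energies) for t in tables]
    # bounds for unassigned pairs
    table_min = [float(e.min()) for (_, _, e) in pair_list]
    row_min = [e.min(axis=1) for (_, _, e) in pair_list]
    col_min = [e.min(axis=0) for (_, _, e) in pair_list]

    n = len(ids)

    def heuristic(prefix):
        k = len(prefix)
        h = 0.0
        for t_idx, (a, b, _e) in enumerate(pair_list):
            if a < k and b < k:
                continue          # already counted in g
            if a < k:             # partner b unassigned: best row entry
                h += float(row_min[t_idx][prefix[a]])
            elif b < k:           # partner a unassigned: best column entry
                h += float(col_min[t_idx][prefix[b]])
            else:                 # both free: table minimum
                h += table_min[t_idx]
        return h

    def g_increment(prefix, value):
        k = len(prefix)
        g = 0.0
        for a, b, e in pair_list:
            if a == k and b < k:
                g += float(e[value, prefix[b]])
            elif b == k and a < k:
                g += float(e[prefix[a], value])
        return g

    heap = []
    counter = itertools.count()
    heapq.heappush(heap, (heuristic(()), next(counter), (), 0.0))
    out_combos, out_energies = [], []
    while heap and len(out_combos) < top_n:
        f, _, prefix, g = heapq.heappop(heap)
        if len(prefix) == n:
            out_combos.append(prefix)
            out_energies.append(g)
            continue
        k = len(prefix)
        for v in range(sizes[k]):
            new_prefix = prefix + (v,)
            ng = g + g_increment(prefix, v)
            heapq.heappush(heap, (ng + heuristic(new_prefix),
                                  next(counter), new_prefix, ng))
    return list(out_combos), np.array(out_energies)


# ---------------------------------------------------------------------------

def combo_orientations(grid: OrientationGrid, combo: RankedCombo) -> dict:
    return {h: grid.orientations(h)[idx] for h, idx in combo.indices.items()}


def _clashing_sidechains(bundle, p: ForceFieldParams, threshold: float):
    """Residues whose current side chain clashes with the rest of the bundle.

    A residue is flagged when the repulsive (vdW) energy of its side-chain
    atoms (beyond CB) against all atoms of other residues exceeds
    ``threshold`` kcal/mol.
    """
    from . import residues as rt
    from .forcefield import AtomArrays, nonbonded_energy
    residues = bundle.residues
    keys = []
    sc_filter = lambda res, atom: atom.name not in ("N", "CA", "C", "O", "H",
                                                    "CB", "OXT")
    for r in residues:
        if rt.n_chi(r.name) == 0:
            continue
        own = AtomArrays.from_residues([r], p, atom_filter=sc_filter)
        if len(own) == 0:
            continue
        rest = AtomArrays.from_residues([x for x in residues if x is not r], p)
        vdw, _ = nonbonded_energy(own, rest, p)
        if vdw > threshold:
            keys.append((r.chain, r.index))
    return keys


def rebuild_and_rescore(bundle, combos, p: ForceFieldParams | None = None,
                        top_k: int | None = None, grid: OrientationGrid = None,
                        repack: str = "clashes", clash_threshold: float = 5.0,
                        repack_types: frozenset | None = None):
    """Apply each ranked combo, repack side chains, and rescore full bundles.

    ``repack`` selects the reoptimization scope: ``"clashes"`` (default)
    relieves only side chains whose repulsive energy against the rest of
    the reoriented bundle exceeds ``clash_threshold``, keeping well-packed
    input rotamers; ``"all"`` re-derives every rotatable side chain;
    ``"none"`` skips repacking. ``repack_types`` optionally restricts
    repacking to the named residue types. Returns the ``top_k``
    (bundle, RankedCombo) pairs sorted by rebuilt total energy.
    """
    from . import residues as rt
    p = p or ForceFieldParams()
    results = []
    for combo in combos:
        oris = combo_orientations(grid, combo)
        rebuilt = apply_combo(bundle, oris)
        if repack == "all":
            mutable = [(r.chain, r.index) for h in rebuilt.helices
                       for r in h.residues if rt.n_chi(r.name) > 0]
        elif repack == "clashes":
            mutable = _clashing_sidechains(rebuilt, p, clash_threshold)
        elif repack == "none":
            mutable = []
        else:
            raise ValueError(f"unknown repack mode {repack!r}")
        if repack_types is not None:
            by_key = {(r.chain, r.index): r for r in rebuilt.residues}
            mutable = [k for k in mutable if by_key[k].name in repack_types]
        if mutable:
            rebuilt = place_side_chains(rebuilt, mutable, p).structure
        energy = bundle_energy(rebuilt, p).total
        results.append((rebuilt, RankedCombo(indices=dict(combo.indices),
                                             estimated_energy=combo.estimated_energy,
                                             rebuilt_energy=float(energy))))
    results.sort(key=lambda x: (x[1].rebuilt_energy,
                                tuple(sorted(x[1].indices.items()))))
    if top_k is not None:
        results = results[:top_k]
    return results


def _backbone_ca(bundle) -> np.ndarray:
    return np.concatenate([h.ca_coords() for h in bundle.helices])


def diversity_select(structures, n: int, energy_window: float = 20.0,
                     rmsd_threshold: float = 2.0, rmsd_floor: float = 0.01):
    """Greedy maximin energy-and-diversity selection.

    ``structures`` is a list of (bundle, RankedCombo) sorted by energy.
    The best structure is always accepted; afterwards the lowest-energy
    structure whose backbone CA RMSD to every accepted one is at least
    ``rmsd_threshold`` is accepted, considering only structures within
    ``energy_window`` of the best. If fewer than ``n`` qualify the
    threshold is halved until ``n`` are found or it drops below
    ``rmsd_floor`` (duplicate conformations are never returned twice).
    """
    if not structures:
        return []
    ordered = sorted(structures, key=lambda x: x[1].rebuilt_energy
                     if x[1].rebuilt_energy is not None
                     else x[1].estimated_energy)
    best_e = (ordered[0][1].rebuilt_energy
              if ordered[0][1].rebuilt_energy is not None
              else ordered[0][1].estimated_energy)
    window = [s for s in ordered
              if ((s[1].rebuilt_energy if s[1].rebuilt_energy is not None
                   else s[1].estimated_energy) - best_e) <= energy_window]
    cas = [_backbone_ca(s[0]) for s in window]
    accepted = [0]
    threshold = rmsd_threshold
    while len(accepted) < min(n, len(window)) and threshold >= rmsd_floor:
        progressed = False
        for i in range(len(window)):
            if i in accepted:
                continue
            if all(rmsd(cas[i], cas[j]) >= threshold for j in accepted):
                accepted.append(i)
                progressed = True
                if len(accepted) == n:
                    break
        if len(accepted) >= n:
            break
        if not progressed:
            threshold /= 2.0
        # keep trying at the (possibly halved) threshold
        if threshold < rmsd_floor:
            break
    return [window[i] for i in sorted(accepted)]


# ---------------------------------------------------------------------------

@dataclass
class ProtocolLog:
    n_pairs: int = 0
    n_combinations: int = 0
    n_ranked: int = 0
    n_rebuilt: int = 0
    n_selected: int = 0
    stages: list = field(default_factory=list)


def superbihelix_protocol(bundle, grid: OrientationGrid | None = None,
                          p: ForceFieldParams | None = None,
                          top_combos: int = 2000, ensemble_size: int = 25,
                          energy_window: float = 20.0,
                          rmsd_threshold: float = 2.0,
                          contact_cutoff: float = 14.0,
                          rebuild_top: int | None = None):
    """Staged pipeline: pair scans -> exact mean-field ranking -> rebuild
    with repacking -> energy+diversity ensemble selection.

    Returns ``(ensemble, log)`` where ensemble is a list of
    (bundle, RankedCombo). All stage sizes are configurable to desk scale.
    """
    p = p or ForceFieldParams()
    grid = grid or default_superbihelix_grid([h.helix_id for h in bundle.helices])
    log = ProtocolLog()
    pairs = contact_pairs(bundle, cutoff=contact_cutoff)
    log.n_pairs = len(pairs)
    log.stages.append(("pair_scan", len(pairs)))
    tables = [pair_energy_scan(bundle, pair, grid, p) for pair in pairs]
    log.n_combinations = grid_combinations(grid)
    ranked = mean_field_rank(tables, grid, top_combos)
    log.n_ranked = len(ranked)
    log.stages.append(("mean_field_rank", len(ranked)))
    to_rebuild = ranked if rebuild_top is None else ranked[:rebuild_top]
    rebuilt = rebuild_and_rescore(bundle, to_rebuild, p, top_k=None, grid=grid)
    log.n_rebuilt = len(rebuilt)
    log.stages.append(("rebuild", len(rebuilt)))
    ensemble = diversity_select(rebuilt, ensemble_size,
                                energy_window=energy_window,
                                rmsd_threshold=rmsd_threshold)
    log.n_selected = len(ensemble)
    log.stages.append(("diversity_select", len(ensemble)))
    return ensemble, log
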