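"""Geometric detection of hydrogen bonds, salt bridges and contacts.

Criteria are standard geometric defaults (donor-acceptor heavy distance
<= 3.5 A with a D-H...A angle >= 120 degrees for hydrogen bonds; charged
nitrogen to carboxylate/phosphate oxygen <= 4.0 A for salt bridges); both
are configurable and recorded in report headers. Histidine protonation is
never guessed: a positively charged His must be flagged on the residue.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from . import residues as rt

__all__ = ["InteractionRecord", "PersistenceSeries", "detect_hbonds",
           "detect_salt_bridges", "detect_nonpolar_contacts", "hb_network",
           "persistence", "anchor_report"]


@dataclass(frozen=True)
class InteractionRecord:
    partner_a: tuple          # (chain, residue index, residue name, atom)
    partner_b: tuple
    kind: str                 # HB | SB | nonpolar | water-mediated-HB
    distance: float
    angle: float | None = None
    frame: int | None = None

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("interaction distance must be positive")
        if self.kind == "HB" and self.angle is None:
            raise ValueError("HB records carry the D-H...A angle")


@dataclass
class PersistenceSeries:
    spec: dict
    present: list
    @property
    def fraction(self) -> float:
        return float(np.mean(self.present)) if self.present else 0.0


def _residues(structure):
    return list(getattr(structure, "residues", structure))


def _res_id(res):
    return (res.chain, res.index, res.name)


# ---------------------------------------------------------------------------

def _donor_triples(res):
    """(donor_atom, hydrogen_atom) pairs of a residue by naming convention."""
    out = []
    for a in res.atoms:
        heavy_name = rt.DONOR_OF_HYDROGEN.get(a.name)
        if heavy_name and res.has_atom(heavy_name):
            out.append((res.atom(heavy_name), a))
    return out


def _acceptors(res):
    return [a for a in res.atoms
            if a.element == "O" and a.name in rt.ACCEPTOR_NAMES
            or (res.is_water and a.element == "O")]


def detect_hbonds(structure, d_max: float = 3.5, angle_min: float = 120.0,
                  include_waters: bool = False):
    """All inter-residue hydrogen bonds meeting the geometric criteria.

    Donor-acceptor heavy-atom distance <= ``d_max`` and D-H...A angle >=
    ``angle_min``. Pairs within one residue are skipped. Output is ordered
    deterministically by (residue index, atom name) of the donor then the
    acceptor.
    """
    residues = [r for r in _residues(structure)
                if include_waters or not r.is_water]
    best = {}   # (donor id, acceptor id) -> record with the best angle
    for rd in residues:
        for donor, hydrogen in _donor_triples(rd):
            for ra in residues:
                if ra is rd:
                    continue
                for acc in _acceptors(ra):
                    d = float(np.linalg.norm(acc.coord - donor.coord))
                    if d > d_max:
                        continue
                    hd = donor.coord - hydrogen.coord
                    ha = acc.coord - hydrogen.coord
                    cosang = np.dot(ha, hd) / (
                        np.linalg.norm(ha) * np.linalg.norm(hd) + 1e-12)
                    ang = float(np.rad2deg(np.arccos(np.clip(cosang, -1, 1))))
                    if ang < angle_min:
                        continue
                    key = (_res_id(rd), donor.name, _res_id(ra), acc.name)
                    rec = InteractionRecord(
                        partner_a=_res_id(rd) + (donor.name,),
                        partner_b=_res_id(ra) + (acc.name,),
                        kind="HB", distance=d, angle=ang)
                    if key not in best or ang > best[key].angle:
                        best[key] = rec
    records = sorted(best.values(),
                     key=lambda r: (r.partner_a[1], r.partner_a[3],
                                    r.partner_b[1], r.partner_b[3]))
    return records


def _positive_atoms(res):
    names = rt.POSITIVE_GROUP_ATOMS.get(res.name, ())
    atoms = [a for a in res.atoms if a.name in names]
    if res.name == "HIS" and res.his_charged:
        atoms += [a for a in res.atoms if a.name in rt.HIS_CHARGED_ATOMS]
    atoms += [a for a in res.atoms if a.formal_charge > 0]
    return atoms


def _negative_atoms(res):
    names = rt.NEGATIVE_GROUP_ATOMS.get(res.name, ())
    atoms = [a for a in res.atoms if a.name in names]
    atoms += [a for a in res.atoms
              if a.name.startswith(("OP", "O1P", "O2P", "O3P"))]
    atoms += [a for a in res.atoms if a.formal_charge < 0]
    # dedupe while keeping order
    seen, out = set(), []
    for a in atoms:
        if id(a) not in seen:
            seen.add(id(a))
            out.append(a)
    return out


def detect_salt_bridges(structure, d_max: float = 4.0):
    """Charged-group nitrogen/oxygen contacts within ``d_max`` A.

    One record per residue pair, at the minimum N-O distance over the two
    charged groups.
    """
    residues = _residues(structure)
    records = []
    for i, rp in enumerate(residues):
        pos = _positive_atoms(rp)
        if not pos:
            continue
        for rn in residues:
            if rn is rp:
                continue
            neg = _negative_atoms(rn)
            if not neg:
                continue
            best = None
            for ap in pos:
                for an in neg:
                    d = float(np.linalg.norm(ap.coord - an.coord))
                    if d <= d_max and (best is None or d < best[0]):
                        best = (d, ap.name, an.name)
            if best:
                records.append(InteractionRecord(
                    partner_a=_res_id(rp) + (best[1],),
                    partner_b=_res_id(rn) + (best[2],),
                    kind="SB", distance=best[0]))
    records.sort(key=lambda r: (r.partner_a[1], r.partner_b[1]))
    return records


def detect_nonpolar_contacts(structure, d_max: float = 4.5):
    """Carbon-carbon side-chain contacts within ``d_max`` A (one per pair)."""
    residues = _residues(structure)
    backbone = {"N", "CA", "C", "O", "H"}
    records = []
    for i, ra in enumerate(residues):
        ca = [a for a in ra.atoms if a.element == "C" and a.name not in backbone]
        if not ca:
            continue
        for rb in residues[i + 1:]:
            cb = [a for a in rb.atoms
                  if a.element == "C" and a.name not in backbone]
            if not cb:
                continue
            dmin, pair = None, None
            for x in ca:
                for y in cb:
                    d = float(np.linalg.norm(x.coord - y.coord))
                    if d <= d_max and (dmin is None or d < dmin):
                        dmin, pair = d, (x.name, y.name)
            if dmin is not None:
                records.append(InteractionRecord(
                    partner_a=_res_id(ra) + (pair[0],),
                    partner_b=_res_id(rb) + (pair[1],),
                    kind="nonpolar", distance=dmin))
    return records


# ---------------------------------------------------------------------------

def hb_network(structure, seed_residue, waters=None,
               allow_water_bridge: bool = False, d_max: float = 3.5,
               angle_min: float = 120.0) -> nx.Graph:
    """Hydrogen-bond network reachable from ``seed_residue``.

    Breadth-first expansion over direct hydrogen bonds; with
    ``allow_water_bridge``, residue-water-residue chains whose both legs
    satisfy the criteria appear as single ``water-mediated-HB`` edges.
    Water legs lacking hydrogens are accepted on the distance criterion
    alone. Nodes are (chain, index, name) residue identifiers.
    """
    residues = _residues(structure)
    waters = _residues(waters) if waters is not None else [
        r for r in residues if r.is_water]
    protein = [r for r in residues if not r.is_water]
    direct = detect_hbonds(protein, d_max, angle_min)
    edges = {}
    for rec in direct:
        a, b = rec.partner_a[:3], rec.partner_b[:3]
        key = tuple(sorted((a, b)))
        edges.setdefault(key, rec)
    if allow_water_bridge and waters:
        # water legs: distance-only when the water has no hydrogens
        for w in waters:
            wo = next((a for a in w.atoms if a.element == "O"), None)
            if wo is None:
                continue
            linked = []
            for r in protein:
                partners = ([a for a, _ in _donor_triples(r)] + _acceptors(r))
                dmin = min((float(np.linalg.norm(a.coord - wo.coord))
                            for a in partners), default=np.inf)
                if dmin <= d_max:
                    linked.append((r, dmin))
            for i in range(len(linked)):
                for j in range(i + 1, len(linked)):
                    a = _res_id(linked[i][0])
                    b = _res_id(linked[j][0])
                    key = tuple(sorted((a, b)))
                    if key not in edges:
                        edges[key] = InteractionRecord(
                            partner_a=a + ("H2O",), partner_b=b + ("H2O",),
                            kind="water-mediated-HB",
                            distance=max(linked[i][1], linked[j][1]),
                            angle=180.0)
    g_all = nx.Graph()
    for (a, b), rec in edges.items():
        g_all.add_edge(a, b, record=rec, kind=rec.kind)
    seed = _res_id(seed_residue) if hasattr(seed_residue, "atoms") else tuple(seed_residue)
    out = nx.Graph()
    out.add_node(seed)
    if seed in g_all:
        component = nx.node_connected_component(g_all, seed)
        out = g_all.subgraph(component).copy()
    return out


# ---------------------------------------------------------------------------

def _match_partner(rec_partner, spec_partner):
    """spec partner: residue index, (chain, index) or (chain, index, name)."""
    if isinstance(spec_partner, int):
        return rec_partner[1] == spec_partner
    spec_partner = tuple(spec_partner)
    return rec_partner[:len(spec_partner)] == spec_partner


def _detect(kind, structure, **kw):
    if kind == "HB":
        return detect_hbonds(structure, **kw)
    if kind == "SB":
        return detect_salt_bridges(structure, **kw)
    if kind == "nonpolar":
        return detect_nonpolar_contacts(structure, **kw)
    raise ValueError(f"unknown interaction kind {kind!r}")


def persistence(frames, spec: dict, **detector_kwargs) -> PersistenceSeries:
    """Per-frame presence of one interaction over an ordered frame series.

    ``spec``: {"kind": "HB"|"SB"|"nonpolar", "partner_a": ..., "partner_b":
    ...} with partners given as residue index, (chain, index) or
    (chain, index, name). The fraction is the mean presence.
    """
    present = []
    for frame in frames:
        records = _detect(spec["kind"], frame, **detector_kwargs)
        hit = any(
            (_match_partner(r.partner_a, spec["partner_a"])
             and _match_partner(r.partner_b, spec["partner_b"]))
            or (_match_partner(r.partner_a, spec["partner_b"])
                and _match_partner(r.partner_b, spec["partner_a"]))
            for r in records)
        present.append(bool(hit))
    return PersistenceSeries(spec=dict(spec), present=present)


def anchor_report(complex_structure, groups: dict, frames=None,
                  hb_kwargs=None, sb_kwargs=None) -> pd.DataFrame:
    """Salt-bridge/hydrogen-bond records crossing named group boundaries.

    ``groups`` maps a group name (e.g. "ICL1", "Galpha5") to a set of
    residue indices or (chain, index) pairs. For every group, all SB and HB
    records with exactly one partner inside the group are reported with
    their distances; if ``frames`` is given a persistence fraction is added
    per record.
    """
    hb_kwargs = hb_kwargs or {}
    sb_kwargs = sb_kwargs or {}
    records = (detect_salt_bridges(complex_structure, **sb_kwargs)
               + detect_hbonds(complex_structure, **hb_kwargs))

    def in_group(partner, members):
        return any(_match_partner(partner, m) for m in members)

    rows = []
    for gname, members in groups.items():
        members = list(members)
        for rec in records:
            a_in = in_group(rec.partner_a, members)
            b_in = in_group(rec.partner_b, members)
            if a_in == b_in:
                continue
            row = {
                "group": gname, "kind": rec.kind,
                "partner_a": "{}:{}{}/{}".format(*rec.partner_a),
                "partner_b": "{}:{}{}/{}".format(*rec.partner_b),
                "distance": rec.distance,
            }
            if frames is not None:
                series = persistence(frames, {
                    "kind": rec.kind,
                    "partner_a": rec.partner_a[:2],
                    "partner_b": rec.partner_b[:2]},
                    **(sb_kwargs if rec.kind == "SB" else hb_kwargs))
                row["persistence"] = series.fraction
            rows.append(row)
    columns = ["group", "kind", "partner_a", "partner_b", "distance"]
    if frames is not None:
        columns.append("persistence")
    return pd.DataFrame(rows, columns=columns)
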