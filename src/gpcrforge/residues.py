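"""Amino-acid side-chain templates, partial charges and donor/acceptor maps.

Side chains are built from internal coordinates (NeRF) relative to the
backbone.  Each template entry places one atom from three previously placed
reference atoms; torsions are either fixed or tied to a rotatable chi angle
(optionally with a constant offset, e.g. the second branch of Leu CD2).

The residue alphabet is deliberately small: the types needed for synthetic
transmembrane bundles and pocket fixtures (plus the six alanizable
hydrophobics I/L/V/F/Y/W).  Unknown types are rejected loudly.
"""
from __future__ import annotations

ONE_TO_THREE = {
    "A": "ALA", "G": "GLY", "S": "SER", "T": "THR", "V": "VAL",
    "L": "LEU", "I": "ILE", "F": "PHE", "Y": "TYR", "W": "TRP",
    "D": "ASP", "E": "GLU", "K": "LYS", "M": "MET",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

#: residue types whose side chain is truncated to Cbeta during pocket alanization
ALANIZABLE = frozenset({"ILE", "LEU", "VAL", "PHE", "TYR", "TRP"})

# chi angle definitions (atom name quadruples), in rotation order
CHI_ATOMS = {
    "ALA": [],
    "GLY": [],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
}

# template rows: (name, element, (ref_a, ref_b, ref_c), bond, angle, torsion)
# torsion is a float (fixed, degrees) or ("chi", k, offset) meaning chi_k+offset.
SIDE_CHAIN_TEMPLATES = {
    "ALA": [],
    "GLY": [],
    "SER": [
        ("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, ("chi", 1, 0.0)),
        ("HG", "H", ("CA", "CB", "OG"), 0.960, 109.5, 180.0),
    ],
    "THR": [
        ("OG1", "O", ("N", "CA", "CB"), 1.433, 109.6, ("chi", 1, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -122.0)),
        ("HG1", "H", ("CA", "CB", "OG1"), 0.960, 109.5, 180.0),
    ],
    "VAL": [
        ("CG1", "C", ("N", "CA", "CB"), 1.527, 110.5, ("chi", 1, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.527, 110.5, ("chi", 1, 122.0)),
    ],
    "LEU": [
        ("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.521, 110.5, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.521, 110.5, ("chi", 2, 122.0)),
    ],
    "ILE": [
        ("CG1", "C", ("N", "CA", "CB"), 1.530, 110.4, ("chi", 1, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -122.0)),
        ("CD1", "C", ("CA", "CB", "CG1"), 1.513, 113.8, ("chi", 2, 0.0)),
    ],
    "PHE": [
        ("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.8, ("chi", 2, 180.0)),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 120.8, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 120.8, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0),
    ],
    "TYR": [
        ("CG", "C", ("N", "CA", "CB"), 1.512, 113.9, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.389, 120.8, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.389, 120.8, ("chi", 2, 180.0)),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 121.1, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 121.1, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.378, 119.5, 0.0),
        ("OH", "O", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0),
        ("HH", "H", ("CE1", "CZ", "OH"), 0.960, 109.5, 180.0),
    ],
    "TRP": [
        ("CG", "C", ("N", "CA", "CB"), 1.498, 113.6, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.365, 126.9, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.433, 126.7, ("chi", 2, 180.0)),
        ("NE1", "N", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
        ("HE1", "H", ("CG", "CD1", "NE1"), 1.010, 125.5, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
        ("CE3", "C", ("CD1", "CG", "CD2"), 1.398, 133.9, 180.0),
        ("CZ2", "C", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
        ("CZ3", "C", ("CG", "CD2", "CE3"), 1.382, 118.6, 180.0),
        ("CH2", "C", ("CD2", "CE2", "CZ2"), 1.368, 117.5, 0.0),
    ],
    "ASP": [
        ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", "O", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 0.0)),
        ("OD2", "O", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 180.0)),
    ],
    "GLU": [
        ("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", "O", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3, 0.0)),
        ("OE2", "O", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3, 180.0)),
    ],
    "LYS": [
        ("CG", "C", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.525, 111.3, ("chi", 2, 0.0)),
        ("CE", "C", ("CB", "CG", "CD"), 1.525, 111.3, ("chi", 3, 0.0)),
        ("NZ", "N", ("CG", "CD", "CE"), 1.489, 111.9, ("chi", 4, 0.0)),
        ("HZ1", "H", ("CD", "CE", "NZ"), 1.010, 109.5, 60.0),
        ("HZ2", "H", ("CD", "CE", "NZ"), 1.010, 109.5, 180.0),
        ("HZ3", "H", ("CD", "CE", "NZ"), 1.010, 109.5, 300.0),
    ],
    "MET": [
        ("CG", "C", ("N", "CA", "CB"), 1.530, 114.1, ("chi", 1, 0.0)),
        ("SD", "S", ("CA", "CB", "CG"), 1.807, 112.7, ("chi", 2, 0.0)),
        ("CE", "C", ("CB", "CG", "SD"), 1.789, 100.8, ("chi", 3, 0.0)),
    ],
}

# ---------------------------------------------------------------------------
# partial charges (elementary charges); CHARMM-flavoured but simplified so
# that every residue carries an integer net charge
BACKBONE_CHARGES = {"N": -0.47, "H": 0.31, "CA": 0.16, "C": 0.51, "O": -0.51,
                    "CB": 0.0}

SIDE_CHAIN_CHARGES = {
    "SER": {"CB": 0.23, "OG": -0.66, "HG": 0.43},
    "THR": {"CB": 0.23, "OG1": -0.66, "HG1": 0.43, "CG2": 0.0},
    "TYR": {"CZ": 0.11, "OH": -0.54, "HH": 0.43},
    "TRP": {"NE1": -0.42, "HE1": 0.42},
    "ASP": {"CG": 0.62, "OD1": -0.81, "OD2": -0.81},
    "GLU": {"CD": 0.62, "OE1": -0.81, "OE2": -0.81},
    "LYS": {"CE": 0.31, "NZ": -0.30, "HZ1": 0.33, "HZ2": 0.33, "HZ3": 0.33},
}

# hydrogen -> heavy-atom donor attachment (protein naming convention)
DONOR_OF_HYDROGEN = {
    "H": "N", "HG": "OG", "HG1": "OG1", "HH": "OH", "HE1": "NE1",
    "HZ1": "NZ", "HZ2": "NZ", "HZ3": "NZ",
}

#: heavy-atom acceptor names (element O throughout this alphabet)
ACCEPTOR_NAMES = {"O", "OG", "OG1", "OH", "OD1", "OD2", "OE1", "OE2", "OXT"}

# positively / negatively charged groups for salt-bridge detection
POSITIVE_GROUP_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "NE"),
}
HIS_CHARGED_ATOMS = ("ND1", "NE2")   # only if the residue is flagged charged
NEGATIVE_GROUP_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

FORMAL_CHARGE = {"ASP": -1, "GLU": -1, "LYS": +1}


def charge_of(resname: str, atom_name: str) -> float:
    """Partial charge for a named protein atom (0.0 if untabulated)."""
    sc = SIDE_CHAIN_CHARGES.get(resname, {})
    if atom_name in sc:
        return sc[atom_name]
    return BACKBONE_CHARGES.get(atom_name, 0.0)


def n_chi(resname: str) -> int:
    if resname not in CHI_ATOMS:
        raise KeyError(f"unsupported residue type {resname!r}")
    return len(CHI_ATOMS[resname])
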