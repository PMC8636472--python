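"""Idealized deoxynucleotide templates.

Base heavy atoms are literal planar coordinates in the standard base
reference frame (x, y in the base plane, z = 0; C1' included), the idealized
geometry commonly used for fiber-model building. The sugar-phosphate moiety
is generated programmatically off C1' with standard bond lengths: a pentose
ring approximated as a regular pentagon in the plane spanned by the
glycosidic direction and the base normal, with C5'/O5'/P/OP1/OP2 and O3'
attached at tetrahedral-ish directions. The resulting nucleotide is not
refined — downstream consumers rely only on atom names and counts, base
planarity, and approximate bond lengths, and every builder output is
clash-checked rather than energy-minimized.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

# planar base heavy atoms (x, y, z=0), standard reference frame, Angstrom
_BASE_XY: dict[str, list[tuple[str, float, float]]] = {
    "DG": [
        ("C1'", -2.477, 5.399),
        ("N9", -1.289, 4.551),
        ("C8", 0.023, 4.962),
        ("N7", 0.870, 3.969),
        ("C5", 0.071, 2.833),
        ("C6", 0.424, 1.460),
        ("O6", 1.554, 0.955),
        ("N1", -0.700, 0.641),
        ("C2", -1.999, 1.087),
        ("N2", -2.949, 0.139),
        ("N3", -2.342, 2.364),
        ("C4", -1.265, 3.177),
    ],
    "DA": [
        ("C1'", -2.479, 5.346),
        ("N9", -1.291, 4.498),
        ("C8", 0.024, 4.897),
        ("N7", 0.877, 3.902),
        ("C5", 0.071, 2.771),
        ("C6", 0.369, 1.398),
        ("N6", 1.611, 0.909),
        ("N1", -0.668, 0.532),
        ("C2", -1.912, 1.023),
        ("N3", -2.320, 2.290),
        ("C4", -1.267, 3.124),
    ],
    "DC": [
        ("C1'", -2.477, 5.402),
        ("N1", -1.285, 4.542),
        ("C2", -1.472, 3.158),
        ("O2", -2.628, 2.709),
        ("N3", -0.391, 2.344),
        ("C4", 0.837, 2.868),
        ("N4", 1.875, 2.027),
        ("C5", 1.056, 4.275),
        ("C6", -0.023, 5.068),
    ],
    "DT": [
        ("C1'", -2.481, 5.354),
        ("N1", -1.284, 4.500),
        ("C2", -1.462, 3.135),
        ("O2", -2.562, 2.608),
        ("N3", -0.298, 2.407),
        ("C4", 0.994, 2.897),
        ("O4", 1.944, 2.119),
        ("C5", 1.106, 4.338),
        ("C7", 2.466, 4.961),
        ("C6", -0.024, 5.057),
    ],
}

GLYCOSIDIC_N = {"DG": "N9", "DA": "N9", "DC": "N1", "DT": "N1", "BGM": "N9", "5CM": "N1"}
# ring atom bonded to the glycosidic nitrogen, used for the alignment frame
GLYCOSIDIC_C = {"DG": "C4", "DA": "C4", "DC": "C2", "DT": "C2", "BGM": "C4", "5CM": "C2"}

SUGAR_PHOSPHATE_ATOMS = frozenset(
    ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'"]
)

PURINE_RING_ATOMS = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
PYRIMIDINE_RING_ATOMS = ("N1", "C2", "N3", "C4", "C5", "C6")

_ELEMENT_OVERRIDES = {"BR": "BR", "P": "P", "K": "K"}


def element_of(atom_name: str) -> str:
    name = atom_name.strip().upper()
    if name in _ELEMENT_OVERRIDES:
        return _ELEMENT_OVERRIDES[name]
    for ch in name:
        if ch.isalpha():
            return ch
    return "X"


def ring_atom_names(resname: str) -> tuple[str, ...]:
    if resname in ("DG", "DA", "BGM"):
        return PURINE_RING_ATOMS
    if resname in ("DC", "DT", "5CM"):
        return PYRIMIDINE_RING_ATOMS
    raise KeyError(f"no ring definition for residue {resname!r}")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


@lru_cache(maxsize=None)
def nucleotide_template(resname: str) -> dict[str, np.ndarray]:
    """Full heavy-atom template for one deoxynucleotide, keyed by atom name.

    Atom counts: DG 22, DA 21, DC 19, DT 20 heavy atoms (5'-phosphate form).
    """
    if resname not in _BASE_XY:
        raise KeyError(f"no template for residue {resname!r}")
    atoms: dict[str, np.ndarray] = {
        name: np.array([x, y, 0.0]) for name, x, y in _BASE_XY[resname]
    }
    c1 = atoms["C1'"]
    n_gly = atoms[GLYCOSIDIC_N[resname]]

    # pentose ring: regular pentagon (edge ~1.45 A) in the plane spanned by
    # the glycosidic direction and the base normal, C1' at one vertex
    e1 = _unit(c1 - n_gly)            # in-plane, pointing away from the base
    e2 = np.array([0.0, 0.0, 1.0])    # base normal
    r = 1.45 / (2.0 * np.sin(np.pi / 5.0))
    center = c1 + r * e1
    ring_order = ["C1'", "C2'", "C3'", "C4'", "O4'"]
    for k, name in enumerate(ring_order):
        phi = np.pi + 2.0 * np.pi * k / 5.0
        atoms[name] = center + r * (np.cos(phi) * e1 + np.sin(phi) * e2)
    n_ring = np.cross(e1, e2)         # sugar-ring normal (unit by construction)

    c3, c4 = atoms["C3'"], atoms["C4'"]
    atoms["O3'"] = c3 + 1.42 * _unit((c3 - center) - 0.9 * n_ring)
    atoms["C5'"] = c4 + 1.51 * _unit((c4 - center) + 0.9 * n_ring)
    atoms["O5'"] = atoms["C5'"] + 1.42 * _unit((atoms["C5'"] - c4) + 0.4 * e2)
    d_po = _unit(atoms["O5'"] - atoms["C5'"])
    atoms["P"] = atoms["O5'"] + 1.60 * d_po
    # two phosphate oxygens perpendicular to the O5'->P direction
    perp1 = _unit(np.cross(d_po, n_ring))
    perp2 = _unit(np.cross(d_po, perp1))
    atoms["OP1"] = atoms["P"] + 1.48 * _unit(0.8 * d_po + perp1)
    atoms["OP2"] = atoms["P"] + 1.48 * _unit(0.8 * d_po + perp2)
    return {k: v.copy() for k, v in atoms.items()}


def base_atom_names(resname: str) -> tuple[str, ...]:
    """Heavy-atom names of the base moiety (everything outside sugar-phosphate)."""
    return tuple(n for n, _, _ in _BASE_XY[resname] if n != "C1'")
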