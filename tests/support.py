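"""Shared synthetic test fixtures (generated, not stored)."""

import numpy as np
import pandas as pd

from quadstruct.structure import ATOM_COLUMNS, GQStructure
from quadstruct.templates import element_of, nucleotide_template


def four_strand_fixture(seq="TTGGGGT", chains="ABCD", brominate=None):
    """Synthetic stand-in for a deposited four-strand quadruplex file:
    strands laid out on a grid from idealized templates (no tetrad geometry
    intended; used to exercise editing, not detection)."""
    rmap = {"T": "DT", "G": "DG", "C": "DC", "A": "DA"}
    rows = []
    for ci, ch in enumerate(chains):
        for ri, b in enumerate(seq, start=1):
            resname = rmap[b]
            tmpl = dict(nucleotide_template(resname))
            if brominate and (ch, ri) in brominate:
                resname = "BGM"
                tmpl["BR"] = tmpl["C8"] + np.array([0.0, 0.0, 1.9])
            for name, xyz in tmpl.items():
                p = xyz + np.array([ci * 25.0, (ri - 1) * 8.0, 0.0])
                rows.append((1, ch, ri, resname, name, element_of(name), *p, 1.0))
    return GQStructure(pd.DataFrame(rows, columns=ATOM_COLUMNS))
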