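"""Atomic G-quadruplex models: PDB I/O, editing, tetrad geometry, building.

A :class:`GQStructure` is a flat atom table (pandas DataFrame) with
(model, chain, resseq, resname, atom name, element, x/y/z, occupancy) rows,
read and written as PDB through Biopython. The editing operations reproduce
the kind of manual model surgery used to prepare quadruplex structures for
simulation: deleting and mutating residues, appending 3' residues, fusing
four strands into one oligonucleotide, adding 5-methyl groups at CpG
cytosines, and dropping K+ ions between tetrad planes.

Tetrads are detected geometrically: four guanines form a quartet when each
guanine's Hoogsteen donor atoms (N1, N2) sit within a cutoff of its cyclic
neighbour's acceptor atoms (O6, N7), forming a directed 4-cycle. Structures
edited here are deliberately *not* energy-minimized; ``count_clashes`` and
junction-gap reports flag where refinement would be needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder
from scipy import optimize
from scipy.spatial import cKDTree

from .geometry import apply_rigid, fit_plane, kabsch
from .sequences import OligoSequence, g_tracts
from .templates import (
    GLYCOSIDIC_C,
    GLYCOSIDIC_N,
    SUGAR_PHOSPHATE_ATOMS,
    base_atom_names,
    element_of,
    nucleotide_template,
    ring_atom_names,
)

__all__ = [
    "GQStructure",
    "Tetrad",
    "read_pdb",
    "write_pdb",
    "delete_residues",
    "mutate_base",
    "append_residue_3prime",
    "join_strands",
    "add_methyl_cpg",
    "detect_tetrads",
    "place_interplane_ions",
    "build_ideal_gq",
    "count_clashes",
]

ATOM_COLUMNS = ["model", "chain", "resseq", "resname", "name", "element",
                "x", "y", "z", "occupancy"]

GUANINE_NAMES = {"DG", "BGM", "G"}
NUCLEOTIDE_NAMES = {"DA", "DC", "DG", "DT", "BGM", "5CM"}


class SelectionError(ValueError):
    """A residue/atom selection resolved to nothing."""


class ConnectivityError(ValueError):
    """Required backbone atoms (O3', P) are missing."""


class TemplateError(KeyError):
    """No idealized template for the requested residue type."""


class TopologyError(ValueError):
    """Sequence cannot fold into the requested quadruplex topology."""


class PDBFormatError(ValueError):
    """Malformed or inconsistent PDB content."""


class GQStructure:
    """Atomic model held as a flat atom table.

    Parameters
    ----------
    atoms : pandas.DataFrame
        One row per atom with columns ``model, chain, resseq, resname, name,
        element, x, y, z, occupancy``. Residue order along each chain is
        5'->3' by ascending ``resseq``.
    metadata : dict
        Free-form provenance (edit log, junction records, warnings).
    """

    def __init__(self, atoms: pd.DataFrame, metadata: dict | None = None):
        missing = [c for c in ATOM_COLUMNS if c not in atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns {missing}")
        df = atoms[ATOM_COLUMNS].reset_index(drop=True).copy()
        if not np.isfinite(df[["x", "y", "z"]].to_numpy()).all():
            raise ValueError("non-finite coordinates")
        dup = df.duplicated(subset=["model", "chain", "resseq", "name"])
        if dup.any():
            raise ValueError("duplicate (model, chain, resseq, atom name) keys")
        self.atoms = df
        self.metadata = dict(metadata or {})

    # -- bookkeeping ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def models(self) -> list[int]:
        return sorted(self.atoms["model"].unique())

    @property
    def chains(self) -> list[str]:
        return list(dict.fromkeys(self.atoms["chain"]))

    def model(self, model_no: int | None = None) -> pd.DataFrame:
        if model_no is None:
            model_no = self.models[0]
        return self.atoms[self.atoms["model"] == model_no]

    def coords(self, model_no: int | None = None) -> np.ndarray:
        return self.model(model_no)[["x", "y", "z"]].to_numpy()

    def residues(self, model_no: int | None = None) -> pd.DataFrame:
        """One row per residue: chain, resseq, resname, in atom-table order."""
        df = self.model(model_no)
        return (df[["chain", "resseq", "resname"]]
                .drop_duplicates()
                .reset_index(drop=True))

    def residue_atoms(self, chain: str, resseq: int,
                      model_no: int | None = None) -> pd.DataFrame:
        df = self.model(model_no)
        sub = df[(df["chain"] == chain) & (df["resseq"] == resseq)]
        if sub.empty:
            raise SelectionError(f"no residue {chain}:{resseq}")
        return sub

    def atom_xyz(self, chain: str, resseq: int, name: str,
                 model_no: int | None = None) -> np.ndarray:
        sub = self.residue_atoms(chain, resseq, model_no)
        row = sub[sub["name"] == name]
        if row.empty:
            raise SelectionError(f"no atom {name} in {chain}:{resseq}")
        return row[["x", "y", "z"]].to_numpy()[0]

    def copy(self) -> "GQStructure":
        return GQStructure(self.atoms.copy(), dict(self.metadata))

    def sequence(self, chain: str | None = None) -> str:
        """One-letter base sequence of a chain (first model)."""
        res = self.residues()
        if chain is not None:
            res = res[res["chain"] == chain]
        letters = {"DA": "A", "DC": "C", "DG": "G", "DT": "T", "BGM": "G", "5CM": "C"}
        return "".join(letters.get(r, "X") for r in res["resname"] if r in letters)


@dataclass(frozen=True)
class Tetrad:
    """A Hoogsteen G-quartet: 4 guanines in cyclic donor->acceptor order."""

    residues: tuple  # 4 x (chain, resseq)
    centroid: np.ndarray
    normal: np.ndarray
    stack_index: int = 0

    def __post_init__(self) -> None:
        if len(self.residues) != 4:
            raise ValueError("a tetrad has exactly 4 guanines")
        n = np.asarray(self.normal, dtype=float)
        object.__setattr__(self, "normal", n / np.linalg.norm(n))
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))


# ----------------------------------------------------------------------
# PDB interchange (Biopython behind the module surface)
# ----------------------------------------------------------------------

def read_pdb(path: str | Path) -> GQStructure:
    """Read ATOM/HETATM/MODEL records into a GQStructure (heavy + H atoms)."""
    parser = PDBParser(QUIET=True)
    try:
        bio = parser.get_structure("s", str(path))
    except Exception as exc:  # Biopython raises assorted types on bad records
        raise PDBFormatError(f"{path}: {exc}") from exc
    rows = []
    for model in bio:
        for chain in model:
            for res in chain:
                resseq = res.id[1]
                resname = res.get_resname().strip()
                for atom in res:
                    x, y, z = atom.get_coord()
                    rows.append((model.id + 1, chain.id, resseq, resname,
                                 atom.get_name(), (atom.element or "").strip().upper()
                                 or element_of(atom.get_name()),
                                 float(x), float(y), float(z),
                                 float(atom.get_occupancy() or 1.0)))
    if not rows:
        raise PDBFormatError(f"{path}: no atoms parsed")
    return GQStructure(pd.DataFrame(rows, columns=ATOM_COLUMNS),
                       metadata={"source": str(path)})


def _to_bio(structure: GQStructure):
    builder = StructureBuilder()
    builder.init_structure("s")
    for m_i, model_no in enumerate(structure.models):
        builder.init_model(m_i)
        df = structure.model(model_no)
        for chain_id in dict.fromkeys(df["chain"]):
            builder.init_chain(str(chain_id))
            cdf = df[df["chain"] == chain_id]
            for (resseq, resname), rdf in cdf.groupby(["resseq", "resname"], sort=False):
                het = " " if resname in NUCLEOTIDE_NAMES else f"H_{resname}"
                builder.init_seg("    ")
                builder.init_residue(resname, het, int(resseq), " ")
                for _, a in rdf.iterrows():
                    builder.init_atom(a["name"], np.array([a.x, a.y, a.z], dtype=float),
                                      0.0, float(a.occupancy), " ", a["name"],
                                      element=a["element"])
    return builder.get_structure()


def write_pdb(structure: GQStructure, path: str | Path) -> None:
    """Write all models as a (multi-MODEL when needed) PDB file."""
    io = PDBIO()
    io.set_structure(_to_bio(structure))
    io.save(str(path), write_end=True)


# ----------------------------------------------------------------------
# Editing operations
# ----------------------------------------------------------------------

ResidueKey = tuple  # (chain, resseq)


def _resolve(structure: GQStructure, selection: Iterable[ResidueKey]) -> list[ResidueKey]:
    keys = [(str(c), int(r)) for c, r in selection]
    existing = set(map(tuple, structure.residues()[["chain", "resseq"]].itertuples(index=False)))
    resolved = [k for k in keys if k in existing]
    return resolved


def delete_residues(structure: GQStructure,
                    selection: Iterable[ResidueKey]) -> GQStructure:
    """Remove all atoms of the selected (chain, resseq) residues.

    Remaining residue numbering is untouched; renumbering is an explicit
    separate step (see :func:`join_strands`).
    """
    selection = list(selection)
    resolved = _resolve(structure, selection)
    if selection and not resolved:
        raise SelectionError(f"selection resolved to no residues: {selection}")
    if not selection:
        return structure.copy()
    mask = structure.atoms.apply(
        lambda a: (a["chain"], a["resseq"]) in set(resolved), axis=1)
    out = GQStructure(structure.atoms[~mask], dict(structure.metadata))
    out.metadata.setdefault("edits", []).append(
        {"op": "delete_residues", "residues": resolved})
    return out


def _glycosidic_frame(structure: GQStructure, chain: str, resseq: int,
                      resname: str) -> np.ndarray:
    names = ["C1'", GLYCOSIDIC_N[resname], GLYCOSIDIC_C[resname]]
    return np.array([structure.atom_xyz(chain, resseq, n) for n in names])


def mutate_base(structure: GQStructure, residue: ResidueKey,
                target: str) -> GQStructure:
    """Swap the base moiety of one residue for an idealized ``target`` base.

    Sugar-phosphate atoms are untouched; base atoms are replaced by the
    target template aligned on the glycosidic frame (C1', glycosidic N, and
    its bonded ring carbon). ``BGM`` -> ``DG`` simply drops the bromine.
    """
    chain, resseq = str(residue[0]), int(residue[1])
    sub = structure.residue_atoms(chain, resseq)
    resname = sub["resname"].iloc[0]
    if resname not in NUCLEOTIDE_NAMES:
        raise TemplateError(f"{chain}:{resseq} ({resname}) is not a nucleotide")
    if target not in {"DA", "DC", "DG", "DT"}:
        raise TemplateError(f"unsupported mutation target {target!r}")

    df = structure.atoms.copy()
    in_res = (df["chain"] == chain) & (df["resseq"] == resseq)

    if resname == "BGM" and target == "DG":
        # debromination: remove BR, keep every guanine atom in place
        df = df[~(in_res & (df["name"].str.upper() == "BR"))].copy()
        df.loc[(df["chain"] == chain) & (df["resseq"] == resseq), "resname"] = "DG"
        out = GQStructure(df, dict(structure.metadata))
        out.metadata.setdefault("edits", []).append(
            {"op": "mutate_base", "residue": (chain, resseq), "from": resname,
             "to": target})
        return out

    frame_have = _glycosidic_frame(structure, chain, resseq, resname)
    tmpl = nucleotide_template(target)
    frame_tmpl = np.array([tmpl["C1'"], tmpl[GLYCOSIDIC_N[target]],
                           tmpl[GLYCOSIDIC_C[target]]])
    R, t, _ = kabsch(frame_tmpl, frame_have, allow_degenerate=True)

    keep = df[~in_res | df["name"].isin(SUGAR_PHOSPHATE_ATOMS)].copy()
    keep.loc[(keep["chain"] == chain) & (keep["resseq"] == resseq), "resname"] = target
    model_no = int(sub["model"].iloc[0])
    new_rows = []
    for name in base_atom_names(target):
        xyz = apply_rigid(tmpl[name], R, t)
        new_rows.append((model_no, chain, resseq, target, name, element_of(name),
                         *xyz, 1.0))
    new_df = pd.concat([keep, pd.DataFrame(new_rows, columns=ATOM_COLUMNS)],
                       ignore_index=True)
    new_df = new_df.sort_values(["model", "chain", "resseq"], kind="stable")
    out = GQStructure(new_df, dict(structure.metadata))
    out.metadata.setdefault("edits", []).append(
        {"op": "mutate_base", "residue": (chain, resseq), "from": resname,
         "to": target})
    return out


def append_residue_3prime(structure: GQStructure, chain: str,
                          base: str) -> GQStructure:
    """Append an idealized ``base`` nucleotide to the 3' end of ``chain``.

    The new residue's 5' phosphate is placed 1.6 A beyond the terminal O3'
    along the C3'->O3' direction and the template oriented to continue the
    chain; geometry is flagged "unrefined" in metadata.
    """
    res = structure.residues()
    cres = res[res["chain"] == chain]
    if cres.empty:
        raise SelectionError(f"no such chain {chain!r}")
    last = int(cres["resseq"].max())
    try:
        o3 = structure.atom_xyz(chain, last, "O3'")
        c3 = structure.atom_xyz(chain, last, "C3'")
    except SelectionError as exc:
        raise ConnectivityError(f"terminal residue {chain}:{last} lacks O3'/C3'") from exc
    d = (o3 - c3) / np.linalg.norm(o3 - c3)
    target_p = o3 + 1.60 * d

    tmpl = nucleotide_template(base)
    # orient template so its P->O5' bond continues along the strand direction
    a = tmpl["O5'"] - tmpl["P"]
    a = a / np.linalg.norm(a)
    v = np.cross(a, d)
    c = float(np.dot(a, d))
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else -np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    model_no = int(structure.atoms["model"].iloc[0])
    rows = []
    for name, xyz in tmpl.items():
        moved = (xyz - tmpl["P"]) @ R.T + target_p
        rows.append((model_no, chain, last + 1, base, name, element_of(name),
                     *moved, 1.0))
    df = pd.concat([structure.atoms, pd.DataFrame(rows, columns=ATOM_COLUMNS)],
                   ignore_index=True)
    df = df.sort_values(["model", "chain", "resseq"], kind="stable")
    out = GQStructure(df, dict(structure.metadata))
    out.metadata.setdefault("edits", []).append(
        {"op": "append_residue_3prime", "chain": chain, "resseq": last + 1,
         "base": base, "refined": False})
    return out


def join_strands(structure: GQStructure, order: Sequence[str] | None = None) -> GQStructure:
    """Fuse chains (in ``order``) into a single chain renumbered 1..N.

    Each junction bonds the 3' O3' of one strand to the 5' P of the next;
    the O3'-P gap distance for every junction is recorded in
    ``metadata["junctions"]`` (geometry is not minimized).
    """
    order = list(order) if order is not None else structure.chains
    if not order:
        raise SelectionError("no chains to join")
    have = set(structure.chains)
    missing = [c for c in order if c not in have]
    if missing:
        raise SelectionError(f"unknown chains {missing}")

    junctions = []
    for up, down in zip(order[:-1], order[1:]):
        res = structure.residues()
        last_up = int(res[res["chain"] == up]["resseq"].max())
        first_down = int(res[res["chain"] == down]["resseq"].min())
        try:
            o3 = structure.atom_xyz(up, last_up, "O3'")
            p = structure.atom_xyz(down, first_down, "P")
        except SelectionError as exc:
            raise ConnectivityError(
                f"junction {up}->{down}: missing O3' or P") from exc
        junctions.append({"from": (up, last_up), "to": (down, first_down),
                          "gap_A": float(np.linalg.norm(p - o3))})

    new_chain = order[0]
    pieces = []
    counter = 0
    for ch in order:
        cdf = structure.atoms[structure.atoms["chain"] == ch].copy()
        mapping = {}
        for rs in dict.fromkeys(cdf["resseq"]):
            counter += 1
            mapping[rs] = counter
        cdf["resseq"] = cdf["resseq"].map(mapping)
        cdf["chain"] = new_chain
        pieces.append(cdf)
    rest = structure.atoms[~structure.atoms["chain"].isin(order)]
    df = pd.concat(pieces + [rest], ignore_index=True)
    out = GQStructure(df, dict(structure.metadata))
    out.metadata["junctions"] = junctions
    out.metadata.setdefault("edits", []).append(
        {"op": "join_strands", "order": order, "n_junctions": len(junctions)})
    return out


def add_methyl_cpg(structure: GQStructure,
                   residues: Iterable[ResidueKey] | OligoSequence) -> GQStructure:
    """5-methylate CpG cytosines: add the C7 methyl carbon, rename DC -> 5CM.

    The methyl carbon is placed in the base plane 1.50 A from C5, directed
    away from the pyrimidine ring centroid — the geometric reading of
    "a methyl group on the 5th ring atom of every cytosine preceding a
    guanine". ``residues`` may be explicit (chain, resseq) keys or an
    :class:`~quadstruct.sequences.OligoSequence` whose methyl flags are
    mapped onto the first chain's residue order.
    """
    if isinstance(residues, OligoSequence):
        chain = structure.chains[0]
        res = structure.residues()
        cres = res[res["chain"] == chain].reset_index(drop=True)
        if len(cres) != len(residues):
            raise SelectionError(
                f"sequence length {len(residues)} != chain {chain} length {len(cres)}")
        keys = [(chain, int(cres["resseq"][i])) for i in residues.methylated_positions]
    else:
        keys = [(str(c), int(r)) for c, r in residues]
    if not keys:
        return structure.copy()

    df = structure.atoms.copy()
    res = structure.residues()
    new_rows = []
    for chain, resseq in keys:
        sub = structure.residue_atoms(chain, resseq)
        if sub["resname"].iloc[0] != "DC":
            raise SelectionError(f"{chain}:{resseq} is {sub['resname'].iloc[0]}, not DC")
        cres = res[res["chain"] == chain].reset_index(drop=True)
        pos = cres.index[cres["resseq"] == resseq]
        nxt = int(pos[0]) + 1
        if nxt >= len(cres) or cres["resname"][nxt] not in GUANINE_NAMES:
            raise SelectionError(f"{chain}:{resseq} is not in a CpG context")
        ring = np.array([structure.atom_xyz(chain, resseq, n)
                         for n in PYR_RING])
        centroid = ring.mean(axis=0)
        c5 = structure.atom_xyz(chain, resseq, "C5")
        _, normal = fit_plane(ring)
        v = c5 - centroid
        v = v - np.dot(v, normal) * normal      # keep the methyl in-plane
        c7 = c5 + 1.50 * v / np.linalg.norm(v)
        in_res = (df["chain"] == chain) & (df["resseq"] == resseq)
        df.loc[in_res, "resname"] = "5CM"
        model_no = int(sub["model"].iloc[0])
        new_rows.append((model_no, chain, resseq, "5CM", "C7", "C", *c7, 1.0))
    df = pd.concat([df, pd.DataFrame(new_rows, columns=ATOM_COLUMNS)],
                   ignore_index=True).sort_values(
        ["model", "chain", "resseq"], kind="stable")
    out = GQStructure(df, dict(structure.metadata))
    out.metadata.setdefault("edits", []).append(
        {"op": "add_methyl_cpg", "residues": keys})
    return out


PYR_RING = ("N1", "C2", "N3", "C4", "C5", "C6")


# ----------------------------------------------------------------------
# Tetrad detection and ion placement
# ----------------------------------------------------------------------

def detect_tetrads(structure: GQStructure, cutoff: float = 3.5,
                   model_no: int | None = None) -> list[Tetrad]:
    """Find Hoogsteen G-quartets as directed 4-cycles of guanines.

    A directed edge a -> b exists when guanine a's N1 and N2 donors are both
    within ``cutoff`` A of b's O6 and N7 acceptors respectively (heavy-atom
    donor-acceptor distances; hydrogens ignored). Tetrads are returned
    stack-ordered, index 0 at the 5'-most tetrad.
    """
    df = structure.model(model_no)
    gres = df[df["resname"].isin(GUANINE_NAMES)][["chain", "resseq"]].drop_duplicates()
    keys = [(str(c), int(r)) for c, r in gres.itertuples(index=False)]

    needed = {"N1", "N2", "O6", "N7"}
    pos: dict[tuple, dict[str, np.ndarray]] = {}
    for key in keys:
        sub = df[(df["chain"] == key[0]) & (df["resseq"] == key[1])]
        have = {n: sub[sub["name"] == n][["x", "y", "z"]].to_numpy()[0]
                for n in needed if (sub["name"] == n).any()}
        if needed <= set(have):
            pos[key] = have
    keys = list(pos)
    if len(keys) < 4:
        return []

    edges: dict[tuple, list[tuple]] = {k: [] for k in keys}
    for a in keys:
        for b in keys:
            if a == b:
                continue
            d1 = np.linalg.norm(pos[a]["N1"] - pos[b]["O6"])
            d2 = np.linalg.norm(pos[a]["N2"] - pos[b]["N7"])
            if d1 <= cutoff and d2 <= cutoff:
                edges[a].append((b, d1 + d2))

    # directed 4-cycles; dedup by residue set, tie-break by total distance
    best: dict[frozenset, tuple[float, tuple]] = {}
    for a in keys:
        for b, dab in edges[a]:
            for c, dbc in edges[b]:
                if c == a:
                    continue
                for d, dcd in edges[c]:
                    if d in (a, b):
                        continue
                    for e, dde in edges[d]:
                        if e != a:
                            continue
                        quad = frozenset((a, b, c, d))
                        total = dab + dbc + dcd + dde
                        if quad not in best or total < best[quad][0]:
                            best[quad] = (total, (a, b, c, d))

    tetrads = []
    for _, cycle in best.values():
        ring_pts = []
        for chain, resseq in cycle:
            sub = df[(df["chain"] == chain) & (df["resseq"] == resseq)]
            names = ring_atom_names(sub["resname"].iloc[0])
            ring_pts.append(sub[sub["name"].isin(names)][["x", "y", "z"]].to_numpy())
        pts = np.vstack(ring_pts)
        centroid, normal = fit_plane(pts)
        tetrads.append(Tetrad(residues=cycle, centroid=centroid, normal=normal))

    if len(tetrads) > 1:
        cents = np.array([t.centroid for t in tetrads])
        mean = cents.mean(axis=0)
        _, _, Vt = np.linalg.svd(cents - mean)
        axis = Vt[0]
        # orient the axis so the tetrad holding the 5'-most guanine comes first
        five_prime = min(range(len(tetrads)),
                         key=lambda i: min(r[1] for r in tetrads[i].residues))
        proj = (cents - mean) @ axis
        if proj[five_prime] > proj.mean():
            axis, proj = -axis, -proj
        order = np.argsort(proj, kind="stable")
        tetrads = [Tetrad(tetrads[i].residues, tetrads[i].centroid,
                          tetrads[i].normal, stack_index=rank)
                   for rank, i in enumerate(order)]
    return tetrads


def place_interplane_ions(structure: GQStructure,
                          tetrads: Sequence[Tetrad]) -> GQStructure:
    """Drop one K+ between each adjacent tetrad pair (n_tetrads - 1 ions).

    Each ion sits at the midpoint of the two tetrads' O6 centroids, the
    coordination site monovalent cations occupy in quadruplexes.
    """
    if len(tetrads) < 2:
        warnings.warn("fewer than 2 tetrads; no ions placed", stacklevel=2)
        return structure.copy()
    ordered = sorted(tetrads, key=lambda t: t.stack_index)
    df = structure.atoms
    model_no = int(df["model"].iloc[0])
    ion_chain = "I"
    start = int(df[df["chain"] == ion_chain]["resseq"].max()) if (
        df["chain"] == ion_chain).any() else 0

    def _o6_centroid(t: Tetrad) -> np.ndarray:
        pts = [structure.atom_xyz(c, r, "O6") for c, r in t.residues]
        return np.mean(pts, axis=0)

    rows = []
    for i, (t1, t2) in enumerate(zip(ordered[:-1], ordered[1:]), start=1):
        mid = 0.5 * (_o6_centroid(t1) + _o6_centroid(t2))
        rows.append((model_no, ion_chain, start + i, "K", "K", "K", *mid, 1.0))
    out_df = pd.concat([df, pd.DataFrame(rows, columns=ATOM_COLUMNS)],
                       ignore_index=True)
    out = GQStructure(out_df, dict(structure.metadata))
    out.metadata.setdefault("edits", []).append(
        {"op": "place_interplane_ions", "n_ions": len(rows)})
    return out


# ----------------------------------------------------------------------
# Idealized builder
# ----------------------------------------------------------------------

_HOOGSTEEN_TARGET = 2.85  # A, heavy-atom donor-acceptor distance


def _solve_tetrad_pose() -> tuple[float, float, float]:
    """In-plane pose (tx, ty, theta) of one guanine under C4 symmetry.

    Chosen so each guanine's N1/N2 meet the 90 deg-rotated copy's O6/N7 at
    the Hoogsteen target distance, with O6 ringing the axis (C1' outside).
    Deterministic: fixed starting points, best residual wins.
    """
    tmpl = nucleotide_template("DG")
    base = np.array([tmpl[n] for n in ("N1", "N2", "O6", "N7", "C1'")])

    rot90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])

    def place(params: np.ndarray) -> np.ndarray:
        tx, ty, th = params
        c, s = np.cos(th), np.sin(th)
        Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return base @ Rz.T + np.array([tx, ty, 0.0])

    def residual(params: np.ndarray) -> float:
        g0 = place(params)
        g1 = g0 @ rot90.T
        d1 = np.linalg.norm(g0[0] - g1[2])  # N1 -> O6
        d2 = np.linalg.norm(g0[1] - g1[3])  # N2 -> N7
        r = (d1 - _HOOGSTEEN_TARGET) ** 2 + (d2 - _HOOGSTEEN_TARGET) ** 2
        # soft preference: O6 near the axis, C1' far from it
        r += 0.01 * max(0.0, np.linalg.norm(g0[2][:2]) - 3.5) ** 2
        r += 0.01 * max(0.0, 8.0 - np.linalg.norm(g0[4][:2])) ** 2
        return r

    best = None
    for th0 in np.linspace(0.0, 2.0 * np.pi, 8, endpoint=False):
        for t0 in ((4.0, 1.0), (2.0, 3.0), (5.0, -1.0)):
            res = optimize.minimize(residual, x0=[t0[0], t0[1], th0],
                                    method="Nelder-Mead",
                                    options={"xatol": 1e-8, "fatol": 1e-12,
                                             "maxiter": 4000})
            if best is None or res.fun < best.fun:
                best = res
    assert best is not None
    return tuple(best.x)  # type: ignore[return-value]


def build_ideal_gq(sequence: OligoSequence, topology: str = "antiparallel",
                   rise: float = 3.3, twist: float = 30.0) -> GQStructure:
    """Construct an idealized stacked-tetrad quadruplex for a 4-tract sequence.

    The four equal G-tracts supply one guanine per tetrad each; tetrads are
    planar, C4-symmetric, with Hoogsteen donor-acceptor contacts near 2.85 A,
    stacked ``rise`` apart with ``twist`` degrees of helical rotation. Loop
    and flanking residues are placed on outer arcs between the tracts they
    connect. For the antiparallel topology alternate strands run in opposite
    directions (odd tracts contribute guanines in reversed order) and their
    nucleotides are flipped; parallel strands all run the same way. The
    construction is deterministic and unrefined (no minimization).
    """
    if topology not in ("parallel", "antiparallel"):
        raise TopologyError(f"unknown topology {topology!r}")
    seq = str(sequence)
    tracts = g_tracts(seq, min_len=2)
    if len(tracts) < 4:
        raise TopologyError(
            f"need 4 G-tracts of length >= 2, found {len(tracts)} in {seq!r}")
    tracts = tracts[:4]
    lengths = {b - a for a, b in tracts}
    if len(lengths) != 1:
        raise TopologyError(f"G-tracts must have equal length, got {sorted(lengths)}")
    n_tet = lengths.pop()

    tx, ty, th = _solve_tetrad_pose()
    c, s = np.cos(th), np.sin(th)
    Rz0 = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    shift = np.array([tx, ty, 0.0])
    tmpl_g = nucleotide_template("DG")
    # 180 deg about x: flips a whole tetrad level upside down, emulating the
    # syn/anti glycosidic alternation of antiparallel stacks while keeping
    # every within-tetrad Hoogsteen contact intact
    flip = np.diag([1.0, -1.0, -1.0])

    def slot_rot(angle_deg: float) -> np.ndarray:
        a = np.radians(angle_deg)
        return np.array([[np.cos(a), -np.sin(a), 0.0],
                         [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]])

    # seq position -> placed template (dict name->xyz)
    placed: dict[int, tuple[str, dict[str, np.ndarray]]] = {}

    for slot, (a, b) in enumerate(tracts):
        reverse_tract = topology == "antiparallel" and slot % 2 == 1
        for k in range(n_tet):
            seq_pos = a + (n_tet - 1 - k if reverse_tract else k)
            flip_level = topology == "antiparallel" and k % 2 == 1
            R = slot_rot(90.0 * slot + twist * k)
            atoms = {}
            for name, xyz in tmpl_g.items():
                p = xyz @ Rz0.T + shift
                if flip_level:
                    p = p @ flip.T
                p = p @ R.T
                p[2] += rise * k
                atoms[name] = p
            placed[seq_pos] = ("DG", atoms)

    # non-tract residues on outer arcs between the tracts they connect
    in_tract = set()
    for a, b in tracts:
        in_tract.update(range(a, b))
    loop_radius = 16.0
    z_top = rise * (n_tet - 1) + 4.0
    extras = [i for i in range(len(seq)) if i not in in_tract]
    # group consecutive extras
    groups: list[list[int]] = []
    for i in extras:
        if groups and groups[-1][-1] == i - 1:
            groups[-1].append(i)
        else:
            groups.append([i])
    letter_to_res = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
    for group in groups:
        start, stop = group[0], group[-1]
        # angular slots of the flanking tracts
        prev_slot = next((j for j, (a, b) in enumerate(tracts) if b == start), None)
        next_slot = next((j for j, (a, b) in enumerate(tracts) if a == stop + 1), None)
        a0 = 90.0 * (prev_slot if prev_slot is not None else
                     (next_slot - 1 if next_slot else 3))
        a1 = a0 + 90.0
        for m, i in enumerate(group):
            frac = (m + 1) / (len(group) + 1)
            ang = a0 + frac * (a1 - a0)
            resname = letter_to_res[seq[i]]
            tmpl = nucleotide_template(resname)
            R = slot_rot(ang)
            # alternate loop residues above/below mid-height to avoid contacts
            z_off = z_top if (groups.index(group) % 2 == 0) else -4.0
            z_off += 2.2 * (m - (len(group) - 1) / 2.0)
            radial = R @ np.array([1.0, 0.0, 0.0])
            # deterministic push-out: step radially until clear of everything
            # already placed (2.2 A margin > the 2.0 A clash threshold)
            others = np.array([xyz for j, (_, a) in placed.items()
                               if abs(j - i) > 1 for xyz in a.values()])
            for extra_r in np.arange(0.0, 20.1, 0.5):
                offset = np.array([loop_radius + extra_r, 0.0, 0.0])
                atoms = {name: (xyz + offset) @ R.T + np.array([0.0, 0.0, z_off])
                         for name, xyz in tmpl.items()}
                if others.size == 0:
                    break
                pts = np.array(list(atoms.values()))
                dmin = np.min(np.linalg.norm(
                    pts[:, None, :] - others[None, :, :], axis=2))
                if dmin > 2.2:
                    break
            placed[i] = (resname, atoms)

    rows = []
    for i in range(len(seq)):
        resname, atoms = placed[i]
        for name, xyz in atoms.items():
            rows.append((1, "A", i + 1, resname, name, element_of(name), *xyz, 1.0))
    out = GQStructure(pd.DataFrame(rows, columns=ATOM_COLUMNS),
                      metadata={"builder": "build_ideal_gq", "topology": topology,
                                "rise_A": rise, "twist_deg": twist,
                                "n_tetrads": n_tet, "refined": False})
    return out


def count_clashes(structure: GQStructure, threshold: float = 2.0,
                  model_no: int | None = None) -> int:
    """Non-bonded heavy-atom pairs closer than ``threshold`` A.

    Pairs within one residue, or between sequence-adjacent residues of the
    same chain, are treated as bonded context and excluded.
    """
    df = structure.model(model_no)
    df = df[df["element"] != "H"].reset_index(drop=True)
    if len(df) < 2:
        return 0
    xyz = df[["x", "y", "z"]].to_numpy()
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(threshold)
    chains = df["chain"].to_numpy()
    resseqs = df["resseq"].to_numpy()
    n = 0
    for i, j in pairs:
        same_chain = chains[i] == chains[j]
        if same_chain and abs(int(resseqs[i]) - int(resseqs[j])) <= 1:
            continue
        n += 1
    return n
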