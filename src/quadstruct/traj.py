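"""Trajectory stability statistics for G-quadruplex models.

Per-residue RMSD/RMSF after optimal (Kabsch) superposition, and per-tetrad
buckle displacement — the mean unsigned angle between each guanine's base
plane and its tetrad's mean plane, a planarity metric that is zero for an
ideal tetrad and grows as bases tilt out of the quartet plane.

Conventions (the field leaves these open, so they are fixed and documented
here): superposition and statistics use heavy atoms only; the RMSD reference
is frame 0 superposed over tetrad-guanine heavy atoms; RMSF is computed
about the time-averaged structure with one re-superposition pass; quartiles
use linear interpolation; buckle is unsigned by default with a signed
variant available (sign from the projection of the base normal onto the
stack axis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import DegenerateSelectionError, apply_rigid, fit_plane, kabsch
from .structure import (
    GQStructure,
    PDBFormatError,
    Tetrad,
    detect_tetrads,
    read_pdb,
    write_pdb,
)
from .templates import ring_atom_names

__all__ = [
    "Trajectory",
    "TrajStats",
    "kabsch_superpose",
    "per_residue_rmsd",
    "per_residue_rmsf",
    "tetrad_buckle_series",
    "analyze_trajectory",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
]


@dataclass
class Trajectory:
    """Frame stack over a fixed atom roster.

    Parameters
    ----------
    frames : (n_frames, n_atoms, 3) array
        Coordinates per frame, Angstrom.
    topology : GQStructure
        Single-model structure providing names/residues for the roster
        (row order defines the atom roster).
    frame_interval_ps : float
        Time between recorded frames, picoseconds.
    """

    frames: np.ndarray
    topology: GQStructure
    frame_interval_ps: float = 100.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (n_frames, n_atoms, 3)")
        n_top = len(self.topology.model())
        if self.frames.shape[1] != n_top:
            raise ValueError(
                f"frame roster ({self.frames.shape[1]} atoms) does not match "
                f"topology ({n_top} atoms)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ps

    def heavy_mask(self) -> np.ndarray:
        return (self.topology.model()["element"] != "H").to_numpy()

    def residue_keys(self) -> list[tuple[str, int]]:
        res = self.topology.residues()
        return [(str(c), int(r)) for c, r in res[["chain", "resseq"]].itertuples(index=False)]

    def atom_residue_keys(self) -> list[tuple[str, int]]:
        df = self.topology.model()
        return [(str(c), int(r)) for c, r in df[["chain", "resseq"]].itertuples(index=False)]


def _tetrad_guanine_mask(traj: Trajectory, tetrads: Sequence[Tetrad]) -> np.ndarray:
    keys = {r for t in tetrads for r in t.residues}
    atom_keys = traj.atom_residue_keys()
    mask = np.array([k in keys for k in atom_keys]) & traj.heavy_mask()
    return mask


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     selection: np.ndarray | None = None
                     ) -> tuple[np.ndarray, float]:
    """Superpose ``mobile`` onto ``reference`` over ``selection`` (bool mask).

    Returns the fully transformed mobile frame and the RMSD over the
    selection. Proper rotation enforced; fewer than 3 non-collinear selected
    atoms raises :class:`DegenerateSelectionError`.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is None:
        selection = np.ones(len(mobile), dtype=bool)
    sel = np.asarray(selection)
    if sel.dtype != bool:
        mask = np.zeros(len(mobile), dtype=bool)
        mask[sel] = True
        sel = mask
    if sel.sum() == 0:
        raise DegenerateSelectionError("empty selection")
    R, t, rmsd = kabsch(mobile[sel], reference[sel])
    return apply_rigid(mobile, R, t), rmsd


def per_residue_rmsd(traj: Trajectory, reference: np.ndarray | None = None,
                     tetrads: Sequence[Tetrad] | None = None) -> pd.DataFrame:
    """Mean per-residue heavy-atom RMSD after global tetrad superposition.

    Each frame is superposed on the reference (default frame 0) over
    tetrad-guanine heavy atoms; per residue, the RMSD over that residue's
    heavy atoms is computed per frame and averaged over frames. If no
    tetrads can be found the superposition falls back to all heavy atoms
    (with a warning).
    """
    if reference is None:
        reference = traj.frames[0]
    if tetrads is None:
        tetrads = detect_tetrads(traj.topology)
    if tetrads:
        sel = _tetrad_guanine_mask(traj, tetrads)
    else:
        warnings.warn("no tetrads detected; superposing on all heavy atoms",
                      stacklevel=2)
        sel = traj.heavy_mask()

    heavy = traj.heavy_mask()
    atom_keys = np.array(traj.atom_residue_keys(), dtype=object)
    res_keys = traj.residue_keys()
    per_frame = np.empty((traj.n_frames, len(res_keys)))
    res_masks = [np.array([tuple(k) == rk for k in atom_keys]) & heavy
                 for rk in res_keys]
    for f in range(traj.n_frames):
        moved, _ = kabsch_superpose(traj.frames[f], reference, sel)
        diff2 = np.sum((moved - reference) ** 2, axis=1)
        for j, rmask in enumerate(res_masks):
            per_frame[f, j] = np.sqrt(diff2[rmask].mean())
    res = traj.topology.residues()
    return pd.DataFrame({
        "chain": res["chain"], "resseq": res["resseq"], "resname": res["resname"],
        "mean_rmsd_A": per_frame.mean(axis=0),
    })


def per_residue_rmsf(traj: Trajectory, tetrads: Sequence[Tetrad] | None = None,
                     n_iter: int = 1) -> pd.DataFrame:
    """Per-residue RMSF about the time-averaged structure.

    Frames are first superposed on frame 0 (over tetrad-guanine heavy atoms
    when available), the average structure computed, and frames re-superposed
    onto that average ``n_iter`` times. RMSF per atom is
    sqrt(mean_t |r(t) - r_mean|^2); residue RMSF is the unweighted mean over
    the residue's heavy atoms.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if tetrads is None:
        tetrads = detect_tetrads(traj.topology)
    sel = (_tetrad_guanine_mask(traj, tetrads) if tetrads else traj.heavy_mask())

    aligned = np.empty_like(traj.frames)
    ref = traj.frames[0]
    for f in range(traj.n_frames):
        aligned[f], _ = kabsch_superpose(traj.frames[f], ref, sel)
    for _ in range(n_iter):
        mean_struct = aligned.mean(axis=0)
        for f in range(traj.n_frames):
            aligned[f], _ = kabsch_superpose(aligned[f], mean_struct, sel)
    mean_struct = aligned.mean(axis=0)
    atom_rmsf = np.sqrt(np.mean(np.sum((aligned - mean_struct) ** 2, axis=2), axis=0))

    heavy = traj.heavy_mask()
    atom_keys = traj.atom_residue_keys()
    res = traj.topology.residues()
    values = []
    for c, r in res[["chain", "resseq"]].itertuples(index=False):
        rmask = np.array([k == (str(c), int(r)) for k in atom_keys]) & heavy
        values.append(float(atom_rmsf[rmask].mean()))
    return pd.DataFrame({"chain": res["chain"], "resseq": res["resseq"],
                         "resname": res["resname"], "rmsf_A": values})


def _base_ring_indices(traj: Trajectory, chain: str, resseq: int) -> np.ndarray:
    df = traj.topology.model().reset_index(drop=True)
    sub = df[(df["chain"] == chain) & (df["resseq"] == resseq)]
    names = ring_atom_names(sub["resname"].iloc[0])
    idx = sub.index[sub["name"].isin(names)].to_numpy()
    if len(idx) < len(names):
        raise KeyError(f"missing ring atoms in {chain}:{resseq}")
    return idx


def tetrad_buckle_series(traj: Trajectory, tetrads: Sequence[Tetrad] | None = None,
                         signed: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frame, per-tetrad buckle displacement with distribution summary.

    For each frame and tetrad: fit the tetrad mean plane (total least squares
    over the 4 guanine rings' atoms), then take each guanine base-ring
    plane's angle to it, folded into [0, 90] degrees; the tetrad's buckle
    displacement is the mean of the four angles. With ``signed=True`` each
    base angle is signed by the projection of its normal onto the stack axis
    before averaging. Missing ring atoms give NaN for that tetrad (warning).

    Returns
    -------
    series : DataFrame (tetrad, frame, time_ps, buckle_deg)
    summary : DataFrame (tetrad, mean, q1, median, q3) — linear-interpolation
        quartiles, the values a violin-plot annotation would show.
    """
    if tetrads is None:
        tetrads = detect_tetrads(traj.topology)
    if not tetrads:
        raise ValueError("no tetrads supplied or detected")
    ordered = sorted(tetrads, key=lambda t: t.stack_index)

    ring_idx: list[list[np.ndarray] | None] = []
    for t in ordered:
        try:
            ring_idx.append([_base_ring_indices(traj, c, r) for c, r in t.residues])
        except KeyError:
            warnings.warn(f"tetrad {t.stack_index}: missing ring atoms -> NaN",
                          stacklevel=2)
            ring_idx.append(None)

    times = traj.times_ps()
    rows = []
    for f in range(traj.n_frames):
        X = traj.frames[f]
        # stack axis per frame from tetrad centroids (signed variant only)
        if signed and len(ordered) > 1:
            cents = np.array([X[np.concatenate(ri)].mean(axis=0)
                              for ri in ring_idx if ri is not None])
            _, _, Vt = np.linalg.svd(cents - cents.mean(axis=0))
            axis = Vt[0]
        else:
            axis = None
        for t, ri in zip(ordered, ring_idx):
            if ri is None:
                rows.append((t.stack_index, f, times[f], np.nan))
                continue
            all_pts = X[np.concatenate(ri)]
            _, t_normal = fit_plane(all_pts)
            angles = []
            for idx in ri:
                _, b_normal = fit_plane(X[idx])
                cosang = abs(float(np.dot(b_normal, t_normal)))
                ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if signed and axis is not None:
                    sign = np.sign(np.dot(np.cross(t_normal, b_normal), axis))
                    ang *= sign if sign != 0 else 1.0
                angles.append(ang)
            rows.append((t.stack_index, f, times[f], float(np.mean(angles))))
    series = pd.DataFrame(rows, columns=["tetrad", "frame", "time_ps", "buckle_deg"])

    summ_rows = []
    for t_idx, g in series.groupby("tetrad"):
        v = g["buckle_deg"].dropna().to_numpy()
        if v.size == 0:
            summ_rows.append((t_idx, np.nan, np.nan, np.nan, np.nan))
        else:
            q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
            summ_rows.append((t_idx, float(v.mean()), float(q1), float(med), float(q3)))
    summary = pd.DataFrame(summ_rows, columns=["tetrad", "mean", "q1", "median", "q3"])
    return series, summary


@dataclass
class TrajStats:
    """Bundle of the stability statistics for one trajectory."""

    rmsd: pd.DataFrame
    rmsf: pd.DataFrame
    buckle_series: pd.DataFrame
    buckle_summary: pd.DataFrame
    tetrads: list = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Trajectory stability statistics", "-" * 48,
                 f"residues          {len(self.rmsd):>8d}",
                 f"tetrads           {len(self.tetrads):>8d}",
                 f"mean RMSD (A)     {self.rmsd['mean_rmsd_A'].mean():>8.3f}",
                 f"mean RMSF (A)     {self.rmsf['rmsf_A'].mean():>8.3f}"]
        for _, r in self.buckle_summary.iterrows():
            lines.append(
                f"tetrad {int(r['tetrad'])} buckle  mean {r['mean']:.2f} deg  "
                f"[Q1 {r['q1']:.2f}, med {r['median']:.2f}, Q3 {r['q3']:.2f}]")
        return "\n".join(lines)

    def plot(self, ax_pair=None):
        """RMSD/RMSF per residue (twin axes) — the conventional summary figure."""
        import matplotlib.pyplot as plt

        if ax_pair is None:
            _, ax1 = plt.subplots(figsize=(8, 3.2))
            ax2 = ax1.twinx()
        else:
            ax1, ax2 = ax_pair
        x = np.arange(len(self.rmsd))
        ax1.plot(x, self.rmsd["mean_rmsd_A"], "-", color="tab:blue", label="RMSD")
        ax2.plot(x, self.rmsf["rmsf_A"], "--", color="tab:orange", label="RMSF")
        ax1.set_xticks(x)
        ax1.set_xticklabels(self.rmsd["resname"].str[-1], fontsize=7)
        ax1.set_xlabel("residue (5' to 3')")
        ax1.set_ylabel("mean RMSD (A)")
        ax2.set_ylabel("RMSF (A)")
        return ax1, ax2


def analyze_trajectory(traj: Trajectory,
                       tetrads: Sequence[Tetrad] | None = None) -> TrajStats:
    """Run the full stability analysis (RMSD, RMSF, buckle) on a trajectory."""
    if tetrads is None:
        tetrads = detect_tetrads(traj.topology)
    rmsd = per_residue_rmsd(traj, tetrads=tetrads)
    rmsf = per_residue_rmsf(traj, tetrads=tetrads)
    series, summary = tetrad_buckle_series(traj, tetrads=tetrads)
    return TrajStats(rmsd=rmsd, rmsf=rmsf, buckle_series=series,
                     buckle_summary=summary, tetrads=list(tetrads))


# ----------------------------------------------------------------------
# Multi-model PDB interchange
# ----------------------------------------------------------------------

def read_multimodel_pdb(path: str | Path,
                        frame_interval_ps: float = 100.0) -> Trajectory:
    """Read MODEL/ENDMDL blocks as trajectory frames (model order = time)."""
    structure = read_pdb(path)
    models = structure.models
    rosters = []
    frames = []
    for m in models:
        df = structure.model(m)
        rosters.append(list(zip(df["chain"], df["resseq"], df["name"])))
        frames.append(df[["x", "y", "z"]].to_numpy())
    for i, r in enumerate(rosters[1:], start=2):
        if r != rosters[0]:
            raise PDBFormatError(
                f"{path}: model {models[i - 1]} atom roster differs from model "
                f"{models[0]}")
    top = GQStructure(structure.model(models[0]).assign(model=1))
    return Trajectory(np.array(frames), top, frame_interval_ps=frame_interval_ps)


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    top = traj.topology.model().reset_index(drop=True)
    pieces = []
    for f in range(traj.n_frames):
        df = top.copy()
        df["model"] = f + 1
        df[["x", "y", "z"]] = traj.frames[f]
        pieces.append(df)
    write_pdb(GQStructure(pd.concat(pieces, ignore_index=True)), path)
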