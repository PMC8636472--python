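"""Synthetic data generators with known ground truth.

Every generator is a pure function of its arguments including the seed, so
parameter-recovery tests can treat the generator settings as the oracle.
The emulated world: Gaussian-band CD basis spectra carrying the canonical
antiparallel (+295/-260 nm) and parallel (+260/-240 nm) signatures; crowding
titrations as linear AP/P mixtures with iid Gaussian noise; two-state
Boltzmann melt curves at 295 nm over the 25-90 degC instrument range; and
rigid-tetrad / mobile-loop toy trajectories around an idealized quadruplex.

What these do NOT emulate: instrument baseline drift, concentration and
path-length scaling, cooperativity deviations from two-state melting, or any
force-field physics — a green recovery test establishes that the analysis
inverts the stated generative model, not that it reproduces wet-lab data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cd import BasisSet, CDSpectrum
from .melt import MeltCurve, boltzmann
from .structure import GQStructure, detect_tetrads
from .traj import Trajectory

__all__ = [
    "SynthConfig",
    "gen_basis_spectra",
    "gen_titration_series",
    "gen_melt_curve",
    "gen_gq_trajectory",
]

# Gaussian bands (center nm, sd nm, amplitude a.u.) carrying the CD signatures
AP_PEAKS = ((295.0, 9.0, 1.0), (260.0, 11.0, -0.55))
P_PEAKS = ((260.0, 8.0, 1.2), (240.0, 6.0, -0.8))


@dataclass(frozen=True)
class SynthConfig:
    """Shared generator settings; the seed fixes all randomness end-to-end."""

    seed: int = 0
    wavelength_grid: tuple = (220.0, 320.0, 1.0)   # start, stop, step (nm)
    temperature_grid: tuple = (25.0, 90.0, 0.5)    # start, stop, step (degC)
    noise_sd: float = 0.0
    ap_peaks: tuple = AP_PEAKS
    p_peaks: tuple = P_PEAKS
    sigma_tetrad: float = 0.2                      # A
    sigma_loop: float = 1.0                        # A
    n_frames: int = 500

    def wavelengths(self) -> np.ndarray:
        start, stop, step = self.wavelength_grid
        return np.arange(start, stop + step / 2, step)

    def temperatures(self) -> np.ndarray:
        start, stop, step = self.temperature_grid
        return np.arange(start, stop + step / 2, step)


def _gaussian_bands(wl: np.ndarray, peaks: Sequence[tuple]) -> np.ndarray:
    out = np.zeros_like(wl, dtype=float)
    for center, sd, amp in peaks:
        out += amp * np.exp(-0.5 * ((wl - center) / sd) ** 2)
    return out


def gen_basis_spectra(config: SynthConfig = SynthConfig()) -> BasisSet:
    """Reference GQ-AP and GQ-P spectra as sums of Gaussian bands.

    Deterministic (no noise on the basis itself). The grid must cover both
    topologies' diagnostic bands (240-295 nm).
    """
    wl = config.wavelengths()
    centers = [c for c, _, _ in (*config.ap_peaks, *config.p_peaks)]
    if centers and (wl.min() > min(centers) or wl.max() < max(centers)):
        raise ValueError("wavelength grid does not cover the configured peaks")
    ap = CDSpectrum(wl, _gaussian_bands(wl, config.ap_peaks),
                    {"condition": "100 mM KCl", "topology": "GQ-AP"})
    p = CDSpectrum(wl, _gaussian_bands(wl, config.p_peaks),
                   {"condition": "100 mM KCl + 30% PEG", "topology": "GQ-P"})
    return BasisSet(ap=ap, p=p)


def gen_titration_series(basis: BasisSet, fractions: Sequence[float],
                         noise_sd: float = 0.0, seed: int = 0,
                         conditions: Sequence | None = None) -> list[CDSpectrum]:
    """Mixtures f*AP + (1-f)*P with iid Gaussian noise, one per fraction."""
    fr = np.asarray(fractions, dtype=float)
    if np.any((fr < 0) | (fr > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    wl = basis.ap.wavelengths
    out = []
    for i, f in enumerate(fr):
        sig = f * basis.ap.ellipticity + (1.0 - f) * basis.p.ellipticity
        if noise_sd > 0:
            sig = sig + rng.normal(0.0, noise_sd, size=wl.size)
        cond = conditions[i] if conditions is not None else i
        out.append(CDSpectrum(wl, sig, {"condition": cond, "true_ap_fraction": float(f)}))
    return out


def gen_melt_curve(tm: float, width: float = 2.0,
                   plateaus: tuple[float, float] = (0.05, 1.0),
                   grid: np.ndarray | None = None, noise_sd: float = 0.0,
                   seed: int = 0, n_reps: int = 1) -> list[MeltCurve]:
    """Replicate 295 nm melt curves from a four-parameter sigmoid plus noise.

    ``plateaus`` is (lower, upper): the folded (low-T) signal is ``upper``
    and decays to ``lower`` as the quadruplex melts. Noise sd is in signal
    units (use a fraction of the amplitude for "percent noise").
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    T = grid if grid is not None else SynthConfig().temperatures()
    lower, upper = plateaus
    clean = boltzmann(T, lower, upper, tm, width)
    rng = np.random.default_rng(seed)
    curves = []
    for r in range(n_reps):
        sig = clean + (rng.normal(0.0, noise_sd, size=T.size) if noise_sd > 0 else 0.0)
        curves.append(MeltCurve(np.asarray(T, dtype=float), sig,
                                replicate_id=f"rep{r + 1}",
                                metadata={"true_tm": tm, "true_width": width}))
    return curves


def gen_gq_trajectory(ideal: GQStructure, sigma_tetrad: float = 0.2,
                      sigma_loop: float = 1.0, n_frames: int = 500,
                      rigid_motion: bool = False, seed: int = 0,
                      frame_interval_ps: float = 100.0) -> Trajectory:
    """Rigid-tetrad / mobile-loop toy trajectory around an idealized GQ.

    Per frame: an optional random global rotation+translation, then iid
    Gaussian displacement per atom with sigma chosen by residue class —
    ``sigma_tetrad`` for guanines belonging to detected tetrads,
    ``sigma_loop`` for everything else. Residue classes come from
    :func:`~quadstruct.structure.detect_tetrads`, so the generator works for
    any repeat length.
    """
    if sigma_loop < sigma_tetrad or sigma_tetrad < 0:
        raise ValueError("require sigma_loop >= sigma_tetrad >= 0")
    tetrads = detect_tetrads(ideal)
    if not tetrads:
        raise ValueError("structure has no detectable tetrads")
    tet_res = {r for t in tetrads for r in t.residues}
    df = ideal.model()
    atom_sigma = np.array([
        sigma_tetrad if (str(c), int(r)) in tet_res else sigma_loop
        for c, r in df[["chain", "resseq"]].itertuples(index=False)])
    base = df[["x", "y", "z"]].to_numpy()
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, len(base), 3))
    for f in range(n_frames):
        X = base + rng.normal(0.0, 1.0, size=base.shape) * atom_sigma[:, None]
        if rigid_motion:
            # uniform random rotation via QR of a Gaussian matrix
            A = rng.normal(size=(3, 3))
            Q, R = np.linalg.qr(A)
            Q = Q @ np.diag(np.sign(np.diag(R)))
            if np.linalg.det(Q) < 0:
                Q[:, 0] *= -1
            X = X @ Q.T + rng.normal(0.0, 5.0, size=3)
        frames[f] = X
    top = GQStructure(df.assign(model=1), dict(ideal.metadata))
    return Trajectory(frames, top, frame_interval_ps=frame_interval_ps)
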