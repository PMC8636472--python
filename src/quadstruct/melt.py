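"""Two-state thermal melt analysis at 295 nm.

Unfolding of an antiparallel G-quadruplex is followed at 295 nm, where the
GQ-AP band decays as the fold melts. The transition is modelled as a
four-parameter Boltzmann sigmoid

    S(T) = lower + (upper - lower) / (1 + exp((T - Tm) / width))

with the melting temperature Tm at the plateau midpoint. Signal direction
(folding band rising or falling with temperature) is auto-detected from the
end-to-end change; ``width`` is kept positive and the plateau roles absorb
the direction.

Replicate Tm sets are compared with an unpaired two-tailed Student t-test
(equal variance); Welch is available via ``equal_var=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MeltCurve",
    "MeltCurveModel",
    "MeltFitResults",
    "average_replicates",
    "fit_melt_curve",
    "compare_tm",
    "boltzmann",
    "read_melt_csv",
    "write_melt_csv",
]


class GridError(ValueError):
    """Temperature grids are incompatible."""


def boltzmann(T, lower, upper, tm, width):
    """Four-parameter sigmoid; equals the plateau midpoint at T = tm."""
    T = np.asarray(T, dtype=float)
    return lower + (upper - lower) / (1.0 + np.exp((T - tm) / width))


@dataclass(frozen=True)
class MeltCurve:
    """295 nm signal versus temperature for one replicate."""

    temperatures: np.ndarray
    signal: np.ndarray
    replicate_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "signal", s)
        if t.ndim != 1 or s.shape != t.shape:
            raise ValueError("temperatures and signal must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if not (np.isfinite(t).all() and np.isfinite(s).all()):
            raise ValueError("non-finite values in melt curve")

    def __len__(self) -> int:
        return self.temperatures.size


def average_replicates(curves: Sequence[MeltCurve]) -> MeltCurve:
    """Pointwise mean signal over replicates sharing one temperature grid."""
    if not curves:
        raise ValueError("no curves supplied")
    t0 = curves[0].temperatures
    for c in curves[1:]:
        if c.temperatures.shape != t0.shape or not np.allclose(c.temperatures, t0, atol=1e-9):
            raise GridError("replicates must share an identical temperature grid")
    mean = np.mean([c.signal for c in curves], axis=0)
    return MeltCurve(t0, mean, replicate_id="mean",
                     metadata={"n_replicates": len(curves)})


class MeltCurveModel:
    """Boltzmann sigmoid melt model for one curve; ``fit()`` -> results.

    Initialization follows the conventional recipe: plateaus from the
    10th/90th signal percentiles, Tm at the steepest finite-difference
    slope, width = (Tmax - Tmin) / 10.
    """

    def __init__(self, curve: MeltCurve):
        if len(curve) < 8:
            raise ValueError("need at least 8 points to constrain a 4-parameter sigmoid")
        self.curve = curve

    def _initial_guess(self) -> tuple[float, float, float, float]:
        t, s = self.curve.temperatures, self.curve.signal
        lo_q, hi_q = np.percentile(s, [10, 90])
        slope = np.gradient(s, t)
        tm0 = float(t[np.argmax(np.abs(slope))])
        width0 = float((t[-1] - t[0]) / 10.0)
        # boltzmann() decays from `upper` to `lower` as T grows (width > 0):
        # assign plateaus by the observed end-to-end direction.
        if s[-1] >= s[0]:
            lower, upper = hi_q, lo_q
        else:
            lower, upper = lo_q, hi_q
        return float(lower), float(upper), tm0, width0

    def fit(self) -> "MeltFitResults":
        t, s = self.curve.temperatures, self.curve.signal
        p0 = self._initial_guess()
        tmin, tmax = float(t[0]), float(t[-1])
        bounds = ([-np.inf, -np.inf, tmin - 10.0, 1e-6],
                  [np.inf, np.inf, tmax + 10.0, (tmax - tmin) * 10.0])
        converged = True
        try:
            popt, pcov = optimize.curve_fit(boltzmann, t, s, p0=p0, bounds=bounds,
                                            maxfev=20000)
            perr = np.sqrt(np.diag(pcov))
        except (RuntimeError, ValueError):
            converged = False
            popt = np.array(p0)
            perr = np.full(4, np.nan)
        lower, upper, tm, width = (float(v) for v in popt)
        resid = s - boltzmann(t, *popt)
        rss = float(resid @ resid)
        # a transition the data cannot resolve: amplitude below noise scale,
        # or Tm pinned to a bound => flag as unconverged, tm unreliable
        amplitude = abs(upper - lower)
        sig_range = float(np.ptp(s))
        flat = sig_range <= 1e-8 * max(1.0, float(np.max(np.abs(s))))
        transition_unseen = not (tmin < tm < tmax)
        if flat or transition_unseen or amplitude < 1e-3 * max(sig_range, 1e-12) \
                or not np.isfinite(perr[2]) or perr[2] > (tmax - tmin):
            converged = False
        return MeltFitResults(model=self, tm=tm, width=width, lower_plateau=lower,
                              upper_plateau=upper, residual_ss=rss,
                              converged=converged, param_se=tuple(perr))


@dataclass(frozen=True)
class MeltFitResults:
    """Fitted sigmoid parameters; Tm in deg C at the plateau midpoint."""

    model: MeltCurveModel
    tm: float
    width: float
    lower_plateau: float
    upper_plateau: float
    residual_ss: float
    converged: bool
    param_se: tuple = (np.nan,) * 4

    @property
    def tm_se(self) -> float:
        return float(self.param_se[2])

    def predict(self, T) -> np.ndarray:
        return boltzmann(T, self.lower_plateau, self.upper_plateau, self.tm, self.width)

    def summary(self) -> str:
        lines = [
            "Boltzmann melt fit  S(T) = lo + (up - lo)/(1 + exp((T - Tm)/w))",
            "-" * 64,
            f"n points        {len(self.model.curve):>12d}",
            f"Tm (deg C)      {self.tm:>12.2f}  (se {self.tm_se:.3g})",
            f"width (deg C)   {self.width:>12.3f}",
            f"upper plateau   {self.upper_plateau:>12.4g}",
            f"lower plateau   {self.lower_plateau:>12.4g}",
            f"residual SS     {self.residual_ss:>12.4g}",
            f"converged       {str(self.converged):>12s}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"tm": self.tm, "width": self.width,
                "upper_plateau": self.upper_plateau,
                "lower_plateau": self.lower_plateau,
                "residual_ss": self.residual_ss, "converged": self.converged}


def fit_melt_curve(curve: MeltCurve) -> MeltFitResults:
    """Functional wrapper: ``MeltCurveModel(curve).fit()``."""
    return MeltCurveModel(curve).fit()


def compare_tm(group_a: Sequence[MeltFitResults | float],
               group_b: Sequence[MeltFitResults | float],
               equal_var: bool = True) -> dict:
    """Unpaired two-tailed t-test on two sets of melting temperatures.

    Accepts either fit results or raw Tm values. Returns t, p, and per-group
    mean +/- SEM. Two identical zero-variance groups give p = 1 by convention.
    """
    def _tms(group):
        return np.array([g.tm if isinstance(g, MeltFitResults) else float(g)
                         for g in group])

    a, b = _tms(group_a), _tms(group_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 Tm values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = stats.ttest_ind(a, b, equal_var=equal_var)
    return {
        "t": float(t_stat),
        "p": float(p_val),
        "mean_a": float(a.mean()),
        "sem_a": float(stats.sem(a)),
        "mean_b": float(b.mean()),
        "sem_b": float(stats.sem(b)),
        "n_a": int(a.size),
        "n_b": int(b.size),
        "equal_var": equal_var,
    }


def read_melt_csv(path: str | Path) -> list[MeltCurve]:
    """Read melt curves from CSV (temperature_C, signal[, replicate])."""
    df = pd.read_csv(path)
    if "replicate" in df.columns:
        return [MeltCurve(g["temperature_C"].to_numpy(), g["signal"].to_numpy(),
                          replicate_id=str(rid))
                for rid, g in df.groupby("replicate", sort=False)]
    return [MeltCurve(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())]


def write_melt_csv(curves: Sequence[MeltCurve], path: str | Path) -> None:
    frames = [pd.DataFrame({"temperature_C": c.temperatures, "signal": c.signal,
                            "replicate": c.replicate_id or str(i)})
              for i, c in enumerate(curves)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
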