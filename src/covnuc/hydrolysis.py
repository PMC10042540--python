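"""First-order GTP hydrolysis fitting.

The triphosphate fraction of the bound nucleotide, read out by HPLC peak
integration at a fixed sampling grid (0, 5, 10, 15, 20, 30, 45, 60, 90,
120 min by default), decays exponentially under intrinsic or GAP-stimulated
hydrolysis. The fit is a single exponential

    f(t) = f0 · exp(−k·t)

with the initial amplitude f0 fitted rather than fixed at 1, because t = 0
samples can show partial conversion. The half-life follows as
t_1/2 = ln 2 / k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DEFAULT_TIME_GRID_MIN",
    "HydrolysisTimeCourse",
    "HydrolysisFit",
    "fit_first_order",
    "half_life",
]

DEFAULT_TIME_GRID_MIN = (0.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0)


@dataclass(frozen=True)
class HydrolysisTimeCourse:
    """Fraction of triphosphate remaining over time (minutes)."""

    times: np.ndarray  # min
    fraction_gtp: np.ndarray  # [0, 1]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fraction_gtp, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fraction_gtp", f)
        if t.shape != f.shape:
            raise ValueError("times and fractions must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(f < 0) or np.any(f > 1.0 + 1e-9):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class HydrolysisFit:
    """First-order fit result: rate (min⁻¹), half-life (min), uncertainties."""

    k: float
    t_half: float
    f0: float
    stderr_k: float
    stderr_f0: float
    flagged: bool = False
    message: str = ""

    def __post_init__(self) -> None:
        if not self.flagged and not math.isclose(
            self.t_half, math.log(2.0) / self.k, rel_tol=1e-9
        ):
            raise ValueError("t_half must equal ln2 / k")


def half_life(k: float) -> float:
    """Half-life (min) of a first-order decay with rate k (min⁻¹)."""
    if k <= 0:
        raise ValueError("rate constant must be positive")
    return math.log(2.0) / k


def fit_first_order(course: HydrolysisTimeCourse) -> HydrolysisFit:
    """Fit f(t) = f0·exp(−k·t) to a triphosphate-fraction time course.

    Requires ≥ 4 points and an on-average decaying signal; non-decaying
    input yields a flagged fit rather than a spurious rate.
    """
    t = course.times
    f = course.fraction_gtp
    if t.size < 4:
        return HydrolysisFit(
            float("nan"), float("nan"), float("nan"), float("nan"), float("nan"),
            flagged=True, message="need at least 4 time points",
        )
    first_half = f[: t.size // 2].mean()
    second_half = f[t.size - t.size // 2:].mean()
    if second_half >= first_half:
        return HydrolysisFit(
            float("nan"), float("nan"), float("nan"), float("nan"), float("nan"),
            flagged=True, message="fraction does not decay on average",
        )

    # Log-linear initial guess over the positive part of the trace.
    pos = f > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(f[pos]), 1)
        k0 = max(-slope, 1e-6)
        f00 = min(max(math.exp(intercept), 1e-3), 1.0)
    else:
        k0, f00 = 1e-2, 1.0

    popt, pcov = curve_fit(
        lambda tt, f0, k: f0 * np.exp(-k * tt), t, f, p0=[f00, k0], maxfev=10000
    )
    f0_hat, k_hat = float(popt[0]), float(popt[1])
    if k_hat <= 0:
        return HydrolysisFit(
            k_hat, float("nan"), f0_hat, float("nan"), float("nan"),
            flagged=True, message="fitted rate is non-positive",
        )
    sd = np.sqrt(np.diag(pcov))
    return HydrolysisFit(
        k=k_hat,
        t_half=math.log(2.0) / k_hat,
        f0=f0_hat,
        stderr_k=float(sd[1]),
        stderr_f0=float(sd[0]),
    )
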