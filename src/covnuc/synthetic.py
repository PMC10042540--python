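"""Seeded synthetic data for every workflow in the package.

Each generator produces one of the four experimental data shapes with the
correct mass-action structure: competition-assay percentage tables,
stopped-flow progress-curve families, covalent-labelling time courses, and
hydrolysis time courses. Defaults follow the experimental conditions of the
assays being emulated (50 µM protein / 50 µM analogue competition mixes;
1 µM protein + 2 µM reporter + {0, 1, 2, 6} µM competitor stopped-flow
series; the 0–120 min hydrolysis sampling grid).

Noise magnitudes are configurable through :class:`SyntheticSpec` — the
defaults (2% multiplicative signal noise, 0.02 absolute fraction noise, 1
percentage-point jitter) are plausible instrument-level choices, not measured
values. Fraction noise is drawn from a truncated Gaussian (resampled into
[0, 1]); the number of resampled draws is recorded on the spec rather than
silently clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from covnuc.equilibrium import CompetitionAssay, exact_competition_oracle
from covnuc.hydrolysis import DEFAULT_TIME_GRID_MIN, HydrolysisTimeCourse
from covnuc.kinetics import (
    BindingScheme,
    MixConditions,
    ProgressCurve,
    SignalModel,
    simulate_competition,
)
from covnuc.labelling import CovalentModel, LabellingTimeCourse, simulate_labelling

__all__ = [
    "SyntheticSpec",
    "gen_competition_assay",
    "gen_stopped_flow_set",
    "gen_labelling_course",
    "gen_hydrolysis_course",
    "DEFAULT_COMPETITOR_SERIES_UM",
    "DEFAULT_STOPPED_FLOW_TIMES_S",
    "DEFAULT_LABELLING_TIMES_H",
]

#: Competitor concentrations of the stopped-flow series (µM).
DEFAULT_COMPETITOR_SERIES_UM = (0.0, 1.0, 2.0, 6.0)

DEFAULT_STOPPED_FLOW_TIMES_S = tuple(np.linspace(0.0, 3.0, 151))

#: ESI-MS sampling times of the labelling competition assay (hours).
DEFAULT_LABELLING_TIMES_H = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 22.0, 24.0)


@dataclass
class SyntheticSpec:
    """Noise model and seed for synthetic data generation.

    ``truncation_counts`` accumulates, per generated dataset, how many
    Gaussian draws fell outside [0, 1] and were redrawn.
    """

    seed: int = 0
    gaussian_sigma_signal: float = 0.02  # relative, multiplicative on AU
    gaussian_sigma_fraction: float = 0.02  # absolute, on [0,1] fractions
    percentage_jitter: float = 1.0  # absolute, percentage points
    truncation_counts: list[int] = field(default_factory=list)

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


def _truncated_fraction_noise(
    rng: np.random.Generator, clean: np.ndarray, sigma: float
) -> tuple[np.ndarray, int]:
    """Additive Gaussian noise on fractions, resampled into [0, 1]."""
    if sigma == 0:
        return clean.copy(), 0
    out = np.empty_like(clean)
    n_trunc = 0
    for i, x in enumerate(clean):
        for _ in range(1000):
            val = x + rng.normal(scale=sigma)
            if 0.0 <= val <= 1.0:
                out[i] = val
                break
            n_trunc += 1
        else:  # pragma: no cover - sigma would have to be absurd
            out[i] = min(max(x, 0.0), 1.0)
    return out, n_trunc


def gen_competition_assay(
    kd_gdp: float,
    kd_analogue: float,
    spec: SyntheticSpec,
    analogue_id: str = "synthetic",
    protein_total: float = 50.0,
    gdp_total: float = 50.0,
    analogue_total: float = 50.0,
) -> CompetitionAssay:
    """Simulate a competition assay percentage table from true affinities.

    The true bound-pool composition comes from the exact two-ligand
    mass-action equilibrium at the given totals (defaults: the 50 µM
    protein:GDP + 50 µM analogue mix). The t = 0 composition encodes the
    GDP : analogue total ratio, matching the estimator's convention for
    inferring GDP_total. Percentage jitter is applied to each pair, which is
    then renormalized to sum to 100.
    """
    rng = spec.rng(stream=1)
    species = exact_competition_oracle(
        kd_gdp, kd_analogue, protein_total, gdp_total, analogue_total
    )
    bound_pool = species.bound_gdp + species.bound_analogue
    eq_gdp = 100.0 * species.bound_gdp / bound_pool
    eq_analogue = 100.0 * species.bound_analogue / bound_pool
    t0_gdp = 100.0 * gdp_total / (gdp_total + analogue_total)
    t0_analogue = 100.0 - t0_gdp

    def jitter_pair(a: float, b: float) -> tuple[float, float]:
        if spec.percentage_jitter == 0:
            return a, b
        aj = a + rng.normal(scale=spec.percentage_jitter)
        bj = b + rng.normal(scale=spec.percentage_jitter)
        aj, bj = np.clip([aj, bj], 0.0, None)
        total = aj + bj
        return 100.0 * aj / total, 100.0 * bj / total

    t0_gdp, t0_analogue = jitter_pair(t0_gdp, t0_analogue)
    eq_gdp, eq_analogue = jitter_pair(eq_gdp, eq_analogue)
    return CompetitionAssay(
        analogue_id=analogue_id,
        analogue_total=analogue_total,
        t0_percent_gdp=t0_gdp,
        t0_percent_analogue=t0_analogue,
        eq_percent_gdp=eq_gdp,
        eq_percent_analogue=eq_analogue,
        reference_kd_gdp=kd_gdp,
    )


def gen_stopped_flow_set(
    scheme: BindingScheme,
    spec: SyntheticSpec,
    protein0: float = 1.0,
    reporter0: float = 2.0,
    competitor_series: Sequence[float] = DEFAULT_COMPETITOR_SERIES_UM,
    times: Sequence[float] = DEFAULT_STOPPED_FLOW_TIMES_S,
    sig: SignalModel = SignalModel(baseline=0.1, amplitude=5.0),
) -> list[tuple[MixConditions, ProgressCurve]]:
    """Simulate the stopped-flow competitor series with Gaussian signal noise.

    Defaults reproduce the experimental design: 1 µM nucleotide-free protein
    mixed with 2 µM fluorescent reporter and 0 / 1 / 2 / 6 µM competitor.
    Signal noise is multiplicative with relative sigma
    ``spec.gaussian_sigma_signal``.
    """
    rng = spec.rng(stream=2)
    t = np.asarray(times, dtype=float)
    out = []
    for comp in competitor_series:
        mix = MixConditions(protein0=protein0, reporter0=reporter0, competitor0=comp)
        curve = simulate_competition(scheme, mix, sig, t)
        signal = curve.signal
        if spec.gaussian_sigma_signal > 0:
            signal = signal * (
                1.0 + rng.normal(scale=spec.gaussian_sigma_signal, size=signal.shape)
            )
        out.append(
            (
                mix,
                ProgressCurve(
                    times=t,
                    signal=signal,
                    noise_sigma=spec.gaussian_sigma_signal or None,
                ),
            )
        )
    return out


def gen_labelling_course(
    model: CovalentModel,
    ph: float,
    spec: SyntheticSpec,
    warhead_total: float = 36.0,
    protein_total: float = 5.0,
    times: Sequence[float] = DEFAULT_LABELLING_TIMES_H,
) -> LabellingTimeCourse:
    """Simulate a covalent-labelling time course with truncated fraction noise."""
    rng = spec.rng(stream=3)
    clean = simulate_labelling(model, ph, warhead_total, protein_total, times)
    noisy, n_trunc = _truncated_fraction_noise(
        rng, clean.fraction_modified, spec.gaussian_sigma_fraction
    )
    spec.truncation_counts.append(n_trunc)
    return LabellingTimeCourse(times=clean.times, fraction_modified=noisy)


def gen_hydrolysis_course(
    k: float,
    spec: SyntheticSpec,
    f0: float = 1.0,
    times: Sequence[float] = DEFAULT_TIME_GRID_MIN,
) -> HydrolysisTimeCourse:
    """Simulate a first-order hydrolysis time course with truncated noise."""
    rng = spec.rng(stream=4)
    t = np.asarray(times, dtype=float)
    clean = f0 * np.exp(-k * t)
    noisy, n_trunc = _truncated_fraction_noise(rng, clean, spec.gaussian_sigma_fraction)
    spec.truncation_counts.append(n_trunc)
    return HydrolysisTimeCourse(times=t, fraction_gtp=noisy)
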