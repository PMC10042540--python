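"""Equilibrium competition between a nucleotide analogue and GDP.

A GTPase saturated with GDP is mixed with an equimolar amount of a
(non-reactive) nucleotide analogue and allowed to re-equilibrate; the bound
nucleotide pool is then quantified by HPLC as percentages of GDP and analogue.
Because both nucleotides bind in the low-picomolar range while the reactants
are tens of micromolar (the tight-binding regime), essentially all protein is
nucleotide-bound and the bound/free partition of the two ligands directly
reflects their relative association constants:

    K_relA = K_A(analogue) / K_A(GDP)
           = ([P:A] [GDP]) / ([A] [P:GDP])

Multiplying by the literature association constant of GDP (reference K_D
2.5 pM) converts the ratio into an absolute K_A and K_D for the analogue.

The module implements this percentage-based derivation ("paper-faithful"
mode) together with an exact mass-action solver for the two-ligand (and
general n-ligand) competitive equilibrium, used both as a validation oracle
and as an alternative "exact" estimation mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CompetitionAssay",
    "SpeciesConcentrations",
    "AffinityEstimate",
    "InfeasibleAssayError",
    "total_gdp_from_t0",
    "equilibrium_species",
    "relative_association",
    "kd_from_relative",
    "solve_competitive_equilibrium",
    "exact_competition_oracle",
    "estimate_affinity",
]

#: Literature dissociation constant of GDP used as the reference, in pM.
REFERENCE_KD_GDP_PM = 2.5


class InfeasibleAssayError(ValueError):
    """Raised when assay percentages imply a negative concentration."""


def _check_percent_pair(p1: float, p2: float, what: str) -> None:
    if not (0.0 <= p1 <= 100.0 and 0.0 <= p2 <= 100.0):
        raise ValueError(f"{what} percentages must lie in [0, 100]; got {p1}, {p2}")
    if abs(p1 + p2 - 100.0) > 0.1:
        raise ValueError(
            f"{what} percentages must sum to 100 within 0.1; got {p1} + {p2} = {p1 + p2}"
        )


@dataclass(frozen=True)
class CompetitionAssay:
    """One analogue-vs-GDP competition experiment (HPLC peak percentages).

    Percentages refer to the protein-bound nucleotide pool. ``t0`` is the
    composition before re-equilibration, ``eq`` after. ``quantifiable`` is
    False when chromatographic peak overlap prevents integration (the
    ethylenediamine-linker analogue co-elutes with GDP), in which case no
    affinity can be derived and estimation returns a flagged result.
    """

    analogue_id: str
    analogue_total: float  # µM
    t0_percent_gdp: float
    t0_percent_analogue: float
    eq_percent_gdp: float
    eq_percent_analogue: float
    reference_kd_gdp: float = REFERENCE_KD_GDP_PM  # pM
    quantifiable: bool = True

    def __post_init__(self) -> None:
        if self.analogue_total <= 0:
            raise ValueError("analogue_total must be positive")
        if self.reference_kd_gdp <= 0:
            raise ValueError("reference_kd_gdp must be positive")
        _check_percent_pair(self.t0_percent_gdp, self.t0_percent_analogue, "t0")
        _check_percent_pair(self.eq_percent_gdp, self.eq_percent_analogue, "equilibrium")

    @staticmethod
    def from_fractions(
        analogue_id: str,
        analogue_total: float,
        t0_frac_gdp: float,
        t0_frac_analogue: float,
        eq_frac_gdp: float,
        eq_frac_analogue: float,
        **kwargs,
    ) -> "CompetitionAssay":
        """Build from 0–1 fractions instead of 0–100 percentages."""
        return CompetitionAssay(
            analogue_id,
            analogue_total,
            100.0 * t0_frac_gdp,
            100.0 * t0_frac_analogue,
            100.0 * eq_frac_gdp,
            100.0 * eq_frac_analogue,
            **kwargs,
        )


@dataclass(frozen=True)
class SpeciesConcentrations:
    """Bound and free concentrations (µM) of GDP and the analogue."""

    gdp_total: float
    bound_gdp: float
    bound_analogue: float
    free_gdp: float
    free_analogue: float

    @property
    def analogue_total(self) -> float:
        return self.bound_analogue + self.free_analogue


@dataclass(frozen=True)
class AffinityEstimate:
    """Derived affinity of one analogue.

    ``k_rel_a`` is the association constant relative to GDP; ``k_a`` is in
    pM⁻¹ and ``k_d`` in pM. ``flagged`` marks estimates that could not be
    computed (with the reason in ``flag_reason``).
    """

    analogue_id: str
    k_rel_a: float
    k_a: float  # pM^-1
    k_d: float  # pM
    mode: str = "paper"
    flagged: bool = False
    flag_reason: str = ""

    def __post_init__(self) -> None:
        if not self.flagged:
            if self.k_rel_a <= 0:
                raise ValueError("k_rel_a must be positive")
            if not math.isclose(self.k_a * self.k_d, 1.0, rel_tol=1e-9):
                raise ValueError("k_a and k_d must be reciprocal")


def total_gdp_from_t0(
    t0_percent_gdp: float, t0_percent_analogue: float, analogue_total: float
) -> float:
    """Total GDP in the assay, inferred from the t=0 bound-pool composition.

    With the analogue added at a known total concentration, the GDP pool
    carried over by the protein follows from the initial percentage ratio:
    ``GDP_total = (%GDP / %analogue) × analogue_total``.
    """
    _check_percent_pair(t0_percent_gdp, t0_percent_analogue, "t0")
    if analogue_total <= 0:
        raise ValueError("analogue_total must be positive")
    if t0_percent_analogue == 0:
        raise ZeroDivisionError(
            "t0 analogue percentage is zero: cannot infer GDP_total for this assay"
        )
    return (t0_percent_gdp / t0_percent_analogue) * analogue_total


def equilibrium_species(
    gdp_total: float,
    eq_percent_analogue: float,
    eq_percent_gdp: float,
    analogue_total: float,
) -> SpeciesConcentrations:
    """Bound/free species at equilibrium from the bound-pool percentages.

    Follows the tight-binding convention of the assay: the protein is fully
    nucleotide-saturated and its total equals ``gdp_total`` (the protein was
    loaded with GDP), so bound concentrations are percentages of ``gdp_total``
    and the free pools follow by mass conservation.
    """
    _check_percent_pair(eq_percent_gdp, eq_percent_analogue, "equilibrium")
    if gdp_total <= 0 or analogue_total <= 0:
        raise ValueError("totals must be positive")
    bound_analogue = eq_percent_analogue / 100.0 * gdp_total
    bound_gdp = eq_percent_gdp / 100.0 * gdp_total
    free_analogue = analogue_total - bound_analogue
    free_gdp = gdp_total - bound_gdp
    if free_analogue < 0 or free_gdp < 0:
        raise InfeasibleAssayError(
            "equilibrium percentages imply a negative free concentration "
            f"(free_analogue={free_analogue:.3g}, free_gdp={free_gdp:.3g} µM)"
        )
    return SpeciesConcentrations(
        gdp_total=gdp_total,
        bound_gdp=bound_gdp,
        bound_analogue=bound_analogue,
        free_gdp=free_gdp,
        free_analogue=free_analogue,
    )


def relative_association(species: SpeciesConcentrations) -> float:
    """Relative association constant K_relA = ([P:A][GDP]) / ([A][P:GDP])."""
    num = species.bound_analogue * species.free_gdp
    den = species.free_analogue * species.bound_gdp
    if den == 0 or num == 0:
        raise ZeroDivisionError(
            "relative association undefined: a species concentration is zero "
            f"(bound_analogue={species.bound_analogue}, free_gdp={species.free_gdp}, "
            f"free_analogue={species.free_analogue}, bound_gdp={species.bound_gdp})"
        )
    return num / den


def kd_from_relative(
    k_rel_a: float,
    reference_kd: float = REFERENCE_KD_GDP_PM,
    analogue_id: str = "",
    mode: str = "paper",
) -> AffinityEstimate:
    """Absolute affinity from the relative association constant.

    ``k_a = k_rel_a / reference_kd`` (pM⁻¹) and ``k_d = 1 / k_a`` (pM).
    """
    if k_rel_a <= 0 or reference_kd <= 0:
        raise ValueError("k_rel_a and reference_kd must be positive")
    k_a = k_rel_a / reference_kd
    return AffinityEstimate(
        analogue_id=analogue_id, k_rel_a=k_rel_a, k_a=k_a, k_d=1.0 / k_a, mode=mode
    )


# ---------------------------------------------------------------------------
# Exact mass-action equilibrium
# ---------------------------------------------------------------------------


class EquilibriumSolverError(RuntimeError):
    """Raised when the mass-action root solve fails to converge."""


def solve_competitive_equilibrium(
    protein_total: float,
    ligand_totals: Sequence[float],
    kds: Sequence[float],
) -> tuple[float, np.ndarray, np.ndarray]:
    """Solve the n-ligand competitive binding equilibrium exactly.

    One protein P competes for n ligands L_i with dissociation constants
    Kd_i (all concentrations in the same unit, here µM):

        bound_i = [P][L_i] / Kd_i,   [L_i] = Ltot_i − bound_i,
        [P] + Σ bound_i = Ptot.

    Eliminating bound_i gives a single monotone equation in the free protein
    concentration p:

        f(p) = p + Σ_i Ltot_i · p / (Kd_i + p) − Ptot = 0

    which is bracketed on (0, Ptot] and solved with Brent's method to
    machine precision.

    Returns ``(free_protein, bound, free)`` with arrays ordered as the input
    ligands.
    """
    ltot = np.asarray(ligand_totals, dtype=float)
    kd = np.asarray(kds, dtype=float)
    if ltot.shape != kd.shape:
        raise ValueError("ligand_totals and kds must have equal length")
    if protein_total < 0 or np.any(ltot < 0) or np.any(kd <= 0):
        raise ValueError("totals must be non-negative and kds positive")
    if protein_total == 0:
        return 0.0, np.zeros_like(ltot), ltot.copy()

    def f(p: float) -> float:
        return p + float(np.sum(ltot * p / (kd + p))) - protein_total

    # f is strictly increasing; f(0) = -Ptot < 0 and f(Ptot) >= 0.
    lo, hi = 0.0, protein_total
    try:
        p_free = brentq(f, lo, hi, xtol=1e-300, rtol=4 * np.finfo(float).eps,
                        maxiter=200)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - defensive
        raise EquilibriumSolverError(
            f"competitive equilibrium solve failed: {exc}; residual at bracket "
            f"ends f(0)={f(lo):.3g}, f(Ptot)={f(hi):.3g}"
        ) from exc
    bound = ltot * p_free / (kd + p_free)
    free = ltot - bound
    resid = abs(p_free + bound.sum() - protein_total)
    if resid > 1e-9 * max(protein_total, 1.0):  # pragma: no cover - defensive
        raise EquilibriumSolverError(
            f"equilibrium residual {resid:.3g} µM exceeds tolerance"
        )
    return p_free, bound, free


def exact_competition_oracle(
    kd_gdp: float,
    kd_analogue: float,
    protein_total: float,
    gdp_total: float,
    analogue_total: float,
) -> SpeciesConcentrations:
    """Exact two-ligand competitive equilibrium (validation oracle).

    Dissociation constants are in pM, totals in µM. Solves the full
    mass-action system (two binding isotherms plus three conservation laws)
    without the tight-binding simplification.
    """
    if kd_gdp <= 0 or kd_analogue <= 0:
        raise ValueError("dissociation constants must be positive")
    if protein_total < 0 or gdp_total <= 0 or analogue_total <= 0:
        raise ValueError("totals must be positive (protein may be zero)")
    kd_uM = np.array([kd_gdp, kd_analogue]) * 1e-6  # pM -> µM
    _, bound, free = solve_competitive_equilibrium(
        protein_total, [gdp_total, analogue_total], kd_uM
    )
    return SpeciesConcentrations(
        gdp_total=gdp_total,
        bound_gdp=float(bound[0]),
        bound_analogue=float(bound[1]),
        free_gdp=float(free[0]),
        free_analogue=float(free[1]),
    )


def _invert_oracle_for_kd(
    species_ratio: float, kd_gdp: float, protein_total: float,
    gdp_total: float, analogue_total: float
) -> float:
    """Find kd_analogue (pM) whose exact equilibrium reproduces the observed
    bound-analogue : bound-GDP ratio."""

    def ratio_minus_target(log10_kd: float) -> float:
        sp = exact_competition_oracle(
            kd_gdp, 10.0 ** log10_kd, protein_total, gdp_total, analogue_total
        )
        return sp.bound_analogue / sp.bound_gdp - species_ratio

    # Bound ratio is strictly decreasing in kd_analogue; bracket over a wide
    # affinity range (1e-6 pM .. 1e9 pM).
    return 10.0 ** brentq(ratio_minus_target, -6.0, 9.0, xtol=1e-12)


def estimate_affinity(assay: CompetitionAssay, mode: str = "paper") -> AffinityEstimate:
    """Full affinity derivation for one competition assay.

    ``mode='paper'`` applies the tight-binding percentage arithmetic
    (GDP_total from the t=0 composition, species from the equilibrium
    percentages, K_relA from the species ratio). ``mode='exact'`` instead
    inverts the exact mass-action equilibrium for the analogue K_D that
    reproduces the observed bound-pool ratio.
    """
    if mode not in ("paper", "exact"):
        raise ValueError(f"unknown mode {mode!r}; expected 'paper' or 'exact'")
    if not assay.quantifiable:
        return AffinityEstimate(
            analogue_id=assay.analogue_id,
            k_rel_a=float("nan"),
            k_a=float("nan"),
            k_d=float("nan"),
            mode=mode,
            flagged=True,
            flag_reason="not quantifiable: chromatographic peak overlap",
        )
    gdp_total = total_gdp_from_t0(
        assay.t0_percent_gdp, assay.t0_percent_analogue, assay.analogue_total
    )
    species = equilibrium_species(
        gdp_total,
        assay.eq_percent_analogue,
        assay.eq_percent_gdp,
        assay.analogue_total,
    )
    if mode == "paper":
        k_rel = relative_association(species)
        return kd_from_relative(
            k_rel, assay.reference_kd_gdp, analogue_id=assay.analogue_id, mode=mode
        )
    ratio = species.bound_analogue / species.bound_gdp
    kd_an = _invert_oracle_for_kd(
        ratio, assay.reference_kd_gdp, gdp_total, gdp_total, assay.analogue_total
    )
    k_rel = assay.reference_kd_gdp / kd_an
    return AffinityEstimate(
        analogue_id=assay.analogue_id,
        k_rel_a=k_rel,
        k_a=1.0 / kd_an,
        k_d=kd_an,
        mode=mode,
    )
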