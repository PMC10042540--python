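"""Published experimental condition sets used as pipeline inputs.

These constants transcribe the printed inputs of the study being analysed:
the HPLC competition-assay percentage tables, the summary kinetic table
(K_D / k_on per nucleotide), the stopped-flow mix design, the
labelling-competition nucleotide pools, and the hydrolysis sampling grid.
They let the analysis chain be exercised end-to-end without raw instrument
files.
"""

from __future__ import annotations

from covnuc.equilibrium import REFERENCE_KD_GDP_PM, CompetitionAssay

__all__ = [
    "PAPER_COMPETITION_ASSAYS",
    "TABLE1_KINETICS",
    "STOPPED_FLOW_DESIGN",
    "LABELLING_COMPETITION_POOLS_UM",
    "REFERENCE_KD_GDP_PM",
]

#: Competition assays of the acetamide GDP analogues vs GDP (50 µM : 50 µM
#: mixes; bound-pool percentages at t = 0 and at equilibrium). The eda
#: analogue co-elutes with GDP on HPLC and is therefore not quantifiable.
PAPER_COMPETITION_ASSAYS: tuple[CompetitionAssay, ...] = (
    CompetitionAssay(
        analogue_id="pdaGDP",
        analogue_total=50.0,
        t0_percent_gdp=37.0,
        t0_percent_analogue=63.0,
        eq_percent_gdp=53.0,
        eq_percent_analogue=47.0,
    ),
    CompetitionAssay(
        analogue_id="bdaGDP",
        analogue_total=50.0,
        t0_percent_gdp=43.0,
        t0_percent_analogue=57.0,
        eq_percent_gdp=60.5,
        eq_percent_analogue=39.5,
    ),
    CompetitionAssay(
        analogue_id="edaGDP",
        analogue_total=50.0,
        t0_percent_gdp=50.0,
        t0_percent_analogue=50.0,
        eq_percent_gdp=50.0,
        eq_percent_analogue=50.0,
        quantifiable=False,
    ),
)

#: Summary kinetics: K_D (pM) and k_on (µM⁻¹s⁻¹) per nucleotide; k_off
#: follows as K_D × k_on.
TABLE1_KINETICS: dict[str, dict[str, float]] = {
    "GDP": {"kd_pM": 2.5, "kon_uM_s": 4.22},
    "pdaGDP": {"kd_pM": 8.6, "kon_uM_s": 3.34},
    "bdaGDP": {"kd_pM": 9.6, "kon_uM_s": 3.12},
}

#: Stopped-flow mix design (post-mix concentrations, µM).
STOPPED_FLOW_DESIGN = {
    "protein0_uM": 1.0,
    "reporter0_uM": 2.0,
    "competitor_series_uM": (0.0, 1.0, 2.0, 6.0),
}

#: Nucleotide pools (µM) of the labelling competition conditions:
#: warhead nucleotide (edaGDP) vs GDP/GTP at 0×, ~1×, 10× and 100× excess.
LABELLING_COMPETITION_POOLS_UM: dict[str, dict[str, float]] = {
    "no_competition": {"edaGDP": 36.0},
    "excess_warhead": {"edaGDP": 305.0, "GDP": 36.0, "GTP": 305.0},
    "equimolar": {"edaGDP": 36.0, "GDP": 36.0, "GTP": 305.0},
    "high_competition": {"edaGDP": 36.0, "GDP": 360.0, "GTP": 3050.0},
}
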