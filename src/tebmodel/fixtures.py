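"""Packaged reference measurements and a reconstructed parameter set.

Everything printed in the main results text is collected here: the
morphometry fixture (see :func:`tebmodel.geometry.reference_geometry`), the
cell-cycle durations, the per-region labeling and apoptotic indices, the
whole-mount tortuosity statistics, the reported model rates, and the
matching-condition constants.

Per-region cell numbers and some per-region labeling indices appear only in
the supplementary tables; the reconstructed parameter set below fills those
slots from the packaged geometry (cell numbers) and from the cap-layer
labeling measurements (rates), and is clearly marked as a reconstruction.
Users holding the supplementary tables should load their own parameter file
instead (``TEBElongationModel.from_param_file``).
"""

from __future__ import annotations

from .elongation import ModelConfig, RegionParams
from .geometry import RegionId, reference_geometry
from .kinetics import rate_from_apoptotic_index, rate_from_labeling_index

__all__ = [
    "REFERENCE",
    "reference_config",
    "reconstructed_region_params",
]

#: Printed reference quantities (units in key names; fractions as given).
REFERENCE = {
    # cell-cycle kinetics
    "s_phase_h": 6.0,
    "g2m_h": 2.0,
    "total_cycle_h": 16.0,
    "brdu_offset_h": 2.0,
    "double_positive_minimum_h": 8.0,
    # apoptotic indices by region (fractions)
    "apoptotic_index": {1: 0.001, 2: 0.003, 3: 0.005, 5: 0.040, 6: 0.053, 7: 0.035},
    "cc3_window_h": 8.0,
    # cap-cell (SMA+) labeling in the donor regions (fractions)
    "sma_brdu_index": {1: 0.372, 2: 0.319},
    # tortuosity statistics
    "mean_deflection_deg": 35.5,
    "mean_inter_bifurcation_um": 1141.0,
    "underestimate_fraction": 0.061,
    "bifurcation_factor": 1.23,
    "turning_factor": 1.06,
    "total_T": 1.31,
    # reported model outputs (mm/day)
    "model1_lambda": {"basal": 1.24, "luminal": 0.78},
    "model3_lambda": {"basal": 0.76, "luminal": 0.81},
    "model4_lambda": {"basal": 0.58, "luminal": 0.62},
    # matching-condition / correction constants
    "delta_minimal": 0.97,
    "delta_literature": 1.55,
    "corrected_apoptotic_index": 0.085,
    "literature_apoptotic_index": 0.11,
    "X_values": {"model2_fit": 0.39, "model3_fit": 0.49, "model4_fit": 0.50, "measured": 0.54},
    # gland displacement (mm/day)
    "interval_rates": [0.57, 0.25, 0.82],
    "mean_displacement_rate": 0.54,
    # cell lengths (um); luminal value is a reconstruction slot
    "cell_length_basal_um": 21.5,
    "cell_length_luminal_um": 7.0,
}


def reference_config(
    X: float | None = 0.54,
    delta: float | None = 0.97,
    T: float | None = 1.31,
    donor_regions: tuple[int, ...] = (1, 2),
) -> ModelConfig:
    """A ModelConfig populated with the packaged reference constants."""
    return ModelConfig(
        cell_length_basal_um=REFERENCE["cell_length_basal_um"],
        cell_length_luminal_um=REFERENCE["cell_length_luminal_um"],
        delta=delta,
        X=X,
        donor_regions=donor_regions,
        T=T,
    )


def reconstructed_region_params() -> list[RegionParams]:
    """Region parameters reconstructed from packaged measurements.

    Cell numbers come from the packaged geometry; proliferation rates from
    the cap-layer labeling indices where printed (regions 1-2), with the
    region-2 value reused for region 3 and the region-1 value for the
    highly proliferative tip body region 5; the low-turnover body regions
    6-7 get half the region-5 rate, reflecting their weak cycle re-entry.
    Death rates come from the printed apoptotic indices.  This set is a
    documented reconstruction, not the supplementary parameter table.
    """
    s, p, w = REFERENCE["s_phase_h"], REFERENCE["brdu_offset_h"], REFERENCE["cc3_window_h"]
    li = {
        1: REFERENCE["sma_brdu_index"][1],
        2: REFERENCE["sma_brdu_index"][2],
        3: REFERENCE["sma_brdu_index"][2],  # reconstruction slot
        4: 0.0,
        5: REFERENCE["sma_brdu_index"][1],  # reconstruction slot
        6: REFERENCE["sma_brdu_index"][1] / 2,  # reconstruction slot
        7: REFERENCE["sma_brdu_index"][1] / 2,  # reconstruction slot
        8: 0.0,
    }
    ai = {i: REFERENCE["apoptotic_index"].get(i, 0.0) for i in range(1, 9)}
    numbers = reference_geometry().cell_numbers()
    return [
        RegionParams(
            RegionId(i),
            N=numbers[i],
            r_per_h=rate_from_labeling_index(li[i], s, p),
            d_per_h=rate_from_apoptotic_index(ai[i], w),
        )
        for i in range(1, 9)
    ]
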