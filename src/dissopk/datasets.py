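"""Published desvenlafaxine ER study values used as package inputs.

These are literature-reported quantities for desvenlafaxine succinate ER
tablets (drug properties, two-compartment disposition constants, measured
tablet dimensions of the Brazilian reference and generic products, the
convolution prediction-error table for the nine DoE dissolution methods,
and the proposed dissolution specification).  They are *inputs*: the package
recomputes derived quantities (SA/V, half-lives, PE%, classifications) from
them rather than restating results.
"""

from __future__ import annotations

import pandas as pd

from .geometry import TabletDimensions, TabletShape

# --- Drug substance properties (desvenlafaxine succinate) ------------------
DESVENLAFAXINE = {
    "pka_acid": 10.45,
    "pka_base": 9.18,
    "logp": 2.63,
    "mw_g_mol": 263.38,
    "diffusion_coeff_cm2_s": 0.75e-5,
    "peff_cm_s": 6.2e-4,
    "blood_plasma_ratio": 1.08,
    "fup_percent": 70.0,
    "solubility_mg_ml": 0.13,  # at pH 10.02
    "solubility_ph": 10.02,
}

# --- Two-compartment disposition constants (top-down IV/IR fit) ------------
DISPOSITION = {
    "cl_l_h_kg": 0.2031,
    "vss_l_kg": 2.2343,
    "k12_1_h": 0.15764,
    "k21_1_h": 0.19244,
    "reported_t_half_h": 9.7,
    "iv_cohort_body_weight_kg": 81.7,  # metadata; simulations use 70 kg
}

# --- Mean tablet dimensions of the marketed products (n = 12 each) ---------
# (weight mg, thickness cm, diameter-or-side cm, + their reported SDs)
PRODUCT_DIMENSIONS = {
    "Reference": {
        "shape": TabletShape.RECT_PRISM,
        "thickness_cm": 0.488,
        "cross_dim_cm": 0.913,
        "weight_mg": 362.0,
        "thickness_sd": 0.005,
        "cross_dim_sd": 0.002,
        "weight_sd": 3.9,
        "reported_sa_v": 8.479,
        "reported_sa_v_sd": 0.049,
    },
    "Generic #1": {
        "shape": TabletShape.CYLINDER,
        "thickness_cm": 0.440,
        "cross_dim_cm": 0.818,
        "weight_mg": 210.0,
        "thickness_sd": 0.005,
        "cross_dim_sd": 0.002,
        "weight_sd": 3.3,
        "reported_sa_v": 9.440,
        "reported_sa_v_sd": 0.058,
    },
    "Generic #2": {
        "shape": TabletShape.CYLINDER,
        "thickness_cm": 0.576,
        "cross_dim_cm": 0.920,
        "weight_mg": 362.0,
        "thickness_sd": 0.009,
        "cross_dim_sd": 0.002,
        "weight_sd": 5.3,
        "reported_sa_v": 7.824,
        "reported_sa_v_sd": 0.052,
    },
}


def mean_tablet(product: str) -> TabletDimensions:
    """TabletDimensions at the reported mean dimensions of a product."""
    d = PRODUCT_DIMENSIONS[product]
    return TabletDimensions(
        shape=d["shape"],
        thickness_cm=d["thickness_cm"],
        cross_dim_cm=d["cross_dim_cm"],
        weight_mg=d["weight_mg"],
    )


# --- Taguchi L9 factor levels and run assignments --------------------------
DOE_FACTORS = ["product", "medium", "apparatus", "speed_rpm"]
DOE_LEVELS = {
    "product": ["Generic #1", "Reference", "Generic #2"],
    "medium": ["0.9% NaCl", "phosphate pH 6.8", "water"],
    "apparatus": ["basket", "paddle_sinker", "paddle"],
    "speed_rpm": [50, 75, 100],
}

# Published run table (run -> product, medium, apparatus, rpm)
DOE_RUNS = pd.DataFrame(
    [
        (1, "Generic #1", "0.9% NaCl", "basket", 50),
        (2, "Generic #1", "phosphate pH 6.8", "paddle_sinker", 75),
        (3, "Generic #1", "water", "paddle", 100),
        (4, "Reference", "0.9% NaCl", "paddle_sinker", 100),
        (5, "Reference", "phosphate pH 6.8", "paddle", 50),
        (6, "Reference", "water", "basket", 75),
        (7, "Generic #2", "0.9% NaCl", "paddle", 75),
        (8, "Generic #2", "phosphate pH 6.8", "basket", 100),
        (9, "Generic #2", "water", "paddle_sinker", 50),
    ],
    columns=["run", "product", "medium", "apparatus", "speed_rpm"],
)

# --- Standard ER dissolution sampling grid (hours) --------------------------
DISSOLUTION_TIMES_H = [1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0]

# --- Reported IR-tablet PK: observed vs model-predicted ---------------------
# (dose mg, metric, observed, predicted, reported P/O ratio; None = not reported)
IR_PK_TABLE = pd.DataFrame(
    [
        (50, "cmax_ng_ml", 249.5, 256.8, 1.03),
        (50, "tmax_h", 3.99, 2.64, 0.66),
        (50, "auc_0_inf", 3617.8, 3490.1, 0.96),
        (50, "auc_0_t", 2931.0, 2850.2, 0.97),
        (100, "cmax_ng_ml", 532.0, 513.48, 0.97),
        (100, "tmax_h", 3.30, 2.64, 0.80),
        (100, "auc_0_inf", None, 6988.4, None),
        (100, "auc_0_t", 6251.0, 5702.8, 0.91),
    ],
    columns=["dose_mg", "metric", "observed", "predicted", "reported_ratio"],
)

# --- Convolution results for the nine DoE dissolution methods ---------------
# Observed reference Cmax/AUC0-t versus the value reconstructed by convolving
# each in vitro profile; reported PE% = 100*(obs - pred)/obs, and the runs
# reported as biopredictive (|PE| <= 10 for both metrics): 1, 3, 4 and 9.
CONVOLUTION_PE_TABLE = pd.DataFrame(
    [
        (1, 77.23, 83.48, -8.09, 1866.80, 1783.20, 4.48),
        (2, 77.23, 96.84, -25.40, 1866.80, 1902.20, -1.90),
        (3, 77.23, 79.35, -2.75, 1866.80, 1748.60, 6.32),
        (4, 77.23, 80.06, -3.67, 1866.80, 1738.70, 6.86),
        (5, 77.23, 74.84, 3.09, 1866.80, 1596.30, 14.49),
        (6, 77.23, 67.77, 12.25, 1866.80, 1493.20, 20.01),
        (7, 77.23, 72.83, 5.69, 1866.80, 1656.40, 11.27),
        (8, 77.23, 74.50, 3.52, 1866.80, 1633.80, 12.48),
        (9, 77.23, 81.13, -5.04, 1866.80, 1776.90, 4.81),
    ],
    columns=[
        "run",
        "cmax_obs",
        "cmax_pred",
        "cmax_pe_reported",
        "auc_obs",
        "auc_pred",
        "auc_pe_reported",
    ],
)

BIOPREDICTIVE_RUNS_REPORTED = [1, 3, 4, 9]

# --- Proposed ER dissolution specification windows (% dissolved) ------------
# 1 h strictly below 20%; 4/8/16 h inclusive ranges; 24 h not less than 80%.
ER_SPEC_WINDOWS = [
    (1.0, None, 20.0, False),   # (time h, lower, upper, bounds inclusive?)
    (4.0, 38.0, 48.0, True),
    (8.0, 50.0, 72.0, True),
    (16.0, 72.0, 93.0, True),
    (24.0, 80.0, None, True),
]
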