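"""Published study constants for the *Polygonum aviculare* bioindication experiment.

The hydroponic dosing study varied Cd, Pb and Cr in half-strength Hoagland's
solution over three levels each — concentrations typical of countryside
(low), urban (central) and heavily polluted (high) soils — while Cu and Zn
stayed at the nutrient-solution background (0.5 and 2 µM). Shoot
concentrations of all five metals were the responses. The fitted quadratic
model coefficients and their significance stars for each response are stored
here and serve as the default ground truth of the synthetic-data generator.
"""

from __future__ import annotations

import numpy as np

from .design import Factor

#: The three dosed metals with their nutrient-solution levels (µM).
FACTORS: tuple[Factor, ...] = (
    Factor("Cd", low=0.0100, central=0.0700, high=0.140),
    Factor("Pb", low=1.83, central=14.5, high=29.0),
    Factor("Cr", low=6.92, central=23.1, high=46.2),
)

FACTOR_NAMES: tuple[str, ...] = tuple(f.name for f in FACTORS)

#: Metals measured in shoots (model responses), in report order.
RESPONSE_METALS: tuple[str, ...] = ("Cd", "Cr", "Pb", "Cu", "Zn")

#: Background concentrations (µM) of the responses that were not varied.
HELD_CONSTANT_UM: dict[str, float] = {"Cu": 0.5, "Zn": 2.0}

#: Term symbols of the 10-term quadratic model, in fixed column order.
TERM_SYMBOLS: tuple[str, ...] = (
    "b0", "b1", "b2", "b3", "b12", "b13", "b23", "b11", "b22", "b33",
)

#: Published regression coefficients (mg kg^-1, coded scale), one column per
#: response metal, rows in TERM_SYMBOLS order (factors: 1=Cd, 2=Pb, 3=Cr).
COEFFICIENTS: dict[str, np.ndarray] = {
    "Cd": np.array([3.1, 0.87, 0.12, -0.0073, -0.050, -0.58, -0.30, -0.32, -0.043, -0.55]),
    "Cr": np.array([0.14, -0.081, 0.12, 0.53, -0.12, -0.046, 0.12, 0.23, 0.32, 0.23]),
    "Pb": np.array([5.9, 0.22, 1.6, -1.7, -3.6, 8.9, 0.20, 4.6, -0.65, 5.8]),
    "Cu": np.array([3.2, 0.49, 0.65, 0.82, 0.49, 2.9, -0.80, 3.6, 3.1, 3.0]),
    "Zn": np.array([33.0, -1.4, 3.4, 1.9, 0.64, -2.0, -3.4, 9.5, 9.7, 9.3]),
}

#: Published significance stars ("" = not significant at alpha 0.05;
#: "*" p<0.05, "**" p<0.01, "***" p<0.001), same row order as COEFFICIENTS.
STARS: dict[str, tuple[str, ...]] = {
    "Cd": ("", "***", "", "", "", "*", "", "", "", ""),
    "Cr": ("", "", "", "***", "", "", "", "", "*", ""),
    "Pb": ("", "", "", "", "", "***", "", "", "", "*"),
    "Cu": ("", "", "", "", "", "***", "", "**", "**", "**"),
    "Zn": ("", "", "**", "", "", "", "*", "***", "***", "***"),
}

#: Default replicate noise sd (mg kg^-1) used by the synthetic generator:
#: 10% of each response's published intercept magnitude.
DEFAULT_NOISE_SD: dict[str, float] = {
    "Cd": 0.31, "Cr": 0.014, "Pb": 0.59, "Cu": 0.32, "Zn": 3.3,
}

#: AAS calibration standard concentrations per metal (three standards each).
#: Units: µg/L except Zn which is mg/L.
CALIBRATION_STANDARDS: dict[str, tuple[float, ...]] = {
    "Cd": (2.0, 4.0, 6.0),
    "Cr": (2.0, 10.0, 25.0),
    "Cu": (2.5, 10.0, 25.0),
    "Pb": (5.0, 20.0, 40.0),
    "Zn": (0.1, 0.5, 0.8),
}

CALIBRATION_UNITS: dict[str, str] = {
    "Cd": "ug/L", "Cr": "ug/L", "Cu": "ug/L", "Pb": "ug/L", "Zn": "mg/L",
}

#: Digest protocol: 100 mg dry shoot powder ashed and taken up in 4 mL acid.
DIGEST_MASS_KG: float = 1.0e-4
DIGEST_VOLUME_L: float = 4.0e-3

#: Factor pairs plotted for each response (abscissa, ordinate), third factor
#: fixed at coded 0 — the published figure layout.
SURFACE_AXES: dict[str, tuple[tuple[str, str], ...]] = {
    "Cd": (("Cd", "Cr"),),
    "Cr": (("Cr", "Pb"),),
    "Pb": (("Cd", "Cr"),),
    "Cu": (("Cd", "Cr"), ("Cd", "Pb")),
    "Zn": (("Pb", "Cd"), ("Cd", "Cr"), ("Pb", "Cr")),
}

#: QC acceptance windows (%): spike recovery and calibration-control checks.
SPIKE_RECOVERY_LIMITS: tuple[float, float] = (90.0, 110.0)
CONTROL_LIMITS: tuple[float, float] = (95.0, 105.0)
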