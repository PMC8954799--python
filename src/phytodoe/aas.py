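"""AAS quantification: calibration lines, blank subtraction, dilution, LoD, QC.

The analytical chain mirrors graphite-furnace AAS practice: peak areas are
the quantification signal; a blank run is subtracted from every sample
signal; a straight calibration line fitted to blank-corrected standard
signals converts net area to solution concentration; the dilution factor
(applied when a sample exceeded the linear range) multiplies back; and the
digest arithmetic (dry-mass portion ashed and taken up in acid) converts
solution concentration to tissue concentration in mg per kg dry weight.

Detection limit: 3 × sd(blank areas) / slope, falling back to
3.3 × residual sd / slope when fewer than three blank runs are available.
QC helpers check spike recoveries against a 90–110% window and calibration
control solutions against 95–105%; both windows are closed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

SPIKE_LIMITS = (90.0, 110.0)
CONTROL_LIMITS = (95.0, 105.0)

#: Factor converting a calibration unit to mg/L.
_UNIT_TO_MG_L = {"ug/L": 1e-3, "mg/L": 1.0}


def _within(percent: float, limits: tuple[float, float]) -> bool:
    # closed interval; absorb float rounding at the boundaries
    lo, hi = limits
    eps = 1e-9 * max(abs(lo), abs(hi))
    return lo - eps <= percent <= hi + eps


class CalibrationError(ValueError):
    """Raised for unusable standard sets or a detection limit above the lowest standard."""


@dataclass
class CalibrationLine:
    metal: str
    slope: float            # signal per concentration unit
    intercept: float        # signal
    residual_sd: float      # signal
    lod: float              # concentration, calibration units
    standard_range: tuple[float, float]
    unit: str = "ug/L"
    n_blanks: int = 0

    @property
    def unit_to_mg_per_l(self) -> float:
        return _UNIT_TO_MG_L[self.unit]


@dataclass
class QCResult:
    kind: str               # "spike_recovery" | "control"
    percent: float
    limits: tuple[float, float]
    passed: bool


def fit_calibration(standards: Sequence[tuple[float, float]],
                    blanks: Sequence[float],
                    metal: str = "", unit: str = "ug/L") -> CalibrationLine:
    """Least-squares line through blank-corrected standard signals.

    ``standards`` are (concentration, mean peak area) pairs; ``blanks`` raw
    blank peak areas. Errors out when the standards do not span at least two
    concentrations, the slope is not positive, or the detection limit lands
    above the lowest standard.
    """
    if unit not in _UNIT_TO_MG_L:
        raise ValueError(f"unknown concentration unit {unit!r}")
    conc = np.asarray([s[0] for s in standards], dtype=float)
    area = np.asarray([s[1] for s in standards], dtype=float)
    blanks = np.asarray(blanks, dtype=float)
    if conc.size < 2 or np.unique(conc).size < 2:
        raise CalibrationError("need at least two distinct standard concentrations")
    if blanks.size < 1:
        raise CalibrationError("need at least one blank measurement")

    net = area - blanks.mean()
    slope, intercept = np.polyfit(conc, net, 1)
    if slope <= 0:
        raise CalibrationError(f"non-positive calibration slope ({slope:g}) for {metal or 'metal'}")
    resid = net - (slope * conc + intercept)
    dof = conc.size - 2
    residual_sd = float(np.sqrt((resid @ resid) / dof)) if dof > 0 else 0.0

    if blanks.size >= 3:
        lod = 3.0 * float(blanks.std(ddof=1)) / slope
    else:
        lod = 3.3 * residual_sd / slope
    lowest = float(conc.min())
    if lod > lowest:
        raise CalibrationError(
            f"LoD {lod:g} {unit} exceeds the lowest standard {lowest:g} {unit}"
            f" for {metal or 'metal'}"
        )
    return CalibrationLine(
        metal=metal, slope=float(slope), intercept=float(intercept),
        residual_sd=residual_sd, lod=float(lod),
        standard_range=(lowest, float(conc.max())), unit=unit,
        n_blanks=int(blanks.size),
    )


def signal_to_solution(peak_area: float, blank_area: float,
                       cal: CalibrationLine,
                       dilution: float = 1.0) -> tuple[float, bool]:
    """Net signal → solution concentration (calibration units) and LoD flag.

    The blank-corrected, intercept-corrected area divides by the slope and
    multiplies by the dilution factor. The below-LoD flag compares the
    *as-measured* (undiluted) concentration against the detection limit; a
    negative net signal flags below detection rather than raising.
    """
    if dilution < 1.0:
        raise ValueError(f"dilution factor must be >= 1, got {dilution}")
    net = (peak_area - blank_area) - cal.intercept
    measured = net / cal.slope
    below = bool(measured < cal.lod or measured <= 0.0)
    return measured * dilution, below


def solution_to_tissue(c_solution_mg_l: float, digest_volume_l: float,
                       sample_mass_kg: float) -> float:
    """Digest arithmetic: mg/L in the digest → mg/kg dry tissue."""
    if digest_volume_l <= 0 or sample_mass_kg <= 0:
        raise ValueError("digest volume and sample mass must be positive")
    return c_solution_mg_l * digest_volume_l / sample_mass_kg


def spike_recovery(measured_spiked: float, measured_base: float,
                   spike_added: float) -> QCResult:
    """Percent of a known added amount recovered; accepted inside 90–110%."""
    if spike_added <= 0:
        raise ValueError("spike amount must be positive")
    percent = (measured_spiked - measured_base) / spike_added * 100.0
    return QCResult("spike_recovery", percent, SPIKE_LIMITS,
                    _within(percent, SPIKE_LIMITS))


def control_check(measured: float, nominal: float) -> QCResult:
    """Control-solution recovery; a fail means the line must be recomputed."""
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    percent = measured / nominal * 100.0
    return QCResult("control", percent, CONTROL_LIMITS,
                    _within(percent, CONTROL_LIMITS))


def quantify_records(records: pd.DataFrame,
                     calibrations: dict[str, CalibrationLine],
                     peak_height_limit_au: float = 0.6) -> pd.DataFrame:
    """Quantify a table of AAS sample records into tissue concentrations.

    Expected columns: ``sample_id, metal, peak_area, blank_area, dilution,
    mass_g, volume_ml``; optional ``peak_height_au`` (linearity guard),
    ``is_control``/``control_nominal`` and ``is_spiked``. Instrument
    replicates (several rows per sample_id/metal) are averaged before
    quantification, with the area sd propagated into ``peak_area_sd``.

    Returns one row per (sample_id, metal): ``tissue_mg_per_kg``,
    ``below_lod`` and a semicolon-joined ``qc_flags`` string.
    """
    required = {"sample_id", "metal", "peak_area", "blank_area",
                "dilution", "mass_g", "volume_ml"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"AAS records missing columns {sorted(missing)}")

    out_rows = []
    group_cols = ["sample_id", "metal"]
    for (sample_id, metal), grp in records.groupby(group_cols, sort=False):
        if metal not in calibrations:
            raise KeyError(f"no calibration line for metal {metal!r}")
        cal = calibrations[metal]
        flags = []
        area = float(grp["peak_area"].mean())
        area_sd = float(grp["peak_area"].std(ddof=1)) if len(grp) > 1 else 0.0
        blank = float(grp["blank_area"].mean())
        dilution = float(grp["dilution"].iloc[0])
        mass_kg = float(grp["mass_g"].iloc[0]) * 1e-3
        volume_l = float(grp["volume_ml"].iloc[0]) * 1e-3

        if "peak_height_au" in grp.columns and \
                np.nanmax(grp["peak_height_au"].to_numpy(dtype=float)) > peak_height_limit_au:
            flags.append(f"peak_height_exceeds_{peak_height_limit_au}AU")

        c_units, below = signal_to_solution(area, blank, cal, dilution)
        if below:
            flags.append("below_lod")
        c_mg_l = c_units * cal.unit_to_mg_per_l
        tissue = solution_to_tissue(c_mg_l, volume_l, mass_kg)

        if bool(grp.get("is_control", pd.Series([False])).iloc[0]) and \
                "control_nominal" in grp.columns:
            qc = control_check(c_units / dilution, float(grp["control_nominal"].iloc[0]))
            if not qc.passed:
                flags.append(f"control_out_of_range_{qc.percent:.1f}%")

        out_rows.append({
            "sample_id": sample_id,
            "metal": metal,
            "tissue_mg_per_kg": tissue,
            "solution_conc": c_units,
            "solution_unit": cal.unit,
            "peak_area_sd": area_sd,
            "below_lod": below,
            "qc_flags": ";".join(flags),
        })
    return pd.DataFrame(out_rows)
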