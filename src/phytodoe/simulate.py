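"""Synthetic shoot-concentration and AAS-signal data.

The generator emulates the replicate-level dataset of the dosing study: for
every design run, each response metal's mean shoot concentration follows
the 10-term quadratic surface with the published coefficient columns as
ground truth, and pot replicates add independent Gaussian noise. The mean
function shares the model-matrix code path of the fitting module, so the
generative model and the fitted model agree by construction.

Defaults are the study's conditions: the 3-factor × 3-level design with the
true coded central levels, three replicates (81 samples), and per-response
noise sd equal to 10% of the published intercept magnitude. Randomness is
driven by one master seed; each response draws from its own deterministic
substream, so adding a response never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .design import Factor, coded_matrix, full_factorial, replicate_design
from .rsm import quadratic_expand


@dataclass
class GeneratorConfig:
    """Ground truth and noise structure for the uptake simulator."""

    coefficients: Mapping[str, np.ndarray] = field(
        default_factory=lambda: dict(reference.COEFFICIENTS))
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(reference.DEFAULT_NOISE_SD))
    replicates: int = 3
    seed: int = 0
    truncate_at_zero: bool = False
    distribution: str = "normal"  # or "lognormal"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for m, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"negative noise sd for {m}")
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError(f"unknown noise distribution {self.distribution!r}")


def _response_rng(seed: int, index: int) -> np.random.Generator:
    # deterministic substream per response metal
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def simulate_uptake(design: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Replicate shoot concentrations (mg/kg) for every run of a coded design.

    Responses are ``mean + noise`` with the mean from the quadratic surface;
    lognormal noise multiplies the positive mean by ``exp(N(0, cv))`` with
    ``cv = sd/|mean|``, keeping the same relative spread. Truncation clips
    at zero (which biases OLS slightly; off by default).
    """
    pts = coded_matrix(design)
    X = quadratic_expand(pts)
    out = design.copy().reset_index(drop=True)
    for idx, (metal, b) in enumerate(config.coefficients.items()):
        b = np.asarray(b, dtype=float)
        if b.shape != (X.shape[1],):
            raise ValueError(
                f"coefficient vector for {metal} has length {b.size}, "
                f"model matrix has {X.shape[1]} columns"
            )
        mean = X @ b
        sd = float(config.noise_sd.get(metal, 0.0))
        rng = _response_rng(config.seed, idx)
        if sd == 0.0:
            values = mean
        elif config.distribution == "normal":
            values = mean + rng.normal(0.0, sd, size=mean.shape)
        else:
            cv = sd / np.maximum(np.abs(mean), 1e-12)
            values = mean * np.exp(rng.normal(0.0, cv, size=mean.shape))
        if config.truncate_at_zero:
            values = np.clip(values, 0.0, None)
        out[metal] = values
    return out


def simulate_study(seed: int = 0,
                   factors: Sequence[Factor] = reference.FACTORS,
                   replicates: int = 3,
                   config: GeneratorConfig | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The full study in one call: 3×3×3 design, 3 replicates, 5 responses.

    Returns ``(design, uptake)`` with 27 unique runs and 81 rows by default.
    """
    if config is None:
        config = GeneratorConfig(seed=seed, replicates=replicates)
    else:
        config = replace(config, seed=seed, replicates=replicates)
    design = replicate_design(full_factorial(factors), config.replicates)
    return design, simulate_uptake(design, config)


# ---------------------------------------------------------------------------
# forward AAS model


@dataclass(frozen=True)
class CalibrationTruth:
    """True instrument line for the AAS forward model (one metal)."""

    metal: str
    slope: float = 100.0        # area per concentration unit
    intercept: float = 0.0      # area
    signal_sd: float = 0.0      # area noise per reading
    blank_mean: float = 5.0     # area of the blank run
    blank_sd: float = 0.0
    standards: tuple[float, ...] = ()
    unit: str = "ug/L"


def default_calibration_truth(signal_sd: float = 0.0,
                              blank_sd: float = 0.0) -> dict[str, CalibrationTruth]:
    return {
        m: CalibrationTruth(
            metal=m, standards=reference.CALIBRATION_STANDARDS[m],
            unit=reference.CALIBRATION_UNITS[m],
            signal_sd=signal_sd, blank_sd=blank_sd,
        )
        for m in reference.RESPONSE_METALS
    }


def simulate_aas_records(uptake: pd.DataFrame,
                         truth: Mapping[str, CalibrationTruth] | None = None,
                         seed: int = 0,
                         instrument_replicates: int = 3,
                         mass_g: float = 0.1,
                         volume_ml: float = 4.0
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Push simulated tissue concentrations through the instrument model.

    Each sample's tissue concentration is converted to the digest solution
    concentration (default 100 mg in 4 mL), expressed in the metal's
    calibration unit, diluted by the smallest integer factor that brings it
    inside the standard range, and turned into peak areas with the true
    line plus noise. Returns ``(records, standards, blanks)`` tables in the
    schemas the quantification module consumes.
    """
    truth = dict(truth) if truth is not None else default_calibration_truth()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77]))
    metals = [m for m in truth if m in uptake.columns]

    std_rows, blank_rows, rec_rows = [], [], []
    for metal in metals:
        tr = truth[metal]
        to_mg_l = {"ug/L": 1e-3, "mg/L": 1.0}[tr.unit]
        for c in tr.standards:
            for rep in range(1, instrument_replicates + 1):
                area = tr.blank_mean + tr.intercept + tr.slope * c \
                    + rng.normal(0.0, tr.signal_sd)
                std_rows.append({"metal": metal, "concentration": c,
                                 "unit": tr.unit, "replicate": rep,
                                 "peak_area": area})
        for rep in range(1, max(instrument_replicates, 3) + 1):
            blank_rows.append({"metal": metal, "replicate": rep,
                               "peak_area": tr.blank_mean + rng.normal(0.0, tr.blank_sd)})

        max_std = max(tr.standards)
        for _, row in uptake.iterrows():
            tissue = float(row[metal])
            sample_id = f"run{int(row['run_id']):02d}_rep{int(row['replicate'])}"
            c_sol_mg_l = max(tissue, 0.0) * (mass_g * 1e-3) / (volume_ml * 1e-3)
            c_units = c_sol_mg_l / to_mg_l
            dilution = max(1.0, float(np.ceil(c_units / max_std)))
            c_read = c_units / dilution
            for irep in range(1, instrument_replicates + 1):
                area = tr.blank_mean + tr.intercept + tr.slope * c_read \
                    + rng.normal(0.0, tr.signal_sd)
                rec_rows.append({
                    "sample_id": sample_id, "metal": metal,
                    "peak_area": area,
                    "peak_height_au": min(0.59, 0.05 + 0.5 * c_read / max_std),
                    "blank_area": tr.blank_mean,
                    "dilution": dilution,
                    "mass_g": mass_g, "volume_ml": volume_ml,
                    "is_control": False, "is_spiked": False,
                    "spike_added": 0.0,
                })
    return (pd.DataFrame(rec_rows), pd.DataFrame(std_rows), pd.DataFrame(blank_rows))


def calibrations_from_tables(standards: pd.DataFrame, blanks: pd.DataFrame):
    """Fit one calibration line per metal from simulated (or real) tables."""
    from .aas import fit_calibration

    cals = {}
    for metal, grp in standards.groupby("metal", sort=False):
        means = grp.groupby("concentration", sort=True)["peak_area"].mean()
        pairs = list(means.items())
        bl = blanks.loc[blanks["metal"] == metal, "peak_area"].to_numpy()
        unit = grp["unit"].iloc[0] if "unit" in grp.columns else "ug/L"
        cals[metal] = fit_calibration(pairs, bl, metal=metal, unit=unit)
    return cals
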