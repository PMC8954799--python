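"""Factors, level coding and replicated full-factorial designs.

A :class:`Factor` is one metal dosed in the growing medium, with named
natural levels (low / central / high, in µM). Coding maps concentrations
affinely so that low → −1 and high → +1; the central level need not land on
0 (in the reference study it codes to −0.08, −0.07 and −0.18 for Cd, Pb and
Cr because the high level is twice the central one rather than symmetric
about it). Designs are plain :class:`pandas.DataFrame` tables with one
coded and one natural column per factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LEVEL_LABELS: tuple[str, str, str] = ("low", "central", "high")


class InvalidFactorError(ValueError):
    """Raised for factors whose levels are not strictly increasing positives."""


@dataclass(frozen=True)
class Factor:
    """A dosed metal with its natural concentration levels in µM."""

    name: str
    low: float
    central: float
    high: float

    def __post_init__(self) -> None:
        if not self.name:
            raise InvalidFactorError("factor needs a non-empty name")
        if not (0.0 < self.low < self.central < self.high):
            raise InvalidFactorError(
                f"factor {self.name!r}: levels must satisfy 0 < low < central < high, "
                f"got ({self.low}, {self.central}, {self.high})"
            )

    @property
    def midrange(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def halfwidth(self) -> float:
        return 0.5 * (self.high - self.low)

    def level(self, label: str) -> float:
        """Natural concentration (µM) of a named level."""
        try:
            return {"low": self.low, "central": self.central, "high": self.high}[label]
        except KeyError:
            raise KeyError(f"unknown level label {label!r}") from None


def code_level(value: float, factor: Factor) -> float:
    """Map a natural concentration (µM) to the coded scale (low→−1, high→+1)."""
    if factor.halfwidth <= 0:
        raise InvalidFactorError(f"factor {factor.name!r} has zero-width range")
    return (value - factor.midrange) / factor.halfwidth


def decode_level(coded: float, factor: Factor) -> float:
    """Inverse of :func:`code_level`: coded value back to µM."""
    return factor.midrange + coded * factor.halfwidth


def coded_central(factor: Factor) -> float:
    """Coded value of the factor's central natural level (full precision)."""
    return code_level(factor.central, factor)


def full_factorial(
    factors: Sequence[Factor],
    levels: Sequence[str] = LEVEL_LABELS,
) -> pd.DataFrame:
    """Enumerate every combination of the named levels, once per run.

    Ordering is deterministic: lexicographic by factor order, with levels
    in the order given (low < central < high by default); the first factor
    varies slowest. Run ids are 1-based. Columns per factor ``m``:
    ``{m}_level`` (label), ``{m}_coded``, ``{m}_uM``; plus ``run_id`` and
    ``replicate`` (all 1 for an unreplicated design).
    """
    if len(factors) < 1:
        raise ValueError("need at least one factor")
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate factor names in {names}")
    if len(levels) < 2:
        raise ValueError("need at least two levels per factor")
    for lab in levels:
        if lab not in LEVEL_LABELS:
            raise ValueError(f"unknown level label {lab!r}")

    rows = []
    for run_id, combo in enumerate(product(levels, repeat=len(factors)), start=1):
        row: dict[str, object] = {"run_id": run_id, "replicate": 1}
        for factor, lab in zip(factors, combo):
            natural = factor.level(lab)
            row[f"{factor.name}_level"] = lab
            row[f"{factor.name}_coded"] = code_level(natural, factor)
            row[f"{factor.name}_uM"] = natural
        rows.append(row)
    return pd.DataFrame(rows)


def replicate_design(design: pd.DataFrame, k: int) -> pd.DataFrame:
    """Repeat the unique runs in ``k`` replicate blocks.

    Each block preserves the original run ordering; ``replicate`` runs 1..k.
    """
    if k < 1:
        raise ValueError(f"replicate count must be >= 1, got {k}")
    unique = design.drop_duplicates(subset="run_id").reset_index(drop=True)
    blocks = []
    for rep in range(1, k + 1):
        block = unique.copy()
        block["replicate"] = rep
        blocks.append(block)
    return pd.concat(blocks, ignore_index=True)


def factor_names(design: pd.DataFrame) -> list[str]:
    """Factor names inferred from the ``*_coded`` columns, in column order."""
    return [c[: -len("_coded")] for c in design.columns if c.endswith("_coded")]


def coded_matrix(design: pd.DataFrame, names: Iterable[str] | None = None) -> np.ndarray:
    """(n_rows, n_factors) array of coded levels."""
    names = list(names) if names is not None else factor_names(design)
    missing = [n for n in names if f"{n}_coded" not in design.columns]
    if missing:
        raise KeyError(f"design lacks coded columns for factors {missing}")
    return design[[f"{n}_coded" for n in names]].to_numpy(dtype=float)


def with_central_at_zero(design: pd.DataFrame, factors: Sequence[Factor]) -> pd.DataFrame:
    """Display convention: snap each factor's central level to coded 0.

    The returned copy is for plotting/reporting only; model fitting should
    use the true coded values stored by :func:`full_factorial`.
    """
    out = design.copy()
    for f in factors:
        col = f"{f.name}_coded"
        if col not in out.columns:
            continue
        central = coded_central(f)
        out.loc[np.isclose(out[col].to_numpy(dtype=float), central), col] = 0.0
    return out


# ---------------------------------------------------------------------------
# delimited-table IO

def read_factors(path: str | Path) -> list[Factor]:
    """Read a factor table CSV with columns name, low_uM, central_uM, high_uM."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"name", "low_uM", "central_uM", "high_uM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"factor table {path} missing columns {sorted(missing)}")
    return [
        Factor(str(r["name"]), float(r["low_uM"]), float(r["central_uM"]), float(r["high_uM"]))
        for _, r in df.iterrows()
    ]


def write_factors(factors: Sequence[Factor], path: str | Path) -> None:
    pd.DataFrame(
        {
            "name": [f.name for f in factors],
            "low_uM": [f.low for f in factors],
            "central_uM": [f.central for f in factors],
            "high_uM": [f.high for f in factors],
        }
    ).to_csv(path, index=False)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("run_id", "replicate"):
        if col not in df.columns:
            raise ValueError(f"design table {path} missing column {col!r}")
    if not any(c.endswith("_coded") for c in df.columns):
        raise ValueError(f"design table {path} has no *_coded factor columns")
    return df
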