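"""End-to-end pipeline: design → responses → fits → surfaces → verdicts → report.

Each stage writes its table under the output directory, so a run can be
resumed or inspected stage by stage; the report JSON embeds the full
configuration and seed needed to regenerate it byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import reference
from .bioindication import RuleConfig, classify, summarize, summary_markdown
from .design import (Factor, full_factorial, read_design, read_factors,
                     replicate_design, write_design, write_factors)
from .rsm import fit_rsm, report_frame
from .simulate import GeneratorConfig, simulate_uptake
from .surfaces import render, surface

log = logging.getLogger("phytodoe")


@dataclass
class PipelineConfig:
    out_dir: Path = Path("phytodoe_out")
    factors_csv: Path | None = None          # default: the reference factors
    levels: tuple[str, ...] = ("low", "central", "high")
    replicates: int = 3
    alpha: float = 0.05
    interference_ratio: float = 1.0
    seed: int = 0
    responses_csv: Path | None = None        # supplied responses skip simulation
    noise_sd: dict[str, float] = field(default_factory=dict)
    truncate_at_zero: bool = False
    resolution: int = 41
    figures: bool = False
    responses: tuple[str, ...] = reference.RESPONSE_METALS

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        for key in ("out_dir", "factors_csv", "responses_csv"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        for key in ("levels", "responses"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        d["levels"] = list(self.levels)
        d["responses"] = list(self.responses)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _stage(name: str, **params) -> None:
    log.info("stage=%s %s", name,
             " ".join(f"{k}={v}" for k, v in params.items()))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report dict (also written to disk)."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    (out / "fits").mkdir(exist_ok=True)
    (out / "surfaces").mkdir(exist_ok=True)

    # -- design ------------------------------------------------------------
    try:
        factors = (read_factors(config.factors_csv) if config.factors_csv
                   else list(reference.FACTORS))
        design = replicate_design(full_factorial(factors, config.levels),
                                  config.replicates)
        design_path = out / "design.csv"
        write_design(design, design_path)
        write_factors(factors, out / "factors.csv")
        _stage("design", runs=design["run_id"].nunique(), rows=len(design),
               sha=_sha256(design_path))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'design' failed: {exc}") from exc

    # -- responses ---------------------------------------------------------
    try:
        if config.responses_csv is not None:
            responses = pd.read_csv(config.responses_csv,
                                    float_precision="round_trip")
            missing = [m for m in config.responses if m not in responses.columns]
            if missing:
                raise ValueError(f"responses file lacks columns {missing}")
            if len(responses) != len(design):
                raise ValueError(
                    f"responses have {len(responses)} rows, design has {len(design)}"
                )
            uptake = design.reset_index(drop=True).join(
                responses[list(config.responses)].reset_index(drop=True))
            source = "supplied"
        else:
            gen = GeneratorConfig(seed=config.seed,
                                  replicates=config.replicates,
                                  truncate_at_zero=config.truncate_at_zero)
            if config.noise_sd:
                gen.noise_sd = {**gen.noise_sd, **config.noise_sd}
            uptake = simulate_uptake(design, gen)
            source = "simulated"
        uptake_path = out / "responses.csv"
        uptake.to_csv(uptake_path, index=False)
        _stage("responses", source=source, sha=_sha256(uptake_path))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'responses' failed: {exc}") from exc

    # -- fits ----------------------------------------------------------------
    fits = {}
    try:
        for metal in config.responses:
            fit = fit_rsm(design, uptake[metal].to_numpy(), response=metal,
                          alpha=config.alpha)
            fits[metal] = fit
            report_frame(fit).to_csv(out / "fits" / f"{metal}.csv", index=False)
            fit.save_json(out / "fits" / f"{metal}.json")
        _stage("fit", models=len(fits), alpha=config.alpha)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'fit' failed: {exc}") from exc

    # -- surfaces ------------------------------------------------------------
    try:
        n_surfaces = 0
        for metal, fit in fits.items():
            for ax, ay in reference.SURFACE_AXES.get(metal, ()):
                grid = surface(fit, (ax, ay), resolution=config.resolution,
                               alpha=config.alpha)
                stem = out / "surfaces" / f"{metal}_{ax}_{ay}"
                grid.write_csv(stem.with_suffix(".csv"))
                if config.figures:
                    render(grid, stem.with_suffix(".png"), which="response")
                    render(grid, Path(str(stem) + "_semiamplitude.png"),
                           which="semiamplitude")
                n_surfaces += 1
        _stage("surfaces", n=n_surfaces, resolution=config.resolution)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'surfaces' failed: {exc}") from exc

    # -- verdicts ------------------------------------------------------------
    try:
        rules = RuleConfig(alpha=config.alpha,
                           interference_ratio=config.interference_ratio)
        fnames = [f.name for f in factors]
        verdicts = [
            classify(fits[m], m if m in fnames else None, rules)
            for m in config.responses
        ]
        verdict_summary = summarize(verdicts)
        (out / "verdicts.json").write_text(json.dumps(verdict_summary, indent=1))
        _stage("verdicts", positive=",".join(verdict_summary["positive"]) or "-")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'verdicts' failed: {exc}") from exc

    # -- report ---------------------------------------------------------------
    report = {
        "config": config.to_dict(),
        "seed": config.seed,
        "design": {"unique_runs": int(design["run_id"].nunique()),
                   "rows": int(len(design))},
        "fits": {m: {"terms": list(f.terms),
                     "coef": f.coef.tolist(),
                     "p": f.p.tolist(),
                     "stars": list(f.stars),
                     "residual_sd": f.residual_sd,
                     "dof": f.dof}
                 for m, f in fits.items()},
        "verdicts": verdict_summary,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    md = ["# Bioindication pipeline report", "",
          f"Design: {report['design']['unique_runs']} unique runs, "
          f"{report['design']['rows']} rows; responses {source}.", "",
          "## Coefficients", ""]
    for m, f in fits.items():
        md.append(f"### {m}")
        md.append(report_frame(f).to_markdown(index=False, floatfmt=".4g"))
        md.append("")
    md += ["## Verdicts", "", summary_markdown(verdicts), ""]
    (out / "report.md").write_text("\n".join(md))
    _stage("report", path=str(out / "report.json"))
    return report


def validate_inputs(factors_csv: Path | None = None,
                    design_csv: Path | None = None,
                    responses_csv: Path | None = None,
                    aas_csv: Path | None = None) -> list[str]:
    """Schema/invariant diagnostics for input tables; empty list = clean."""
    diags: list[str] = []

    if factors_csv is not None:
        try:
            df = pd.read_csv(factors_csv)
            required = ["name", "low_uM", "central_uM", "high_uM"]
            for col in required:
                if col not in df.columns:
                    diags.append(f"{factors_csv}: missing column {col!r}")
            if not diags:
                for i, row in df.iterrows():
                    try:
                        Factor(str(row["name"]), float(row["low_uM"]),
                               float(row["central_uM"]), float(row["high_uM"]))
                    except Exception as exc:
                        diags.append(f"{factors_csv}:{i + 2}: {exc}")
        except Exception as exc:
            diags.append(f"{factors_csv}: unreadable ({exc})")

    if design_csv is not None:
        try:
            read_design(design_csv)
        except Exception as exc:
            diags.append(f"{design_csv}: {exc}")

    if responses_csv is not None:
        try:
            df = pd.read_csv(responses_csv)
            for col in ("run_id", "replicate"):
                if col not in df.columns:
                    diags.append(f"{responses_csv}: missing column {col!r}")
            value_cols = [c for c in df.columns if c not in ("run_id", "replicate")]
            if not value_cols:
                diags.append(f"{responses_csv}: no response columns")
        except Exception as exc:
            diags.append(f"{responses_csv}: unreadable ({exc})")

    if aas_csv is not None:
        try:
            df = pd.read_csv(aas_csv)
            for col in ("sample_id", "metal", "peak_area", "blank_area",
                        "dilution", "mass_g", "volume_ml"):
                if col not in df.columns:
                    diags.append(f"{aas_csv}: missing column {col!r}")
        except Exception as exc:
            diags.append(f"{aas_csv}: unreadable ({exc})")

    return diags
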