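"""Bioindication verdicts from fitted coefficient tables.

A plant bioindicates a metal when its shoot concentration tracks the
medium concentration of that metal — a significant, positive linear own
term — without being driven by the other metals. The classifier formalises
that reading of a coefficient table:

1. A metal that was a varied factor is a candidate only if its own linear
   coefficient is significant and positive (more dosed → more absorbed).
2. Among candidates, significant terms involving *another* metal
   (interactions or that metal's square) are interference: none → clean
   bioindicator; all smaller in magnitude than ``interference_ratio`` times
   the own linear estimate → bioindicator with minor interference;
   otherwise not a bioindicator.
3. A metal that was held constant in the medium (no own factor) can only
   bioindicate if nothing in its model is significant at all — its uptake
   is then independent of the varied metals.

The candidate's own squared term is curvature of its own dose response,
not interference, and is ignored by rule 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from .rsm import RSMFit, coefficient_tests, term_factors


class Status(str, Enum):
    BIOINDICATOR = "bioindicator"
    MINOR_INTERFERENCE = "bioindicator_minor_interference"
    NOT_BIOINDICATOR = "not_bioindicator"

    @property
    def positive(self) -> bool:
        return self is not Status.NOT_BIOINDICATOR


@dataclass(frozen=True)
class RuleConfig:
    """Verdict thresholds: significance level and interference-size ratio."""

    alpha: float = 0.05
    interference_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.interference_ratio <= 0:
            raise ValueError("interference_ratio must be positive")


@dataclass
class Verdict:
    metal: str
    status: Status
    evidence: list[dict] = field(default_factory=list)

    @property
    def positive(self) -> bool:
        return self.status.positive

    def to_dict(self) -> dict:
        return {
            "metal": self.metal,
            "status": self.status.value,
            "positive": self.positive,
            "evidence": self.evidence,
        }


def _entry(fit: RSMFit, i: int, role: str) -> dict:
    p = None
    if fit.p is not None and np.isfinite(fit.p[i]):
        p = float(fit.p[i])
    return {
        "term": fit.terms[i],
        "estimate": float(fit.coef[i]),
        "p": p,
        "stars": fit.stars[i] if fit.stars else "",
        "role": role,
    }


def classify(fit: RSMFit, own_factor: str | None,
             rules: RuleConfig = RuleConfig()) -> Verdict:
    """Classify one response metal from its fitted (or published) model.

    ``own_factor`` names the design factor corresponding to the response
    metal, or ``None`` for responses held constant in the medium. Fits with
    p-values are re-annotated at ``rules.alpha``; published fits keep their
    printed significance flags.
    """
    if own_factor is not None and own_factor not in fit.factors:
        raise KeyError(
            f"own factor {own_factor!r} is not among the fit's factors {list(fit.factors)}"
        )
    fit = coefficient_tests(fit, alpha=rules.alpha)
    sig = np.asarray(fit.significant, dtype=bool)
    if sig.shape != (len(fit.terms),):
        raise ValueError("fit carries no significance annotations")

    non_intercept = [i for i, t in enumerate(fit.terms) if t != "Intercept"]

    if own_factor is None:
        hits = [i for i in non_intercept if sig[i]]
        if hits:
            return Verdict(fit.response, Status.NOT_BIOINDICATOR,
                           [_entry(fit, i, "foreign_significant") for i in hits])
        return Verdict(fit.response, Status.BIOINDICATOR, [])

    i_own = fit.terms.index(own_factor)
    own_est = float(fit.coef[i_own])
    if not sig[i_own] or own_est <= 0:
        return Verdict(fit.response, Status.NOT_BIOINDICATOR,
                       [_entry(fit, i_own, "own_linear_not_supporting")])

    evidence = [_entry(fit, i_own, "own_linear")]
    interfering = [
        i for i in non_intercept
        if sig[i] and not term_factors(fit.terms[i]) <= {own_factor}
    ]
    if not interfering:
        return Verdict(fit.response, Status.BIOINDICATOR, evidence)
    evidence += [_entry(fit, i, "interference") for i in interfering]
    if all(abs(float(fit.coef[i])) < rules.interference_ratio * abs(own_est)
           for i in interfering):
        return Verdict(fit.response, Status.MINOR_INTERFERENCE, evidence)
    return Verdict(fit.response, Status.NOT_BIOINDICATOR, evidence)


def summarize(verdicts: Sequence[Verdict]) -> dict:
    """Machine-readable summary of a batch of verdicts."""
    if not verdicts:
        raise ValueError("need at least one verdict")
    return {
        "n": len(verdicts),
        "positive": [v.metal for v in verdicts if v.positive],
        "negative": [v.metal for v in verdicts if not v.positive],
        "verdicts": [v.to_dict() for v in verdicts],
    }


def summary_markdown(verdicts: Sequence[Verdict]) -> str:
    lines = [
        "| Metal | Verdict | Evidence |",
        "| --- | --- | --- |",
    ]
    for v in verdicts:
        ev = "; ".join(
            f"{e['term']}={e['estimate']:g}{e['stars']} ({e['role']})"
            for e in v.evidence
        ) or "no significant terms"
        lines.append(f"| {v.metal} | {v.status.value} | {ev} |")
    pos = ", ".join(v.metal for v in verdicts if v.positive) or "none"
    lines.append("")
    lines.append(f"Bioindication supported for: {pos}.")
    return "\n".join(lines)


def write_verdicts(verdicts: Sequence[Verdict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(summarize(verdicts), indent=1))
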