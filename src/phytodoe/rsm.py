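"""Quadratic response-surface model: construction, OLS fit, inference, prediction.

For F coded factors :math:`x_1..x_F` the model of one response (shoot
concentration, mg kg⁻¹) is

.. math::

    y = b_0 + \\sum_i b_i x_i + \\sum_{i<j} b_{ij} x_i x_j
        + \\sum_i b_{ii} x_i^2 + \\varepsilon

fitted by ordinary least squares on the coded design. With three factors the
model matrix has the fixed column order
``[1, x1, x2, x3, x1x2, x1x3, x2x3, x1², x2², x3²]``; coefficient reports
use the matching symbols ``b0, b1, b2, b3, b12, b13, b23, b11, b22, b33``.

Inference is classical: residual variance on ``n − p`` degrees of freedom,
standard errors from ``s² diag((XᵀX)⁻¹)``, two-sided Student-t p-values,
and the conventional star labels (* p<0.05, ** p<0.01, *** p<0.001). The
stored ``(XᵀX)⁻¹`` matrix gives the prediction variance
``s² x₀ᵀ(XᵀX)⁻¹x₀`` used by the surface module for confidence
semiamplitudes. Coefficients are on the coded scale throughout, so their
magnitudes are directly comparable across factors.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats


class SingularDesignError(ValueError):
    """Raised when the model matrix is rank deficient; names the columns."""


def term_names(factors: Sequence[str]) -> list[str]:
    """Term labels in fixed order: intercept, linear, pairwise, squared."""
    names = ["Intercept"]
    names += list(factors)
    f = list(factors)
    names += [f"{f[i]}:{f[j]}" for i in range(len(f)) for j in range(i + 1, len(f))]
    names += [f"{m}^2" for m in f]
    return names


def term_symbols(n_factors: int) -> list[str]:
    """Classical b-subscript symbols matching :func:`term_names` order."""
    syms = ["b0"] + [f"b{i}" for i in range(1, n_factors + 1)]
    syms += [
        f"b{i}{j}"
        for i in range(1, n_factors + 1)
        for j in range(i + 1, n_factors + 1)
    ]
    syms += [f"b{i}{i}" for i in range(1, n_factors + 1)]
    return syms


def term_factors(term: str) -> frozenset[str]:
    """Set of factor names a term involves (empty for the intercept)."""
    if term == "Intercept":
        return frozenset()
    if term.endswith("^2"):
        return frozenset({term[:-2]})
    return frozenset(term.split(":"))


def quadratic_expand(points: np.ndarray) -> np.ndarray:
    """Expand (n, F) coded points into the (n, 1+F+F(F−1)/2+F) model matrix."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n, F = pts.shape
    cols = [np.ones(n)]
    cols += [pts[:, i] for i in range(F)]
    cols += [pts[:, i] * pts[:, j] for i in range(F) for j in range(i + 1, F)]
    cols += [pts[:, i] ** 2 for i in range(F)]
    return np.column_stack(cols)


def build_model_matrix(design: pd.DataFrame | np.ndarray,
                       factors: Sequence[str] | None = None
                       ) -> tuple[np.ndarray, list[str]]:
    """Model matrix and term names from a design table (or coded array).

    A DataFrame must carry one ``{factor}_coded`` column per factor; a bare
    array is taken as already-coded points, one factor per column.
    """
    if isinstance(design, pd.DataFrame):
        from .design import coded_matrix, factor_names
        names = list(factors) if factors is not None else factor_names(design)
        pts = coded_matrix(design, names)
    else:
        pts = np.atleast_2d(np.asarray(design, dtype=float))
        names = list(factors) if factors is not None else [
            f"x{i+1}" for i in range(pts.shape[1])
        ]
    return quadratic_expand(pts), term_names(names)


@dataclass
class RSMFit:
    """A fitted (or published) quadratic model for one response metal.

    ``xtx_inv``, ``residual_sd``, ``dof`` carry the inferential state needed
    for prediction standard errors; they are ``None`` on fits reconstructed
    from a published coefficient table, whose significance flags come from
    the printed stars instead of computed p-values.
    """

    response: str
    factors: tuple[str, ...]
    terms: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray | None = None
    t: np.ndarray | None = None
    p: np.ndarray | None = None
    stars: tuple[str, ...] = ()
    significant: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    residual_sd: float | None = None
    dof: int | None = None
    n_obs: int | None = None
    xtx_inv: np.ndarray | None = None
    alpha: float = 0.05

    @property
    def symbols(self) -> list[str]:
        return term_symbols(len(self.factors))

    def coef_by_symbol(self) -> dict[str, float]:
        return dict(zip(self.symbols, self.coef.tolist()))

    # -- prediction ---------------------------------------------------------

    def predict(self, point: Sequence[float]) -> tuple[float, float]:
        """Mean response and its standard error at a coded point.

        Points outside the coded cube [−1, +1]^F extrapolate; a warning is
        issued but the value is still returned. The standard error is NaN
        when the fit carries no inferential state (published coefficients).
        """
        x = np.asarray(point, dtype=float)
        if x.shape != (len(self.factors),):
            raise ValueError(
                f"expected a point of length {len(self.factors)}, got shape {x.shape}"
            )
        if np.any(np.abs(x) > 1.0 + 1e-9):
            warnings.warn(
                f"point {x.tolist()} lies outside the coded cube [-1, 1]^"
                f"{len(self.factors)}; extrapolating", stacklevel=2,
            )
        row = quadratic_expand(x[None, :])[0]
        yhat = float(row @ self.coef)
        if self.xtx_inv is None or self.residual_sd is None:
            return yhat, float("nan")
        var = self.residual_sd**2 * float(row @ self.xtx_inv @ row)
        return yhat, float(np.sqrt(max(var, 0.0)))

    def predict_many(self, points: np.ndarray, interval: str = "confidence"
                     ) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised mean response and se over (n, F) coded points.

        ``interval="prediction"`` adds the replicate-noise variance term,
        giving the se of a new observation rather than of the mean.
        """
        X = quadratic_expand(points)
        yhat = X @ self.coef
        if self.xtx_inv is None or self.residual_sd is None:
            return yhat, np.full(len(X), np.nan)
        leverage = np.einsum("ij,jk,ik->i", X, self.xtx_inv, X)
        if interval == "prediction":
            leverage = leverage + 1.0
        elif interval != "confidence":
            raise ValueError(f"unknown interval kind {interval!r}")
        se = self.residual_sd * np.sqrt(np.clip(leverage, 0.0, None))
        return yhat, se

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "response": self.response,
            "factors": list(self.factors),
            "terms": list(self.terms),
            "coef": arr(self.coef),
            "se": arr(self.se),
            "t": arr(self.t),
            "p": arr(self.p),
            "stars": list(self.stars),
            "significant": arr(self.significant.astype(int)),
            "residual_sd": self.residual_sd,
            "dof": self.dof,
            "n_obs": self.n_obs,
            "xtx_inv": arr(self.xtx_inv),
            "alpha": self.alpha,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RSMFit":
        def arr(a, dtype=float):
            return None if a is None else np.asarray(a, dtype=dtype)

        return cls(
            response=d["response"],
            factors=tuple(d["factors"]),
            terms=tuple(d["terms"]),
            coef=arr(d["coef"]),
            se=arr(d.get("se")),
            t=arr(d.get("t")),
            p=arr(d.get("p")),
            stars=tuple(d.get("stars", ())),
            significant=np.asarray(d.get("significant", []), dtype=bool),
            residual_sd=d.get("residual_sd"),
            dof=d.get("dof"),
            n_obs=d.get("n_obs"),
            xtx_inv=arr(d.get("xtx_inv")),
            alpha=d.get("alpha", 0.05),
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load_json(cls, path: str | Path) -> "RSMFit":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_published(cls, response: str, factors: Sequence[str],
                       coef: Sequence[float] | np.ndarray,
                       stars: Sequence[str]) -> "RSMFit":
        """Reconstruct a fit from a printed coefficient column and its stars.

        Such a fit predicts mean responses and feeds the verdict rules, but
        carries no standard errors or information matrix.
        """
        factors = tuple(factors)
        terms = tuple(term_names(factors))
        coef = np.asarray(coef, dtype=float)
        if coef.shape != (len(terms),):
            raise ValueError(
                f"expected {len(terms)} coefficients for {len(factors)} factors, "
                f"got {coef.shape}"
            )
        stars = tuple(stars)
        if len(stars) != len(terms):
            raise ValueError("stars must align with the coefficient vector")
        return cls(
            response=response, factors=factors, terms=terms, coef=coef,
            stars=stars, significant=np.array([s != "" for s in stars]),
        )


def stars_for(p: float) -> str:
    """Significance star label for a two-sided p-value."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def fit_rsm(X: np.ndarray | pd.DataFrame, y: Sequence[float],
            response: str = "y",
            factors: Sequence[str] | None = None,
            run_means: bool = False,
            alpha: float = 0.05) -> RSMFit:
    """Ordinary-least-squares fit of the quadratic model.

    ``X`` is either a prebuilt model matrix (with ``factors`` naming the
    coded columns it was built from) or a design DataFrame, in which case
    the model matrix is constructed here. With ``run_means=True`` and a
    design DataFrame, replicate observations are averaged per run before
    fitting (the default uses every replicate, so replication contributes
    pure-error information to the residual variance).
    """
    if isinstance(X, pd.DataFrame):
        design = X
        yv = np.asarray(y, dtype=float)
        if run_means:
            tmp = design.copy()
            tmp["__y"] = yv
            agg = {c: "first" for c in design.columns
                   if c not in ("replicate", "run_id")}
            agg["__y"] = "mean"
            tmp = tmp.groupby("run_id", as_index=False, sort=False).agg(agg)
            yv = tmp.pop("__y").to_numpy()
            design = tmp
        Xm, terms = build_model_matrix(design, factors)
        from .design import factor_names
        fnames = tuple(factors) if factors is not None else tuple(factor_names(design))
    else:
        Xm = np.asarray(X, dtype=float)
        yv = np.asarray(y, dtype=float)
        if factors is None:
            # infer F from the quadratic column count 1 + 2F + F(F-1)/2
            p = Xm.shape[1]
            F = next((f for f in range(1, 12) if 1 + 2 * f + f * (f - 1) // 2 == p), None)
            if F is None:
                raise ValueError(f"cannot infer factor count from {p} columns")
            factors = [f"x{i+1}" for i in range(F)]
        fnames = tuple(factors)
        terms = term_names(fnames)

    n, p = Xm.shape
    if len(yv) != n:
        raise ValueError(f"y has length {len(yv)}, model matrix has {n} rows")
    dof = n - p
    if dof <= 0:
        raise ValueError(f"non-positive degrees of freedom: {n} observations, {p} terms")

    rank = np.linalg.matrix_rank(Xm)
    if rank < p:
        # pivoted QR localises the dependent columns
        _, _, piv = linalg.qr(Xm, mode="economic", pivoting=True)
        bad = sorted(terms[j] for j in piv[rank:])
        raise SingularDesignError(
            f"model matrix is rank deficient (rank {rank} < {p}); "
            f"linearly dependent columns: {bad}"
        )

    coef, _, _, _ = np.linalg.lstsq(Xm, yv, rcond=None)
    resid = yv - Xm @ coef
    rss = float(resid @ resid)
    residual_sd = float(np.sqrt(rss / dof))
    xtx_inv = np.linalg.inv(Xm.T @ Xm)
    se = residual_sd * np.sqrt(np.diag(xtx_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)

    fit = RSMFit(
        response=response, factors=fnames, terms=tuple(terms),
        coef=coef, se=se, t=tval, p=pval,
        residual_sd=residual_sd, dof=dof, n_obs=n, xtx_inv=xtx_inv,
    )
    return coefficient_tests(fit, alpha=alpha)


def coefficient_tests(fit: RSMFit, alpha: float = 0.05) -> RSMFit:
    """Annotate a fit with significance flags (p < alpha) and star labels."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if fit.p is None:
        # published fits: flags come from the stars, alpha recorded only
        return dataclasses.replace(fit, alpha=alpha)
    stars = tuple(stars_for(pv) for pv in fit.p)
    significant = fit.p < alpha
    return dataclasses.replace(fit, stars=stars, significant=significant, alpha=alpha)


def predict(fit: RSMFit, point: Sequence[float]) -> tuple[float, float]:
    """Module-level alias for :meth:`RSMFit.predict`."""
    return fit.predict(point)


def report_frame(fit: RSMFit) -> pd.DataFrame:
    """Coefficient table (symbol, term, estimate, se, t, p, stars)."""
    n = len(fit.terms)
    nan = np.full(n, np.nan)
    return pd.DataFrame(
        {
            "symbol": fit.symbols,
            "term": list(fit.terms),
            "estimate": fit.coef,
            "se": fit.se if fit.se is not None else nan,
            "t": fit.t if fit.t is not None else nan,
            "p": fit.p if fit.p is not None else nan,
            "stars": list(fit.stars) if fit.stars else [""] * n,
        }
    )


def natural_units_coefficients(fit: RSMFit, factor_objs) -> dict[str, float]:
    """Back-transform coded-scale coefficients to natural (µM) units.

    Helper for interpretation only: substitutes
    ``x_i = (c_i − mid_i)/half_i`` into the quadratic and collects terms.
    Reports use the coded scale, where magnitudes are comparable.
    """
    mids = np.array([f.midrange for f in factor_objs])
    halves = np.array([f.halfwidth for f in factor_objs])
    F = len(factor_objs)
    syms = fit.symbols
    b = dict(zip(syms, fit.coef))
    lin = {i: b[f"b{i+1}"] / halves[i] for i in range(F)}
    quad = {i: b[f"b{i+1}{i+1}"] / halves[i] ** 2 for i in range(F)}
    cross = {}
    k = 0
    for i in range(F):
        for j in range(i + 1, F):
            cross[(i, j)] = b[f"b{i+1}{j+1}"] / (halves[i] * halves[j])
            k += 1
    out = {}
    const = b["b0"]
    for i in range(F):
        const += -lin[i] * mids[i] + quad[i] * mids[i] ** 2
    for (i, j), c in cross.items():
        const += c * mids[i] * mids[j]
    out["b0"] = const
    for i in range(F):
        li = lin[i] - 2.0 * quad[i] * mids[i]
        for (a, jj), c in cross.items():
            if a == i:
                li -= c * mids[jj]
            elif jj == i:
                li -= c * mids[a]
        out[f"b{i+1}"] = li
    for (i, j), c in cross.items():
        out[f"b{i+1}{j+1}"] = c
    for i in range(F):
        out[f"b{i+1}{i+1}"] = quad[i]
    return out
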