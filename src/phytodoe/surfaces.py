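"""Response surfaces and confidence-semiamplitude grids over two factors.

The fitted model is evaluated on a regular lattice over the coded square
[−1, +1]² of two chosen factors, with the remaining factor(s) held at fixed
coded values (0 by default — the convention of the published figures, even
though the design's true central levels code slightly below 0). Alongside
the predicted response, the half-width of the 95% confidence interval of
the mean response (the "semiamplitude", ``t(1−α/2, dof) × se(ŷ)``) is
gridded; nodes where |ŷ| exceeds it form the region where the response is
significantly different from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rsm import RSMFit


@dataclass
class SurfaceGrid:
    """Gridded surface values over two coded factors.

    ``x`` runs along the abscissa (first axis factor), ``y`` along the
    ordinate; value arrays are indexed ``[iy, ix]`` (row = ordinate node).
    """

    response_name: str
    axes: tuple[str, str]
    fixed: dict[str, float]
    x: np.ndarray
    y: np.ndarray
    response: np.ndarray | None = None
    semiamplitude: np.ndarray | None = None
    significant: np.ndarray | None = None
    alpha: float | None = None

    def same_lattice(self, other: "SurfaceGrid") -> bool:
        return (
            self.axes == other.axes
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: x, y, response, semiamplitude, significant."""
        xx, yy = np.meshgrid(self.x, self.y)
        data = {"x": xx.ravel(), "y": yy.ravel()}
        if self.response is not None:
            data["response"] = self.response.ravel()
        if self.semiamplitude is not None:
            data["semiamplitude"] = self.semiamplitude.ravel()
        if self.significant is not None:
            data["significant"] = self.significant.ravel()
        return pd.DataFrame(data)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _lattice_points(fit: RSMFit, axes: Sequence[str], fixed: dict[str, float],
                    resolution: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ax, ay = axes
    if ax == ay:
        raise ValueError("axis factors must be distinct")
    for a in (ax, ay):
        if a not in fit.factors:
            raise KeyError(f"unknown factor {a!r}; fit has {list(fit.factors)}")
    if resolution < 2:
        raise ValueError("resolution must be at least 2 nodes per axis")
    others = [f for f in fit.factors if f not in (ax, ay)]
    unknown_fixed = set(fixed) - set(others)
    if unknown_fixed:
        raise KeyError(f"fixed levels given for non-held factors {sorted(unknown_fixed)}")
    x = np.linspace(-1.0, 1.0, resolution)
    y = np.linspace(-1.0, 1.0, resolution)
    xx, yy = np.meshgrid(x, y)
    pts = np.zeros((resolution * resolution, len(fit.factors)))
    idx = {f: i for i, f in enumerate(fit.factors)}
    pts[:, idx[ax]] = xx.ravel()
    pts[:, idx[ay]] = yy.ravel()
    for f in others:
        pts[:, idx[f]] = fixed.get(f, 0.0)
    return x, y, pts


def response_grid(fit: RSMFit, axes: Sequence[str],
                  fixed: dict[str, float] | None = None,
                  resolution: int = 41) -> SurfaceGrid:
    """Predicted mean response over the coded square of two factors."""
    fixed = dict(fixed or {})
    x, y, pts = _lattice_points(fit, axes, fixed, resolution)
    yhat, _ = fit.predict_many(pts)
    return SurfaceGrid(
        response_name=fit.response, axes=(axes[0], axes[1]), fixed=fixed,
        x=x, y=y, response=yhat.reshape(resolution, resolution),
    )


def semiamplitude_grid(fit: RSMFit, axes: Sequence[str],
                       fixed: dict[str, float] | None = None,
                       resolution: int = 41, alpha: float = 0.05,
                       interval: str = "confidence") -> SurfaceGrid:
    """Half-width of the (1−alpha) interval of the mean response, per node.

    ``interval="prediction"`` widens to a new-observation interval.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if fit.dof is None or fit.residual_sd is None or fit.xtx_inv is None:
        raise ValueError(
            "fit carries no inferential state (published coefficients?); "
            "semiamplitudes need a fitted model"
        )
    fixed = dict(fixed or {})
    x, y, pts = _lattice_points(fit, axes, fixed, resolution)
    _, se = fit.predict_many(pts, interval=interval)
    tq = stats.t.ppf(1.0 - alpha / 2.0, fit.dof)
    return SurfaceGrid(
        response_name=fit.response, axes=(axes[0], axes[1]), fixed=fixed,
        x=x, y=y, semiamplitude=(tq * se).reshape(resolution, resolution),
        alpha=alpha,
    )


def significance_mask(response: SurfaceGrid, semi: SurfaceGrid) -> np.ndarray:
    """Boolean grid: |predicted response| exceeds the semiamplitude."""
    if not response.same_lattice(semi):
        raise ValueError("response and semiamplitude grids are on different lattices")
    if response.response is None or semi.semiamplitude is None:
        raise ValueError("need a response grid and a semiamplitude grid")
    return np.abs(response.response) > semi.semiamplitude


def surface(fit: RSMFit, axes: Sequence[str],
            fixed: dict[str, float] | None = None,
            resolution: int = 41, alpha: float = 0.05) -> SurfaceGrid:
    """Response, semiamplitude and significance mask on one lattice."""
    rsp = response_grid(fit, axes, fixed, resolution)
    semi = semiamplitude_grid(fit, axes, fixed, resolution, alpha)
    mask = significance_mask(rsp, semi)
    return replace(rsp, semiamplitude=semi.semiamplitude, significant=mask,
                   alpha=alpha)


def render(grid: SurfaceGrid, path: str | Path, n_levels: int = 10,
           which: str = "response") -> Path:
    """Write a filled-contour plot with iso-level lines, axes in coded units."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = getattr(grid, which)
    if values is None:
        raise ValueError(f"grid holds no {which!r} values")
    values = np.asarray(values, dtype=float)
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < 1e-12:
        # degenerate constant surface: a single level
        levels = np.array([lo - 1e-9, lo + 1e-9])
    else:
        levels = np.linspace(lo, hi, n_levels)

    fig, ax = plt.subplots(figsize=(5, 4))
    cf = ax.contourf(grid.x, grid.y, values, levels=levels, cmap="viridis",
                     extend="both")
    ax.contour(grid.x, grid.y, values, levels=levels, colors="k",
               linewidths=0.5)
    ax.set_xlabel(f"{grid.axes[0]} (coded)")
    ax.set_ylabel(f"{grid.axes[1]} (coded)")
    fixed = ", ".join(f"{k}={v:g}" for k, v in grid.fixed.items()) or "none"
    label = {"response": "predicted response (mg/kg)",
             "semiamplitude": "95% CI semiamplitude (mg/kg)"}.get(which, which)
    ax.set_title(f"{grid.response_name}: {label}\nfixed: {fixed}", fontsize=9)
    fig.colorbar(cf, ax=ax)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def contour_levels(values: np.ndarray, n_levels: int = 10) -> np.ndarray:
    """The evenly spaced levels :func:`render` draws over a value range."""
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi - lo < 1e-12:
        return np.array([lo])
    return np.linspace(lo, hi, n_levels)
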