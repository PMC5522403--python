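"""Compressive spatial summation (CSS) population receptive field model.

A voxel's receptive field is an isotropic 2-D Gaussian

    G(x, y) = exp(-((x - x0)^2 + (y - y0)^2) / (2 sigma^2))

and its neural response to a binary stimulus frame S is the spatially
summed stimulus drive passed through a static power law,

    r(t) = beta * [ sum_xy S(x, y, t) G(x, y) dA ]^n ,

with exponent n in (0, 1]; n = 1 recovers the conventional linear pRF
model, n < 1 produces compressive (subadditive) spatial summation.  The
BOLD prediction is r(t) convolved with a hemodynamic response function
sampled at TR resolution.

Fitting is two-stage: a coarse grid over (x0, y0, sigma, n) with the
amplitude beta solved in closed form by least squares at every grid point,
followed by bounded derivative-free refinement (Powell) from the best
coarse point, again with beta profiled out.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .stimulus import ApertureMovie, FieldGrid

__all__ = [
    "PRFParams",
    "VoxelTimeSeries",
    "PRFFit",
    "CoverageMap",
    "SearchConfig",
    "gaussian_field",
    "css_response",
    "double_gamma_hrf",
    "predict_bold",
    "fit_prf",
    "fit_many",
    "coarse_fit",
    "average_runs_by_width",
    "coverage_map",
    "fits_to_frame",
]


@dataclass(frozen=True)
class PRFParams:
    """CSS pRF parameters: center (deg), size (deg), exponent, amplitude."""

    x0: float
    y0: float
    sigma: float
    n_exp: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.n_exp <= 0:
            raise ValueError(f"n_exp must be positive, got {self.n_exp}")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


@dataclass
class VoxelTimeSeries:
    """BOLD signal for one voxel at TR resolution."""

    values: np.ndarray
    tr_s: float = 2.0
    run_id: str | None = None
    width_deg: float | None = None  # bar-width label for per-width averaging

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")


@dataclass
class PRFFit:
    """Best-fit parameters plus goodness of fit for one voxel."""

    params: PRFParams
    variance_explained: float
    converged: bool = True
    voxel_id: int | str | None = None

    @property
    def polar_angle(self) -> float:
        """atan2(y0, x0), radians in (-pi, pi]."""
        return math.atan2(self.params.y0, self.params.x0)

    @property
    def eccentricity(self) -> float:
        return math.hypot(self.params.x0, self.params.y0)


@dataclass
class CoverageMap:
    """Per-pixel visual-field coverage density in [0, 1]."""

    grid: FieldGrid
    density: np.ndarray

    def hemifield_integrals(self) -> tuple[float, float]:
        """(left, right) hemifield density integrals (deg^2)."""
        xx, _ = self.grid.meshgrid()
        a = self.grid.pixel_area
        left = float(self.density[xx < 0].sum() * a)
        right = float(self.density[xx > 0].sum() * a)
        return left, right


def gaussian_field(params: PRFParams, grid: FieldGrid) -> np.ndarray:
    """Unit-peak isotropic Gaussian receptive field sampled on the grid."""
    xx, yy = grid.meshgrid()
    return np.exp(-((xx - params.x0) ** 2 + (yy - params.y0) ** 2)
                  / (2.0 * params.sigma ** 2))


def css_response(params: PRFParams, movie: ApertureMovie) -> np.ndarray:
    """Neural response per frame: beta * (stimulus-Gaussian overlap)^n."""
    g = gaussian_field(params, movie.grid)
    drive = movie.frames.reshape(movie.n_frames, -1).astype(float) @ g.ravel()
    drive *= movie.grid.pixel_area
    return params.beta * drive ** params.n_exp


def double_gamma_hrf(tr_s: float = 2.0, duration_s: float = 32.0,
                     peak_s: float = 6.0, undershoot_s: float = 16.0,
                     undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR resolution, unit peak."""
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    t = np.arange(0.0, duration_s + tr_s / 2, tr_s)
    h = stats.gamma.pdf(t, peak_s) - undershoot_ratio * stats.gamma.pdf(t, undershoot_s)
    return h / h.max()


def predict_bold(params: PRFParams, movie: ApertureMovie, hrf: np.ndarray,
                 baseline: float = 0.0) -> VoxelTimeSeries:
    """Convolve the CSS neural response with an HRF, truncated to movie length."""
    hrf = np.asarray(hrf, dtype=float)
    if hrf.size == 0:
        raise ValueError("hrf must be non-empty")
    neural = css_response(params, movie)
    bold = np.convolve(neural, hrf)[: movie.n_frames] + baseline
    return VoxelTimeSeries(values=bold, tr_s=movie.tr_s, width_deg=movie.width_deg)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class SearchConfig:
    """Coarse-grid and refinement settings for :func:`fit_prf`.

    The coarse lattice covers center positions on an ``n_xy`` x ``n_xy``
    grid within the stimulus extent, log-spaced sigmas and a handful of
    exponents; refinement is bounded Powell with beta profiled out.
    """

    n_xy: int = 9
    sigmas: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 6.0)
    n_exps: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
    sigma_bounds: tuple[float, float] = (0.25, 8.0)
    n_bounds: tuple[float, float] = (0.05, 1.0)
    sse_tol: float = 1e-6
    max_iter: int = 500

    def lattice(self, extent: float) -> np.ndarray:
        """(K, 4) array of coarse (x0, y0, sigma, n) combinations.

        Row-major order over (x0, y0, sigma, n) with x0 slowest, so ties
        resolve deterministically to the first-encountered minimum.
        """
        xs = np.linspace(-extent, extent, self.n_xy)
        combos = [(x, y, s, n)
                  for x in xs for y in xs
                  for s in self.sigmas for n in self.n_exps]
        return np.array(combos, dtype=float)


class CoarsePredictions:
    """Predicted (beta = 1) BOLD time series for every coarse lattice point.

    Building this is the expensive part of the coarse stage and depends only
    on the movie, HRF and search configuration, so it is shared across
    voxels by :func:`fit_many`.
    """

    def __init__(self, movie: ApertureMovie, cfg: SearchConfig, hrf: np.ndarray):
        self.lattice = cfg.lattice(movie.grid.extent_deg)
        xx, yy = movie.grid.meshgrid()
        pts = np.column_stack([xx.ravel(), yy.ravel()])  # (P, 2)
        S = movie.frames.reshape(movie.n_frames, -1).astype(float)
        # Gaussians for all lattice points: (K, P)
        d2 = ((pts[None, :, 0] - self.lattice[:, None, 0]) ** 2
              + (pts[None, :, 1] - self.lattice[:, None, 1]) ** 2)
        G = np.exp(-d2 / (2.0 * self.lattice[:, None, 2] ** 2))
        drive = (S @ G.T) * movie.grid.pixel_area  # (T, K)
        neural = drive ** self.lattice[None, :, 3]
        hrf = np.asarray(hrf, dtype=float)
        T = movie.n_frames
        full = np.apply_along_axis(lambda c: np.convolve(c, hrf)[:T], 0, neural)
        self.pred = full.T  # (K, T)
        self.pred_ss = np.einsum("kt,kt->k", self.pred, self.pred)


def _coarse_best(ts: np.ndarray, coarse: CoarsePredictions) -> tuple[int, float, float]:
    """Best coarse lattice index, its closed-form beta and SSE."""
    proj = coarse.pred @ ts  # (K,)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(coarse.pred_ss > 0, proj / coarse.pred_ss, 0.0)
    beta = np.maximum(beta, 0.0)
    yy = float(ts @ ts)
    sse = yy - 2.0 * beta * proj + beta ** 2 * coarse.pred_ss
    k = int(np.argmin(sse))
    return k, float(beta[k]), float(sse[k])


def coarse_fit(ts: VoxelTimeSeries, movie: ApertureMovie, cfg: SearchConfig | None = None,
               hrf: np.ndarray | None = None,
               coarse: CoarsePredictions | None = None) -> tuple[PRFParams, int]:
    """Coarse-grid stage only: best lattice params (with profiled beta) and index."""
    cfg = cfg or SearchConfig()
    if hrf is None:
        hrf = double_gamma_hrf(movie.tr_s)
    if coarse is None:
        coarse = CoarsePredictions(movie, cfg, hrf)
    y = np.asarray(ts.values, dtype=float)
    if np.isnan(y).any():
        raise ValueError("time series contains NaNs")
    k, beta, _ = _coarse_best(y, coarse)
    x0, y0, s, n = coarse.lattice[k]
    return PRFParams(x0, y0, s, n, beta), k


def _sse_profiled(theta: np.ndarray, y: np.ndarray, S: np.ndarray,
                  pixel_area: float, pts: np.ndarray, hrf: np.ndarray,
                  T: int) -> tuple[float, float]:
    x0, y0, sigma, n = theta
    g = np.exp(-((pts[:, 0] - x0) ** 2 + (pts[:, 1] - y0) ** 2) / (2.0 * sigma ** 2))
    drive = (S @ g) * pixel_area
    neural = drive ** n
    pred = np.convolve(neural, hrf)[:T]
    pp = float(pred @ pred)
    beta = max(0.0, float(pred @ y) / pp) if pp > 0 else 0.0
    resid = y - beta * pred
    return float(resid @ resid), beta


def fit_prf(ts: VoxelTimeSeries, movie: ApertureMovie, cfg: SearchConfig | None = None,
            hrf: np.ndarray | None = None,
            coarse: CoarsePredictions | None = None,
            voxel_id: int | str | None = None) -> PRFFit:
    """Fit the CSS pRF model to one voxel's time series.

    Returns the refined parameters and variance explained
    (1 - SS_res / SS_tot).  A constant (zero-variance) series is flagged
    not-converged with variance_explained 0 rather than raising.
    """
    cfg = cfg or SearchConfig()
    if hrf is None:
        hrf = double_gamma_hrf(movie.tr_s)
    y = np.asarray(ts.values, dtype=float)
    if len(y) != movie.n_frames:
        raise ValueError(
            f"time series length {len(y)} != movie frame count {movie.n_frames}")
    if np.isnan(y).any():
        raise ValueError("time series contains NaNs")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return PRFFit(PRFParams(0.0, 0.0, 1.0, 1.0, 0.0),
                      variance_explained=0.0, converged=False, voxel_id=voxel_id)

    if coarse is None:
        coarse = CoarsePredictions(movie, cfg, hrf)
    k, _, _ = _coarse_best(y, coarse)
    x0, y0, s0, n0 = coarse.lattice[k]

    extent = movie.grid.extent_deg
    bounds = [(-extent, extent), (-extent, extent), cfg.sigma_bounds, cfg.n_bounds]
    S = movie.frames.reshape(movie.n_frames, -1).astype(float)
    xx, yy = movie.grid.meshgrid()
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    hrf = np.asarray(hrf, dtype=float)
    T = movie.n_frames

    def objective(theta: np.ndarray) -> float:
        return _sse_profiled(theta, y, S, movie.grid.pixel_area, pts, hrf, T)[0]

    theta0 = np.clip([x0, y0, s0, n0],
                     [b[0] for b in bounds], [b[1] for b in bounds])
    res = optimize.minimize(
        objective, theta0, method="Powell", bounds=bounds,
        options={"xtol": 1e-7, "ftol": cfg.sse_tol * 1e-3,
                 "maxiter": cfg.max_iter})
    # one restart from the solution tightens shallow-valley convergence
    res2 = optimize.minimize(
        objective, res.x, method="Powell", bounds=bounds,
        options={"xtol": 1e-8, "ftol": cfg.sse_tol * 1e-4,
                 "maxiter": cfg.max_iter})
    best = res2 if res2.fun <= res.fun else res
    sse, beta = _sse_profiled(best.x, y, S, movie.grid.pixel_area, pts, hrf, T)
    ve = max(0.0, min(1.0, 1.0 - sse / ss_tot))
    params = PRFParams(float(best.x[0]), float(best.x[1]),
                       float(best.x[2]), float(best.x[3]), beta)
    return PRFFit(params, variance_explained=ve,
                  converged=bool(best.success or res.success), voxel_id=voxel_id)


def fit_many(Y: np.ndarray, movie: ApertureMovie, cfg: SearchConfig | None = None,
             hrf: np.ndarray | None = None, tr_s: float | None = None) -> list[PRFFit]:
    """Fit every row of a (voxels, TRs) array, sharing the coarse stage."""
    cfg = cfg or SearchConfig()
    if hrf is None:
        hrf = double_gamma_hrf(movie.tr_s)
    coarse = CoarsePredictions(movie, cfg, hrf)
    tr = tr_s if tr_s is not None else movie.tr_s
    return [fit_prf(VoxelTimeSeries(row, tr_s=tr), movie, cfg, hrf,
                    coarse=coarse, voxel_id=i)
            for i, row in enumerate(np.asarray(Y, dtype=float))]


def average_runs_by_width(runs: list[VoxelTimeSeries]) -> dict[float, VoxelTimeSeries]:
    """Average runs pointwise within each bar-width label, widths kept apart."""
    if not runs:
        raise ValueError("need at least one run")
    by_width: dict[float, list[VoxelTimeSeries]] = {}
    for r in runs:
        by_width.setdefault(r.width_deg, []).append(r)
    out: dict[float, VoxelTimeSeries] = {}
    for w, group in by_width.items():
        lengths = {len(g.values) for g in group}
        if len(lengths) != 1:
            raise ValueError(f"length mismatch within width {w}: {sorted(lengths)}")
        trs = {g.tr_s for g in group}
        if len(trs) != 1:
            raise ValueError(f"TR mismatch within width {w}")
        mean = np.mean([g.values for g in group], axis=0)
        out[w] = VoxelTimeSeries(mean, tr_s=group[0].tr_s, width_deg=w)
    return out


def coverage_map(fits: list[PRFFit], grid: FieldGrid,
                 ve_threshold: float = 0.1) -> CoverageMap:
    """Visual-field coverage: pointwise max of unit-peak Gaussian fields.

    Voxels below the variance-explained threshold are excluded; if nothing
    passes, an all-zero map is returned with a warning.
    """
    if not 0 <= ve_threshold < 1:
        raise ValueError("ve_threshold must be in [0, 1)")
    density = np.zeros((grid.n_pix, grid.n_pix))
    included = [f for f in fits if f.variance_explained >= ve_threshold]
    if not included:
        warnings.warn("no voxel passes the variance-explained threshold; "
                      "coverage map is empty", stacklevel=2)
        return CoverageMap(grid=grid, density=density)
    for f in included:
        g = gaussian_field(PRFParams(f.params.x0, f.params.y0, f.params.sigma), grid)
        np.maximum(density, g, out=density)
    return CoverageMap(grid=grid, density=density)


def fits_to_frame(fits: list[PRFFit]):
    """Tabulate fits (one row per voxel) for CSV export."""
    import pandas as pd

    rows = [{
        "voxel_id": f.voxel_id,
        "x0": f.params.x0, "y0": f.params.y0,
        "sigma": f.params.sigma, "n_exp": f.params.n_exp,
        "beta": f.params.beta,
        "variance_explained": f.variance_explained,
        "polar_angle": f.polar_angle, "eccentricity": f.eccentricity,
        "converged": f.converged,
    } for f in fits]
    return pd.DataFrame(rows)
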