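"""Confounder-corrected PDFF / R2* / field-map estimation.

Three estimators over the standard single-R2* multi-peak fat-water model:

``magnitude_fit``
    Per-voxel bounded nonlinear least squares of the magnitude model
    ``|W + F c_n| exp(-R2* TE_n)`` against the magnitude data.  Phase-error
    robust, but inherently ambiguous about fat/water dominance, so both a
    water-dominant and a fat-dominant initialization are tried and the
    lower-residual solution kept.

``estimate_field_map`` + ``complex_fit``
    The field map psi is estimated by minimizing the sum of per-voxel
    variable-projection residuals ``D(psi)`` over a discrete psi grid plus a
    pairwise smoothness penalty ``lambda * |psi_v - psi_u|``, solved with
    iterated conditional modes (ICM, checkerboard sweeps; the cost is
    non-increasing by construction).  Given psi, the complex fit demodulates
    the data, finds R2* by 1-D search on the variable-projection residual,
    and solves linearly for complex (W, F).

``hybrid_fit``
    Per-voxel minimization of the convex combination
    ``w * (complex residual) + (1 - w) * (magnitude residual)``, initialized
    from the complex fit; the endpoints w = 1 and w = 0 delegate to the
    complex and magnitude fits exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .acquisition_sim import EchoSeries
from .sequence_design import _magnitude_model_jacobian
from .signal_model import FatSpectrum, fat_phasor

R2STAR_CAP_S = 1000.0
PDFF_CLIP_PCT = (-5.0, 105.0)


@dataclass
class FitResult:
    """Quantitative maps produced by one fitting method.

    ``pdff_pct`` is clipped to the display range [-5, 105] %;
    ``pdff_raw_pct`` retains unclipped values so statistics are undistorted.
    Voxels with no usable signal are False in ``valid`` and NaN in the maps.
    """

    pdff_pct: np.ndarray
    pdff_raw_pct: np.ndarray
    r2star_map: np.ndarray
    psi_map: np.ndarray
    water_map: np.ndarray
    fat_map: np.ndarray
    residual_map: np.ndarray
    valid: np.ndarray
    method_tag: str

    def __post_init__(self) -> None:
        shape = self.pdff_pct.shape
        for name in ("pdff_raw_pct", "r2star_map", "psi_map", "water_map",
                     "fat_map", "residual_map", "valid"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape mismatch")


def _finalize_maps(shape, w, f, r2s, psi, resid, valid, tag) -> FitResult:
    total = w + f
    with np.errstate(invalid="ignore", divide="ignore"):
        pdff_raw = np.where(total > 0, 100.0 * f / total, np.nan)
    pdff_raw = np.where(valid, pdff_raw, np.nan)
    return FitResult(
        pdff_pct=np.clip(pdff_raw, *PDFF_CLIP_PCT),
        pdff_raw_pct=pdff_raw,
        r2star_map=np.where(valid, r2s, np.nan),
        psi_map=np.where(valid, psi, np.nan),
        water_map=np.where(valid, w, np.nan),
        fat_map=np.where(valid, f, np.nan),
        residual_map=np.where(valid, resid, np.nan),
        valid=valid,
        method_tag=tag,
    )


def _valid_mask(series: EchoSeries, mask: np.ndarray | None) -> np.ndarray:
    signal = np.abs(series.images).max(axis=0)
    valid = signal > 1e-12 * max(signal.max(), 1e-300)
    if mask is not None:
        valid &= mask
    return valid


def magnitude_fit(
    series: EchoSeries,
    spectrum: FatSpectrum,
    b0_t: float | None = None,
    *,
    mask: np.ndarray | None = None,
    species_scaling: tuple[float, float] = (1.0, 1.0),
    inits: tuple[str, ...] = ("water", "fat"),
    r2star_cap_s: float = R2STAR_CAP_S,
) -> FitResult:
    """Magnitude-based per-voxel fit of (W, F, R2*).

    ``species_scaling = (g_w, g_f)`` models known multiplicative signal
    factors on water and fat (e.g. steady-state saturation levels); the
    returned W and F are the descaled proton densities, so fitting
    steady-state data with its matching scaling removes the T1 bias.
    ``mask`` restricts the (per-voxel, iterative) fit to a subset of voxels.
    """
    if series.n_echoes < 4:
        raise ValueError("magnitude fitting needs at least 4 echoes")
    b0 = series.params.b0_t if b0_t is None else b0_t
    g_w, g_f = species_scaling
    tes = np.asarray(series.tes_ms, float)
    te_s = tes * 1e-3
    c = fat_phasor(spectrum, tes, b0)
    valid = _valid_mask(series, mask)

    shape = series.shape
    w_map = np.zeros(shape)
    f_map = np.zeros(shape)
    r2_map = np.zeros(shape)
    res_map = np.zeros(shape)

    def residual_and_jac(x, y):
        # fit in scaled variables u = g_w W, v = g_f F
        model, jac = _magnitude_model_jacobian(x[0], x[1], x[2], c, te_s)
        return model - y, jac

    bounds = ([0.0, 0.0, 0.0], [np.inf, np.inf, r2star_cap_s])
    init_ff = {"water": 0.05, "fat": 0.95}
    for ix, iy in zip(*np.nonzero(valid)):
        y = np.abs(series.images[:, ix, iy])
        s0 = y[0]
        best = None
        for init in inits:
            ff0 = init_ff[init]
            x0 = np.array([s0 * (1 - ff0), s0 * ff0, 30.0])
            sol = least_squares(
                lambda x: residual_and_jac(x, y)[0],
                x0,
                jac=lambda x: residual_and_jac(x, y)[1],
                bounds=bounds,
                method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        w_map[ix, iy] = best.x[0] / g_w
        f_map[ix, iy] = best.x[1] / g_f
        r2_map[ix, iy] = best.x[2]
        res_map[ix, iy] = 2.0 * best.cost  # sum of squared residuals

    return _finalize_maps(shape, w_map, f_map, r2_map, np.zeros(shape), res_map,
                          valid, "magnitude")


def _varpro_projectors(c: np.ndarray, te_s: np.ndarray, r2_grid: np.ndarray) -> np.ndarray:
    """Residual projectors I - B (B^H B)^-1 B^H for each R2* on the grid."""
    ne = te_s.size
    projectors = np.empty((r2_grid.size, ne, ne), dtype=complex)
    eye = np.eye(ne)
    for i, r2 in enumerate(r2_grid):
        decay = np.exp(-r2 * te_s)
        b = np.stack([decay, c * decay], axis=1)  # ne x 2
        pinv = np.linalg.pinv(b)
        projectors[i] = eye - b @ pinv
    return projectors


def field_map_cost(
    series: EchoSeries,
    spectrum: FatSpectrum,
    psi_grid_hz: np.ndarray,
    r2_grid_s: np.ndarray | None = None,
    b0_t: float | None = None,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel variable-projection data cost D(psi) on the psi grid.

    Returns ``(D, valid)`` where ``D`` has shape (nx, ny, n_psi); invalid
    voxels carry zero cost.
    """
    b0 = series.params.b0_t if b0_t is None else b0_t
    tes = np.asarray(series.tes_ms, float)
    te_s = tes * 1e-3
    c = fat_phasor(spectrum, tes, b0)
    if r2_grid_s is None:
        r2_grid_s = np.linspace(0.0, 300.0, 7)
    projectors = _varpro_projectors(c, te_s, np.asarray(r2_grid_s, float))
    valid = _valid_mask(series, mask)
    data = series.images[:, valid].T  # Nv x ne

    n_psi = psi_grid_hz.size
    d_cost = np.zeros((*series.shape, n_psi))
    costs_v = np.empty((data.shape[0], n_psi))
    for i, psi in enumerate(psi_grid_hz):
        demod = data * np.exp(-1j * 2.0 * np.pi * psi * te_s)[np.newaxis, :]
        best = np.full(data.shape[0], np.inf)
        for proj in projectors:
            r = demod @ proj.T  # (E d)_i = sum_j E_ij d_j
            np.minimum(best, np.sum(np.abs(r) ** 2, axis=1), out=best)
        costs_v[:, i] = best
    d_cost[valid] = costs_v
    return d_cost, valid


def estimate_field_map(
    series: EchoSeries,
    spectrum: FatSpectrum,
    b0_t: float | None = None,
    lambda_smooth: float = 0.05,
    *,
    psi_step_hz: float = 2.0,
    psi_span_hz: float | None = None,
    max_sweeps: int = 50,
    max_step_fraction: float = 0.25,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Smoothness-regularized field-map estimation on a discrete psi grid.

    Minimizes ``sum_v D_v(psi_v) + lambda * sum_(v,u) |psi_v - psi_u|``
    (4-neighborhood) by ICM with checkerboard sweeps, starting from the
    voxelwise data-cost minimizer.  The grid spans at least
    ``+- 1/(2 dTE)`` and the step must stay below ``max_step_fraction``
    of the fat-water ambiguity period ``1/dTE``.
    """
    dte_s = series.params.dte_ms * 1e-3
    ambiguity_hz = 1.0 / dte_s
    if psi_step_hz > max_step_fraction * ambiguity_hz:
        raise ValueError("psi grid too coarse relative to the fat-water ambiguity period")
    span = psi_span_hz if psi_span_hz is not None else ambiguity_hz / 2.0
    psi_grid = np.arange(-span, span + psi_step_hz / 2, psi_step_hz)

    d_cost, valid = field_map_cost(series, spectrum, psi_grid, b0_t=b0_t, mask=mask)

    nx, ny = series.shape
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    colors = (ii + jj) % 2

    def total_cost(lab):
        psi = psi_grid[lab]
        cost = d_cost[ii, jj, lab][valid].sum()
        cost += lambda_smooth * np.abs(np.diff(psi, axis=0)).sum()
        cost += lambda_smooth * np.abs(np.diff(psi, axis=1)).sum()
        return cost

    # coarse-to-fine initialization: either the voxelwise data-cost
    # minimizer or the best single constant field, whichever is cheaper
    # under the regularized cost (the constant wins at strong smoothing)
    labels = np.argmin(d_cost, axis=-1)
    labels[~valid] = psi_grid.size // 2
    const_label = int(np.argmin(d_cost[valid].sum(axis=0)))
    const_labels = np.full((nx, ny), const_label)
    if total_cost(const_labels) < total_cost(labels):
        labels = const_labels

    prev_cost = total_cost(labels)
    for _ in range(max_sweeps):
        for color in (0, 1):
            sel = (colors == color) & valid
            if not sel.any():
                continue
            psi_cur = psi_grid[labels]
            # neighbor penalty for every candidate label, at selected voxels
            pen = np.zeros((sel.sum(), psi_grid.size))
            padded = np.pad(psi_cur, 1, mode="edge")
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nb = padded[1 + di : 1 + di + nx, 1 + dj : 1 + dj + ny][sel]
                pen += np.abs(psi_grid[np.newaxis, :] - nb[:, np.newaxis])
            cand = d_cost[sel] + lambda_smooth * pen
            labels[sel] = np.argmin(cand, axis=1)
        cost = total_cost(labels)
        if cost > prev_cost + 1e-9:  # ICM must not increase the cost
            raise RuntimeError("ICM cost increased; optimizer inconsistency")
        if prev_cost - cost < 1e-12 * max(abs(prev_cost), 1.0):
            break
        prev_cost = cost

    psi_map = psi_grid[labels].astype(float)
    psi_map[~valid] = np.nan
    return psi_map


def complex_fit(
    series: EchoSeries,
    psi_map: np.ndarray,
    spectrum: FatSpectrum,
    b0_t: float | None = None,
    *,
    mask: np.ndarray | None = None,
    r2star_cap_s: float = R2STAR_CAP_S,
) -> FitResult:
    """Complex fit given the field map: linear (W, F), 1-D R2* search."""
    b0 = series.params.b0_t if b0_t is None else b0_t
    tes = np.asarray(series.tes_ms, float)
    te_s = tes * 1e-3
    c = fat_phasor(spectrum, tes, b0)
    valid = _valid_mask(series, mask) & np.isfinite(psi_map)

    shape = series.shape
    w_map = np.zeros(shape)
    f_map = np.zeros(shape)
    r2_map = np.zeros(shape)
    res_map = np.zeros(shape)

    def varpro(r2, d):
        decay = np.exp(-r2 * te_s)
        b = np.stack([decay, c * decay], axis=1)
        coef, *_ = np.linalg.lstsq(b, d, rcond=None)
        r = d - b @ coef
        return float(np.sum(np.abs(r) ** 2)), coef

    for ix, iy in zip(*np.nonzero(valid)):
        d = series.images[:, ix, iy] * np.exp(-1j * 2 * np.pi * psi_map[ix, iy] * te_s)
        sol = minimize_scalar(lambda r2: varpro(r2, d)[0], bounds=(0.0, r2star_cap_s),
                              method="bounded", options={"xatol": 1e-8})
        cost, coef = varpro(sol.x, d)
        w_map[ix, iy] = abs(coef[0])
        f_map[ix, iy] = abs(coef[1])
        r2_map[ix, iy] = sol.x
        res_map[ix, iy] = cost

    return _finalize_maps(shape, w_map, f_map, r2_map, np.where(valid, psi_map, 0.0),
                          res_map, valid, "complex")


def hybrid_fit(
    series: EchoSeries,
    spectrum: FatSpectrum,
    b0_t: float | None = None,
    weight_w: float = 0.5,
    *,
    psi_map: np.ndarray | None = None,
    lambda_smooth: float = 0.05,
    mask: np.ndarray | None = None,
    r2star_cap_s: float = R2STAR_CAP_S,
) -> FitResult:
    """Weighted combination of complex- and magnitude-based fitting.

    Minimizes ``w * ||complex residual||^2 + (1 - w) * ||magnitude
    residual||^2`` per voxel over (W, F, R2*, common phase), initialized
    from the complex fit.  ``weight_w = 1`` and ``0`` delegate to the pure
    complex and magnitude fits.
    """
    if not 0.0 <= weight_w <= 1.0:
        raise ValueError("weight_w must lie in [0, 1]")
    b0 = series.params.b0_t if b0_t is None else b0_t
    if weight_w == 0.0:
        return magnitude_fit(series, spectrum, b0, mask=mask, r2star_cap_s=r2star_cap_s)
    if psi_map is None:
        psi_map = estimate_field_map(series, spectrum, b0, lambda_smooth, mask=mask)
    cfit = complex_fit(series, psi_map, spectrum, b0, mask=mask, r2star_cap_s=r2star_cap_s)
    if weight_w == 1.0:
        return cfit

    tes = np.asarray(series.tes_ms, float)
    te_s = tes * 1e-3
    c = fat_phasor(spectrum, tes, b0)
    valid = cfit.valid
    shape = series.shape
    w_map = np.zeros(shape)
    f_map = np.zeros(shape)
    r2_map = np.zeros(shape)
    res_map = np.zeros(shape)
    sw, sm = np.sqrt(weight_w), np.sqrt(1.0 - weight_w)

    for ix, iy in zip(*np.nonzero(valid)):
        s = series.images[:, ix, iy]
        y = np.abs(s)
        psi = psi_map[ix, iy]
        carrier = np.exp(1j * 2 * np.pi * psi * te_s)

        def resid(x):
            w, f, r2, phi = x
            model_c = (w + f * c) * np.exp(1j * phi) * carrier * np.exp(-r2 * te_s)
            rc = model_c - s
            rm = np.abs(w + f * c) * np.exp(-r2 * te_s) - y
            return np.concatenate([sw * rc.real, sw * rc.imag, sm * rm])

        # initialize from the complex fit, including its overall phase
        phi0 = 0.0
        d = s * np.conj(carrier)
        decay0 = np.exp(-cfit.r2star_map[ix, iy] * te_s)
        num = np.vdot(np.stack([decay0, c * decay0], axis=1) @ np.array(
            [cfit.water_map[ix, iy], cfit.fat_map[ix, iy]]), d)
        if abs(num) > 0:
            phi0 = float(np.angle(num))
        x0 = np.array([cfit.water_map[ix, iy], cfit.fat_map[ix, iy],
                       cfit.r2star_map[ix, iy], phi0])
        sol = least_squares(resid, x0,
                            bounds=([0, 0, 0, -2 * np.pi], [np.inf, np.inf, r2star_cap_s, 2 * np.pi]),
                            method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        w_map[ix, iy], f_map[ix, iy], r2_map[ix, iy] = sol.x[:3]
        res_map[ix, iy] = 2.0 * sol.cost

    return _finalize_maps(shape, w_map, f_map, r2_map,
                          np.where(valid, psi_map, 0.0), res_map, valid, "hybrid")
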