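"""Per-voxel time-density-curve fitting and perfusion parameter maps.

Dynamic contrast CT gives each voxel a time-density curve (TDC): attenuation
in Hounsfield units (HU) versus acquisition time. The first-pass bolus is
modeled as a Gaussian on a flat baseline,

    s(t) = baseline + amplitude * exp(-(t - peak_time)^2 / (2 width^2)),

and three arterial-input-free perfusion surrogates derive from the fit:

* TTP (time to peak) = ``peak_time`` — seconds from scan start;
* CBV surrogate      = area under the baseline-subtracted fitted curve,
  ``amplitude * width * sqrt(2*pi)`` (HU*s);
* CBF surrogate      = maximum upslope of the fitted curve,
  ``amplitude * exp(-1/2) / width`` (HU/s).

These are relative, intra-cohort-comparable quantities: no arterial input
function is measured, no deconvolution is performed, and blood flow is
treated as uniform and stable over the scan.

All fitting goes through one vectorized Levenberg-Marquardt routine, so the
per-voxel scalar path and the whole-map path are numerically identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TimeDensityCurve",
    "GaussianTDCFit",
    "PerfusionMaps",
    "gaussian_bolus",
    "extract_tdc",
    "fit_gaussian_tdc",
    "compute_indices",
    "build_perfusion_maps",
    "render_pseudocolor",
]

#: Fits with amplitude below max(3 * robust residual sd, this floor) are
#: flagged degenerate; 0.5 HU is below the noise level of any clinical scan.
MIN_AMPLITUDE_HU = 0.5


def gaussian_bolus(t, baseline, amplitude, peak_time, width):
    """Gaussian bolus on a flat baseline. Broadcasts like numpy."""
    t = np.asarray(t, dtype=float)
    z = (t - peak_time) / width
    return baseline + amplitude * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class TimeDensityCurve:
    """One voxel's contrast-enhancement series.

    Parameters
    ----------
    times : array of float
        Acquisition times in seconds, strictly increasing, length >= 5.
    values : array of float
        Attenuation in HU, same length as ``times``.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.ndim != 1 or values.shape != times.shape:
            raise ValueError("times and values must be 1-D and equally long")
        if times.size < 5:
            raise ValueError("a time-density curve needs at least 5 samples")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class GaussianTDCFit:
    """Fitted bolus parameters for one voxel.

    ``converged`` is False when the optimizer stalled; ``degenerate`` is True
    when no credible bolus is present (amplitude below the noise-scaled
    threshold, or peak time outside the scanned window). Degenerate fits have
    undefined perfusion indices.
    """

    baseline: float
    amplitude: float
    peak_time: float
    width: float
    rss: float
    converged: bool
    degenerate: bool


@dataclass(frozen=True)
class PerfusionMaps:
    """Voxelwise TTP (s), CBV (HU*s) and CBF (HU/s) over a mask.

    Voxels outside the fitted region, and voxels whose fit is non-converged
    or degenerate, carry NaN; ``valid_mask`` marks usable voxels.
    """

    ttp: np.ndarray
    cbv: np.ndarray
    cbf: np.ndarray
    valid_mask: np.ndarray


def extract_tdc(ctp: np.ndarray, voxel, times=None, frame_interval_s: float = 1.5) -> TimeDensityCurve:
    """Pull one voxel's curve out of a 4-D (x, y, z, t) CTP volume.

    ``times`` defaults to ``frame_index * frame_interval_s``.
    """
    ctp = np.asarray(ctp)
    if ctp.ndim != 4:
        raise ValueError("ctp must be 4-D (x, y, z, t)")
    x, y, z = voxel
    shape = ctp.shape[:3]
    if not (0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]):
        raise IndexError(f"voxel {voxel!r} outside grid {shape}")
    if times is None:
        times = np.arange(ctp.shape[3], dtype=float) * frame_interval_s
    times = np.asarray(times, dtype=float)
    if times.size != ctp.shape[3]:
        raise ValueError("times length must equal the number of frames")
    return TimeDensityCurve(times=times, values=ctp[x, y, z, :].astype(float))


# ---------------------------------------------------------------------------
# Batch Levenberg-Marquardt fitter
# ---------------------------------------------------------------------------

def _initial_params(values: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Moment-style starting point: baseline from the first 3 frames,
    amplitude from the max, peak at the argmax, width from the
    above-half-maximum span (floored at one frame interval)."""
    n = values.shape[0]
    dt = float(np.min(np.diff(times)))
    baseline = values[:, :3].mean(axis=1)
    amplitude = np.maximum(values.max(axis=1) - baseline, 0.0)
    peak_time = times[values.argmax(axis=1)]
    half = baseline + 0.5 * amplitude
    span = (values >= half[:, None]).sum(axis=1) * dt
    width = np.maximum(0.5 * span, dt)
    p = np.empty((n, 4))
    p[:, 0], p[:, 1], p[:, 2], p[:, 3] = baseline, amplitude, peak_time, width
    return p


def _clip_params(p: np.ndarray, times: np.ndarray) -> np.ndarray:
    dt = float(np.min(np.diff(times)))
    span = float(times[-1] - times[0])
    p[:, 1] = np.maximum(p[:, 1], 0.0)          # amplitude >= 0
    p[:, 3] = np.clip(p[:, 3], 0.5 * dt, span)  # width in [dt/2, span]
    return p


def _model_and_jacobian(p: np.ndarray, times: np.ndarray):
    b, a, pt, w = p[:, 0:1], p[:, 1:2], p[:, 2:3], p[:, 3:4]
    u = (times[None, :] - pt) / w
    e = np.exp(-0.5 * u * u)
    model = b + a * e
    jac = np.empty(p.shape[:1] + times.shape + (4,))
    jac[..., 0] = 1.0
    jac[..., 1] = e
    jac[..., 2] = a * e * u / w
    jac[..., 3] = a * e * u * u / w
    return model, jac


def fit_gaussian_tdc_batch(values: np.ndarray, times: np.ndarray,
                           max_iter: int = 60, tol: float = 1e-14,
                           degenerate_amplitude_floor: float = MIN_AMPLITUDE_HU):
    """Fit every row of ``values`` (n_voxels x n_frames) with a damped
    Gauss-Newton (Levenberg-Marquardt) iteration.

    Returns arrays ``(params (n,4), rss (n,), converged (n,), degenerate (n,))``.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    n = values.shape[0]

    p = _clip_params(_initial_params(values, times), times)
    model, _ = _model_and_jacobian(p, times)
    cost = np.einsum("ij,ij->i", model - values, model - values)
    lam = np.full(n, 1e-3)
    converged = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)

    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        pa = p[idx]
        model, jac = _model_and_jacobian(pa, times)
        r = model - values[idx]
        g = np.einsum("itk,it->ik", jac, r)
        h = np.einsum("itk,itl->ikl", jac, jac)
        # LM damping on the diagonal (Marquardt scaling)
        diag = np.einsum("ikk->ik", h).copy()
        diag[diag <= 0] = 1.0
        h_damped = h + lam[idx, None, None] * diag[:, None, :] * np.eye(4)
        try:
            step = -np.linalg.solve(h_damped, g[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - damped H is SPD
            step = -np.linalg.lstsq(h_damped.reshape(-1, 4), g.reshape(-1))[0]
        trial = _clip_params(pa + step, times)
        tmodel, _ = _model_and_jacobian(trial, times)
        tr = tmodel - values[idx]
        tcost = np.einsum("ij,ij->i", tr, tr)
        better = tcost <= cost[idx]
        p[idx[better]] = trial[better]
        lam[idx[better]] *= 0.3
        lam[idx[~better]] *= 10.0
        small_step = np.max(np.abs(step), axis=1) < 1e-10 * (1.0 + np.max(np.abs(pa), axis=1))
        small_gain = np.abs(cost[idx] - tcost) < tol * (1.0 + cost[idx])
        done = better & (small_step | small_gain)
        stuck = (~better) & (lam[idx] > 1e10)
        cost[idx[better]] = tcost[better]
        converged[idx[done]] = True
        active[idx[done | stuck]] = False

    # Degeneracy: amplitude below noise-scaled threshold, or peak outside scan.
    resid_model, _ = _model_and_jacobian(p, times)
    resid = values - resid_model
    robust_sd = 1.4826 * np.median(
        np.abs(resid - np.median(resid, axis=1, keepdims=True)), axis=1)
    amp_threshold = np.maximum(3.0 * robust_sd, degenerate_amplitude_floor)
    degenerate = (p[:, 1] < amp_threshold) | (p[:, 2] < times[0]) | (p[:, 2] > times[-1])
    return p, cost, converged, degenerate


def fit_gaussian_tdc(tdc: TimeDensityCurve, **kwargs) -> GaussianTDCFit:
    """Nonlinear least-squares Gaussian fit of a single curve.

    Never raises on non-convergence; inspect ``converged``/``degenerate``.
    """
    p, rss, conv, degen = fit_gaussian_tdc_batch(tdc.values[None, :], tdc.times, **kwargs)
    return GaussianTDCFit(
        baseline=float(p[0, 0]), amplitude=float(p[0, 1]),
        peak_time=float(p[0, 2]), width=float(p[0, 3]),
        rss=float(rss[0]), converged=bool(conv[0]), degenerate=bool(degen[0]),
    )


_SQRT_2PI = float(np.sqrt(2.0 * np.pi))
_INV_SQRT_E = float(np.exp(-0.5))


def compute_indices(fit: GaussianTDCFit):
    """Closed-form perfusion surrogates from a fitted curve.

    Returns ``(ttp, cbv, cbf)``; all NaN for degenerate or failed fits.
    """
    if fit.degenerate or not fit.converged:
        return (float("nan"),) * 3
    ttp = fit.peak_time
    cbv = fit.amplitude * fit.width * _SQRT_2PI
    cbf = fit.amplitude * _INV_SQRT_E / fit.width
    return ttp, cbv, cbf


def build_perfusion_maps(ctp: np.ndarray, roi: np.ndarray, times=None,
                         frame_interval_s: float = 1.5, **fit_kwargs) -> PerfusionMaps:
    """Fit every ROI voxel and assemble TTP/CBV/CBF maps.

    Voxels outside ``roi`` and voxels with unusable fits are NaN.
    """
    ctp = np.asarray(ctp, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if ctp.ndim != 4:
        raise ValueError("ctp must be 4-D (x, y, z, t)")
    if roi.shape != ctp.shape[:3]:
        raise ValueError("roi shape must match the spatial grid")
    if not roi.any():
        raise ValueError("empty ROI")
    if times is None:
        times = np.arange(ctp.shape[3], dtype=float) * frame_interval_s
    times = np.asarray(times, dtype=float)

    curves = ctp[roi]  # (n_roi, n_frames)
    p, _, conv, degen = fit_gaussian_tdc_batch(curves, times, **fit_kwargs)
    valid = conv & ~degen

    shape = ctp.shape[:3]
    ttp = np.full(shape, np.nan)
    cbv = np.full(shape, np.nan)
    cbf = np.full(shape, np.nan)
    valid_mask = np.zeros(shape, dtype=bool)

    amp, width, peak = p[:, 1], p[:, 3], p[:, 2]
    vt = np.where(valid, peak, np.nan)
    vv = np.where(valid, amp * width * _SQRT_2PI, np.nan)
    vf = np.where(valid, amp * _INV_SQRT_E / width, np.nan)
    ttp[roi], cbv[roi], cbf[roi] = vt, vv, vf
    valid_mask[roi] = valid
    return PerfusionMaps(ttp=ttp, cbv=cbv, cbf=cbf, valid_mask=valid_mask)


def render_pseudocolor(map3d: np.ndarray, slice_index: int, cmap: str = "jet"):
    """Min-max-normalized colormap rendering of one axial slice (visual QC).

    Returns an RGBA uint8 array. An all-NaN slice renders black with a warning.
    """
    import warnings

    from matplotlib import colormaps

    map3d = np.asarray(map3d, dtype=float)
    if not (0 <= slice_index < map3d.shape[2]):
        raise IndexError(f"slice {slice_index} out of range 0..{map3d.shape[2] - 1}")
    sl = map3d[:, :, slice_index]
    finite = np.isfinite(sl)
    out = np.zeros(sl.shape + (4,), dtype=np.uint8)
    out[..., 3] = 255
    if not finite.any():
        warnings.warn("pseudo-color slice contains no valid voxels", stacklevel=2)
        return out
    lo, hi = np.nanmin(sl), np.nanmax(sl)
    norm = np.zeros_like(sl) if hi == lo else (sl - lo) / (hi - lo)
    rgba = colormaps[cmap](np.where(finite, norm, 0.0))
    rgba[~finite] = (0.0, 0.0, 0.0, 1.0)
    return (rgba * 255).astype(np.uint8)
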