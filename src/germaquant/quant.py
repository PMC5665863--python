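"""Per-cell intensity measurement, background handling and normalization.

Measurement reads the mean intensity inside each 1.75 um core sphere.
Background is estimated from 8-12 core-sized spots placed in signal-free
tissue across two Z planes and subtracted (floored at zero).  A depth-bias
QC compares control-cell intensities in top / middle / bottom z bands to
catch residual depth attenuation that scan-time laser-power correction
failed to remove.

Three normalization modes put raw intensities onto comparable scales:

* ``max``      — divide by the per-sample maximum (gradient profiles on
                 [0, 1], e.g. Eya / Cas along the AP axis);
* ``control``  — divide by the mean of internal-control cells (mosaic-clone
                 fold changes; the control mean maps to 1);
* ``decay``    — divide by the value predicted at the cell's AP position by
                 a one-phase exponential decay fitted to the internal
                 control cells, removing a spatial gradient before
                 comparing clone and control cells at different positions.

The decay model is y(x) = plateau + (y0 - plateau) * exp(-K x), the
standard "one phase decay" parameterisation (plateau, Y0, K; span =
Y0 - plateau).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .detection import SpotSet, _sphere_mask_box
from .stack import VoxelStack


class NormalizationError(ValueError):
    pass


class SamplingError(ValueError):
    pass


# --------------------------------------------------------------------------
# intensity measurement
# --------------------------------------------------------------------------


def measure_intensities(stack: VoxelStack, cores: SpotSet) -> pd.DataFrame:
    """Mean intensity per channel inside each core sphere.

    Voxel membership is a centre-in-sphere test in um.  Cores whose sphere
    is clipped by the stack boundary are measured over the in-bounds subset
    and flagged ``edge``; a sphere containing no voxel centre raises.
    """
    vs = np.asarray(stack.voxel_size)
    radius = cores.diameter_um / 2.0
    out = {"cell_id": cores.spots["id"].to_numpy()}
    means = {name: np.empty(len(cores)) for name in stack.channel_names}
    edge = np.zeros(len(cores), dtype=bool)
    for i, center in enumerate(cores.centers_um):
        box, mask = _sphere_mask_box(stack.shape_zyx, vs, center, radius)
        if box is None or not np.any(mask):
            raise ValueError(
                f"core sphere at {center} um contains no voxel centre (voxel size {tuple(vs)})"
            )
        clipped = np.any(center - radius < -vs / 2) or np.any(
            center + radius > (np.array(stack.shape_zyx) - 0.5) * vs
        )
        edge[i] = clipped
        for ci, name in enumerate(stack.channel_names):
            means[name][i] = stack.data[ci][box][mask].mean()
    for name in stack.channel_names:
        out[f"{name}_raw"] = means[name]
    out["edge"] = edge
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# background
# --------------------------------------------------------------------------


@dataclass
class BackgroundEstimate:
    """Per-channel background mean/sd from core-sized spots in empty tissue."""

    mean: dict  # channel -> a.u.
    sd: dict
    n_spots: int
    centers_um: np.ndarray  # (n, 3)
    z_planes: tuple  # the two z levels used


def estimate_background(stack: VoxelStack, nuclei_centers_um: np.ndarray,
                        nucleus_diameter_um: float = 2.5, n_spots: int = 10,
                        core_diameter_um: float = 1.75, manual_centers_um=None,
                        rng: np.random.Generator | None = None) -> BackgroundEstimate:
    """Estimate per-channel background from spots away from all nuclei.

    Spots are either supplied (``manual_centers_um``) or sampled: two z
    planes are chosen and ``n_spots`` non-overlapping core-sized spheres
    are placed at least one nucleus radius + core radius away from every
    detected nucleus.  Manual centres overlapping a nucleus raise
    :class:`SamplingError`.
    """
    if not 1 <= n_spots:
        raise SamplingError("n_spots must be >= 1")
    vs = np.asarray(stack.voxel_size)
    nuclei = np.asarray(nuclei_centers_um).reshape(-1, 3)
    keepout = nucleus_diameter_um / 2.0 + core_diameter_um / 2.0
    if manual_centers_um is not None:
        centers = np.asarray(manual_centers_um, dtype=float).reshape(-1, 3)
        if len(nuclei) and np.min(
            np.linalg.norm(centers[:, None, :] - nuclei[None, :, :], axis=2)
        ) < keepout:
            raise SamplingError("manual background spot overlaps a detected nucleus")
        z_planes = tuple(sorted(set(np.round(centers[:, 0], 3))))
        if len(z_planes) < 2:
            raise SamplingError("background spots must span two distinct z planes")
    else:
        rng = rng if rng is not None else np.random.default_rng(0)
        centers, z_planes = _sample_background_spots(
            stack, nuclei, keepout, n_spots, core_diameter_um, rng
        )
    mean, sd = {}, {}
    radius = core_diameter_um / 2.0
    for ci, name in enumerate(stack.channel_names):
        vals = []
        for c in centers:
            box, mask = _sphere_mask_box(stack.shape_zyx, vs, c, radius)
            if box is None or not np.any(mask):
                raise SamplingError(f"background spot at {c} um is outside the stack")
            vals.append(stack.data[ci][box][mask].mean())
        vals = np.asarray(vals)
        mean[name] = float(vals.mean())
        sd[name] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return BackgroundEstimate(mean, sd, len(centers), centers, z_planes)


def _sample_background_spots(stack, nuclei, keepout, n_spots, core_diameter, rng):
    extent = np.asarray(stack.extent_um)
    radius = core_diameter / 2.0
    z_planes = sorted(rng.uniform(radius, extent[0] - radius, size=2))
    per_plane = [n_spots - n_spots // 2, n_spots // 2]
    centers = []
    attempts = 0
    for z, quota in zip(z_planes, per_plane):
        placed = 0
        while placed < quota:
            attempts += 1
            if attempts > 20_000:
                raise SamplingError(
                    f"could not place {n_spots} background spots clear of nuclei"
                )
            c = np.array([z, rng.uniform(radius, extent[1] - radius),
                          rng.uniform(radius, extent[2] - radius)])
            if len(nuclei) and np.min(np.linalg.norm(nuclei - c, axis=1)) < keepout:
                continue
            if centers and np.min(np.linalg.norm(np.array(centers) - c, axis=1)) < core_diameter:
                continue
            centers.append(c)
            placed += 1
    return np.array(centers), tuple(z_planes)


def subtract_background(raw: pd.DataFrame, bg: BackgroundEstimate,
                        channels=None) -> pd.DataFrame:
    """``<ch>_bgsub = max(<ch>_raw - background mean, 0)`` per channel."""
    out = raw.copy()
    for name in channels or bg.mean:
        out[f"{name}_bgsub"] = np.maximum(out[f"{name}_raw"] - bg.mean[name], 0.0)
    return out


# --------------------------------------------------------------------------
# depth-bias QC
# --------------------------------------------------------------------------


@dataclass
class DepthQC:
    band_means: dict  # {"top": .., "middle": .., "bottom": ..}
    max_ratio: float
    tolerance: float
    passed: bool | None  # None = not evaluable
    bands: np.ndarray | None = None  # per-cell band label


def depth_bias_qc(z_um: np.ndarray, values: np.ndarray, tolerance: float = 0.15) -> DepthQC:
    """Check residual depth bias on control-cell intensities.

    Cells are split into top / middle / bottom bands by z terciles; the QC
    passes iff the maximum pairwise ratio of band means is <= 1 +
    tolerance.  Bands with fewer than 3 cells make the QC not-evaluable.
    """
    z = np.asarray(z_um, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(z) < 9:
        return DepthQC({}, np.nan, tolerance, None)
    t1, t2 = np.quantile(z, [1 / 3, 2 / 3])
    band = np.where(z <= t1, "top", np.where(z <= t2, "middle", "bottom"))
    means = {}
    for b in ("top", "middle", "bottom"):
        sel = v[band == b]
        if len(sel) < 3:
            return DepthQC({}, np.nan, tolerance, None, band)
        means[b] = float(sel.mean())
    vals = np.array(list(means.values()))
    if np.any(vals <= 0):
        return DepthQC(means, np.inf, tolerance, False, band)
    ratio = float(vals.max() / vals.min())
    return DepthQC(means, ratio, tolerance, ratio <= 1 + tolerance, band)


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------


def normalize_max(values: np.ndarray, sample_ids=None, exclude=None) -> np.ndarray:
    """Divide by the per-sample maximum over non-excluded cells.

    Results lie in [0, 1] and the per-sample maximum cell is exactly 1.
    An all-zero sample normalizes to all zeros with a warning.
    """
    v = np.asarray(values, dtype=float)
    samples = np.asarray(sample_ids) if sample_ids is not None else np.zeros(len(v), dtype=int)
    excl = np.asarray(exclude, dtype=bool) if exclude is not None else np.zeros(len(v), bool)
    out = np.empty_like(v)
    for s in np.unique(samples):
        sel = samples == s
        pool = v[sel & ~excl]
        m = pool.max() if len(pool) else 0.0
        if m <= 0:
            warnings.warn(f"sample {s}: all-zero channel, normalized values set to 0",
                          stacklevel=2)
            out[sel] = 0.0
        else:
            out[sel] = v[sel] / m
    return out


def normalize_to_control_mean(values: np.ndarray, control_mask: np.ndarray,
                              scope_mask=None) -> np.ndarray:
    """Divide by the mean over internal-control cells (within scope).

    Requires >= 3 in-scope control cells with a positive mean; the control
    mean maps to 1, so a clone cell's value reads directly as fold change.
    """
    v = np.asarray(values, dtype=float)
    ctrl = np.asarray(control_mask, dtype=bool)
    scope = np.asarray(scope_mask, dtype=bool) if scope_mask is not None else np.ones_like(ctrl)
    pool = v[ctrl & scope]
    if len(pool) < 3:
        raise NormalizationError(f"need >= 3 in-scope control cells, have {len(pool)}")
    m = pool.mean()
    if m <= 0:
        raise NormalizationError("control mean is zero; cannot normalize")
    return v / m


# --------------------------------------------------------------------------
# one-phase decay fitting
# --------------------------------------------------------------------------


@dataclass
class DecayFit:
    """Fitted one-phase decay y(x) = plateau + (y0 - plateau) exp(-K x)."""

    plateau: float
    y0: float
    K: float  # per um, >= 0
    r_squared: float
    n_points: int
    converged: bool

    def predict(self, ap_um) -> np.ndarray:
        x = np.asarray(ap_um, dtype=float)
        return self.plateau + (self.y0 - self.plateau) * np.exp(-self.K * x)


def _decay(x, plateau, y0, K):
    return plateau + (y0 - plateau) * np.exp(-K * x)


def fit_one_phase_decay(ap_um, intensities, weights=None, max_restarts: int = 3) -> DecayFit:
    """Least-squares one-phase-decay fit with K >= 0 and plateau >= 0.

    Initialisation: plateau-hat = min y, y0-hat = max y, K-hat from a
    log-linear regression of (y - plateau-hat).  R-squared is
    1 - SS_res / SS_tot about the mean; constant data (SS_tot = 0) is a
    documented degenerate case reported as an exact constant fit with
    R-squared = 0.  Non-convergence after bounded restarts reports the best
    parameters with ``converged=False``.
    """
    x = np.asarray(ap_um, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if len(x) < 4:
        raise ValueError(f"need >= 4 points to fit a 3-parameter decay, have {len(x)}")
    if np.any(y < 0):
        raise ValueError("intensities must be >= 0")
    sigma = None if weights is None else 1.0 / np.sqrt(np.asarray(weights, dtype=float))

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        c = float(y[0])
        return DecayFit(plateau=c, y0=c, K=0.0, r_squared=0.0, n_points=len(x), converged=True)

    p_hat = float(y.min())
    y0_hat = float(y.max())
    span = y - p_hat
    pos = span > 0
    if pos.sum() >= 2 and np.ptp(x[pos]) > 0:
        slope = np.polyfit(x[pos], np.log(span[pos]), 1)[0]
        k_hat = max(-slope, 1e-6)
    else:
        k_hat = 1.0 / max(np.ptp(x), 1.0)

    best = None
    lower = [0.0, -np.inf, 0.0]
    upper = [np.inf, np.inf, np.inf]
    for attempt in range(max_restarts):
        p0 = [p_hat, y0_hat, k_hat * (10.0**attempt if attempt else 1.0)]
        p0[2] = min(p0[2], 1e3)
        try:
            popt, _ = curve_fit(_decay, x, y, p0=p0, sigma=sigma,
                                bounds=(lower, upper), maxfev=20_000)
        except RuntimeError:
            continue
        ss_res = float(np.sum((y - _decay(x, *popt)) ** 2))
        if best is None or ss_res < best[1]:
            best = (popt, ss_res)
        if ss_res <= 1e-3 * ss_tot or attempt == 0 and ss_res < ss_tot:
            break
    if best is None:
        return DecayFit(p_hat, y0_hat, k_hat, r_squared=-np.inf, n_points=len(x), converged=False)
    (plateau, y0, K), ss_res = best
    return DecayFit(
        plateau=float(plateau), y0=float(y0), K=float(K),
        r_squared=1.0 - ss_res / ss_tot, n_points=len(x), converged=True,
    )


def normalize_to_decay_prediction(values: np.ndarray, ap_um: np.ndarray, fit: DecayFit,
                                  floor_frac: float = 0.05, accept_unconverged: bool = False):
    """Divide each cell by the decay-curve prediction at its AP position.

    Control cells lying on the curve map to ~1, so clone values read as
    positional fold change.  Predictions below ``floor_frac * y0`` are
    clamped to that floor (and the cell flagged) to avoid divide-by-small
    blow-ups where the curve approaches zero posteriorly.

    Returns ``(normalized values, floored flags)``.
    """
    if not fit.converged and not accept_unconverged:
        raise NormalizationError("decay fit did not converge; pass accept_unconverged=True")
    v = np.asarray(values, dtype=float)
    pred = fit.predict(ap_um)
    floor = floor_frac * max(fit.y0, 0.0)
    if floor <= 0:
        floor = np.finfo(float).tiny
    floored = pred < floor
    return v / np.maximum(pred, floor), floored
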