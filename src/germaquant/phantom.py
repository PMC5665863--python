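"""Synthetic germarium phantom: seeded 3D stacks plus ground truth.

The phantom emulates what the downstream pipeline needs to see in a real
confocal stack of a germarium: follicle-cell-sized nuclei (~2.5 um) sitting
on a curved epithelial shell, an anterior-high exponentially decaying
reporter gradient, a steep Eya rise and a gradual Cas rise along the
anterior-posterior (AP) axis, mosaic-clone patches with multiplicative
marker effects, depth-dependent signal attenuation, PSF blur and shot /
read-out noise.  Every run is fully determined by its seed, and the
generator returns the ground truth (centres, diameters, clone flags, true
per-channel expression, any applied rotation) so each pipeline stage can be
scored without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .stack import VoxelStack


class PhantomConfigError(ValueError):
    """Raised for inconsistent phantom parameters."""


class CrowdingError(RuntimeError):
    """Raised when rejection sampling cannot place all nuclei."""


# --------------------------------------------------------------------------
# expression profiles along the AP axis
# --------------------------------------------------------------------------

PROFILE_KINDS = ("one_phase_decay", "logistic_rise", "linear_rise", "constant")


@dataclass(frozen=True)
class ProfileSpec:
    """Deterministic mean expression as a function of AP position (um).

    kind:
        ``one_phase_decay``  y(x) = plateau + (y0 - plateau) * exp(-K x)
        ``logistic_rise``    y(x) = floor + (ceiling - floor) / (1 + exp(-steepness (x - midpoint)))
        ``linear_rise``      y(x) = max(intercept + slope * x, 0)
        ``constant``         y(x) = value
    cell_sd:
        sigma of multiplicative lognormal cell-to-cell noise (0 = none).
        Lognormal keeps intensities strictly positive and right-skewed,
        as fluorescence intensities are.
    """

    kind: str
    params: dict = field(default_factory=dict)
    cell_sd: float = 0.0

    def __post_init__(self):
        if self.kind not in PROFILE_KINDS:
            raise PhantomConfigError(f"unknown profile kind {self.kind!r}; one of {PROFILE_KINDS}")
        if self.cell_sd < 0:
            raise PhantomConfigError("cell_sd must be >= 0")
        p = self.params
        if self.kind == "one_phase_decay" and p.get("K", 0.0) < 0:
            raise PhantomConfigError("decay rate K must be >= 0")
        if self.kind == "logistic_rise" and p.get("ceiling", 1.0) < p.get("floor", 0.0):
            raise PhantomConfigError("logistic ceiling must be >= floor")

    def mean_at(self, ap_um):
        """Deterministic mean expression at AP position(s) in um."""
        x = np.asarray(ap_um, dtype=float)
        p = self.params
        if self.kind == "one_phase_decay":
            plateau, y0, K = p["plateau"], p["y0"], p["K"]
            return plateau + (y0 - plateau) * np.exp(-K * x)
        if self.kind == "logistic_rise":
            floor = p.get("floor", 0.0)
            ceiling = p.get("ceiling", 1.0)
            mid, steep = p["midpoint"], p["steepness"]
            return floor + (ceiling - floor) / (1.0 + np.exp(-steep * (x - mid)))
        if self.kind == "linear_rise":
            return np.maximum(p.get("intercept", 0.0) + p["slope"] * x, 0.0)
        return np.full_like(x, float(p["value"]))


def sample_expression(ap_um: float, spec: ProfileSpec, rng: np.random.Generator) -> float:
    """One cell's expression: profile mean times one lognormal draw.

    With ``cell_sd == 0`` the deterministic mean is returned exactly.
    """
    if ap_um < 0:
        raise ValueError("ap_um must be >= 0")
    mean = float(spec.mean_at(ap_um))
    if spec.cell_sd == 0.0:
        return mean
    return mean * float(rng.lognormal(mean=0.0, sigma=spec.cell_sd))


# --------------------------------------------------------------------------
# parameters and ground truth
# --------------------------------------------------------------------------


def default_marker_profiles() -> dict:
    """Study-condition defaults for a germarium-like phantom.

    The nuclear stain is flat along AP; the Wnt-reporter gradient is
    anterior-high one-phase decay; Eya rises steeply near the region 2a/2b
    boundary while Cas rises gradually across region 2b; the clone marker is
    flat (rendered only in clone nuclei).  Amplitudes are arbitrary units
    chosen so the nuclear stain peaks near 100 counts.
    """
    return {
        "nuclear": ProfileSpec("constant", {"value": 100.0}, cell_sd=0.15),
        "eya": ProfileSpec(
            "logistic_rise",
            {"floor": 5.0, "ceiling": 100.0, "midpoint": 22.0, "steepness": 0.8},
            cell_sd=0.2,
        ),
        "cas": ProfileSpec("linear_rise", {"intercept": 2.0, "slope": 2.0}, cell_sd=0.2),
        "reporter": ProfileSpec(
            "one_phase_decay", {"plateau": 10.0, "y0": 100.0, "K": 0.08}, cell_sd=0.2
        ),
        "clone": ProfileSpec("constant", {"value": 80.0}, cell_sd=0.1),
    }


@dataclass
class PhantomParams:
    """Everything that determines a phantom stack (with the seed).

    Geometry is an ellipsoidal epithelial shell (semi-axes in um, z/y/x
    order; x is the AP axis) of finite thickness on which nuclei are placed.
    The imaging model mirrors the acquisition the pipeline targets: 0.43 um
    z step and 0.14 um xy sampling, depth-dependent attenuation which is
    normally compensated at scan time (``pre_corrected``), Gaussian PSF,
    constant background, and Poisson + Gaussian noise.
    """

    n_cells: int = 50
    shell_semi_axes: tuple[float, float, float] = (10.0, 10.0, 20.0)  # (z, y, x) um
    shell_thickness: float = 2.5
    nucleus_diameter_mean: float = 2.5
    nucleus_diameter_sd: float = 0.15
    ap_length: float | None = None  # defaults to 2 * semi_x
    voxel_size: tuple[float, float, float] = (0.43, 0.14, 0.14)
    marker_profiles: dict = field(default_factory=default_marker_profiles)
    clone_fraction: float = 0.3
    clone_mode: str = "fraction"  # "fraction" (independent count) or "patch" (contiguous)
    clone_effects: dict = field(default_factory=dict)  # channel -> multiplier > 0
    clone_channel: str = "clone"
    clone_polarity: str = "positive"  # "positive": marker in clones; "negative": marker lost
    attenuation_per_um: float = 0.01
    pre_corrected: bool = True  # laser-power ramp divides attenuation back out
    psf_sigma: float = 0.2  # um, isotropic optical blur
    gaussian_sd: float = 2.0  # additive read-out noise (counts)
    poisson_scale: float = 1.0  # photons per count; 0 disables shot noise
    background_level: float = 5.0
    margin_um: float = 3.0  # empty border around the shell
    random_tilt_deg: float = 0.0  # rigid rotation applied to the whole sample
    max_voxels: int = 300_000_000
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise PhantomConfigError("n_cells must be >= 1")
        if any(v <= 0 for v in self.voxel_size):
            raise PhantomConfigError("voxel sizes must be > 0")
        if not 0.0 <= self.clone_fraction <= 1.0:
            raise PhantomConfigError("clone_fraction must be in [0, 1]")
        if any(m <= 0 for m in self.clone_effects.values()):
            raise PhantomConfigError("clone effect multipliers must be > 0")
        if self.attenuation_per_um < 0:
            raise PhantomConfigError("attenuation_per_um must be >= 0")
        if self.clone_mode not in ("fraction", "patch"):
            raise PhantomConfigError("clone_mode must be 'fraction' or 'patch'")
        if self.clone_polarity not in ("positive", "negative"):
            raise PhantomConfigError("clone_polarity must be 'positive' or 'negative'")

    @property
    def ap_length_um(self) -> float:
        return self.ap_length if self.ap_length is not None else 2.0 * self.shell_semi_axes[2]


@dataclass
class PhantomTruth:
    """Ground truth for one generated phantom.

    ``nuclei`` has one row per nucleus: id, centre (z/y/x um, in the frame
    of the rendered stack), ap_true_um (position along the unrotated AP
    axis), diameter_um, clone flag, and one ``<channel>_true`` column per
    channel with the noise-free mean expression.
    """

    nuclei: pd.DataFrame
    profiles: dict
    rotation: np.ndarray  # 3x3 orthonormal, applied to centred coordinates
    translation: np.ndarray  # (z, y, x) um offset applied after rotation
    params: PhantomParams

    def channel_truth(self, channel: str) -> np.ndarray:
        return self.nuclei[f"{channel}_true"].to_numpy()


# --------------------------------------------------------------------------
# nucleus placement
# --------------------------------------------------------------------------


def place_nuclei(params: PhantomParams, rng: np.random.Generator):
    """Rejection-sample nucleus centres on the ellipsoidal shell.

    Returns (centers_um (n,3) in centred shell coordinates, diameters_um,
    clone_flags).  Centres are at least ``0.8 * nucleus_diameter_mean``
    apart; exceeding 1e5 rejections raises :class:`CrowdingError`.
    """
    semi = np.asarray(params.shell_semi_axes, dtype=float)  # (z, y, x)
    min_dist = 0.8 * params.nucleus_diameter_mean
    centers = []
    rejections = 0
    while len(centers) < params.n_cells:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        surface = semi * u
        # offset along the outward surface normal, within the shell thickness
        normal = surface / semi**2
        normal /= np.linalg.norm(normal)
        offset = rng.uniform(-params.shell_thickness / 2, params.shell_thickness / 2)
        cand = surface + offset * normal
        if centers and np.min(np.linalg.norm(np.array(centers) - cand, axis=1)) < min_dist:
            rejections += 1
            if rejections > 100_000:
                raise CrowdingError(
                    f"shell too crowded: placed {len(centers)}/{params.n_cells} nuclei"
                )
            continue
        centers.append(cand)
    centers = np.array(centers)
    diameters = rng.normal(params.nucleus_diameter_mean, params.nucleus_diameter_sd, params.n_cells)
    diameters = np.clip(diameters, 0.5 * params.nucleus_diameter_mean, None)
    clone = _assign_clones(centers, params, rng)
    return centers, diameters, clone


def _assign_clones(centers: np.ndarray, params: PhantomParams, rng: np.random.Generator):
    n = len(centers)
    n_clone = int(round(params.clone_fraction * n))
    flags = np.zeros(n, dtype=bool)
    if n_clone == 0:
        return flags
    if params.clone_mode == "fraction":
        flags[rng.choice(n, size=n_clone, replace=False)] = True
    else:  # contiguous patch grown from a random seed nucleus
        seed_idx = int(rng.integers(n))
        dist = np.linalg.norm(centers - centers[seed_idx], axis=1)
        flags[np.argsort(dist)[:n_clone]] = True
    return flags


def _random_rotation(max_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Rotation by a uniform angle in [0, max_deg] about a random axis."""
    if max_deg == 0:
        return np.eye(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0, max_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------


def generate_truth(params: PhantomParams, rng: np.random.Generator | None = None) -> PhantomTruth:
    """Place nuclei, draw per-cell expressions, and record geometry."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    centers, diameters, clone = place_nuclei(params, rng)

    semi_x = params.shell_semi_axes[2]
    # anterior tip of the shell at ap = 0; the shell thickness can push a
    # centre marginally past the tip, so clamp at 0
    ap_true = np.clip(centers[:, 2] + semi_x, 0.0, None)

    rows = {
        "id": np.arange(len(centers)),
        "diameter_um": diameters,
        "clone": clone,
        "ap_true_um": ap_true,
    }
    for name, spec in params.marker_profiles.items():
        expr = np.array([sample_expression(a, spec, rng) for a in ap_true])
        mult = params.clone_effects.get(name)
        if mult is not None:
            expr = np.where(clone, expr * mult, expr)
        if name == params.clone_channel:
            visible = clone if params.clone_polarity == "positive" else ~clone
            expr = np.where(visible, expr, 0.0)
        rows[f"{name}_true"] = expr

    rotation = _random_rotation(params.random_tilt_deg, rng)
    rotated = centers @ rotation.T
    # shift into positive stack coordinates with a uniform margin
    translation = params.margin_um - rotated.min(axis=0)
    placed = rotated + translation

    df = pd.DataFrame(rows)
    df[["z_um", "y_um", "x_um"]] = placed
    order = ["id", "z_um", "y_um", "x_um", "ap_true_um", "diameter_um", "clone"] + [
        f"{n}_true" for n in params.marker_profiles
    ]
    return PhantomTruth(
        nuclei=df[order],
        profiles=dict(params.marker_profiles),
        rotation=rotation,
        translation=translation,
        params=params,
    )


def render_stack(truth: PhantomTruth, params: PhantomParams | None = None,
                 rng: np.random.Generator | None = None) -> VoxelStack:
    """Render a truth table into a noisy multi-channel voxel stack.

    Each nucleus is a spherical Gaussian blob (sigma = diameter / 4) whose
    amplitude is its true expression, so the mean intensity inside the
    nucleus sphere is proportional to expression.  Depth attenuation
    ``exp(-attenuation_per_um * z)`` models signal loss into the sample; in
    ``pre_corrected`` mode the scan-time laser ramp divides it back out
    exactly.  PSF blur, constant background, then Poisson and Gaussian
    noise follow, in that order.
    """
    params = params or truth.params
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    vs = np.asarray(params.voxel_size)
    centers = truth.nuclei[["z_um", "y_um", "x_um"]].to_numpy()
    extent = centers.max(axis=0) + params.margin_um
    shape = np.ceil(extent / vs).astype(int) + 1
    channels = list(params.marker_profiles)
    if int(np.prod(shape)) * len(channels) > params.max_voxels:
        raise PhantomConfigError(
            f"stack of shape {tuple(shape)} x {len(channels)} channels exceeds voxel budget"
        )

    diameters = truth.nuclei["diameter_um"].to_numpy()
    data = np.zeros((len(channels), *shape), dtype=np.float64)
    for ci, name in enumerate(channels):
        amps = truth.channel_truth(name)
        vol = data[ci]
        for center, diam, amp in zip(centers, diameters, amps):
            if amp > 0:
                _paint_blob(vol, vs, center, diam / 4.0, amp)
        if params.attenuation_per_um > 0 and not params.pre_corrected:
            z_um = np.arange(shape[0]) * vs[0]
            vol *= np.exp(-params.attenuation_per_um * z_um)[:, None, None]
        if params.psf_sigma > 0:
            ndimage.gaussian_filter(vol, sigma=params.psf_sigma / vs, output=vol)
        vol += params.background_level
        if params.poisson_scale > 0:
            vol[:] = rng.poisson(np.maximum(vol, 0) * params.poisson_scale) / params.poisson_scale
        if params.gaussian_sd > 0:
            vol += rng.normal(0.0, params.gaussian_sd, size=vol.shape)
        np.maximum(vol, 0.0, out=vol)

    return VoxelStack(data=data, voxel_size=tuple(vs), channel_names=channels)


def _paint_blob(vol: np.ndarray, vs: np.ndarray, center_um: np.ndarray,
                sigma_um: float, amplitude: float) -> None:
    """Add an isotropic Gaussian blob into ``vol`` over a +-4 sigma box."""
    lo = np.maximum(np.floor((center_um - 4 * sigma_um) / vs).astype(int), 0)
    hi = np.minimum(np.ceil((center_um + 4 * sigma_um) / vs).astype(int) + 1, vol.shape)
    if np.any(lo >= hi):
        return
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    r2 = sum(((g * v - c) ** 2 for g, v, c in zip(grids, vs, center_um)))
    vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * np.exp(-r2 / (2 * sigma_um**2))


def generate_phantom(params: PhantomParams):
    """Convenience wrapper: one seeded (truth, stack) pair."""
    rng = np.random.default_rng(params.seed)
    truth = generate_truth(params, rng)
    stack = render_stack(truth, params, rng)
    return truth, stack


def write_truth_csv(path, truth: PhantomTruth) -> None:
    truth.nuclei.to_csv(path, index=False)


def snr_params(snr: float = 10.0, **overrides) -> PhantomParams:
    """Phantom parameters at a given peak-signal-to-noise ratio.

    SNR is defined as nuclear-stain peak amplitude over the Gaussian noise
    sd; shot noise stays on at the default photon scale.
    """
    base = PhantomParams(**overrides)
    peak = base.marker_profiles["nuclear"].mean_at(0.0)
    return replace(base, gaussian_sd=float(peak) / snr)
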