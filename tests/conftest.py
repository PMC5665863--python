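"""Shared fixtures: phantoms are generated once per session and reused."""

import numpy as np
import pytest

import germaquant as gq


@pytest.fixture(scope="session")
def phantom_50():
    """50-cell germarium phantom at SNR 10 (seed 42), tilted 30 degrees."""
    params = gq.snr_params(10.0, n_cells=50, seed=42, random_tilt_deg=30.0)
    truth, stack = gq.generate_phantom(params)
    return params, truth, stack


@pytest.fixture(scope="session")
def clean_phantom():
    """Small noiseless, blur-free, attenuation-free phantom for oracles."""
    params = gq.PhantomParams(
        n_cells=12, shell_semi_axes=(6.0, 6.0, 12.0), seed=7,
        nucleus_diameter_sd=0.0,  # uniform nuclei: in-sphere mean tracks expression
        gaussian_sd=0.0, poisson_scale=0.0, background_level=0.0,
        psf_sigma=0.0, attenuation_per_um=0.0,
    )
    truth, stack = gq.generate_phantom(params)
    return params, truth, stack


@pytest.fixture(scope="session")
def detected_50(phantom_50):
    params, truth, stack = phantom_50
    coarse = gq.detect_spots(stack, "nuclear", 2.5, 0.25)
    cores = gq.refine_cores(stack, coarse, 1.75)
    return coarse, cores


def single_nucleus_stack(expression=50.0, center=(5.0, 5.0, 5.0), diameter=2.5,
                         extra=None, **overrides):
    """One (optionally two) rendered nuclei with imaging artefacts off."""
    import pandas as pd

    rows = [dict(id=0, z_um=center[0], y_um=center[1], x_um=center[2],
                 ap_true_um=center[2], diameter_um=diameter, clone=False,
                 nuclear_true=expression)]
    if extra is not None:
        rows.append(dict(id=1, z_um=extra[0][0], y_um=extra[0][1], x_um=extra[0][2],
                         ap_true_um=extra[0][2], diameter_um=diameter, clone=False,
                         nuclear_true=extra[1]))
    kwargs = dict(
        n_cells=len(rows),
        marker_profiles={"nuclear": gq.ProfileSpec("constant", {"value": expression})},
        gaussian_sd=0.0, poisson_scale=0.0, background_level=0.0,
        psf_sigma=0.0, attenuation_per_um=0.0, margin_um=4.0,
    )
    kwargs.update(overrides)
    params = gq.PhantomParams(**kwargs)
    truth = gq.PhantomTruth(
        nuclei=pd.DataFrame(rows), profiles=params.marker_profiles,
        rotation=np.eye(3), translation=np.zeros(3), params=params,
    )
    stack = gq.render_stack(truth, params)
    return truth, stack
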