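"""Shared fixtures: small rendered scenes with known ground truth."""

import warnings

import numpy as np
import pytest

from retitort.core import FundusImage
from retitort.synthetic import VesselPathSpec, render_scene


def make_sparse_scene(noise_sd=0.0, illumination=0.0, seed=1):
    """Three vessels (arc, sinusoid, straight artery) in a 400x300 image."""
    paths = [
        VesselPathSpec(
            "circular_arc", length_px=200, radius_px=3, arc_radius_px=100,
            start_point=(100, 50), start_direction=(0, 1),
        ),
        VesselPathSpec(
            "sinusoid", length_px=300, radius_px=3, amplitude_px=10, wavelength_px=100,
            start_point=(200, 50), start_direction=(0, 1),
        ),
        VesselPathSpec(
            "straight", length_px=250, radius_px=2, start_point=(50, 30),
            start_direction=(0.6, 0.8), vessel_class="artery",
        ),
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return render_scene(
            paths, image_size=(400, 300), noise_sd=noise_sd,
            illumination_gradient=illumination, seed=seed,
            disk_center=(390, 290), disk_radius_px=8,
        )


def make_ring_scene(R, tube_radius=2.5):
    """A nearly closed circle of radius R, centered, no disk."""
    size = int(2 * R + 90)
    c = size / 2
    sp = VesselPathSpec(
        "circular_arc", length_px=2 * np.pi * R * 0.98, radius_px=tube_radius,
        arc_radius_px=R, start_point=(c + R, c), start_direction=(0, 1),
    )
    return render_scene(
        [sp], image_size=(size, size), noise_sd=0.0, illumination_gradient=0.0,
        seed=0, disk_center=(3, 3), disk_radius_px=1e-3,
    )


def make_bar_scene(theta=0.0, length=200.0, radius=2.5, size=(256, 256)):
    """A straight vessel through the image center at orientation theta."""
    u = np.array([np.sin(theta), np.cos(theta)])
    center = np.array([size[0] / 2, size[1] / 2])
    start = center - length / 2 * u
    sp = VesselPathSpec(
        "straight", length_px=length, radius_px=radius,
        start_point=tuple(start), start_direction=tuple(u),
    )
    return render_scene(
        [sp], image_size=size, noise_sd=0.0, illumination_gradient=0.0,
        seed=0, disk_center=(3, 3), disk_radius_px=1e-3,
    )


@pytest.fixture(scope="session")
def sparse_scene():
    return make_sparse_scene()


@pytest.fixture(scope="session")
def noisy_scene():
    return make_sparse_scene(noise_sd=0.05, illumination=0.3)


@pytest.fixture(scope="session")
def texture_image():
    """Vessel-free scene with noise: locally stationary texture."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc = render_scene(
            [], image_size=(300, 300), noise_sd=0.05, illumination_gradient=0.3, seed=3
        )
    return sc.image


@pytest.fixture(scope="session")
def av_scene():
    """Parallel artery/vein pairs for feature and classifier tests."""
    paths = []
    rng = np.random.default_rng(7)
    for i in range(8):
        cls = "artery" if i % 2 == 0 else "vein"
        radius = 2.4 if cls == "artery" else 3.0
        paths.append(
            VesselPathSpec(
                "straight", length_px=150, radius_px=radius,
                start_point=(25 + i * 22.0, 20 + rng.uniform(0, 5)),
                start_direction=(0, 1), vessel_class=cls,
            )
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return render_scene(
            paths, image_size=(220, 200), noise_sd=0.0, illumination_gradient=0.0,
            seed=2, disk_center=(3, 3), disk_radius_px=1e-3,
        )
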