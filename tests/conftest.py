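"""Shared fixtures and helpers for the rgcmosaic test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.spatial import cKDTree

from rgcmosaic import (
    DetectionParams,
    MosaicSpec,
    RetinaGeometry,
    generate_mosaic,
    make_retina_mask,
    render_image,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def brute_force_nnd(points: np.ndarray) -> np.ndarray:
    """O(n²) all-pairs nearest-neighbour oracle, independent of the tree code."""
    pts = np.asarray(points, dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def match_detections(
    truth_mm: np.ndarray, detected_mm: np.ndarray, radius_mm: float
) -> tuple[float, float]:
    """(precision, recall) matching detections to the nearest ground-truth
    point within ``radius_mm``; each truth point is credited at most once."""
    if len(detected_mm) == 0:
        return 1.0, 0.0
    d, idx = cKDTree(truth_mm).query(np.asarray(detected_mm))
    tp = len(set(idx[d < radius_mm]))
    return tp / len(detected_mm), tp / len(truth_mm)


def blob_image(
    n_points: int,
    seed: int,
    *,
    point_radius_mm: float = 0.72,
    retina_radius_mm: float = 0.75,
    exclusion_um: float = 25.0,
    soma_um: float = 14.0,
    noise_sd: float = 0.0,
):
    """Well-separated in-range blobs on a synthetic retina.

    The point field sits ~30 µm inside the rendered disc so every soma lies
    wholly on tissue. Returns (points, image, geometry-with-extracted-mask).
    """
    spec = MosaicSpec(
        field_radius_mm=point_radius_mm,
        target_density_per_mm2=1.25 * n_points / (np.pi * point_radius_mm**2),
        exclusion_radius_um=exclusion_um,
        seed=seed,
    )
    pts = generate_mosaic(spec)
    if len(pts) < n_points:  # Poisson shortfall: bump the seed deterministically
        return blob_image(
            n_points,
            seed + 7919,
            point_radius_mm=point_radius_mm,
            retina_radius_mm=retina_radius_mm,
            exclusion_um=exclusion_um,
            soma_um=soma_um,
            noise_sd=noise_sd,
        )
    pts = pts[:n_points]
    image, geom = render_image(
        pts,
        soma_diameter_um=soma_um,
        peak_intensity=200.0,
        background_sd=noise_sd,
        seed=seed,
        field_radius_mm=retina_radius_mm,
    )
    mask = make_retina_mask(image, DetectionParams())
    geometry = RetinaGeometry(
        mask=mask, pixel_size_um=geom.pixel_size_um, onh_xy_px=geom.onh_xy_px
    )
    return pts, image, geometry


@pytest.fixture(scope="session")
def poisson_mosaic_20k() -> np.ndarray:
    """~20k-point homogeneous Poisson mosaic (shared across tests)."""
    return generate_mosaic(
        MosaicSpec(
            field_radius_mm=2.0,
            target_density_per_mm2=1700.0,
            exclusion_radius_um=0.0,
            seed=42,
        )
    )
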