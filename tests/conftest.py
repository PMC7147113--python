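"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from flsquant.segmentation import SliceComponent


def dense_dog_oracle(image: np.ndarray, sigma_small: float, sigma_large: float) -> np.ndarray:
    """Difference of Gaussians by dense direct 2D convolution.

    Builds explicit sampled-and-normalised Gaussian kernels (radius
    4*sigma, matching the filter's truncation), reflect-pads the image, and
    convolves by brute-force sliding windows.  Shares no code path with the
    implementation under test.
    """
    out = []
    img = np.asarray(image, dtype=float)
    for sigma in (sigma_small, sigma_large):
        radius = int(4.0 * sigma + 0.5)
        ax = np.arange(-radius, radius + 1, dtype=float)
        k1 = np.exp(-(ax**2) / (2 * sigma**2))
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        padded = np.pad(img, radius, mode="symmetric")  # edge-repeating reflection
        windows = np.lib.stride_tricks.sliding_window_view(
            padded, kernel.shape
        )
        # correlation == convolution here: the kernel is symmetric
        out.append(np.einsum("ijkl,kl->ij", windows, kernel))
    return out[0] - out[1]


def make_component(
    slice_index: int,
    x: float,
    y: float,
    area: int = 1,
    anchor: tuple[int, int] | None = None,
) -> SliceComponent:
    """Construct a SliceComponent with a synthetic pixel set of given area."""
    r0, c0 = anchor if anchor is not None else (int(y), int(x))
    pixels = frozenset((r0, c0 + i) for i in range(area))
    return SliceComponent(
        slice_index=slice_index,
        centroid=(x, y),
        area_px=area,
        pixel_set=pixels,
        mean_intensity=1.0,
    )


def random_instance(rng, max_slices: int = 8, max_per_slice: int = 5):
    """Random per-slice component lists for tracer stress tests."""
    n_slices = int(rng.integers(1, max_slices + 1))
    per_slice = []
    for z in range(n_slices):
        comps = [
            make_component(
                z,
                float(rng.uniform(0, 10)),
                float(rng.uniform(0, 10)),
                area=int(rng.integers(1, 9)),
                anchor=(int(rng.integers(0, 30)), int(rng.integers(0, 30))),
            )
            for _ in range(int(rng.integers(0, max_per_slice + 1)))
        ]
        per_slice.append(comps)
    return per_slice


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
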