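"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own code paths: areas are
counted by full-image distance scans, Otsu by exhaustive threshold search,
Pearson by the explicit two-pass formula.
"""

from __future__ import annotations

import numpy as np
import pytest

from lipoquant.synthetic import SceneParams, simulate_cell


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def disk_pixels(shape, center, radius, inner=None):
    """Set of (row, col) with inner <= Euclidean distance <= radius, by a
    full-image scan."""
    out = set()
    for r in range(shape[0]):
        for c in range(shape[1]):
            d = np.hypot(r - center[0], c - center[1])
            if d <= radius + 1e-9 and (inner is None or d >= inner - 1e-9):
                out.add((r, c))
    return out


def otsu_variance_curve(values, nbins=256):
    """Exhaustive between-class variance for every candidate bin split of the
    256-bin histogram. Returns (bin centers, variance per split), where the
    variance at index k belongs to the threshold candidate centers[k]
    (class 1 = bins <= k). Empty-bin plateaus produce exact ties."""
    values = np.asarray(values, dtype=float).ravel()
    hist, bin_edges = np.histogram(values, bins=nbins)
    centers = (bin_edges[:-1] + bin_edges[1:]) / 2
    total = hist.sum()
    variances = np.full(nbins, -np.inf)
    for k in range(nbins - 1):
        w0 = hist[: k + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (hist[k + 1 :] * centers[k + 1 :]).sum() / w1
        variances[k] = w0 * w1 * (mu0 - mu1) ** 2
    return centers, variances


def exhaustive_otsu_threshold(values, nbins=256):
    """Bin-center threshold maximizing the exhaustive between-class variance."""
    centers, variances = otsu_variance_curve(values, nbins)
    return centers[int(np.argmax(variances))]


def assert_threshold_is_otsu_maximizer(values, threshold, nbins=256):
    """Assert that ``threshold`` attains the exhaustive-search maximum
    between-class variance (ties across empty-bin plateaus allowed)."""
    centers, variances = otsu_variance_curve(values, nbins)
    k = int(np.argmin(np.abs(centers - threshold)))
    assert np.isclose(centers[k], threshold, atol=1e-9)
    assert variances[k] >= variances.max() * (1 - 1e-9)


def pearson_direct(x, y):
    """Two-pass Pearson formula, written out explicitly."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    dx = x - x.mean()
    dy = y - y.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def basic_scene():
    """Zero-noise default scene shared by several suites."""
    return simulate_cell(SceneParams(seed=7))


@pytest.fixture
def ring_scene():
    """Surface-ring decorated scene with positively correlated distractors."""
    params = SceneParams(
        seed=11,
        n_lds=5,
        n_nonspecific_spots=3,
        min_ld_separation_px=28,
        decorator_mode="surface_ring",
        on_ld_intensity_fraction=0.5,
        nonspecific_intensity_fraction=0.3,
        ring_outer_pad_px=3.0,
    )
    return simulate_cell(params)
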