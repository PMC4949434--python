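"""Shared fixtures and fixture builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


def render_nuclei(centers, shape=(256, 256), sigma=2.2, peak=3000.0,
                  offset=100.0) -> np.ndarray:
    """Render Gaussian nuclei at explicit centers (ground-truth builder)."""
    img = np.full(shape, offset, dtype=float)
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    for (r, c) in centers:
        r0, r1 = int(max(0, r - 10)), int(min(shape[0], r + 11))
        c0, c1 = int(max(0, c - 10)), int(min(shape[1], c + 11))
        rr = rows[r0:r1] - r
        cc = cols[:, c0:c1] - c
        img[r0:r1, c0:c1] += peak * np.exp(-(rr ** 2 + cc ** 2) / (2 * sigma ** 2))
    return img


def grid_centers(n_side: int, spacing: float, origin: float = 15.0) -> np.ndarray:
    """A regular n_side x n_side grid of points."""
    axis = origin + spacing * np.arange(n_side)
    rr, cc = np.meshgrid(axis, axis, indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()])


@pytest.fixture(scope="session")
def epithelial_field():
    from emtscreen import synthdata

    return synthdata.simulate_field(synthdata.epithelial_spec(noise_sd=0.0),
                                    (256, 256), seed=11)


@pytest.fixture(scope="session")
def mesenchymal_field():
    from emtscreen import synthdata

    return synthdata.simulate_field(synthdata.mesenchymal_spec(noise_sd=0.0),
                                    (256, 256), seed=11)


@pytest.fixture(scope="session")
def small_screen():
    """A 2-plate 384-well screen with its normalisation, reused read-only."""
    from emtscreen import synthdata
    from emtscreen.platenorm import normalize_screen

    layouts, truth = synthdata.default_screen(n_plates=2, seed=123)
    raw = synthdata.simulate_screen(layouts, truth, seed=123)
    normalized, stats = normalize_screen(raw)
    return {"layouts": layouts, "truth": truth, "raw": raw,
            "normalized": normalized, "stats": stats}
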