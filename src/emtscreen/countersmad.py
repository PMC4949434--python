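"""p-Smad2 nuclear-translocation counter-screen.

TGF-beta drives C-terminally phosphorylated Smad2 into the nucleus within
the hour; a receptor-kinase inhibitor abolishes that translocation, while a
late-stage plasticity modulator leaves it intact.  The counter-screen
therefore measures, per well, the nuclear:cytoplasmic p-Smad2 intensity
ratio (cytoplasm approximated by a ring around each nucleus — the assay has
no cytoplasm stain), converts it to a translocation-inhibition fraction
between the stimulated and reference-inhibitor anchors measured on the same
run, and classifies primary hits into receptor-like versus plasticity
modulators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import disk

HIT_CLASSES = ("receptor_like", "plasticity_modulator", "indeterminate")


@dataclass
class CounterScreenConfig:
    ring_width: int = 4            # px, cytoplasmic ring around the nucleus
    background_quantile: float = 5.0  # percentile subtracted from both compartments
    min_cells: int = 10            # fewer measurable cells -> invalid well
    inhibition_cut: float = 0.5    # receptor-like at or above this inhibition
    strength_floor: float = 15.0   # primary strength required for a confident class


def nc_ratio(nuclei_labels: np.ndarray, psmad2_image: np.ndarray,
             ring_width: int = 4, background_quantile: float = 5.0,
             min_cells: int = 10) -> tuple[np.ndarray, float]:
    """Per-cell and well-median nuclear:cytoplasmic p-Smad2 ratio.

    For each nucleus: mean background-subtracted p-Smad2 inside the nucleus
    mask over the mean in its cytoplasmic ring (the nucleus dilated by
    ``ring_width`` minus all nucleus pixels).  Background is the image's
    ``background_quantile`` percentile.  Cells with an empty ring or a
    non-positive cytoplasmic mean are skipped; a well with fewer than
    ``min_cells`` measurable cells is invalid (median NaN).
    """
    labels = np.asarray(nuclei_labels)
    img = np.asarray(psmad2_image, dtype=float)
    if labels.shape != img.shape:
        raise ValueError("label grid and image shapes differ")
    bg = float(np.percentile(img, background_quantile))
    corrected = img - bg
    any_nucleus = labels > 0
    structure = disk(ring_width)
    scale = float(np.max(np.abs(corrected))) if corrected.size else 0.0
    eps = 1e-9 * max(scale, 1.0)
    ratios = []
    for nid in np.unique(labels):
        if nid == 0:
            continue
        nuc = labels == nid
        ring = ndi.binary_dilation(nuc, structure=structure) & ~any_nucleus
        if not ring.any():
            continue
        nuc_mean = float(np.mean(corrected[nuc]))
        cyt = float(np.mean(corrected[ring]))
        if abs(nuc_mean) < eps and abs(cyt) < eps:
            # no differential signal anywhere (e.g. a uniform image after
            # background subtraction): unit ratio by convention
            ratios.append(1.0)
            continue
        if cyt <= 0:
            if nuc_mean <= 0:
                continue
            # nuclear-only signal: floor the cytoplasmic estimate at 1% of
            # the nuclear mean so the ratio stays finite (<= 100)
            cyt = 0.01 * nuc_mean
        ratios.append(nuc_mean / cyt)
    ratios = np.asarray(ratios, dtype=float)
    median = float(np.median(ratios)) if len(ratios) >= min_cells else float("nan")
    return ratios, median


def translocation_inhibition(compound_ratio: float, stimulated_ratio: float,
                             inhibitor_ratio: float, eps: float = 1e-6) -> float:
    """Fractional inhibition of p-Smad2 translocation, clipped to [0, 1].

    ``(R_stim - R_compound) / (R_stim - R_refinhibitor)`` with the stimulated
    (DMSO + TGF-beta) and saturating-receptor-inhibitor wells of the same run
    as anchors.  Indistinguishable anchors invalidate the run.
    """
    if stimulated_ratio <= inhibitor_ratio + eps:
        raise ValueError("anchors indistinguishable: stimulated ratio must "
                         "exceed the reference-inhibitor ratio")
    frac = (stimulated_ratio - compound_ratio) / (stimulated_ratio - inhibitor_ratio)
    return float(np.clip(frac, 0.0, 1.0))


def classify_hits(strengths: pd.Series, inhibitions: pd.Series,
                  strength_floor: float = 15.0, inhibition_cut: float = 0.5,
                  ) -> pd.Series:
    """Split primary hits by their counter-screen behaviour.

    ``receptor_like``: strong phenotype and inhibition at or above the cut
    (acts like a TGF-beta receptor-kinase inhibitor).
    ``plasticity_modulator``: strong phenotype with little effect on
    p-Smad2 translocation — the interesting class.  Everything else is
    ``indeterminate``.  Indices of the two series must match.
    """
    s = strengths.astype(float)
    i = inhibitions.astype(float)
    unmatched = s.index.symmetric_difference(i.index)
    if len(unmatched):
        raise ValueError(f"unmatched compound keys: {list(unmatched)[:10]}")
    i = i.reindex(s.index)
    out = pd.Series("indeterminate", index=s.index, dtype=object)
    strong = (s >= strength_floor) & i.notna()
    out[strong & (i >= inhibition_cut)] = "receptor_like"
    out[strong & (i < inhibition_cut)] = "plasticity_modulator"
    return out


def counter_screen_table(strengths: pd.Series, ratios: pd.Series,
                         stimulated_ratio: float, inhibitor_ratio: float,
                         config: CounterScreenConfig | None = None) -> pd.DataFrame:
    """Per-compound counter-screen table: ratio, inhibition and class."""
    cfg = config or CounterScreenConfig()
    inhib = ratios.map(lambda r: translocation_inhibition(
        r, stimulated_ratio, inhibitor_ratio) if np.isfinite(r) else np.nan)
    classes = classify_hits(strengths, inhib, cfg.strength_floor, cfg.inhibition_cut)
    return pd.DataFrame({
        "nc_ratio": ratios, "inhibition": inhib, "class": classes,
        "strength": strengths,
    })
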