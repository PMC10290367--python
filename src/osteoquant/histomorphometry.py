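"""Tissue-fraction quantification on labeled histology sections.

Sections arrive as hard-labeled 2-D images (each pixel already assigned to
background, old bone, new bone/callus, cartilage, or non-bone tissue by a
human annotator or a renderer). Global fractions are percentages of the
non-background area; sectoral fractions split the callus between the cis
cortex, endosteal region, and trans cortex as percentages of total callus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabelSection", "TissueFractions", "tissue_fractions", "sectoral_fractions"]


@dataclass
class LabelSection:
    """2-D integer label image with a legend mapping codes to tissue classes."""

    label_image: np.ndarray
    legend: dict[int, str]
    background_label: int = 0
    pixel_size_um: float | None = None
    ignore_label: int | None = None  # optional artifact label, excluded everywhere

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        if self.label_image.ndim != 2:
            raise ValueError("label image must be 2-D")
        present = np.unique(self.label_image)
        unknown = [int(v) for v in present if int(v) not in self.legend
                   and int(v) != self.ignore_label]
        if unknown:
            raise ValueError(f"labels {unknown} missing from the legend")
        if self.background_label not in self.legend:
            raise ValueError("legend must include the background label")


@dataclass(frozen=True)
class TissueFractions:
    percent_by_class: dict[str, float]  # % of non-background pixels
    sector_percent: dict[str, float] = field(default_factory=dict)  # % of callus


def tissue_fractions(section: LabelSection) -> TissueFractions:
    """Per-class percentages of the non-background area (sums to 100)."""
    img = section.label_image
    mask = img != section.background_label
    if section.ignore_label is not None:
        mask &= img != section.ignore_label
    n_fg = int(mask.sum())
    if n_fg == 0:
        raise ValueError("section contains no non-background pixels")
    pct = {}
    for code, name in section.legend.items():
        if code == section.background_label:
            continue
        pct[name] = 100.0 * int((img[mask] == code).sum()) / n_fg
    return TissueFractions(pct)


def sectoral_fractions(
    section: LabelSection,
    sector_masks: dict[str, np.ndarray],
    callus_classes: tuple[str, ...] = ("new_bone", "callus"),
) -> dict[str, float]:
    """Callus share per anatomical sector, as % of total callus pixels.

    ``sector_masks`` (typically cis / endosteal / trans) must be disjoint
    and jointly cover every callus pixel. Returns NaN percentages when the
    section has no callus.
    """
    img = section.label_image
    callus_codes = [c for c, n in section.legend.items()
                    if any(key in n for key in callus_classes)]
    if not callus_codes:
        raise ValueError("legend contains no callus/new-bone class")
    callus = np.isin(img, callus_codes)

    masks = {k: np.asarray(m, dtype=bool) for k, m in sector_masks.items()}
    stack = np.stack(list(masks.values()))
    if (stack.sum(axis=0) > 1).any():
        raise ValueError("sector masks overlap")
    covered = stack.any(axis=0)
    n_callus = int(callus.sum())
    if n_callus == 0:
        return {k: float("nan") for k in masks}
    if np.logical_and(callus, ~covered).any():
        raise ValueError("sector masks do not cover all callus pixels")
    return {k: 100.0 * int((callus & m).sum()) / n_callus for k, m in masks.items()}
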