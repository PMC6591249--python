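"""Whole-animal segmentation and per-animal intensity summaries.

Segmentation must be identical across strains that will be compared, so one
Otsu threshold is computed on the pixels of *all* dark-corrected frames
sharing a promoter x fluorophore group, then applied to every frame in the
group.  Each frame is binarized, opened to remove spurious pixels, stripped
of small components, and reduced to its largest connected component (the
instrument images one animal per frame).  The per-animal summary is the
arithmetic mean of corrected pixel values inside the mask — a concentration
proxy — together with the mask area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import morphology

from .calibrate import correct_frame
from .frames import ImageFrame, read_tiff
from .simcam import DarkCurrentMap

__all__ = [
    "SegmentationError",
    "AnimalMeasurement",
    "CohortMeasurements",
    "QuantifyParams",
    "pooled_otsu_threshold",
    "segment_frame",
    "summarize_animal",
    "quantify_frames",
    "quantify_cohorts",
]


class SegmentationError(ValueError):
    """Raised when a frame yields no animal mask after cleanup."""


@dataclass(frozen=True)
class AnimalMeasurement:
    """Per-animal summary: mean dark-corrected voxel intensity and area."""

    animal_id: str
    mean_voxel_intensity: float
    area_px: int
    strain_label: str
    channel: str


@dataclass
class CohortMeasurements:
    """All measurements for one strain x channel cohort.

    ``group_key`` identifies the promoter x fluorophore group whose pooled
    pixels set ``threshold_used``; every cohort in a group shares it.
    """

    strain_label: str
    channel: str
    animals: list[AnimalMeasurement] = field(default_factory=list)
    threshold_used: float = float("nan")
    group_key: str = ""

    @property
    def values(self) -> np.ndarray:
        """Per-animal mean voxel intensities as an array."""
        return np.array([a.mean_voxel_intensity for a in self.animals], dtype=float)

    def __len__(self) -> int:
        return len(self.animals)


@dataclass(frozen=True)
class QuantifyParams:
    opening_radius: int = 1
    min_object_size: int = 50


def _pixels(frame: ImageFrame | np.ndarray) -> np.ndarray:
    return np.asarray(frame.pixels if isinstance(frame, ImageFrame) else frame, dtype=float)


def pooled_otsu_threshold(corrected_frames: Sequence[ImageFrame | np.ndarray]) -> float:
    """Otsu threshold on the pooled pixel histogram of a frame group.

    Candidate thresholds are the 255 interior edges of a 256 equal-width bin
    grid spanning the pooled min-max; the returned threshold minimizes the
    within-class (intraclass) variance of the raw pooled values split into
    background (<= t) and foreground (> t), with ties resolved to the lowest
    candidate.
    """
    if len(corrected_frames) == 0:
        raise ValueError("at least one frame is required")
    pooled = np.concatenate([_pixels(f).ravel() for f in corrected_frames])
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:
        raise ValueError("pooled pixels are constant; no threshold exists")

    candidates = np.linspace(lo, hi, 257)[1:-1]
    pooled.sort()
    csum = np.concatenate(([0.0], np.cumsum(pooled)))
    csum2 = np.concatenate(([0.0], np.cumsum(pooled**2)))
    n = pooled.size

    n_bg = np.searchsorted(pooled, candidates, side="right")
    valid = (n_bg > 0) & (n_bg < n)
    n_bg = n_bg[valid]
    candidates = candidates[valid]
    s_bg, s2_bg = csum[n_bg], csum2[n_bg]
    s_fg, s2_fg = csum[-1] - s_bg, csum2[-1] - s2_bg
    n_fg = n - n_bg
    # total within-class sum of squares; same argmin as the weighted
    # intraclass variance (divide by n)
    ss_within = (s2_bg - s_bg**2 / n_bg) + (s2_fg - s_fg**2 / n_fg)
    return float(candidates[np.argmin(ss_within)])


def segment_frame(
    corrected_frame: ImageFrame | np.ndarray,
    threshold: float,
    opening_radius: int = 1,
    min_object_size: int = 50,
) -> np.ndarray:
    """Binarize at > threshold, open, drop small objects, keep the largest.

    Raises :class:`SegmentationError` if nothing survives cleanup, which
    callers must treat as "no animal detected" and exclude the frame.
    """
    if opening_radius < 0:
        raise ValueError("opening_radius must be non-negative")
    if min_object_size < 1:
        raise ValueError("min_object_size must be at least 1")
    mask = _pixels(corrected_frame) > threshold
    if opening_radius > 0:
        mask = morphology.opening(mask, morphology.disk(opening_radius))
    if not mask.any():
        raise SegmentationError("no animal detected: empty mask after cleanup")
    labels, n_labels = morphology.label(mask, return_num=True)
    sizes = np.bincount(labels.ravel())[1:]
    largest = int(np.argmax(sizes)) + 1
    # dropping sub-minimum components and keeping the largest survivor is
    # equivalent to keeping the largest component iff it meets the minimum
    if sizes[largest - 1] < min_object_size:
        raise SegmentationError("no animal detected: empty mask after cleanup")
    return labels == largest


def summarize_animal(
    corrected_frame: ImageFrame | np.ndarray,
    mask: np.ndarray,
    animal_id: str,
    strain_label: str,
    channel: str,
) -> AnimalMeasurement:
    """Mean corrected intensity and pixel area inside the animal mask."""
    if not mask.any():
        raise SegmentationError("cannot summarize an empty mask")
    px = _pixels(corrected_frame)
    return AnimalMeasurement(
        animal_id=animal_id,
        mean_voxel_intensity=float(px[mask].mean()),
        area_px=int(mask.sum()),
        strain_label=strain_label,
        channel=channel,
    )


def quantify_frames(
    grouped_frames: Mapping[tuple[str, str, str], Sequence[tuple[str, ImageFrame]]],
    dark: DarkCurrentMap,
    params: QuantifyParams = QuantifyParams(),
) -> tuple[list[CohortMeasurements], pd.DataFrame]:
    """Run correction, pooled thresholding and segmentation on in-memory frames.

    ``grouped_frames`` maps ``(strain_label, channel, group_key)`` to
    ``(animal_id, raw_frame)`` pairs.  One Otsu threshold is computed per
    ``group_key`` over every frame of every cohort in that group.  Frames
    failing segmentation are excluded and returned in a log table with the
    reason.
    """
    corrected: dict[tuple[str, str, str], list[tuple[str, np.ndarray]]] = {}
    for key, items in grouped_frames.items():
        if len(items) == 0:
            raise ValueError(f"cohort {key} has no frames")
        corrected[key] = [
            (animal_id, correct_frame(frame, dark).pixels) for animal_id, frame in items
        ]

    thresholds: dict[str, float] = {}
    for group_key in {key[2] for key in corrected}:
        pooled = [
            px
            for key, items in corrected.items()
            if key[2] == group_key
            for _, px in items
        ]
        thresholds[group_key] = pooled_otsu_threshold(pooled)

    cohorts: list[CohortMeasurements] = []
    excluded = []
    for (strain_label, channel, group_key), items in corrected.items():
        cohort = CohortMeasurements(
            strain_label=strain_label,
            channel=channel,
            threshold_used=thresholds[group_key],
            group_key=group_key,
        )
        for animal_id, px in items:
            try:
                mask = segment_frame(
                    px,
                    cohort.threshold_used,
                    opening_radius=params.opening_radius,
                    min_object_size=params.min_object_size,
                )
            except SegmentationError as err:
                excluded.append(
                    {
                        "animal_id": animal_id,
                        "strain_label": strain_label,
                        "channel": channel,
                        "reason": str(err),
                    }
                )
                continue
            cohort.animals.append(
                summarize_animal(px, mask, animal_id, strain_label, channel)
            )
        if not cohort.animals:
            raise SegmentationError(
                f"cohort {strain_label}/{channel}: no animal segmented successfully"
            )
        cohorts.append(cohort)
    log = pd.DataFrame(excluded, columns=["animal_id", "strain_label", "channel", "reason"])
    return cohorts, log


def quantify_cohorts(
    manifest: str | Path | pd.DataFrame,
    dark: DarkCurrentMap,
    params: QuantifyParams = QuantifyParams(),
) -> tuple[list[CohortMeasurements], pd.DataFrame]:
    """Manifest-driven variant of :func:`quantify_frames`.

    The manifest is a TSV (or DataFrame) with columns ``frame_path``,
    ``strain_label``, ``channel``, ``animal_id`` and optionally ``group``
    (the promoter x fluorophore group key; defaults to the channel, i.e. all
    strains sharing a fluorophore share a threshold).
    """
    table = (
        manifest
        if isinstance(manifest, pd.DataFrame)
        else pd.read_csv(manifest, sep="\t")
    )
    required = {"frame_path", "strain_label", "channel", "animal_id"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    if "group" not in table.columns:
        table = table.assign(group=table["channel"])

    grouped: dict[tuple[str, str, str], list[tuple[str, ImageFrame]]] = {}
    for row in table.itertuples(index=False):
        frame = read_tiff(row.frame_path)
        key = (str(row.strain_label), str(row.channel), str(row.group))
        grouped.setdefault(key, []).append((str(row.animal_id), frame))
    return quantify_frames(grouped, dark, params)
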