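"""Forward simulator for the whole-animal fluorescence instrument.

Generates dark frames, dilution-series frames, and cohorts of worm images
with a complete ground-truth answer key, so every downstream stage
(calibration, segmentation, background correction, effect-size inference)
can be verified against known inputs.

The noise model is the standard CCD chain: per-pixel expected photon count

    lambda(x, y) = (concentration + autofluorescence) * pathlength(x, y) * exposure

inside the animal and zero outside, Poisson shot noise on the photon count,
a per-pixel dark-current offset, additive Gaussian read noise, rounding to
integer ADU, and clipping at sensor saturation.  The animal itself is a
cylindrical tube swept along a "U"-shaped centerline — the pose the
microfluidic chamber forces — with the optical depth of tissue collapsed
into a single chord-length factor ``pathlength = sqrt(1 - (d/r)^2)``
(the chamber is shallower than the depth of field, so all signal along z is
integrated into one plane).

Between-animal variability of both reporter concentration and
autofluorescence is lognormal, the conventional positive-support model for
expression distributions; cohort-level intron effects enter as a
multiplicative factor on the mean reporter concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .frames import DEFAULT_PIXEL_SIZE_UM, ImageFrame

__all__ = [
    "CameraModel",
    "DarkCurrentMap",
    "WormPhantom",
    "StrainSpec",
    "GroundTruth",
    "DEFAULT_FRAME_SHAPE",
    "DEFAULT_TUBE_RADIUS_PX",
    "sample_dark_current_map",
    "render_worm_phantom",
    "render_disk_phantom",
    "simulate_frame",
    "simulate_cohort",
    "simulate_dilution_series",
]

#: default frame geometry: 192 rows x 256 columns at 2.7 um/px
DEFAULT_FRAME_SHAPE: tuple[int, int] = (192, 256)
#: default visible half-width of the worm in pixels: the body fills the
#: 65-um-wide holding channel, so 65 / 2.7 / 2 ~= 12 px
DEFAULT_TUBE_RADIUS_PX = 12
#: default unconfined body radius: an adult is ~75 um across, slightly
#: wider than the channel, so the body presses against the walls
DEFAULT_WORM_RADIUS_PX = 13.8
#: imaging-chamber depth: 50 um / 2.7 um/px
DEFAULT_CHAMBER_DEPTH_PX = 18.5
#: default separation of the two arms of the "U" centerline, pixels
DEFAULT_CHANNEL_WIDTH_PX = 80

# channel-specific autofluorescence defaults: tissue autofluorescence is
# substantially stronger under GFP excitation/emission optics than under
# mCherry optics, so the GFP default is several-fold higher.
AUTOFLUOR_MEAN_DEFAULTS = {"mcherry": 200.0, "megfp": 800.0}


@dataclass(frozen=True)
class DarkCurrentMap:
    """Per-pixel expected dark signal, in ADU."""

    offsets: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.offsets, dtype=float)
        if arr.ndim != 2:
            raise ValueError("dark-current map must be 2-D")
        if np.any(arr < 0):
            raise ValueError("dark-current offsets must be non-negative")
        object.__setattr__(self, "offsets", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.offsets.shape


@dataclass(frozen=True)
class CameraModel:
    """Camera forward model: gain, exposure, dark current, read noise, saturation.

    ``gain`` is ADU per detected photon; ``exposure`` is in seconds;
    ``read_noise_sd`` is the standard deviation of additive Gaussian read
    noise in ADU; ``saturation`` defaults to the full ADC range
    ``2**bit_depth - 1``.
    """

    gain: float = 2.0
    exposure: float = 0.05
    dark_map: DarkCurrentMap | None = None
    read_noise_sd: float = 2.0
    bit_depth: int = 16
    saturation: float | None = None

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")
        full_well = 2**self.bit_depth - 1
        sat = full_well if self.saturation is None else self.saturation
        if not 0 < sat <= full_well:
            raise ValueError(f"saturation must be in (0, {full_well}]")
        object.__setattr__(self, "saturation", float(sat))


@dataclass(frozen=True)
class WormPhantom:
    """A simulated animal: boolean tissue mask plus normalized optical depth.

    ``pathlength`` is the chord length of the cylindrical body at each pixel,
    normalized to 1 on the centerline and strictly positive exactly where
    ``mask`` is true.
    """

    mask: np.ndarray
    pathlength: np.ndarray
    pose_seed: int

    def __post_init__(self) -> None:
        if self.mask.shape != self.pathlength.shape:
            raise ValueError("mask and pathlength shapes differ")
        if not np.array_equal(self.mask, self.pathlength > 0):
            raise ValueError("pathlength must be > 0 exactly on the mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class StrainSpec:
    """Generative parameters for one strain x channel cohort.

    ``base_concentration`` is the expected reporter emission rate per unit
    pathlength per second for the intronless reference construct (0 for
    wild type, which carries no transgene); ``effect_multiplier`` scales it
    multiplicatively (1.0 = intronless reference).  ``animal_cv`` and
    ``autofluor_cv`` are coefficients of variation of the lognormal
    between-animal distributions.
    """

    label: str
    channel: str = "mcherry"
    base_concentration: float = 2000.0
    effect_multiplier: float = 1.0
    animal_cv: float = 0.2
    autofluor_mean: float | None = None
    autofluor_cv: float = 0.25

    def __post_init__(self) -> None:
        if self.channel not in AUTOFLUOR_MEAN_DEFAULTS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.base_concentration < 0 or self.effect_multiplier < 0:
            raise ValueError("concentration parameters must be non-negative")
        if self.animal_cv < 0 or self.autofluor_cv < 0:
            raise ValueError("coefficients of variation must be non-negative")
        if self.autofluor_mean is None:
            object.__setattr__(
                self, "autofluor_mean", AUTOFLUOR_MEAN_DEFAULTS[self.channel]
            )
        elif self.autofluor_mean < 0:
            raise ValueError("autofluor_mean must be non-negative")

    @property
    def mean_concentration(self) -> float:
        return self.base_concentration * self.effect_multiplier


@dataclass
class GroundTruth:
    """The simulator's answer key for one cohort.

    ``animals`` has one row per simulated frame with the drawn concentration
    and autofluorescence rate; cohort-level quantities are always computed
    from these stored draws, never re-estimated from images.
    """

    strain_label: str
    channel: str
    animals: pd.DataFrame = field(repr=False)
    phantoms: list[WormPhantom] = field(default_factory=list, repr=False)

    @property
    def mean_concentration(self) -> float:
        return float(self.animals["true_concentration"].mean())

    def concentration_ratio_vs(self, reference: "GroundTruth") -> float:
        """Empirical mean-concentration ratio against a reference cohort."""
        ref = reference.mean_concentration
        if ref <= 0:
            raise ValueError("reference cohort has non-positive mean concentration")
        return self.mean_concentration / ref


def sample_dark_current_map(
    rows: int, cols: int, mean_offset: float = 100.0, pixel_sd: float = 5.0, seed: int = 0
) -> DarkCurrentMap:
    """Draw a per-pixel dark-current map.

    Offsets are independent draws from a normal(mean_offset, pixel_sd)
    truncated at zero (negative draws are clamped), reproducible given
    ``seed``.
    """
    if rows < 1 or cols < 1:
        raise ValueError("map dimensions must be at least 1x1")
    if mean_offset < 0 or pixel_sd < 0:
        raise ValueError("mean_offset and pixel_sd must be non-negative")
    rng = np.random.default_rng(seed)
    offsets = rng.normal(mean_offset, pixel_sd, size=(rows, cols)) if pixel_sd > 0 else np.full(
        (rows, cols), float(mean_offset)
    )
    return DarkCurrentMap(offsets=np.clip(offsets, 0.0, None))


def _segment_distance(
    r: np.ndarray, c: np.ndarray, a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Distance from pixels (r, c) to the segment a-b (points as (row, col))."""
    d = b - a
    len2 = float(d @ d)
    t = ((r - a[0]) * d[0] + (c - a[1]) * d[1]) / len2
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(r - (a[0] + t * d[0]), c - (a[1] + t * d[1]))


def render_worm_phantom(
    rows: int = DEFAULT_FRAME_SHAPE[0],
    cols: int = DEFAULT_FRAME_SHAPE[1],
    channel_width_px: int = DEFAULT_CHANNEL_WIDTH_PX,
    tube_radius_px: float = DEFAULT_TUBE_RADIUS_PX,
    pose_seed: int = 0,
    worm_radius_px: float | None = None,
    chamber_depth_px: float = DEFAULT_CHAMBER_DEPTH_PX,
) -> WormPhantom:
    """Render a U-posed worm phantom with small seeded pose jitter.

    The centerline is two straight arms joined by a semicircular bend of
    radius ``channel_width_px / 2``; the body is a tube of visible
    half-width ``tube_radius_px`` around it.  The optical-depth profile is
    that of a cylindrical body of radius ``worm_radius_px`` confined in a
    chamber ``chamber_depth_px`` deep: the chord ``2 * sqrt(R^2 - d^2)``
    capped at the chamber depth and normalized to 1 on the axis,

        pathlength(d) = min(2 R sqrt(1 - (d/R)^2), D) / min(2 R, D).

    An adult animal is slightly wider than the holding channel, so by
    default the core of the body spans the full chamber depth
    (pathlength 1) and the profile falls off only near the channel walls —
    which is why one segmentation threshold yields consistent animal sizes
    across strains of different brightness.  For an unconfined body
    (``2 * worm_radius_px <= chamber_depth_px``) the profile reduces to the
    pure cylinder chord ``sqrt(1 - (d/R)^2)``.

    Raises ``ValueError`` if the jittered phantom would leave the frame.
    """
    if tube_radius_px < 1:
        raise ValueError("tube_radius_px must be at least 1")
    if worm_radius_px is None:
        worm_radius_px = 1.15 * tube_radius_px
    if worm_radius_px < tube_radius_px:
        raise ValueError("worm_radius_px must be >= tube_radius_px (visible half-width)")
    if chamber_depth_px <= 0:
        raise ValueError("chamber_depth_px must be positive")
    rng = np.random.default_rng(pose_seed)

    bend_radius = 0.5 * channel_width_px * (1.0 + rng.uniform(-0.05, 0.05))
    arm_len = 0.50 * rows * (1.0 + rng.uniform(-0.06, 0.06))
    theta = rng.normal(0.0, 0.02)
    center = np.array(
        [
            0.5 * rows + rng.uniform(-3.0, 3.0),
            0.5 * cols + rng.uniform(-3.0, 3.0),
        ]
    )

    # untransformed geometry: arc center at origin, arms rising in -row
    arc_center = np.array([0.0, 0.0])
    left_top = np.array([-arm_len, -bend_radius])
    right_top = np.array([-arm_len, bend_radius])
    left_bot = np.array([0.0, -bend_radius])
    right_bot = np.array([0.0, bend_radius])

    rot = np.array(
        [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
    )
    # place the U so its vertical midline sits on `center`
    mid = np.array([(-arm_len + bend_radius) / 2.0, 0.0])

    def place(p: np.ndarray) -> np.ndarray:
        return rot @ (p - mid) + center

    p_lt, p_rt, p_lb, p_rb = map(place, (left_top, right_top, left_bot, right_bot))
    p_arc = place(arc_center)

    # bound the centerline by sampled points, padded by the tube radius
    ts = np.linspace(0.0, 1.0, 64)[:, None]
    arc_angles = np.linspace(0.0, math.pi, 64)
    arc_pts = np.stack(
        [bend_radius * np.sin(arc_angles), -bend_radius * np.cos(arc_angles)], axis=1
    )
    centerline = np.vstack(
        [
            p_lt + ts * (p_lb - p_lt),
            p_rt + ts * (p_rb - p_rt),
            (rot @ (arc_pts - mid).T).T + center,
        ]
    )
    extent = tube_radius_px + 1.0
    lo = centerline.min(axis=0) - extent
    hi = centerline.max(axis=0) + extent
    if lo[0] < 0 or lo[1] < 0 or hi[0] > rows - 1 or hi[1] > cols - 1:
        raise ValueError(
            f"phantom (extent rows {lo[0]:.0f}..{hi[0]:.0f}, cols {lo[1]:.0f}..{hi[1]:.0f}) "
            f"does not fit a {rows}x{cols} frame"
        )

    rr, cc = np.meshgrid(np.arange(rows, dtype=float), np.arange(cols, dtype=float), indexing="ij")
    d_left = _segment_distance(rr, cc, p_lt, p_lb)
    d_right = _segment_distance(rr, cc, p_rt, p_rb)

    # distance to the bottom semicircular arc: |distance to arc center - R|
    # on the arc's angular span, else distance to the arc endpoints (which
    # the arm segments already cover).
    dr, dc = rr - p_arc[0], cc - p_arc[1]
    rad = np.hypot(dr, dc)
    # arc spans the half-plane "below" the chord through the arm bottoms
    below = dr * math.cos(theta) + dc * math.sin(theta) >= 0
    d_arc = np.where(below, np.abs(rad - bend_radius), np.inf)

    dist = np.minimum(np.minimum(d_left, d_right), d_arc)
    chord = 2.0 * worm_radius_px * np.sqrt(
        np.clip(1.0 - (dist / worm_radius_px) ** 2, 0.0, None)
    )
    axis_depth = min(2.0 * worm_radius_px, chamber_depth_px)
    pathlength = np.minimum(chord, chamber_depth_px) / axis_depth
    pathlength[dist >= tube_radius_px] = 0.0
    return WormPhantom(mask=pathlength > 0, pathlength=pathlength, pose_seed=pose_seed)


def render_disk_phantom(
    rows: int = DEFAULT_FRAME_SHAPE[0],
    cols: int = DEFAULT_FRAME_SHAPE[1],
    radius_px: int = 40,
) -> WormPhantom:
    """Uniform-pathlength disk used for dilution-series frames.

    Emulates a well of fluorophore solution filling the chamber depth:
    pathlength is 1 everywhere inside the disk.
    """
    rr, cc = np.meshgrid(np.arange(rows, dtype=float), np.arange(cols, dtype=float), indexing="ij")
    dist = np.hypot(rr - (rows - 1) / 2.0, cc - (cols - 1) / 2.0)
    mask = dist < radius_px
    return WormPhantom(mask=mask, pathlength=mask.astype(float), pose_seed=-1)


def simulate_frame(
    phantom: WormPhantom,
    concentration: float,
    autofluor: float,
    camera: CameraModel,
    seed: int = 0,
) -> ImageFrame:
    """Simulate one raw camera frame of one animal.

    Expected photons per pixel are
    ``(concentration + autofluor) * pathlength * exposure`` inside the mask
    and zero outside; observed ADU are
    ``clip(round(gain * Poisson(lambda) + dark + N(0, read_noise_sd)), 0, saturation)``.
    """
    if concentration < 0 or autofluor < 0:
        raise ValueError("concentration and autofluor must be non-negative")
    if camera.dark_map is None:
        raise ValueError("camera has no dark-current map")
    if camera.dark_map.shape != phantom.shape:
        raise ValueError(
            f"dark map shape {camera.dark_map.shape} != phantom shape {phantom.shape}"
        )
    rng = np.random.default_rng(seed)
    lam = (concentration + autofluor) * phantom.pathlength * camera.exposure
    signal = np.zeros(phantom.shape, dtype=float)
    if lam.any():
        m = phantom.mask
        signal[m] = camera.gain * rng.poisson(lam[m])
    adu = signal + camera.dark_map.offsets
    if camera.read_noise_sd > 0:
        adu = adu + rng.normal(0.0, camera.read_noise_sd, size=phantom.shape)
    adu = np.clip(np.rint(adu), 0, camera.saturation)
    return ImageFrame(pixels=adu.astype(np.uint16), bit_depth=camera.bit_depth)


def _lognormal_draws(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """Lognormal draws parameterized by arithmetic mean and CV (cv=0: constant)."""
    if mean == 0 or cv == 0:
        return np.full(n, float(mean))
    sigma2 = math.log1p(cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def simulate_cohort(
    spec: StrainSpec,
    phantom_params: dict | None,
    camera: CameraModel,
    n_animals: int,
    seed: int = 0,
) -> tuple[list[ImageFrame], GroundTruth]:
    """Simulate a cohort of ``n_animals`` single-animal frames for one strain.

    Per animal the reporter concentration is lognormal with mean
    ``base_concentration * effect_multiplier`` and CV ``animal_cv``,
    autofluorescence is lognormal(autofluor_mean, autofluor_cv), and a fresh
    phantom pose is drawn.  All draws are recorded in the returned
    :class:`GroundTruth`.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be at least 1")
    phantom_params = dict(phantom_params or {})
    if camera.dark_map is not None:
        phantom_params.setdefault("rows", camera.dark_map.shape[0])
        phantom_params.setdefault("cols", camera.dark_map.shape[1])
    rng = np.random.default_rng(seed)
    concentrations = _lognormal_draws(rng, spec.mean_concentration, spec.animal_cv, n_animals)
    autofluors = _lognormal_draws(rng, spec.autofluor_mean, spec.autofluor_cv, n_animals)
    pose_seeds = rng.integers(0, 2**31, size=n_animals)
    frame_seeds = rng.integers(0, 2**31, size=n_animals)

    frames: list[ImageFrame] = []
    phantoms: list[WormPhantom] = []
    records = []
    for i in range(n_animals):
        phantom = render_worm_phantom(pose_seed=int(pose_seeds[i]), **phantom_params)
        frame = simulate_frame(
            phantom, float(concentrations[i]), float(autofluors[i]), camera, int(frame_seeds[i])
        )
        frames.append(frame)
        phantoms.append(phantom)
        records.append(
            {
                "animal_id": f"{spec.label}_{i:04d}",
                "strain_label": spec.label,
                "channel": spec.channel,
                "true_concentration": float(concentrations[i]),
                "true_autofluor": float(autofluors[i]),
                "pose_seed": int(pose_seeds[i]),
            }
        )
    truth = GroundTruth(
        strain_label=spec.label,
        channel=spec.channel,
        animals=pd.DataFrame.from_records(records),
        phantoms=phantoms,
    )
    return frames, truth


def simulate_dilution_series(
    concentrations: Sequence[float],
    replicates: int,
    camera: CameraModel,
    seed: int = 0,
    disk_radius_px: int = 40,
) -> tuple[dict[float, list[ImageFrame]], pd.DataFrame]:
    """Simulate a fluorophore dilution series on a uniform disk phantom.

    Returns frames grouped by concentration level plus a truth table with
    the analytic expected masked ADU (before clipping) per level.
    """
    concs = [float(c) for c in concentrations]
    if len(concs) < 3:
        raise ValueError("a dilution series needs at least 3 concentration levels")
    if any(c <= 0 for c in concs):
        raise ValueError("concentrations must be strictly positive")
    if replicates < 1:
        raise ValueError("replicates must be at least 1")
    if camera.dark_map is None:
        raise ValueError("camera has no dark-current map")
    rows, cols = camera.dark_map.shape
    phantom = render_disk_phantom(rows, cols, disk_radius_px)
    rng = np.random.default_rng(seed)
    grouped: dict[float, list[ImageFrame]] = {}
    records = []
    for c in concs:
        frame_seeds = rng.integers(0, 2**31, size=replicates)
        grouped[c] = [
            simulate_frame(phantom, c, 0.0, camera, int(s)) for s in frame_seeds
        ]
        records.append(
            {
                "concentration": c,
                "expected_signal_adu": camera.gain * c * camera.exposure,
                "n_frames": replicates,
            }
        )
    return grouped, pd.DataFrame.from_records(records)
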