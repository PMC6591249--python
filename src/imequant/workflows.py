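"""End-to-end pipeline chains over the simulator.

These functions wire the stages together the way a real experiment would
run them: simulate (or load) raw frames, estimate and subtract the
dark-current map, pool an Otsu threshold per promoter x fluorophore group,
segment, summarize, subtract the wild-type autofluorescence baseline, and
estimate the percent effect.  They exist so that closed-loop validation —
program a known effect into the simulator, recover it through the full
chain — is a single call in tests, scripts and the CLI alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import calibrate, quantify, simcam, stats

__all__ = [
    "RecoveryResult",
    "default_camera",
    "run_recovery_experiment",
    "recovery_percent_over_seeds",
    "dilution_series_linearity",
    "bootstrap_coverage",
]


def default_camera(
    rows: int = simcam.DEFAULT_FRAME_SHAPE[0],
    cols: int = simcam.DEFAULT_FRAME_SHAPE[1],
    seed: int = 0,
    saturation: float | None = None,
) -> simcam.CameraModel:
    """Default instrument: 16-bit camera with a freshly sampled dark map."""
    dark = simcam.sample_dark_current_map(rows, cols, seed=seed)
    return simcam.CameraModel(dark_map=dark, saturation=saturation)


@dataclass(frozen=True)
class RecoveryResult:
    """One closed-loop recovery run: estimated vs programmed percent effect."""

    effect: stats.EffectSizeResult
    programmed_percent: float
    truth_percent: float  # from the simulator's stored draws
    n_excluded: int


def run_recovery_experiment(
    effect_multiplier: float,
    channel: str = "mcherry",
    base_concentration: float = 2000.0,
    n_per_group: int = 200,
    n_wildtype: int = 100,
    seed: int = 1,
    n_boot: int = 2000,
    n_dark_frames: int = 100,
    camera: simcam.CameraModel | None = None,
) -> RecoveryResult:
    """Simulate a two-cohort experiment and recover its programmed effect.

    A control cohort (multiplier 1.0), a test cohort
    (``effect_multiplier``), and a wild-type cohort (no transgene) are
    simulated; the dark map is estimated from simulated dark frames; the
    transgenic cohorts share one pooled Otsu threshold while the wild type
    (a different brightness regime entirely) gets its own; the wild-type
    population mean is subtracted; the percent increase is estimated with a
    bootstrap CI.
    """
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31))  # noqa: E731
    camera = camera or default_camera(seed=sub())

    control = simcam.StrainSpec(
        label="control", channel=channel, base_concentration=base_concentration
    )
    test = simcam.StrainSpec(
        label="test",
        channel=channel,
        base_concentration=base_concentration,
        effect_multiplier=effect_multiplier,
    )
    wildtype = simcam.StrainSpec(label="wildtype", channel=channel, base_concentration=0.0)

    frames_c, truth_c = simcam.simulate_cohort(control, None, camera, n_per_group, sub())
    frames_t, truth_t = simcam.simulate_cohort(test, None, camera, n_per_group, sub())
    frames_w, _ = simcam.simulate_cohort(wildtype, None, camera, n_wildtype, sub())

    rows, cols = camera.dark_map.shape
    dark_rng_seed = sub()
    blank = simcam.WormPhantom(
        mask=np.zeros((rows, cols), dtype=bool),
        pathlength=np.zeros((rows, cols)),
        pose_seed=-1,
    )
    dark_frames = [
        simcam.simulate_frame(blank, 0.0, 0.0, camera, s)
        for s in np.random.default_rng(dark_rng_seed).integers(0, 2**31, n_dark_frames)
    ]
    dark_est = calibrate.estimate_dark_current(dark_frames)

    group = f"{channel}:transgene"
    grouped = {
        ("control", channel, group): [
            (row.animal_id, f) for row, f in zip(truth_c.animals.itertuples(), frames_c)
        ],
        ("test", channel, group): [
            (row.animal_id, f) for row, f in zip(truth_t.animals.itertuples(), frames_t)
        ],
        ("wildtype", channel, f"{channel}:wildtype"): [
            (f"wildtype_{i:04d}", f) for i, f in enumerate(frames_w)
        ],
    }
    cohorts, log = quantify.quantify_frames(grouped, dark_est)
    by_label = {c.strain_label: c for c in cohorts}

    baseline = stats.autofluorescence_baseline(by_label["wildtype"])
    corrected_c = stats.background_correct(by_label["control"], baseline)
    corrected_t = stats.background_correct(by_label["test"], baseline)
    effect = stats.effect_size(
        corrected_c,
        corrected_t,
        n_boot=n_boot,
        seed=sub(),
        control_label="control",
        test_label="test",
    )
    truth_percent = 100.0 * (truth_t.concentration_ratio_vs(truth_c) - 1.0)
    return RecoveryResult(
        effect=effect,
        programmed_percent=100.0 * (effect_multiplier - 1.0),
        truth_percent=truth_percent,
        n_excluded=len(log),
    )


def recovery_percent_over_seeds(
    effect_multiplier: float,
    seeds: list[int],
    channel: str = "mcherry",
    base_concentration: float = 2000.0,
    n_per_group: int = 200,
    **kwargs,
) -> float:
    """Mean estimated percent increase across independent seeded experiments."""
    estimates = [
        run_recovery_experiment(
            effect_multiplier,
            channel=channel,
            base_concentration=base_concentration,
            n_per_group=n_per_group,
            seed=s,
            **kwargs,
        ).effect.percent_increase
        for s in seeds
    ]
    return float(np.mean(estimates))


def dilution_series_linearity(
    seed: int = 1,
    n_levels: int = 9,
    replicates: int = 20,
    base_concentration: float = 50.0,
    fold_per_step: float = 2.0,
    r2_min: float = 0.99,
    saturation: float | None = None,
) -> calibrate.LinearityReport:
    """Simulate a geometric dilution series and assess its linear range.

    By default the series spans ``fold_per_step ** (n_levels - 1)`` in
    concentration; ``saturation`` defaults to a value the top two levels
    exceed, emulating a camera driven past full well only at the brightest
    levels.
    """
    rng = np.random.default_rng(seed)
    concentrations = [base_concentration * fold_per_step**i for i in range(n_levels)]
    camera_tmp = simcam.CameraModel()
    if saturation is None:
        # clip only the top two levels: midpoint (geometric) between the
        # expected signal of levels n-3 and n-2, plus the dark offset
        sig = [camera_tmp.gain * c * camera_tmp.exposure for c in concentrations]
        saturation = float(np.sqrt(sig[-3] * sig[-2]) + 100.0)
    camera = default_camera(seed=int(rng.integers(0, 2**31)), saturation=saturation)
    grouped, _truth = simcam.simulate_dilution_series(
        concentrations, replicates, camera, seed=int(rng.integers(0, 2**31))
    )
    dark = camera.dark_map
    phantom_mask = simcam.render_disk_phantom(*dark.shape).mask
    level_means = []
    raw_means = []
    for c in concentrations:
        corrected = [calibrate.correct_frame(f, dark).pixels for f in grouped[c]]
        level_means.append((c, float(np.mean([px[phantom_mask].mean() for px in corrected]))))
        raw_means.append(
            float(np.mean([np.asarray(f.pixels, float)[phantom_mask].mean() for f in grouped[c]]))
        )
    return calibrate.assess_linearity(
        level_means, r2_min=r2_min, saturation=saturation, raw_level_means=raw_means
    )


def bootstrap_coverage(
    effect_multiplier: float = 1.5,
    n_per_group: int = 100,
    n_replicates: int = 500,
    n_boot: int = 2000,
    animal_cv: float = 0.2,
    seed: int = 1,
) -> float:
    """Empirical coverage of the 95% bootstrap CI at a fixed programmed effect.

    Each replicate draws control and test cohorts of per-animal
    concentrations from the generator's lognormal between-animal model
    (means 1 and ``effect_multiplier``, CV ``animal_cv``) and checks whether
    the percentile-bootstrap CI covers the programmed percent increase.
    Returns coverage in percent.
    """
    rng = np.random.default_rng(seed)
    programmed = 100.0 * (effect_multiplier - 1.0)
    hits = 0
    spec_c = simcam.StrainSpec(label="c", base_concentration=1.0, animal_cv=animal_cv)
    spec_t = simcam.StrainSpec(
        label="t", base_concentration=1.0, effect_multiplier=effect_multiplier, animal_cv=animal_cv
    )
    for _ in range(n_replicates):
        control = simcam._lognormal_draws(rng, spec_c.mean_concentration, animal_cv, n_per_group)
        test = simcam._lognormal_draws(rng, spec_t.mean_concentration, animal_cv, n_per_group)
        res = stats.effect_size(
            control, test, n_boot=n_boot, seed=int(rng.integers(0, 2**31))
        )
        if res.ci_low <= programmed <= res.ci_high:
            hits += 1
    return 100.0 * hits / n_replicates
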