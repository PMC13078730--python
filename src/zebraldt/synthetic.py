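"""Synthetic ZebraBox-style locomotor cohort generator.

The generator emulates the canonical light-dark transition (LDT) recording:
60 minutes of three alternating 10-minute light/dark cycles starting in
light.  Control larvae are quiet in light and hyperactive in dark, with a
spike at each light-to-dark transition that habituates exponentially within
the dark phase.  All 13 per-minute parameters are derived from a small set
of latent drivers (active seconds, large-movement fraction, class-typical
speeds) so that the ZebraBox consistency invariants hold by construction.

Exposure effects are likewise applied to the latent drivers: scaling the
activity driver changes the duration-type parameters, scaling a class speed
changes the distance/speed-type parameters, and the derived matrix stays
internally consistent either way.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import (
    BIN_SECONDS,
    DARK,
    LIGHT,
    N_MINUTES,
    N_PARAMETERS,
    PARAMETERS,
    ActivityClassThresholds,
    ConfigurationError,
    PhaseSchedule,
    feature_names,
)
from .containers import CONTROL, EXPOSED, FeatureMatrix, LocomotorRecord

# Parameters whose effect multiplier acts on the activity-time driver vs on
# the class-typical speed drivers.
_DURATION_PARAMS = frozenset({"dur", "durb", "inadur", "smldur", "lardur"})
_SPEED_DRIVER_OF = {
    "inadist": "ina", "inaspd": "ina",
    "smldist": "sml", "smlspd": "sml",
    "lardist": "lar", "larspd": "lar",
}
_TOTAL_DIST_PARAMS = frozenset({"dist", "distb"})


@dataclass(frozen=True)
class EffectSpec:
    """Exposure effect: which parameters change, where, and by how much.

    ``multiplier`` scales the latent drivers behind ``affected_params``
    during minutes of ``affected_phase`` from ``onset_min`` onward
    (0-based minute offset).  ``multiplier == 1`` means no effect.
    """

    affected_params: tuple[str, ...] = ("dur", "dist")
    affected_phase: str = DARK  # light, dark or both
    multiplier: float = 1.2
    onset_min: int = 0

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ConfigurationError("effect multiplier must be > 0")
        unknown = set(self.affected_params) - set(PARAMETERS)
        if unknown:
            raise ConfigurationError(
                f"unknown affected_params {sorted(unknown)}; allowed: {PARAMETERS}"
            )
        if self.affected_phase not in (LIGHT, DARK, "both"):
            raise ConfigurationError("affected_phase must be light, dark or both")
        if self.onset_min < 0:
            raise ConfigurationError("onset_min must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic LDT cohort.

    Behavioral level defaults give ~6 s/min active time in light and a dark
    response of ~16 s/min baseline plus an ~18 s transition spike decaying
    at ``habituation_rate`` per minute.  ``between_larva_cv`` is the
    coefficient of variation of a per-larva activity scale factor;
    ``within_larva_noise_sd`` the log-scale SD of per-minute multiplicative
    noise on the latent drivers.
    """

    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)
    thresholds: ActivityClassThresholds = field(default_factory=ActivityClassThresholds)
    n_control: int = 36
    n_exposed: int = 36
    effect: EffectSpec = field(default_factory=EffectSpec)
    between_larva_cv: float = 0.25
    within_larva_noise_sd: float = 0.30
    habituation_rate: float = 0.25
    seed: int = 0
    # Latent behavioral levels (control group).
    light_active_s: float = 6.0
    dark_active_s: float = 16.0
    dark_spike_s: float = 18.0
    light_large_frac: float = 0.15
    dark_large_frac: float = 0.45
    inactive_speed: float = 0.3
    small_speed: float = 4.0
    large_speed: float = 16.0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_exposed < 2:
            raise ConfigurationError("n_control and n_exposed must be >= 2")
        if self.between_larva_cv < 0:
            raise ConfigurationError("between_larva_cv must be >= 0")
        if self.within_larva_noise_sd < 0:
            raise ConfigurationError("within_larva_noise_sd must be >= 0")
        if not 0 <= self.habituation_rate < 1:
            raise ConfigurationError("habituation_rate must be in [0, 1)")
        if not 0 <= self.effect.onset_min < self.schedule.total_min:
            raise ConfigurationError(
                f"effect onset_min must be in [0, {self.schedule.total_min})"
            )
        t = self.thresholds
        if not self.inactive_speed < t.freeze_speed:
            raise ConfigurationError("inactive_speed must lie below freeze_speed")
        if not t.freeze_speed < self.small_speed < t.burst_speed:
            raise ConfigurationError(
                "small_speed must lie between freeze_speed and burst_speed"
            )
        if not self.large_speed > t.burst_speed:
            raise ConfigurationError("large_speed must lie above burst_speed")


def _effect_mask(config: GeneratorConfig, group: str) -> np.ndarray:
    """Boolean mask over minutes where the exposure effect applies."""
    sched = config.schedule
    if group == CONTROL or config.effect.multiplier == 1.0:
        return np.zeros(sched.total_min, dtype=bool)
    phases = sched.phases()
    in_phase = (
        np.ones_like(phases, dtype=bool)
        if config.effect.affected_phase == "both"
        else phases == config.effect.affected_phase
    )
    after_onset = np.arange(sched.total_min) >= config.effect.onset_min
    return in_phase & after_onset


def latent_drivers(config: GeneratorConfig, group: str) -> dict[str, np.ndarray]:
    """Noise-free latent driver profiles over the recording for one group.

    Returns per-minute arrays: ``active_s`` (expected active seconds),
    ``large_frac`` and the three class speeds, with the exposure effect (for
    the exposed group) already folded in.
    """
    sched = config.schedule
    phases = sched.phases()
    t_in = np.array([sched.minute_in_phase(m) for m in range(1, sched.total_min + 1)])

    decay = (1.0 - config.habituation_rate) ** t_in
    active = np.where(
        phases == DARK,
        config.dark_active_s + config.dark_spike_s * decay,
        config.light_active_s,
    ).astype(float)
    large_frac = np.where(
        phases == DARK, config.dark_large_frac, config.light_large_frac
    ).astype(float)
    speeds = {
        "ina": np.full(sched.total_min, config.inactive_speed),
        "sml": np.full(sched.total_min, config.small_speed),
        "lar": np.full(sched.total_min, config.large_speed),
    }

    mask = _effect_mask(config, group)
    if mask.any():
        eff = config.effect
        affected = set(eff.affected_params)
        if affected & _DURATION_PARAMS:
            active = np.where(mask, active * eff.multiplier, active)
        speed_classes = {_SPEED_DRIVER_OF[p] for p in affected if p in _SPEED_DRIVER_OF}
        if affected & _TOTAL_DIST_PARAMS:
            speed_classes |= {"ina", "sml", "lar"}
        for cls in speed_classes:
            speeds[cls] = np.where(mask, speeds[cls] * eff.multiplier, speeds[cls])

    active = np.clip(active, 0.0, BIN_SECONDS)
    return {"active_s": active, "large_frac": large_frac, **speeds}


def _matrix_from_drivers(drivers: dict[str, np.ndarray]) -> np.ndarray:
    """Derive the 13 x T parameter matrix from latent drivers."""
    active = drivers["active_s"]
    lardur = active * drivers["large_frac"]
    smldur = active - lardur
    inadur = BIN_SECONDS - active
    dists = {
        "ina": inadur * drivers["ina"],
        "sml": smldur * drivers["sml"],
        "lar": lardur * drivers["lar"],
    }
    durs = {"ina": inadur, "sml": smldur, "lar": lardur}

    def spd(cls: str) -> np.ndarray:
        d = durs[cls]
        return np.where(d > 0, dists[cls] / np.where(d > 0, d, 1.0), 0.0)

    cols = {
        "inadur": inadur, "inadist": dists["ina"], "inaspd": spd("ina"),
        "smldur": smldur, "smldist": dists["sml"], "smlspd": spd("sml"),
        "lardur": lardur, "lardist": dists["lar"], "larspd": spd("lar"),
        "dist": dists["ina"] + dists["sml"] + dists["lar"],
        # burst aggregates equal the large-activity class in generated data
        "distb": dists["lar"],
        "dur": smldur + lardur,
        "durb": lardur,
    }
    return np.vstack([cols[p] for p in PARAMETERS])


def mean_profile(config: GeneratorConfig, group: str) -> np.ndarray:
    """Pre-noise expected 13 x 60 parameter matrix for a group."""
    return _matrix_from_drivers(latent_drivers(config, group))


def _lognormal_factor(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and log-scale SD sigma."""
    if sigma == 0:
        return np.ones(size)
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_record(
    config: GeneratorConfig, group: str, rng: np.random.Generator, larva_id: str
) -> LocomotorRecord:
    """Draw one larva's internally consistent 13 x 60 locomotor matrix.

    Noise is applied to the latent drivers — a per-larva activity scale
    (between-larva variability) and per-minute factors on active time and
    class speeds — and the parameter matrix is re-derived, so every record
    satisfies the ZebraBox consistency invariants exactly.
    """
    if group not in (CONTROL, EXPOSED):
        raise ConfigurationError(f"group must be {CONTROL!r} or {EXPOSED!r}")
    drivers = latent_drivers(config, group)
    T = config.schedule.total_min

    cv = config.between_larva_cv
    sigma_b = np.sqrt(np.log1p(cv**2))
    larva_scale = float(_lognormal_factor(rng, sigma_b, ()))

    sw = config.within_larva_noise_sd
    active = drivers["active_s"] * larva_scale * _lognormal_factor(rng, sw, T)
    active = np.clip(active, 0.0, BIN_SECONDS)
    noisy = {
        "active_s": active,
        "large_frac": drivers["large_frac"],
        "ina": drivers["ina"] * _lognormal_factor(rng, sw, T),
        "sml": drivers["sml"] * _lognormal_factor(rng, sw, T),
        "lar": drivers["lar"] * _lognormal_factor(rng, sw, T),
    }
    record = LocomotorRecord(larva_id=larva_id, group=group, values=_matrix_from_drivers(noisy))
    record.validate()
    return record


def generate_cohort(config: GeneratorConfig) -> list[LocomotorRecord]:
    """Generate the full control + exposed cohort.

    Each larva gets its own counter-derived RNG stream
    (``default_rng([seed, index])``), so cohorts are reproducible
    independently of generation order.
    """
    records: list[LocomotorRecord] = []
    groups = [CONTROL] * config.n_control + [EXPOSED] * config.n_exposed
    for i, group in enumerate(groups):
        rng = np.random.default_rng([config.seed, i])
        within = i if group == CONTROL else i - config.n_control
        records.append(
            generate_record(config, group, rng, larva_id=f"{group}_{within + 1:03d}")
        )
    return records


def generate_null_matrix(n_per_class: int, n_features: int, seed: int) -> FeatureMatrix:
    """A pure-noise two-class dataset: i.i.d. uniform values on [0, 1).

    Shape (2 * n_per_class) x n_features with balanced control/exposed
    labels — the 'random data' baseline for classifier null calibration.
    """
    if n_per_class < 2:
        raise ConfigurationError("n_per_class must be >= 2")
    if n_features < 1:
        raise ConfigurationError("n_features must be >= 1")
    rng = np.random.default_rng(seed)
    features = rng.random((2 * n_per_class, n_features))
    labels = np.array([CONTROL] * n_per_class + [EXPOSED] * n_per_class)
    ids = [f"{lab}_{i % n_per_class + 1:03d}" for i, lab in enumerate(labels)]
    names = (
        feature_names()
        if n_features == N_PARAMETERS * N_MINUTES
        else [f"f{i:04d}" for i in range(n_features)]
    )
    return FeatureMatrix(sample_ids=ids, labels=labels, features=features, feature_names=names)


def cohort_to_long_frame(records: list[LocomotorRecord]) -> pd.DataFrame:
    """Long-format table: larva_id, group, minute (1-based), parameter, value."""
    frames = []
    for rec in records:
        n_min = rec.values.shape[1]
        frames.append(
            pd.DataFrame(
                {
                    "larva_id": rec.larva_id,
                    "group": rec.group,
                    "minute": np.tile(np.arange(1, n_min + 1), N_PARAMETERS),
                    "parameter": np.repeat(list(PARAMETERS), n_min),
                    "value": rec.values.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_cohort(records: list[LocomotorRecord], csv_path, config: GeneratorConfig | None = None,
                 manifest_path=None) -> None:
    """Write a cohort as long CSV plus an optional JSON manifest of the config."""
    # %.17g guarantees float64 round-trips bit-exactly through the CSV
    cohort_to_long_frame(records).to_csv(csv_path, index=False, float_format="%.17g")
    if manifest_path is not None:
        if config is None:
            raise ValueError("manifest requested but no config given")
        Path(manifest_path).write_text(json.dumps(config_to_dict(config), indent=2))


def config_to_dict(config: GeneratorConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if isinstance(d.get("schedule"), dict):
        d["schedule"] = PhaseSchedule(**d["schedule"])
    if isinstance(d.get("thresholds"), dict):
        d["thresholds"] = ActivityClassThresholds(**d["thresholds"])
    if isinstance(d.get("effect"), dict):
        eff = dict(d["effect"])
        if isinstance(eff.get("affected_params"), list):
            eff["affected_params"] = tuple(eff["affected_params"])
        d["effect"] = EffectSpec(**eff)
    return GeneratorConfig(**d)
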