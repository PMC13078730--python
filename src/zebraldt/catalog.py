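"""Parameter catalog and light/dark phase schedule for the LDT assay.

The ZebraBox quantization output reports 13 locomotor parameters per
minute-bin: durations, distances and average speeds partitioned into three
activity classes (inactive/"freeze", small and large movement), plus totals
and burst aggregates.  The canonical recording is 60 minutes of three
alternating 10-minute light/dark cycles starting in light.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: The 13 ZebraBox per-minute parameters, in canonical order.
PARAMETERS: tuple[str, ...] = (
    "inadur",   # time inactive (s)
    "inadist",  # distance while inactive (mm)
    "inaspd",   # speed while inactive (mm/s)
    "smldur",   # time a little active (s)
    "smldist",  # distance while a little active (mm)
    "smlspd",   # speed while a little active (mm/s)
    "lardur",   # time very active (s)
    "lardist",  # distance while very active (mm)
    "larspd",   # speed while very active (mm/s)
    "dist",     # total distance covered (mm)
    "distb",    # distance covered in bursts (mm)
    "dur",      # total time active (s)
    "durb",     # time active in bursts (s)
)

N_PARAMETERS = len(PARAMETERS)
N_MINUTES = 60
N_FEATURES = N_PARAMETERS * N_MINUTES  # 780

#: Seconds per minute-bin; durations within one bin sum to this.
BIN_SECONDS = 60.0

LIGHT = "light"
DARK = "dark"


class ConfigurationError(ValueError):
    """A generator or schedule configuration violates an invariant."""


@dataclass(frozen=True)
class PhaseSchedule:
    """Alternating light/dark phase layout of one recording.

    Parameters
    ----------
    phase_length_min:
        Length of each phase in minutes.
    n_cycles:
        Number of light+dark cycles.
    start_phase:
        Phase of the first minutes, ``"light"`` or ``"dark"``.
    """

    phase_length_min: int = 10
    n_cycles: int = 3
    start_phase: str = LIGHT

    def __post_init__(self) -> None:
        if self.phase_length_min < 1:
            raise ConfigurationError("phase_length_min must be >= 1")
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")
        if self.start_phase not in (LIGHT, DARK):
            raise ConfigurationError(
                f"start_phase must be '{LIGHT}' or '{DARK}', got {self.start_phase!r}"
            )

    @property
    def total_min(self) -> int:
        return 2 * self.n_cycles * self.phase_length_min

    def phase_of_minute(self, minute: int) -> str:
        """Phase of a 1-based minute index."""
        if not 1 <= minute <= self.total_min:
            raise ValueError(f"minute must be in 1..{self.total_min}")
        block = (minute - 1) // self.phase_length_min
        first = self.start_phase
        second = DARK if first == LIGHT else LIGHT
        return first if block % 2 == 0 else second

    def phases(self) -> np.ndarray:
        """Array of phase labels for minutes 1..total_min."""
        return np.array(
            [self.phase_of_minute(m) for m in range(1, self.total_min + 1)]
        )

    def minute_in_phase(self, minute: int) -> int:
        """0-based position of a 1-based minute within its phase."""
        return (minute - 1) % self.phase_length_min


@dataclass(frozen=True)
class ActivityClassThresholds:
    """Speed cut-offs separating the three activity classes (mm/s)."""

    freeze_speed: float = 1.0
    burst_speed: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.freeze_speed < self.burst_speed:
            raise ConfigurationError(
                "thresholds must satisfy 0 < freeze_speed < burst_speed"
            )


def feature_name(parameter: str, minute: int) -> str:
    """Name of the flattened feature for ``parameter`` at 1-based ``minute``."""
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}; allowed: {PARAMETERS}")
    if not 1 <= minute <= N_MINUTES:
        raise ValueError(f"minute must be in 1..{N_MINUTES}")
    return f"{parameter}@min{minute:02d}"


def feature_names() -> list[str]:
    """All 780 feature names, parameter-major then minute."""
    return [feature_name(p, m) for p in PARAMETERS for m in range(1, N_MINUTES + 1)]


def parse_feature_name(name: str) -> tuple[str, int]:
    """Invert :func:`feature_name`."""
    param, _, min_part = name.partition("@min")
    minute = int(min_part)
    if param not in PARAMETERS or not 1 <= minute <= N_MINUTES:
        raise ValueError(f"malformed feature name {name!r}")
    return param, minute
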