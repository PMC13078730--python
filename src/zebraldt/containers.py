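"""In-memory containers: per-larva locomotor records and cohort feature matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import (
    BIN_SECONDS,
    N_FEATURES,
    N_MINUTES,
    N_PARAMETERS,
    PARAMETERS,
    feature_names,
)

CONTROL = "control"
EXPOSED = "exposed"

_IDX = {p: i for i, p in enumerate(PARAMETERS)}


class ValidationError(ValueError):
    """A record or matrix violates a structural invariant."""


@dataclass
class LocomotorRecord:
    """One larva's 13 x 60 locomotor parameter matrix plus identity metadata.

    ``values[i, j]`` is parameter ``PARAMETERS[i]`` during 1-based minute
    ``j + 1``.  Durations are seconds per minute-bin, distances mm, speeds mm/s.
    """

    larva_id: str
    group: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_PARAMETERS, N_MINUTES):
            raise ValidationError(
                f"record {self.larva_id!r}: values must be "
                f"{N_PARAMETERS} x {N_MINUTES}, got {self.values.shape}"
            )

    def param(self, name: str) -> np.ndarray:
        """The 60-minute trace of one parameter."""
        return self.values[_IDX[name]]

    def validate(self, atol: float = 1e-6) -> None:
        """Check the ZebraBox consistency invariants.

        Per minute: the three class durations sum to 60 s; the class
        distances sum to ``dist``; ``dur`` is active (small + large) time;
        class speeds equal distance/duration (0 where duration is 0); and
        the burst aggregates never exceed the totals.
        """
        v = self.values
        if np.any(v < -atol):
            raise ValidationError(f"record {self.larva_id!r}: negative values")
        g = self.param
        if not np.allclose(g("inadur") + g("smldur") + g("lardur"), BIN_SECONDS, atol=atol):
            raise ValidationError(
                f"record {self.larva_id!r}: class durations do not sum to {BIN_SECONDS} s"
            )
        if not np.allclose(g("inadist") + g("smldist") + g("lardist"), g("dist"), atol=atol):
            raise ValidationError(
                f"record {self.larva_id!r}: class distances do not sum to dist"
            )
        if not np.allclose(g("smldur") + g("lardur"), g("dur"), atol=atol):
            raise ValidationError(f"record {self.larva_id!r}: dur != smldur + lardur")
        for cls in ("ina", "sml", "lar"):
            dur, dist, spd = g(cls + "dur"), g(cls + "dist"), g(cls + "spd")
            expect = np.where(dur > 0, dist / np.where(dur > 0, dur, 1.0), 0.0)
            if not np.allclose(spd, expect, atol=atol):
                raise ValidationError(
                    f"record {self.larva_id!r}: {cls}spd != {cls}dist / {cls}dur"
                )
        if np.any(g("distb") > g("dist") + atol) or np.any(g("durb") > g("dur") + atol):
            raise ValidationError(
                f"record {self.larva_id!r}: burst aggregates exceed totals"
            )


@dataclass
class FeatureMatrix:
    """Cohort matrix of flattened feature vectors with class labels.

    For LDT cohorts each row is one larva's 780-length vector
    (13 parameters x 60 minutes, parameter-major); the container also holds
    arbitrary-width matrices such as uniform-random null datasets.
    """

    sample_ids: list[str]
    labels: np.ndarray
    features: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        n, p = self.features.shape
        if not self.feature_names:
            self.feature_names = [f"f{i:04d}" for i in range(p)]
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValidationError("sample_ids/labels length must match feature rows")
        if len(self.feature_names) != p:
            raise ValidationError("feature_names length must match feature columns")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample_ids must be unique")
        if np.any(~np.isfinite(self.features)):
            raise ValidationError("feature matrix contains missing/non-finite values")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(map(str, self.labels)))

    def require_two_groups(self) -> tuple[str, str]:
        cls = self.classes
        if len(cls) != 2:
            raise ValidationError(
                f"two-group analysis requires exactly 2 class labels, got {cls}"
            )
        return cls[0], cls[1]

    def validate_ldt(self) -> None:
        """Check the flattened-LDT shape: exactly 780 named features."""
        if self.n_features != N_FEATURES:
            raise ValidationError(
                f"LDT feature matrix must have {N_FEATURES} features, "
                f"got {self.n_features}"
            )
        if self.feature_names != feature_names():
            raise ValidationError("feature names do not match the parameter catalog")

    def relabel(self, labels: np.ndarray) -> "FeatureMatrix":
        """Same features, new labels (used for label permutation)."""
        return FeatureMatrix(
            sample_ids=list(self.sample_ids),
            labels=np.asarray(labels),
            features=self.features,
            feature_names=list(self.feature_names),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        if "sample_id" not in df.columns or "label" not in df.columns:
            raise ValidationError("frame must have sample_id and label columns")
        feats = df.drop(columns=["sample_id", "label"])
        return cls(
            sample_ids=df["sample_id"].astype(str).tolist(),
            labels=df["label"].astype(str).to_numpy(),
            features=feats.to_numpy(dtype=float),
            feature_names=list(feats.columns),
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))
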