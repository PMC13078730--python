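"""Reading locomotor tables and flattening them to the 780-feature form.

Each larva's 13 x 60 parameter matrix is unrolled into a single vector of
length 780 (= 13 x 60), parameter-major: ``inadur@min01 .. inadur@min60,
inadist@min01, ...``.  Values are copied without normalization or scaling.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import N_MINUTES, PARAMETERS, PhaseSchedule, feature_names
from .containers import FeatureMatrix, LocomotorRecord, ValidationError

LONG_COLUMNS = ("larva_id", "group", "minute", "parameter", "value")


def _records_from_cells(df: pd.DataFrame, n_minutes: int) -> list[LocomotorRecord]:
    """Pivot a validated long table into per-larva records."""
    records = []
    for larva_id, sub in df.groupby("larva_id", sort=True):
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise ValidationError(
                f"larva {larva_id!r} has inconsistent group labels: {sorted(groups)}"
            )
        wide = sub.pivot(index="parameter", columns="minute", values="value")
        missing = [
            (p, m)
            for p in PARAMETERS
            for m in range(1, n_minutes + 1)
            if p not in wide.index or m not in wide.columns or pd.isna(wide.at[p, m])
        ]
        if missing:
            shown = ", ".join(f"{p}@min{m}" for p, m in missing[:5])
            raise ValidationError(
                f"larva {larva_id!r}: {len(missing)} missing cell(s), e.g. {shown}"
            )
        values = wide.reindex(index=list(PARAMETERS), columns=range(1, n_minutes + 1))
        records.append(
            LocomotorRecord(
                larva_id=str(larva_id),
                group=str(groups[0]),
                values=values.to_numpy(dtype=float),
            )
        )
    return records


def read_long_table(path, schedule: PhaseSchedule | None = None) -> list[LocomotorRecord]:
    """Read a long-format cohort CSV into per-larva records.

    Expects columns ``larva_id, group, minute, parameter, value`` with
    1-based minutes spanning the full recording and one row per
    (larva, parameter, minute) cell.  Missing, duplicate or unknown cells
    raise :class:`ValidationError` naming the offending larva or parameter.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schedule = schedule or PhaseSchedule()
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = set(LONG_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"missing required columns: {sorted(missing_cols)}")

    unknown = set(df["parameter"].unique()) - set(PARAMETERS)
    if unknown:
        raise ValidationError(
            f"unknown parameter(s) {sorted(unknown)}; allowed names: {list(PARAMETERS)}"
        )
    n_minutes = schedule.total_min
    bad_minutes = df.loc[(df["minute"] < 1) | (df["minute"] > n_minutes), "minute"]
    if len(bad_minutes):
        raise ValidationError(
            f"minute values outside 1..{n_minutes}: {sorted(bad_minutes.unique())[:5]}"
        )
    dups = df.duplicated(subset=["larva_id", "parameter", "minute"])
    if dups.any():
        first = df.loc[dups, ["larva_id", "parameter", "minute"]].iloc[0]
        raise ValidationError(
            f"duplicate cell for larva {first['larva_id']!r}, "
            f"{first['parameter']}@min{first['minute']}"
        )
    return _records_from_cells(df, n_minutes)


def read_wide_table(path, schedule: PhaseSchedule | None = None) -> list[LocomotorRecord]:
    """Read a wide cohort CSV: larva_id, group, minute, then 13 parameter columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"larva_id", "group", "minute", *PARAMETERS}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing required columns: {sorted(missing)}")
    long = df.melt(
        id_vars=["larva_id", "group", "minute"],
        value_vars=list(PARAMETERS),
        var_name="parameter",
        value_name="value",
    )
    schedule = schedule or PhaseSchedule()
    dups = long.duplicated(subset=["larva_id", "parameter", "minute"])
    if dups.any():
        raise ValidationError("duplicate (larva, minute) rows in wide table")
    return _records_from_cells(long, schedule.total_min)


def vectorize(record: LocomotorRecord) -> tuple[np.ndarray, list[str]]:
    """Flatten one 13 x 60 record to its 780-length feature vector.

    Ordering is parameter-major then minute; values are copied unchanged.
    Returns the vector and the matching ``param@minXX`` feature names.
    """
    if record.values.shape[1] != N_MINUTES:
        raise ValidationError(
            f"record {record.larva_id!r} has {record.values.shape[1]} minutes; "
            f"expected {N_MINUTES}"
        )
    if np.any(~np.isfinite(record.values)):
        raise ValidationError(f"record {record.larva_id!r} has missing values")
    return record.values.ravel().copy(), feature_names()


def assemble_matrix(records: list[LocomotorRecord]) -> FeatureMatrix:
    """Stack vectorized records into a cohort feature matrix with labels."""
    if not records:
        raise ValidationError("no records to assemble")
    labels = np.array([r.group for r in records])
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValidationError(
            f"need at least two groups; got only {counts.index.tolist()}"
        )
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValidationError(f"each group needs >= 2 records; too few in {small}")
    vectors = [vectorize(r)[0] for r in records]
    return FeatureMatrix(
        sample_ids=[r.larva_id for r in records],
        labels=labels,
        features=np.vstack(vectors),
        feature_names=feature_names(),
    )
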