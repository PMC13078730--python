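"""Null calibration of classifier accuracy: random-data and label-permutation
baselines, their mean ± SD summaries, and the significance threshold.

Classifier accuracy on genuinely uninformative data should sit near 50%,
but it fluctuates; the spread of that fluctuation is what an observed
accuracy must beat to count as a real exposure effect.  Two null
distributions are built: (a) datasets of the same shape as a two-group LDT
comparison filled with i.i.d. uniform random values, and (b) label
permutations of an actual two-group dataset with the features untouched.
The significance threshold is the null mean + 1.96 x SD (a
normal-approximation upper 95% confidence limit); an empirical-quantile
alternative is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import FeatureMatrix
from .harness import ClassifierSpec, FAMILIES, make_folds, pooled_accuracy
from .synthetic import generate_null_matrix

RANDOM_DATA = "random_data"
LABEL_PERMUTATION = "label_permutation"

Z_95 = 1.96  # one-sided upper 95% limit of a normal band


@dataclass(frozen=True)
class NullDistribution:
    """Accuracies of one classifier family across randomized datasets."""

    family: str
    kind: str  # random_data | label_permutation
    accuracies: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.accuracies) < 2:
            raise ValueError("a null distribution needs >= 2 replicates")

    @property
    def n_reps(self) -> int:
        return len(self.accuracies)

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1))

    @property
    def upper95(self) -> float:
        return self.mean + Z_95 * self.sd


@dataclass(frozen=True)
class PooledNullSummary:
    """All-family pooled null: mean of family means, sqrt of mean variance."""

    family_means: dict[str, float]
    family_sds: dict[str, float]

    @property
    def overall_mean(self) -> float:
        return float(np.mean(list(self.family_means.values())))

    @property
    def overall_sd(self) -> float:
        return float(np.sqrt(np.mean([s**2 for s in self.family_sds.values()])))

    @property
    def overall_upper95(self) -> float:
        return self.overall_mean + Z_95 * self.overall_sd


def summarize_null(dist: NullDistribution) -> tuple[float, float, float]:
    """(mean, sd, upper 95% limit = mean + 1.96 sd) of a null distribution."""
    return dist.mean, dist.sd, dist.upper95


def pool_families(dists: list[NullDistribution]) -> PooledNullSummary:
    """Pool per-family nulls: average the means, average the variances."""
    if not dists:
        raise ValueError("need at least one family distribution")
    return PooledNullSummary(
        family_means={d.family: d.mean for d in dists},
        family_sds={d.family: d.sd for d in dists},
    )


def _rep_seeds(seed: int, n: int, stream: int) -> np.ndarray:
    return (
        np.random.SeedSequence([seed, stream]).generate_state(n) % (2**31)
    ).astype(int)


def random_data_baseline(
    n_per_class: int,
    n_features: int,
    families: list[str] | None = None,
    n_reps: int = 100,
    seed: int = 0,
    k: int = 5,
) -> dict[str, NullDistribution]:
    """Random-data null: fresh uniform matrices through the full harness.

    Each replicate draws a new (2 x n_per_class) x n_features matrix of
    uniform values, builds a fresh stratified fold assignment, and records
    each family's pooled dual-coding accuracy.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    families = list(families or FAMILIES)
    acc: dict[str, list[float]] = {f: [] for f in families}
    for rep_seed in _rep_seeds(seed, n_reps, stream=0):
        matrix = generate_null_matrix(n_per_class, n_features, seed=int(rep_seed))
        folds = make_folds(
            matrix.labels, k=k, seed=int(rep_seed), sample_ids=matrix.sample_ids
        )
        for fam in families:
            acc[fam].append(pooled_accuracy(matrix, ClassifierSpec(fam), folds))
    return {
        f: NullDistribution(family=f, kind=RANDOM_DATA, accuracies=tuple(acc[f]))
        for f in families
    }


def permutation_baseline(
    matrix: FeatureMatrix,
    families: list[str] | None = None,
    n_perms: int = 100,
    seed: int = 0,
    k: int = 5,
    n_perms_per_family: dict[str, int] | None = None,
) -> dict[str, NullDistribution]:
    """Label-permutation null: shuffle the labels, keep the features.

    Each replicate applies a uniform random permutation to the label vector
    (the identity permutation is not excluded) and reruns the dual-coding
    fivefold harness with a replicate-specific fold seed.
    ``n_perms_per_family`` can reduce the replicate count for slow families.
    """
    if n_perms < 2:
        raise ValueError("n_perms must be >= 2")
    families = list(families or FAMILIES)
    matrix.require_two_groups()
    per_family = {f: (n_perms_per_family or {}).get(f, n_perms) for f in families}
    max_reps = max(per_family.values())
    acc: dict[str, list[float]] = {f: [] for f in families}
    for rep, rep_seed in enumerate(_rep_seeds(seed, max_reps, stream=1)):
        rng = np.random.default_rng(int(rep_seed))
        permuted = matrix.relabel(rng.permutation(matrix.labels))
        folds = make_folds(
            permuted.labels, k=k, seed=int(rep_seed), sample_ids=permuted.sample_ids
        )
        for fam in families:
            if rep < per_family[fam]:
                acc[fam].append(pooled_accuracy(permuted, ClassifierSpec(fam), folds))
    return {
        f: NullDistribution(family=f, kind=LABEL_PERMUTATION, accuracies=tuple(acc[f]))
        for f in families
    }


def is_significant(
    observed_accuracy: float,
    null: NullDistribution | PooledNullSummary,
    method: str = "normal",
) -> tuple[bool, float]:
    """Significance call for an observed pooled accuracy against a null.

    ``significant`` is True when the accuracy exceeds the null's upper 95%
    limit (mean + 1.96 SD, or the empirical 97.5th percentile with
    ``method="quantile"``).  The empirical p-value
    ``(1 + #{null >= observed}) / (n_reps + 1)`` is returned when the null
    retains its replicate accuracies, NaN for a pooled summary.
    """
    if method not in ("normal", "quantile"):
        raise ValueError("method must be 'normal' or 'quantile'")
    if isinstance(null, PooledNullSummary):
        if method == "quantile":
            raise ValueError("quantile method needs per-replicate accuracies")
        return observed_accuracy > null.overall_upper95, float("nan")
    if method == "quantile":
        threshold = float(np.quantile(null.accuracies, 0.975))
    else:
        threshold = null.upper95
    accs = np.asarray(null.accuracies)
    p_emp = (1 + int(np.sum(accs >= observed_accuracy))) / (null.n_reps + 1)
    return observed_accuracy > threshold, p_emp
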