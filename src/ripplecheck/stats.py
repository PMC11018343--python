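"""Group comparisons and summary statistics.

Two unpaired groups are compared with the Mann-Whitney U test (exact
enumeration for small tie-free samples, normal approximation with tie
and continuity correction otherwise; U reported for the first-listed
group).  Three or more groups use the Kruskal-Wallis rank test with tie
correction and a chi-square p-value.  Descriptive summaries are the
mean with a seeded percentile-bootstrap 99% confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

from .core import ValidationError

log = logging.getLogger("ripplecheck")


@dataclass
class GroupComparison:
    groups: dict[str, np.ndarray]
    H: float
    p: float
    posthoc: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    ci_level: float = 0.99
    degenerate: bool = False


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (U of first group, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValidationError("both groups need at least one value")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    small = len(x) <= 20 and len(y) <= 20
    method = "exact" if (small and not ties) else "asymptotic"
    res = spstats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p-value."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise ValidationError("need >=2 groups with >=2 values each")
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        log.warning("all values identical across groups; degenerate comparison")
        return 0.0, 1.0
    h, p = spstats.kruskal(*arrays)
    return float(h), float(p)


def compare_conditions(
    values_by_condition: dict[str, np.ndarray],
    posthoc: bool = True,
    ci_level: float = 0.99,
) -> GroupComparison:
    """Omnibus Kruskal-Wallis across conditions plus pairwise post-hocs."""
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_condition.items()}
    names = list(groups)
    flat = np.concatenate(list(groups.values()))
    degenerate = bool(np.all(flat == flat[0]))
    h, p = kruskal_wallis(*groups.values())
    ph: dict[tuple[str, str], tuple[float, float]] = {}
    if posthoc and not degenerate:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                ph[(names[i], names[j])] = mann_whitney(groups[names[i]], groups[names[j]])
    return GroupComparison(
        groups=groups, H=h, p=p, posthoc=ph, ci_level=ci_level, degenerate=degenerate
    )


def mean_ci(
    values,
    level: float = 0.99,
    n_boot: int = 10000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Mean with a seeded percentile-bootstrap confidence interval."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValidationError("mean_ci needs at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    boot_means = values[idx].mean(axis=1)
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot_means, [tail, 1.0 - tail])
    return float(values.mean()), float(lo), float(hi)
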