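"""Cohort statistics: agreement, bootstrap uncertainty, permutation power.

Three pieces of machinery compare counting methods and groups across a
cohort:

* Spearman rank correlation for agreement between counting methods (the
  count distributions need not be normal; normality is screened with the
  Shapiro-Wilk test).
* Bootstrapped mean distributions: resample a group 1,000 times with
  replacement and keep each replicate's mean, giving an uncertainty
  distribution for the group mean count.
* A bootstrapped permutation test for the difference in group mean counts:
  each of 1,000 rounds bootstraps both groups at a common random fraction
  (40-100 %) of their original sizes, then runs a 10,000-round label
  permutation test of the absolute mean difference and records its p-value.
  The decision looks at the whole p-value distribution: when more than 40 %
  of the round p-values exceed 0.10 the evidence is weak and the null is
  retained; otherwise it is rejected.  (Retaining on many large p-values is
  the logically consistent polarity of this rule; the thresholds 0.10 and
  40 % are fixed.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


def shapiro_normality(values: np.ndarray, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro-Wilk W screen; returns (W, p, is_normal at alpha)."""
    w, p = sps.shapiro(np.asarray(values, dtype=float))
    return float(w), float(p), bool(p >= alpha)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; two-sided p.

    Raises on constant input (the rank correlation is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman's rho is undefined")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class BootstrapResult:
    group: str
    n_boot: int
    mean_distribution: np.ndarray
    median_of_means: float


def bootstrap_mean_distribution(
    values: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    group: str = "",
) -> BootstrapResult:
    """Distribution of group means over ``n_boot`` resamples with replacement."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty group")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    return BootstrapResult(
        group=group,
        n_boot=n_boot,
        mean_distribution=means,
        median_of_means=float(np.median(means)),
    )


def permutation_pvalue(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided label-permutation p for the difference of group means.

    Labels are permuted without replacement within the pooled sample; the
    p-value uses the add-one convention (b + 1) / (n_perm + 1) so it is
    never exactly zero.  All-identical pooled values give p = 1.
    """
    rng = rng or np.random.default_rng()
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    observed = abs(a.mean() - b.mean())
    n, na = pooled.size, a.size
    # vectorised permutations in blocks to bound memory
    count = 0
    block = max(1, int(2e6 // max(n, 1)))
    remaining = n_perm
    while remaining > 0:
        m = min(block, remaining)
        perm = np.tile(pooled, (m, 1))
        perm = rng.permuted(perm, axis=1)
        diffs = np.abs(perm[:, :na].mean(axis=1) - perm[:, na:].mean(axis=1))
        count += int(np.sum(diffs >= observed))
        remaining -= m
    return (count + 1) / (n_perm + 1)


@dataclass
class PermutationResult:
    n_rounds: int
    n_perm: int
    p_values: np.ndarray
    frac_p_above_cut: float
    reject_null: bool
    p_cut: float = 0.10
    decision_frac: float = 0.40
    notes: list[str] = field(default_factory=list)

    # kept for plotting the p-value distribution
    @property
    def frac_p_above_0_10(self) -> float:
        return self.frac_p_above_cut


def permutation_power_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_rounds: int = 1000,
    frac_range: tuple[float, float] = (0.4, 1.0),
    n_perm: int = 10000,
    p_cut: float = 0.10,
    decision_frac: float = 0.40,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """Bootstrapped permutation test of a group difference in mean count.

    Per round: a common resampling fraction f ~ U(frac_range) is drawn, each
    group is bootstrapped at ceil(f * size) with replacement (preserving the
    size ratio), and a permutation test of the absolute mean difference at
    ``n_perm`` label permutations records its p-value.  The null is
    rejected when the fraction of round p-values above ``p_cut`` stays
    below ``decision_frac``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 members")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_values = np.empty(n_rounds)
    notes: list[str] = []
    for r in range(n_rounds):
        f = rng.uniform(*frac_range)
        na = math.ceil(f * a.size)
        nb = math.ceil(f * b.size)
        boot_a = a[rng.integers(0, a.size, na)]
        boot_b = b[rng.integers(0, b.size, nb)]
        if np.ptp(np.concatenate([boot_a, boot_b])) == 0:
            notes.append(f"round {r}: degenerate pooled sample, p set to 1")
        p_values[r] = permutation_pvalue(boot_a, boot_b, n_perm=n_perm, rng=rng)
    frac_above = float(np.mean(p_values > p_cut))
    return PermutationResult(
        n_rounds=n_rounds,
        n_perm=n_perm,
        p_values=p_values,
        frac_p_above_cut=frac_above,
        reject_null=bool(frac_above < decision_frac),
        p_cut=p_cut,
        decision_frac=decision_frac,
        notes=notes,
    )
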