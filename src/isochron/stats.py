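"""Group inference: label-permutation tests and a balanced
random-intercept estimator.

Permutation tests exchange group labels, recompute the statistic (mean
or variance difference by default) and report a two-sided p-value with
the add-one rule ``p = (1 + #{|null| >= |obs|}) / (1 + n_perm)``, so p
is never exactly 0.

The mixed-model analogue targets the balanced design "endpoint ~ 1 +
Group + (1 | participant)": with the same number of observations per
participant the fixed group effect and both variance components have
closed-form ANOVA method-of-moments estimators, which is all the
synthetic recovery studies need.  Unbalanced designs are rejected with
a pointer to full REML tooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = ["PermResult", "VarianceComponents", "perm_test",
           "variance_perm_test", "fit_random_intercept",
           "interaction_perm_test"]


@dataclass
class PermResult:
    """Observed statistic, permutation null and two-sided p-value."""

    observed: float
    null_distribution: np.ndarray
    p: float
    n_perm: int
    seed: int | None
    statistic_name: str


@dataclass
class VarianceComponents:
    """Balanced random-intercept point estimates.

    ``group_effect`` is the difference of group means (second group
    label minus first, in sorted label order); ``sd_intercept`` the
    between-participant SD; ``sd_residual`` the within-participant SD.
    """

    fixed_intercept: float
    group_effect: float
    sd_intercept: float
    sd_residual: float
    n_participants: int
    n_obs: int


def _stat_fn(statistic) -> tuple[Callable[[np.ndarray, np.ndarray], float], str]:
    if callable(statistic):
        return statistic, getattr(statistic, "__name__", "custom")
    if statistic in (None, "mean", "mean-difference"):
        return (lambda a, b: float(np.mean(a) - np.mean(b))), "mean-difference"
    if statistic in ("var", "variance-difference"):
        return (lambda a, b: float(np.var(a, ddof=1) - np.var(b, ddof=1))), \
            "variance-difference"
    raise ValueError(f"unknown statistic {statistic!r}")


def perm_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    statistic="mean",
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence | np.random.Generator | None = 0,
) -> PermResult:
    """Two-sided group-label permutation test.

    Labels are reshuffled ``n_perm`` times (Monte Carlo, with
    replacement among permutations); the p-value uses the add-one rule
    and compares absolute values, so it lies in (0, 1].
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    fn, name = _stat_fn(statistic)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = fn(a, b)
    # sorting the pool makes the Monte-Carlo null invariant to group
    # relabeling and to input order under a fixed seed
    pooled = np.sort(np.concatenate([a, b]))
    na, n = a.size, pooled.size

    if name in ("mean-difference", "variance-difference"):
        # vectorized: one (n_perm x n) matrix of shuffled pooled values
        order = np.argsort(rng.random((n_perm, n)), axis=1)
        shuffled = pooled[order]
        pa, pb = shuffled[:, :na], shuffled[:, na:]
        if name == "mean-difference":
            null = pa.mean(axis=1) - pb.mean(axis=1)
        else:
            null = pa.var(axis=1, ddof=1) - pb.var(axis=1, ddof=1)
    else:
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(pooled)
            null[i] = fn(perm[:na], perm[na:])

    tol = 1e-12 * max(1.0, abs(obs))
    p = (1.0 + np.sum(np.abs(null) >= abs(obs) - tol)) / (1.0 + n_perm)
    return PermResult(observed=float(obs), null_distribution=null, p=float(p),
                      n_perm=n_perm,
                      seed=seed if isinstance(seed, int) else None,
                      statistic_name=name)


def variance_perm_test(
    variability: pd.DataFrame,
    groups: pd.Series | dict,
    column: str = "var_amplitude",
    n_perm: int = 1000,
    seed=0,
) -> PermResult:
    """Permutation test on subject-level variability values.

    ``variability`` is the per-subject output of the peak-variability
    step; ``groups`` maps subject -> group label (two labels).
    """
    g = pd.Series(groups)
    merged = variability.set_index("subject")[column]
    labels = sorted(g.unique())
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    a = merged[g[g == labels[0]].index].to_numpy()
    b = merged[g[g == labels[1]].index].to_numpy()
    return perm_test(a, b, statistic="mean", n_perm=n_perm, seed=seed)


def fit_random_intercept(
    values: Sequence[float],
    subjects: Sequence,
    groups: Sequence,
) -> VarianceComponents:
    """Closed-form balanced estimator for ``y ~ 1 + Group + (1 | subject)``.

    With n subjects each contributing m observations:

    * ``group_effect`` — difference of raw group means;
    * ``sd_residual^2`` — pooled within-subject variance;
    * ``sd_intercept^2`` — method of moments,
      ``max(0, S^2 - sd_residual^2 / m)`` where ``S^2`` is the pooled
      within-group variance of subject means.

    Raises
    ------
    ValueError
        On unbalanced designs (use dedicated mixed-model tooling, e.g.
        statsmodels MixedLM or lme4, for those).
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "subject": list(subjects), "group": list(groups)})
    counts = df.groupby("subject").size()
    if counts.nunique() != 1:
        raise ValueError(
            "unbalanced design: observations per participant differ "
            f"({counts.min()}..{counts.max()}); use REML mixed-model tooling")
    m = int(counts.iloc[0])
    subj_group = df.groupby("subject")["group"].first()
    labels = sorted(df["group"].unique())
    if len(labels) != 2:
        raise ValueError("exactly two groups required")

    subj_means = df.groupby("subject")["y"].mean()
    group_means = {lab: subj_means[subj_group[subj_group == lab].index].mean()
                   for lab in labels}
    group_effect = float(group_means[labels[1]] - group_means[labels[0]])

    if m > 1:
        within = df.groupby("subject")["y"].var(ddof=1)
        var_resid = float(within.mean())
    else:
        var_resid = 0.0

    dev_sq, dof = 0.0, 0
    for lab in labels:
        means = subj_means[subj_group[subj_group == lab].index]
        dev_sq += float(((means - means.mean()) ** 2).sum())
        dof += len(means) - 1
    s2 = dev_sq / dof if dof > 0 else 0.0
    var_intercept = max(0.0, s2 - var_resid / m)

    return VarianceComponents(
        fixed_intercept=float(group_means[labels[0]]),
        group_effect=group_effect,
        sd_intercept=float(np.sqrt(var_intercept)),
        sd_residual=float(np.sqrt(var_resid)),
        n_participants=int(len(counts)),
        n_obs=int(len(df)),
    )


def interaction_perm_test(
    peaks: pd.DataFrame,
    groups: pd.Series | dict,
    value_column: str = "amplitude",
    n_perm: int = 1000,
    seed=0,
) -> PermResult:
    """Permutation analogue of a Group x Time (tone position) interaction.

    Each subject is summarized by the least-squares slope of the
    endpoint against tone position (the repetition-suppression trend);
    the test statistic is the group difference of mean trends, with
    group labels permuted across subjects.
    """
    g = pd.Series(groups)
    trends = {}
    for subj, grp in peaks.groupby("subject"):
        per_pos = grp.groupby("position")[value_column].mean()
        if len(per_pos) < 2:
            raise ValueError(f"subject {subj}: need >= 2 positions for a trend")
        trends[subj] = float(np.polyfit(per_pos.index.to_numpy(dtype=float),
                                        per_pos.to_numpy(), 1)[0])
    tr = pd.Series(trends)
    labels = sorted(g.unique())
    a = tr[g[g == labels[0]].index].to_numpy()
    b = tr[g[g == labels[1]].index].to_numpy()
    res = perm_test(a, b, statistic="mean", n_perm=n_perm, seed=seed)
    res.statistic_name = "position-trend-difference"
    return res
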