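"""Group statistics: one-way ANOVA with Tukey HSD and compact letter
display, two-sample t test, and two-sample Kolmogorov-Smirnov test."""
from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["GroupComparison", "compare_groups", "compact_letter_display"]

TESTS = ("anova_tukey", "t_test", "ks_test")


@dataclass
class GroupComparison:
    test: str
    groups: list
    statistic: float
    p_value: float
    alpha: float = 0.05
    letters: dict | None = None
    pairwise: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)


def compact_letter_display(groups: list, sig_pairs: set) -> dict:
    """Letters such that two groups share a letter iff they are not
    significantly different (insert-and-absorb algorithm).

    ``sig_pairs`` holds frozensets {a, b} of significantly different pairs.
    """
    columns: list[set] = [set(groups)]
    for pair in sig_pairs:
        a, b = sorted(pair, key=lambda g: groups.index(g))
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            for new in (col - {b}, col - {a}):
                if new and not any(new <= other for other in columns):
                    columns.append(new)
    # absorb strict subsets
    columns = [c for c in columns if not any(c < d for d in columns)]
    columns.sort(key=lambda c: min(groups.index(g) for g in c))
    alphabet = string.ascii_lowercase
    letters = {g: "" for g in groups}
    for letter, col in zip(alphabet, columns):
        for g in groups:
            if g in col:
                letters[g] += letter
    return letters


def compare_groups(
    table: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    test: str = "anova_tukey",
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare group means per the named design.

    ``anova_tukey`` runs a one-way ANOVA followed by Tukey's HSD
    mean-separation test and assigns compact letters; ``t_test`` and
    ``ks_test`` require exactly two groups.
    """
    if test not in TESTS:
        raise ValueError(f"test must be one of {TESTS}, got {test!r}")
    names = list(pd.unique(table[group]))
    samples = [table.loc[table[group] == g, value].to_numpy(dtype=float) for g in names]
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    if any(s.size < 2 for s in samples):
        raise ValueError("every group needs n >= 2")
    if all(s.std(ddof=1) == 0 for s in samples):
        raise ValueError("degenerate data: zero variance in every group")

    if test == "t_test":
        if len(names) != 2:
            raise ValueError("t_test requires exactly 2 groups")
        stat, p = sps.ttest_ind(samples[0], samples[1], equal_var=True)
        return GroupComparison(test=test, groups=names, statistic=float(stat),
                               p_value=float(p), alpha=alpha)
    if test == "ks_test":
        if len(names) != 2:
            raise ValueError("ks_test requires exactly 2 groups")
        stat, p = sps.ks_2samp(samples[0], samples[1])
        return GroupComparison(test=test, groups=names, statistic=float(stat),
                               p_value=float(p), alpha=alpha)

    f_stat, p = sps.f_oneway(*samples)
    tuk = pairwise_tukeyhsd(
        endog=table[value].to_numpy(dtype=float),
        groups=table[group].to_numpy(),
        alpha=alpha,
    )
    pair_df = pd.DataFrame(
        data=tuk.summary().data[1:], columns=tuk.summary().data[0]
    )
    sig_pairs = {
        frozenset((row["group1"], row["group2"]))
        for _, row in pair_df.iterrows()
        if bool(row["reject"])
    }
    letters = compact_letter_display(names, sig_pairs)
    return GroupComparison(
        test=test, groups=names, statistic=float(f_stat), p_value=float(p),
        alpha=alpha, letters=letters, pairwise=pair_df,
        extra={"n_per_group": {g: int(s.size) for g, s in zip(names, samples)}},
    )
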