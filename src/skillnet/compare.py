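"""Group comparison of network statistics by bootstrap-CI non-overlap.

Two strata differ on a (statistic, node) cell when their bootstrap
percentile CIs share no point; touching endpoints count as overlap.
This is a deliberately conservative criterion and no multiple-testing
correction is applied — the report carries the number of comparisons so
readers can judge.  Note the caveat that CI non-overlap between groups of
very different sample size does not fully account for differences in the
weight distributions across groups.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .resampling import BootstrapSummary

__all__ = ["GroupComparison", "compare_groups", "compare_all", "AGE_PAIR_MARKERS"]

# Marker symbols for the three canonical age contrasts.
AGE_PAIR_MARKERS = {
    ("3-5", "6-8"): "*",
    ("6-8", "9-11"): "°",
    ("3-5", "9-11"): "+",
}


@dataclass
class GroupComparison:
    """CI-overlap comparison of two strata's bootstrap summaries."""

    group_a: str
    group_b: str
    table: pd.DataFrame  # per (statistic, node): CIs, differs flag, direction
    marker: str = ""

    @property
    def n_comparisons(self) -> int:
        return len(self.table)

    @property
    def n_differences(self) -> int:
        return int(self.table["differs"].sum())

    def differences(self) -> pd.DataFrame:
        return self.table[self.table["differs"]]


def compare_groups(
    a: BootstrapSummary, b: BootstrapSummary, name_a: str = "a", name_b: str = "b",
    marker: str = "",
) -> GroupComparison:
    """Flag every (statistic, node) cell whose CIs do not overlap."""
    if a.labels != b.labels:
        sym = set(a.labels) ^ set(b.labels)
        raise ValidationError(f"node label mismatch between groups: {sorted(sym)}")
    if set(a.stat_samples) != set(b.stat_samples):
        sym = set(a.stat_samples) ^ set(b.stat_samples)
        raise ValidationError(f"statistic mismatch between groups: {sorted(sym)}")
    if a.level != b.level:
        raise ValidationError("groups were bootstrapped at different CI levels")
    ta = a.stat_table().set_index(["statistic", "node"])
    tb = b.stat_table().set_index(["statistic", "node"])
    rows = []
    for key in ta.index:
        ra, rb = ta.loc[key], tb.loc[key]
        differs = (ra["ci_high"] < rb["ci_low"]) or (rb["ci_high"] < ra["ci_low"])
        if differs:
            direction = name_b if ra["ci_high"] < rb["ci_low"] else name_a
        else:
            direction = ""
        rows.append(
            {
                "statistic": key[0],
                "node": key[1],
                f"{name_a}_mean": ra["boot_mean"],
                f"{name_a}_ci_low": ra["ci_low"],
                f"{name_a}_ci_high": ra["ci_high"],
                f"{name_b}_mean": rb["boot_mean"],
                f"{name_b}_ci_low": rb["ci_low"],
                f"{name_b}_ci_high": rb["ci_high"],
                "differs": bool(differs),
                "higher_group": direction,
            }
        )
    return GroupComparison(
        group_a=name_a, group_b=name_b, table=pd.DataFrame(rows), marker=marker
    )


def compare_all(
    summaries: dict[str, BootstrapSummary],
    pairs: list[tuple[str, str]] | None = None,
) -> list[GroupComparison]:
    """Pairwise CI-overlap comparisons across strata.

    Default pairs are the three canonical age contrasts (3-5 vs 6-8,
    6-8 vs 9-11, 3-5 vs 9-11), annotated with their marker symbols
    (*, °, +), restricted to strata actually present.
    """
    if pairs is None:
        pairs = [pr for pr in AGE_PAIR_MARKERS if pr[0] in summaries and pr[1] in summaries]
    out = []
    for pa, pb in pairs:
        for name in (pa, pb):
            if name not in summaries:
                raise ValidationError(f"unknown stratum {name!r}")
        marker = AGE_PAIR_MARKERS.get((pa, pb), AGE_PAIR_MARKERS.get((pb, pa), ""))
        out.append(compare_groups(summaries[pa], summaries[pb], pa, pb, marker=marker))
    return out
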