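"""Group comparison: percent-of-control normalization and one-way ANOVA.

The control group's mean defines 100%; groups are compared with a classic
one-way ANOVA (between/within mean-square ratio against the F tail), with
significance tiers at p<0.05 (*), p<0.01 (**) and p<0.001 (***).  Values
are reported as mean ± SD.  Alongside the omnibus p, each non-control
group also gets a two-group ANOVA against the control (equivalent to a
squared equal-variance t test), since starred panels conventionally mark
vs-control contrasts.  A Holm-adjusted column across the ten parameters
is emitted as a clearly-marked extension; the primary p values carry no
multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .schema import MorphometricProfile

__all__ = [
    "GroupTable",
    "ComparisonResult",
    "normalize_to_control",
    "one_way_anova",
    "significance_tier",
    "compare_profiles",
    "profiles_to_frame",
]


@dataclass
class GroupTable:
    """Per-section values of one parameter, split into named groups."""

    parameter: str
    groups: Dict[str, np.ndarray]
    control_group: str = "control"

    def __post_init__(self):
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        if self.control_group not in self.groups:
            raise ValueError(f"control group {self.control_group!r} missing")
        for name, vals in self.groups.items():
            if vals.size < 2:
                raise ValueError(f"group {name!r} needs n >= 2 for ANOVA")


def normalize_to_control(table: GroupTable) -> GroupTable:
    """Express every value as a percent of the control-group mean."""
    control_mean = float(table.groups[table.control_group].mean())
    if control_mean == 0.0:
        raise ValueError("control-group mean is zero; cannot normalize")
    return GroupTable(
        parameter=table.parameter,
        groups={k: v / control_mean * 100.0 for k, v in table.groups.items()},
        control_group=table.control_group,
    )


def one_way_anova(groups: Sequence[np.ndarray]) -> Tuple[float, float]:
    """Classical one-way ANOVA: returns (F, p).

    Raises when the pooled within-group variance is zero (p would be
    degenerate) or any group has fewer than two observations.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    grand = np.concatenate(arrays).mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((a - m) ** 2).sum() for a, m in zip(arrays, means)))
    df_b = len(arrays) - 1
    df_w = int(ns.sum()) - len(arrays)
    if ssw == 0.0:
        raise ValueError("zero within-group variance; ANOVA undefined")
    f_stat = (ssb / df_b) / (ssw / df_w)
    p = float(f_dist.sf(f_stat, df_b, df_w))
    return f_stat, p


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ComparisonResult:
    """One parameter's group comparison."""

    parameter: str
    group_means: Dict[str, float]
    group_sds: Dict[str, float]
    percent_of_control: Dict[str, float]
    f_stat: float
    p_value: float
    tier: str
    #: per non-control group: two-group ANOVA against the control
    vs_control_p: Dict[str, float] = field(default_factory=dict)
    holm_adjusted_p: Optional[float] = None  # extension, not in the source method

    def as_row(self) -> dict:
        row = {"parameter": self.parameter, "F": self.f_stat,
               "p": self.p_value, "tier": self.tier,
               "holm_p": self.holm_adjusted_p}
        for g in self.group_means:
            row[f"mean_{g}"] = self.group_means[g]
            row[f"sd_{g}"] = self.group_sds[g]
            row[f"pct_control_{g}"] = self.percent_of_control[g]
        for g, p in self.vs_control_p.items():
            row[f"p_vs_control_{g}"] = p
        return row


def profiles_to_frame(profiles: Sequence[MorphometricProfile],
                      groups: Sequence[str]) -> pd.DataFrame:
    """Long-format frame: one row per section, columns = parameters + group."""
    if len(profiles) != len(groups):
        raise ValueError("profiles and group tags must align")
    rows = []
    for prof, g in zip(profiles, groups):
        row = prof.as_dict()
        row["group"] = g
        rows.append(row)
    return pd.DataFrame(rows)


def compare_profiles(
    profiles: Sequence[MorphometricProfile],
    groups: Sequence[str],
    control_group: str = "control",
) -> List[ComparisonResult]:
    """One ComparisonResult per morphometric parameter."""
    frame = profiles_to_frame(profiles, groups)
    results: List[ComparisonResult] = []
    for param in MorphometricProfile.PARAM_NAMES:
        table = GroupTable(
            parameter=param,
            groups={g: frame.loc[frame["group"] == g, param].to_numpy()
                    for g in frame["group"].unique()},
            control_group=control_group,
        )
        try:
            f_stat, p = one_way_anova(list(table.groups.values()))
        except ValueError:
            # degenerate (e.g. a constant parameter): no test possible
            f_stat, p = np.nan, np.nan
        control_mean = float(table.groups[control_group].mean())
        pct = {
            g: (float(v.mean()) / control_mean * 100.0 if control_mean != 0 else np.nan)
            for g, v in table.groups.items()
        }
        vs_control = {}
        for g, v in table.groups.items():
            if g == control_group:
                continue
            try:
                _, p2 = one_way_anova([table.groups[control_group], v])
            except ValueError:
                p2 = np.nan
            vs_control[g] = p2
        results.append(ComparisonResult(
            parameter=param,
            group_means={g: float(v.mean()) for g, v in table.groups.items()},
            group_sds={g: float(v.std(ddof=1)) for g, v in table.groups.items()},
            percent_of_control=pct,
            f_stat=f_stat,
            p_value=p,
            tier=significance_tier(p) if np.isfinite(p) else "na",
            vs_control_p=vs_control,
        ))
    # Holm adjustment across the ten parameters (extension)
    finite = [i for i, r in enumerate(results) if np.isfinite(r.p_value)]
    ps = np.array([results[i].p_value for i in finite])
    order = np.argsort(ps)
    m = len(ps)
    running_max = 0.0
    for rank, j in enumerate(order):
        running_max = max(running_max, (m - rank) * ps[j])
        results[finite[j]].holm_adjusted_p = float(min(1.0, running_max))
    return results


def results_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])
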