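"""Group comparison across the 2-geometry x 2-flow experimental design.

The four groups are capillary/PPFC crossed with static (0 mPa) and
perfused (10 mPa) conditions.  The replication unit is the biological
sample (one seeded tube or chamber): per-cell measurements are averaged
within each sample before testing, because cells sharing a device are
not independent observations.  A per-cell mode exists but its output is
explicitly labelled as pseudo-replicated.

Testing is classical one-way ANOVA followed by Tukey's HSD (the
Tukey-Kramer extension when group sizes are unbalanced), with
family-wise alpha 0.05 by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GROUPS",
    "GroupedMeasurements",
    "ComparisonResult",
    "anova_oneway",
    "tukey_hsd",
    "compare_groups",
    "GEOMETRY_PAIRS",
    "FLOW_PAIRS",
]

GROUPS: Tuple[str, ...] = ("cap_static", "cap_flow", "ppfc_static", "ppfc_flow")

#: Pairs contrasting the two device geometries at matched flow ('#' pairs).
GEOMETRY_PAIRS = (("cap_static", "ppfc_static"), ("cap_flow", "ppfc_flow"))
#: Pairs contrasting perfused vs static within a geometry ('*' pairs).
FLOW_PAIRS = (("cap_static", "cap_flow"), ("ppfc_static", "ppfc_flow"))


class InsufficientReplicationError(ValueError):
    """A group has fewer than two observations."""


class SchemaError(ValueError):
    """The per-cell table is missing required columns or is empty."""


@dataclass
class GroupedMeasurements:
    """Observations (one value per sample) keyed by group label."""

    observations: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.observations = {k: np.asarray(v, dtype=np.float64) for k, v in self.observations.items()}
        if len(self.observations) < 2:
            raise ValueError("need at least two groups")
        for name, vals in self.observations.items():
            if vals.size < 2:
                raise InsufficientReplicationError(
                    f"group {name!r} has {vals.size} observation(s); >= 2 required"
                )

    @property
    def groups(self) -> List[str]:
        return list(self.observations)


@dataclass
class ComparisonResult:
    """ANOVA F/p plus the Tukey pairwise table for one measure."""

    measure: str
    f_statistic: float
    anova_p: float
    tukey: pd.DataFrame
    alpha: float
    unit: str = "sample"


def anova_oneway(data: GroupedMeasurements) -> Tuple[float, float]:
    """Classical one-way ANOVA F and p.

    Between/within mean squares with (k - 1, N - k) degrees of freedom.
    When all observations are identical the F statistic is defined as 0
    with p = 1 (no evidence of any group effect); when groups differ
    with zero within-group variance, F is infinite and p = 0.
    """
    groups = [data.observations[g] for g in data.groups]
    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = k - 1
    df_within = n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return float(f), p


def tukey_hsd(data: GroupedMeasurements, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise mean differences with studentized-range adjusted p.

    Uses the Tukey-Kramer standard error, valid for unbalanced designs.
    Returns a frame with columns group_a, group_b, difference
    (mean_b - mean_a), p_adj and significant (p_adj < alpha).
    """
    names = data.groups
    groups = [data.observations[g] for g in names]
    k = len(groups)
    df_within = sum(g.size for g in groups) - k
    ms_within = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_within

    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            ga, gb = groups[a], groups[b]
            diff = gb.mean() - ga.mean()
            if ms_within == 0.0:
                p_adj = 1.0 if diff == 0.0 else 0.0
            else:
                se = np.sqrt(ms_within / 2.0 * (1.0 / ga.size + 1.0 / gb.size))
                q = abs(diff) / se
                p_adj = float(np.clip(sps.studentized_range.sf(q, k, df_within), 0.0, 1.0))
            rows.append(
                {
                    "group_a": names[a],
                    "group_b": names[b],
                    "difference": float(diff),
                    "p_adj": p_adj,
                    "significant": p_adj < alpha,
                }
            )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "difference", "p_adj", "significant"])


def _aggregate(cells: pd.DataFrame, measure: str, unit: str) -> GroupedMeasurements:
    if unit == "sample":
        per_sample = cells.groupby(["group", "sample_id"], sort=True)[measure].mean()
        obs = {g: per_sample.loc[g].to_numpy() for g in per_sample.index.get_level_values(0).unique()}
    else:  # per-cell pseudo-replication, labelled as such downstream
        obs = {g: sub[measure].to_numpy() for g, sub in cells.groupby("group", sort=True)}
    return GroupedMeasurements(obs)


def compare_groups(
    cells: pd.DataFrame,
    measures: Sequence[str] = ("runx2_mean", "contrast", "entropy"),
    alpha: float = 0.05,
    unit: str = "sample",
) -> Dict[str, ComparisonResult]:
    """ANOVA + Tukey per measure on a per-cell table.

    The table needs ``group`` and ``sample_id`` columns plus one column
    per measure.  With ``unit='sample'`` (default) cells are averaged
    within each sample first; ``unit='cell'`` treats every cell as an
    observation (pseudo-replication; flagged in the result's ``unit``).
    """
    if unit not in ("sample", "cell"):
        raise ValueError(f"unit must be 'sample' or 'cell', got {unit!r}")
    if cells is None or len(cells) == 0:
        raise SchemaError("per-cell table is empty")
    required = {"group", "sample_id", *measures}
    missing = sorted(required - set(cells.columns))
    if missing:
        raise SchemaError(f"per-cell table missing columns: {missing}")

    results: Dict[str, ComparisonResult] = {}
    for measure in measures:
        data = _aggregate(cells.dropna(subset=[measure]), measure, unit)
        f, p = anova_oneway(data)
        tukey = tukey_hsd(data, alpha)
        results[measure] = ComparisonResult(
            measure=measure, f_statistic=f, anova_p=p, tukey=tukey, alpha=alpha,
            unit=unit if unit == "sample" else "cell (pseudo-replication)",
        )
    return results


def significance_summary(results: Dict[str, ComparisonResult]) -> str:
    """Plain-text report using '#' for geometry pairs and '*' for flow pairs."""
    lines = []
    for measure, res in results.items():
        lines.append(f"{measure}: F = {res.f_statistic:.3f}, p = {res.anova_p:.4g} "
                     f"(alpha = {res.alpha}, unit = {res.unit})")
        for _, row in res.tukey.iterrows():
            pair = (row.group_a, row.group_b)
            marker = ""
            if pair in GEOMETRY_PAIRS or pair[::-1] in GEOMETRY_PAIRS:
                marker = " #"
            elif pair in FLOW_PAIRS or pair[::-1] in FLOW_PAIRS:
                marker = " *"
            flag = "significant" if row.significant else "n.s."
            lines.append(
                f"  {row.group_b} - {row.group_a}: diff = {row.difference:+.4g}, "
                f"p_adj = {row.p_adj:.4g} [{flag}]{marker}"
            )
    return "\n".join(lines)
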