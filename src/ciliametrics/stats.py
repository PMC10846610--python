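"""Group comparisons across strains and conditions.

Two-group comparisons use Welch's unequal-variance two-tailed t-test with
Welch–Satterthwaite degrees of freedom (a pooled-variance flag exists for
the classic Student variant). No multiple-testing correction is applied by
default; Benjamini–Hochberg is available and its use is recorded in the
report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_groups", "benjamini_hochberg", "export_report"]


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    percent_change: float  # 100 * (mean_b - mean_a) / mean_a
    t_statistic: float
    p_value: float
    df: float
    equal_var: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def compare_groups(
    values_a,
    values_b,
    label_a: str = "a",
    label_b: str = "b",
    equal_var: bool = False,
) -> GroupComparison:
    """Welch's (default) or pooled two-tailed unpaired t-test plus the
    percent change of group b relative to group a.

    Degenerate zero-variance inputs are handled explicitly: identical
    constant groups give t = 0, p = 1; constant groups with different means
    give infinite t and p = 0.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 finite values")

    mean_a, mean_b = float(a.mean()), float(b.mean())
    sd_a = float(a.std(ddof=1))
    sd_b = float(b.std(ddof=1))

    if sd_a == 0.0 and sd_b == 0.0:
        if mean_a == mean_b:
            t, p = 0.0, 1.0
        else:
            t, p = math_copysign_inf(mean_b - mean_a), 0.0
        df = float(a.size + b.size - 2)
    else:
        res = sps.ttest_ind(b, a, equal_var=equal_var)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)

    pct = 100.0 * (mean_b - mean_a) / mean_a if mean_a != 0 else float("nan")
    return GroupComparison(
        group_a=label_a, group_b=label_b,
        n_a=int(a.size), n_b=int(b.size),
        mean_a=mean_a, mean_b=mean_b, sd_a=sd_a, sd_b=sd_b,
        percent_change=pct, t_statistic=t, p_value=p, df=df,
        equal_var=equal_var,
    )


def math_copysign_inf(x: float) -> float:
    return float("inf") if x > 0 else float("-inf")


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(p_values, float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def export_report(
    tables: dict[str, pd.DataFrame],
    group_map: dict[str, str],
    out_dir: str | Path,
    metric_cols: dict[str, list[str]] | None = None,
    metadata: dict | None = None,
    adjust: bool = False,
) -> dict:
    """Write a tidy measurement CSV and a JSON of all group comparisons.

    ``tables`` maps a metric-family name (e.g. ``"streaks"``) to a
    per-sample DataFrame that must carry a ``group`` column naming the
    condition; ``group_map`` maps group labels to the reference label used
    as baseline ("a") for the percent change. Tables that lack a ``group``
    column are refused with the offending names.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not tables:
        raise ValueError("no tables to report")
    bad = [name for name, t in tables.items() if "group" not in t.columns]
    if bad:
        raise ValueError(f"tables missing the required 'group' column: {bad}")

    metric_cols = metric_cols or {
        name: [c for c in t.columns
               if c != "group" and np.issubdtype(t[c].dtype, np.number)]
        for name, t in tables.items()
    }

    tidy_rows = []
    for name, t in tables.items():
        for col in metric_cols.get(name, []):
            for _, row in t.iterrows():
                tidy_rows.append({
                    "family": name, "metric": col,
                    "group": row["group"], "value": row[col],
                })
    tidy = pd.DataFrame(tidy_rows)
    tidy.to_csv(out_dir / "measurements.csv", index=False)

    comparisons = []
    for (family, metric), sub in tidy.groupby(["family", "metric"]):
        groups = sorted(sub["group"].unique())
        baselines = {group_map.get(g, g) for g in groups}
        for base in sorted(baselines):
            for g in groups:
                if g == base:
                    continue
                va = sub.loc[sub["group"] == base, "value"]
                vb = sub.loc[sub["group"] == g, "value"]
                if va.count() < 2 or vb.count() < 2:
                    continue
                cmp_ = compare_groups(va, vb, label_a=base, label_b=g)
                d = cmp_.to_dict()
                d.update({"family": family, "metric": metric})
                comparisons.append(d)

    if adjust and comparisons:
        adj = benjamini_hochberg([c["p_value"] for c in comparisons])
        for c, q in zip(comparisons, adj):
            c["p_adjusted_bh"] = float(q)

    report = {
        "comparisons": comparisons,
        "p_adjustment": "benjamini_hochberg" if adjust else "none",
        "metadata": metadata or {},
    }
    with open(out_dir / "comparisons.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
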