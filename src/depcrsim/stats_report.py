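"""Group comparisons and report generation.

Conventions used throughout: Welch's unequal-variance two-sample t-test,
two-sided, with no multiple-comparison correction; one-way ANOVA followed
by Tukey's HSD (studentized range) for >= 3 groups; and the five-level
significance-star labelling
'ns' (p >= 0.05), '*' (p < 0.05), '**' (p < 0.01), '***' (p < 0.001),
'****' (p < 0.0001).
"""

from __future__ import annotations

import hashlib
import json
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatsError


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class AnovaTukeyResult:
    f: float
    p: float
    pairwise_p: dict[tuple[str, str], float]


@dataclass
class GroupComparison:
    """One metric compared across groups, with significance labelling."""

    metric: str
    groups: dict[str, tuple[float, ...]]
    test: str  # "welch_t" | "anova_tukey"
    statistics: dict
    stars: dict[str, str]


def _check_group(values: Sequence[float], label: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise StatsError(f"group {label!r} needs >= 2 values, got {arr.size}")
    return arr


def welch_t(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch's two-sample t-test (two-sided, Welch-Satterthwaite df)."""
    x = _check_group(a, "a")
    y = _check_group(b, "b")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if np.allclose(x.mean(), y.mean()):
            # identical constant groups: no evidence of any difference
            return WelchResult(0.0, float(x.size + y.size - 2), 1.0)
        raise StatsError(
            "both groups have zero variance with different means: "
            "Welch's t-test is degenerate"
        )
    res = sps.ttest_ind(x, y, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD post hoc over >= 3 groups."""
    if len(groups) < 3:
        raise StatsError(f"ANOVA + Tukey requires >= 3 groups, got {len(groups)}")
    labels = list(groups)
    arrays = [_check_group(groups[l], l) for l in labels]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0.0:
        raise StatsError("all values identical across groups: ANOVA is degenerate")
    f, p = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    pairwise = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pairwise[(labels[i], labels[j])] = float(hsd.pvalue[i, j])
    return AnovaTukeyResult(float(f), float(p), pairwise)


def significance_stars(p: float) -> str:
    """Five-level star label; boundary conventions: 'ns' iff p >= 0.05."""
    if math.isnan(p) or not (0.0 <= p <= 1.0):
        raise StatsError(f"p-value outside [0, 1]: {p}")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    metric: str,
    groups: Mapping[str, Sequence[float]],
    test: str = "welch_t",
) -> GroupComparison:
    """Run the requested test over the groups and attach star labels."""
    gdict = {str(k): tuple(float(v) for v in vals) for k, vals in groups.items()}
    if test == "welch_t":
        if len(gdict) != 2:
            raise StatsError("welch_t comparison requires exactly 2 groups")
        (la, va), (lb, vb) = gdict.items()
        res = welch_t(va, vb)
        stats_d = {"t": res.t, "df": res.df, "p": res.p}
        stars = {f"{la} vs {lb}": significance_stars(res.p)}
    elif test == "anova_tukey":
        res = anova_tukey(gdict)
        stats_d = {
            "F": res.f,
            "p": res.p,
            "pairwise_p": {f"{a} vs {b}": v for (a, b), v in res.pairwise_p.items()},
        }
        stars = {
            f"{a} vs {b}": significance_stars(v) for (a, b), v in res.pairwise_p.items()
        }
    else:
        raise StatsError(f"unknown test {test!r}")
    return GroupComparison(metric, gdict, test, stats_d, stars)


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return "Inf" if math.isinf(f) else f
    return obj


def experiment_report(
    manifest: Mapping,
    metrics: pd.DataFrame,
    comparisons: Sequence[GroupComparison] = (),
) -> dict:
    """Assemble the metrics-per-condition + significance-stars report bundle.

    Deterministic: regenerating from the same manifest and inputs yields a
    byte-identical JSON serialization (keys sorted, no timestamps; the
    manifest hash provides provenance).
    """
    manifest = dict(manifest)
    manifest_json = json.dumps(_jsonable(manifest), sort_keys=True)
    config_hash = hashlib.sha256(manifest_json.encode()).hexdigest()
    df = metrics.copy()
    idx_names = [n or ("replicate" if i == 0 else f"index{i}")
                 for i, n in enumerate(df.index.names)]
    df.index = df.index.set_names(idx_names)
    tidy = df.reset_index().melt(id_vars=idx_names, var_name="metric", value_name="value")
    report = {
        "manifest": _jsonable(manifest),
        "config_hash": config_hash,
        "metrics": _jsonable(tidy.to_dict(orient="records")),
        "comparisons": [
            {
                "metric": c.metric,
                "test": c.test,
                "groups": _jsonable(c.groups),
                "statistics": _jsonable(c.statistics),
                "stars": dict(c.stars),
            }
            for c in comparisons
        ],
    }
    return report


def write_report(report: Mapping, out_dir) -> dict[str, Path]:
    """Write the report as JSON plus tidy TSV tables; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    jp = out / "report.json"
    jp.write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
    paths["json"] = jp
    mp = out / "metrics.tsv"
    pd.DataFrame(report["metrics"]).to_csv(mp, sep="\t", index=False)
    paths["metrics"] = mp
    if report.get("comparisons"):
        rows = []
        for c in report["comparisons"]:
            for pair, label in c["stars"].items():
                stats_d = c["statistics"]
                pval = stats_d.get("p") if c["test"] == "welch_t" else stats_d["pairwise_p"].get(pair)
                rows.append(
                    {"metric": c["metric"], "test": c["test"], "comparison": pair,
                     "p": pval, "stars": label}
                )
        cp = out / "comparisons.tsv"
        pd.DataFrame(rows).to_csv(cp, sep="\t", index=False)
        paths["comparisons"] = cp
    return paths
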