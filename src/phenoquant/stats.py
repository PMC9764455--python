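"""Group-comparison statistics and the pipeline-level report.

The study-wide conventions: two-sample Student's t tests on raw
per-individual measurements (pooled variance; two-tailed by default,
right-tailed where a direction is pre-specified), summaries as mean, SD
and the mean ± 2 SD interval, and raw (unadjusted) p values, with an
optional Benjamini-Hochberg adjustment. The right tail is fixed to test
"second group greater" and that orientation is echoed in every result.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "TestResult",
    "t_test",
    "group_summary",
    "comparison_report",
]


@dataclass
class GroupSample:
    label: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("group values must be finite")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    tail: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    orientation: str = "right tail tests mean(b) > mean(a)"


def t_test(a: GroupSample, b: GroupSample, tail: str = "two",
           welch: bool = False) -> TestResult:
    """Two-sample Student's t test (pooled variance by default).

    The statistic is ``(mean(b) - mean(a)) / SE`` so a positive t means
    the second group is larger; ``tail="right"`` tests mean(b) > mean(a).
    Degenerate inputs: zero pooled variance with equal means gives
    t = 0, p = 1; with unequal means it is an error.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs at least 2 values")
    if tail not in ("two", "right"):
        raise ValueError("tail must be 'two' or 'right'")
    ma, mb = a.values.mean(), b.values.mean()
    va = a.values.var(ddof=1)
    vb = b.values.var(ddof=1)
    if welch:
        se2 = va / a.n + vb / b.n
        if se2 == 0:
            if ma == mb:
                df = float(a.n + b.n - 2)
                return TestResult(0.0, df, 1.0, tail, ma, mb,
                                  float(np.sqrt(va)), float(np.sqrt(vb)))
            raise ValueError("zero variance with unequal means: t undefined")
        df = se2 ** 2 / ((va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1))
        t = (mb - ma) / np.sqrt(se2)
    else:
        df = float(a.n + b.n - 2)
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / df
        if sp2 == 0:
            if ma == mb:
                return TestResult(0.0, df, 1.0, tail, ma, mb,
                                  float(np.sqrt(va)), float(np.sqrt(vb)))
            raise ValueError("zero pooled variance with unequal means: "
                             "t undefined")
        t = (mb - ma) / np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    if tail == "two":
        p = 2.0 * float(sps.t.sf(abs(t), df))
    else:
        p = float(sps.t.sf(t, df))
    return TestResult(float(t), float(df), min(p, 1.0), tail, float(ma),
                      float(mb), float(np.sqrt(va)), float(np.sqrt(vb)))


def group_summary(sample: GroupSample) -> dict:
    """Mean, sample SD (n-1), and the mean ± 2 SD interval (the box-and-
    tails convention: the box is one SD, the tails two SDs, ~95%)."""
    if sample.n < 1:
        raise ValueError("empty sample")
    mean = float(sample.values.mean())
    if sample.n == 1:
        return {"label": sample.label, "n": 1, "mean": mean, "sd": None,
                "interval_2sd": None}
    sd = float(sample.values.std(ddof=1))
    return {"label": sample.label, "n": sample.n, "mean": mean, "sd": sd,
            "interval_2sd": (mean - 2 * sd, mean + 2 * sd)}


def comparison_report(metrics: pd.DataFrame, group_order=None,
                      tail: str = "two", alpha: float = 0.05,
                      adjust: str | None = None) -> pd.DataFrame:
    """Per-metric group comparison across the pipeline's measurements.

    ``metrics`` is tidy: columns ``metric``, ``group``, ``value`` (one row
    per individual measurement). For each metric, group summaries are
    computed; when exactly two groups share the metric, a t test is run
    (``group_order`` fixes which is "a" and which is "b"). p values are
    raw by default, mirroring the per-figure convention; ``adjust="bh"``
    applies Benjamini-Hochberg. A caveat is emitted when more than 10
    metrics are tested without adjustment. A metric missing for a group
    is reported absent, never imputed.
    """
    required = {"metric", "group", "value"}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metrics frame needs columns {sorted(required)}")
    groups = list(group_order) if group_order is not None else \
        sorted(metrics["group"].unique())
    rows = []
    for metric, sub in metrics.groupby("metric", sort=True):
        present = [g for g in groups if g in set(sub["group"])]
        row: dict = {"metric": metric}
        for gi, g in enumerate(groups):
            tag = chr(ord("a") + gi)
            if g in present:
                vals = sub.loc[sub["group"] == g, "value"].to_numpy()
                s = group_summary(GroupSample(g, vals))
                row[f"group_{tag}"] = g
                row[f"n_{tag}"] = s["n"]
                row[f"mean_{tag}"] = s["mean"]
                row[f"sd_{tag}"] = s["sd"]
            else:
                row[f"group_{tag}"] = g
                row[f"n_{tag}"] = 0
                row[f"mean_{tag}"] = None
                row[f"sd_{tag}"] = None
        if len(present) == 2 and len(groups) == 2:
            va = sub.loc[sub["group"] == groups[0], "value"].to_numpy()
            vb = sub.loc[sub["group"] == groups[1], "value"].to_numpy()
            if len(va) >= 2 and len(vb) >= 2:
                res = t_test(GroupSample(groups[0], va),
                             GroupSample(groups[1], vb), tail=tail)
                row.update({"t": res.statistic, "df": res.df, "p": res.p,
                            "tail": res.tail, "orientation": res.orientation})
        rows.append(row)
    report = pd.DataFrame(rows)
    if "p" in report.columns:
        if adjust == "bh":
            mask = report["p"].notna()
            report.loc[mask, "p_adjusted"] = _bh_adjust(
                report.loc[mask, "p"].to_numpy())
            report["significant"] = report.get("p_adjusted", report["p"]) < alpha
        else:
            report["significant"] = report["p"] < alpha
            n_tested = int(report["p"].notna().sum())
            if n_tested > 10:
                warnings.warn(
                    f"{n_tested} metrics tested with raw (unadjusted) p "
                    "values; consider adjust='bh'")
    return report


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def write_report(report: pd.DataFrame, csv_path=None, json_path=None) -> None:
    if csv_path is not None:
        report.to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(json.loads(report.to_json(orient="records")), fh, indent=1)
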