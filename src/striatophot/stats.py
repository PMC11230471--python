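"""Small statistics layer: t-tests and group report tables.

Implements the classical one-sample, paired and unpaired (Student) t-tests
with one- or two-tailed p-values, plus a report builder that mirrors
figure-legend tables: per-group n, mean ± SEM (or median with min-max),
test statistics and significance stars (* p<0.05, ** p<0.01, *** p<0.001).

Degenerate inputs (zero variance) do not raise: the result carries a
``degenerate`` flag and the limit p-value (1 when the effect is zero,
0 when a nonzero effect lies in the tested tail).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import ParameterError

_TAILS = ("two", "left", "right")


@dataclass
class TestResult:
    test_kind: str  # one_sample | paired | unpaired
    tail: str  # two | left | right
    n: int
    statistic: float
    df: float
    p_value: float
    n2: Optional[int] = None
    mean_effect: float = float("nan")
    sem: float = float("nan")
    labels: tuple = ("", "")
    degenerate: bool = False

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _p_from_t(t: float, df: float, tail: str) -> float:
    if tail == "two":
        return 2.0 * float(sstats.t.sf(abs(t), df))
    if tail == "right":
        return float(sstats.t.sf(t, df))
    return float(sstats.t.cdf(t, df))


def _degenerate_p(effect: float, tail: str) -> float:
    if effect == 0.0:
        return 1.0
    in_tail = (tail == "two" or (tail == "right" and effect > 0)
               or (tail == "left" and effect < 0))
    return 0.0 if in_tail else 1.0


def t_test(x, y=None, kind: str = "one_sample", tail: str = "two",
           null_value: float = 0.0, equal_var: bool = True,
           labels: tuple = ("", "")) -> TestResult:
    """Classical t-test of the stated kind and tail.

    ``kind`` is ``one_sample`` (x against ``null_value``), ``paired``
    (x − y against ``null_value``) or ``unpaired`` (two groups; Student
    pooled-variance by default, Welch with ``equal_var=False``).
    """
    if tail not in _TAILS:
        raise ParameterError(f"tail must be one of {_TAILS}")
    x = np.asarray(x, dtype=float)
    if kind in ("one_sample", "paired"):
        if kind == "paired":
            y = np.asarray(y, dtype=float)
            if y.shape != x.shape:
                raise ParameterError("paired test requires equal-length samples")
            d = x - y - null_value
        else:
            d = x - null_value
        n = d.size
        if n < 2:
            raise ParameterError("need n >= 2")
        mean = float(np.mean(d))
        sd = float(np.std(d, ddof=1))
        dof = n - 1
        if sd == 0.0:
            return TestResult(test_kind=kind, tail=tail, n=n, statistic=0.0 if mean == 0
                              else float(np.sign(mean)) * float("inf"),
                              df=dof, p_value=_degenerate_p(mean, tail),
                              mean_effect=mean, sem=0.0, labels=labels,
                              degenerate=True)
        t = mean / (sd / np.sqrt(n))
        return TestResult(test_kind=kind, tail=tail, n=n, statistic=float(t), df=dof,
                          p_value=_p_from_t(t, dof, tail), mean_effect=mean,
                          sem=sd / np.sqrt(n), labels=labels)

    if kind != "unpaired":
        raise ParameterError(f"unknown test kind '{kind}'")
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ParameterError("need n >= 2 per group")
    diff = float(np.mean(x) - np.mean(y))
    v1, v2 = float(np.var(x, ddof=1)), float(np.var(y, ddof=1))
    if v1 == 0.0 and v2 == 0.0:
        return TestResult(test_kind=kind, tail=tail, n=n1, n2=n2,
                          statistic=0.0 if diff == 0
                          else float(np.sign(diff)) * float("inf"),
                          df=n1 + n2 - 2, p_value=_degenerate_p(diff, tail),
                          mean_effect=diff, sem=0.0, labels=labels, degenerate=True)
    if equal_var:
        dof = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / dof
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        dof = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    t = diff / se
    return TestResult(test_kind=kind, tail=tail, n=n1, n2=n2, statistic=float(t),
                      df=float(dof), p_value=_p_from_t(t, dof, tail),
                      mean_effect=diff, sem=float(se), labels=labels)


def group_report(df: pd.DataFrame, value: str, group: str,
                 one_sample_null: Optional[float] = None,
                 one_sample_tail: str = "two",
                 pairwise_tail: str = "two", paired: bool = False,
                 equal_var: bool = True,
                 aggregate: str = "mean_sem") -> pd.DataFrame:
    """Build a figure-legend-style report table from per-session metrics.

    One descriptive row per group (n, mean ± SEM or median with min-max);
    optional one-sample tests of each group against ``one_sample_null``;
    pairwise tests between every pair of groups. Groups with n = 1 get
    descriptives only, with a note. Aggregation across rows is whatever
    the input frame holds (one row per session/mouse or per trial) —
    the caller decides and the table's ``n`` reports it.
    """
    if value not in df.columns or group not in df.columns:
        raise ParameterError(f"columns '{value}' and '{group}' are required")
    rows = []
    groups = list(dict.fromkeys(df[group]))
    samples = {g: df.loc[df[group] == g, value].to_numpy(dtype=float)
               for g in groups}
    for g in groups:
        x = samples[g]
        row = {"row_kind": "group", "group": str(g), "n": x.size}
        if aggregate == "median_minmax":
            row.update(center=float(np.median(x)), spread_lo=float(np.min(x)),
                       spread_hi=float(np.max(x)), aggregate="median_minmax")
        else:
            row.update(center=float(np.mean(x)),
                       sem=float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1
                       else float("nan"),
                       aggregate="mean_sem")
        if one_sample_null is not None:
            if x.size < 2:
                row["note"] = "n=1: test skipped"
            else:
                res = t_test(x, kind="one_sample", tail=one_sample_tail,
                             null_value=one_sample_null)
                row.update(test="one_sample", tail=one_sample_tail,
                           t=res.statistic, df=res.df, p=res.p_value,
                           stars=res.stars)
        rows.append(row)
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            x, y = samples[g1], samples[g2]
            row = {"row_kind": "comparison", "group": f"{g1} vs {g2}",
                   "n": x.size, "n2": y.size}
            if x.size < 2 or y.size < 2:
                row["note"] = "n=1: test skipped"
            else:
                kind = "paired" if paired else "unpaired"
                res = t_test(x, y, kind=kind, tail=pairwise_tail,
                             equal_var=equal_var, labels=(str(g1), str(g2)))
                row.update(test=kind, tail=pairwise_tail, t=res.statistic,
                           df=res.df, p=res.p_value, stars=res.stars,
                           center=res.mean_effect)
            rows.append(row)
    return pd.DataFrame(rows)
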