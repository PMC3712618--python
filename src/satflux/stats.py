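"""Two-group descriptive statistics and unpaired t-tests.

Group results are reported as mean +/- SEM with the percent change of the
treated group relative to control; comparisons use the unpaired t-test,
either with a pooled variance (classic Student) or the Welch-Satterthwaite
variant, one- or two-tailed. The one-tailed p is directed by the sign of
the observed difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

__all__ = ["GroupSummary", "ComparisonResult", "summarize", "percent_change", "t_test"]


@dataclass
class GroupSummary:
    """Mean +/- SEM of one group (SEM = sample sd / sqrt(n); 0 for n = 1)."""

    label: str
    n: int
    mean: float
    sem: float


@dataclass
class ComparisonResult:
    """Unpaired two-group comparison of one variable."""

    variable: str
    control: GroupSummary
    treated: GroupSummary
    percent_change: float
    t_stat: float
    df: float
    p_value: float
    tails: str
    variance_model: str
    flagged: bool = False


def summarize(values, label: str = "") -> GroupSummary:
    """Mean and standard error of the mean of a sample (n >= 1)."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 1:
        raise ValidationError("values: must be nonempty")
    sem = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return GroupSummary(label=label, n=int(x.size), mean=float(np.mean(x)), sem=sem)


def percent_change(control_mean: float, treated_mean: float) -> float:
    """100 * (treated - control) / control."""
    if control_mean == 0:
        raise ValidationError("control_mean: must be nonzero for a percent change")
    return 100.0 * (treated_mean - control_mean) / control_mean


def t_test(
    a,
    b,
    tails: str = "two",
    variance_model: str = "pooled",
    variable: str = "",
    labels: tuple[str, str] = ("control", "treated"),
) -> ComparisonResult:
    """Unpaired t-test of samples ``a`` (control) vs ``b`` (treated).

    ``variance_model`` is "pooled" (Student) or "welch"
    (Welch-Satterthwaite df); ``tails`` is "one" or "two". When the
    hypothesized direction is taken as the observed one, the one-tailed p is
    half the two-tailed p. Two zero-variance samples with equal means are
    reported as p = 1 with ``flagged`` set.
    """
    if tails not in ("one", "two"):
        raise ValidationError("tails: must be 'one' or 'two'")
    if variance_model not in ("pooled", "welch"):
        raise ValidationError("variance_model: must be 'pooled' or 'welch'")
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("samples: each group needs n >= 2")

    ctrl = summarize(x, labels[0])
    trt = summarize(y, labels[1])
    pct = percent_change(ctrl.mean, trt.mean) if ctrl.mean != 0 else np.nan

    flagged = False
    if np.ptp(x) == 0.0 and np.ptp(y) == 0.0:  # exactly constant samples
        # no within-group variability: the test statistic is undefined
        flagged = True
        equal = ctrl.mean == trt.mean
        t_stat = 0.0 if equal else np.inf * np.sign(trt.mean - ctrl.mean)
        p_two = 1.0 if equal else 0.0
        df = float(x.size + y.size - 2)
    else:
        res = sps.ttest_ind(y, x, equal_var=(variance_model == "pooled"))
        t_stat = float(res.statistic)
        p_two = float(res.pvalue)
        df = float(res.df)

    p = p_two / 2.0 if tails == "one" else p_two
    return ComparisonResult(
        variable=variable,
        control=ctrl,
        treated=trt,
        percent_change=float(pct),
        t_stat=float(t_stat),
        df=df,
        p_value=float(p),
        tails=tails,
        variance_model=variance_model,
        flagged=flagged,
    )
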