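"""Between-device agreement statistics for a paired cohort.

For each motor or HR parameter measured by two devices on the same
subjects, this module computes:

* the intraclass correlation coefficient, default ICC(2,1) — two-way
  random effects, absolute agreement, single measures — with ICC(3,1)
  (consistency) available;
* the squared Pearson correlation with its two-sided p-value;
* a paired t-test on the device differences;
* Bland-Altman mean difference and 95% limits of agreement
  (mean +/- 1.96 x sample SD of the differences).

Differences are taken watch minus reference throughout.  No
multiple-testing correction is applied (alpha = 0.05 per comparison).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PairedMeasurements",
    "AgreementResult",
    "icc",
    "pearson_r2",
    "paired_ttest",
    "bland_altman",
    "agreement_result",
    "agreement_report",
    "REPORT_COLUMNS",
]


@dataclass
class PairedMeasurements:
    """One parameter measured by two devices on the same subjects.

    ``value_a`` is the reference device, ``value_b`` the watch."""

    subject_id: list[str]
    value_a: np.ndarray
    value_b: np.ndarray
    parameter_name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.value_a = np.asarray(self.value_a, dtype=float)
        self.value_b = np.asarray(self.value_b, dtype=float)
        if not (len(self.subject_id) == len(self.value_a) == len(self.value_b)):
            raise ValueError("subject ids and both value arrays must align")
        if len(self.value_a) < 2:
            raise ValueError("need at least 2 pairs")
        if not (np.all(np.isfinite(self.value_a)) and np.all(np.isfinite(self.value_b))):
            raise ValueError("values must be finite")

    @property
    def n(self) -> int:
        return len(self.value_a)

    @property
    def differences(self) -> np.ndarray:
        """Watch minus reference."""
        return self.value_b - self.value_a


@dataclass
class AgreementResult:
    parameter: str
    n: int
    icc: float
    icc_form: str
    r2: float
    corr_p: float
    ttest_p: float
    mean_diff: float
    loa_low: float
    loa_high: float
    mean_a: float = np.nan
    sd_a: float = np.nan
    mean_b: float = np.nan
    sd_b: float = np.nan
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not np.isnan(self.r2) and not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("r2 must lie in [0, 1]")
        if self.icc > 1.0 + 1e-12:
            raise ValueError("ICC cannot exceed 1")
        if not (self.loa_low <= self.mean_diff <= self.loa_high):
            raise ValueError("limits of agreement must bracket the mean difference")


def _mean_squares(pairs: PairedMeasurements):
    """Two-way ANOVA mean squares for an n x 2 subjects-by-devices table."""
    data = np.column_stack([pairs.value_a, pairs.value_b])
    n, k = data.shape
    gm = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - gm) ** 2)
    ssc = n * np.sum((col_means - gm) ** 2)
    sst = np.sum((data - gm) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc(pairs: PairedMeasurements, form: str = "icc2_1") -> float:
    """Intraclass correlation for two devices.

    ``icc2_1``: two-way random effects, absolute agreement, single
    measures — ``(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))``.
    ``icc3_1``: two-way mixed, consistency —
    ``(MSR - MSE) / (MSR + (k-1) MSE)``.

    With zero between-subject variance the value is returned as computed
    (possibly <= 0) with a warning.
    """
    if pairs.n < 3:
        raise ValueError("ICC needs at least 3 pairs")
    msr, msc, mse, n, k = _mean_squares(pairs)
    denom_common = msr + (k - 1) * mse
    if form == "icc2_1":
        denom = denom_common + (k / n) * (msc - mse)
    elif form == "icc3_1":
        denom = denom_common
    else:
        raise ValueError("form must be 'icc2_1' or 'icc3_1'")
    if denom == 0:
        warnings.warn("degenerate table: zero total variance; ICC set to 1",
                      stacklevel=2)
        return 1.0
    value = (msr - mse) / denom
    if msr <= mse:
        warnings.warn("no between-subject variance excess; ICC <= 0",
                      stacklevel=2)
    return float(value)


def pearson_r2(pairs: PairedMeasurements) -> tuple[float, float]:
    """Squared Pearson correlation and its two-sided p-value (t with n-2 df)."""
    if pairs.n < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if pairs.value_a.std() == 0 or pairs.value_b.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(pairs.value_a, pairs.value_b)
    return float(res.statistic**2), float(res.pvalue)


def paired_ttest(pairs: PairedMeasurements) -> float:
    """Two-sided paired t-test p-value on watch minus reference.

    Degenerate conventions: identical devices (all differences zero) return
    p = 1; a constant non-zero difference returns the smallest positive
    float.  Both are flagged with a warning.
    """
    d = pairs.differences
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            warnings.warn("identical devices: zero differences, p = 1 by "
                          "convention", stacklevel=2)
            return 1.0
        warnings.warn("constant non-zero difference: p reported as the "
                      "smallest positive float", stacklevel=2)
        return float(np.finfo(float).tiny)
    return float(stats.ttest_rel(pairs.value_b, pairs.value_a).pvalue)


def bland_altman(pairs: PairedMeasurements) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement
    (mean +/- 1.96 x sample SD of watch-minus-reference differences)."""
    if pairs.n < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    d = pairs.differences
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def agreement_result(pairs: PairedMeasurements, icc_form: str = "icc2_1") -> AgreementResult:
    """All agreement statistics for one parameter."""
    mean_diff, loa_low, loa_high = bland_altman(pairs)
    degenerate = pairs.differences.std(ddof=1) == 0
    try:
        r2, corr_p = pearson_r2(pairs)
    except ValueError:
        r2, corr_p = np.nan, np.nan
        degenerate = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        icc_val = icc(pairs, form=icc_form)
        p = paired_ttest(pairs)
    return AgreementResult(
        parameter=pairs.parameter_name,
        n=pairs.n,
        icc=icc_val,
        icc_form=icc_form,
        r2=r2,
        corr_p=corr_p,
        ttest_p=p,
        mean_diff=mean_diff,
        loa_low=loa_low,
        loa_high=loa_high,
        mean_a=float(pairs.value_a.mean()),
        sd_a=float(pairs.value_a.std(ddof=1)),
        mean_b=float(pairs.value_b.mean()),
        sd_b=float(pairs.value_b.std(ddof=1)),
        degenerate=bool(degenerate),
    )


#: column order of the tidy report (regression-tested)
REPORT_COLUMNS = [
    "parameter",
    "n",
    "mean_reference",
    "sd_reference",
    "mean_watch",
    "sd_watch",
    "icc",
    "icc_form",
    "r2",
    "corr_p",
    "ttest_p",
    "mean_diff",
    "loa_low",
    "loa_high",
    "degenerate",
]


def agreement_report(
    table: pd.DataFrame,
    parameters: list[str] | None = None,
    icc_form: str = "icc2_1",
) -> pd.DataFrame:
    """Agreement statistics for every parameter of a tidy paired table.

    ``table`` has columns ``subject_id, device, parameter, value`` with
    ``device`` in {"reference", "watch"}.  Subjects missing either device
    for a parameter are dropped (count logged).  Returns one row per
    parameter with the :data:`REPORT_COLUMNS` schema, in the order given by
    ``parameters`` (default: order of appearance).
    """
    required = {"subject_id", "device", "parameter", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if parameters is None:
        parameters = list(pd.unique(table["parameter"]))
    rows = []
    for param in parameters:
        sub = table[table["parameter"] == param]
        wide = sub.pivot_table(index="subject_id", columns="device",
                               values="value", aggfunc="mean")
        if not {"reference", "watch"}.issubset(wide.columns):
            raise ValueError(f"parameter '{param}' lacks one device side")
        complete = wide.dropna(subset=["reference", "watch"])
        dropped = len(wide) - len(complete)
        if dropped:
            logger.info("parameter %s: dropped %d subjects missing one side",
                        param, dropped)
        pairs = PairedMeasurements(
            subject_id=list(complete.index),
            value_a=complete["reference"].to_numpy(),
            value_b=complete["watch"].to_numpy(),
            parameter_name=param,
        )
        r = agreement_result(pairs, icc_form=icc_form)
        rows.append(
            {
                "parameter": r.parameter,
                "n": r.n,
                "mean_reference": r.mean_a,
                "sd_reference": r.sd_a,
                "mean_watch": r.mean_b,
                "sd_watch": r.sd_b,
                "icc": r.icc,
                "icc_form": r.icc_form,
                "r2": r.r2,
                "corr_p": r.corr_p,
                "ttest_p": r.ttest_p,
                "mean_diff": r.mean_diff,
                "loa_low": r.loa_low,
                "loa_high": r.loa_high,
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
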