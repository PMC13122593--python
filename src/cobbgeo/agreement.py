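"""Reader-agreement and error statistics for angle measurements.

Implements the evaluation machinery used to compare an automatic Cobb
measurement against an expert consensus: the three-reader consensus
rule, MAE / MdAE / RMSE error metrics, the intraclass correlation
coefficient ICC(2,1) (two-way random effects, absolute agreement,
single measurement), Bland-Altman limits of agreement, and
severity-stratified summary tables.

Conventions (surfaced in output metadata):

* ICC form is ICC(2,1) via the ANOVA mean-squares formulation.
* Bland-Altman uses the sample (n-1) standard deviation and the fixed
  1.96 multiplier for the 95% limits of agreement.
* Consensus cases whose readings spread more than the tolerance are
  flagged for adjudication, never guessed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AgreementInputError
from .geometry import Severity, classify_severity

__all__ = [
    "ReadingSet",
    "AgreementResult",
    "consensus_reference",
    "error_metrics",
    "icc_agreement",
    "bland_altman",
    "agreement_result",
    "stratified_report",
]

NEEDS_ADJUDICATION = "NEEDS_ADJUDICATION"


@dataclass
class ReadingSet:
    """Per-case angle readings: cases x raters, degrees."""

    values: np.ndarray
    case_ids: list[str]
    rater_ids: list[str]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise AgreementInputError("readings must be a 2-D cases x raters matrix")
        n, k = self.values.shape
        if len(self.case_ids) != n or len(self.rater_ids) != k:
            raise AgreementInputError("id lists must match matrix shape")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, case_col: str = "case_id") -> "ReadingSet":
        """Build from a table with a case-id column and one column per rater.

        Cases with any missing reading are excluded with a warning.
        """
        raters = [c for c in df.columns if c != case_col]
        warnings = []
        mask = df[raters].notna().all(axis=1)
        if not mask.all():
            dropped = df.loc[~mask, case_col].astype(str).tolist()
            warnings.append(f"excluded cases with missing readings: {dropped}")
        kept = df.loc[mask]
        return cls(
            values=kept[raters].to_numpy(dtype=float),
            case_ids=kept[case_col].astype(str).tolist(),
            rater_ids=list(raters),
            warnings=warnings,
        )

    @classmethod
    def from_csv(cls, path: str | Path, case_col: str = "case_id") -> "ReadingSet":
        return cls.from_dataframe(pd.read_csv(path), case_col=case_col)


@dataclass
class AgreementResult:
    """Error and agreement summary of one prediction-vs-reference set."""

    mae: float
    mdae: float
    rmse: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    icc: float
    n_cases: int
    icc_form: str = "ICC(2,1) two-way random, absolute agreement, single measurement"
    sd_convention: str = "sample (n-1)"

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "mae_deg": self.mae,
            "mdae_deg": self.mdae,
            "rmse_deg": self.rmse,
            "bias_deg": self.bias,
            "sd_diff_deg": self.sd_diff,
            "loa_low_deg": self.loa_low,
            "loa_high_deg": self.loa_high,
            "icc": self.icc,
            "icc_form": self.icc_form,
            "sd_convention": self.sd_convention,
        }


def consensus_reference(
    readings: ReadingSet, tolerance: float = 3.0
) -> pd.DataFrame:
    """Three-reader consensus: mean when the spread is within tolerance.

    Per case: when the maximum pairwise difference among the three
    readings is <= ``tolerance`` degrees the consensus is their
    arithmetic mean; otherwise the case is flagged
    ``NEEDS_ADJUDICATION`` with no value (joint re-reading happens
    outside this package).  Requires exactly three raters.
    """
    if readings.values.shape[1] != 3:
        raise AgreementInputError("consensus protocol requires exactly 3 raters")
    if not tolerance > 0:
        raise AgreementInputError("tolerance must be positive")
    spread = readings.values.max(axis=1) - readings.values.min(axis=1)
    ok = spread <= tolerance
    consensus = np.where(ok, readings.values.mean(axis=1), np.nan)
    return pd.DataFrame(
        {
            "case_id": readings.case_ids,
            "consensus": consensus,
            "flag": np.where(ok, "", NEEDS_ADJUDICATION),
        }
    )


def error_metrics(
    pred: Sequence[float], ref: Sequence[float]
) -> tuple[float, float, float]:
    """(MAE, MdAE, RMSE) of pred against ref, degrees."""
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape or p.ndim != 1 or p.size < 1:
        raise AgreementInputError("pred and ref must be equal-length 1-D, size >= 1")
    err = np.abs(p - r)
    return (
        float(err.mean()),
        float(np.median(err)),
        float(np.sqrt(np.mean(err**2))),
    )


def icc_agreement(readings: ReadingSet | np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rating.

    Mean-squares formulation over an n x k complete matrix::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    where MSR, MSC, MSE are the rows (cases), columns (raters) and
    residual mean squares of the two-way ANOVA without replication.
    """
    x = readings.values if isinstance(readings, ReadingSet) else np.asarray(readings, float)
    if x.ndim != 2:
        raise AgreementInputError("readings must be 2-D")
    n, k = x.shape
    if k < 2 or n < 3:
        raise AgreementInputError("need >= 2 raters and >= 3 cases for ICC")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if msr <= 0 and ssr == 0:
        raise AgreementInputError("zero between-case variance: ICC undefined")
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise AgreementInputError("degenerate readings: ICC undefined")
    return float((msr - mse) / denom)


def bland_altman(
    pred: Sequence[float], ref: Sequence[float]
) -> tuple[float, float, float, float]:
    """(bias, sd_diff, loa_low, loa_high) of pred - ref differences.

    Bias is the mean difference, sd_diff the sample (n-1) standard
    deviation, and the 95% limits of agreement are bias +/- 1.96*sd.
    """
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape or p.ndim != 1 or p.size < 2:
        raise AgreementInputError("pred and ref must be equal-length 1-D, size >= 2")
    d = p - r
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def agreement_result(pred: Sequence[float], ref: Sequence[float]) -> AgreementResult:
    """Full error + agreement summary of a pred-vs-ref pair of columns."""
    mae, mdae, rmse = error_metrics(pred, ref)
    p = np.asarray(pred, float)
    r = np.asarray(ref, float)
    if p.size >= 2:
        bias, sd, lo, hi = bland_altman(p, r)
    else:
        bias, sd, lo, hi = float(p[0] - r[0]), math.nan, math.nan, math.nan
    try:
        icc = icc_agreement(np.column_stack([p, r]))
    except AgreementInputError:
        icc = math.nan
    return AgreementResult(
        mae=mae, mdae=mdae, rmse=rmse, bias=bias, sd_diff=sd,
        loa_low=lo, loa_high=hi, icc=icc, n_cases=int(p.size),
    )


def stratified_report(
    pred: Sequence[float], ref: Sequence[float]
) -> dict[str, AgreementResult]:
    """Per-severity-stratum agreement summary plus the overall row.

    Strata are derived from the reference values via the clinical
    mapping (<=10 sub-threshold, <20 mild, 20-35 moderate, >35 severe);
    empty strata are omitted.
    """
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise AgreementInputError("pred and ref must be equal-length 1-D")
    strata = np.array([classify_severity(v).value for v in r])
    out: dict[str, AgreementResult] = {}
    for sev in Severity:
        mask = strata == sev.value
        if mask.any():
            out[sev.value] = agreement_result(p[mask], r[mask])
    out["overall"] = agreement_result(p, r)
    return out
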