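"""Prediction-score vs clinical-covariate correlation analysis.

The two tau species in CSF are tightly linearly related, which licenses a
regression imputation: fit p-tau on t-tau over the complete cases, fill a
record missing exactly one tau from the fitted line (inverting it when
t-tau is the missing one), and exclude records missing both.  The
diagnostic vote score is then correlated pairwise (Pearson by default)
against the biomarker and cognitive covariates over the records complete
for each pair.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .spectra_io import ClinicalRecord

__all__ = [
    "RegressionFit",
    "CorrelationMatrix",
    "fit_linear",
    "impute_tau",
    "correlation_matrix",
    "records_to_frame",
    "ImputationError",
]

#: Default variable order of the correlation matrix.
MATRIX_VARIABLES = (
    "score", "abeta42", "t_tau", "p_tau", "mmse", "cdr_sum", "cdr_glob", "age", "sex",
)


class ImputationError(ValueError):
    """Raised when the tau relation cannot be fitted for imputation."""


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least squares fit y = slope*x + intercept with Pearson r."""

    slope: float
    intercept: float
    r: float
    n: int

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept

    def invert(self, y: float) -> float:
        if self.slope == 0:
            raise ZeroDivisionError("cannot invert a zero-slope fit")
        return (y - self.intercept) / self.slope


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise correlations with per-pair sample counts.

    Entries are NaN where a variable has zero variance or fewer than three
    complete pairs exist — flagged, never silently dropped.
    """

    variables: tuple[str, ...]
    r: np.ndarray
    n_pairwise: np.ndarray

    def lookup(self, a: str, b: str) -> float:
        i, j = self.variables.index(a), self.variables.index(b)
        return float(self.r[i, j])


def fit_linear(x, y) -> RegressionFit:
    """OLS of y on x over complete (finite) pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need at least 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return RegressionFit(float(res.slope), float(res.intercept), float(res.rvalue), int(x.size))


def impute_tau(records: list[ClinicalRecord], refit_inverse: bool = False):
    """Regression imputation of the tau biomarkers.

    Fits p-tau on t-tau over complete cases; records missing exactly one tau
    are filled from that relation (a missing t-tau by inverting the line, or
    with ``refit_inverse`` by a separate t-on-p fit); records missing both
    taus cannot be recovered and are excluded.

    Returns ``(imputed_records, imputed_flags, excluded_ids, fit)`` where
    ``imputed_flags`` maps sample_id to the field that was filled.
    """
    complete = [r for r in records if r.t_tau is not None and r.p_tau is not None]
    if len(complete) < 3:
        raise ImputationError(
            f"need >=3 records with both taus, got {len(complete)}"
        )
    fit = fit_linear([r.t_tau for r in complete], [r.p_tau for r in complete])
    inv_fit = (
        fit_linear([r.p_tau for r in complete], [r.t_tau for r in complete])
        if refit_inverse
        else None
    )
    out: list[ClinicalRecord] = []
    flags: dict[str, str] = {}
    excluded: list[str] = []
    for r in records:
        has_t, has_p = r.t_tau is not None, r.p_tau is not None
        if has_t and has_p:
            out.append(r)
        elif has_t:
            out.append(replace(r, p_tau=fit.predict(r.t_tau)))
            flags[r.sample_id] = "p_tau"
        elif has_p:
            t = inv_fit.predict(r.p_tau) if inv_fit else fit.invert(r.p_tau)
            out.append(replace(r, t_tau=t))
            flags[r.sample_id] = "t_tau"
        else:
            excluded.append(r.sample_id)
    return out, flags, excluded, fit


def records_to_frame(
    records: list[ClinicalRecord], scores: dict[str, float] | None = None
) -> pd.DataFrame:
    """Tabulate records (and optional per-sample vote scores) for the
    correlation matrix.  Sex is coded F=0, M=1, unknown missing."""
    sex_code = {"F": 0.0, "M": 1.0}
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "score": None if scores is None else scores.get(r.sample_id),
                "abeta42": r.abeta42,
                "t_tau": r.t_tau,
                "p_tau": r.p_tau,
                "mmse": r.mmse,
                "cdr_sum": r.cdr_sum,
                "cdr_glob": r.cdr_glob,
                "age": r.age,
                "sex": sex_code.get(r.sex),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id").astype(float)


def correlation_matrix(
    frame: pd.DataFrame,
    variables: tuple[str, ...] | None = None,
    method: str = "pearson",
) -> CorrelationMatrix:
    """Pairwise-complete correlation matrix over the given variables.

    ``method`` is ``"pearson"`` (default) or ``"spearman"``.  Pairs with
    fewer than three complete records, or a zero-variance variable, get NaN.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be pearson or spearman")
    variables = variables or tuple(v for v in MATRIX_VARIABLES if v in frame.columns)
    sub = frame[list(variables)]
    if len(sub) < 3:
        raise ValueError("need at least 3 records")
    r = sub.corr(method=method, min_periods=3).to_numpy()
    notna = sub.notna().to_numpy().astype(int)
    n_pair = notna.T @ notna
    # zero-variance variables: flag the whole row/column as undefined
    for j, v in enumerate(variables):
        col = sub[v].dropna()
        if len(col) >= 1 and np.ptp(col.to_numpy()) == 0:
            r[j, :] = np.nan
            r[:, j] = np.nan
    np.fill_diagonal(r, np.where(np.isnan(np.diag(r)), np.nan, 1.0))
    return CorrelationMatrix(tuple(variables), r, n_pair)
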