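"""Membrane-proteomics deformability predictor.

RBC deformability correlates with the membrane level of several structural
proteins and with the amount of hemoglobin bound to the inner membrane
surface (indexed by the membrane-bound beta-subunit, HBB).  This module
fits, from per-unit Ln(LFQ) tables,

* single-protein correlations: response ~ [protein], R = |Pearson r|,
* the combined linear predictor: response = a * [protein] + b * [HBB]
  (+ intercept), R = multiple correlation, p from the overall F-test,

and applies a fitted predictor to rank candidate transfusion units against
a recipient.  The response is the unit's median elongation ratio by
default; the mean (AER) is supported via ``response``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import (
    DegenerateFitError,
    EmptyInputError,
    InsufficientDataError,
    MissingColumnError,
)
from .stats import UnitRanking

__all__ = [
    "BiomarkerFit",
    "log_transform",
    "fit_single",
    "fit_combined",
    "evaluate_panel",
    "predict_and_select",
    "read_proteomics_table",
]

# Predictor condition number above which a collinearity warning is raised.
_COLLINEARITY_COND = 1e8


@dataclass(frozen=True)
class BiomarkerFit:
    """A fitted linear deformability predictor."""

    predictors: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    r: float
    p_value: float
    n: int
    response_name: str = "mer"
    has_intercept: bool = True
    notes: str = ""

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Predicted response per row; NaN where a predictor is missing."""
        y = np.full(len(table), self.intercept if self.has_intercept else 0.0)
        for name, coef in zip(self.predictors, self.coefficients):
            if name not in table.columns:
                raise MissingColumnError(f"candidate table lacks predictor {name!r}")
            y = y + coef * table[name].to_numpy(dtype=float)
        return y

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "r": self.r,
            "p_value": self.p_value,
            "n": self.n,
            "response_name": self.response_name,
            "has_intercept": self.has_intercept,
            "notes": self.notes,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def log_transform(lfq) -> np.ndarray | float:
    """Ln(LFQ): natural log of a raw label-free intensity.

    Non-positive intensities are the label-free convention for "not
    quantified": they map to NaN (missing) with a warning, never to a
    pseudo-count, and units carrying them are excluded from fits that use
    that protein.
    """
    arr = np.asarray(lfq, dtype=float)
    out = np.where(arr > 0, np.log(np.where(arr > 0, arr, 1.0)), np.nan)
    n_missing = int(np.count_nonzero(~(arr > 0)))
    if n_missing:
        warnings.warn(
            f"{n_missing} non-positive LFQ intensit{'y' if n_missing == 1 else 'ies'} "
            "treated as missing",
            UserWarning,
            stacklevel=2,
        )
    if np.isscalar(lfq):
        return float(out)
    return out


def _complete_rows(table: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    for c in columns:
        if c not in table.columns:
            raise MissingColumnError(f"table lacks column {c!r}")
    sub = table.loc[:, list(columns)].apply(pd.to_numeric, errors="coerce")
    return sub.dropna()


def fit_single(
    table: pd.DataFrame, protein: str, response: str = "mer"
) -> BiomarkerFit:
    """Least-squares fit of the response on one protein's Ln(LFQ) level.

    R is the absolute Pearson correlation; p its two-sided significance.
    """
    sub = _complete_rows(table, [protein, response])
    if len(sub) < 3:
        raise InsufficientDataError(
            f"single-protein fit needs >= 3 complete units, got {len(sub)}"
        )
    x = sub[protein].to_numpy()
    y = sub[response].to_numpy()
    if np.ptp(x) == 0:
        raise DegenerateFitError(f"predictor {protein!r} has zero variance")
    res = sps.linregress(x, y)
    return BiomarkerFit(
        predictors=(protein,),
        coefficients=(float(res.slope),),
        intercept=float(res.intercept),
        r=abs(float(res.rvalue)),
        p_value=float(res.pvalue),
        n=len(sub),
        response_name=response,
    )


def fit_combined(
    table: pd.DataFrame,
    protein: str,
    hbb: str = "hbb",
    response: str = "mer",
    *,
    include_intercept: bool = True,
) -> BiomarkerFit:
    """Two-predictor least squares: response ~ [protein] + [HBB].

    R is the multiple correlation sqrt(R^2); p the overall F-test.  The
    printed form of the predictor omits an intercept; that variant is
    available with ``include_intercept=False`` (R is then computed on the
    uncentered total sum of squares and is not a Pearson-type quantity).
    """
    sub = _complete_rows(table, [protein, hbb, response])
    if len(sub) < 4:
        raise InsufficientDataError(
            f"combined fit needs >= 4 complete units, got {len(sub)}"
        )
    X = sub[[protein, hbb]].to_numpy()
    y = sub[response].to_numpy()
    if np.ptp(X[:, 0]) == 0 or np.ptp(X[:, 1]) == 0:
        raise DegenerateFitError("a predictor has zero variance")
    notes = ""
    if np.linalg.cond(X - X.mean(axis=0)) > _COLLINEARITY_COND:
        notes = "collinear predictors"
        warnings.warn(
            f"predictors {protein!r} and {hbb!r} are nearly collinear; "
            "coefficients are unstable",
            UserWarning,
            stacklevel=2,
        )
    design = sm.add_constant(X) if include_intercept else X
    res = sm.OLS(y, design).fit()
    if include_intercept:
        intercept, coefs = float(res.params[0]), res.params[1:]
    else:
        intercept, coefs = 0.0, res.params
    r2 = max(float(res.rsquared), 0.0)
    return BiomarkerFit(
        predictors=(protein, hbb),
        coefficients=tuple(float(c) for c in coefs),
        intercept=intercept,
        r=float(np.sqrt(r2)),
        p_value=float(res.f_pvalue),
        n=len(sub),
        response_name=response,
        has_intercept=include_intercept,
        notes=notes,
    )


def evaluate_panel(
    table: pd.DataFrame,
    proteins: Sequence[str],
    hbb: str = "hbb",
    response: str = "mer",
    *,
    sort_by_r: bool = False,
) -> pd.DataFrame:
    """Single and HBB-combined correlations for a protein panel.

    One row per single protein (HBB included if in the panel) followed by
    one row per HBB + protein pair, i.e. the structure of a published
    correlation table.  Columns: predictor, kind, r, p_value, n,
    coefficients, intercept.
    """
    proteins = list(proteins)
    if not proteins:
        raise EmptyInputError("empty protein panel")
    rows = []
    for p in proteins:
        f = fit_single(table, p, response)
        rows.append({
            "predictor": p, "kind": "single", "r": f.r, "p_value": f.p_value,
            "n": f.n, "coefficients": list(f.coefficients),
            "intercept": f.intercept,
        })
    for p in proteins:
        if p == hbb:
            continue
        f = fit_combined(table, p, hbb, response)
        rows.append({
            "predictor": f"{hbb}+{p}", "kind": "combined", "r": f.r,
            "p_value": f.p_value, "n": f.n,
            "coefficients": list(f.coefficients), "intercept": f.intercept,
        })
    df = pd.DataFrame(rows)
    if sort_by_r:
        df = df.sort_values("r", ascending=False, ignore_index=True)
    return df


def predict_and_select(
    fit: BiomarkerFit,
    candidate_units: pd.DataFrame,
    recipient_response: float,
    tolerance: float = 0.01,
    unit_id_column: str = "unit_id",
) -> tuple[list[UnitRanking], list[str], list[str]]:
    """Rank candidate units by their *predicted* deformability.

    Each unit's response is predicted from its Ln(LFQ) levels and compared
    with the recipient's measured response under the same better-than /
    at-least-equal semantics as direct MER ranking.  Units with a missing
    predictor are returned in the third element (unrankable) rather than
    ranked.  Returns (rankings, selected_unit_ids, unrankable_unit_ids).
    """
    from .core import DeformabilityProfile  # lightweight carrier for ranking
    from .stats import rank_units

    preds = fit.predict(candidate_units)
    ids = candidate_units[unit_id_column].astype(str).tolist()
    unrankable = [uid for uid, p in zip(ids, preds) if not np.isfinite(p)]
    rankable = [
        (uid, DeformabilityProfile(
            mer=float(p), aer=float(p), pct_udfc=0.0, pct_ldfc=0.0,
            pct_mid=0.0, pct_hdfc=0.0, n_cells=0, sample_id=uid,
        ))
        for uid, p in zip(ids, preds) if np.isfinite(p)
    ]
    if not rankable:
        raise EmptyInputError("no candidate unit has all predictors")
    recipient = DeformabilityProfile(
        mer=float(recipient_response), aer=float(recipient_response),
        pct_udfc=0.0, pct_ldfc=0.0, pct_mid=0.0, pct_hdfc=0.0, n_cells=0,
        sample_id="recipient",
    )
    rankings, selected = rank_units(rankable, recipient, tolerance)
    return rankings, selected, unrankable


def read_proteomics_table(path) -> pd.DataFrame:
    """Read a wide per-unit proteomics CSV (unit_id + Ln(LFQ) columns)."""
    df = pd.read_csv(path)
    if "unit_id" not in df.columns:
        raise MissingColumnError("proteomics table needs a unit_id column")
    return df
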