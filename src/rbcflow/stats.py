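"""Population-level statistics: normality screening, two-group comparison
of deformability parameters, and donor-unit vs recipient ranking."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DeformabilityProfile
from .errors import EmptyInputError, InsufficientDataError, InvariantViolationError

__all__ = [
    "GroupComparison",
    "UnitRanking",
    "PROFILE_PARAMETERS",
    "normality_check",
    "compare_groups",
    "rank_units",
    "comparison_table",
]

#: Deformability parameters a profile exposes for group comparison.
PROFILE_PARAMETERS = ("mer", "aer", "pct_hdfc", "pct_ldfc", "pct_udfc")

# Above this group size the t-test is considered robust to non-normality,
# so no warning is raised for a non-normal group.
_NORMALITY_N = 30


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample comparison of one deformability parameter across units."""

    parameter: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_stat: float
    p_value: float
    min_a: float
    max_a: float
    min_b: float
    max_b: float
    normality_p_a: float | None
    normality_p_b: float | None
    test: str = "student"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class UnitRanking:
    """Verdict of one donor unit against the intended recipient."""

    unit_id: str
    unit_mer: float
    recipient_mer: float
    verdict: Literal["higher", "equal_within_tol", "lower"]
    tolerance: float
    selected: bool = False


def normality_check(values: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk normality test; returns (W, p).

    p < 0.05 flags a non-normal distribution.  Requires n >= 3 and a
    non-constant sample.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise InsufficientDataError(f"normality test needs n >= 3, got {v.size}")
    if np.ptp(v) == 0:
        raise InsufficientDataError("constant sample: normality is undefined")
    with warnings.catch_warnings():
        # scipy warns for n > 5000; the p-value is still usable for screening
        warnings.simplefilter("ignore")
        w, p = sps.shapiro(v)
    return float(w), float(p)


def _parameter_values(profiles: Sequence[DeformabilityProfile], parameter: str) -> np.ndarray:
    if parameter not in PROFILE_PARAMETERS:
        raise InvariantViolationError(
            f"unknown parameter {parameter!r}; choose from {PROFILE_PARAMETERS}"
        )
    return np.array([getattr(p, parameter) for p in profiles], dtype=float)


def compare_groups(
    profiles_a: Sequence[DeformabilityProfile],
    profiles_b: Sequence[DeformabilityProfile],
    parameter: str = "mer",
    *,
    welch: bool = False,
) -> GroupComparison:
    """Compare one deformability parameter between two groups of units.

    Unit-level values are compared with a two-sample t-test — pooled-
    variance Student by default, Welch with ``welch=True``.  Each group is
    screened with Shapiro-Wilk; a warning is raised when a group looks
    non-normal and is too small (n < 30) for the t-test to be robust.
    """
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise InsufficientDataError("each group needs >= 2 units")
    a = _parameter_values(profiles_a, parameter)
    b = _parameter_values(profiles_b, parameter)
    t, p = sps.ttest_ind(a, b, equal_var=not welch)

    def _norm_p(v: np.ndarray) -> float | None:
        try:
            return normality_check(v)[1]
        except InsufficientDataError:
            return None

    np_a, np_b = _norm_p(a), _norm_p(b)
    for label, v, pn in (("A", a, np_a), ("B", b, np_b)):
        if pn is not None and pn < 0.05 and v.size < _NORMALITY_N:
            warnings.warn(
                f"group {label} ({parameter}) looks non-normal (Shapiro-Wilk "
                f"p={pn:.3g}) and n={v.size} < {_NORMALITY_N}: t-test may be "
                "unreliable",
                UserWarning,
                stacklevel=2,
            )
    return GroupComparison(
        parameter=parameter,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=int(a.size),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=int(b.size),
        t_stat=float(t), p_value=float(p),
        min_a=float(a.min()), max_a=float(a.max()),
        min_b=float(b.min()), max_b=float(b.max()),
        normality_p_a=np_a, normality_p_b=np_b,
        test="welch" if welch else "student",
    )


def comparison_table(
    profiles_a: Sequence[DeformabilityProfile],
    profiles_b: Sequence[DeformabilityProfile],
    parameters: Sequence[str] = PROFILE_PARAMETERS,
    *,
    welch: bool = False,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """All-parameter group comparison as one tidy table (one row per
    parameter: means +/- SD, extremes, t, p).  ``bonferroni`` multiplies
    p-values by the number of parameters (off by default; raw per-parameter
    p-values are the convention here)."""
    rows = [compare_groups(profiles_a, profiles_b, p, welch=welch).to_dict()
            for p in parameters]
    df = pd.DataFrame(rows)
    if bonferroni:
        df["p_value"] = np.minimum(df["p_value"] * len(parameters), 1.0)
    return df


def rank_units(
    units: Sequence[tuple[str, DeformabilityProfile]],
    recipient: DeformabilityProfile,
    tolerance: float = 0.01,
    *,
    udfc_tiebreak: bool = False,
) -> tuple[list[UnitRanking], list[str]]:
    """Classify donor units against a recipient by MER and select the best.

    Each unit is ``higher`` / ``equal_within_tol`` / ``lower`` according to
    the sign of (unit MER - recipient MER) against ``tolerance``.  Selection
    follows "better than, or at least equal to, the recipient": all
    ``higher`` units if any, else all ``equal_within_tol`` units, else the
    maximal-MER unit with a warning.  With ``udfc_tiebreak`` the selection
    is ordered by %UDFC ascending (lower is better) before MER descending.
    """
    if len(units) == 0:
        raise EmptyInputError("no units to rank")
    if tolerance < 0:
        raise InvariantViolationError(f"tolerance must be >= 0, got {tolerance}")
    rankings: list[UnitRanking] = []
    for uid, prof in units:
        diff = prof.mer - recipient.mer
        if diff > tolerance:
            verdict = "higher"
        elif diff < -tolerance:
            verdict = "lower"
        else:
            verdict = "equal_within_tol"
        rankings.append(UnitRanking(
            unit_id=uid, unit_mer=prof.mer, recipient_mer=recipient.mer,
            verdict=verdict, tolerance=tolerance,
        ))
    by_id = {uid: prof for uid, prof in units}
    higher = [r for r in rankings if r.verdict == "higher"]
    equal = [r for r in rankings if r.verdict == "equal_within_tol"]
    if higher:
        chosen = higher
    elif equal:
        chosen = equal
    else:
        best = max(rankings, key=lambda r: r.unit_mer)
        warnings.warn(
            f"no unit reaches the recipient's MER ({recipient.mer:.3f}); "
            f"falling back to the maximal-MER unit {best.unit_id} "
            f"({best.unit_mer:.3f})",
            UserWarning,
            stacklevel=2,
        )
        chosen = [best]

    def _sort_key(r: UnitRanking):
        if udfc_tiebreak:
            return (by_id[r.unit_id].pct_udfc, -r.unit_mer)
        return (-r.unit_mer,)

    selected_ids = [r.unit_id for r in sorted(chosen, key=_sort_key)]
    rankings = [
        UnitRanking(**{**r.__dict__, "selected": r.unit_id in selected_ids})
        for r in rankings
    ]
    return rankings, selected_ids
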