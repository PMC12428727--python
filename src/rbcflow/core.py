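"""Elongation-ratio distribution statistics for RBC deformability profiling.

A cell sheared in a flow chamber elongates from a disc into an ellipse; its
elongation ratio ER = A/B (major over minor axis) is 1 for an undeformed,
rigid cell and grows with deformability.  A specimen is characterised by the
ER distribution of its cell population, summarised by:

* **MER** — median elongation ratio,
* **AER** — average (mean) elongation ratio,
* **%UDFC** — undeformable cells, ER < 1.1,
* **%LDFC** — low-deformable cells, 1.1 <= ER < 1.3,
* **%HDFC** — highly deformable cells, ER >= 2.5,

plus the unnamed middle band (1.3 <= ER < 2.5), reported here as ``pct_mid``
so the four bands partition the population exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConventionViolationError,
    EmptyInputError,
    InvalidMeasurementError,
    InvariantViolationError,
)

__all__ = [
    "ERSample",
    "ThresholdScheme",
    "DeformabilityProfile",
    "ERDistributionCurve",
    "elongation_ratio",
    "compute_profile",
    "distribution_curve",
    "aggregate_fields",
    "read_cell_table",
    "write_cell_table",
    "CELL_TABLE_COLUMNS",
]

#: Canonical CSV dialect for per-cell measurement tables.
CELL_TABLE_COLUMNS = [
    "sample_id",
    "field_id",
    "cell_id",
    "major_um",
    "minor_um",
    "er",
    "qc_pass",
]

# Protocol targets for a specimen-level measurement: total cells counted and
# number of microscopy fields imaged. Advisory — deviations warn, never fail.
CELL_COUNT_RANGE = (10_000, 15_000)
FIELD_COUNT_RANGE = (25, 35)


@dataclass(frozen=True)
class ThresholdScheme:
    """ER cut-points defining the deformability sub-populations.

    ``boundary_convention`` controls edge membership:

    * ``disjoint_bins`` (default): half-open bands UDFC [1, 1.1),
      LDFC [1.1, 1.3), MID [1.3, 2.5), HDFC [2.5, inf).
    * ``cumulative``: upper edges closed, matching cumulative-curve
      read-offs — UDFC [1, 1.1], LDFC (1.1, 1.3], MID (1.3, 2.5), HDFC
      [2.5, inf).  Still a partition; only boundary membership differs.
    """

    udfc_upper: float = 1.1
    ldfc_upper: float = 1.3
    hdfc_lower: float = 2.5
    boundary_convention: Literal["disjoint_bins", "cumulative"] = "disjoint_bins"

    def __post_init__(self) -> None:
        if not (1.0 < self.udfc_upper < self.ldfc_upper < self.hdfc_lower):
            raise InvariantViolationError(
                "thresholds must satisfy 1.0 < udfc_upper < ldfc_upper < hdfc_lower, "
                f"got {self.udfc_upper}, {self.ldfc_upper}, {self.hdfc_lower}"
            )
        if self.boundary_convention not in ("disjoint_bins", "cumulative"):
            raise InvariantViolationError(
                f"unknown boundary convention {self.boundary_convention!r}"
            )

    def to_dict(self) -> dict:
        return {
            "udfc_upper": self.udfc_upper,
            "ldfc_upper": self.ldfc_upper,
            "hdfc_lower": self.hdfc_lower,
            "boundary_convention": self.boundary_convention,
        }


@dataclass
class ERSample:
    """A specimen's per-cell elongation ratios.

    values are dimensionless, every value >= 1 by the major/minor
    convention.  ``n_fields`` is the number of microscopy fields the cells
    came from (None when unknown, e.g. a bare CSV of ratios).
    """

    values: np.ndarray
    sample_id: str = "sample"
    n_fields: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    def validate(self, require_nonempty: bool = True) -> None:
        if require_nonempty and self.values.size == 0:
            raise EmptyInputError(f"sample {self.sample_id!r} has no ER values")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise InvariantViolationError(
                f"sample {self.sample_id!r} contains non-finite ER values"
            )
        if self.values.size and np.any(self.values < 1.0):
            raise InvariantViolationError(
                f"sample {self.sample_id!r} contains ER < 1 "
                f"(min {self.values.min():.4f}); axes must be sorted major >= minor"
            )

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class DeformabilityProfile:
    """Summary deformability parameters of one cell population."""

    mer: float
    aer: float
    pct_udfc: float
    pct_ldfc: float
    pct_mid: float
    pct_hdfc: float
    n_cells: int
    thresholds: ThresholdScheme = field(default_factory=ThresholdScheme)
    n_fields: int | None = None
    sample_id: str = "sample"

    def to_dict(self) -> dict:
        return {
            "mer": self.mer,
            "aer": self.aer,
            "pct_hdfc": self.pct_hdfc,
            "pct_ldfc": self.pct_ldfc,
            "pct_udfc": self.pct_udfc,
            "pct_mid": self.pct_mid,
            "n_cells": self.n_cells,
            "n_fields": self.n_fields,
            "thresholds": self.thresholds.to_dict(),
            "boundary_convention": self.thresholds.boundary_convention,
            "sample_id": self.sample_id,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "DeformabilityProfile":
        thr = d.get("thresholds", {})
        return cls(
            mer=d["mer"],
            aer=d["aer"],
            pct_udfc=d["pct_udfc"],
            pct_ldfc=d["pct_ldfc"],
            pct_mid=d["pct_mid"],
            pct_hdfc=d["pct_hdfc"],
            n_cells=d["n_cells"],
            thresholds=ThresholdScheme(
                udfc_upper=thr.get("udfc_upper", 1.1),
                ldfc_upper=thr.get("ldfc_upper", 1.3),
                hdfc_lower=thr.get("hdfc_lower", 2.5),
                boundary_convention=thr.get("boundary_convention", "disjoint_bins"),
            ),
            n_fields=d.get("n_fields"),
            sample_id=d.get("sample_id", "sample"),
        )

    @classmethod
    def from_json(cls, path) -> "DeformabilityProfile":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ERDistributionCurve:
    """Histogram and cumulative distribution of a specimen's ER values."""

    bin_edges: np.ndarray
    density: np.ndarray  # fraction of cells per bin; sums to 1
    cumulative: np.ndarray  # running sum, ends at 1

    def median_from_curve(self) -> float:
        """Median ER read off the cumulative curve by linear interpolation.

        This mimics deriving MER graphically from the cumulative
        distribution; it agrees with the raw-sample median to within one
        bin width.
        """
        edges = self.bin_edges
        cum = np.concatenate([[0.0], self.cumulative])
        idx = int(np.searchsorted(cum, 0.5))
        idx = min(max(idx, 1), len(cum) - 1)
        c0, c1 = cum[idx - 1], cum[idx]
        if c1 == c0:
            return float(edges[idx])
        frac = (0.5 - c0) / (c1 - c0)
        return float(edges[idx - 1] + frac * (edges[idx] - edges[idx - 1]))


def elongation_ratio(major_axis: float, minor_axis: float) -> float:
    """ER = A/B for one cell; exactly 1.0 for an undeformed (round) cell.

    Raises
    ------
    InvalidMeasurementError
        if either axis is non-positive or non-finite.
    ConventionViolationError
        if major < minor; the caller must sort the axes.
    """
    major_axis = float(major_axis)
    minor_axis = float(minor_axis)
    if not (np.isfinite(major_axis) and np.isfinite(minor_axis)):
        raise InvalidMeasurementError("axes must be finite")
    if minor_axis <= 0 or major_axis <= 0:
        raise InvalidMeasurementError(
            f"axes must be positive, got A={major_axis}, B={minor_axis}"
        )
    if major_axis < minor_axis:
        raise ConventionViolationError(
            f"major axis ({major_axis}) < minor axis ({minor_axis}); sort axes first"
        )
    if major_axis == minor_axis:
        return 1.0
    return major_axis / minor_axis


def _band_counts(values: np.ndarray, scheme: ThresholdScheme) -> tuple[int, int, int, int]:
    """Counts in (UDFC, LDFC, MID, HDFC) under the scheme's convention."""
    u, l, h = scheme.udfc_upper, scheme.ldfc_upper, scheme.hdfc_lower
    if scheme.boundary_convention == "disjoint_bins":
        udfc = int(np.count_nonzero(values < u))
        ldfc = int(np.count_nonzero((values >= u) & (values < l)))
        hdfc = int(np.count_nonzero(values >= h))
    else:  # cumulative: upper edges closed
        udfc = int(np.count_nonzero(values <= u))
        ldfc = int(np.count_nonzero((values > u) & (values <= l)))
        hdfc = int(np.count_nonzero(values >= h))
    mid = int(values.size) - udfc - ldfc - hdfc
    return udfc, ldfc, mid, hdfc


def compute_profile(
    sample: ERSample, scheme: ThresholdScheme | None = None
) -> DeformabilityProfile:
    """Summarise an ER sample into its deformability profile.

    MER is the empirical median (midpoint of the two central order
    statistics for even n), AER the arithmetic mean, and the four band
    percentages are direct counts under ``scheme``'s boundary convention;
    under ``disjoint_bins`` they always sum to exactly 100.
    """
    if scheme is None:
        scheme = ThresholdScheme()
    sample.validate()
    v = sample.values
    udfc, ldfc, mid, hdfc = _band_counts(v, scheme)
    n = v.size
    return DeformabilityProfile(
        mer=float(np.median(v)),
        aer=float(np.mean(v)),
        pct_udfc=100.0 * udfc / n,
        pct_ldfc=100.0 * ldfc / n,
        pct_mid=100.0 * mid / n,
        pct_hdfc=100.0 * hdfc / n,
        n_cells=n,
        thresholds=scheme,
        n_fields=sample.n_fields,
        sample_id=sample.sample_id,
    )


def distribution_curve(sample: ERSample, bin_width: float = 0.05) -> ERDistributionCurve:
    """Histogram + cumulative ER distribution with the given bin width.

    Bins cover [1, max(values)] in steps of ``bin_width`` (the last bin is
    extended to include the maximum).  Densities are fractions of cells,
    so they sum to 1 and the cumulative curve ends at 1.
    """
    if bin_width <= 0:
        raise InvalidMeasurementError(f"bin_width must be > 0, got {bin_width}")
    sample.validate()
    v = sample.values
    top = max(float(v.max()), 1.0 + bin_width)
    n_bins = int(np.ceil((top - 1.0) / bin_width - 1e-12))
    edges = 1.0 + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], top) + 1e-12  # include the max value
    counts, _ = np.histogram(v, bins=edges)
    density = counts / v.size
    return ERDistributionCurve(
        bin_edges=edges, density=density, cumulative=np.cumsum(density)
    )


def aggregate_fields(
    per_field_tables: Iterable[pd.DataFrame], sample_id: str = "sample"
) -> ERSample:
    """Pool QC-passing cells from per-field measurement tables into one sample.

    Each table uses the canonical cell-table dialect (``CELL_TABLE_COLUMNS``);
    only rows with ``qc_pass`` truthy contribute.  Warns (never fails) when
    the pooled count or field count falls outside the measurement protocol's
    targets of 10,000-15,000 cells over 25-35 fields.
    """
    tables = list(per_field_tables)
    if not tables:
        raise EmptyInputError("no field tables given")
    ers: list[np.ndarray] = []
    for t in tables:
        if len(t) == 0:
            continue
        mask = t["qc_pass"].astype(bool).to_numpy()
        ers.append(t.loc[mask, "er"].to_numpy(dtype=float))
    values = np.concatenate(ers) if ers else np.empty(0)
    if values.size == 0:
        raise EmptyInputError("no QC-passing cells across fields")
    n_fields = len(tables)
    lo_c, hi_c = CELL_COUNT_RANGE
    lo_f, hi_f = FIELD_COUNT_RANGE
    if not (lo_c <= values.size <= hi_c):
        warnings.warn(
            f"pooled cell count {values.size} outside protocol target "
            f"{lo_c}-{hi_c}",
            UserWarning,
            stacklevel=2,
        )
    if not (lo_f <= n_fields <= hi_f):
        warnings.warn(
            f"field count {n_fields} outside protocol target {lo_f}-{hi_f}",
            UserWarning,
            stacklevel=2,
        )
    sample = ERSample(values=values, sample_id=sample_id, n_fields=n_fields)
    sample.validate()
    return sample


def read_cell_table(path) -> pd.DataFrame:
    """Read a per-cell measurement CSV in the canonical dialect."""
    df = pd.read_csv(path)
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise InvariantViolationError(f"cell table {path} missing columns {missing}")
    return df


def write_cell_table(df: pd.DataFrame, path) -> None:
    cols = CELL_TABLE_COLUMNS + [c for c in df.columns if c not in CELL_TABLE_COLUMNS]
    df.loc[:, cols].to_csv(path, index=False)
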