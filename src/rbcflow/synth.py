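"""Synthetic data generators: ER populations, field images with ground
truth, unit cohorts, and membrane-proteomics tables.

Every stage of the analysis is testable against these generators without
any external data.  The within-sample ER model is

    ER = 1 + X,   X ~ w * |Normal(0, rigid_spread)|  (rigid spike near 1)
                    + (1 - w) * LogNormal(tail_shape, tail_scale)

a two-component mixture on [0, inf): a narrow half-normal spike of
undeformable cells at ER ~ 1 plus a right-skewed lognormal bulk of
deformable cells.  The lognormal tail (rather than, say, a gamma) is what
lets a single shape family reach the profiles seen in real units: a unit
can combine a low undeformable fraction (%UDFC ~ 1) with a heavy
high-deformability tail (%HDFC ~ 6) at median ER ~ 1.55, a corner of
profile space a gamma tail cannot reach.  Calibration to (MER, %UDFC,
%HDFC) targets is closed-form up to a small fixed-point iteration on the
mixture weight, hence exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.ndimage import gaussian_filter
from scipy.stats import halfnorm, lognorm, norm

from .core import ERSample, ThresholdScheme
from .errors import (
    CalibrationInfeasibleError,
    InvalidMeasurementError,
    InvariantViolationError,
    PlacementFailureError,
)
from .imaging import FieldImage

__all__ = [
    "PopulationModel",
    "CohortPreset",
    "ImagingParams",
    "ProteomicsSimParams",
    "PRBC_PRESET",
    "CRBC_PRESET",
    "COHORT_PRESETS",
    "PROTEIN_PANEL",
    "model_cdf",
    "model_quantile",
    "model_band_percentages",
    "simulate_er_population",
    "calibrate_population",
    "simulate_cohort",
    "render_field",
    "render_specimen",
    "simulate_proteomics",
]

#: Membrane proteins carried by the proteomics generator; `hbb` is the
#: membrane-bound hemoglobin beta-subunit.
PROTEIN_PANEL = ["hbb", "ezrin", "stomatin", "band_4_1", "flotillin_1", "flotillin_2"]


# ---------------------------------------------------------------------------
# ER population model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationModel:
    """Mixture model of one specimen's ER distribution (see module docs).

    rigid_fraction
        mixture weight w of the undeformable spike, in [0, 1].
    rigid_spread
        half-normal scale of the spike (ER units above 1).
    tail_shape
        lognormal sigma of the deformable component (dimensionless skew).
    tail_scale
        lognormal median of the deformable component (ER units above 1).
    """

    rigid_fraction: float = 0.02
    rigid_spread: float = 0.03
    tail_shape: float = 0.65
    tail_scale: float = 0.5
    description: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.rigid_fraction <= 1.0:
            raise InvariantViolationError(
                f"rigid_fraction must be in [0,1], got {self.rigid_fraction}"
            )
        if self.rigid_spread <= 0 or self.tail_shape <= 0 or self.tail_scale <= 0:
            raise InvariantViolationError(
                "rigid_spread, tail_shape and tail_scale must be > 0"
            )


def model_cdf(model: PopulationModel, er) -> np.ndarray:
    """Exact mixture CDF of ER (vectorized)."""
    x = np.asarray(er, dtype=float) - 1.0
    w = model.rigid_fraction
    spike = halfnorm.cdf(x, scale=model.rigid_spread)
    tail = lognorm.cdf(x, model.tail_shape, scale=model.tail_scale)
    return w * spike + (1.0 - w) * tail


def model_quantile(model: PopulationModel, q: float) -> float:
    """Exact mixture quantile by root finding (the analytic MER oracle)."""
    if not 0.0 < q < 1.0:
        raise InvalidMeasurementError(f"quantile must be in (0,1), got {q}")
    lo, hi = 1.0, 1.0 + 10.0 * (model.tail_scale * np.exp(3 * model.tail_shape)
                                + model.rigid_spread)
    return float(optimize.brentq(lambda e: model_cdf(model, e) - q, lo, hi,
                                 xtol=1e-12))


def model_band_percentages(
    model: PopulationModel, scheme: ThresholdScheme | None = None
) -> dict[str, float]:
    """Analytic band masses (%) of the mixture under a threshold scheme.

    Boundaries carry zero mass for this continuous model, so the
    disjoint/cumulative conventions coincide here.
    """
    if scheme is None:
        scheme = ThresholdScheme()
    f_u = model_cdf(model, scheme.udfc_upper)
    f_l = model_cdf(model, scheme.ldfc_upper)
    f_h = model_cdf(model, scheme.hdfc_lower)
    return {
        "pct_udfc": 100.0 * float(f_u),
        "pct_ldfc": 100.0 * float(f_l - f_u),
        "pct_mid": 100.0 * float(f_h - f_l),
        "pct_hdfc": 100.0 * float(1.0 - f_h),
    }


def simulate_er_population(
    model: PopulationModel, n: int, seed: int | np.random.Generator = 0,
    sample_id: str = "synthetic",
) -> ERSample:
    """Draw n per-cell ER values from the mixture; reproducible per seed."""
    if n < 1:
        raise InvalidMeasurementError(f"population size must be >= 1, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    is_rigid = rng.random(n) < model.rigid_fraction
    x = rng.lognormal(mean=np.log(model.tail_scale), sigma=model.tail_shape, size=n)
    n_rigid = int(is_rigid.sum())
    if n_rigid:
        x[is_rigid] = np.abs(rng.normal(0.0, model.rigid_spread, size=n_rigid))
    return ERSample(values=1.0 + x, sample_id=sample_id)


# ---------------------------------------------------------------------------
# Calibration: profile targets -> model parameters
# ---------------------------------------------------------------------------

def calibrate_population(
    target_mer: float,
    target_udfc_pct: float,
    target_hdfc_pct: float | None = None,
    *,
    scheme: ThresholdScheme | None = None,
    rigid_spread: float = 0.03,
    tail_shape: float = 0.65,
) -> PopulationModel:
    """Solve for a :class:`PopulationModel` matching profile targets.

    With all three targets given, both lognormal parameters and the spike
    weight are solved so the analytic median, %UDFC and %HDFC match within
    1e-3.  With ``target_hdfc_pct`` omitted (or 0), ``tail_shape`` is held
    fixed and only the scale and spike weight are solved — the
    high-deformability fraction then emerges from the calibrated shape.
    Deterministic: same targets always give the same parameters.
    """
    if scheme is None:
        scheme = ThresholdScheme()
    u_pct = float(target_udfc_pct)
    h_pct = float(target_hdfc_pct) if target_hdfc_pct else None
    if not 1.0 < target_mer < scheme.hdfc_lower:
        raise CalibrationInfeasibleError(
            f"target MER {target_mer} must lie in (1, {scheme.hdfc_lower})"
        )
    if u_pct < 0 or u_pct >= 100 or (h_pct is not None and h_pct < 0):
        raise CalibrationInfeasibleError("band percentages must be in [0, 100)")
    if h_pct is not None and u_pct + h_pct >= 100:
        raise CalibrationInfeasibleError("%UDFC + %HDFC must be < 100")

    x_m = target_mer - 1.0
    x_u = scheme.udfc_upper - 1.0
    x_h = scheme.hdfc_lower - 1.0
    u = u_pct / 100.0
    h = h_pct / 100.0 if h_pct is not None else None

    sigma = rigid_spread
    s = tail_shape
    scale = 0.5  # starting tail scale; overwritten in the tail-median regime
    w = 0.0
    rigid_dominated = u_pct >= 50.0  # median must then sit inside the spike
    if rigid_dominated and h_pct:
        raise CalibrationInfeasibleError(
            "cannot pin %HDFC for a rigid-dominated population (%UDFC >= 50); "
            "omit target_hdfc_pct"
        )

    def _weight(sig: float, sc: float) -> float:
        l_u = lognorm.cdf(x_u, s, scale=sc)
        fh_u = halfnorm.cdf(x_u, scale=sig)
        denom = fh_u - l_u
        w_new = (u - l_u) / denom if denom > 0 else -1.0
        if w_new < -1e-6:
            raise CalibrationInfeasibleError(
                f"%UDFC target {u_pct} below the deformable component's own "
                f"mass under {scheme.udfc_upper} ({100 * l_u:.2f}%)"
            )
        return float(np.clip(w_new, 0.0, 1.0 - 1e-9))

    for _ in range(200):
        w_new = _weight(sigma, scale)
        if rigid_dominated:
            # solve the spike spread so the mixture median lands on target;
            # tail parameters stay at their conventional defaults
            l_m = lognorm.cdf(x_m, s, scale=scale)
            p = (0.5 - (1.0 - w_new) * l_m) / w_new if w_new > 0 else np.nan
            if not (0.0 < p < 1.0):
                raise CalibrationInfeasibleError(
                    f"median target {target_mer} unreachable with %UDFC {u_pct}"
                )
            sigma_new, scale_new = float(x_m / halfnorm.ppf(p)), scale
        else:
            sigma_new = sigma
            fh_m = halfnorm.cdf(x_m, scale=sigma)
            q_m = (0.5 - w_new * fh_m) / (1.0 - w_new)
            if not (0.0 < q_m < 1.0):
                raise CalibrationInfeasibleError(
                    f"median target {target_mer} unreachable with %UDFC {u_pct}"
                )
            if h is not None:
                q_h = 1.0 - h / (1.0 - w_new)
                if not (0.0 < q_m < q_h < 1.0):
                    raise CalibrationInfeasibleError(
                        f"targets (MER {target_mer}, %HDFC {h_pct}) inconsistent"
                    )
                z_m, z_h = norm.ppf(q_m), norm.ppf(q_h)
                s = (np.log(x_h) - np.log(x_m)) / (z_h - z_m)
                if s <= 0:
                    raise CalibrationInfeasibleError("implied tail shape <= 0")
            scale_new = float(x_m * np.exp(-s * norm.ppf(q_m)))
        converged = (abs(w_new - w) < 1e-12 and abs(sigma_new - sigma) < 1e-12
                     and abs(scale_new - scale) < 1e-12)
        w, sigma, scale = w_new, sigma_new, scale_new
        if converged:
            break

    model = PopulationModel(
        rigid_fraction=w, rigid_spread=sigma, tail_shape=float(s),
        tail_scale=float(scale),
        description=f"calibrated to MER={target_mer}, %UDFC={u_pct}"
        + (f", %HDFC={h_pct}" if h_pct is not None else ""),
    )
    # verify the analytic profile actually matches
    med = model_quantile(model, 0.5)
    bands = model_band_percentages(model, scheme)
    ok = abs(med - target_mer) < 1e-3 and abs(bands["pct_udfc"] - u_pct) < 0.1
    if h_pct is not None:
        ok = ok and abs(bands["pct_hdfc"] - h_pct) < 0.1
    if not ok:
        raise CalibrationInfeasibleError(
            f"calibration did not converge for targets MER={target_mer}, "
            f"%UDFC={u_pct}, %HDFC={h_pct}: got median {med:.4f}, bands {bands}"
        )
    return model


def _calibrate_units_vectorized(
    mer_targets: np.ndarray,
    udfc_targets: np.ndarray,
    rigid_spread: float,
    tail_shape: float,
    udfc_upper: float = 1.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-shape calibration for many units at once.

    Returns (tail_scale, rigid_fraction) arrays.  Assumes every unit's
    median lies in the deformable bulk (true for targets >= ~1.2 at the
    default spike spread); weights are clipped to [0, 1) so %UDFC targets
    below the tail's intrinsic mass yield a spikeless unit.
    """
    x_m = np.asarray(mer_targets, float) - 1.0
    u = np.asarray(udfc_targets, float) / 100.0
    x_u = udfc_upper - 1.0
    fh_m = halfnorm.cdf(x_m, scale=rigid_spread)
    fh_u = halfnorm.cdf(x_u, scale=rigid_spread)
    w = np.zeros_like(x_m)
    scale = x_m.copy()
    for _ in range(60):
        q_m = (0.5 - w * fh_m) / (1.0 - w)
        if np.any((q_m <= 0) | (q_m >= 1)):
            raise CalibrationInfeasibleError(
                "unit target outside the fixed-shape calibration's range"
            )
        scale = x_m * np.exp(-tail_shape * norm.ppf(q_m))
        l_u = lognorm.cdf(x_u, tail_shape, scale=scale)
        w_new = np.clip((u - l_u) / (fh_u - l_u), 0.0, 1.0 - 1e-9)
        if np.max(np.abs(w_new - w)) < 1e-12:
            w = w_new
            break
        w = w_new
    return scale, w


# ---------------------------------------------------------------------------
# Cohort presets and simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortPreset:
    """Between-unit variability of a cohort: mean +/- SD of unit MER and
    %UDFC, and the cohort size in units."""

    name: str
    mer_mean: float
    mer_sd: float
    udfc_mean: float
    udfc_sd: float
    n_units: int

    def __post_init__(self) -> None:
        if self.mer_mean < 1 or self.mer_sd < 0 or self.udfc_sd < 0:
            raise InvariantViolationError("invalid cohort preset")


#: Adult-donor packed RBC units: MER 1.52 +/- 0.11, %UDFC 3.18 +/- 3.83, 156 units.
PRBC_PRESET = CohortPreset("PRBC", mer_mean=1.52, mer_sd=0.11,
                           udfc_mean=3.18, udfc_sd=3.83, n_units=156)
#: Cord-blood RBC samples: MER 1.61 +/- 0.07, %UDFC 2.21 +/- 1.06, 78 units.
CRBC_PRESET = CohortPreset("CRBC", mer_mean=1.61, mer_sd=0.07,
                           udfc_mean=2.21, udfc_sd=1.06, n_units=78)
COHORT_PRESETS = {"PRBC": PRBC_PRESET, "CRBC": CRBC_PRESET}

# Unit-level MER targets are truncated below at this floor (a population
# with median under it is not a viable unit) and above just under the
# high-deformability threshold.
_MER_FLOOR = 1.05


def simulate_cohort(
    preset: CohortPreset,
    seed: int | np.random.Generator = 0,
    cells_per_unit: int = 10_000,
    n_units: int | None = None,
    tail_shape: float = 0.65,
    rigid_spread: float = 0.03,
) -> list[tuple[str, ERSample]]:
    """Simulate a cohort of units, each a full ER population.

    Per unit, a target MER ~ Normal(mer_mean, mer_sd) truncated to
    [1.05, hdfc_lower) and a target %UDFC ~ Normal(udfc_mean, udfc_sd)
    truncated at 0 are drawn, a population model is calibrated to them
    (fixed tail shape), and ``cells_per_unit`` ERs are sampled.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = preset.n_units if n_units is None else n_units
    mer_hi = ThresholdScheme().hdfc_lower - 0.05

    def _trunc_normal(mean, sd, lo, hi, size):
        if sd == 0:
            return np.full(size, float(np.clip(mean, lo, hi)))
        out = rng.normal(mean, sd, size)
        bad = (out < lo) | (out > hi)
        while bad.any():
            out[bad] = rng.normal(mean, sd, int(bad.sum()))
            bad = (out < lo) | (out > hi)
        return out

    mer_t = _trunc_normal(preset.mer_mean, preset.mer_sd, _MER_FLOOR, mer_hi, n)
    udfc_t = _trunc_normal(preset.udfc_mean, preset.udfc_sd, 0.0, 99.0, n)
    scales, weights = _calibrate_units_vectorized(
        mer_t, udfc_t, rigid_spread, tail_shape
    )
    out = []
    for i in range(n):
        model = PopulationModel(
            rigid_fraction=float(weights[i]), rigid_spread=rigid_spread,
            tail_shape=tail_shape, tail_scale=float(scales[i]),
        )
        uid = f"{preset.name}-U{i:03d}"
        sample = simulate_er_population(model, cells_per_unit, rng, sample_id=uid)
        out.append((uid, sample))
    return out


# ---------------------------------------------------------------------------
# Field-image rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImagingParams:
    """Geometry and photometry of synthetic microscopy fields.

    Fields are square with area ``field_area_mm2`` (0.1 mm^2 as in the
    flow-chamber protocol).  Cells are filled ellipses whose projected
    area is drawn per cell and preserved under elongation; the major axis
    aligns with the flow (image x) up to Gaussian angular jitter.
    """

    pixel_size: float = 0.15  # um per pixel
    field_area_mm2: float = 0.1
    cells_per_field: int = 400
    cell_area_um2_mean: float = 55.0
    cell_area_um2_sd: float = 8.0
    angular_jitter_deg: float = 5.0
    blur_sigma_px: float = 0.0
    noise_sd: float = 0.0
    background_level: float = 30.0
    foreground_level: float = 200.0
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_area_mm2 <= 0 or self.pixel_size <= 0:
            raise InvariantViolationError("field area and pixel size must be > 0")
        if self.cells_per_field < 0:
            raise InvariantViolationError("cells_per_field must be >= 0")

    @property
    def side_px(self) -> int:
        side_um = np.sqrt(self.field_area_mm2 * 1e6)
        return int(round(side_um / self.pixel_size))


TRUTH_COLUMNS = ["field_id", "cell_id", "x", "y", "major_um", "minor_um",
                 "er", "area_um2", "orientation"]


def _ellipse_mask(shape, cx, cy, a_px, b_px, theta):
    """Bounding box and inside-mask of pixels whose centers fall inside the
    rotated ellipse (pixel centers at integer coordinates)."""
    h, w = shape
    r = int(np.ceil(a_px)) + 1
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
    if x0 >= x1 or y0 >= y1:
        return (slice(0, 0), slice(0, 0)), np.zeros((0, 0), bool)
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    dx, dy = np.meshgrid(xs, ys)
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    return (slice(y0, y1), slice(x0, x1)), inside


def render_field(
    er_values: Sequence[float] | np.ndarray,
    params: ImagingParams | None = None,
    seed: int | np.random.Generator | None = None,
    field_id: str = "field_000",
) -> tuple[FieldImage, pd.DataFrame]:
    """Render one field of shear-elongated cells and its ground truth.

    Each ER value becomes one filled ellipse: area ~ Normal(mean, sd)
    clipped at 15 um^2, semi-axes a = sqrt(area*er/pi), b = sqrt(area/
    (pi*er)), orientation ~ flow direction + jitter.  Placement is by
    rejection sampling against a bounding-circle overlap test (unless
    ``allow_overlap``) and keeps cells clear of the border.  The truth
    table records exact centers, axes and ER per cell.
    """
    if params is None:
        params = ImagingParams()
    er = np.asarray(er_values, dtype=float)
    if er.size and er.min() < 1.0:
        raise InvariantViolationError("cell ER values must be >= 1")
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    side = params.side_px
    img = np.full((side, side), params.background_level, dtype=float)
    rows = []
    if er.size:
        areas = np.clip(
            rng.normal(params.cell_area_um2_mean, params.cell_area_um2_sd, er.size),
            15.0, None,
        )
        a_um = np.sqrt(areas * er / np.pi)
        b_um = np.sqrt(areas / (np.pi * er))
        thetas = rng.normal(0.0, np.deg2rad(params.angular_jitter_deg), er.size)
        a_px = a_um / params.pixel_size
        b_px = b_um / params.pixel_size
        # occupancy of already-placed cells dilated by one pixel, so distinct
        # cells can never become 8-connected after rasterization
        occupied = np.zeros((side, side), dtype=bool)
        dil = np.ones((3, 3), dtype=bool)
        from scipy.ndimage import binary_dilation

        for i in range(er.size):
            margin = a_px[i] + 2.0
            if 2 * margin >= side:
                raise PlacementFailureError(
                    f"cell {i} (major {a_px[i]:.0f} px) cannot fit in the field"
                )
            for attempt in range(2000):
                cx = rng.uniform(margin, side - margin)
                cy = rng.uniform(margin, side - margin)
                box, inside = _ellipse_mask(img.shape, cx, cy, a_px[i],
                                            b_px[i], thetas[i])
                if params.allow_overlap or not occupied[box][inside].any():
                    break
            else:
                raise PlacementFailureError(
                    f"could not place cell {i}/{er.size} without overlap; "
                    "reduce cells_per_field or set allow_overlap"
                )
            img[box][inside] = params.foreground_level
            if not params.allow_overlap:
                occupied[box] |= binary_dilation(inside, structure=dil)
            rows.append((field_id, i, cx, cy, 2 * a_um[i], 2 * b_um[i],
                         er[i], areas[i], thetas[i]))
    if params.blur_sigma_px > 0:
        img = gaussian_filter(img, params.blur_sigma_px)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    field = FieldImage(pixels=img, pixel_size=params.pixel_size, field_id=field_id)
    return field, truth


def render_specimen(
    sample: ERSample,
    params: ImagingParams | None = None,
    n_fields: int = 25,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[FieldImage], pd.DataFrame]:
    """Split a specimen's ER values over ``n_fields`` fields and render each.

    Returns the field images and the concatenated truth table; together
    they form a fully known benchmark for the segmentation stage.
    """
    if params is None:
        params = ImagingParams()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chunks = np.array_split(sample.values, n_fields)
    fields, truths = [], []
    for i, chunk in enumerate(chunks):
        fid = f"{sample.sample_id}_f{i:03d}"
        fld, truth = render_field(chunk, params, seed=rng, field_id=fid)
        fields.append(fld)
        truths.append(truth)
    return fields, pd.concat(truths, ignore_index=True)


# ---------------------------------------------------------------------------
# Proteomics simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteomicsSimParams:
    """Linear deformability model behind synthetic Ln(LFQ) tables.

    The response (unit MER) is ``a * [protein] + b * [hbb] + intercept +
    Normal(0, noise_sd)`` where the predictors are Ln(LFQ) membrane-protein
    levels.  Defaults put Ln(LFQ) in the low-20s (typical label-free
    intensities), a positive coefficient on the structural protein (protein
    loss lowers deformability) and a negative one on membrane-bound
    hemoglobin (bound Hb stiffens the cell), with noise sized so the
    two-predictor multiple correlation is ~0.77.  Non-causal panel proteins
    are drawn independently.
    """

    n_units: int = 15
    protein: str = "flotillin_1"
    coef_protein: float = 0.05
    coef_hbb: float = -0.04
    intercept: float = 1.25
    noise_sd: float = 0.034
    lnlfq_means: dict = field(default_factory=lambda: {
        "hbb": 20.0, "ezrin": 23.0, "stomatin": 24.0, "band_4_1": 23.5,
        "flotillin_1": 22.0, "flotillin_2": 21.5,
    })
    lnlfq_sds: dict = field(default_factory=lambda: {
        "hbb": 0.8, "ezrin": 0.5, "stomatin": 0.5, "band_4_1": 0.5,
        "flotillin_1": 0.5, "flotillin_2": 0.5,
    })
    response_name: str = "mer"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 3:
            raise InvariantViolationError(f"need >= 3 units, got {self.n_units}")
        if self.noise_sd < 0:
            raise InvalidMeasurementError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.protein not in PROTEIN_PANEL:
            raise InvariantViolationError(f"unknown protein {self.protein!r}")


def simulate_proteomics(
    params: ProteomicsSimParams | None = None,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a wide per-unit Ln(LFQ) table with a known linear response.

    Columns: ``unit_id``, one Ln(LFQ) column per panel protein, the noisy
    response (named by ``response_name``), and ``<response_name>_true``
    (the noise-free linear part, the generator's ground truth).
    """
    if params is None:
        params = ProteomicsSimParams()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = params.n_units
    data = {"unit_id": [f"U{i:03d}" for i in range(n)]}
    for p in PROTEIN_PANEL:
        data[p] = rng.normal(params.lnlfq_means[p], params.lnlfq_sds[p], n)
    true = (params.coef_protein * data[params.protein]
            + params.coef_hbb * data["hbb"] + params.intercept)
    data[params.response_name] = true + rng.normal(0.0, params.noise_sd, n)
    data[f"{params.response_name}_true"] = true
    return pd.DataFrame(data)
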