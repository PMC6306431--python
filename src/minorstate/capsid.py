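"""CAPSID: curvature of amide proton shifts induced by denaturant.

A residue in fast exchange with a low-lying excited state (within roughly
10 kJ/mol of the ground state) shows a curved temperature dependence of its
amide chemical shift, because the excited-state population changes with
temperature. The curvature alone is an unreliable detector - it depends on
both the shift difference and the free-energy gap - so the measurement is
repeated at several guanidinium (Gdm) concentrations: Gdm destabilizes the
ground state relative to compact excited states, so a genuine excited state
produces a systematic trend of curvature with [Gdm].

The analysis is two nested quadratic fits:

1. per residue and Gdm level, shift vs temperature: y = a + b*x + c*x^2,
   with the second-order coefficient c as the curvature measure;
2. per residue, c vs [Gdm], again quadratic, returning mean and standard
   deviation of the slope and curvature.

A coefficient is significant when mean +/- 2*sd does not span zero; a
residue is called significant when its slope or curvature passes that test.
The sign of the dominant curvature classifies the shape (concave -> the
excited state resonates downfield of the ground state; convex -> upfield).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field as dataclass_field

import numpy as np

__all__ = [
    "ShiftSeries",
    "CurvatureRecord",
    "GdmCurvatureFit",
    "Shape",
    "ShiftDirection",
    "fit_temperature_quadratic",
    "fit_curvature_vs_gdm",
    "classify_shape",
    "run_capsid",
]

#: Default per-point measurement uncertainty of a peak position, ppm.
DEFAULT_NOISE_PPM = 0.0075

#: Reduced chi-square above which a fit is considered poor and discarded.
#: Set well above the noise-only expectation (~1) so that only measurement
#: pathologies are dropped, not residues whose genuine excited-state response
#: deviates systematically from the quadratic form.
DEFAULT_CHI2_MAX = 10.0


class Shape(str, enum.Enum):
    CONCAVE = "concave"
    CONVEX = "convex"
    FLAT_NONZERO = "flat_nonzero"
    NONE = "none"


class ShiftDirection(str, enum.Enum):
    DOWNFIELD = "downfield"
    UPFIELD = "upfield"
    UNDETERMINED = "undetermined"


@dataclass
class ShiftSeries:
    """Per-residue amide shift measurements on a (temperature x [Gdm]) grid.

    records is a list of (temperature_K, gdm_M, shift_ppm); missing grid
    points (peak overlap) are simply absent.
    """

    residue_id: str
    records: list[tuple[float, float, float]]

    def at_gdm(self, gdm: float, tol: float = 1e-9):
        """(temperatures, shifts) arrays at one Gdm level."""
        pts = [(t, s) for t, g, s in self.records if abs(g - gdm) <= tol]
        pts.sort()
        t = np.array([p[0] for p in pts])
        s = np.array([p[1] for p in pts])
        return t, s

    def gdm_levels(self) -> list[float]:
        return sorted({g for _, g, _ in self.records})


@dataclass
class CurvatureRecord:
    residue_id: str
    gdm: float
    a: float  # ppm, at the centered-temperature origin
    b: float  # ppm/K
    c: float  # ppm/K^2 - the curvature measure
    c_sd: float
    fit_chi2: float  # reduced chi-square of the quadratic fit
    n_points: int
    usable: bool = True
    reason: str = ""


@dataclass
class GdmCurvatureFit:
    residue_id: str
    slope: float = np.nan  # ppm/K^2/M
    slope_sd: float = np.nan
    curvature: float = np.nan  # ppm/K^2/M^2
    curvature_sd: float = np.nan
    intercept: float = np.nan
    fit_chi2: float = np.nan  # reduced chi-square of the c(g) fit
    n_levels: int = 0
    significant_slope: bool = False
    significant_curvature: bool = False
    significant: bool = False
    shape: Shape = Shape.NONE
    excited_shift_direction: ShiftDirection = ShiftDirection.UNDETERMINED
    discarded: bool = False
    discard_reason: str = ""
    records: list = dataclass_field(default_factory=list)


def _weighted_quadratic(x: np.ndarray, y: np.ndarray, sd: np.ndarray):
    """Weighted least-squares fit of y = p0 + p1*x + p2*x^2.

    Returns (coefficients, coefficient sds from the covariance, reduced chi2).
    """
    X = np.column_stack([np.ones_like(x), x, x * x])
    w = 1.0 / sd
    coef, *_ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
    cov = np.linalg.inv((X * w[:, None] ** 2).T @ X)
    resid = (y - X @ coef) * w
    dof = len(x) - 3
    red_chi2 = float(resid @ resid / dof) if dof > 0 else 0.0
    return coef, np.sqrt(np.diag(cov)), red_chi2


def fit_temperature_quadratic(series: ShiftSeries, gdm: float,
                              noise_ppm: float = DEFAULT_NOISE_PPM,
                              min_points: int = 3) -> CurvatureRecord:
    """Quadratic fit of shift vs temperature at one Gdm level.

    Temperature is centered at its mean before fitting (the second-order
    coefficient is invariant to centering; the low-order coefficients are
    better conditioned). Coefficient standard deviations come from the
    linear-model covariance with a fixed per-point sd *noise_ppm*.
    """
    t, shift = series.at_gdm(gdm)
    if len(t) < min_points or len(np.unique(t)) < 3:
        return CurvatureRecord(series.residue_id, gdm, np.nan, np.nan, np.nan,
                               np.nan, np.nan, len(t), usable=False,
                               reason=f"fewer than {min_points} distinct temperatures")
    tc = t - t.mean()
    sd = np.full_like(t, noise_ppm)
    coef, coef_sd, red_chi2 = _weighted_quadratic(tc, shift, sd)
    return CurvatureRecord(series.residue_id, gdm, a=float(coef[0]), b=float(coef[1]),
                           c=float(coef[2]), c_sd=float(coef_sd[2]),
                           fit_chi2=red_chi2, n_points=len(t))


def fit_curvature_vs_gdm(records: list[CurvatureRecord],
                         chi2_max: float = DEFAULT_CHI2_MAX) -> GdmCurvatureFit:
    """Weighted quadratic fit of the stage-1 curvature c against [Gdm].

    Weights are the stage-1 coefficient sds. Significance of the slope and
    curvature uses the +/-2 sd sign rule: a coefficient is significant when
    mean - 2 sd and mean + 2 sd have the same sign. A residue is discarded
    when either fitting stage has reduced chi-square above *chi2_max*, or
    when fewer than 3 Gdm levels are usable.
    """
    rid = records[0].residue_id
    usable = [r for r in records if r.usable]
    fit = GdmCurvatureFit(residue_id=rid, records=records)
    if len(usable) < 3:
        fit.discarded = True
        fit.discard_reason = f"only {len(usable)} usable Gdm levels (need >=3)"
        return fit
    bad_stage1 = [r for r in usable if r.fit_chi2 > chi2_max]
    if bad_stage1:
        fit.discarded = True
        fit.discard_reason = (
            "poor temperature fits (reduced chi2 > "
            f"{chi2_max}) at [Gdm] = {[r.gdm for r in bad_stage1]}"
        )
        return fit
    g = np.array([r.gdm for r in usable])
    c = np.array([r.c for r in usable])
    c_sd = np.array([r.c_sd for r in usable])
    coef, coef_sd, red_chi2 = _weighted_quadratic(g, c, c_sd)
    fit.intercept = float(coef[0])
    fit.slope, fit.slope_sd = float(coef[1]), float(coef_sd[1])
    fit.curvature, fit.curvature_sd = float(coef[2]), float(coef_sd[2])
    fit.fit_chi2 = red_chi2
    fit.n_levels = len(usable)
    if red_chi2 > chi2_max:
        fit.discarded = True
        fit.discard_reason = f"poor c([Gdm]) fit: reduced chi2 {red_chi2:.2f} > {chi2_max}"
        return fit
    fit.significant_slope = _sign_rule(fit.slope, fit.slope_sd)
    fit.significant_curvature = _sign_rule(fit.curvature, fit.curvature_sd)
    fit.significant = fit.significant_slope or fit.significant_curvature
    if fit.significant:
        fit.shape, fit.excited_shift_direction = classify_shape(fit, usable)
    return fit


def _sign_rule(mean: float, sd: float) -> bool:
    """Significant iff (mean - 2 sd) and (mean + 2 sd) share a sign."""
    return (mean - 2.0 * sd) * (mean + 2.0 * sd) > 0


def classify_shape(fit: GdmCurvatureFit,
                   records: list[CurvatureRecord]) -> tuple[Shape, ShiftDirection]:
    """Shape and excited-state shift direction from the dominant curvature sign.

    Predominantly positive c across the Gdm levels means the temperature
    curves open upward (concave): the excited state resonates downfield of
    the ground state. Predominantly negative c means convex: upfield. A
    significant Gdm dependence whose c values straddle zero (near-zero mean)
    is classified flat_nonzero with undetermined direction.
    """
    usable = [r for r in records if r.usable]
    c = np.array([r.c for r in usable])
    w = 1.0 / np.array([r.c_sd for r in usable]) ** 2
    mean_c = float(np.sum(w * c) / np.sum(w))
    sd_mean = float(1.0 / np.sqrt(np.sum(w)))
    if mean_c > 2.0 * sd_mean:
        return Shape.CONCAVE, ShiftDirection.DOWNFIELD
    if mean_c < -2.0 * sd_mean:
        return Shape.CONVEX, ShiftDirection.UPFIELD
    return Shape.FLAT_NONZERO, ShiftDirection.UNDETERMINED


def analyze_series(series: ShiftSeries, noise_ppm: float = DEFAULT_NOISE_PPM,
                   min_points: int = 3, chi2_max: float = DEFAULT_CHI2_MAX) -> GdmCurvatureFit:
    """Both fitting stages for a single residue."""
    records = [fit_temperature_quadratic(series, g, noise_ppm, min_points)
               for g in series.gdm_levels()]
    return fit_curvature_vs_gdm(records, chi2_max=chi2_max)


def run_capsid(dataset: list[ShiftSeries], bound_dataset: list[ShiftSeries] | None = None,
               noise_ppm: float = DEFAULT_NOISE_PPM, min_points: int = 3,
               chi2_max: float = DEFAULT_CHI2_MAX) -> dict:
    """Full CAPSID analysis of one (or a free/bound pair of) dataset(s).

    Returns a dict with per-residue GdmCurvatureFit objects, the list of
    significant residues, and - when a second dataset is given - an overlap
    report of the significant sets (the free/bound comparison).
    """
    if not dataset:
        raise ValueError("empty dataset")

    def _run(ds):
        fits = {s.residue_id: analyze_series(s, noise_ppm, min_points, chi2_max)
                for s in ds}
        sig = sorted([rid for rid, f in fits.items() if f.significant])
        return fits, sig

    fits, significant = _run(dataset)
    out = {
        "fits": fits,
        "significant": significant,
        "n_residues": len(fits),
        "n_discarded": sum(f.discarded for f in fits.values()),
    }
    if bound_dataset is not None:
        bound_fits, bound_sig = _run(bound_dataset)
        a, b = set(significant), set(bound_sig)
        out["bound_fits"] = bound_fits
        out["bound_significant"] = bound_sig
        out["overlap"] = {
            "both": sorted(a & b),
            "free_only": sorted(a - b),
            "bound_only": sorted(b - a),
            "jaccard": len(a & b) / len(a | b) if a | b else np.nan,
        }
    return out
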