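"""Internal-standard quantification and the bioanalytical validation
calculus: 1/x-weighted linear calibration, back-calculation acceptance,
LOD/LOQ, recovery, matrix effect, and trueness/precision from a
multi-day QC design.

Acceptance follows the usual bioanalytical rules: R² > 0.995 over at
least six calibration points, back-calculated deviations within ±15 %
(±20 % at the LLOQ), LOD at S/N ≥ 3, LOQ at triplicate CV ≤ 20 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chemmass import ion_mz
from .peakcraft import detect_peaks, extract_xic
from .spectra_io import CompoundEntry, Run, SampleSheet

__all__ = [
    "CalibrationCurve",
    "QuantResult",
    "PrecisionRow",
    "fit_calibration",
    "quantify",
    "estimate_conc_by_is",
    "compute_lod",
    "compute_loq",
    "compute_recovery",
    "compute_matrix_effect",
    "precision_trueness",
    "measure_area_ratio",
    "build_calibration_from_runs",
]

R2_MIN = 0.995
DEV_MAX_PCT = 15.0
DEV_MAX_LLOQ_PCT = 20.0
MIN_LEVELS = 6


@dataclass
class CalibrationCurve:
    """1/x-weighted linear calibration of area ratio vs nominal µM."""

    analyte: str
    levels: list[tuple[float, list[float]]]  # (nominal µM, replicate ratios)
    slope: float
    intercept: float
    r2: float
    deviations_pct: dict[float, list[float]] = field(default_factory=dict)
    lloq: float | None = None
    uloq: float | None = None
    weighting: str = "1/x"

    @property
    def n_points_used(self) -> int:
        return len(self.levels)

    @property
    def accepted(self) -> bool:
        """R² > 0.995 over >= 6 levels, |mean deviation| <= 15 %
        (<= 20 % at the LLOQ) at every level in the accepted range."""
        if self.r2 <= R2_MIN or self.n_points_used < MIN_LEVELS:
            return False
        if self.lloq is None or self.uloq is None:
            return False
        for nominal, devs in self.deviations_pct.items():
            limit = DEV_MAX_LLOQ_PCT if nominal == self.lloq else DEV_MAX_PCT
            if abs(float(np.mean(devs))) > limit:
                return False
        return True


def fit_calibration(
    levels: list[tuple[float, list[float]]], analyte: str = ""
) -> CalibrationCurve:
    """Fit area ratio vs nominal concentration, weighted 1/x.

    The line is fitted on per-level mean ratios with weights 1/x; R² is
    computed on the same weighted fit (1 - SSE_w/SST_w). Back-calculated
    concentrations, (ratio - intercept)/slope, are evaluated per
    replicate; the LLOQ is the lowest level whose mean deviation is
    within ±20 % with all higher accepted levels within ±15 %.
    """
    levels = sorted(levels, key=lambda lv: lv[0])
    if len(levels) < MIN_LEVELS:
        raise ValueError(f"need at least {MIN_LEVELS} calibration levels")
    x = np.array([lv[0] for lv in levels], dtype=float)
    if np.any(x <= 0):
        raise ValueError("nominal concentrations must be positive")
    if np.unique(x).size != x.size:
        raise ValueError("duplicate calibration levels")
    y = np.array([float(np.mean(lv[1])) for lv in levels])
    w = 1.0 / x
    # weighted least squares via sqrt-weight design scaling
    sw = np.sqrt(w)
    A = np.column_stack([sw * x, sw])
    coef, *_ = np.linalg.lstsq(A, sw * y, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    yhat = slope * x + intercept
    ybar_w = float(np.sum(w * y) / np.sum(w))
    sse = float(np.sum(w * (y - yhat) ** 2))
    sst = float(np.sum(w * (y - ybar_w) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst

    deviations: dict[float, list[float]] = {}
    for nominal, ratios in levels:
        backs = [(r - intercept) / slope for r in ratios]
        deviations[nominal] = [100.0 * (b - nominal) / nominal for b in backs]

    mean_dev = {lv: abs(float(np.mean(d))) for lv, d in deviations.items()}
    lloq = next((lv for lv in x if mean_dev[lv] <= DEV_MAX_LLOQ_PCT), None)
    uloq = next((lv for lv in reversed(x) if mean_dev[lv] <= DEV_MAX_PCT), None)
    return CalibrationCurve(
        analyte=analyte,
        levels=levels,
        slope=slope,
        intercept=intercept,
        r2=float(r2),
        deviations_pct=deviations,
        lloq=None if lloq is None else float(lloq),
        uloq=None if uloq is None else float(uloq),
    )


@dataclass
class QuantResult:
    concentration: float  # µM
    flag: str | None = None  # None | "<LLOQ" | ">ULOQ"


def quantify(sample_ratio: float, curve: CalibrationCurve) -> QuantResult:
    """Back-calculate a sample's concentration from its analyte/IS area
    ratio; flags results outside the curve's accepted range."""
    if curve.slope == 0:
        raise ZeroDivisionError("calibration slope is zero")
    conc = (sample_ratio - curve.intercept) / curve.slope
    flag = None
    if curve.lloq is not None and conc < curve.lloq:
        flag = "<LLOQ"
    elif curve.uloq is not None and conc > curve.uloq:
        flag = ">ULOQ"
    return QuantResult(concentration=float(conc), flag=flag)


def estimate_conc_by_is(
    analyte_area: float, is_area: float, is_conc: float
) -> float:
    """Single-point estimate: analyte_area / IS_area x IS concentration.

    Assumes a response factor of 1 relative to the matched-class internal
    standard; an estimate, not a validated quantification."""
    if is_area <= 0:
        raise ValueError("internal-standard area must be positive")
    return analyte_area / is_area * is_conc


def compute_lod(levels_with_snr: list[tuple[float, float]]) -> float | None:
    """Lowest concentration with S/N >= 3; None when no level qualifies."""
    if not levels_with_snr:
        raise ValueError("empty input")
    for conc, snr in sorted(levels_with_snr):
        if snr >= 3.0:
            return conc
    return None


def compute_loq(levels_with_replicates: list[tuple[float, list[float]]]) -> float | None:
    """Lowest concentration with replicate CV <= 20 %; None when no level
    qualifies."""
    if not levels_with_replicates:
        raise ValueError("empty input")
    for conc, reps in sorted(levels_with_replicates):
        reps = np.asarray(reps, dtype=float)
        if reps.size < 2:
            continue
        mean = reps.mean()
        if mean <= 0:
            continue
        cv = 100.0 * reps.std(ddof=1) / mean
        if cv <= 20.0:
            return conc
    return None


def compute_recovery(area_spiked_pre: float, areas_spiked_post: list[float]) -> float:
    """Extraction recovery %: pre-extraction spike area over the mean
    post-extraction spike area x 100."""
    post = float(np.mean(areas_spiked_post))
    if post <= 0:
        raise ValueError("post-extraction mean area must be positive")
    return 100.0 * area_spiked_pre / post


def compute_matrix_effect(
    curve_matrix: CalibrationCurve, curve_solvent: CalibrationCurve
) -> float:
    """Matrix effect %: matrix-calibration slope over solvent-calibration
    slope x 100 (100 % = no suppression or enhancement)."""
    if curve_solvent.slope == 0:
        raise ZeroDivisionError("solvent calibration slope is zero")
    return 100.0 * curve_matrix.slope / curve_solvent.slope


@dataclass
class PrecisionRow:
    level: float  # nominal µM
    trueness_pct: float
    repeatability_cv_pct: float
    intermediate_cv_pct: float
    n_days: int
    n_total: int


def precision_trueness(
    qc: dict[float, dict[int, list[float]]],
    max_missing_fraction: float = 0.2,
) -> list[PrecisionRow]:
    """Trueness and precision from a days x replicates QC design.

    ``qc`` maps nominal level -> day index -> measured concentrations.
    Trueness is 100 x mean(measured)/nominal. Repeatability is the pooled
    within-day CV; intermediate precision adds the between-day variance
    component from a one-way (by day) decomposition:
    CV_IP = sqrt(s_within² + s_between²) / grand mean.
    """
    rows = []
    for level in sorted(qc):
        days = {d: [v for v in vals if np.isfinite(v)] for d, vals in qc[level].items()}
        days = {d: vals for d, vals in days.items() if len(vals) >= 2}
        if len(days) < 2:
            raise ValueError(f"level {level}: need >= 2 days with >= 2 replicates")
        n_planned = sum(len(v) for v in qc[level].values())
        n_used = sum(len(v) for v in days.values())
        if n_used < (1.0 - max_missing_fraction) * n_planned:
            raise ValueError(f"level {level}: too many missing measurements")
        all_vals = np.concatenate([np.asarray(v, dtype=float) for v in days.values()])
        grand = all_vals.mean()
        # one-way ANOVA by day
        ss_within = sum(
            float(np.sum((np.asarray(v) - np.mean(v)) ** 2)) for v in days.values()
        )
        df_within = sum(len(v) - 1 for v in days.values())
        ms_within = ss_within / df_within
        day_means = np.array([np.mean(v) for v in days.values()])
        day_ns = np.array([len(v) for v in days.values()], dtype=float)
        ss_between = float(np.sum(day_ns * (day_means - grand) ** 2))
        ms_between = ss_between / (len(days) - 1)
        n0 = (day_ns.sum() - np.sum(day_ns**2) / day_ns.sum()) / (len(days) - 1)
        var_between = max(0.0, (ms_between - ms_within) / n0)
        repeatability = 100.0 * math.sqrt(ms_within) / grand
        intermediate = 100.0 * math.sqrt(ms_within + var_between) / grand
        rows.append(
            PrecisionRow(
                level=level,
                trueness_pct=100.0 * grand / level,
                repeatability_cv_pct=repeatability,
                intermediate_cv_pct=intermediate,
                n_days=len(days),
                n_total=int(n_used),
            )
        )
    return rows


# --------------------------------------------------------------------------
# Measurement glue: runs -> area ratios -> curves
# --------------------------------------------------------------------------


def _peak_area(
    run: Run, entry: CompoundEntry, ppm: float, rt_tol: float, min_snr: float
) -> tuple[float, float]:
    """(area, snr) of the XIC peak nearest the library RT, or (0, 0)."""
    mz = ion_mz(entry.neutral_formula, entry.adduct).mz
    xic = extract_xic(run, mz, ppm, ms_level=1)
    peaks = detect_peaks(xic, min_snr=min_snr)
    if entry.expected_rt is not None:
        peaks = [p for p in peaks if abs(p.apex_rt - entry.expected_rt) <= rt_tol]
    if not peaks:
        return 0.0, 0.0
    best = min(peaks, key=lambda p: abs(p.apex_rt - (entry.expected_rt or p.apex_rt)))
    return best.area, best.snr


def measure_area_ratio(
    run: Run,
    analyte: CompoundEntry,
    internal_standard: CompoundEntry,
    ppm: float = 5.0,
    rt_tol: float = 0.15,
    min_snr: float = 3.0,
) -> tuple[float, float]:
    """(analyte/IS area ratio, analyte S/N) measured on one run."""
    a_area, a_snr = _peak_area(run, analyte, ppm, rt_tol, min_snr)
    is_area, _ = _peak_area(run, internal_standard, ppm, rt_tol, min_snr)
    if is_area <= 0:
        raise ValueError(
            f"{internal_standard.name}: no internal-standard peak in run"
        )
    return a_area / is_area, a_snr


def build_calibration_from_runs(
    runs: list[Run],
    sheet: SampleSheet,
    library: list[CompoundEntry],
    analyte_names: list[str] | None = None,
    ppm: float = 5.0,
    rt_tol: float = 0.15,
) -> dict[str, CalibrationCurve]:
    """Measure calibrant runs and fit one 1/x-weighted curve per analyte."""
    by_name = {e.name: e for e in library}
    by_run_id = {r.metadata.get("run_id"): r for r in runs}
    analytes = [
        e
        for e in library
        if not e.is_internal_standard
        and e.internal_standard_ref
        and (analyte_names is None or e.name in analyte_names)
    ]
    curves = {}
    cal_rows = sheet.rows("calibrant")
    for entry in analytes:
        is_entry = by_name[entry.internal_standard_ref]
        per_level: dict[float, list[float]] = {}
        for _, row in cal_rows.iterrows():
            run = by_run_id[row["run_id"]]
            ratio, _ = measure_area_ratio(run, entry, is_entry, ppm, rt_tol)
            per_level.setdefault(float(row["level_uM"]), []).append(ratio)
        curves[entry.name] = fit_calibration(
            sorted(per_level.items()), analyte=entry.name
        )
    return curves
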