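"""Calibration and quantification of targeted urinary organic acids.

Two quantification modes mirror clinical practice:

* ``external_calibration`` — response ratio (analyte peak area / ISTD peak
  area) against a 6-point standard curve, ordinary least squares.
* ``relative_istd`` — for analytes without pure standards (surrogate- and
  medication markers): concentration = area ratio × spiked ISTD
  concentration, assuming a response factor equal to the ISTD's.

Concentrations are reported in µmol/L and, after creatinine normalization,
in µmol/mmol creatinine. LOD and LOQ are the concentrations at which the
signal-to-noise ratio reaches 3 and 10 respectively.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .panel import Panel, PanelEntry
from .signals_io import PeakList, PeakMeasurement, extract_eic, integrate_peak

__all__ = [
    "CalibrationCurve",
    "AnalyteResult",
    "SampleQuant",
    "Injection",
    "QCReport",
    "QuantError",
    "fit_calibration",
    "quantify",
    "quantify_relative",
    "estimate_lod_loq",
    "precision",
    "normalize_creatinine",
    "check_batch_qc",
    "measure_injection",
    "quantify_injection",
    "calibrate_batch",
]


class QuantError(ValueError):
    """Raised for degenerate designs, missing ISTD signal, or bad inputs."""


@dataclass
class CalibrationCurve:
    """OLS line of response ratio vs nominal concentration for one analyte."""

    analyte: str
    points: list[tuple[float, float]]  # (conc µmol/L, response ratio)
    slope: float
    intercept: float
    r2: float


@dataclass
class AnalyteResult:
    conc: float = 0.0  # µmol/L
    conc_norm: float = 0.0  # µmol/mmol creatinine
    below_lod: bool = False
    ambiguous: bool = False


@dataclass
class SampleQuant:
    """Per-sample quantification results for every panel analyte."""

    sample_id: str
    results: dict[str, AnalyteResult] = field(default_factory=dict)
    age_group: str | None = None
    creatinine_mm: float | None = None
    dilution_factor: float = 1.0

    def conc_norm(self, analyte: str) -> float:
        return self.results[analyte].conc_norm


def fit_calibration(
    points: list[tuple[float, float]],
    analyte: str = "",
    weighting: str | None = None,
) -> CalibrationCurve:
    """Fit response ratio vs concentration by (optionally 1/x-weighted) OLS.

    At least two distinct concentration levels are required; standard
    batches use six.
    """
    if len(points) < 2:
        raise QuantError(f"{analyte or 'calibration'}: need >= 2 points")
    conc = np.array([p[0] for p in points], dtype=float)
    ratio = np.array([p[1] for p in points], dtype=float)
    if np.allclose(conc, conc[0]):
        raise QuantError(
            f"{analyte or 'calibration'}: all concentrations identical "
            "(degenerate design)"
        )
    if weighting is None:
        fit = stats.linregress(conc, ratio)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    elif weighting == "1/x":
        w = np.where(conc > 0, 1.0 / np.maximum(conc, 1e-12), 0.0)
        if not np.any(w > 0):
            raise QuantError("1/x weighting needs at least one positive level")
        X = np.column_stack([np.ones_like(conc), conc])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], ratio * sw, rcond=None)
        intercept, slope = float(beta[0]), float(beta[1])
        pred = intercept + slope * conc
        sst = float(np.sum(w * (ratio - np.average(ratio, weights=w)) ** 2))
        ssr = float(np.sum(w * (ratio - pred) ** 2))
        r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    else:
        raise QuantError(f"unknown weighting {weighting!r}")
    return CalibrationCurve(analyte=analyte, points=list(points),
                            slope=slope, intercept=intercept, r2=r2)


def quantify(
    area_ratio: float, curve: CalibrationCurve, dilution_factor: float = 1.0
) -> tuple[float, bool]:
    """Back-calculate a concentration (µmol/L) from a response ratio.

    Returns (conc, below_lod); negative back-calculations clip to zero with
    the below-LOD flag set, for downstream imputation.
    """
    if curve.slope <= 0:
        raise QuantError(f"{curve.analyte}: non-positive calibration slope")
    conc = (area_ratio - curve.intercept) / curve.slope * dilution_factor
    if conc < 0:
        return 0.0, True
    return float(conc), False


def quantify_relative(
    analyte_area: float,
    istd_area: float,
    istd_conc: float,
    dilution_factor: float = 1.0,
) -> float:
    """Relative-ISTD concentration: area ratio × spiked ISTD concentration."""
    if istd_area <= 0:
        raise QuantError("ISTD area is zero: failed injection or missing spike")
    return analyte_area / istd_area * istd_conc * dilution_factor


def estimate_lod_loq(curve: CalibrationCurve, noise: float) -> tuple[float, float]:
    """LOD (S/N = 3) and LOQ (S/N = 10) in concentration units.

    ``noise`` is the response-ratio standard deviation of the blank signal;
    dividing by the calibration slope converts it to concentration.
    """
    if curve.slope <= 0:
        raise QuantError(f"{curve.analyte}: non-positive calibration slope")
    if noise < 0:
        raise QuantError("noise must be >= 0")
    return 3.0 * noise / curve.slope, 10.0 * noise / curve.slope


def precision(values) -> float:
    """Coefficient of variation (%) of replicate concentrations."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise QuantError("precision needs >= 2 replicates")
    mean = arr.mean()
    if mean <= 0:
        raise QuantError("CV undefined for non-positive mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def normalize_creatinine(conc: float, creatinine_mm: float) -> float:
    """µmol/L divided by mmol/L creatinine → µmol/mmol creatinine."""
    if creatinine_mm <= 0:
        raise QuantError("creatinine must be > 0 mmol/L (sample unreportable)")
    return conc / creatinine_mm


@dataclass
class Injection:
    """One position in the batch injection sequence."""

    position: int
    sample_id: str
    sample_type: str  # qc | blank | calibrant | patient | control


@dataclass
class QCReport:
    placement_ok: bool
    placement_issues: list[str] = field(default_factory=list)
    flagged_analytes: dict[str, float] = field(default_factory=dict)  # recovery %
    carryover_analytes: list[str] = field(default_factory=list)


def check_batch_qc(
    injections: list[Injection],
    qc_measured: dict[str, float] | None = None,
    qc_targets: dict[str, float] | None = None,
    tolerance_pct: float = 20.0,
    blank_areas: dict[str, float] | None = None,
    qc_areas: dict[str, float] | None = None,
    carryover_fraction: float = 0.05,
) -> QCReport:
    """Verify the batch QC scheme and QC analyte recoveries.

    Placement rule: a QC sample and a blank open the batch, and the pair is
    re-injected after every 24th sample. Analytes whose measured QC
    concentration deviates from its target by more than ``tolerance_pct``
    are flagged; a blank peak area above ``carryover_fraction`` of the QC
    area flags carry-over.
    """
    if not any(inj.sample_type == "qc" for inj in injections):
        raise QuantError("batch contains no QC injection")
    issues: list[str] = []
    seq = sorted(injections, key=lambda i: i.position)
    types = [i.sample_type for i in seq]
    if types[:2] != ["qc", "blank"]:
        issues.append("batch must start with a QC injection followed by a blank")
    pending = 0
    i = 2 if types[:2] == ["qc", "blank"] else 0
    while i < len(seq):
        t = types[i]
        if t in ("qc", "blank"):
            if t == "qc" and i + 1 < len(seq) and types[i + 1] == "blank":
                pending = 0
                i += 2
                continue
            i += 1
            continue
        pending += 1
        if pending > 24:
            issues.append(
                f"more than 24 samples since the last QC/blank pair "
                f"(at position {seq[i].position})"
            )
            pending = 0
        i += 1

    flagged: dict[str, float] = {}
    if qc_measured and qc_targets:
        for analyte, target in qc_targets.items():
            if target <= 0 or analyte not in qc_measured:
                continue
            recovery = 100.0 * qc_measured[analyte] / target
            if abs(recovery - 100.0) > tolerance_pct:
                flagged[analyte] = recovery

    carryover: list[str] = []
    if blank_areas and qc_areas:
        for analyte, blank_area in blank_areas.items():
            qc_area = qc_areas.get(analyte, 0.0)
            if qc_area > 0 and blank_area > carryover_fraction * qc_area:
                carryover.append(analyte)

    return QCReport(
        placement_ok=not issues,
        placement_issues=issues,
        flagged_analytes=flagged,
        carryover_analytes=sorted(carryover),
    )


# ---------------------------------------------------------------------------
# Batch orchestration: PeakList -> areas -> concentrations
# ---------------------------------------------------------------------------

def measure_injection(
    peaklist: PeakList,
    panel: Panel,
    mz_tol_ppm: float = 10.0,
    rt_window: float = 0.2,
) -> tuple[dict[str, PeakMeasurement], dict[str, PeakMeasurement]]:
    """Extract and integrate every panel analyte and ISTD in one injection.

    Returns (analyte measurements, ISTD measurements) keyed by name.
    """
    analyte_meas = {}
    for entry in panel.entries:
        eic = extract_eic(peaklist, entry.target_mz, mz_tol_ppm)
        analyte_meas[entry.name] = integrate_peak(eic, entry.rt, rt_window)
    istd_meas = {}
    for istd in panel.istds:
        eic = extract_eic(peaklist, istd.mz, mz_tol_ppm)
        istd_meas[istd.name] = integrate_peak(eic, istd.rt, rt_window)
    return analyte_meas, istd_meas


def _ambiguous_names(panel: Panel, mz_tol_ppm: float, rt_window: float) -> set[str]:
    """Analytes whose extraction window overlaps another panel entry's."""
    out: set[str] = set()
    entries = panel.entries
    for i, a in enumerate(entries):
        for b in entries[i + 1 :]:
            dppm = abs(a.target_mz - b.target_mz) / a.target_mz * 1e6
            if dppm <= mz_tol_ppm and abs(a.rt - b.rt) <= rt_window:
                out.update((a.name, b.name))
    return out


def calibrate_batch(
    calibrant_levels: list[tuple[dict[str, float], PeakList]],
    panel: Panel,
    mz_tol_ppm: float = 10.0,
    rt_window: float = 0.2,
    weighting: str | None = None,
) -> dict[str, CalibrationCurve]:
    """Fit per-analyte curves from calibrant injections.

    ``calibrant_levels`` pairs each injection with its nominal concentration
    map {analyte: µmol/L}. Only analytes quantified by external calibration
    get a curve.
    """
    points: dict[str, list[tuple[float, float]]] = {
        e.name: [] for e in panel.calibrated
    }
    for nominal, peaklist in calibrant_levels:
        analyte_meas, istd_meas = measure_injection(
            peaklist, panel, mz_tol_ppm, rt_window
        )
        for entry in panel.calibrated:
            if entry.name not in nominal:
                continue
            istd = istd_meas[entry.istd_name]
            if istd.area <= 0:
                raise QuantError(
                    f"{peaklist.sample_id}: ISTD {entry.istd_name} not found"
                )
            ratio = analyte_meas[entry.name].area / istd.area
            points[entry.name].append((nominal[entry.name], ratio))
    return {
        name: fit_calibration(pts, analyte=name, weighting=weighting)
        for name, pts in points.items()
        if len(pts) >= 2
    }


def quantify_injection(
    peaklist: PeakList,
    panel: Panel,
    curves: dict[str, CalibrationCurve],
    mz_tol_ppm: float = 10.0,
    rt_window: float = 0.2,
) -> SampleQuant:
    """Quantify one injection: areas → concentrations → creatinine-normalized.

    External-calibration analytes need a fitted curve; relative-ISTD
    analytes are computed from the area ratio and the spiked ISTD
    concentration. Peaks reported not-found carry the below-LOD flag.
    """
    analyte_meas, istd_meas = measure_injection(peaklist, panel, mz_tol_ppm, rt_window)
    ambiguous = _ambiguous_names(panel, mz_tol_ppm, rt_window)
    meta = peaklist.meta
    quant = SampleQuant(
        sample_id=peaklist.sample_id,
        age_group=meta.age_group,
        creatinine_mm=meta.creatinine_mm,
        dilution_factor=meta.dilution_factor,
    )
    for entry in panel.entries:
        meas = analyte_meas[entry.name]
        istd = istd_meas[entry.istd_name]
        result = AnalyteResult(ambiguous=entry.name in ambiguous)
        if istd.area <= 0:
            raise QuantError(
                f"{peaklist.sample_id}: ISTD {entry.istd_name} not found"
            )
        if not meas.found:
            result.below_lod = True
        elif entry.quant_mode == "external_calibration":
            curve = curves.get(entry.name)
            if curve is None:
                raise QuantError(f"no calibration curve for {entry.name}")
            ratio = meas.area / istd.area
            result.conc, result.below_lod = quantify(
                ratio, curve, meta.dilution_factor
            )
        else:
            istd_conc = panel.istd(entry.istd_name).conc_um
            result.conc = quantify_relative(
                meas.area, istd.area, istd_conc, meta.dilution_factor
            )
        if meta.creatinine_mm:
            result.conc_norm = normalize_creatinine(result.conc, meta.creatinine_mm)
        quant.results[entry.name] = result
    return quant
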