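"""Synthetic cohorts, IEM cases, and instrument-level data.

The generator emulates the study design end to end so every pipeline stage
runs offline: control cohorts with log-normal analyte levels in two age
groups, IEM cases as fold-change elevations of designated biomarkers,
6-level calibration batches with QC/blank placement, and centroided
full-scan peak lists with Gaussian chromatographic peaks at the panel
retention times.

Defaults define the emulated study conditions: 46 controls per age group,
log2-SD 0.5 around a geometric-mean normalized concentration of twice each
analyte's low calibration limit, LOD at one tenth of that limit, and — as
in real normal urine — no detectable surrogate-standard or medication
analytes in controls. Everything is seeded; there is no global random
state.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import Panel, load_disease_markers
from .quant import AnalyteResult, Injection, SampleQuant
from .signals_io import PeakList, SampleMeta, write_peaklist_tsv

__all__ = [
    "CohortSpec",
    "CaseSpec",
    "InstrumentModel",
    "SynthError",
    "default_cohort_spec",
    "default_case_specs",
    "simulate_cohort",
    "simulate_case",
    "render_sample",
    "render_instrument_data",
    "calibration_levels",
]

CONTROL_SD_LOG2 = 0.5
N_CAL_LEVELS = 6
QC_INTERVAL = 24


class SynthError(ValueError):
    """Raised for inconsistent simulation specifications."""


@dataclass
class CohortSpec:
    """Control-cohort generating parameters.

    ``analyte_params`` maps detected analytes to (mean_log2, sd_log2) of the
    normalized concentration (log2 µmol/mmol creatinine); analytes absent
    from the map are never detected in controls. ``lods`` are normalized
    LODs (µmol/mmol).
    """

    analyte_params: dict[str, tuple[float, float]]
    lods: dict[str, float]
    n_per_group: int = 46
    creatinine_median_mm: float = 1.0
    creatinine_sd_log2: float = 0.5
    creatinine_range_mm: tuple[float, float] = (0.1, 2.0)
    dilution_factor: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise SynthError("need >= 2 controls per age group")
        for name, (_, sd) in self.analyte_params.items():
            if sd < 0:
                raise SynthError(f"{name}: sd must be >= 0")


@dataclass
class CaseSpec:
    """An IEM case: biomarkers elevated as fold-changes over control means.

    ``medication_markers`` lists medication analytes present in the urine
    (rendered at ``medication_fold`` times their LOD).
    """

    disease: str
    fold_changes: dict[str, float]
    medication_markers: list[str] = field(default_factory=list)
    medication_fold: float = 50.0

    def __post_init__(self) -> None:
        for name, fold in self.fold_changes.items():
            if fold <= 0:
                raise SynthError(f"{name}: fold-change must be > 0")


@dataclass
class InstrumentModel:
    """Instrument response model for rendering peak lists.

    ``response_factor`` is peak area (counts·min) per µmol/L in the
    injected solution, applied to analytes and ISTDs alike; ``sigma_rt`` is
    the Gaussian peak SD in minutes; ``noise_sd`` the per-scan baseline
    noise SD in counts; ``mass_error_ppm_sd`` the per-peak mass-accuracy
    draw typical of a calibrated QTOF.
    """

    response_factor: float = 500.0
    sigma_rt: float = 0.008
    noise_sd: float = 0.0
    scan_rate_hz: float = 8.0
    mass_error_ppm_sd: float = 0.0
    rt_span: tuple[float, float] = (0.3, 9.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.response_factor <= 0 or self.sigma_rt <= 0:
            raise SynthError("response_factor and sigma_rt must be > 0")


def default_cohort_spec(panel: Panel, seed: int = 0, **overrides) -> CohortSpec:
    """Study-condition defaults derived from the panel calibration ranges."""
    params: dict[str, tuple[float, float]] = {}
    lods: dict[str, float] = {}
    for entry in panel.entries:
        if entry.quant_mode == "external_calibration":
            params[entry.name] = (math.log2(2.0 * entry.calib_low), CONTROL_SD_LOG2)
            lods[entry.name] = entry.calib_low / 10.0
        else:
            # surrogate-standard and medication analytes: absent in controls
            lods[entry.name] = 1.0
    return CohortSpec(analyte_params=params, lods=lods, seed=seed, **overrides)


def default_case_specs() -> dict[str, CaseSpec]:
    """Built-in IEM case specifications from the packaged disease map.

    Fold-changes put the designated biomarkers at z ≈ 5–15 given the
    default control log2-SD of 0.5.
    """
    markers = load_disease_markers()
    folds = {
        "IVA": {"Isovalerylglycine": 50.0, "3-Hydroxyisovaleric acid": 20.0},
        "MCADD": {"Hexanoylglycine": 30.0, "Suberylglycine": 30.0,
                  "Phenylpropionylglycine": 30.0},
        "PA": {"Propionylglycine": 30.0, "2-Methylcitric acid": 25.0,
               "3-Hydroxypropionic acid": 25.0, "Tiglylglycine": 10.0},
        "GA1": {"3-Hydroxyglutaric acid": 40.0, "Glutaric acid": 30.0},
        "MMA": {"Methylmalonic acid": 50.0, "2-Methylcitric acid": 10.0},
        "MSUD": {"2-Hydroxy-3-methylpentanoic acid": 40.0,
                 "2-Hydroxy-3-methylbutyric acid": 40.0,
                 "3-Methyl-2-oxovaleric acid": 15.0,
                 "alpha-Ketoisovaleric acid": 15.0},
        "OXOPRO": {"Pyroglutamic acid": 30.0},
    }
    out = {}
    for disease, fc in folds.items():
        assert set(fc) <= set(markers[disease]["biomarkers"]) | set(fc)
        out[disease] = CaseSpec(disease=disease, fold_changes=fc)
    return out


def _draw_sample(
    rng: np.random.Generator,
    spec: CohortSpec,
    panel: Panel,
    sample_id: str,
    age_group: str,
) -> SampleQuant:
    lo, hi = spec.creatinine_range_mm
    creat = float(np.clip(
        spec.creatinine_median_mm
        * 2.0 ** rng.normal(0.0, spec.creatinine_sd_log2),
        lo, hi,
    ))
    sq = SampleQuant(
        sample_id=sample_id,
        age_group=age_group,
        creatinine_mm=creat,
        dilution_factor=spec.dilution_factor,
    )
    for entry in panel.entries:
        name = entry.name
        lod = spec.lods[name]
        if name in spec.analyte_params:
            mean_log2, sd_log2 = spec.analyte_params[name]
            conc_norm = float(2.0 ** rng.normal(mean_log2, sd_log2))
            below = conc_norm < lod
        else:
            conc_norm = 0.0
            below = True
        sq.results[name] = AnalyteResult(
            conc=conc_norm * creat,
            conc_norm=conc_norm,
            below_lod=below,
        )
    return sq


def simulate_cohort(
    spec: CohortSpec, panel: Panel, age_groups: tuple[str, ...] = ("0-2y", ">2y")
) -> tuple[list[SampleQuant], pd.DataFrame]:
    """Draw a control cohort; returns (samples, ground-truth table).

    Deterministic for a fixed ``spec.seed``. The truth table records the
    drawn normalized concentration per sample and analyte.
    """
    rng = np.random.default_rng(spec.seed)
    samples: list[SampleQuant] = []
    records = []
    for group in age_groups:
        tag = group.replace(">", "gt").replace("-", "_")
        for i in range(spec.n_per_group):
            sq = _draw_sample(rng, spec, panel, f"ctrl-{tag}-{i:03d}", group)
            samples.append(sq)
            for name, res in sq.results.items():
                records.append(
                    {"sample_id": sq.sample_id, "age_group": group,
                     "analyte": name, "conc_norm": res.conc_norm}
                )
    return samples, pd.DataFrame.from_records(records)


def simulate_case(
    case: CaseSpec,
    spec: CohortSpec,
    panel: Panel,
    age_group: str = "0-2y",
    seed: int | None = None,
    sample_id: str | None = None,
) -> SampleQuant:
    """Draw one IEM case: a control draw with designated biomarkers scaled.

    Biomarkers detected in controls are multiplied by their fold-change;
    biomarkers absent from the control distribution (surrogate-standard
    analytes) are placed at fold × LOD. Medication markers, when specified,
    appear at ``medication_fold`` × LOD.
    """
    names = set(panel.names)
    unknown = (set(case.fold_changes) | set(case.medication_markers)) - names
    if unknown:
        raise SynthError(f"{case.disease}: biomarkers not in panel: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sq = _draw_sample(
        rng, spec, panel,
        sample_id or f"case-{case.disease}", age_group,
    )
    for name, fold in case.fold_changes.items():
        res = sq.results[name]
        if name in spec.analyte_params:
            conc_norm = res.conc_norm * fold
        else:
            conc_norm = spec.lods[name] * fold
        sq.results[name] = AnalyteResult(
            conc=conc_norm * sq.creatinine_mm,
            conc_norm=conc_norm,
            below_lod=conc_norm < spec.lods[name],
        )
    for name in case.medication_markers:
        conc_norm = spec.lods[name] * case.medication_fold
        sq.results[name] = AnalyteResult(
            conc=conc_norm * sq.creatinine_mm,
            conc_norm=conc_norm,
            below_lod=False,
        )
    return sq


# ---------------------------------------------------------------------------
# Instrument-level rendering
# ---------------------------------------------------------------------------

def calibration_levels(panel: Panel, n_levels: int = N_CAL_LEVELS) -> list[dict[str, float]]:
    """Per-level nominal concentrations spanning each calibration range.

    Level k holds, for every calibrated analyte, the k-th of ``n_levels``
    log-spaced concentrations between its low and high calibration limits.
    """
    levels: list[dict[str, float]] = [dict() for _ in range(n_levels)]
    for entry in panel.calibrated:
        concs = np.geomspace(entry.calib_low, entry.calib_high, n_levels)
        for k in range(n_levels):
            levels[k][entry.name] = float(concs[k])
    return levels


def simulate_calibration_r2(
    panel: Panel,
    seed: int = 42,
    noise_cv: float = 0.05,
    n_levels: int = N_CAL_LEVELS,
) -> dict[str, float]:
    """Coefficient of determination of simulated calibration fits.

    For every calibrated analyte, generates ``n_levels`` log-spaced levels
    spanning its calibration range with multiplicative response noise
    (response ratio = slope × conc × (1 + e), e ~ Normal(0, noise_cv)),
    fits the OLS line, and returns {analyte: r2}.
    """
    from .quant import fit_calibration

    rng = np.random.default_rng(seed)
    r2: dict[str, float] = {}
    for entry in panel.calibrated:
        concs = np.geomspace(entry.calib_low, entry.calib_high, n_levels)
        slope = 1.0 / math.sqrt(entry.calib_low * entry.calib_high)
        ratios = slope * concs * (1.0 + rng.normal(0.0, noise_cv, n_levels))
        curve = fit_calibration(list(zip(concs, ratios)), analyte=entry.name)
        r2[entry.name] = curve.r2
    return r2


def render_sample(
    concs_injected: dict[str, float],
    sample_id: str,
    panel: Panel,
    model: InstrumentModel,
    rng: np.random.Generator,
    meta: SampleMeta | None = None,
    include_istds: bool = True,
) -> PeakList:
    """Render one injection as a centroided peak list.

    ``concs_injected`` are concentrations in the injected solution
    (µmol/L). Each species becomes a Gaussian chromatographic peak at its
    panel retention time with area = response_factor × concentration, a
    centroid per scan at the target m/z (± a per-peak mass-accuracy draw),
    plus optional per-scan baseline noise at every monitored m/z.
    """
    t0, t1 = model.rt_span
    dt = 1.0 / (model.scan_rate_hz * 60.0)
    rts = np.arange(t0, t1, dt)
    n_scans = len(rts)

    species: list[tuple[float, float, float]] = []  # (mz, rt, conc)
    for entry in panel.entries:
        conc = concs_injected.get(entry.name, 0.0)
        if conc > 0:
            species.append((entry.target_mz, entry.rt, conc))
    if include_istds:
        for istd in panel.istds:
            species.append((istd.mz, istd.rt, istd.conc_um))

    # accumulate per-scan centroid lists keyed by monitored m/z channel
    channel_mz = sorted({round(mz, 5) for mz, _, _ in species}
                        | {round(e.target_mz, 5) for e in panel.entries}
                        | {round(i.mz, 5) for i in panel.istds})
    signal = {mz: np.zeros(n_scans) for mz in channel_mz}
    obs_mz = {mz: mz for mz in channel_mz}

    sigma = model.sigma_rt
    norm = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
    for mz, rt, conc in species:
        key = round(mz, 5)
        area = model.response_factor * conc
        lo = np.searchsorted(rts, rt - 4.0 * sigma)
        hi = np.searchsorted(rts, rt + 4.0 * sigma)
        window = rts[lo:hi]
        signal[key][lo:hi] += area * norm * np.exp(
            -0.5 * ((window - rt) / sigma) ** 2
        )
        if model.mass_error_ppm_sd > 0:
            obs_mz[key] = mz * (
                1.0 + rng.normal(0.0, model.mass_error_ppm_sd) * 1e-6
            )

    if model.noise_sd > 0:
        for key in channel_mz:
            signal[key] += np.abs(rng.normal(0.0, model.noise_sd, n_scans))

    scans = []
    keys = np.array(channel_mz)
    observed = np.array([obs_mz[k] for k in channel_mz])
    stack = np.vstack([signal[k] for k in channel_mz])  # channels x scans
    for k in range(n_scans):
        inten = stack[:, k]
        mask = inten > 0
        order = np.argsort(observed[mask])
        scans.append((float(rts[k]), observed[mask][order], inten[mask][order]))
    return PeakList(sample_id=sample_id, scans=scans, meta=meta or SampleMeta())


def render_instrument_data(
    sample_truths: list[tuple[str, SampleMeta, dict[str, float]]],
    panel: Panel,
    model: InstrumentModel,
    out_dir: str | Path | None = None,
    qc_concs: dict[str, float] | None = None,
) -> tuple[list[PeakList], list[Injection], pd.DataFrame, list[dict[str, float]]]:
    """Render a full analytical batch: QC, blank, calibrants, then samples.

    ``sample_truths`` gives, per sample, the urine concentrations (µmol/L);
    the injected solution is urine / dilution factor. A QC sample and a
    blank open the batch and are re-injected after every 24th sample.
    Returns (peak lists, injection sequence, manifest, calibrant levels);
    with ``out_dir`` set, peak-list TSVs and a manifest CSV are written.
    """
    rng = np.random.default_rng(model.seed)
    levels = calibration_levels(panel)
    if qc_concs is None:
        qc_concs = {
            e.name: float(math.sqrt(e.calib_low * e.calib_high))
            for e in panel.calibrated
        }

    peaklists: list[PeakList] = []
    injections: list[Injection] = []
    rows = []
    pos = 0

    def add(sample_id: str, stype: str, concs: dict[str, float],
            meta: SampleMeta, level: int | None = None) -> None:
        nonlocal pos
        pos += 1
        pl = render_sample(concs, sample_id, panel, model, rng, meta=meta)
        peaklists.append(pl)
        injections.append(Injection(position=pos, sample_id=sample_id,
                                    sample_type=stype))
        rows.append({
            "position": pos, "sample_id": sample_id, "sample_type": stype,
            "age_group": meta.age_group or "",
            "creatinine_mm": meta.creatinine_mm or "",
            "dilution_factor": meta.dilution_factor,
            "cal_level": "" if level is None else level,
        })

    def add_qc_blank() -> None:
        add("QC", "qc", qc_concs, SampleMeta(sample_type="qc"))
        add("BLANK", "blank", {}, SampleMeta(sample_type="blank"))

    add_qc_blank()
    for k, level in enumerate(levels, start=1):
        add(f"CAL{k}", "calibrant", level,
            SampleMeta(sample_type="calibrant"), level=k)
    since_qc = 0
    for sample_id, meta, urine_concs in sample_truths:
        if since_qc >= QC_INTERVAL:
            add_qc_blank()
            since_qc = 0
        injected = {
            name: conc / meta.dilution_factor for name, conc in urine_concs.items()
        }
        add(sample_id, meta.sample_type, injected, meta)
        since_qc += 1
    if since_qc >= QC_INTERVAL:
        add_qc_blank()

    manifest = pd.DataFrame.from_records(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for pl, inj in zip(peaklists, injections):
            write_peaklist_tsv(pl, out_dir / f"{inj.position:03d}_{pl.sample_id}.tsv")
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return peaklists, injections, manifest, levels
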