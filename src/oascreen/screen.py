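"""Age-stratified reference intervals and diagnostic z-score profiles.

Creatinine-normalized concentrations are log2-transformed and standardized
against a control cohort in two age groups (0-2 years and >2 years).
Missing values and values below the limit of detection are imputed with the
LOD before the log transform. Analytes never detected in controls get a
fixed log2 SD of 0.774 = log2(5)/3, so that a measurement at five times the
LOD reports a z-score of exactly 3 — the convention that makes "detected at
all" interpretable on the same scale as true reference intervals.

A z-score profile plots z per analyte in panel order with guide lines at
±2.5 (borderline) and ±3.0 (significant); most inborn errors of metabolism
show their diagnostic biomarkers well above +3.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .panel import Panel
from .quant import SampleQuant

__all__ = [
    "AGE_GROUPS",
    "ND_SD_LOG2",
    "RefEntry",
    "ReferenceStats",
    "ZScoreProfile",
    "ScreenError",
    "assign_age_group",
    "build_reference",
    "zscore",
    "profile_sample",
    "render_profile_plot",
]

AGE_GROUPS = ("0-2y", ">2y")

#: Fixed log2 SD for analytes not detected in any control: log2(5)/3, i.e.
#: five times the LOD maps to z = 3.
ND_SD_LOG2 = 0.774

#: Degenerate-cohort floor on the estimated log2 SD (robustness guard).
SD_FLOOR_LOG2 = 0.1

BORDERLINE_Z = 2.5
SIGNIFICANT_Z = 3.0


class ScreenError(ValueError):
    """Raised for invalid cohorts, age groups, or profiles."""


def assign_age_group(age_years: float) -> str:
    """Map an age in years onto the two reference groups (2.0 -> '0-2y')."""
    return AGE_GROUPS[0] if age_years <= 2.0 else AGE_GROUPS[1]


@dataclass
class RefEntry:
    """Reference statistics for one analyte in one age group."""

    mean_log2: float
    sd_log2: float
    n: int
    lod_norm: float  # µmol/mmol creatinine
    not_detected: bool = False


@dataclass
class ReferenceStats:
    """Per-analyte, per-age-group log2 reference statistics."""

    groups: dict[str, dict[str, RefEntry]]
    version: str = "1"

    def entry(self, age_group: str, analyte: str) -> RefEntry:
        if age_group not in self.groups:
            raise ScreenError(
                f"unknown age group {age_group!r}; have {sorted(self.groups)}"
            )
        return self.groups[age_group][analyte]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "groups": {
                g: {a: vars(e) for a, e in entries.items()}
                for g, entries in self.groups.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceStats":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        groups = {
            g: {a: RefEntry(**e) for a, e in entries.items()}
            for g, entries in payload["groups"].items()
        }
        return cls(groups=groups, version=str(payload.get("version", "1")))


def build_reference(
    controls: list[SampleQuant],
    lods: dict[str, float],
    analytes: list[str] | None = None,
    sd_floor: float = SD_FLOOR_LOG2,
    nd_sd: float = ND_SD_LOG2,
) -> ReferenceStats:
    """Estimate reference statistics from a control cohort.

    Controls must carry an age group. Per analyte and age group, missing
    and below-LOD values are imputed with the LOD before log2; an analyte
    imputed in *every* control is marked not-detected and assigned
    mean = log2(LOD) and the fixed SD ``nd_sd``. Estimated SDs below
    ``sd_floor`` (degenerate cohorts) are raised to the floor.
    """
    if not controls:
        raise ScreenError("empty control cohort")
    by_group: dict[str, list[SampleQuant]] = {}
    for sample in controls:
        if sample.age_group is None:
            raise ScreenError(f"{sample.sample_id}: control lacks an age group")
        by_group.setdefault(sample.age_group, []).append(sample)

    if analytes is None:
        seen: list[str] = []
        for sample in controls:
            for name in sample.results:
                if name not in seen:
                    seen.append(name)
        analytes = seen

    groups: dict[str, dict[str, RefEntry]] = {}
    for group, samples in by_group.items():
        if len(samples) < 2:
            raise ScreenError(f"age group {group!r}: need >= 2 controls")
        entries: dict[str, RefEntry] = {}
        for analyte in analytes:
            lod = lods.get(analyte, 0.0)
            if lod <= 0:
                raise ScreenError(f"{analyte}: LOD must be > 0")
            values = []
            n_imputed = 0
            for sample in samples:
                res = sample.results.get(analyte)
                if res is None or res.below_lod or res.conc_norm < lod:
                    values.append(lod)
                    n_imputed += 1
                else:
                    values.append(res.conc_norm)
            log_values = np.log2(values)
            if n_imputed == len(values):
                entries[analyte] = RefEntry(
                    mean_log2=float(math.log2(lod)),
                    sd_log2=nd_sd,
                    n=len(values),
                    lod_norm=lod,
                    not_detected=True,
                )
            else:
                sd = float(np.std(log_values, ddof=1))
                entries[analyte] = RefEntry(
                    mean_log2=float(np.mean(log_values)),
                    sd_log2=max(sd, sd_floor),
                    n=len(values),
                    lod_norm=lod,
                    not_detected=False,
                )
        groups[group] = entries
    return ReferenceStats(groups=groups)


def zscore(conc_norm: float, ref: RefEntry) -> float:
    """Standardized log2 deviation from the reference, LOD-imputed.

    Values at or below the LOD are set to the LOD first, so a not-detected
    analyte measured below LOD scores exactly 0 and one at five times the
    LOD scores 3 (with the fixed SD 0.774).
    """
    value = max(conc_norm, ref.lod_norm)
    return (math.log2(value) - ref.mean_log2) / ref.sd_log2


def _flag(z: float, borderline: float, significant: float) -> str:
    if z > significant:
        return "elevated"
    if z > borderline:
        return "borderline"
    if z < -borderline:
        return "decreased"
    return "normal"


@dataclass
class ZScoreProfile:
    """Per-sample screening profile: z and flag for every panel analyte."""

    sample_id: str
    age_group: str
    analytes: list[str]
    conc_norm: dict[str, float] = field(default_factory=dict)
    z: dict[str, float] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)

    @property
    def flagged(self) -> dict[str, str]:
        return {a: f for a, f in self.flags.items() if f != "normal"}


def profile_sample(
    sample: SampleQuant,
    ref: ReferenceStats,
    panel: Panel,
    borderline: float = BORDERLINE_Z,
    significant: float = SIGNIFICANT_Z,
) -> ZScoreProfile:
    """Score one sample against the age-matched reference statistics.

    Flags: elevated (z > significant), borderline (borderline < z <=
    significant), decreased (z < -borderline), else normal.
    """
    if sample.age_group not in ref.groups:
        raise ScreenError(
            f"{sample.sample_id}: age group {sample.age_group!r} not in reference"
        )
    entries = ref.groups[sample.age_group]
    profile = ZScoreProfile(
        sample_id=sample.sample_id,
        age_group=sample.age_group,
        analytes=panel.names,
    )
    for entry in panel.entries:
        name = entry.name
        if name not in entries:
            raise ScreenError(f"reference lacks analyte {name!r}")
        res = sample.results.get(name)
        conc = 0.0 if res is None or res.below_lod else res.conc_norm
        z = zscore(conc, entries[name])
        profile.conc_norm[name] = conc
        profile.z[name] = z
        profile.flags[name] = _flag(z, borderline, significant)
    return profile


def render_profile_plot(profile: ZScoreProfile, out_path: str | Path) -> Path:
    """Write the z-score profile plot (one marker per analyte, panel order).

    Guide lines mark ±2.5 and ±3.0; flagged analytes are highlighted and
    labeled. Deterministic for a given profile.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = profile.analytes
    z = np.array([profile.z[n] for n in names])
    flagged = np.array([profile.flags[n] != "normal" for n in names])
    x = np.arange(len(names))

    fig, ax = plt.subplots(figsize=(14, 5))
    ax.axhspan(-BORDERLINE_Z, BORDERLINE_Z, color="0.93", zorder=0)
    for level, style in ((BORDERLINE_Z, ":"), (SIGNIFICANT_Z, "--")):
        for sign in (1, -1):
            ax.axhline(sign * level, color="0.4", linestyle=style, linewidth=0.8)
    ax.plot(x[~flagged], z[~flagged], "o", color="tab:blue", markersize=4)
    if flagged.any():
        ax.plot(x[flagged], z[flagged], "o", color="tab:red", markersize=6)
        for xi, zi, name in zip(x[flagged], z[flagged], np.array(names)[flagged]):
            ax.annotate(name, (xi, zi), fontsize=7, rotation=60,
                        textcoords="offset points", xytext=(2, 4))
    ax.set_xticks(x)
    ax.set_xticklabels(names, rotation=90, fontsize=5)
    ax.set_ylabel("z-score (log2 scale)")
    ax.set_title(f"{profile.sample_id} (age group {profile.age_group})")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
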