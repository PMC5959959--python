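"""Targeted organic-acid panel: data model, mass arithmetic, feature matching.

The panel covers 75 urinary analytes (71 disease markers, 4 medication
markers) monitored as deprotonated ions in negative-mode electrospray, each
paired with one of 19 stable-isotope-labeled internal standards (ISTDs).
A transcription of the published panel ships with the package
(``data/table1_panel.csv`` / ``data/table1_istds.csv``); molecular formulas
were assigned from the analyte identities and validated against the printed
ion m/z values (see :func:`validate_masses`).
"""
from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "PROTON_MASS",
    "PanelEntry",
    "Istd",
    "Panel",
    "MatchResult",
    "PanelValidationError",
    "monoisotopic_mass",
    "mz_deprotonated",
    "isotope_shift",
    "load_panel",
    "load_default_panel",
    "write_panel",
    "match_feature",
    "validate_masses",
    "load_disease_markers",
]

# IUPAC 2021 monoisotopic atomic masses (Da); panel scope is CHNOS.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

#: Mass of a proton (Da): removing H and keeping the electron, M - H + e-.
PROTON_MASS = 1.007276466

#: Mass added per 2H (D) or 13C label relative to the light isotope.
DEUTERIUM_SHIFT = 2.01410177785 - MONOISOTOPIC_MASS["H"]
CARBON13_SHIFT = 13.00335483507 - MONOISOTOPIC_MASS["C"]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class PanelValidationError(ValueError):
    """Raised when a panel file violates the panel schema or invariants."""


def _parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise PanelValidationError(
                f"cannot parse formula {formula!r} at position {pos}"
            )
        pos = match.end()
        element, digits = match.groups()
        if not element:
            continue
        if element not in MONOISOTOPIC_MASS:
            raise PanelValidationError(
                f"unknown element {element!r} in formula {formula!r}"
            )
        n = int(digits) if digits else 1
        if n <= 0:
            raise PanelValidationError(f"non-positive count in formula {formula!r}")
        counts[element] = counts.get(element, 0) + n
    if pos != len(formula):
        raise PanelValidationError(f"cannot parse formula {formula!r}")
    return counts


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of a CHNOS molecular formula.

    An empty formula is the empty sum, 0.0.
    """
    counts = _parse_formula(formula)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items())


def mz_deprotonated(formula: str) -> float:
    """m/z of the [M-H]- ion: monoisotopic mass minus a proton.

    The molecule must contain at least one hydrogen to lose.
    """
    counts = _parse_formula(formula)
    if counts.get("H", 0) < 1:
        raise PanelValidationError(
            f"formula {formula!r} has no hydrogen to deprotonate"
        )
    return monoisotopic_mass(formula) - PROTON_MASS


def isotope_shift(n_deuterium: int = 0, n_carbon13: int = 0) -> float:
    """Mass shift (Da) of a stable-isotope label (2H and/or 13C atoms)."""
    return n_deuterium * DEUTERIUM_SHIFT + n_carbon13 * CARBON13_SHIFT


@dataclass(frozen=True)
class PanelEntry:
    """One targeted analyte of the panel.

    ``target_mz`` is the monitored negative-mode ion, normally [M-H]- of
    ``formula``; when ``is_fragment`` is true it is an in-source fragment and
    is stored verbatim. ``quant_mode`` is ``external_calibration`` for the 68
    analytes with a calibration range and ``relative_istd`` for the
    surrogate-standard and medication analytes (no range).
    """

    name: str
    hmdb_id: str
    formula: str | None
    target_mz: float
    rt: float
    istd_name: str
    calib_low: float | None
    calib_high: float | None
    category: str  # "disease" | "medication"
    quant_mode: str  # "external_calibration" | "relative_istd"
    is_fragment: bool = False

    def __post_init__(self) -> None:
        errors = []
        if self.target_mz <= 0:
            errors.append("target_mz must be > 0")
        if self.rt < 0:
            errors.append("rt must be >= 0")
        if self.category not in ("disease", "medication"):
            errors.append(f"unknown category {self.category!r}")
        if self.quant_mode not in ("external_calibration", "relative_istd"):
            errors.append(f"unknown quant_mode {self.quant_mode!r}")
        has_range = self.calib_low is not None and self.calib_high is not None
        if has_range and self.calib_low >= self.calib_high:
            errors.append("calib_low must be < calib_high")
        if has_range != (self.quant_mode == "external_calibration"):
            errors.append(
                "calibration range must be present exactly for "
                "external_calibration analytes"
            )
        if errors:
            raise PanelValidationError(f"{self.name}: " + "; ".join(errors))


@dataclass(frozen=True)
class Istd:
    """A stable-isotope-labeled internal standard.

    ``mz`` is computed from the unlabeled base formula plus the label shift;
    ``conc_um`` is the spiked concentration in the injected sample (µmol/L).
    """

    name: str
    base_formula: str
    n_deuterium: int
    n_carbon13: int
    rt: float
    conc_um: float

    @property
    def mz(self) -> float:
        return mz_deprotonated(self.base_formula) + isotope_shift(
            self.n_deuterium, self.n_carbon13
        )


@dataclass
class Panel:
    """Ordered analyte entries plus the ISTD records they reference."""

    entries: list[PanelEntry]
    istds: list[Istd] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise PanelValidationError(f"duplicate analyte names: {sorted(dupes)}")
        known = {i.name for i in self.istds}
        dangling = sorted(
            {e.istd_name for e in self.entries} - known
        )
        if dangling:
            raise PanelValidationError(f"dangling ISTD references: {dangling}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, name: str) -> PanelEntry:
        for entry in self.entries:
            if entry.name == name:
                return entry
        raise KeyError(name)

    def istd(self, name: str) -> Istd:
        for istd in self.istds:
            if istd.name == name:
                return istd
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def calibrated(self) -> list[PanelEntry]:
        return [e for e in self.entries if e.quant_mode == "external_calibration"]


@dataclass
class MatchResult:
    """Panel entries matching an observed feature, best match first."""

    entries: list[PanelEntry]
    ambiguous: bool

    def __bool__(self) -> bool:
        return bool(self.entries)


def _row_to_entry(row: dict, line_no: int) -> PanelEntry:
    def opt_float(key: str) -> float | None:
        raw = (row.get(key) or "").strip()
        return float(raw) if raw else None

    try:
        return PanelEntry(
            name=row["name"].strip(),
            hmdb_id=row["hmdb_id"].strip(),
            formula=(row.get("formula") or "").strip() or None,
            target_mz=float(row["target_mz"]),
            rt=float(row["rt"]),
            istd_name=row["istd"].strip(),
            calib_low=opt_float("calib_low"),
            calib_high=opt_float("calib_high"),
            category=row["category"].strip(),
            quant_mode=row["quant_mode"].strip(),
            is_fragment=str(row.get("is_fragment", "0")).strip() in ("1", "true", "True"),
        )
    except (KeyError, ValueError) as exc:
        if isinstance(exc, PanelValidationError):
            raise PanelValidationError(f"row {line_no}: {exc}") from None
        raise PanelValidationError(f"row {line_no}: {exc!r}") from None


def _load_istds(path: Path) -> list[Istd]:
    istds = []
    with open(path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                istds.append(
                    Istd(
                        name=row["name"].strip(),
                        base_formula=row["base_formula"].strip(),
                        n_deuterium=int(row["n_deuterium"]),
                        n_carbon13=int(row["n_carbon13"]),
                        rt=float(row["rt"]),
                        conc_um=float(row["conc_um"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise PanelValidationError(f"{path} row {i}: {exc!r}") from None
    return istds


def load_panel(path: str | Path, istd_path: str | Path | None = None) -> Panel:
    """Load and validate a panel from CSV (or JSON written by write_panel).

    CSV panels take the ISTD table from ``istd_path`` (default: sibling file
    ``<stem>_istds.csv`` or the packaged ISTD table). All schema violations
    are reported with their row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        try:
            entries = [PanelEntry(**row) for row in payload["entries"]]
            istds = [Istd(**row) for row in payload["istds"]]
        except (KeyError, TypeError) as exc:
            raise PanelValidationError(f"{path}: {exc!r}") from None
        return Panel(entries=entries, istds=istds)

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        entries = [_row_to_entry(row, i) for i, row in enumerate(reader, start=2)]
    if istd_path is None:
        sibling = path.with_name(path.stem + "_istds.csv")
        alt = path.with_name("table1_istds.csv")
        if sibling.exists():
            istd_path = sibling
        elif alt.exists():
            istd_path = alt
        else:
            istd_path = _packaged("table1_istds.csv")
    istds = _load_istds(Path(istd_path))
    return Panel(entries=entries, istds=istds)


def _packaged(name: str) -> Path:
    return Path(resources.files("oascreen").joinpath("data", name))  # type: ignore[arg-type]


def load_default_panel() -> Panel:
    """The packaged 75-analyte panel with its 19 ISTDs."""
    return load_panel(_packaged("table1_panel.csv"), _packaged("table1_istds.csv"))


def load_disease_markers() -> dict:
    """Packaged disease-to-biomarker map (interpretive aid, editable copy)."""
    return json.loads(_packaged("disease_markers.json").read_text(encoding="utf-8"))


def write_panel(panel: Panel, path: str | Path) -> None:
    """Serialize a panel to JSON; load_panel round-trips it identically."""
    path = Path(path)
    payload = {
        "entries": [asdict(e) for e in panel.entries],
        "istds": [asdict(i) for i in panel.istds],
    }
    path.write_text(json.dumps(payload, indent=1), encoding="utf-8")


def match_feature(
    panel: Panel,
    mz: float,
    rt: float,
    mz_tol_ppm: float = 10.0,
    rt_tol_min: float = 0.2,
) -> MatchResult:
    """Panel entries consistent with an observed (m/z, RT) feature.

    Matches require both |Δm/z| within the ppm tolerance and |ΔRT| within
    the RT tolerance; results are ranked by RT closeness, then mass
    closeness. More than one surviving entry (isobaric isomers such as
    adipic vs 3-methylglutaric acid) sets the ambiguity flag — such peaks
    need the full biomarker profile and clinical context to resolve.
    """
    if mz_tol_ppm <= 0 or rt_tol_min <= 0:
        raise ValueError("tolerances must be > 0")
    hits = []
    for entry in panel.entries:
        dmz = abs(mz - entry.target_mz)
        drt = abs(rt - entry.rt)
        if dmz / entry.target_mz * 1e6 <= mz_tol_ppm and drt <= rt_tol_min:
            hits.append((drt, dmz, entry))
    hits.sort(key=lambda h: (h[0], h[1]))
    entries = [h[2] for h in hits]
    return MatchResult(entries=entries, ambiguous=len(entries) > 1)


def validate_masses(panel: Panel, tol_da: float = 0.0005) -> dict[str, float]:
    """Check stored ion m/z against [M-H]- computed from each formula.

    Returns {analyte: |Δm/z| in Da} for entries exceeding ``tol_da``.
    Fragment-flagged ions and entries without a formula are exempt (their
    m/z values are stored verbatim).
    """
    bad = {}
    for entry in panel.entries:
        if entry.formula is None or entry.is_fragment:
            continue
        delta = abs(mz_deprotonated(entry.formula) - entry.target_mz)
        if delta > tol_da:
            bad[entry.name] = delta
    return bad
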