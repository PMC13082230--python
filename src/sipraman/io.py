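"""Spectra, band tables, and their text-format I/O.

Single-cell Raman spectra are exchanged as long-format CSV/TSV with columns
``cell_id, wavenumber_cm1, intensity`` and an optional sibling JSON manifest
carrying per-cell metadata (sample group, isotope condition).  Biomarker band
tables — the ¹²C and ¹³C endmember centers of the cytochrome c quartet and
the phenylalanine ring-breathing band — are packaged as JSON and can also be
supplied by the user as JSON or TSV.

Three band tables ship with the package:

``reference_strains``
    Positions measured on pure chemoautotrophic reference strains:
    747/1125/1312/1584 cm⁻¹ (Cyt c) shifting to 725/1115/1300/1536 cm⁻¹
    under ¹³C, and phenylalanine 1002 → 965 cm⁻¹.  This is the default.
``sediment_enrichment``
    Positions from enriched coastal-sediment cells (1310 → 1300,
    1584 → 1531; phenylalanine 1000 → 965 cm⁻¹).
``strain_TX1``
    Positions from the isolated sulfur-oxidizing strain TX1; the ¹³C values
    reflect incomplete labeling after 5 days (phenylalanine 1003 → 985 cm⁻¹
    is flagged ``observed_partial``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, LookupError_, ValidationError

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "BandDefinition",
    "BandTable",
    "PACKAGED_TABLES",
    "read_spectra_csv",
    "write_spectra_csv",
    "load_band_table",
]

ISOTOPE_CONDITIONS = ("12C", "13C", "none")
PACKAGED_TABLES = ("reference_strains", "sediment_enrichment", "strain_TX1")


@dataclass
class Spectrum:
    """One cell's Raman trace: a strictly increasing wavenumber axis (cm⁻¹)
    and intensities in arbitrary units, plus provenance metadata."""

    cell_id: str
    axis: np.ndarray
    intensities: np.ndarray
    sample_group: str = ""
    isotope_condition: str = "none"
    preprocessing_steps: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.axis.ndim != 1 or self.intensities.ndim != 1:
            raise ValidationError(f"{self.cell_id}: axis and intensities must be 1-D")
        if len(self.axis) != len(self.intensities):
            raise ValidationError(
                f"{self.cell_id}: axis length {len(self.axis)} != "
                f"intensity length {len(self.intensities)}"
            )
        if len(self.axis) < 2:
            raise ValidationError(f"{self.cell_id}: need at least 2 points")
        if not (np.all(np.isfinite(self.axis)) and np.all(np.isfinite(self.intensities))):
            raise ValidationError(f"{self.cell_id}: non-finite values")
        if np.any(np.diff(self.axis) <= 0):
            raise ValidationError(f"{self.cell_id}: axis must be strictly increasing")
        if self.isotope_condition not in ISOTOPE_CONDITIONS:
            raise ValidationError(
                f"{self.cell_id}: isotope_condition must be one of {ISOTOPE_CONDITIONS}"
            )

    def with_intensities(self, intensities: np.ndarray, step: str | None = None,
                         axis: np.ndarray | None = None) -> "Spectrum":
        """Return a copy with new intensities (and optionally a new axis),
        appending ``step`` to the preprocessing provenance."""
        steps = list(self.preprocessing_steps)
        if step is not None:
            steps.append(step)
        return replace(
            self,
            axis=self.axis.copy() if axis is None else np.asarray(axis, float),
            intensities=np.asarray(intensities, float),
            preprocessing_steps=steps,
            warnings=list(self.warnings),
        )

    @property
    def step(self) -> float:
        """Median axis spacing in cm⁻¹."""
        return float(np.median(np.diff(self.axis)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.axis)
        return bool(np.all(np.abs(d - d[0]) <= rtol * abs(d[0])))


@dataclass
class SpectrumSet:
    """A cohort of single-cell spectra with a manifest (set id, per-cell
    metadata, provenance such as the simulation seed)."""

    spectra: list[Spectrum]
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.cell_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate cell_ids in set: {dupes}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, cell_id: str) -> Spectrum:
        for s in self.spectra:
            if s.cell_id == cell_id:
                return s
        raise KeyError(cell_id)

    @property
    def cell_ids(self) -> list[str]:
        return [s.cell_id for s in self.spectra]


@dataclass
class BandDefinition:
    """A biomarker band: ¹²C and ¹³C endmember centers and a search window.

    ``role`` distinguishes the cytochrome c quartet (``cyt_c``) from the
    phenylalanine ring-breathing band (``phenylalanine``); the sorting rule
    counts them separately.  Isotope substitution always lowers the
    wavenumber, so ``c13 < c12`` is enforced.
    """

    name: str
    mode_label: str
    c12: float
    c13: float
    window_halfwidth: float = 10.0
    required: bool = True
    role: str = "cyt_c"
    caveat: str | None = None

    def __post_init__(self) -> None:
        if not self.c13 < self.c12:
            raise ValidationError(
                f"band {self.name}: c13 ({self.c13}) must be < c12 ({self.c12}) "
                "(isotope redshift)"
            )
        if self.window_halfwidth <= 0:
            raise ValidationError(f"band {self.name}: window_halfwidth must be > 0")
        if self.role not in ("cyt_c", "phenylalanine", "other"):
            raise ValidationError(f"band {self.name}: unknown role {self.role!r}")

    @property
    def window(self) -> tuple[float, float]:
        """Search window [c13 − w, c12 + w] in cm⁻¹."""
        return (self.c13 - self.window_halfwidth, self.c12 + self.window_halfwidth)

    @property
    def span(self) -> float:
        """Full isotopic shift c12 − c13 in cm⁻¹."""
        return self.c12 - self.c13


@dataclass
class BandTable:
    """A named collection of biomarker band definitions."""

    table_id: str
    bands: list[BandDefinition]
    notes: str = ""

    def __post_init__(self) -> None:
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValidationError(f"table {self.table_id}: duplicate band names")
        if not any(b.required for b in self.bands):
            raise ValidationError(f"table {self.table_id}: needs >= 1 required band")

    def __iter__(self):
        return iter(self.bands)

    def __getitem__(self, name: str) -> BandDefinition:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    def by_role(self, role: str) -> list[BandDefinition]:
        return [b for b in self.bands if b.role == role]


# ---------------------------------------------------------------------------
# spectra CSV + manifest JSON

_REQUIRED_COLUMNS = ("cell_id", "wavenumber_cm1", "intensity")


def read_spectra_csv(path: str | Path, manifest_path: str | Path | None = None) -> SpectrumSet:
    """Read a long-format spectra CSV/TSV into a validated :class:`SpectrumSet`.

    The delimiter is sniffed from the extension (``.tsv`` → tab).  If
    ``manifest_path`` is None a sibling ``<stem>.manifest.json`` is used when
    present.  Per-cell axes are sorted ascending.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if len(df) and not np.all(np.isfinite(df[["wavenumber_cm1", "intensity"]].to_numpy(float))):
        raise ValidationError(f"{path}: non-finite wavenumber or intensity values")
    if df.duplicated(subset=["cell_id", "wavenumber_cm1"]).any():
        raise ValidationError(f"{path}: duplicate (cell_id, wavenumber) rows")

    if manifest_path is None:
        sibling = path.with_name(path.stem + ".manifest.json")
        manifest_path = sibling if sibling.exists() else None
    manifest: dict = {}
    if manifest_path is not None and Path(manifest_path).exists():
        with open(manifest_path) as fh:
            manifest = json.load(fh)
    cell_meta: Mapping[str, dict] = manifest.get("cells", {})

    spectra = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("wavenumber_cm1")
        meta = cell_meta.get(str(cell_id), {})
        spectra.append(
            Spectrum(
                cell_id=str(cell_id),
                axis=grp["wavenumber_cm1"].to_numpy(float),
                intensities=grp["intensity"].to_numpy(float),
                sample_group=meta.get("sample_group", ""),
                isotope_condition=meta.get("isotope_condition", "none"),
                preprocessing_steps=list(meta.get("preprocessing_steps", [])),
            )
        )
    return SpectrumSet(spectra=spectra, manifest=manifest)


def write_spectra_csv(sset: SpectrumSet, path: str | Path) -> None:
    """Write a :class:`SpectrumSet` as long-format CSV (rows ordered by
    cell_id, then wavenumber) plus a sibling ``<stem>.manifest.json``."""
    path = Path(path)
    frames = []
    for s in sorted(sset.spectra, key=lambda s: s.cell_id):
        frames.append(
            pd.DataFrame(
                {"cell_id": s.cell_id, "wavenumber_cm1": s.axis, "intensity": s.intensities}
            )
        )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=list(_REQUIRED_COLUMNS))
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    out.to_csv(path, sep=sep, index=False, float_format="%.12g")

    manifest = dict(sset.manifest)
    cells = {cid: dict(manifest.get("cells", {}).get(cid, {})) for cid in sset.cell_ids}
    for s in sset.spectra:
        cells[s.cell_id].update(
            sample_group=s.sample_group,
            isotope_condition=s.isotope_condition,
            preprocessing_steps=list(s.preprocessing_steps),
        )
    manifest["cells"] = cells
    with open(path.with_name(path.stem + ".manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# band tables


def _table_from_obj(obj: dict) -> BandTable:
    try:
        bands = [BandDefinition(**b) for b in obj["bands"]]
        return BandTable(table_id=obj["table_id"], bands=bands, notes=obj.get("notes", ""))
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed band table: {exc}") from exc


def load_band_table(id_or_path: str | Path) -> BandTable:
    """Load a band table by packaged id (``reference_strains``,
    ``sediment_enrichment``, ``strain_TX1``) or from a JSON/TSV path."""
    key = str(id_or_path)
    if key in PACKAGED_TABLES:
        text = resources.files("sipraman").joinpath(f"data/{key}.json").read_text()
        return _table_from_obj(json.loads(text))
    path = Path(id_or_path)
    if not path.exists():
        raise LookupError_(
            f"{id_or_path!r} is neither a packaged table {PACKAGED_TABLES} nor a file"
        )
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            return _table_from_obj(json.load(fh))
    if path.suffix.lower() in (".tsv", ".tab", ".txt"):
        df = pd.read_csv(path, sep="\t")
        need = {"name", "mode_label", "c12", "c13"}
        if not need.issubset(df.columns):
            raise FormatError(f"{path}: band TSV needs columns {sorted(need)}")
        bands = []
        for _, row in df.iterrows():
            kwargs = dict(
                name=str(row["name"]), mode_label=str(row["mode_label"]),
                c12=float(row["c12"]), c13=float(row["c13"]),
            )
            for opt in ("window_halfwidth", "required", "role"):
                if opt in df.columns and not pd.isna(row[opt]):
                    kwargs[opt] = row[opt]
            if "required" in kwargs:
                kwargs["required"] = bool(kwargs["required"])
            if "window_halfwidth" in kwargs:
                kwargs["window_halfwidth"] = float(kwargs["window_halfwidth"])
            bands.append(BandDefinition(**kwargs))
        return BandTable(table_id=path.stem, bands=bands)
    raise FormatError(f"{path}: band tables must be .json or .tsv")
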