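"""Cohort-level reports: machine-readable summaries of a classified cohort
and mean ± SD group spectra for ¹²C vs ¹³C comparison figures."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import SpectrumSet, Spectrum
from .preprocess import MeanSpectrum, average_spectra

__all__ = ["CohortReport", "group_mean_spectra", "mean_spectra_table"]


@dataclass
class CohortReport:
    """Summary of one classified cohort: activity counts, per-band shift
    statistics, the ranked sort-candidate list, and every parameter needed
    to regenerate the result."""

    set_id: str
    n_cells: int
    n_active: int
    band_summary: dict = field(default_factory=dict)
    sort_candidates: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    version: str = ""
    seed: int | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_active > self.n_cells:
            raise ParameterError("n_active cannot exceed n_cells")

    def to_dict(self) -> dict:
        return {
            "set_id": self.set_id,
            "n_cells": self.n_cells,
            "n_active": self.n_active,
            "band_summary": self.band_summary,
            "sort_candidates": list(self.sort_candidates),
            "params": self.params,
            "version": self.version,
            "seed": self.seed,
            "warnings": list(self.warnings),
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def group_mean_spectra(sset: SpectrumSet, by: str = "isotope_condition") -> dict[str, MeanSpectrum]:
    """Mean ± SD spectrum per group (default: isotope condition).

    All spectra must already share one axis (preprocess first).
    """
    if len(sset) == 0:
        raise ParameterError("empty SpectrumSet")
    groups: dict[str, list[Spectrum]] = {}
    for s in sset:
        key = getattr(s, by) if by in ("isotope_condition", "sample_group") else s.sample_group
        groups.setdefault(str(key), []).append(s)
    return {
        key: average_spectra(SpectrumSet(spectra=members, manifest={}))
        for key, members in sorted(groups.items())
    }


def mean_spectra_table(means: dict[str, MeanSpectrum]) -> pd.DataFrame:
    """Long-format table (group, wavenumber_cm1, mean, sd, n) of group means."""
    frames = []
    for key, m in means.items():
        frames.append(
            pd.DataFrame(
                {
                    "group": key,
                    "wavenumber_cm1": m.axis,
                    "mean": m.mean,
                    "sd": m.sd,
                    "n": m.n,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def apex_position(mean: MeanSpectrum, lo: float, hi: float) -> float:
    """Wavenumber of the maximum of a mean spectrum within [lo, hi]."""
    mask = (mean.axis >= lo) & (mean.axis <= hi)
    if not mask.any():
        raise ParameterError(f"window [{lo}, {hi}] outside axis")
    idx = np.argmax(np.asarray(mean.mean)[mask])
    return float(np.asarray(mean.axis)[mask][idx])
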