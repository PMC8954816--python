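"""CSV readers/writers, run configuration and logging.

All tabular interchange is plain RFC-4180 CSV (UTF-8, "." decimal) with
mandatory headers; units are fixed by column name (rt always minutes, m/z
always Th, concentrations always ng/mL, times always minutes) and never
guessed.  Readers validate row by row: malformed rows never propagate as
NaN — they are collected into an error report with their line numbers and
logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .chem import ValidationError
from .metid import Peak, ProductIonSpectrum
from .nca import ConcentrationTimeProfile
from .quantcal import round_sig

logger = logging.getLogger("dmpkit.io")

__all__ = [
    "ReadResult",
    "read_peak_table",
    "write_peak_table",
    "read_ms2_table",
    "write_ms2_table",
    "read_batch_table",
    "read_profiles",
    "write_profiles",
    "write_report",
    "RunConfig",
    "configure_logging",
]

PEAK_COLUMNS = ("condition", "rt_min", "mz", "intensity")
MS2_COLUMNS = ("precursor_mz", "fragment_mz", "intensity")
BATCH_COLUMNS = (
    "run_id",
    "sample_type",
    "level_id",
    "nominal_conc",
    "area_ratio",
    "dilution_factor",
    "condition",
)
PROFILE_COLUMNS = ("subject_id", "dose_mg_kg", "time_min", "conc_ng_ml", "blq")
SAMPLE_TYPES = {"STD", "QC", "DIL", "STAB", "UNK"}


@dataclass
class ReadResult:
    """Typed records plus per-row errors (line number, message)."""

    records: list
    errors: list[tuple[int, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _load_csv(path, required: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [col for col in required if col not in frame.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(frame.columns)}"
        )
    return frame


def read_peak_table(path) -> ReadResult:
    """Read a centroided peak table (condition, rt_min, mz, intensity)."""
    frame = _load_csv(path, PEAK_COLUMNS)
    result = ReadResult(records=[])
    for idx, row in frame.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            result.records.append(
                Peak(
                    condition=row["condition"],
                    rt=float(row["rt_min"]),
                    mz=float(row["mz"]),
                    intensity=float(row["intensity"]),
                )
            )
        except (ValueError, ValidationError) as exc:
            result.errors.append((line, str(exc)))
            logger.warning("%s line %d: %s", path, line, exc)
    return result


def write_peak_table(peaks: Sequence[Peak], path) -> None:
    frame = pd.DataFrame(
        {
            "condition": [p.condition for p in peaks],
            "rt_min": [p.rt for p in peaks],
            "mz": [repr(p.mz) for p in peaks],
            "intensity": [p.intensity for p in peaks],
        }
    )
    frame.to_csv(path, index=False, lineterminator="\n")


def read_ms2_table(path) -> ReadResult:
    """Read product-ion spectra (precursor_mz, fragment_mz, intensity),
    grouped by precursor in file order."""
    frame = _load_csv(path, MS2_COLUMNS)
    groups: dict[str, list[tuple[float, float]]] = {}
    errors: list[tuple[int, str]] = []
    for idx, row in frame.iterrows():
        line = int(idx) + 2
        try:
            float(row["precursor_mz"])
            fragment = (float(row["fragment_mz"]), float(row["intensity"]))
        except ValueError as exc:
            errors.append((line, str(exc)))
            logger.warning("%s line %d: %s", path, line, exc)
            continue
        groups.setdefault(row["precursor_mz"], []).append(fragment)
    records = []
    for precursor, fragments in groups.items():
        try:
            records.append(
                ProductIonSpectrum(
                    precursor_mz=float(precursor), fragments=tuple(fragments)
                )
            )
        except ValidationError as exc:
            errors.append((0, f"precursor {precursor}: {exc}"))
            logger.warning("%s precursor %s: %s", path, precursor, exc)
    return ReadResult(records=records, errors=errors)


def write_ms2_table(spectra: Sequence[ProductIonSpectrum], path) -> None:
    rows = []
    for spectrum in spectra:
        for mz, intensity in spectrum.fragments:
            rows.append(
                {
                    "precursor_mz": repr(spectrum.precursor_mz),
                    "fragment_mz": repr(mz),
                    "intensity": intensity,
                }
            )
    pd.DataFrame(rows, columns=MS2_COLUMNS).to_csv(
        path, index=False, lineterminator="\n"
    )


def read_batch_table(path) -> pd.DataFrame:
    """Read a quantification batch (STD/QC/DIL/STAB/UNK rows).

    Numeric columns are converted strictly; any malformed row aborts with a
    message naming the line, since batch statistics must never silently
    drop replicates.
    """
    frame = _load_csv(path, BATCH_COLUMNS)
    out = frame.copy()
    bad = ~out["sample_type"].isin(SAMPLE_TYPES)
    if bad.any():
        lines = [int(i) + 2 for i in out.index[bad]]
        raise ValidationError(
            f"{path}: invalid sample_type at line(s) {lines}; "
            f"allowed {sorted(SAMPLE_TYPES)}"
        )
    for column in ("nominal_conc", "area_ratio", "dilution_factor"):
        try:
            out[column] = out[column].map(
                lambda v: float(v) if str(v).strip() != "" else np.nan
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: column {column}: {exc}") from None
    return out


def read_profiles(path) -> list[ConcentrationTimeProfile]:
    """Read concentration-time profiles grouped by subject."""
    frame = _load_csv(path, PROFILE_COLUMNS[:4])
    has_blq = "blq" in frame.columns
    profiles = []
    for subject, group in frame.groupby("subject_id", sort=False):
        try:
            times = group["time_min"].astype(float).to_numpy()
            concs = group["conc_ng_ml"].astype(float).to_numpy()
            dose = float(group["dose_mg_kg"].iloc[0])
            blq = (
                group["blq"].astype(int).astype(bool).to_numpy()
                if has_blq
                else None
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: subject {subject}: {exc}") from None
        order = np.argsort(times)
        profiles.append(
            ConcentrationTimeProfile(
                subject_id=str(subject),
                dose=dose,
                times=times[order],
                concs=concs[order],
                blq=blq[order] if blq is not None else None,
            )
        )
    return profiles


def write_profiles(profiles: Sequence[ConcentrationTimeProfile], path) -> None:
    rows = []
    for profile in profiles:
        for t, c, b in zip(profile.times, profile.concs, profile.blq):
            rows.append(
                {
                    "subject_id": profile.subject_id,
                    "dose_mg_kg": profile.dose,
                    "time_min": t,
                    "conc_ng_ml": repr(float(c)),
                    "blq": int(b),
                }
            )
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(
        path, index=False, lineterminator="\n"
    )


_MZ_COLUMNS = {"mz", "precursor_mz", "fragment_mz"}
_SIG3_COLUMNS = {"mean_accuracy_pct", "cv_pct"}


def _format_cell(column: str, value) -> str:
    if isinstance(value, float):
        if column in _MZ_COLUMNS:
            return f"{value:.4f}"
        if column in _SIG3_COLUMNS:
            return f"{round_sig(value, 3):g}"
        return f"{value:g}"
    return str(value)


def write_report(frame: pd.DataFrame, path, fmt: str = "tsv") -> None:
    """Write a report table deterministically as TSV or Markdown.

    Column order is preserved; m/z columns print at 4 decimal places and
    percentage statistics at 3 significant figures.
    """
    if fmt not in {"tsv", "markdown"}:
        raise ValidationError(f"unsupported report format {fmt!r}")
    columns = list(frame.columns)
    formatted = [
        [_format_cell(col, row[col]) for col in columns]
        for _, row in frame.iterrows()
    ]
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as handle:
        if fmt == "tsv":
            handle.write("\t".join(columns) + "\n")
            for row in formatted:
                handle.write("\t".join(row) + "\n")
        else:
            handle.write("| " + " | ".join(columns) + " |\n")
            handle.write("|" + "|".join(" --- " for _ in columns) + "|\n")
            for row in formatted:
                handle.write("| " + " | ".join(row) + " |\n")


class RunConfig(BaseModel):
    """Tolerances and run-level settings shared across subcommands."""

    tol_ppm: float = Field(default=5.0, gt=0)
    frag_tol_mda: float = Field(default=10.0, gt=0)
    rt_tol_min: float = Field(default=0.2, gt=0)
    acceptance_band_pct: float = Field(default=25.0, gt=0, le=100)
    max_steps: int = Field(default=3, ge=1)
    drop_fraction: float = Field(default=0.8, gt=0, le=1)
    seed: int = 0
    verbosity: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as handle:
            return cls.model_validate(json.load(handle))


def configure_logging(verbosity: int = 0) -> None:
    level = logging.WARNING
    if verbosity == 1:
        level = logging.INFO
    elif verbosity >= 2:
        level = logging.DEBUG
    logging.basicConfig(
        level=level, format="%(levelname)s %(name)s: %(message)s"
    )
    logging.getLogger("dmpkit").setLevel(level)
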