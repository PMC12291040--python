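"""Spectrum records, peak-list parsing and elemental-formula masses.

Input dialects
--------------
``mgf``
    Mascot generic format read with :mod:`pyteomics.mgf`.  Each ``BEGIN
    IONS``/``END IONS`` block must carry ``PEPMASS`` (precursor m/z) and
    ``RTINSECONDS`` (converted to minutes here); an optional user field
    ``CLASS=<label>`` supplies the drug-class label.
``msp``
    NIST MSP text libraries read with :mod:`matchms`.  ``Name:``,
    ``PrecursorMZ:`` and ``RT:`` (minutes) are required per block; the class
    label is taken from a ``class=<label>`` token inside ``Comment:``.
``csv_peaks``
    Long-format CSV with one row per peak and columns ``analyte_id, class,
    precursor_mz, rt_min, fragment_mz, intensity``; rows sharing an
    ``analyte_id`` form one spectrum (first occurrence order is kept).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from pyteomics import mass as _pyteomics_mass

__all__ = [
    "SpectrumRecord",
    "parse_spectra",
    "write_mgf",
    "parse_formula",
    "monoisotopic_mass",
    "SUPPORTED_ELEMENTS",
]

#: Elements accepted by :func:`parse_formula` — enough for small-molecule NPS.
SUPPORTED_ELEMENTS = ("C", "H", "N", "O", "S", "P", "F", "Cl", "Br", "I")


@dataclass
class SpectrumRecord:
    """One analyte's centroided MS/MS peak list with its chromatographic context.

    ``peaks`` is an ordered list of ``(fragment_mz, intensity)`` pairs;
    intensities are arbitrary detector counts.  ``class_label`` is empty for
    unknowns.  ``ce_range_tag`` records the collision-energy ramp the spectrum
    was acquired with (e.g. ``"10-30V"``).
    """

    analyte_id: str
    precursor_mz: float
    retention_time: float
    peaks: list[tuple[float, float]]
    class_label: str = ""
    ce_range_tag: str = ""

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(
                f"record {self.analyte_id!r}: precursor m/z must be positive, "
                f"got {self.precursor_mz}"
            )
        if self.retention_time < 0:
            raise ValueError(
                f"record {self.analyte_id!r}: retention time must be >= 0"
            )
        for mz, inten in self.peaks:
            if mz <= 0:
                raise ValueError(
                    f"record {self.analyte_id!r}: fragment m/z must be positive"
                )
            if inten < 0:
                raise ValueError(
                    f"record {self.analyte_id!r}: intensities must be >= 0"
                )


class SpectrumParseError(ValueError):
    """A spectral input file violated the declared dialect."""


def parse_spectra(path: str | Path, format: str) -> list[SpectrumRecord]:
    """Read ``path`` in the named dialect and return one record per spectrum.

    Parameters
    ----------
    path
        Input file.
    format
        One of ``"mgf"``, ``"msp"`` or ``"csv_peaks"``.

    Raises
    ------
    SpectrumParseError
        On a malformed block (the message names the record index / offending
        field) or a missing precursor m/z / retention time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mgf":
        return _parse_mgf(path)
    if format == "msp":
        return _parse_msp(path)
    if format == "csv_peaks":
        return _parse_csv_peaks(path)
    raise ValueError(f"unknown spectral format {format!r}")


def _parse_mgf(path: Path) -> list[SpectrumRecord]:
    from pyteomics import mgf

    records: list[SpectrumRecord] = []
    try:
        entries = list(mgf.read(str(path)))
    except Exception as exc:  # pyteomics raises assorted parse errors
        raise SpectrumParseError(f"{path.name}: malformed MGF: {exc}") from exc
    for i, entry in enumerate(entries):
        params = entry.get("params", {})
        title = str(params.get("title", f"spectrum_{i}"))
        pepmass = params.get("pepmass")
        if pepmass is None:
            raise SpectrumParseError(
                f"{path.name}: record {i} ({title!r}) has no PEPMASS"
            )
        precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
        if "rtinseconds" not in params:
            raise SpectrumParseError(
                f"{path.name}: record {i} ({title!r}) has no RTINSECONDS"
            )
        rt_min = float(params["rtinseconds"]) / 60.0
        label = str(params.get("class", ""))
        peaks = list(
            zip(
                (float(x) for x in entry["m/z array"]),
                (float(y) for y in entry["intensity array"]),
            )
        )
        records.append(
            SpectrumRecord(
                analyte_id=title,
                precursor_mz=precursor,
                retention_time=rt_min,
                peaks=peaks,
                class_label=label,
            )
        )
    return records


_COMMENT_CLASS_RE = re.compile(r"\bclass=([^\s;,]+)", re.IGNORECASE)


def _parse_msp(path: Path) -> list[SpectrumRecord]:
    from matchms.importing import load_from_msp

    records: list[SpectrumRecord] = []
    try:
        spectra = list(load_from_msp(str(path), metadata_harmonization=True))
    except Exception as exc:
        raise SpectrumParseError(f"{path.name}: malformed MSP: {exc}") from exc
    n_blocks = sum(
        1
        for line in path.read_text().splitlines()
        if line.lower().startswith("name:")
    )
    if len(spectra) != n_blocks:
        raise SpectrumParseError(
            f"{path.name}: {n_blocks} blocks declared but only {len(spectra)} "
            "parsed cleanly — check for malformed blocks (e.g. a Num Peaks "
            "count that does not match the listed peaks)"
        )
    for i, spec in enumerate(spectra):
        meta = spec.metadata
        name = str(meta.get("compound_name") or meta.get("name") or f"spectrum_{i}")
        precursor = meta.get("precursor_mz")
        if precursor is None:
            raise SpectrumParseError(
                f"{path.name}: record {i} ({name!r}) has no PrecursorMZ"
            )
        rt = meta.get("retention_time", meta.get("rt"))
        if rt is None:
            raise SpectrumParseError(
                f"{path.name}: record {i} ({name!r}) has no RT"
            )
        declared = meta.get("num_peaks")
        n_actual = len(spec.peaks.mz)
        if declared is not None and int(declared) != n_actual:
            raise SpectrumParseError(
                f"{path.name}: record {i} ({name!r}) declares Num Peaks="
                f"{declared} but lists {n_actual}"
            )
        label = ""
        comment = meta.get("comment", "")
        if comment:
            m = _COMMENT_CLASS_RE.search(str(comment))
            if m:
                label = m.group(1)
        peaks = list(
            zip(
                (float(x) for x in spec.peaks.mz),
                (float(y) for y in spec.peaks.intensities),
            )
        )
        records.append(
            SpectrumRecord(
                analyte_id=name,
                precursor_mz=float(precursor),
                retention_time=float(rt),
                peaks=peaks,
                class_label=label,
            )
        )
    return records


_CSV_PEAK_COLUMNS = [
    "analyte_id",
    "class",
    "precursor_mz",
    "rt_min",
    "fragment_mz",
    "intensity",
]


def _parse_csv_peaks(path: Path) -> list[SpectrumRecord]:
    try:
        frame = pd.read_csv(path, dtype={"analyte_id": str, "class": str})
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in _CSV_PEAK_COLUMNS if c not in frame.columns]
    if missing:
        raise SpectrumParseError(
            f"{path.name}: missing required column(s) {', '.join(missing)}"
        )
    if frame.empty:
        return []
    frame["class"] = frame["class"].fillna("")
    records: list[SpectrumRecord] = []
    for i, (analyte_id, group) in enumerate(frame.groupby("analyte_id", sort=False)):
        prec = group["precursor_mz"].unique()
        rt = group["rt_min"].unique()
        if len(prec) != 1 or len(rt) != 1:
            raise SpectrumParseError(
                f"{path.name}: record {i} ({analyte_id!r}) has inconsistent "
                "precursor_mz / rt_min across its peak rows"
            )
        if pd.isna(prec[0]):
            raise SpectrumParseError(
                f"{path.name}: record {i} ({analyte_id!r}) has no precursor_mz"
            )
        records.append(
            SpectrumRecord(
                analyte_id=str(analyte_id),
                precursor_mz=float(prec[0]),
                retention_time=float(rt[0]),
                peaks=list(zip(group["fragment_mz"].astype(float),
                               group["intensity"].astype(float))),
                class_label=str(group["class"].iloc[0]),
            )
        )
    return records


def write_mgf(records: Sequence[SpectrumRecord], path: str | Path) -> None:
    """Write records as MGF (RT in RTINSECONDS, class label as CLASS=...)."""
    import numpy as np
    from pyteomics import mgf

    entries = []
    for r in records:
        params = {
            "TITLE": r.analyte_id,
            "PEPMASS": r.precursor_mz,
            "RTINSECONDS": r.retention_time * 60.0,
        }
        if r.class_label:
            params["CLASS"] = r.class_label
        entries.append(
            {
                "params": params,
                "m/z array": np.array([mz for mz, _ in r.peaks]),
                "intensity array": np.array([i for _, i in r.peaks]),
            }
        )
    with open(path, "w") as handle:
        mgf.write(entries, handle)


# -- elemental formulas ------------------------------------------------------

_FORMULA_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | dict[str, int]) -> dict[str, int]:
    """Parse a Hill-style formula string (``"C17H14N"``) into an element map.

    Only the elements in :data:`SUPPORTED_ELEMENTS` are accepted; counts must
    be positive integers.
    """
    if isinstance(formula, dict):
        counts = dict(formula)
        consumed_ok = True
    else:
        counts = {}
        pos = 0
        for m in _FORMULA_TOKEN_RE.finditer(formula):
            if m.start() != pos or not m.group(0):
                break
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
            pos = m.end()
        consumed_ok = pos == len(formula) and len(formula) > 0
    if not consumed_ok:
        raise ValueError(f"cannot parse elemental formula {formula!r}")
    for element, count in counts.items():
        if element not in SUPPORTED_ELEMENTS:
            raise ValueError(f"unsupported element {element!r} in formula")
        if not isinstance(count, int) or count <= 0:
            raise ValueError(f"element counts must be positive integers ({element}={count})")
    return counts


def monoisotopic_mass(formula: str | dict[str, int]) -> float:
    """Monoisotopic (neutral) mass in Da of an elemental formula.

    Sums count x monoisotopic atomic mass over elements, using the IUPAC
    atomic-mass table shipped with :mod:`pyteomics.mass`.  No electron-mass
    correction is applied, so the result is the neutral-species mass; for
    small fragments the difference from the cation m/z (~0.00055 Da) is below
    the 0.0005-Da tolerance typically quoted for HRMS fragment annotation.

    >>> round(monoisotopic_mass("C17H14N"), 4)
    232.1126
    """
    counts = parse_formula(formula)
    return float(_pyteomics_mass.calculate_mass(composition=counts))
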