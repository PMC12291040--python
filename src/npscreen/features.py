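"""Eight-variable spectral feature matrix construction.

Each analyte is summarised by precursor m/z, retention time, the m/z of its
three most intense fragments above a relative-intensity threshold (10% of
the base peak by default), and the three corresponding neutral losses.  The
neutral-loss reference is configurable: the base peak (in which case the
top-ranked fragment *is* the base peak and its loss is exactly 0) or the
precursor ion (the usual chemical convention).  Analytes with fewer than
three surviving fragments keep their remaining slots flagged missing —
values are never silently fabricated; imputation is an explicit, separate
step in the chemometrics layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .spectra import SpectrumRecord

__all__ = [
    "FEATURE_COLUMNS",
    "FeatureVector",
    "FeatureMatrix",
    "FeatureExtractionError",
    "extract_features",
    "build_matrix",
    "read_feature_table",
    "write_feature_table",
]

#: Fixed column order of the feature matrix.
FEATURE_COLUMNS = (
    "precursor_mz",
    "rt_min",
    "frag1_mz",
    "frag2_mz",
    "frag3_mz",
    "nl1",
    "nl2",
    "nl3",
)

NlReference = Literal["base_peak", "precursor"]


class FeatureExtractionError(ValueError):
    """Raised when a spectrum cannot yield a valid feature vector."""


@dataclass
class FeatureVector:
    """One analyte's row of the eight-variable matrix.

    ``frag_mz`` / ``neutral_loss`` hold NaN in missing slots; ``missing_mask``
    flags the six fragment/neutral-loss slots (True = missing).
    """

    precursor_mz: float
    retention_time: float
    frag_mz: tuple[float, float, float]
    neutral_loss: tuple[float, float, float]
    missing_mask: tuple[bool, bool, bool, bool, bool, bool]

    def values(self) -> np.ndarray:
        """The 8-variable row in :data:`FEATURE_COLUMNS` order (NaN = missing)."""
        return np.array(
            [self.precursor_mz, self.retention_time, *self.frag_mz, *self.neutral_loss],
            dtype=float,
        )

    def mask(self) -> np.ndarray:
        """Boolean missing mask aligned with :meth:`values` (first two always present)."""
        return np.array([False, False, *self.missing_mask], dtype=bool)


def _rank_peaks(peaks: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    # descending intensity; ties broken by lower m/z, then input order
    indexed = [(inten, mz, i) for i, (mz, inten) in enumerate(peaks)]
    indexed.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [(mz, inten) for inten, mz, _ in indexed]


def extract_features(
    record: SpectrumRecord,
    rel_intensity_threshold: float = 0.10,
    nl_reference: NlReference = "base_peak",
    include_base_peak: bool = True,
    precursor_tolerance: float = 0.5,
) -> FeatureVector:
    """Reduce one spectrum to the eight-variable feature vector.

    Fragments with relative intensity (to the base peak) at or above
    ``rel_intensity_threshold`` are ranked by descending intensity (ties:
    lower m/z first, then input order); the top three fill the fragment
    slots.  ``neutral_loss[i] = |reference - frag_mz[i]|`` where the
    reference is the base-peak m/z (default) or the precursor m/z.  With
    ``include_base_peak=False`` the base peak serves only as the reference
    and the slots are filled by the next most intense surviving fragments.

    Raises
    ------
    FeatureExtractionError
        On an empty peak list, all-zero intensities, or a surviving fragment
        heavier than ``precursor_mz + precursor_tolerance``.
    """
    if not record.peaks:
        raise FeatureExtractionError(f"record {record.analyte_id!r}: empty peak list")
    if not 0 < rel_intensity_threshold <= 1:
        raise ValueError("rel_intensity_threshold must be in (0, 1]")
    ranked = _rank_peaks(record.peaks)
    base_mz, base_intensity = ranked[0]
    if base_intensity <= 0:
        raise FeatureExtractionError(
            f"record {record.analyte_id!r}: all intensities are zero"
        )
    survivors = [
        (mz, inten)
        for mz, inten in ranked
        if inten / base_intensity >= rel_intensity_threshold
    ]
    if not include_base_peak:
        survivors = survivors[1:]
    reference = base_mz if nl_reference == "base_peak" else record.precursor_mz
    if nl_reference not in ("base_peak", "precursor"):
        raise ValueError(f"unknown nl_reference {nl_reference!r}")

    frag = [math.nan] * 3
    nl = [math.nan] * 3
    miss = [True] * 6
    for slot, (mz, _) in enumerate(survivors[:3]):
        if mz > record.precursor_mz + precursor_tolerance:
            raise FeatureExtractionError(
                f"record {record.analyte_id!r}: fragment {mz:.4f} exceeds "
                f"precursor {record.precursor_mz:.4f}"
            )
        frag[slot] = mz
        nl[slot] = abs(reference - mz)
        miss[slot] = False
        miss[slot + 3] = False
    return FeatureVector(
        precursor_mz=record.precursor_mz,
        retention_time=record.retention_time,
        frag_mz=tuple(frag),
        neutral_loss=tuple(nl),
        missing_mask=tuple(miss),
    )


@dataclass
class FeatureMatrix:
    """n x 8 numeric feature table with row identities and a missing mask.

    ``values`` holds NaN wherever ``mask`` is True.  Column order is fixed to
    :data:`FEATURE_COLUMNS`.
    """

    analyte_ids: list[str]
    class_labels: list[str]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = len(self.analyte_ids)
        if len(self.class_labels) != n:
            raise ValueError("class_labels length must match analyte_ids")
        if self.values.shape != (n, len(FEATURE_COLUMNS)):
            raise ValueError(
                f"values must be {n}x{len(FEATURE_COLUMNS)}, got {self.values.shape}"
            )
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        # keep NaN and mask synchronised
        self.values = np.where(self.mask, np.nan, self.values)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def columns(self) -> tuple[str, ...]:
        return FEATURE_COLUMNS

    def subset(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            analyte_ids=[self.analyte_ids[i] for i in idx],
            class_labels=[self.class_labels[i] for i in idx],
            values=self.values[idx],
            mask=self.mask[idx],
        )

    def rows_of_class(self, label: str) -> list[int]:
        return [i for i, c in enumerate(self.class_labels) if c == label]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for label in self.class_labels:
            counts[label] = counts.get(label, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(FEATURE_COLUMNS))
        frame.insert(0, "class", self.class_labels)
        frame.insert(0, "analyte_id", self.analyte_ids)
        return frame


def build_matrix(
    records: Sequence[SpectrumRecord],
    rel_intensity_threshold: float = 0.10,
    nl_reference: NlReference = "base_peak",
    include_base_peak: bool = True,
) -> FeatureMatrix:
    """Extract features from every record and stack them, preserving row order.

    Raises
    ------
    FeatureExtractionError
        Aggregated over all failing records, naming each analyte_id.
    """
    if not records:
        raise ValueError("records must be non-empty")
    rows: list[FeatureVector] = []
    failures: list[str] = []
    for record in records:
        try:
            rows.append(
                extract_features(
                    record,
                    rel_intensity_threshold=rel_intensity_threshold,
                    nl_reference=nl_reference,
                    include_base_peak=include_base_peak,
                )
            )
        except FeatureExtractionError as exc:
            failures.append(f"{record.analyte_id}: {exc}")
    if failures:
        raise FeatureExtractionError(
            "feature extraction failed for "
            f"{len(failures)} record(s): " + "; ".join(failures)
        )
    return FeatureMatrix(
        analyte_ids=[r.analyte_id for r in records],
        class_labels=[r.class_label for r in records],
        values=np.vstack([v.values() for v in rows]),
        mask=np.vstack([v.mask() for v in rows]),
    )


def write_feature_table(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write the feature table as CSV (UTF-8, dot decimal); blank cell = missing."""
    matrix.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path: str | Path) -> FeatureMatrix:
    """Read a feature-table CSV back into a :class:`FeatureMatrix`.

    The header must include ``analyte_id``, ``class`` and the eight variable
    columns.  Blank or NA cells become missing; any other non-numeric cell is
    an error naming the column.
    """
    frame = pd.read_csv(path, dtype={"analyte_id": str, "class": str})
    required = ["analyte_id", "class", *FEATURE_COLUMNS]
    missing_cols = [c for c in required if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"feature table missing column(s): {', '.join(missing_cols)}")
    numeric = np.empty((len(frame), len(FEATURE_COLUMNS)), dtype=float)
    for j, col in enumerate(FEATURE_COLUMNS):
        parsed = pd.to_numeric(frame[col], errors="coerce")
        bad = parsed.isna() & frame[col].notna() & (frame[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-numeric value {frame[col][row]!r} in column {col!r} (row {row})"
            )
        numeric[:, j] = parsed.to_numpy(dtype=float)
    mask = np.isnan(numeric)
    if mask[:, :2].any():
        row = int(np.argwhere(mask[:, :2])[0][0])
        raise ValueError(
            f"precursor_mz / rt_min may not be missing (row {row})"
        )
    return FeatureMatrix(
        analyte_ids=frame["analyte_id"].astype(str).tolist(),
        class_labels=frame["class"].fillna("").astype(str).tolist(),
        values=numeric,
        mask=mask,
    )
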