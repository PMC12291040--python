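"""Seeded generators of NPS-like MS/MS spectra and feature matrices.

The panel generator emulates the *statistical* shape of a multi-class
screening panel — per-class precursor-mass windows, retention-time windows,
characteristic neutral-loss motifs, intensity spread and occasional missing
fragments — not fragmentation chemistry.  Every draw is driven by a single
NumPy generator stream, so a (templates, sizes, seed) triple reproduces a
panel bit-for-bit.

The default template set names the nine drug classes of the screening panel
(benzodiazepines, cathinones, fentanyls, JWH, nitazenes, PINACA,
tryptamines, arylcyclohexylamines, phenethylamines) with the class sizes
used there (17, 22, 18, 17, 4, 17, 5, 4, 6); a set of 17 minor classes of
two or three analytes each tops the panel up to 159 records and exercises
the "fewer than four analytes" exclusion path.  All template values
(mass windows, losses, noise levels) are invented, chosen to be plausible
for protonated small molecules in the 150-560 Th range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix, FEATURE_COLUMNS
from .spectra import SpectrumRecord

__all__ = [
    "ClassTemplate",
    "SyntheticPanel",
    "MODELED_CLASS_SIZES",
    "MINOR_CLASS_SIZES",
    "default_templates",
    "well_separated_templates",
    "minor_class_templates",
    "no_nps_template",
    "overlapping_templates",
    "generate_panel",
    "generate_feature_matrix",
]

#: Class sizes of the nine modeled classes in the screening panel.
MODELED_CLASS_SIZES: dict[str, int] = {
    "benzodiazepines": 17,
    "cathinones": 22,
    "fentanyls": 18,
    "JWH": 17,
    "nitazenes": 4,
    "PINACA": 17,
    "tryptamines": 5,
    "arylcyclohexylamines": 4,
    "phenethylamines": 6,
}

_MINOR_NAMES = [
    "WIN", "SC1", "SC2", "SC3", "brorphine_analogues", "lysergamides",
    "piperazines", "aminoindanes", "benzofurans", "arylalkylamines",
    "designer_opioids", "plant_alkaloids", "dissociatives", "sedatives",
    "thiophene_analogues", "steroids", "carbazoles",
]

#: Sizes of the 17 minor (unmodeled, < 4 analytes) classes; totals 49.
MINOR_CLASS_SIZES: dict[str, int] = {
    name: (2 if name in ("steroids", "carbazoles") else 3) for name in _MINOR_NAMES
}

# relative-intensity pattern of characteristic fragments, by rank
_BASE_WEIGHTS = np.array([1.0, 0.65, 0.40, 0.25, 0.15, 0.10])


@dataclass
class ClassTemplate:
    """Generative recipe for one drug class in the 8-variable feature space."""

    class_label: str
    precursor_range: tuple[float, float]
    rt_range: tuple[float, float]
    characteristic_losses: list[tuple[float, float]]  # (loss Da, occurrence prob)
    n_extra_fragments: tuple[int, int] = (1, 3)
    intensity_concentration: float = 40.0
    missing_fragment_prob: float = 0.05
    feature_noise_sd: float = 0.003  # m/z jitter, Th

    def __post_init__(self) -> None:
        lo, hi = self.precursor_range
        if not lo < hi:
            raise ValueError(f"{self.class_label}: degenerate precursor range")
        lo, hi = self.rt_range
        if not lo < hi:
            raise ValueError(f"{self.class_label}: degenerate RT range")
        for loss, prob in self.characteristic_losses:
            if not 0 <= prob <= 1:
                raise ValueError(f"{self.class_label}: probability outside [0, 1]")
            if loss <= 0:
                raise ValueError(f"{self.class_label}: losses must be positive")


@dataclass
class SyntheticPanel:
    """A generated spectrum panel plus its ground truth and the seed used."""

    records: list[SpectrumRecord]
    truth: pd.DataFrame  # analyte_id, class, precursor_mz, rt_min, losses_kept
    seed: int


def default_templates(include_minor: bool = True) -> list[ClassTemplate]:
    """The shipped panel: nine modeled classes, optionally plus 17 minor ones.

    The nine classes are well separated: each has its own neutral-loss motif,
    and precursor/RT windows overlap only where the loss motifs differ
    strongly (e.g. cathinones vs phenethylamines).
    """
    templates = [
        ClassTemplate("benzodiazepines", (285, 330), (4.5, 6.0),
                      [(26.003, 1.0), (35.011, 0.95), (63.021, 0.85)]),
        ClassTemplate("cathinones", (150, 222), (1.5, 3.5),
                      [(18.011, 1.0), (31.042, 0.95), (46.065, 0.85)]),
        ClassTemplate("fentanyls", (320, 420), (5.0, 7.2),
                      [(84.081, 1.0), (146.096, 0.95), (188.107, 0.85)]),
        ClassTemplate("JWH", (330, 392), (8.0, 10.5),
                      [(109.028, 1.0), (127.054, 0.95), (169.065, 0.85)]),
        ClassTemplate("nitazenes", (380, 442), (6.2, 7.6),
                      [(72.081, 1.0), (100.076, 0.95), (120.081, 0.85)]),
        ClassTemplate("PINACA", (336, 398), (8.2, 10.8),
                      [(145.053, 1.0), (163.063, 0.95), (201.079, 0.85)]),
        ClassTemplate("tryptamines", (189, 291), (2.0, 4.0),
                      [(17.027, 1.0), (58.066, 0.95), (77.039, 0.85)]),
        ClassTemplate("arylcyclohexylamines", (220, 282), (3.8, 5.3),
                      [(36.021, 1.0), (81.070, 0.95), (98.073, 0.85)]),
        ClassTemplate("phenethylamines", (166, 232), (1.0, 2.9),
                      [(33.034, 1.0), (48.045, 0.95), (66.050, 0.85)]),
    ]
    if include_minor:
        templates.extend(minor_class_templates())
    return templates


def minor_class_templates() -> list[ClassTemplate]:
    """Seventeen small classes (2-3 analytes) below the SIMCA modeling floor."""
    templates = []
    for i, name in enumerate(_MINOR_NAMES):
        lo = 150.0 + 14.0 * i
        templates.append(
            ClassTemplate(
                class_label=name,
                precursor_range=(lo, lo + 28.0),
                rt_range=(1.0 + 0.55 * i, 1.7 + 0.55 * i),
                characteristic_losses=[
                    (20.0 + 3.7 * i, 1.0),
                    (45.5 + 2.9 * i, 0.9),
                    (71.0 + 4.3 * i, 0.8),
                ],
            )
        )
    return templates


def well_separated_templates() -> list[ClassTemplate]:
    """The nine modeled classes in an idealized, fully unimodal configuration.

    Identical to :func:`default_templates` except that every characteristic
    loss occurs with probability 1 and no fragment is ever dropped, so each
    class forms a single tight cluster in the 8-variable space.  Used by
    calibration and end-to-end recovery tests, where fragment dropout would
    split a class into sub-clusters and confound the property under test.
    """
    out = []
    for t in default_templates(include_minor=False):
        out.append(
            ClassTemplate(
                class_label=t.class_label,
                precursor_range=t.precursor_range,
                rt_range=t.rt_range,
                characteristic_losses=[(l, 1.0) for l, _ in t.characteristic_losses],
                n_extra_fragments=t.n_extra_fragments,
                intensity_concentration=t.intensity_concentration,
                missing_fragment_prob=0.0,
                feature_noise_sd=t.feature_noise_sd,
            )
        )
    return out


def no_nps_template() -> ClassTemplate:
    """A template far from every default class (a non-NPS seizure look-alike)."""
    return ClassTemplate(
        class_label="no_nps",
        precursor_range=(500, 560),
        rt_range=(11.0, 12.5),
        characteristic_losses=[(210.5, 1.0), (230.7, 0.95), (250.9, 0.85)],
    )


def overlapping_templates() -> tuple[ClassTemplate, ClassTemplate]:
    """Two structurally similar classes sharing loss motifs and mass windows.

    Mimics analogue families built on a common scaffold: the shared losses
    make their neutral-loss feature clusters overlap, so both SIMCA models
    tend to accept samples of either class.
    """
    shared = [(109.028, 1.0), (127.054, 0.95), (169.065, 0.9)]
    a = ClassTemplate("indole_a", (330, 392), (8.0, 10.5), list(shared))
    b = ClassTemplate("indole_b", (336, 398), (8.1, 10.6), list(shared))
    return a, b


def _panel_sizes(
    templates: Sequence[ClassTemplate], n_per_class: int | dict[str, int]
) -> list[int]:
    if isinstance(n_per_class, int):
        if n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        return [n_per_class] * len(templates)
    sizes = []
    for t in templates:
        n = n_per_class.get(t.class_label)
        if n is None or n < 1:
            raise ValueError(f"no valid size for class {t.class_label!r}")
        sizes.append(int(n))
    return sizes


def default_panel_sizes() -> dict[str, int]:
    """Sizes for the full 159-record default panel (9 modeled + 17 minor classes)."""
    return {**MODELED_CLASS_SIZES, **MINOR_CLASS_SIZES}


def generate_panel(
    templates: Sequence[ClassTemplate],
    n_per_class: int | dict[str, int],
    seed: int,
) -> SyntheticPanel:
    """Draw a labeled spectrum panel from class templates (deterministic per seed).

    Per record: precursor and RT uniform in the template windows; one
    fragment per retained characteristic loss at ``precursor - loss`` plus
    Gaussian m/z jitter, with rank-patterned intensities whose relative
    spread is ``1/sqrt(intensity_concentration)``; a few low-intensity
    nuisance fragments below the 10% relative-intensity threshold; each
    characteristic fragment independently dropped with
    ``missing_fragment_prob`` (the first is always kept so every spectrum
    stays non-empty).
    """
    templates = list(templates)
    if not templates:
        raise ValueError("at least one template is required")
    sizes = _panel_sizes(templates, n_per_class)
    rng = np.random.default_rng(seed)
    records: list[SpectrumRecord] = []
    truth_rows = []
    for template, n in zip(templates, sizes):
        conc = template.intensity_concentration
        for k in range(n):
            analyte_id = f"{template.class_label}_{k:03d}"
            precursor = float(rng.uniform(*template.precursor_range))
            rt = float(rng.uniform(*template.rt_range))
            kept: list[float] = []
            peaks: list[tuple[float, float]] = []
            for rank, (loss, prob) in enumerate(template.characteristic_losses):
                keep = rng.random() < prob and not (
                    rng.random() < template.missing_fragment_prob
                )
                if rank == 0:
                    keep = True
                if not keep:
                    continue
                kept.append(loss)
                mz = precursor - loss + rng.normal(0, template.feature_noise_sd)
                base = _BASE_WEIGHTS[min(rank, len(_BASE_WEIGHTS) - 1)]
                rel = base * rng.gamma(shape=conc, scale=1.0 / conc)
                peaks.append((mz, 1e4 * rel))
            n_extra = int(rng.integers(template.n_extra_fragments[0],
                                       template.n_extra_fragments[1] + 1))
            for _ in range(n_extra):
                mz = float(rng.uniform(50.0, max(60.0, precursor - 10.0)))
                peaks.append((mz, 1e4 * float(rng.uniform(0.01, 0.08))))
            records.append(
                SpectrumRecord(
                    analyte_id=analyte_id,
                    precursor_mz=precursor,
                    retention_time=rt,
                    peaks=peaks,
                    class_label=template.class_label,
                    ce_range_tag="10-30V",
                )
            )
            truth_rows.append(
                {
                    "analyte_id": analyte_id,
                    "class": template.class_label,
                    "precursor_mz": precursor,
                    "rt_min": rt,
                    "losses_kept": ";".join(f"{l:.3f}" for l in kept),
                }
            )
    return SyntheticPanel(records=records, truth=pd.DataFrame(truth_rows), seed=seed)


def generate_feature_matrix(
    class_params: dict[str, tuple[np.ndarray, np.ndarray]],
    n_per_class: int | dict[str, int],
    seed: int,
) -> FeatureMatrix:
    """Sample class-clustered rows directly in the 8-variable space.

    ``class_params`` maps each label to a (mean, covariance) pair; rows per
    class are drawn from the corresponding multivariate normal.  Used by
    calibration tests that need exact distributional control without going
    through spectra.  Covariances must be symmetric positive semi-definite
    (rank-deficient is allowed — it yields exactly low-rank classes).
    """
    if not class_params:
        raise ValueError("class_params must be non-empty")
    rng = np.random.default_rng(seed)
    ids: list[str] = []
    labels: list[str] = []
    blocks: list[np.ndarray] = []
    for label, (mean, cov) in class_params.items():
        mean = np.asarray(mean, dtype=float)
        cov = np.asarray(cov, dtype=float)
        if mean.shape != (len(FEATURE_COLUMNS),) or cov.shape != (
            len(FEATURE_COLUMNS),
            len(FEATURE_COLUMNS),
        ):
            raise ValueError(f"class {label!r}: mean/covariance of wrong shape")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError(f"class {label!r}: covariance not symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-8 * max(1.0, eigvals.max()):
            raise ValueError(f"class {label!r}: covariance not positive semi-definite")
        if isinstance(n_per_class, int):
            n = n_per_class
        else:
            n = int(n_per_class[label])
        if n < 1:
            raise ValueError("n_per_class must be >= 1")
        blocks.append(rng.multivariate_normal(mean, cov, size=n, method="svd"))
        ids.extend(f"{label}_{k:03d}" for k in range(n))
        labels.extend([label] * n)
    values = np.vstack(blocks)
    return FeatureMatrix(
        analyte_ids=ids,
        class_labels=labels,
        values=values,
        mask=np.zeros_like(values, dtype=bool),
    )
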