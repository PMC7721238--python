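"""Assembly of the 223-column feature matrix.

Combines (a) a 25-variable clinical/demographic table and (b) per-subject
morphometric summaries in the FreeSurfer stats-table text dialect into a
single :class:`~scdprog.matrix.FeatureMatrix`.

The 198 MRI features follow the Desikan-Killiany parcellation: 46 global
segmentation volumes (mm^3, unnormalized), 68 mean cortical thicknesses
(mm, unnormalized), 68 regional white-matter volumes each divided by the
subject's total WM volume, and 16 subcortical volumes each divided by the
subject's total subcortical volume.  The two normalized blocks therefore sum
to exactly 1 per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import FeatureMatrix

__all__ = [
    "DEFAULT_CLINICAL_FEATURES",
    "BINARY_CLINICAL_FEATURES",
    "GLOBAL_STRUCTURES",
    "CORTICAL_ROIS",
    "WM_ROIS",
    "SUBCORTICAL_ROIS",
    "MRI_FEATURE_NAMES",
    "MorphometrySummaries",
    "load_clinical_table",
    "parse_stats_table",
    "normalize_block",
    "assemble_mri_features",
    "build_feature_matrix",
]


# ---------------------------------------------------------------------------
# Canonical schemas
# ---------------------------------------------------------------------------

#: The 25 clinical/demographic predictors: sociodemographics, baseline somatic
#: disease status, baseline psychometrics, and the follow-up-acquired
#: new-onset variables.  Config-driven: pass a different list to
#: :func:`load_clinical_table` / :func:`build_feature_matrix` to change it.
#: MMSE is deliberately absent from the predictor set (it is reported
#: descriptively but is not a predictor); re-include it via a custom schema.
DEFAULT_CLINICAL_FEATURES: tuple[str, ...] = (
    "gender",
    "age",
    "education",
    "smoke",
    "drink",
    "bmi",
    "hypertension_baseline",
    "diabetes_baseline",
    "hyperlipidemia_baseline",
    "sleep_disorder_baseline",
    "stroke_baseline",
    "heart_disease_baseline",
    "surgery_baseline",
    "moca_baseline",
    "gds_baseline",
    "social_support",
    "hypertension_followup",
    "diabetes_followup",
    "hyperlipidemia_followup",
    "sleep_disorder_followup",
    "stroke_followup",
    "heart_disease_followup",
    "surgery_followup",
    "hearing_loss_followup",
    "gds_followup",
)

#: Clinical predictors coded {0, 1}.
BINARY_CLINICAL_FEATURES: frozenset[str] = frozenset(
    {
        "gender",
        "stroke_baseline",
        "heart_disease_baseline",
        "surgery_baseline",
        "stroke_followup",
        "heart_disease_followup",
        "surgery_followup",
    }
)

_HEMI_GLOBAL = (
    "Lateral-Ventricle",
    "Inf-Lat-Vent",
    "Cerebellum-White-Matter",
    "Cerebellum-Cortex",
    "Thalamus-Proper",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens-area",
    "VentralDC",
    "vessel",
    "choroid-plexus",
    "Cerebral-White-Matter",
    "Cerebral-Cortex",
)

#: 46 global segmentation structures (32 lateralized + 14 midline).  The
#: exact membership of this set is a configuration default, overridable per
#: call; it follows the standard whole-brain segmentation volume table.
GLOBAL_STRUCTURES: tuple[str, ...] = tuple(
    f"{hemi}-{name}" for name in _HEMI_GLOBAL for hemi in ("Left", "Right")
) + (
    "3rd-Ventricle",
    "4th-Ventricle",
    "5th-Ventricle",
    "Brain-Stem",
    "CSF",
    "Optic-Chiasm",
    "WM-hypointensities",
    "non-WM-hypointensities",
    "CC_Posterior",
    "CC_Mid_Posterior",
    "CC_Central",
    "CC_Mid_Anterior",
    "CC_Anterior",
    "Total-Ventricles",
)

_DK_REGIONS = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

#: 68 cortical thickness ROIs (34 Desikan-Killiany regions per hemisphere).
CORTICAL_ROIS: tuple[str, ...] = tuple(
    f"{hemi}-{r}" for hemi in ("lh", "rh") for r in _DK_REGIONS
)

#: 68 gyral white-matter volume ROIs underneath the same parcels.
WM_ROIS: tuple[str, ...] = tuple(
    f"wm-{hemi}-{r}" for hemi in ("lh", "rh") for r in _DK_REGIONS
)

_SUBCORT = (
    "Thalamus-Proper",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens-area",
    "VentralDC",
)

#: 16 subcortical gray-matter volume ROIs.
SUBCORTICAL_ROIS: tuple[str, ...] = tuple(
    f"{hemi}-{name}" for hemi in ("Left", "Right") for name in _SUBCORT
)

#: All 198 assembled MRI feature names, block-prefixed to keep them unique.
MRI_FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"global:{n}" for n in GLOBAL_STRUCTURES)
    + tuple(f"thick:{n}" for n in CORTICAL_ROIS)
    + tuple(f"wm:{n}" for n in WM_ROIS)
    + tuple(f"subcort:{n}" for n in SUBCORTICAL_ROIS)
)

assert len(GLOBAL_STRUCTURES) == 46
assert len(CORTICAL_ROIS) == 68
assert len(WM_ROIS) == 68
assert len(SUBCORTICAL_ROIS) == 16
assert len(MRI_FEATURE_NAMES) == 198


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

_LABEL_CODES = {"pSCD": 1, "sSCD": 0, "1": 1, "0": 0, 1: 1, 0: 0}


def load_clinical_table(
    path: str | Path,
    schema: Sequence[str] | None = None,
    subject_column: str = "subject_id",
    label_column: str = "label",
) -> pd.DataFrame:
    """Load the per-subject clinical/demographic table.

    Parameters
    ----------
    path
        Delimited text file (CSV or TSV, auto-detected) with a header row.
    schema
        Names of the columns to treat as predictors; defaults to the
        canonical 25-variable list.
    subject_column, label_column
        Identifier column and (optional) outcome column.  Labels may be coded
        ``pSCD``/``sSCD`` or ``1``/``0``.

    Returns
    -------
    pandas.DataFrame
        Indexed by subject id, columns = schema order (plus ``label`` if an
        outcome column was present), rows in file order.
    """
    schema = list(schema) if schema is not None else list(DEFAULT_CLINICAL_FEATURES)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in [subject_column, *schema] if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table is missing required column(s): {missing}")
    out = df[[subject_column, *schema]].copy()
    for col in schema:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {out[col].iloc[row]!r} in column {col!r}, row {row}"
            )
        if coerced.isna().any():
            raise ValueError(f"missing value(s) in clinical column {col!r}")
        out[col] = coerced.astype(float)
    for col in schema:
        if col in BINARY_CLINICAL_FEATURES and not np.isin(out[col], [0.0, 1.0]).all():
            raise ValueError(f"binary clinical column {col!r} must be coded 0/1")
    if label_column in df.columns:
        try:
            out[label_column] = [
                _LABEL_CODES[v if not isinstance(v, str) else v.strip()]
                for v in df[label_column]
            ]
        except KeyError as exc:
            raise ValueError(f"unrecognized outcome label {exc.args[0]!r}") from None
    out = out.set_index(subject_column)
    out.index = out.index.map(str)
    if out.index.duplicated().any():
        raise ValueError("duplicate subject ids in clinical table")
    return out


# ---------------------------------------------------------------------------
# FreeSurfer-style stats tables
# ---------------------------------------------------------------------------

_VALUE_COLUMN = {
    "global": "Volume_mm3",
    "wm": "Volume_mm3",
    "subcortical": "Volume_mm3",
    "cortical_thickness": "ThickAvg",
}


def parse_stats_table(path: str | Path, kind: str) -> dict[str, float]:
    """Parse one FreeSurfer-style stats table into a region -> value map.

    The dialect: lines beginning ``#`` are metadata (an optional
    ``# ColHeaders ...`` line names the data columns); data rows are
    whitespace-delimited, one per structure.  For ``cortical_thickness`` the
    mean-thickness column is returned, for the volumetric kinds the mm^3
    volume column.  Tables without a ColHeaders line must have exactly two
    columns (name, value).
    """
    if kind not in _VALUE_COLUMN:
        raise ValueError(
            f"unknown stats-table kind {kind!r}; expected one of {sorted(_VALUE_COLUMN)}"
        )
    headers: list[str] | None = None
    out: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.startswith("ColHeaders"):
                headers = body.split()[1:]
            continue
        parts = stripped.split()
        if headers is not None:
            if len(parts) != len(headers):
                raise ValueError(f"row {stripped!r} does not match ColHeaders")
            row = dict(zip(headers, parts))
            name = row.get("StructName")
            if name is None:
                raise ValueError("ColHeaders line lacks a StructName column")
            value_col = _VALUE_COLUMN[kind]
            if value_col not in row:
                raise ValueError(f"stats table lacks required column {value_col!r}")
            value = float(row[value_col])
        else:
            if len(parts) != 2:
                raise ValueError(
                    f"headerless stats row {stripped!r} must have exactly two columns"
                )
            name, value = parts[0], float(parts[1])
        if name in out:
            raise ValueError(f"duplicate region name {name!r} in stats table")
        out[name] = value
    if not out:
        raise ValueError(f"stats table {path} contains no data rows")
    return out


# ---------------------------------------------------------------------------
# MRI feature assembly
# ---------------------------------------------------------------------------


@dataclass
class MorphometrySummaries:
    """Per-subject morphometric summaries, one map per feature block.

    ``global_volumes`` and the two volume blocks are in mm^3; cortical
    thickness is mean thickness in mm.  Keys are checked against the
    configured region lists: absent required regions raise, unexpected extra
    regions warn and are dropped.
    """

    global_volumes: Mapping[str, float]
    cortical_thickness: Mapping[str, float]
    wm_volumes: Mapping[str, float]
    subcortical_volumes: Mapping[str, float]
    expected_global: Sequence[str] = field(default=GLOBAL_STRUCTURES)
    expected_cortical: Sequence[str] = field(default=CORTICAL_ROIS)
    expected_wm: Sequence[str] = field(default=WM_ROIS)
    expected_subcortical: Sequence[str] = field(default=SUBCORTICAL_ROIS)

    def __post_init__(self) -> None:
        blocks = [
            ("global", self.global_volumes, self.expected_global),
            ("cortical_thickness", self.cortical_thickness, self.expected_cortical),
            ("wm", self.wm_volumes, self.expected_wm),
            ("subcortical", self.subcortical_volumes, self.expected_subcortical),
        ]
        for block, values, expected in blocks:
            absent = [r for r in expected if r not in values]
            if absent:
                raise ValueError(f"{block} block is missing required region(s): {absent[:5]}")
            extra = sorted(set(values) - set(expected))
            if extra:
                warnings.warn(
                    f"{block} block has {len(extra)} unrecognized region(s) "
                    f"(e.g. {extra[:3]}); they are ignored",
                    stacklevel=3,
                )

    def ordered(self, block: str) -> np.ndarray:
        values, expected = {
            "global": (self.global_volumes, self.expected_global),
            "cortical_thickness": (self.cortical_thickness, self.expected_cortical),
            "wm": (self.wm_volumes, self.expected_wm),
            "subcortical": (self.subcortical_volumes, self.expected_subcortical),
        }[block]
        return np.array([float(values[r]) for r in expected])


def normalize_block(volumes: Sequence[float]) -> np.ndarray:
    """Divide each regional volume by the block total (so the block sums to 1)."""
    v = np.asarray(volumes, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("block total volume must be positive")
    return v / total


def assemble_mri_features(summaries: MorphometrySummaries) -> pd.Series:
    """Assemble the 198 MRI features for one subject.

    Global volumes and cortical thicknesses pass through unchanged; the WM
    and subcortical volume blocks are normalized by their respective totals.
    """
    g = summaries.ordered("global")
    t = summaries.ordered("cortical_thickness")
    w = summaries.ordered("wm")
    s = summaries.ordered("subcortical")
    for block, v in (("global", g), ("wm", w), ("subcortical", s)):
        if (v <= 0).any():
            raise ValueError(f"non-positive volume in {block} block")
    if ((t <= 0) | (t > 6)).any():
        raise ValueError("cortical thickness outside the plausible (0, 6] mm band")
    names = (
        [f"global:{n}" for n in summaries.expected_global]
        + [f"thick:{n}" for n in summaries.expected_cortical]
        + [f"wm:{n}" for n in summaries.expected_wm]
        + [f"subcort:{n}" for n in summaries.expected_subcortical]
    )
    values = np.concatenate([g, t, normalize_block(w), normalize_block(s)])
    return pd.Series(values, index=names)


def build_feature_matrix(
    clinical: pd.DataFrame,
    mri: Mapping[str, pd.Series],
    schema: Sequence[str] | None = None,
    label_column: str = "label",
) -> FeatureMatrix:
    """Join the clinical block and per-subject MRI vectors into one matrix.

    Column order is schema order: the clinical block first, then the MRI
    block as produced by :func:`assemble_mri_features`.  Under the canonical
    configuration the result has 25 + 198 = 223 columns.
    """
    schema = list(schema) if schema is not None else list(DEFAULT_CLINICAL_FEATURES)
    clin_subjects = [str(s) for s in clinical.index]
    mri_subjects = {str(s) for s in mri}
    only_clin = sorted(set(clin_subjects) - mri_subjects)
    only_mri = sorted(mri_subjects - set(clin_subjects))
    if only_clin or only_mri:
        raise ValueError(
            f"subject mismatch between clinical and MRI inputs: "
            f"clinical-only {only_clin[:5]}, MRI-only {only_mri[:5]}"
        )
    missing = [c for c in schema if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table is missing schema column(s): {missing}")

    mri_names: list[str] | None = None
    rows = []
    for subject in clin_subjects:
        vec = mri[subject]
        if mri_names is None:
            mri_names = [str(i) for i in vec.index]
        elif [str(i) for i in vec.index] != mri_names:
            raise ValueError(f"MRI feature names for subject {subject!r} are inconsistent")
        rows.append(vec.to_numpy(dtype=float))
    assert mri_names is not None
    values = np.hstack([clinical[schema].to_numpy(dtype=float), np.vstack(rows)])
    labels = None
    if label_column in clinical.columns:
        labels = clinical[label_column].to_numpy(dtype=int)
    return FeatureMatrix(
        subject_ids=clin_subjects,
        feature_names=list(schema) + mri_names,
        values=values,
        labels=labels,
    )
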