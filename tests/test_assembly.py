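"""Feature assembly: clinical tables, stats-table parsing, MRI normalization."""

import numpy as np
import pandas as pd
import pytest

from scdprog import assembly
from scdprog.assembly import (
    CORTICAL_ROIS,
    DEFAULT_CLINICAL_FEATURES,
    GLOBAL_STRUCTURES,
    MRI_FEATURE_NAMES,
    SUBCORTICAL_ROIS,
    WM_ROIS,
    MorphometrySummaries,
    assemble_mri_features,
    build_feature_matrix,
    load_clinical_table,
    normalize_block,
    parse_stats_table,
)


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------


def write_clinical_csv(path, n_rows=3, label=True, drop=None, education=9.50):
    cols = {"subject_id": [f"s{i}" for i in range(n_rows)]}
    for c in DEFAULT_CLINICAL_FEATURES:
        if c in assembly.BINARY_CLINICAL_FEATURES:
            cols[c] = [i % 2 for i in range(n_rows)]
        elif c == "education":
            cols[c] = [education] * n_rows
        else:
            cols[c] = [float(i + 1) for i in range(n_rows)]
    if label:
        cols["label"] = ["pSCD" if i % 2 else "sSCD" for i in range(n_rows)]
    df = pd.DataFrame(cols)
    if drop:
        df = df.drop(columns=[drop])
    df.to_csv(path, index=False)
    return df


def test_clinical_round_trip(tmp_path):
    path = tmp_path / "clin.csv"
    write_clinical_csv(path, n_rows=3)
    df = load_clinical_table(path)
    assert len(df) == 3
    assert list(df.columns[:-1]) == list(DEFAULT_CLINICAL_FEATURES)
    assert len(DEFAULT_CLINICAL_FEATURES) == 25
    assert df["label"].tolist() == [0, 1, 0]


def test_clinical_missing_column_is_schema_error(tmp_path):
    path = tmp_path / "clin.csv"
    write_clinical_csv(path, drop="education")
    with pytest.raises(ValueError, match="education"):
        load_clinical_table(path)


def test_clinical_non_numeric_value_names_location(tmp_path):
    path = tmp_path / "clin.csv"
    df = write_clinical_csv(path)
    df["age"] = df["age"].astype(object)
    df.loc[1, "age"] = "old"
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="age"):
        load_clinical_table(path)


def test_clinical_table1_group_means_round_trip(tmp_path):
    """Two synthetic subjects carrying the per-group mean education values."""
    path = tmp_path / "clin.csv"
    df = write_clinical_csv(path, n_rows=2, education=0.0)
    df.loc[0, "education"] = 9.50  # stable-group mean
    df.loc[1, "education"] = 7.17  # progressive-group mean
    df.to_csv(path, index=False)
    out = load_clinical_table(path)
    assert out["education"].tolist() == [9.50, 7.17]


# ---------------------------------------------------------------------------
# stats tables
# ---------------------------------------------------------------------------

STATS_WITH_HEADERS = """\
# Title Segmentation Statistics
# ColHeaders Index SegId NVoxels Volume_mm3 StructName
 1  10  100 100.0 RegionA
 2  11  200 200.0 RegionB
 3  12  300 300.0 RegionC
"""


def test_parse_stats_table_round_trip(tmp_path):
    p = tmp_path / "aseg.stats"
    p.write_text(STATS_WITH_HEADERS)
    out = parse_stats_table(p, kind="global")
    assert out == {"RegionA": 100.0, "RegionB": 200.0, "RegionC": 300.0}


def test_parse_stats_table_thickness_column(tmp_path):
    p = tmp_path / "aparc.stats"
    p.write_text(
        "# ColHeaders StructName NumVert SurfArea ThickAvg\n"
        "bankssts 100 60 2.5\n"
        "insula 120 70 3.0\n"
    )
    out = parse_stats_table(p, kind="cortical_thickness")
    assert out == {"bankssts": 2.5, "insula": 3.0}


def test_parse_stats_table_duplicate_region(tmp_path):
    p = tmp_path / "dup.stats"
    p.write_text("RegionA 1.0\nRegionA 2.0\n")
    with pytest.raises(ValueError, match="duplicate"):
        parse_stats_table(p, kind="wm")


def test_parse_stats_table_empty(tmp_path):
    p = tmp_path / "empty.stats"
    p.write_text("# only comments here\n")
    with pytest.raises(ValueError, match="no data rows"):
        parse_stats_table(p, kind="subcortical")


def test_parse_stats_table_unknown_kind(tmp_path):
    p = tmp_path / "x.stats"
    p.write_text("A 1.0\n")
    with pytest.raises(ValueError, match="unknown"):
        parse_stats_table(p, kind="surface_area")


# ---------------------------------------------------------------------------
# MRI assembly
# ---------------------------------------------------------------------------


def make_summaries(rng=None, scale=1.0):
    rng = rng or np.random.default_rng(0)
    return MorphometrySummaries(
        global_volumes={n: float(rng.uniform(500, 9000)) for n in GLOBAL_STRUCTURES},
        cortical_thickness={n: float(rng.uniform(1.5, 4.0)) for n in CORTICAL_ROIS},
        wm_volumes={n: scale * float(rng.uniform(1000, 4000)) for n in WM_ROIS},
        subcortical_volumes={n: float(rng.uniform(500, 2500)) for n in SUBCORTICAL_ROIS},
    )


def test_normalize_block_symmetry():
    assert np.allclose(normalize_block([7.0, 7.0]), [0.5, 0.5])


def test_assemble_blocks_sum_to_one_and_thickness_unchanged():
    s = make_summaries()
    vec = assemble_mri_features(s)
    assert len(vec) == 198
    wm = vec[[f"wm:{n}" for n in WM_ROIS]]
    sub = vec[[f"subcort:{n}" for n in SUBCORTICAL_ROIS]]
    assert abs(wm.sum() - 1.0) < 1e-12
    assert abs(sub.sum() - 1.0) < 1e-12
    # thickness and global volumes pass through unchanged
    for n in CORTICAL_ROIS[:5]:
        assert vec[f"thick:{n}"] == s.cortical_thickness[n]
    for n in GLOBAL_STRUCTURES[:5]:
        assert vec[f"global:{n}"] == s.global_volumes[n]


def test_assemble_subcortical_matches_hand_sum():
    s = make_summaries()
    vec = assemble_mri_features(s)
    total = sum(s.subcortical_volumes.values())
    for n in SUBCORTICAL_ROIS:
        assert vec[f"subcort:{n}"] == pytest.approx(s.subcortical_volumes[n] / total, rel=1e-12)


def test_assemble_wm_scale_invariance():
    rng = np.random.default_rng(5)
    s1 = make_summaries(np.random.default_rng(5))
    s2 = MorphometrySummaries(
        global_volumes=s1.global_volumes,
        cortical_thickness=s1.cortical_thickness,
        wm_volumes={k: 17.0 * v for k, v in s1.wm_volumes.items()},
        subcortical_volumes=s1.subcortical_volumes,
    )
    v1 = assemble_mri_features(s1)
    v2 = assemble_mri_features(s2)
    wm_names = [f"wm:{n}" for n in WM_ROIS]
    assert np.allclose(v1[wm_names], v2[wm_names])


def test_missing_region_is_error():
    s = make_summaries()
    broken = dict(s.wm_volumes)
    broken.pop(WM_ROIS[0])
    with pytest.raises(ValueError, match="missing required region"):
        MorphometrySummaries(
            global_volumes=s.global_volumes,
            cortical_thickness=s.cortical_thickness,
            wm_volumes=broken,
            subcortical_volumes=s.subcortical_volumes,
        )


def test_unknown_region_warns():
    s = make_summaries()
    extra = dict(s.subcortical_volumes, **{"Mystery-Region": 10.0})
    with pytest.warns(UserWarning, match="unrecognized"):
        MorphometrySummaries(
            global_volumes=s.global_volumes,
            cortical_thickness=s.cortical_thickness,
            wm_volumes=s.wm_volumes,
            subcortical_volumes=extra,
        )


# ---------------------------------------------------------------------------
# matrix build
# ---------------------------------------------------------------------------


def build_inputs(tmp_path, n=5):
    path = tmp_path / "clin.csv"
    write_clinical_csv(path, n_rows=n)
    clinical = load_clinical_table(path)
    rng = np.random.default_rng(1)
    mri = {s: assemble_mri_features(make_summaries(rng)) for s in clinical.index}
    return clinical, mri


def test_build_feature_matrix_canonical_dimension(tmp_path):
    clinical, mri = build_inputs(tmp_path, n=5)
    fm = build_feature_matrix(clinical, mri)
    assert fm.values.shape == (5, 223)
    assert fm.feature_names[:25] == list(DEFAULT_CLINICAL_FEATURES)
    assert fm.feature_names[25:] == list(MRI_FEATURE_NAMES)
    assert fm.labels is not None and len(fm.labels) == 5


def test_build_feature_matrix_subject_mismatch(tmp_path):
    clinical, mri = build_inputs(tmp_path, n=3)
    mri.pop(clinical.index[0])
    with pytest.raises(ValueError, match="mismatch"):
        build_feature_matrix(clinical, mri)


def test_build_feature_matrix_permutation_safe(tmp_path):
    clinical, mri = build_inputs(tmp_path, n=4)
    fm = build_feature_matrix(clinical, mri)
    perm = [2, 0, 3, 1]
    fm_perm = build_feature_matrix(clinical.iloc[perm], mri)
    for out_row, subject in enumerate(fm_perm.subject_ids):
        in_row = fm.subject_ids.index(subject)
        assert np.array_equal(fm_perm.values[out_row], fm.values[in_row])
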