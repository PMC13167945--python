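import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from warfdose.core import (
    FixedCovariates,
    Genotype,
    NormalizationStats,
    PatientRecord,
    TargetRange,
    Visit,
    assign_target_range,
    denormalize,
    encode_fixed,
    normalize,
    read_cohort,
    write_cohort,
)


@pytest.mark.parametrize(
    "indication, expected",
    [
        ("mechanical_valve", (2.0, 2.5)),
        ("bioprosthetic_valve", (1.8, 2.3)),
        ("valve_repair", (1.5, 2.5)),
        ("other", (2.0, 3.0)),
    ],
)
def test_target_range_by_indication(indication, expected):
    tr = assign_target_range(indication)
    assert (tr.low, tr.high) == expected


def test_target_range_override_wins():
    tr = assign_target_range("mechanical_valve", override=TargetRange(2.5, 3.5))
    assert (tr.low, tr.high) == (2.5, 3.5)


def test_target_range_rejects_unknown_label():
    with pytest.raises(ValueError, match="aortic_stent"):
        assign_target_range("aortic_stent")


def test_normalize_hand_values():
    stats = NormalizationStats({"weight": 55.7}, {"weight": 10.3})
    assert normalize(55.7, stats, "weight") == 0.0
    assert normalize(66.0, stats, "weight") == pytest.approx(1.0)


def test_normalize_errors():
    stats = NormalizationStats({"x": 0.0}, {"x": 1.0})
    with pytest.raises(KeyError):
        normalize(1.0, stats, "y")
    with pytest.raises(ValueError):
        normalize(float("nan"), stats, "x")


@settings(derandomize=True, max_examples=50)
@given(
    x=st.floats(-1e6, 1e6),
    mean=st.floats(-100, 100),
    std=st.floats(0.01, 100),
)
def test_normalize_roundtrip_and_affine(x, mean, std):
    stats = NormalizationStats({"f": mean}, {"f": std})
    assert denormalize(normalize(x, stats, "f"), stats, "f") == pytest.approx(x, abs=1e-6)
    assert normalize(mean, stats, "f") == pytest.approx(0.0)
    assert normalize(mean + std, stats, "f") == pytest.approx(1.0)


def test_constant_feature_flagged_with_unit_std():
    stats = NormalizationStats.from_arrays({"c": np.full(5, 3.0)})
    assert "c" in stats.constant_features
    assert stats.std["c"] == 1.0


def test_genotype_encoding_counts():
    g = Genotype("*1/*3", "GA")
    assert g.cyp2c9_variant_alleles == 1
    assert g.cyp2c9_star3 == 1
    assert g.vkorc1_a_alleles == 1
    assert Genotype("*3/*3", "AA").cyp2c9_variant_alleles == 2
    with pytest.raises(ValueError):
        Genotype("*1/*4", "AA")


def test_unknown_genotype_encodes_as_nan():
    fc = FixedCovariates(60, 165, 70, Genotype(known=False))
    vec = encode_fixed(fc)
    assert np.isnan(vec["vkorc1_a_alleles"])
    assert vec["age"] == 60


def test_patient_record_invariants():
    fc = FixedCovariates(60, 165, 70)
    with pytest.raises(ValueError, match="strictly increase"):
        PatientRecord("p", fc, (Visit(3, 2.0, 2.5), Visit(3, 2.1, 2.5)))
    rec = PatientRecord("p", fc, (Visit(3, 2.0, 2.5),), indication="mechanical_valve")
    assert rec.target.low == 2.0


def _toy_cohort():
    fc1 = FixedCovariates(60, 165, 70, Genotype("*1/*1", "AA"), digoxin=True)
    fc2 = FixedCovariates(45.5, 172, 80, Genotype("*1/*3", "GA"), amiodarone=True)
    fc3 = FixedCovariates(70, 155, 52, Genotype(known=False))
    return [
        PatientRecord("a", fc1, (Visit(3, 1.8, 2.5), Visit(7, 2.2, 2.75)),
                      indication="mechanical_valve"),
        PatientRecord("b", fc2, (Visit(5, 2.4, 2.0), Visit(12, 2.1, 2.0), Visit(26, 2.2, 2.0)),
                      indication="bioprosthetic_valve"),
        PatientRecord("c", fc3, (Visit(4, 1.6, 3.0),), indication="other",
                      target=TargetRange(2.5, 3.5)),
    ]


def test_cohort_roundtrip(tmp_path):
    path = tmp_path / "cohort.csv"
    records = _toy_cohort()
    write_cohort(records, path)
    back = read_cohort(path)
    assert back == records
    # bit-stability: writing the read-back cohort reproduces the file
    path2 = tmp_path / "cohort2.csv"
    write_cohort(back, path2)
    assert path.read_text() == path2.read_text()


def test_read_cohort_duplicate_day_rejected(tmp_path):
    path = tmp_path / "dup.csv"
    write_cohort(_toy_cohort(), path)
    text = path.read_text().splitlines()
    text.append(text[1])  # duplicate patient a's first visit row
    path.write_text("\n".join(text) + "\n")
    with pytest.raises(ValueError, match="duplicate visit day 3 for patient 'a'"):
        read_cohort(path)


def test_read_cohort_unsorted_visits_warn_and_sort(tmp_path):
    path = tmp_path / "unsorted.csv"
    write_cohort(_toy_cohort(), path)
    lines = path.read_text().splitlines()
    lines[1], lines[2] = lines[2], lines[1]  # swap patient a's two visit rows
    path.write_text("\n".join(lines) + "\n")
    with pytest.warns(UserWarning, match="re-sorting"):
        back = read_cohort(path)
    assert [v.day for v in back[0].visits] == [3, 7]


def test_read_cohort_missing_column(tmp_path):
    path = tmp_path / "bad.csv"
    write_cohort(_toy_cohort(), path)
    import pandas as pd

    df = pd.read_csv(path).drop(columns=["inr"])
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="inr"):
        read_cohort(path)
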