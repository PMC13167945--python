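import numpy as np
import pytest

from warfdose.core import FixedCovariates, Genotype, PatientRecord, Visit
from warfdose.dataset import (
    STEP_FEATURES,
    build_cohort_samples,
    build_samples,
    collate,
    compute_stats,
    denormalize_label,
    make_split,
)


def _record(n_visits=5, pid="p"):
    visits = tuple(
        Visit(day=3 + 7 * i, inr=1.8 + 0.1 * i, dose=2.5 + 0.25 * i) for i in range(n_visits)
    )
    return PatientRecord(pid, FixedCovariates(60, 165, 70), visits,
                         indication="mechanical_valve")


def test_one_sample_per_decision_visit():
    assert len(build_samples(_record(5))) == 4
    assert build_samples(_record(1)) == []


def test_sample_structure_and_masking():
    rec = _record(5)
    s = [x for x in build_samples(rec) if x.decision_visit == 3][0]
    assert len(s.steps) == 3
    assert s.steps[-1].masked and not any(st.masked for st in s.steps[:-1])
    # the hidden dose is zeroed in the builder; the label carries it
    assert s.steps[-1].dose == 0.0
    assert s.label == rec.visits[2].dose
    # first step duplicates its own dose as dose_prev
    assert s.steps[0].dose_prev == rec.visits[0].dose
    # intermediate intervals are day differences
    assert s.steps[0].interval_next == rec.visits[1].day - rec.visits[0].day


def test_inr_target_masks_inr_instead():
    s = build_samples(_record(3), target="inr")[-1]
    assert s.steps[-1].inr == 0.0
    assert s.steps[-1].dose > 0
    assert s.label == _record(3).visits[-1].inr


def test_sample_count_matches_visit_arithmetic(tiny_cohort):
    samples = build_cohort_samples(tiny_cohort)
    expected = sum(max(0, r.n_visits - 1) for r in tiny_cohort)
    assert len(samples) == expected


def test_split_partitions_patients(small_cohort):
    plan = make_split(small_cohort, seed=1)
    ids = {r.patient_id for r in small_cohort}
    assert len(plan.test_ids) == 12  # 10% of 120
    for k, (train, val) in enumerate(plan.folds):
        assert set(train) | set(val) | set(plan.test_ids) == ids
        assert not set(train) & set(val)
        assert not set(val) & set(plan.test_ids)
        assert not set(train) & set(plan.test_ids)


def test_split_fold_sizes_and_determinism():
    records = [_record(3, pid=f"p{i}") for i in range(100)]
    plan = make_split(records, seed=5, k=10)
    assert len(plan.test_ids) == 10
    assert all(len(val) == 9 for _, val in plan.folds)
    assert all(len(train) == 81 for train, _ in plan.folds)
    assert plan == make_split(records, seed=5, k=10)
    with pytest.raises(ValueError):
        make_split(records[:5], seed=0, k=10)


def test_split_roundtrip_json(tmp_path, small_cohort):
    plan = make_split(small_cohort, seed=9)
    plan.to_json(tmp_path / "plan.json")
    from warfdose.dataset import SplitPlan

    assert SplitPlan.from_json(tmp_path / "plan.json") == plan


def test_collate_padding_and_mask(tiny_cohort):
    samples = build_cohort_samples(tiny_cohort)
    stats = compute_stats(samples)
    short = [s for s in samples if len(s.steps) == 2][0]
    long = [s for s in samples if len(s.steps) == 5][0]
    batch = collate([short, long], stats)
    assert batch.steps.shape == (2, 5, len(STEP_FEATURES))
    assert batch.mask[0].tolist() == [True, True, False, False, False]
    assert batch.mask[1].all()
    assert np.all(batch.steps[0, 2:] == 0.0)
    # equal-length batch has an all-true mask
    eq = collate([long, long], stats)
    assert eq.mask.all()


def test_label_denormalization_roundtrip(tiny_cohort):
    samples = build_cohort_samples(tiny_cohort)[:10]
    stats = compute_stats(samples)
    batch = collate(samples, stats)
    back = denormalize_label(batch.labels, stats)
    assert np.allclose(back, [s.label for s in samples])


def test_mask_channel_identifies_decision_step(tiny_cohort):
    samples = build_cohort_samples(tiny_cohort)[:20]
    stats = compute_stats(samples)
    batch = collate(samples, stats)
    mask_channel = batch.steps[:, :, STEP_FEATURES.index("masked")]
    for b, s in enumerate(samples):
        L = len(s.steps)
        assert mask_channel[b, L - 1] == 1.0
        assert np.all(mask_channel[b, : L - 1] == 0.0)


def test_truncation_keeps_most_recent_steps(tiny_cohort):
    samples = build_cohort_samples(tiny_cohort)
    stats = compute_stats(samples)
    long = [s for s in samples if len(s.steps) >= 5][0]
    with pytest.warns(UserWarning, match="truncated"):
        batch = collate([long], stats, max_len=3)
    assert batch.lengths[0] == 3
    # last (decision) step survives truncation
    assert batch.steps[0, 2, STEP_FEATURES.index("masked")] == 1.0


def test_stats_exclude_test_patients(small_cohort):
    plan = make_split(small_cohort, seed=4)
    train_ids, _ = plan.fold(0)
    by_id = {r.patient_id: r for r in small_cohort}
    train_samples = build_cohort_samples([by_id[i] for i in train_ids])
    stats = compute_stats(train_samples)
    # perturbing every test patient's doses must not change the stats
    perturbed = []
    for r in small_cohort:
        if r.patient_id in plan.test_ids:
            visits = tuple(Visit(v.day, v.inr, v.dose + 5.0) for v in r.visits)
            r = PatientRecord(r.patient_id, r.fixed, visits, r.indication, r.target)
        perturbed.append(r)
    by_id2 = {r.patient_id: r for r in perturbed}
    stats2 = compute_stats(build_cohort_samples([by_id2[i] for i in train_ids]))
    assert stats.mean == stats2.mean and stats.std == stats2.std


def test_sample_cache_jsonl_roundtrip(tmp_path, tiny_cohort):
    from warfdose.dataset import samples_from_jsonl, samples_to_jsonl

    samples = build_cohort_samples(tiny_cohort)[:15]
    samples_to_jsonl(samples, tmp_path / "cache.jsonl")
    back = samples_from_jsonl(tmp_path / "cache.jsonl")
    assert back == list(samples)


def test_nonpositive_label_dropped_with_warning():
    visits = (Visit(3, 1.8, 2.5), Visit(7, 2.0, 0.0), Visit(14, 2.1, 2.5))
    rec = PatientRecord("p", FixedCovariates(60, 165, 70), visits)
    with pytest.warns(UserWarning, match="dropped"):
        samples = build_samples(rec)
    assert [s.decision_visit for s in samples] == [3]
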