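"""Synthetic cohort generation, derived scores, and recall degradation."""

import dataclasses

import numpy as np
import pytest

from asrtscreen.cohort import (
    PACC5_SUBTESTS,
    Participant,
    default_design,
    dataframe_to_cohort,
    cohort_to_dataframe,
    generate_cohort,
    generate_recalls,
    impute_education,
    pacc5_composite,
    read_records_jsonl,
    scale_design,
    write_records_jsonl,
)
from asrtscreen.textpair import normalize_transcript

STORY = (
    "Anna Clarke left her house on Mill Road early on Tuesday morning to catch "
    "the train to Manchester where her sister Margaret was recovering in hospital "
    "after an operation on her knee and Anna brought yellow and red tulips"
)


def _zero_rate_design(n=4, **overrides):
    design = scale_design(default_design(), n)
    groups = {}
    for gid, spec in design.groups.items():
        groups[gid] = dataclasses.replace(
            spec,
            omission_rate=overrides.get("omission_rate", 0.0),
            substitution_rate=0.0,
            filler_insertion_rate=0.0,
            delayed_extra_omission_rate=overrides.get("delayed_extra_omission_rate", 0.0),
        )
    return dataclasses.replace(
        design, groups=groups, education_missing_rate=0.0, pacc5_missing_rate=0.0
    )


class TestGenerateCohort:
    def test_default_counts_match_two_by_two_design(self):
        cohort = generate_cohort(default_design(), seed=3)
        cu = [p for p in cohort if p.diagnosis == "CU"]
        mci = [p for p in cohort if p.diagnosis != "CU"]
        assert sum(p.amyloid == "positive" for p in cu) == 47
        assert sum(p.amyloid == "negative" for p in cu) == 46
        assert sum(p.amyloid == "positive" for p in mci) == 46
        assert sum(p.amyloid == "negative" for p in mci) == 54

    def test_seeded_determinism(self):
        a = generate_cohort(default_design(), seed=11)
        b = generate_cohort(default_design(), seed=11)
        assert a == b
        c = generate_cohort(default_design(), seed=12)
        assert a != c

    def test_zero_age_sd_gives_constant_ages(self):
        design = default_design()
        groups = {
            gid: dataclasses.replace(spec, age_sd=0.0)
            for gid, spec in design.groups.items()
        }
        cohort = generate_cohort(dataclasses.replace(design, groups=groups), seed=0)
        for p in cohort:
            assert p.age == pytest.approx(design.groups[p.group].age_mean)

    def test_nonpositive_group_size_rejected(self):
        design = default_design()
        bad = dataclasses.replace(design.groups[1], n=0)
        with pytest.raises(ValueError, match="positive"):
            generate_cohort(
                dataclasses.replace(design, groups={**design.groups, 1: bad}), seed=0
            )

    def test_mmse_within_eligibility_window(self):
        for p in generate_cohort(default_design(), seed=5):
            lo = 26 if p.diagnosis == "CU" else 23
            assert lo <= p.mmse <= 30

    def test_group_classification_is_total(self):
        cohort = generate_cohort(default_design(), seed=5)
        counts = {gid: 0 for gid in (1, 2, 3, 4)}
        for p in cohort:
            counts[p.group] += 1
        assert counts == {1: 46, 2: 54, 3: 47, 4: 46}

    def test_cohort_csv_roundtrip(self, tmp_path):
        cohort = generate_cohort(scale_design(default_design(), 5), seed=2)
        df = cohort_to_dataframe(cohort)
        back = dataframe_to_cohort(df)
        for orig, rt in zip(cohort, back):
            assert orig.id == rt.id
            assert orig.education == (
                pytest.approx(rt.education) if rt.education is not None else None
            )
            assert orig.pacc5_subtests.keys() == rt.pacc5_subtests.keys()


class TestGenerateRecalls:
    def test_zero_rates_reproduce_source_tokens(self):
        design = _zero_rate_design()
        cohort = generate_cohort(design, seed=1)
        records = generate_recalls(cohort, [STORY], design, seed=1)
        src = normalize_transcript(STORY).tokens
        for rec in records:
            assert normalize_transcript(rec.immediate_recall).tokens == src
            assert normalize_transcript(rec.delayed_recall).tokens == src

    def test_one_record_per_participant_per_story(self):
        design = _zero_rate_design()
        cohort = generate_cohort(design, seed=1)
        records = generate_recalls(cohort, [STORY, STORY], design, seed=1)
        assert len(records) == 2 * len(cohort)
        keys = {(r.participant_id, r.story_id) for r in records}
        assert len(keys) == len(records)

    def test_seeded_determinism(self):
        design = _zero_rate_design(omission_rate=0.3)
        cohort = generate_cohort(design, seed=4)
        a = generate_recalls(cohort, [STORY], design, seed=9)
        b = generate_recalls(cohort, [STORY], design, seed=9)
        assert a == b

    def test_empty_story_rejected(self):
        design = _zero_rate_design()
        cohort = generate_cohort(design, seed=1)
        with pytest.raises(ValueError):
            generate_recalls(cohort, ["  "], design, seed=0)
        with pytest.raises(ValueError):
            generate_recalls(cohort, [], design, seed=0)

    @pytest.mark.parametrize("rates", [(0.1, 0.5)])
    def test_higher_omission_retains_fewer_tokens(self, rates):
        src_len = len(normalize_transcript(STORY).tokens)
        fractions = []
        for rate in rates:
            design = _zero_rate_design(n=30, omission_rate=rate)
            cohort = generate_cohort(design, seed=2)
            records = generate_recalls(cohort, [STORY], design, seed=2)
            assert len(records) >= 100
            kept = [
                len(normalize_transcript(r.immediate_recall).tokens) / src_len
                for r in records
            ]
            fractions.append(np.mean(kept))
        assert fractions[1] < fractions[0]

    def test_retention_monotone_over_rate_grid(self):
        src_len = len(normalize_transcript(STORY).tokens)
        means = []
        for rate in (0.0, 0.2, 0.4, 0.6, 0.8):
            design = _zero_rate_design(n=30, omission_rate=rate)
            cohort = generate_cohort(design, seed=7)
            records = generate_recalls(cohort, [STORY], design, seed=7)
            means.append(
                np.mean(
                    [
                        len(normalize_transcript(r.immediate_recall).tokens) / src_len
                        for r in records
                    ]
                )
            )
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_delayed_extra_omission_shortens_delayed_recall(self):
        design = _zero_rate_design(n=30, omission_rate=0.2, delayed_extra_omission_rate=0.3)
        cohort = generate_cohort(design, seed=3)
        records = generate_recalls(cohort, [STORY], design, seed=3)
        imm = np.mean([len(normalize_transcript(r.immediate_recall).tokens) for r in records])
        dly = np.mean([len(normalize_transcript(r.delayed_recall).tokens) for r in records])
        assert dly < imm

    def test_records_jsonl_roundtrip(self, tmp_path):
        design = _zero_rate_design(omission_rate=0.2)
        cohort = generate_cohort(design, seed=1)
        records = generate_recalls(cohort, [STORY], design, seed=1)
        path = tmp_path / "records.jsonl"
        write_records_jsonl(records, path)
        assert read_records_jsonl(path) == records


class TestPACC5Composite:
    def test_mean_of_available_subtests(self):
        subtests = dict(zip(PACC5_SUBTESTS, [1.0, 0.5, None, None, 0.0]))
        assert pacc5_composite(subtests) == pytest.approx(0.5)

    @pytest.mark.parametrize("value", [0.0, 1.0])
    def test_constant_subtests(self, value):
        subtests = {k: value for k in PACC5_SUBTESTS}
        assert pacc5_composite(subtests) == pytest.approx(value)

    def test_order_invariance_and_full_mean(self, rng):
        values = list(rng.normal(size=5))
        forward = dict(zip(PACC5_SUBTESTS, values))
        backward = dict(zip(reversed(PACC5_SUBTESTS), values))
        assert pacc5_composite(forward) == pytest.approx(np.mean(values))
        assert pacc5_composite(backward) == pytest.approx(np.mean(values))

    def test_all_missing_yields_missing_marker(self):
        assert pacc5_composite({k: None for k in PACC5_SUBTESTS}) is None


def _participant(pid, education):
    return Participant(
        id=pid,
        site="UK",
        age=70.0,
        sex="female",
        education=education,
        diagnosis="CU",
        amyloid="negative",
        mmse=28,
        cdr_g=0.0,
        pacc5_subtests={},
    )


class TestImputeEducation:
    def test_odd_count_median(self):
        cohort = [_participant(f"p{i}", e) for i, e in enumerate([12, 16, 20, None])]
        imputed = impute_education(cohort)
        assert imputed[3].education == 16

    def test_even_count_median_is_mean_of_middle(self):
        cohort = [_participant(f"p{i}", e) for i, e in enumerate([12, 16, None])]
        assert impute_education(cohort)[2].education == 14

    def test_no_missing_is_identity(self):
        cohort = [_participant(f"p{i}", e) for i, e in enumerate([12.0, 16.0])]
        assert impute_education(cohort) == cohort

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            impute_education([_participant("p0", None)])
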