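import numpy as np
import pytest
from hypothesis import given, strategies as st

from gcq import (
    LabelRecord,
    LoadError,
    MontageMap,
    REFERENCE_CHANNELS,
    REFERENCE_MONTAGE,
    Trial,
    ValidationError,
    assign_class,
    parse_montage_text,
    read_deap_arrays,
    read_recording_set,
    validate_montage,
    write_recording_set,
)

scores = st.floats(min_value=1.0, max_value=9.0, allow_nan=False)


class TestAssignClass:
    @pytest.mark.parametrize(
        "valence,arousal,expected",
        [
            (3.0, 3.0, 1),     # low/low
            (2.0, 7.0, 2),     # high arousal, low valence
            (7.0, 2.0, 3),     # low arousal, high valence
            (7.0, 7.0, 4),
            (4.5, 4.5, 4),     # the boundary score counts as high
            (4.5, 2.0, 3),
            (2.0, 4.5, 2),
            (1.0, 9.0, 2),
            (9.0, 1.0, 3),
        ],
    )
    def test_quadrants(self, valence, arousal, expected):
        assert assign_class(valence, arousal) == expected

    @pytest.mark.parametrize("valence,arousal,axis", [
        (0.5, 5.0, "valence"), (5.0, 9.5, "arousal"), (float("nan"), 5.0, "valence"),
    ])
    def test_out_of_range_names_axis(self, valence, arousal, axis):
        with pytest.raises(ValidationError, match=axis):
            assign_class(valence, arousal)

    @given(valence=scores, arousal=scores)
    def test_total_partition_of_score_square(self, valence, arousal):
        """Every score pair maps to exactly one of the 4.5-cut quadrants."""
        cid = assign_class(valence, arousal)
        assert cid in (1, 2, 3, 4)
        assert (arousal >= 4.5) == (cid in (2, 4))
        assert (valence >= 4.5) == (cid in (3, 4))


class TestMontage:
    def test_reference_montage_passes_with_printed_sizes(self):
        report = validate_montage(REFERENCE_CHANNELS, REFERENCE_MONTAGE)
        assert report.passed
        assert report.area_sizes == (5, 5, 4, 4, 5, 5)

    def test_reference_area_memberships(self):
        areas = dict(zip(REFERENCE_MONTAGE.area_names, REFERENCE_MONTAGE.areas))
        assert set(areas["Area 1"]) == {"Fp1", "AF3", "F3", "FC5", "F7"}
        assert set(areas["Area 3"]) == {"FC1", "CP1", "C3", "T7"}
        assert set(areas["Area 6"]) == {"CP6", "P4", "PO4", "O2", "P8"}

    def test_missing_channel_fails_listing_it(self):
        montage = MontageMap(
            area_names=REFERENCE_MONTAGE.area_names,
            areas=tuple(
                tuple(c for c in area if c != "P8")
                for area in REFERENCE_MONTAGE.areas
            ),
            channel_order=REFERENCE_CHANNELS,
            excluded=REFERENCE_MONTAGE.excluded,
        )
        report = validate_montage(REFERENCE_CHANNELS, montage)
        assert not report.passed
        assert "P8" in report.unassigned

    def test_duplicate_channel_fails_listing_it(self):
        areas = list(REFERENCE_MONTAGE.areas)
        areas[1] = areas[1] + ("Fp1",)  # Fp1 already in Area 1
        montage = MontageMap(
            REFERENCE_MONTAGE.area_names, tuple(areas), REFERENCE_CHANNELS,
            excluded=REFERENCE_MONTAGE.excluded,
        )
        report = validate_montage(REFERENCE_CHANNELS, montage)
        assert not report.passed
        assert "Fp1" in report.duplicates

    def test_parse_montage_text_roundtrip(self):
        text = "\n".join(
            f"{name}: {' '.join(members)}"
            for name, members in zip(
                REFERENCE_MONTAGE.area_names, REFERENCE_MONTAGE.areas
            )
        )
        parsed = parse_montage_text(text)
        assert parsed.areas == REFERENCE_MONTAGE.areas
        assert parsed.area_sizes == (5, 5, 4, 4, 5, 5)


class TestTrialInvariants:
    def test_channel_count_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            Trial(np.zeros((3, 64)), 128.0, ("a", "b"))

    def test_non_finite_rejected(self):
        data = np.zeros((2, 64))
        data[1, 10] = np.nan
        with pytest.raises(ValidationError, match="non-finite"):
            Trial(data, 128.0, ("a", "b"))

    def test_reorder_permutes_rows(self, rng):
        data = rng.standard_normal((3, 32))
        trial = Trial(data, 128.0, ("x", "y", "z"))
        back = trial.reorder(("z", "x", "y"))
        assert back.channel_names == ("z", "x", "y")
        np.testing.assert_array_equal(back.data[0], data[2])


class TestRecordingSetIO:
    def test_write_read_roundtrip(self, small_recordings, tmp_path):
        root = write_recording_set(small_recordings, tmp_path / "ds")
        loaded = read_recording_set(root)
        assert len(loaded) == len(small_recordings)
        for a, b in zip(small_recordings.trials, loaded.trials):
            np.testing.assert_array_equal(a.data, b.data)
        assert [r.class_id for r in loaded.labels] == [
            r.class_id for r in small_recordings.labels
        ]

    def test_missing_trial_file_names_trial(self, small_recordings, tmp_path):
        root = write_recording_set(small_recordings, tmp_path / "ds")
        victim = small_recordings.trials[2]
        (root / "trials" / f"{victim.subject_id}__{victim.trial_id}.npy").unlink()
        with pytest.raises(LoadError, match=victim.trial_id):
            read_recording_set(root)

    def test_invalid_scores_rejected_and_counted(self, small_recordings, tmp_path, caplog):
        root = write_recording_set(small_recordings, tmp_path / "ds")
        labels = (root / "labels.csv").read_text().splitlines()
        labels[1] = labels[1].rsplit(",", 1)[0] + ",12.0"  # arousal out of range
        (root / "labels.csv").write_text("\n".join(labels) + "\n")
        with caplog.at_level("WARNING"):
            loaded = read_recording_set(root)
        assert len(loaded) == len(small_recordings) - 1
        assert any("reject" in r.message for r in caplog.records)


class TestDeapAdapter:
    def test_extra_peripheral_channels_dropped(self, rng, caplog):
        data = rng.standard_normal((4, 40, 256))
        labels = np.column_stack(
            [rng.uniform(1, 9, 4), rng.uniform(1, 9, 4), np.zeros(4), np.zeros(4)]
        )
        with caplog.at_level("WARNING"):
            rs = read_deap_arrays(data, labels, subject_id="s01")
        assert len(rs) == 4
        assert rs.trials[0].n_channels == 32
        np.testing.assert_array_equal(rs.trials[0].data, data[0, :32, :])
        assert any("non-EEG" in r.message for r in caplog.records)

    def test_too_few_channels_rejected(self, rng):
        with pytest.raises(LoadError, match="channels"):
            read_deap_arrays(
                rng.standard_normal((2, 6, 256)), np.full((2, 4), 5.0), "s01"
            )


def test_label_record_derives_class():
    rec = LabelRecord("s01", "t01", valence=6.0, arousal=2.0)
    assert rec.class_id == 3
    with pytest.raises(ValidationError):
        LabelRecord("s01", "t01", valence=6.0, arousal=2.0, class_id=1)
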