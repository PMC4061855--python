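"""Epoched-EEG data model: IO round trips, re-referencing, artifact
rejection and per-condition trial screening."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_epochset, make_labels
from toneosc import synth
from toneosc.edf import quantization_step
from toneosc.epochs import (EpochSet, FormatError, LabelledDataError,
                            read_epochs, reject_artifacts,
                            rereference_to_average_mastoids, screen_subject,
                            write_epochs)


def _random_es(rng, n_trials=6, channels=("Fz", "Cz", "M2"), n_samples=128):
    data = rng.normal(0, 20, size=(n_trials, len(channels), n_samples))
    return make_epochset(data, channel_names=channels)


class TestRoundTrips:
    def test_fixture_round_trip_is_exact(self, rng, tmp_path):
        es = _random_es(rng)
        p = write_epochs(es, tmp_path / "x.npz", "fixture")
        back = read_epochs(p, "fixture")
        assert np.array_equal(back.data, es.data)
        assert back.fs == es.fs and back.t0 == es.t0
        assert back.channel_names == es.channel_names
        pd.testing.assert_frame_equal(
            back.trial_labels[es.trial_labels.columns], es.trial_labels,
            check_dtype=False,
        )

    def test_edf_round_trip_within_16bit_quantization(self, rng, tmp_path):
        es = _random_es(rng, n_trials=4)
        p = write_epochs(es, tmp_path / "x.edf", "edf")
        back = read_epochs(p, "edf")
        q = quantization_step(es)
        err = np.abs(back.data - es.data).max(axis=(0, 2))
        assert np.all(err <= 1.01 * q)
        assert back.fs == es.fs and back.t0 == es.t0
        assert back.channel_names == es.channel_names

    def test_empty_epochset_refuses_to_write(self, tmp_path):
        es = make_epochset(np.empty((0, 2, 64)), labels=make_labels(0))
        with pytest.raises(FormatError):
            write_epochs(es, tmp_path / "x.npz", "fixture")

    def test_missing_sidecar_is_labelled_data_error(self, rng, tmp_path):
        es = _random_es(rng, n_trials=3)
        p = write_epochs(es, tmp_path / "x.edf", "edf")
        p.with_suffix(p.suffix + ".labels.tsv").unlink()
        with pytest.raises(LabelledDataError):
            read_epochs(p, "edf")

    def test_trial_count_mismatch_is_format_error(self, rng, tmp_path):
        es = _random_es(rng, n_trials=4)
        p = write_epochs(es, tmp_path / "x.edf", "edf")
        sidecar = p.with_suffix(p.suffix + ".labels.tsv")
        text = sidecar.read_text().splitlines()
        sidecar.write_text("\n".join(text[:-1]) + "\n")  # drop one trial row
        with pytest.raises(FormatError):
            read_epochs(p, "edf")

    def test_unknown_channel_loads_but_is_flagged_unmapped(self, rng, tmp_path, montage):
        es = _random_es(rng, channels=("Fz", "Cz", "XX9"))
        p = write_epochs(es, tmp_path / "x.edf", "edf")
        back = read_epochs(p, "edf")
        assert "XX9" in back.channel_names
        assert montage.unmapped(back.channel_names) == ["XX9"]


class TestInvariants:
    def test_label_vocabulary_enforced(self):
        labels = make_labels(2, tone="rising-falling")
        with pytest.raises(LabelledDataError):
            make_epochset(np.zeros((2, 1, 8)), labels=labels)

    def test_one_label_row_per_trial(self):
        with pytest.raises(LabelledDataError):
            make_epochset(np.zeros((3, 1, 8)), labels=make_labels(2))


class TestRereference:
    def test_zero_right_mastoid_is_identity(self, montage):
        data = np.random.default_rng(0).normal(size=(3, 39, 64))
        names = list(montage.all_channels)
        data[:, names.index("M2"), :] = 0.0
        es = make_epochset(data, channel_names=names)
        out = rereference_to_average_mastoids(es, montage)
        assert np.array_equal(out.data, es.data)

    def test_constant_arithmetic(self, montage):
        names = list(montage.all_channels)
        data = np.zeros((1, 39, 16))
        data[:, names.index("Cz"), :] = 4.0
        data[:, names.index("M2"), :] = 2.0
        out = rereference_to_average_mastoids(make_epochset(data, channel_names=names), montage)
        assert np.allclose(out.data[:, names.index("Cz")], 3.0)

    def test_matches_brute_force_on_random_dipole(self, montage, rng):
        names = list(montage.all_channels)
        data = rng.normal(size=(4, 39, 32))
        es = make_epochset(data, channel_names=names)
        out = rereference_to_average_mastoids(es, montage)
        m2 = data[:, names.index("M2"), :]
        for c in range(39):  # brute-force oracle channel by channel
            assert np.allclose(out.data[:, c, :], data[:, c, :] - m2 / 2.0)

    def test_linearity(self, montage, rng):
        names = list(montage.all_channels)
        a = make_epochset(rng.normal(size=(2, 39, 16)), channel_names=names)
        b = make_epochset(rng.normal(size=(2, 39, 16)), channel_names=names)
        s = make_epochset(a.data + b.data, channel_names=names)
        lhs = rereference_to_average_mastoids(s, montage).data
        rhs = (rereference_to_average_mastoids(a, montage).data
               + rereference_to_average_mastoids(b, montage).data)
        assert np.allclose(lhs, rhs)

    def test_missing_mastoid_raises(self, montage, rng):
        es = _random_es(rng, channels=("Fz", "Cz"))
        with pytest.raises(LabelledDataError):
            rereference_to_average_mastoids(es, montage)


class TestRejection:
    def test_spiked_trial_is_the_only_one_masked(self, rng):
        data = rng.normal(0, 5, size=(8, 3, 128))
        data[5, 1, 60] += 500.0
        es = make_epochset(data)
        out = reject_artifacts(es, 150.0)
        assert list(np.flatnonzero(out.reject_mask)) == [5]
        assert np.array_equal(out.data, es.data)

    def test_infinite_threshold_masks_nothing(self, rng):
        out = reject_artifacts(_random_es(rng), np.inf)
        assert not out.reject_mask.any()

    def test_monotone_in_threshold(self, rng):
        es = make_epochset(rng.normal(0, 60, size=(30, 4, 128)))
        prev = None
        for thr in (50.0, 100.0, 200.0, 400.0):
            n = reject_artifacts(es, thr).reject_mask.sum()
            if prev is not None:
                assert n <= prev
            prev = n

    def test_recovers_generator_contamination_rate(self):
        design = synth.scaled_design(
            master_seed=3, groups={"Chinese": 2}, n_standards=400, n_deviants=100,
            n_blocks=1, artifact_rate=0.24,
        )
        es = synth.generate_block(design, "Chinese", "Chinese-01", "pre", 0)
        out = reject_artifacts(es, 150.0, design.montage)
        assert abs(out.reject_mask.mean() - 0.24) < 0.06


class TestScreening:
    @staticmethod
    def _session(per_cell):
        frames, arrays = [], []
        for tone in ("low-falling", "high-rising"):
            for cond, n in per_cell.items() if isinstance(per_cell, dict) else per_cell(tone):
                frames.append(make_labels(n, tone=tone, condition=cond))
        labels = pd.concat(frames, ignore_index=True)
        labels["trial"] = np.arange(len(labels))
        return make_epochset(np.zeros((len(labels), 1, 8)), labels=labels)

    def test_exactly_at_minimum_is_retained(self):
        es = self._session({"standard": 50, "deviant": 50})
        assert screen_subject(es, 50) is True

    def test_one_short_cell_excludes(self):
        def cells(tone):
            if tone == "low-falling":
                return [("standard", 50), ("deviant", 49)]
            return [("standard", 50), ("deviant", 50)]

        assert screen_subject(self._session(cells), 50) is False

    def test_zero_minimum_always_true_and_monotone(self):
        es = self._session({"standard": 10, "deviant": 3})
        assert screen_subject(es, 0) is True
        results = [screen_subject(es, m) for m in (0, 3, 4, 10, 11)]
        assert results == [True, True, False, False, False]

    def test_rejected_trials_do_not_count(self):
        es = self._session({"standard": 50, "deviant": 50})
        es.reject_mask[:1] = True
        assert screen_subject(es, 50) is False

    def test_absent_cell_raises(self):
        es = make_epochset(np.zeros((4, 1, 8)), labels=make_labels(4))
        with pytest.raises(LabelledDataError):
            screen_subject(es, 1)
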