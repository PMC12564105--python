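"""Threshold labeling, class balancing, inversion augmentation, splitting."""

import numpy as np
import pandas as pd
import pytest

from opmclean import (
    LABEL_BLINK,
    LABEL_CARDIAC,
    LABEL_NONE,
    UNLABELED,
    ArtifactDataset,
    assemble_dataset,
    augment_invert,
    label_components,
    score_components,
    shorten_waveforms,
    split_dataset,
)
from opmclean.preprocessing import bandpass_filter, ica_decompose, segment_epochs


def _table(scores, epoch_id=0):
    return pd.DataFrame(
        {
            "epoch_id": epoch_id,
            "component_id": np.arange(len(scores)),
            "rdc_mog": [s[0] for s in scores],
            "rdc_mcg": [s[1] for s in scores],
        }
    )


class TestLabelComponents:
    def test_rule_application(self):
        out = label_components(_table([(0.72, 0.05), (0.1, 0.65), (0.05, 0.04)]))
        assert out["label"].tolist() == [LABEL_BLINK, LABEL_CARDIAC, LABEL_NONE]

    def test_gap_component_unlabeled(self):
        out = label_components(_table([(0.25, 0.1)]))
        assert out["label"].tolist() == [UNLABELED]

    def test_only_highest_above_delta_wins(self):
        out = label_components(_table([(0.5, 0.05), (0.4, 0.05), (0.1, 0.1)]))
        assert out["label"].tolist() == [LABEL_BLINK, UNLABELED, LABEL_NONE]

    def test_double_winner_takes_larger_score(self):
        # one component tops both references: larger score decides
        out = label_components(_table([(0.6, 0.4), (0.05, 0.05)]))
        assert out["label"].tolist() == [LABEL_BLINK, LABEL_NONE]
        out = label_components(_table([(0.4, 0.6), (0.05, 0.05)]))
        assert out["label"].tolist() == [LABEL_CARDIAC, LABEL_NONE]

    def test_double_winner_tie_goes_to_cardiac(self):
        out = label_components(_table([(0.5, 0.5)]))
        assert out["label"].tolist() == [LABEL_CARDIAC]

    def test_per_epoch_independence(self):
        t = pd.concat(
            [_table([(0.7, 0.1), (0.1, 0.1)], 0), _table([(0.9, 0.1), (0.1, 0.1)], 1)],
            ignore_index=True,
        )
        out = label_components(t)
        assert out[out.epoch_id == 0]["label"].tolist() == [LABEL_BLINK, LABEL_NONE]
        assert out[out.epoch_id == 1]["label"].tolist() == [LABEL_BLINK, LABEL_NONE]

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError, match="delta"):
            label_components(_table([(0.5, 0.5)]), delta=0.2, lam=0.3)

    def test_label_coding(self):
        assert (LABEL_CARDIAC, LABEL_BLINK, LABEL_NONE) == (0, 1, 2)


def _pools(n_blink, n_cardiac, n_none, length=100, seed=0):
    rng = np.random.default_rng(seed)
    n = n_blink + n_cardiac + n_none
    waveforms = rng.standard_normal((n, length))
    labels = np.array(
        [LABEL_BLINK] * n_blink + [LABEL_CARDIAC] * n_cardiac + [LABEL_NONE] * n_none
    )
    prov = [("s", 0, i, False) for i in range(n)]
    return waveforms, labels, prov


class TestAssemble:
    def test_published_bookkeeping_counts(self):
        w, y, p = _pools(480, 480, 5000)
        ds = assemble_dataset(w, y, p, seed=0)
        assert ds.class_counts == {LABEL_CARDIAC: 480, LABEL_BLINK: 480, LABEL_NONE: 1920}

    def test_deficit_raises_with_count(self):
        w, y, p = _pools(10, 10, 35)
        with pytest.raises(ValueError, match="deficit 5"):
            assemble_dataset(w, y, p, seed=0)

    def test_deterministic(self):
        w, y, p = _pools(20, 25, 200)
        a = assemble_dataset(w, y, p, seed=3)
        b = assemble_dataset(w, y, p, seed=3)
        np.testing.assert_array_equal(a.waveforms, b.waveforms)

    def test_unlabeled_ignored(self):
        w, y, p = _pools(10, 10, 50)
        y[0] = UNLABELED
        ds = assemble_dataset(w, y, p, seed=0)
        assert ds.class_counts[LABEL_BLINK] == 9
        assert ds.class_counts[LABEL_CARDIAC] == 9
        assert ds.class_counts[LABEL_NONE] == 36

    def test_empty_pool_raises(self):
        w, y, p = _pools(0, 10, 50)
        with pytest.raises(ValueError, match="empty pool"):
            assemble_dataset(w, y, p, seed=0)


class TestAugmentInvert:
    def test_doubles_and_preserves_ratio(self):
        w, y, p = _pools(480, 480, 5000)
        ds = augment_invert(assemble_dataset(w, y, p, seed=0))
        assert ds.class_counts == {LABEL_CARDIAC: 960, LABEL_BLINK: 960, LABEL_NONE: 3840}
        assert len(ds) == 5760

    def test_added_samples_are_negatives(self):
        w, y, p = _pools(5, 5, 20)
        base = assemble_dataset(w, y, p, seed=0)
        aug = augment_invert(base)
        n = len(base)
        np.testing.assert_array_equal(aug.waveforms[n:], -aug.waveforms[:n])
        np.testing.assert_array_equal(aug.labels[n:], aug.labels[:n])

    def test_double_augment_quadruples(self):
        w, y, p = _pools(5, 5, 20)
        ds = augment_invert(augment_invert(assemble_dataset(w, y, p, seed=0)))
        assert len(ds) == 4 * 30

    def test_twins_share_group_id(self):
        w, y, p = _pools(5, 5, 20)
        aug = augment_invert(assemble_dataset(w, y, p, seed=0))
        n = len(aug) // 2
        np.testing.assert_array_equal(aug.group_ids[:n], aug.group_ids[n:])


class TestSplit:
    def _full(self):
        w, y, p = _pools(480, 480, 5000)
        return augment_invert(assemble_dataset(w, y, p, seed=0))

    def test_published_split_sizes(self):
        train, test = split_dataset(self._full(), seed=0)
        assert (len(train), len(test)) == (4608, 1152)

    def test_stratified(self):
        train, test = split_dataset(self._full(), seed=1)
        for c, n_total in ((LABEL_CARDIAC, 960), (LABEL_BLINK, 960), (LABEL_NONE, 3840)):
            n_te = test.class_counts[c]
            assert abs(n_te - n_total // 5) <= 2  # twin pairing quantizes by 2

    def test_no_leakage_up_to_sign(self):
        train, test = split_dataset(self._full(), seed=2)
        train_set = {w.tobytes() for w in np.abs(train.waveforms)}
        test_set = {w.tobytes() for w in np.abs(test.waveforms)}
        assert not (train_set & test_set)

    def test_twins_co_partitioned(self):
        train, test = split_dataset(self._full(), seed=3)
        assert not (set(train.group_ids.tolist()) & set(test.group_ids.tolist()))

    def test_deterministic(self):
        a_tr, a_te = split_dataset(self._full(), seed=4)
        b_tr, b_te = split_dataset(self._full(), seed=4)
        np.testing.assert_array_equal(a_te.waveforms, b_te.waveforms)

    def test_too_small_rejected(self):
        ds = ArtifactDataset(np.zeros((3, 10)), np.array([0, 1, 2]))
        with pytest.raises(ValueError, match="small"):
            split_dataset(ds)


class TestShorten:
    def test_stride_subsampling(self):
        ds = ArtifactDataset(np.arange(40, dtype=float).reshape(2, 20), np.array([0, 1]))
        out = shorten_waveforms(ds, 10)
        np.testing.assert_array_equal(out.waveforms[0], np.arange(0, 20, 2))

    def test_indivisible_length_rejected(self):
        ds = ArtifactDataset(np.zeros((2, 20)), np.array([0, 1]))
        with pytest.raises(ValueError, match="divide"):
            shorten_waveforms(ds, 7)


class TestDatasetIO:
    def test_hdf5_roundtrip(self, tmp_path):
        w, y, p = _pools(5, 5, 20)
        ds = augment_invert(assemble_dataset(w, y, p, seed=0))
        path = tmp_path / "ds.h5"
        ds.to_hdf5(path)
        back = ArtifactDataset.from_hdf5(path)
        np.testing.assert_array_equal(back.waveforms, ds.waveforms)
        np.testing.assert_array_equal(back.labels, ds.labels)
        np.testing.assert_array_equal(back.group_ids, ds.group_ids)


class TestScoreComponentsOnSession:
    def test_injected_artifacts_win_their_reference(self, short_session):
        rec, truth = short_session
        filt = bandpass_filter(rec)
        eps = segment_epochs(filt)
        epoch = eps.epochs[0]
        dec = ica_decompose(epoch[rec.meg_indices], seed=0)
        table = score_components(
            dec, epoch[rec.mog_index], epoch[rec.mcg_index], epoch_id=0
        )
        blink_true = int(
            np.argmax(np.abs(np.corrcoef(dec.sources, truth.blink_source[:10000])[:-1, -1]))
        )
        cardiac_true = int(
            np.argmax(np.abs(np.corrcoef(dec.sources, truth.cardiac_source[:10000])[:-1, -1]))
        )
        assert int(table.rdc_mog.idxmax()) == blink_true
        assert int(table.rdc_mcg.idxmax()) == cardiac_true
        labeled = label_components(table)
        assert labeled.loc[blink_true, "label"] == LABEL_BLINK
        assert labeled.loc[cardiac_true, "label"] == LABEL_CARDIAC

    def test_reference_rescaling_invariance(self, short_session):
        rec, _ = short_session
        filt = bandpass_filter(rec)
        epoch = segment_epochs(filt).epochs[0]
        dec = ica_decompose(epoch[rec.meg_indices], n_components=8, seed=0)
        a = score_components(dec, epoch[rec.mog_index], epoch[rec.mcg_index])
        b = score_components(dec, 10.0 * epoch[rec.mog_index], 10.0 * epoch[rec.mcg_index])
        np.testing.assert_allclose(a.rdc_mog, b.rdc_mog)
        np.testing.assert_allclose(a.rdc_mcg, b.rdc_mcg)

    def test_length_mismatch_rejected(self, short_session):
        rec, _ = short_session
        epoch = segment_epochs(bandpass_filter(rec)).epochs[0]
        dec = ica_decompose(epoch[rec.meg_indices], n_components=4, seed=0)
        with pytest.raises(ValueError, match="window"):
            score_components(dec, epoch[rec.mog_index][:-1], epoch[rec.mcg_index][:-1])
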