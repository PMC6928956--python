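"""Labeling policies: threshold selection, querying, propagation, summaries."""

import numpy as np
import pytest

from harlearn import EnsembleModel, FeatureSet, LabelingPolicy, Oracle, label_chunk, select_threshold, summarize_queries
from harlearn.base_learners import BaseModel
from harlearn.errors import ConfigError, LabelingError
from harlearn.labeling import PREDICTED, PROPAGATED, QUERIED


class _ScriptedPosteriors:
    """Stub classifier yielding preset two-class posteriors per row.

    The chunk's feature column 0 carries the row position, which indexes the
    scripted confidence table.
    """

    def __init__(self, conf, pred_is_first):
        self.conf = np.asarray(conf, dtype=float)
        self.first = np.asarray(pred_is_first, dtype=bool)

    def predict_posterior(self, X):
        pos = np.atleast_2d(X)[:, 0].astype(int)
        post = np.empty((len(pos), 2))
        c = self.conf[pos]
        f = self.first[pos]
        post[f, 0], post[f, 1] = c[f], 1 - c[f]
        post[~f, 0], post[~f, 1] = 1 - c[~f], c[~f]
        return post


def scripted_ensemble(conf, pred_first=None, personal=False):
    n = len(conf)
    pred_first = np.ones(n, bool) if pred_first is None else np.asarray(pred_first)
    m = BaseModel(
        kind="lda",
        origin="personal" if personal else "user_independent",
        selected_features=np.array([0]), class_list=["a", "b"],
        clf=_ScriptedPosteriors(conf, pred_first), n_features_total=1,
    )
    return EnsembleModel([m])


def chunk_of(n, true_labels=None):
    labels = np.repeat("a", n).astype(object) if true_labels is None \
        else np.asarray(true_labels, dtype=object)
    return FeatureSet(
        subject_ids=np.repeat("S", n), w=np.arange(n),
        X=np.arange(n, dtype=float)[:, None], labels=labels,
        feature_names=["pos"],
    )


def oracle_for(chunk):
    return Oracle.from_feature_set(chunk)


def reference_semi_supervised(conf, true, pred, th, radius):
    """Independent loop implementation of the semi-supervised policy."""
    n = len(conf)
    queried = [i for i in range(n) if conf[i] < th]
    labels = list(pred)
    source = [PREDICTED] * n
    for q in queried:
        labels[q] = true[q]
        source[q] = QUERIED
    for j in range(n):
        if source[j] == QUERIED:
            continue
        best = None
        for q in queried:
            d = abs(j - q)
            if d <= radius and (best is None or d < abs(j - best)):
                best = q
        if best is not None:
            labels[j] = true[best]
            source[j] = PROPAGATED
    return labels, source


class TestSelectThreshold:
    def test_ui_only_uses_high_threshold(self):
        pol = LabelingPolicy()
        assert select_threshold(scripted_ensemble([0.9]), pol) == 0.95

    def test_single_ui_member_still_high(self):
        pol = LabelingPolicy()
        ens = scripted_ensemble([0.9])
        assert ens.n_members == 1
        assert select_threshold(ens, pol) == 0.95

    def test_personal_member_lowers_threshold(self):
        pol = LabelingPolicy()
        assert select_threshold(scripted_ensemble([0.9], personal=True), pol) == 0.75

    def test_other_modes_rejected(self):
        for mode in ("non_supervised", "supervised"):
            with pytest.raises(ConfigError):
                select_threshold(scripted_ensemble([0.9]), LabelingPolicy(mode=mode))


class TestLabelChunk:
    def test_propagation_around_single_query(self):
        """A query at w=10 with radius 2 relabels windows 8, 9, 11, 12."""
        conf = np.full(20, 0.9)
        conf[10] = 0.6
        true = ["b"] * 20
        chunk = chunk_of(20, true)
        ens = scripted_ensemble(conf, personal=True)
        out = label_chunk(ens, chunk, LabelingPolicy(), oracle_for(chunk))
        assert out.threshold == 0.75
        assert list(np.flatnonzero(out.source == QUERIED)) == [10]
        assert list(np.flatnonzero(out.source == PROPAGATED)) == [8, 9, 11, 12]
        assert all(out.assigned_labels[i] == "b" for i in (8, 9, 10, 11, 12))
        assert all(out.assigned_labels[i] == "a" for i in range(8))

    def test_all_confident_equals_non_supervised(self):
        conf = np.full(15, 0.99)
        chunk = chunk_of(15)
        ens = scripted_ensemble(conf)
        semi = label_chunk(ens, chunk, LabelingPolicy(), oracle_for(chunk))
        non = label_chunk(ens, chunk, LabelingPolicy(mode="non_supervised"),
                          oracle_for(chunk))
        np.testing.assert_array_equal(semi.assigned_labels, non.assigned_labels)
        assert semi.query_fraction == 0.0
        assert np.all(semi.source == PREDICTED)

    def test_supervised_labels_everything(self):
        true = list("ab" * 10)
        chunk = chunk_of(20, true)
        out = label_chunk(scripted_ensemble(np.ones(20)), chunk,
                          LabelingPolicy(mode="supervised"), oracle_for(chunk))
        np.testing.assert_array_equal(out.assigned_labels, np.array(true, dtype=object))
        assert out.query_fraction == 1.0
        assert out.replaced_fraction == 1.0

    def test_alternating_confidences_match_reference(self):
        """Hand-scripted chunk checked against the loop reference."""
        conf = np.array([0.9 if i % 2 == 0 else 0.6 for i in range(20)])
        true = ["b"] * 20
        chunk = chunk_of(20, true)
        pol = LabelingPolicy(th_ui=0.75, th_personal=0.75)
        ens = scripted_ensemble(conf)
        out = label_chunk(ens, chunk, pol, oracle_for(chunk))
        assert list(np.flatnonzero(out.source == QUERIED)) == list(range(1, 20, 2))
        ref_labels, ref_source = reference_semi_supervised(
            conf, true, ["a"] * 20, 0.75, 2)
        np.testing.assert_array_equal(out.assigned_labels,
                                      np.array(ref_labels, dtype=object))
        np.testing.assert_array_equal(out.source, np.array(ref_source, dtype=object))

    def test_random_chunks_match_reference(self, rng):
        """Propagation with conflicts (nearest query wins, ties to the earlier
        one) agrees with the brute-force reference on random chunks."""
        for _ in range(50):
            n = int(rng.integers(5, 40))
            conf = rng.uniform(0.5, 1.0, n)
            true = rng.choice(["a", "b"], n).tolist()
            pred_first = rng.random(n) < 0.5
            chunk = chunk_of(n, true)
            personal = bool(rng.random() < 0.5)
            ens = scripted_ensemble(conf, pred_first, personal=personal)
            pol = LabelingPolicy()
            out = label_chunk(ens, chunk, pol, oracle_for(chunk))
            th = 0.75 if personal else 0.95
            pred = ["a" if f else "b" for f in pred_first]
            ref_labels, ref_source = reference_semi_supervised(
                conf, true, pred, th, 2)
            np.testing.assert_array_equal(out.assigned_labels,
                                          np.array(ref_labels, dtype=object))
            np.testing.assert_array_equal(out.source,
                                          np.array(ref_source, dtype=object))

    def test_equivalence_limits(self, rng):
        """Thresholds 0/0 reproduce non-supervised output; 1.01/1.01
        reproduce supervised output."""
        n = 30
        conf = rng.uniform(0.5, 1.0, n)
        true = rng.choice(["a", "b"], n).tolist()
        chunk = chunk_of(n, true)
        ens = scripted_ensemble(conf)
        zero = label_chunk(ens, chunk, LabelingPolicy(th_ui=0, th_personal=0),
                           oracle_for(chunk))
        non = label_chunk(ens, chunk, LabelingPolicy(mode="non_supervised"),
                          oracle_for(chunk))
        np.testing.assert_array_equal(zero.assigned_labels, non.assigned_labels)
        assert zero.query_fraction == 0.0
        full = label_chunk(ens, chunk,
                           LabelingPolicy(th_ui=1.01, th_personal=1.01),
                           oracle_for(chunk))
        sup = label_chunk(ens, chunk, LabelingPolicy(mode="supervised"),
                          oracle_for(chunk))
        np.testing.assert_array_equal(full.assigned_labels, sup.assigned_labels)
        assert full.query_fraction == 1.0

    def test_oracle_failure_names_window(self):
        chunk = chunk_of(5)
        bad = Oracle(lambda s, w: (_ for _ in ()).throw(
            LabelingError(f"oracle has no label for (subject {s}, w={w})")))
        with pytest.raises(LabelingError, match=r"w="):
            label_chunk(scripted_ensemble(np.full(5, 0.1)), chunk,
                        LabelingPolicy(), bad)


class TestSummaries:
    def test_fraction_arithmetic(self):
        chunk = chunk_of(20)
        source = np.array([PREDICTED] * 20, dtype=object)
        source[[3, 10]] = QUERIED
        source[[1, 2, 4, 5, 8, 9]] = PROPAGATED
        from harlearn.labeling import LabeledChunk

        lc = LabeledChunk(chunk, chunk.labels, source, round_index=1)
        assert lc.query_fraction == pytest.approx(0.10)
        assert lc.replaced_fraction == pytest.approx(0.40)
        df = summarize_queries([lc])
        overall = df[df["round"] == "overall"].iloc[0]
        assert overall["query_fraction"] == pytest.approx(0.10)
        assert overall["replaced_fraction"] == pytest.approx(0.40)

    def test_supervised_and_non_supervised_extremes(self, rng):
        chunk = chunk_of(10)
        sup = label_chunk(scripted_ensemble(np.ones(10)), chunk,
                          LabelingPolicy(mode="supervised"), oracle_for(chunk))
        non = label_chunk(scripted_ensemble(np.ones(10)), chunk,
                          LabelingPolicy(mode="non_supervised"), oracle_for(chunk))
        assert (sup.query_fraction, sup.replaced_fraction) == (1.0, 1.0)
        assert (non.query_fraction, non.replaced_fraction) == (0.0, 0.0)


def test_policy_validation():
    with pytest.raises(ConfigError, match="mode"):
        LabelingPolicy(mode="other")
    with pytest.raises(ConfigError, match="th_ui"):
        LabelingPolicy(th_ui=1.5)
    with pytest.raises(ConfigError, match="radius"):
        LabelingPolicy(propagation_radius=-1)
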