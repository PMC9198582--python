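"""Scoring and threshold optimization against brute-force oracles."""

import numpy as np
import pytest

from vitisvae.patches import Patch
from vitisvae.scoring import (ScoreRecord, score_patches, optimize_threshold,
                              evaluate_stratified, score_histogram,
                              write_scores, read_scores)


def rec(score, label, stage="early", metric="mse", pid=None):
    return ScoreRecord(patch_id=pid or f"p{score}", score=float(score),
                       metric=metric, label=label, stage_tag=stage)


class IdentityModel:
    def reconstruct(self, batch):
        return np.asarray(batch)


def make_patch(value, label="healthy"):
    return Patch(pixels=np.full((64, 64, 3), value), origin=(0, 0),
                 scene_id="s", label=label)


# ---------------------------------------------------------------- scoring

def test_perfect_reconstruction_scores_zero():
    records = score_patches(IdentityModel(), [make_patch(0.3)], metric="l1")
    assert records[0].score == 0.0
    assert records[0].label == "healthy"


def test_scores_are_deterministic_across_calls():
    rng = np.random.default_rng(0)
    patches = [Patch(pixels=rng.uniform(0, 1, (64, 64, 3)), origin=(0, 0),
                     scene_id=f"s{i}", label="healthy") for i in range(5)]

    class Blur:
        def reconstruct(self, batch):
            return np.asarray(batch) * 0.9 + 0.05

    a = [r.score for r in score_patches(Blur(), patches)]
    b = [r.score for r in score_patches(Blur(), patches)]
    assert a == b


def test_unknown_metric_rejected():
    with pytest.raises(ValueError, match="unknown metric"):
        score_patches(IdentityModel(), [make_patch(0.1)], metric="rmse")


# ---------------------------------------------------------------- threshold

def brute_force_best(records):
    scores = np.array([r.score for r in records])
    labels = np.array([r.label == "anomalous" for r in records])
    cands = np.concatenate([scores - 1e-9, scores + 1e-9,
                            [scores.min() - 1, scores.max() + 1]])
    best_acc, best_thr = -1.0, None
    for t in np.sort(cands):
        acc = ((scores > t) == labels).mean()
        if acc > best_acc:
            best_acc, best_thr = acc, t
    return best_acc


def test_textbook_separable_case():
    records = [rec(s, "healthy") for s in (0.1, 0.2, 0.3)] + \
              [rec(s, "anomalous") for s in (0.5, 0.6)]
    out = optimize_threshold(records)
    assert out.accuracy == 1.0
    assert out.threshold == pytest.approx(0.4)
    assert (out.tp, out.tn, out.fp, out.fn) == (2, 3, 0, 0)


def test_no_separation_gives_majority_accuracy():
    records = [rec(0.5, "healthy", pid=f"h{i}") for i in range(4)] + \
              [rec(0.5, "anomalous", pid=f"a{i}") for i in range(4)]
    assert optimize_threshold(records).accuracy == pytest.approx(0.5)


def test_accuracy_at_least_majority_class():
    rng = np.random.default_rng(1)
    for trial in range(20):
        n_h, n_a = rng.integers(1, 30, 2)
        records = [rec(s, "healthy", pid=f"h{i}") for i, s in
                   enumerate(rng.uniform(0, 1, n_h))] + \
                  [rec(s, "anomalous", pid=f"a{i}") for i, s in
                   enumerate(rng.uniform(0, 1, n_a))]
        out = optimize_threshold(records)
        assert out.accuracy >= max(n_h, n_a) / (n_h + n_a) - 1e-12
        assert out.tp + out.tn + out.fp + out.fn == n_h + n_a


def test_matches_exhaustive_search_on_random_instances():
    rng = np.random.default_rng(2)
    for trial in range(50):
        n = int(rng.integers(2, 200))
        scores = np.round(rng.uniform(0, 1, n), 2)  # force ties
        labels = rng.random(n) < rng.uniform(0.2, 0.8)
        if labels.all() or not labels.any():
            continue
        records = [rec(s, "anomalous" if l else "healthy", pid=f"r{i}")
                   for i, (s, l) in enumerate(zip(scores, labels))]
        out = optimize_threshold(records)
        assert out.accuracy == pytest.approx(brute_force_best(records))


def test_accuracy_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    scores = rng.uniform(0, 1, 60)
    labels = rng.random(60) < 0.5
    labels[0], labels[1] = True, False
    base = [rec(s, "anomalous" if l else "healthy", pid=f"b{i}")
            for i, (s, l) in enumerate(zip(scores, labels))]
    warped = [rec(np.exp(3 * s), "anomalous" if l else "healthy", pid=f"w{i}")
              for i, (s, l) in enumerate(zip(scores, labels))]
    assert optimize_threshold(base).accuracy == \
        pytest.approx(optimize_threshold(warped).accuracy)


def test_single_class_input_rejected():
    with pytest.raises(ValueError, match="single class"):
        optimize_threshold([rec(0.1, "healthy"), rec(0.2, "healthy", pid="x")])
    with pytest.raises(ValueError, match="no score records"):
        optimize_threshold([])


# ---------------------------------------------------------------- stratified

def test_single_stratum_equals_joint():
    records = [rec(0.1, "healthy"), rec(0.9, "anomalous", pid="a")]
    table = evaluate_stratified(records, threshold=0.5)
    assert table["joint"] == table["early"]


def test_strata_counts_sum_to_joint():
    rng = np.random.default_rng(4)
    records = [rec(s, "anomalous" if l else "healthy",
                   stage="early" if i % 2 else "late", pid=f"s{i}")
               for i, (s, l) in enumerate(zip(rng.uniform(0, 1, 40),
                                              rng.random(40) < 0.5))]
    table = evaluate_stratified(records, threshold=0.5)
    for field in ("tp", "tn", "fp", "fn"):
        assert getattr(table["early"], field) + getattr(table["late"], field) \
            == getattr(table["joint"], field)
    # the joint accuracy is the count-weighted mean of the strata
    w = sum(table[s].accuracy * table[s].n for s in ("early", "late"))
    assert table["joint"].accuracy == pytest.approx(w / table["joint"].n)


def test_unknown_stratum_field_rejected():
    with pytest.raises(ValueError, match="stratum field"):
        evaluate_stratified([rec(0.1, "healthy"), rec(0.9, "anomalous", pid="a")],
                            0.5, strata="variety")


# ---------------------------------------------------------------- histogram

def test_histogram_conserves_counts_per_label():
    rng = np.random.default_rng(5)
    records = [rec(s, "healthy", pid=f"h{i}") for i, s in
               enumerate(rng.uniform(0, 1, 30))] + \
              [rec(s, "anomalous", pid=f"a{i}") for i, s in
               enumerate(rng.uniform(0, 2, 20))]
    hist = score_histogram(records, bins=10)
    assert hist["healthy"].sum() == 30
    assert hist["anomalous"].sum() == 20
    assert len(hist["edges"]) == 11


def test_all_equal_scores_occupy_single_bin():
    records = [rec(0.7, "healthy", pid=f"h{i}") for i in range(5)]
    hist = score_histogram(records, bins=4)
    assert (hist["healthy"] > 0).sum() == 1
    with pytest.raises(ValueError, match="bins"):
        score_histogram(records, bins=1)


# ---------------------------------------------------------------- io

def test_scores_round_trip(tmp_path):
    records = [rec(0.25, "healthy"), rec(0.75, "anomalous", stage="late", pid="a")]
    path = write_scores(records, tmp_path / "scores.jsonl")
    assert read_scores(path) == records
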