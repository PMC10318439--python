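from fractions import Fraction
import math

import numpy as np
import pytest

from glycosite.metrics import (ConfusionCounts, EvalConfig, binarize,
                               cluster_sites, confusion, dcc, dice, evaluate,
                               mcc, ppv_sensitivity)
from glycosite.synthetic import FixtureSpec, make_structure

from conftest import random_rotation_matrix


# ---------------------------------------------------------------------------
# Independent oracles: direct substitution in exact rational arithmetic


def oracle_dice(tp, fp, fn):
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else float(Fraction(2 * tp, denom))


def oracle_mcc(tp, fp, fn, tn):
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom2)


def oracle_components(points, cutoff):
    """Brute-force connected components of the <=cutoff adjacency graph."""
    n = len(points)
    seen = [False] * n
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in range(n):
                if not seen[v] and np.linalg.norm(points[u] - points[v]) <= cutoff:
                    seen[v] = True
                    stack.append(v)
        comps.append(sorted(comp))
    return sorted(comps)


class TestDice:
    @pytest.mark.parametrize("tp,fp,fn,expected", [
        (5, 0, 0, 1.0),
        (0, 3, 2, 0.0),
        (2, 1, 1, 2 * 2 / 6),
    ])
    def test_examples(self, tp, fp, fn, expected):
        assert dice(ConfusionCounts(tp, fp, fn, 10)) == pytest.approx(expected)

    def test_vacuous_convention(self):
        assert dice(ConfusionCounts(0, 0, 0, 7)) == 1.0

    def test_permutation_invariant_in_residue_order(self, rng):
        pred = rng.integers(0, 2, 60)
        truth = rng.integers(0, 2, 60)
        perm = rng.permutation(60)
        assert dice(confusion(pred, truth)) == dice(confusion(pred[perm],
                                                              truth[perm]))


class TestMcc:
    def test_endpoints(self):
        assert mcc(ConfusionCounts(5, 0, 0, 10)) == pytest.approx(1.0)
        assert mcc(ConfusionCounts(0, 4, 6, 0)) == pytest.approx(-1.0)

    def test_worked_example_against_oracle(self):
        c = ConfusionCounts(50, 30, 20, 900)
        expected = oracle_mcc(50, 30, 20, 900)
        assert expected == pytest.approx(0.6414, abs=1e-4)
        assert mcc(c) == pytest.approx(expected, rel=1e-12)

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionCounts(0, 0, 5, 5)) == 0.0


class TestOracleEquivalence:
    def test_thousand_random_confusion_matrices(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 40, 4))
            c = ConfusionCounts(tp, fp, fn, tn)
            assert dice(c) == pytest.approx(oracle_dice(tp, fp, fn), abs=1e-12)
            assert mcc(c) == pytest.approx(oracle_mcc(tp, fp, fn, tn), abs=1e-12)
            ppv, sens = ppv_sensitivity(c)
            assert ppv == pytest.approx(
                float(Fraction(tp, tp + fp)) if tp + fp else 0.0, abs=1e-12)
            assert sens == pytest.approx(
                float(Fraction(tp, tp + fn)) if tp + fn else 0.0, abs=1e-12)

    def test_matches_sklearn_on_label_vectors(self, rng):
        from sklearn.metrics import f1_score, matthews_corrcoef
        for _ in range(25):
            pred = rng.integers(0, 2, 80)
            truth = rng.integers(0, 2, 80)
            if pred.sum() == 0 and truth.sum() == 0:
                continue
            c = confusion(pred, truth)
            assert dice(c) == pytest.approx(
                f1_score(truth, pred, zero_division=0), abs=1e-12)
            assert mcc(c) == pytest.approx(
                matthews_corrcoef(truth, pred), abs=1e-9)


class TestPpvSensitivity:
    @pytest.mark.parametrize("tp,fp,fn,expected", [
        (4, 0, 0, (1.0, 1.0)),
        (0, 0, 0, (0.0, 0.0)),
        (3, 1, 2, (0.75, 0.6)),
    ])
    def test_examples(self, tp, fp, fn, expected):
        assert ppv_sensitivity(ConfusionCounts(tp, fp, fn, 5)) == \
            pytest.approx(expected)


class TestBinarize:
    def test_all_zero(self):
        assert binarize(np.zeros(5)).tolist() == [0] * 5

    def test_threshold_inclusive(self):
        assert binarize(np.array([0.5]), 0.5).tolist() == [1]
        assert binarize(np.array([0.499999]), 0.5).tolist() == [0]

    def test_zero_threshold_all_positive(self):
        assert binarize(np.zeros(4), 0.0).tolist() == [1] * 4


class TestClusterSites:
    def test_two_close_positives_merge(self):
        coords = np.array([[0, 0, 0], [5, 0, 0]], float)
        sites = cluster_sites([1, 1], coords, 8.0)
        assert len(sites) == 1
        np.testing.assert_allclose(sites[0].center, [2.5, 0, 0])

    def test_distant_positives_split(self):
        coords = np.array([[0, 0, 0], [30, 0, 0]], float)
        assert len(cluster_sites([1, 1], coords, 8.0)) == 2

    def test_no_positives(self):
        assert cluster_sites([0, 0], np.zeros((2, 3)), 8.0) == []

    def test_degenerate_mode_single_site(self, rng):
        coords = rng.uniform(0, 100, (20, 3))
        sites = cluster_sites(np.ones(20, int), coords, np.inf)
        assert len(sites) == 1

    def test_matches_brute_force_components(self, rng):
        coords = rng.uniform(0, 40, (50, 3))
        labels = rng.integers(0, 2, 50)
        sites = cluster_sites(labels, coords, 8.0)
        pos = np.flatnonzero(labels)
        expected = oracle_components(coords[pos], 8.0)
        got = sorted(sorted(int(np.flatnonzero(pos == m)[0]) for m in s.members)
                     for s in sites)
        assert got == expected


class TestDcc:
    @staticmethod
    def _sites(centers):
        from glycosite.metrics import Site
        return [Site(np.array([i]), np.asarray(c, float))
                for i, c in enumerate(centers)]

    def test_identical_sites_zero(self):
        s = self._sites([[1, 2, 3], [9, 9, 9]])
        assert dcc(s, s) == [0.0, 0.0]

    def test_translation_by_three(self):
        true = self._sites([[0, 0, 0]])
        pred = self._sites([[3, 0, 0]])
        assert dcc(pred, true) == [pytest.approx(3.0)]

    def test_matches_brute_force_nearest_scan(self, rng):
        pred = self._sites(rng.uniform(0, 50, (3, 3)))
        true = self._sites(rng.uniform(0, 50, (2, 3)))
        got = dcc(pred, true)
        for val, p in zip(got, pred):
            expected = min(np.linalg.norm(p.center - t.center) for t in true)
            assert val == pytest.approx(expected)

    def test_empty_predictions(self):
        assert dcc([], self._sites([[0, 0, 0]])) == []

    def test_no_true_sites_rejected(self):
        with pytest.raises(ValueError):
            dcc(self._sites([[0, 0, 0]]), [])

    def test_rigid_transform_invariant(self, rng):
        R = random_rotation_matrix(rng)
        t = rng.uniform(-10, 10, 3)
        pred = rng.uniform(0, 30, (3, 3))
        true = rng.uniform(0, 30, (2, 3))
        base = dcc(self._sites(pred), self._sites(true))
        moved = dcc(self._sites(pred @ R.T + t), self._sites(true @ R.T + t))
        np.testing.assert_allclose(base, moved, atol=1e-9)

    def test_single_site_closed_form(self, helix_structure):
        st, labels = helix_structure
        cb = st.cb_coords
        pred = labels.copy()
        true_sites = cluster_sites(labels, cb, 8.0)
        pred_sites = cluster_sites(pred, cb, 8.0)
        assert len(true_sites) == len(pred_sites) == 1
        centroid_dist = np.linalg.norm(
            cb[labels == 1].mean(axis=0) - cb[pred == 1].mean(axis=0))
        assert dcc(pred_sites, true_sites)[0] == pytest.approx(centroid_dist)


@pytest.fixture(scope="module")
def pair():
    a, la = make_structure(FixtureSpec(n_residues=40, site_size=3, seed=21))
    b, lb = make_structure(FixtureSpec(n_residues=45, site_size=3, seed=22))
    return [(a, la), (b, lb)]


class TestEvaluate:

    def test_perfect_predictions(self, pair):
        preds = [labels.astype(float) for _, labels in pair]
        report = evaluate(preds, [st for st, _ in pair])
        agg = report.aggregate
        assert agg["mean_dice"] == 1.0
        assert agg["coverage_pct"] == 100.0
        assert agg["pct_dice_over_0.6"] == 100.0
        assert agg["mean_dcc"] == pytest.approx(0.0)
        assert agg["pct_dcc_under_4A"] == 100.0

    def test_empty_predictions_everywhere(self, pair):
        preds = [np.zeros(len(st)) for st, _ in pair]
        agg = evaluate(preds, [st for st, _ in pair]).aggregate
        assert agg["coverage_pct"] == 0.0
        assert np.isnan(agg["mean_dcc"])
        assert all(r.dcc_values == [] for r in
                   evaluate(preds, [st for st, _ in pair]).per_structure)

    def test_mixed_coverage(self, pair):
        preds = [pair[0][1].astype(float), np.zeros(len(pair[1][0]))]
        agg = evaluate(preds, [st for st, _ in pair]).aggregate
        assert agg["coverage_pct"] == 50.0

    def test_length_mismatch_rejected(self, pair):
        with pytest.raises(ValueError, match="probabilities"):
            evaluate([np.zeros(3)], [pair[0][0]])

    def test_prediction_count_mismatch_rejected(self, pair):
        with pytest.raises(ValueError, match="per structure"):
            evaluate([np.zeros(40)], [st for st, _ in pair])

    def test_json_and_frame_outputs(self, pair, tmp_path):
        preds = [labels.astype(float) for _, labels in pair]
        report = evaluate(preds, [st for st, _ in pair])
        text = report.to_json(tmp_path / "report.json")
        assert (tmp_path / "report.json").exists() and "mean_dice" in text
        frame = report.to_frame()
        assert len(frame) == 2 and "dice" in frame.columns
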