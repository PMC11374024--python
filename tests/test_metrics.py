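"""CAFA metric oracles: brute-force enumeration checks and limiting cases."""

import numpy as np
import pytest

from gofusion.metrics import (
    aupr,
    auc_frequency_correlation,
    evaluate_predictions,
    fmax,
    information_content,
    propagate_scores,
    smin,
    term_auc_by_frequency,
    weighted_fmax,
)

GRID = 0.01


def taus(grid=GRID):
    return [round(k * grid, 10) for k in range(1, int(round(1 / grid)) + 1)]


def fmax_bruteforce(scores, truth, grid=GRID):
    """Literal triple loop over thresholds, proteins, and terms."""
    best, best_tau = 0.0, taus(grid)[0]
    n, m = scores.shape
    for tau in taus(grid):
        prs, rcs = [], []
        for i in range(n):
            pred = [j for j in range(m) if scores[i, j] >= tau]
            true = [j for j in range(m) if truth[i, j] > 0]
            tp = len(set(pred) & set(true))
            if pred:
                prs.append(tp / len(pred))
            if true:
                rcs.append(tp / len(true))
        pr = sum(prs) / len(prs) if prs else 0.0
        rc = sum(rcs) / len(rcs) if rcs else 0.0
        f = 2 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0
        if f > best:
            best, best_tau = f, tau
    return best, best_tau


def wfmax_bruteforce(scores, truth, ic, grid=GRID):
    best, best_tau = 0.0, taus(grid)[0]
    n, m = scores.shape
    for tau in taus(grid):
        prs, rcs = [], []
        for i in range(n):
            pred = [j for j in range(m) if scores[i, j] >= tau]
            true = [j for j in range(m) if truth[i, j] > 0]
            wtp = sum(ic[j] for j in pred if j in true)
            wpred = sum(ic[j] for j in pred)
            wtrue = sum(ic[j] for j in true)
            if pred:
                prs.append(wtp / wpred if wpred > 0 else 0.0)
            if true:
                rcs.append(wtp / wtrue if wtrue > 0 else 0.0)
        pr = sum(prs) / len(prs) if prs else 0.0
        rc = sum(rcs) / len(rcs) if rcs else 0.0
        f = 2 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0
        if f > best:
            best, best_tau = f, tau
    return best, best_tau


def smin_bruteforce(scores, truth, ic, grid=GRID):
    best, best_tau = np.inf, taus(grid)[0]
    n, m = scores.shape
    for tau in taus(grid):
        rus, mis = [], []
        for i in range(n):
            pred = {j for j in range(m) if scores[i, j] >= tau}
            true = {j for j in range(m) if truth[i, j] > 0}
            rus.append(sum(ic[j] for j in true - pred))
            mis.append(sum(ic[j] for j in pred - true))
        ru, mi = sum(rus) / n, sum(mis) / n
        s = (ru**2 + mi**2) ** 0.5
        if s < best - 1e-15:
            best, best_tau = s, tau
    return best, best_tau


def aupr_bruteforce(scores, truth):
    """Step-wise PR summation over score-sorted cells (distinct scores)."""
    cells = sorted(
        zip(scores.ravel().tolist(), truth.ravel().tolist()), key=lambda c: -c[0]
    )
    n_pos = sum(t for _s, t in cells)
    tp = 0
    area = 0.0
    for k, (_s, t) in enumerate(cells, start=1):
        if t > 0:
            tp += 1
            area += (tp / k) * (1 / n_pos)
    return area


def random_instance(rng, n_max=20, m_max=15):
    n = int(rng.integers(2, n_max + 1))
    m = int(rng.integers(2, m_max + 1))
    scores = rng.random((n, m))
    truth = (rng.random((n, m)) < 0.3).astype(float)
    if not truth.any():
        truth[0, 0] = 1.0
    return scores, truth


class TestFmax:
    def test_perfect_predictor(self):
        truth = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        value, tau = fmax(truth, truth)
        assert value == 1.0
        assert tau == pytest.approx(GRID)

    def test_all_zero_scores(self):
        truth = np.array([[1.0, 0.0]])
        assert fmax(np.zeros((1, 2)), truth)[0] == 0.0

    def test_frozen_2x3_fixture_matches_enumeration(self):
        scores = np.array([[0.9, 0.6, 0.1], [0.8, 0.2, 0.7]])
        truth = np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
        value, tau = fmax(scores, truth)
        oracle_value, oracle_tau = fmax_bruteforce(scores, truth)
        assert value == pytest.approx(oracle_value, abs=1e-9)
        assert tau == pytest.approx(oracle_tau)
        # frozen value computed once with the brute-force oracle: the best
        # threshold keeps only the top prediction per protein (pr 1, rc 3/4)
        assert value == pytest.approx(6 / 7, abs=1e-9)

    def test_no_truth_raises(self):
        with pytest.raises(ValueError):
            fmax(np.ones((2, 2)), np.zeros((2, 2)))


class TestInformationContent:
    def test_universal_term_has_zero_ic(self):
        ic = information_content({"t": 16}, 16)
        assert ic.ic["t"] == 0.0

    def test_quarter_frequency_is_two_bits(self):
        assert information_content({"t": 4}, 16).ic["t"] == pytest.approx(2.0)

    def test_monotone_in_counts(self):
        ic = information_content({"anc": 12, "desc": 3}, 16)
        assert ic.ic["anc"] <= ic.ic["desc"]

    def test_zero_protein_count_raises(self):
        with pytest.raises(ValueError):
            information_content({"t": 1}, 0)


class TestSminWeightedFmax:
    def test_perfect_prediction_limits(self):
        truth = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
        ic = np.array([1.0, 2.0, 0.5])
        assert smin(truth, truth, ic)[0] == 0.0
        assert weighted_fmax(truth, truth, ic)[0] == 1.0

    def test_all_zero_scores_give_average_true_ic(self):
        truth = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        ic = np.array([1.5, 2.0, 0.5])
        expected = np.mean([1.5 + 0.5, 2.0])
        assert smin(np.zeros_like(truth), truth, ic)[0] == pytest.approx(expected)

    def test_uniform_ic_reduces_weighted_fmax_to_fmax(self):
        rng = np.random.default_rng(0)
        scores, truth = random_instance(rng)
        ic = np.full(scores.shape[1], 1.7)
        assert weighted_fmax(scores, truth, ic)[0] == pytest.approx(
            fmax(scores, truth)[0], abs=1e-12
        )

    def test_2x3_fixture_matches_bruteforce(self):
        scores = np.array([[0.9, 0.6, 0.1], [0.8, 0.2, 0.7]])
        truth = np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
        ic = information_content({"a": 2, "b": 1, "c": 1}, 2)
        vec = ic.as_array(["a", "b", "c"])
        assert smin(scores, truth, vec)[0] == pytest.approx(
            smin_bruteforce(scores, truth, vec)[0], abs=1e-9
        )
        assert weighted_fmax(scores, truth, vec)[0] == pytest.approx(
            wfmax_bruteforce(scores, truth, vec)[0], abs=1e-9
        )


class TestAUPR:
    def test_perfect_separation(self):
        scores = np.array([[0.9, 0.8, 0.2, 0.1]])
        truth = np.array([[1.0, 1.0, 0.0, 0.0]])
        assert aupr(scores, truth) == pytest.approx(1.0)

    def test_constant_scores_give_positive_fraction(self):
        truth = np.array([[1.0, 0.0, 0.0, 1.0, 0.0]])
        assert aupr(np.full((1, 5), 0.3), truth) == pytest.approx(0.4)

    def test_six_cell_hand_fixture(self):
        scores = np.array([[0.9, 0.8, 0.7, 0.6, 0.5, 0.4]])
        truth = np.array([[1.0, 0.0, 1.0, 0.0, 0.0, 1.0]])
        # hand-traced curve: precisions 1/1, 2/3, 3/6 at the positives
        expected = (1.0 + 2 / 3 + 0.5) / 3
        assert aupr(scores, truth) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores, truth = random_instance(rng)
        assert aupr(scores, truth) == pytest.approx(
            aupr(1 / (1 + np.exp(-5 * scores)), truth), abs=1e-12
        )

    def test_zero_positives_raise(self):
        with pytest.raises(ValueError):
            aupr(np.ones((2, 2)), np.zeros((2, 2)))


class TestTermAUC:
    def test_bin_assignment_by_ceiling(self):
        rng = np.random.default_rng(2)
        scores = rng.random((40, 2))
        truth = (rng.random((40, 2)) < 0.5).astype(float)
        report = term_auc_by_frequency(scores, truth, {"a": 3, "b": 97}, ["a", "b"])
        assert 1 in report.bin_mean and 20 in report.bin_mean

    def test_perfect_ranking_gives_auc_one(self):
        truth = np.array([[1.0], [1.0], [0.0], [0.0]])
        scores = np.array([[0.9], [0.8], [0.3], [0.2]])
        report = term_auc_by_frequency(scores, truth, {"t": 2}, ["t"])
        assert report.term_auc["t"] == 1.0

    def test_random_scores_hover_near_half(self):
        rng = np.random.default_rng(3)
        truth = (rng.random((500, 1)) < 0.3).astype(float)
        scores = rng.random((500, 1))
        report = term_auc_by_frequency(scores, truth, {"t": 50}, ["t"])
        assert abs(report.term_auc["t"] - 0.5) < 0.1

    def test_degenerate_columns_are_skipped(self):
        scores = np.random.default_rng(4).random((5, 2))
        truth = np.zeros((5, 2))
        truth[:, 1] = [1, 0, 0, 1, 0]
        report = term_auc_by_frequency(scores, truth, {"a": 1, "b": 2}, ["a", "b"])
        assert report.skipped == ["a"]


class TestCorrelation:
    def test_perfect_linearity(self):
        auc = {f"t{i}": 0.5 + i / 100 for i in range(10)}
        counts = {f"t{i}": 50 + i for i in range(10)}
        assert auc_frequency_correlation(auc, counts) == pytest.approx(1.0)

    def test_zero_variance_returns_nan_with_warning(self):
        with pytest.warns(UserWarning):
            r = auc_frequency_correlation({"a": 0.7, "b": 0.7}, {"a": 1, "b": 9})
        assert np.isnan(r)

    def test_five_pair_hand_fixture(self):
        auc = {"a": 0.6, "b": 0.7, "c": 0.55, "d": 0.9, "e": 0.8}
        counts = {"a": 5, "b": 20, "c": 3, "d": 80, "e": 40}
        x = np.array([auc[t] for t in "abcde"])
        y = np.array([counts[t] for t in "abcde"], dtype=float)
        xm, ym = x - x.mean(), y - y.mean()
        expected = float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
        assert auc_frequency_correlation(auc, counts) == pytest.approx(expected, abs=1e-12)


class TestScorePropagation:
    def test_ancestor_scores_dominate_descendants(self, chain_graph):
        from gofusion.ontology import build_adjacency

        A = build_adjacency(chain_graph, "MF").A
        scores = np.array([[0.1, 0.2, 0.9]])
        prop = propagate_scores(A, scores)
        assert prop.tolist() == [[0.9, 0.9, 0.9]]

    def test_propagation_never_decreases_recall(self, chain_graph):
        from gofusion.ontology import build_adjacency

        A = build_adjacency(chain_graph, "MF").A
        rng = np.random.default_rng(5)
        scores = rng.random((10, 3))
        truth = np.zeros((10, 3))
        truth[:, 0] = 1.0
        truth[:5, 1] = 1.0
        prop = propagate_scores(A, scores)
        for tau in np.arange(0.05, 1.0, 0.05):
            rc_raw = ((scores >= tau) & (truth > 0)).sum() / truth.sum()
            rc_prop = ((prop >= tau) & (truth > 0)).sum() / truth.sum()
            assert rc_prop >= rc_raw


class TestEvaluateAll:
    def test_report_fields_are_consistent(self, study_task):
        rng = np.random.default_rng(6)
        from gofusion.ontology import annotation_matrix, build_adjacency

        graph = study_task["graph"]
        terms = graph.namespace_terms("MF")
        ids = study_task["protein_ids"][:100]
        truth = annotation_matrix(study_task["annotations"], ids, terms)
        scores = np.clip(truth * 0.8 + rng.random(truth.shape) * 0.2, 0, 1)
        counts = study_task["annotations"].term_counts()
        report = evaluate_predictions(
            scores, truth, {t: counts.get(t, 0) for t in terms}, terms,
            A=build_adjacency(graph, "MF").A,
        )
        assert 0 <= report.fmax <= 1
        assert 0 <= report.aupr <= 1
        assert report.smin >= 0
        assert report.n_proteins == 100
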