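"""CAFA-style evaluation: Fmax, weighted Fmax, Smin, AUPR, rare-term AUC.

Conventions (all protein-centric measures sweep a score threshold grid
over (0, 1], default step 0.01):

* precision at a threshold averages only over proteins with at least one
  predicted term at that threshold (the CAFA m(tau) convention); recall
  averages over all proteins that carry at least one true term;
* truth matrices are expected to be ancestor-closed, and prediction
  scores should be max-propagated up the ontology (see
  :func:`propagate_scores`) so predictions respect the true-path rule;
* information content is the marginal surprisal
  ic(t) = -log2(count(t) / n_proteins), so a universally annotated term
  carries no information and rare terms carry a lot — Smin and weighted
  Fmax therefore reward getting the specific, informative terms right;
* AUPR is micro-averaged over all (protein, term) cells; per-term ROC
  AUC uses the rank-based (Mann-Whitney) formulation with mid-ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

DEFAULT_GRID = 0.01


def _threshold_grid(grid: float) -> np.ndarray:
    if not 0.0 < grid <= 1.0:
        raise ValueError("grid step must lie in (0, 1]")
    n = int(round(1.0 / grid))
    return np.round(np.arange(1, n + 1) * grid, 10)


def _check_shapes(scores: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, float)
    if scores.shape != truth.shape:
        raise ValueError(f"shape mismatch: scores {scores.shape} vs truth {truth.shape}")
    return scores, truth


def fmax(
    scores: np.ndarray, truth: np.ndarray, grid: float = DEFAULT_GRID
) -> tuple[float, float]:
    """Maximum protein-centric F1 over the threshold grid.

    Returns (value, threshold); ties resolve to the smallest threshold.
    """
    scores, truth = _check_shapes(scores, truth)
    has_truth = truth.any(axis=1)
    if not has_truth.any():
        raise ValueError("no protein carries a true term")
    best, best_tau = 0.0, float(_threshold_grid(grid)[0])
    for tau in _threshold_grid(grid):
        pred = scores >= tau
        tp = (pred & (truth > 0)).sum(axis=1)
        npred = pred.sum(axis=1)
        ntrue = truth.sum(axis=1)
        covered = npred > 0
        pr = float(np.mean(tp[covered] / npred[covered])) if covered.any() else 0.0
        rc = float(np.mean(tp[has_truth] / ntrue[has_truth]))
        f = 2 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0
        if f > best:
            best, best_tau = f, float(tau)
    return best, best_tau


@dataclass
class InformationContent:
    """Per-term surprisal ic(t) = -log2(count(t)/n) in bits."""

    ic: dict[str, float]
    base: int = 2
    source_counts: dict[str, int] = field(default_factory=dict)

    def as_array(self, terms: Sequence[str]) -> np.ndarray:
        return np.array([self.ic[t] for t in terms])


def information_content(
    counts: Mapping[str, int], n_proteins: int
) -> InformationContent:
    """Marginal information content from ancestor-closed term counts."""
    if n_proteins <= 0:
        raise ValueError("n_proteins must be positive")
    ic = {
        t: float(-np.log2(max(c, 1) / n_proteins)) for t, c in counts.items()
    }
    return InformationContent(ic=ic, source_counts=dict(counts))


def smin(
    scores: np.ndarray,
    truth: np.ndarray,
    ic: np.ndarray | InformationContent,
    grid: float = DEFAULT_GRID,
    terms: Sequence[str] | None = None,
) -> tuple[float, float]:
    """Minimum semantic distance sqrt(ru^2 + mi^2) over the grid.

    ru = mean missing information (true terms not predicted), mi = mean
    misinformation (predicted-but-false terms), both in IC units.
    """
    scores, truth = _check_shapes(scores, truth)
    if not truth.any():
        raise ValueError("no protein carries a true term")
    ic_vec = ic.as_array(terms) if isinstance(ic, InformationContent) else np.asarray(ic, float)
    best, best_tau = np.inf, float(_threshold_grid(grid)[0])
    for tau in _threshold_grid(grid):
        pred = scores >= tau
        ru = float(np.mean(((truth > 0) & ~pred) @ ic_vec))
        mi = float(np.mean((pred & (truth == 0)) @ ic_vec))
        s = float(np.hypot(ru, mi))
        if s < best - 1e-15:
            best, best_tau = s, float(tau)
    return best, best_tau


def weighted_fmax(
    scores: np.ndarray,
    truth: np.ndarray,
    ic: np.ndarray | InformationContent,
    grid: float = DEFAULT_GRID,
    terms: Sequence[str] | None = None,
) -> tuple[float, float]:
    """Fmax with IC-weighted true/false positive and negative sums."""
    scores, truth = _check_shapes(scores, truth)
    has_truth = truth.any(axis=1)
    if not has_truth.any():
        raise ValueError("no protein carries a true term")
    ic_vec = ic.as_array(terms) if isinstance(ic, InformationContent) else np.asarray(ic, float)
    best, best_tau = 0.0, float(_threshold_grid(grid)[0])
    for tau in _threshold_grid(grid):
        pred = scores >= tau
        wtp = (pred & (truth > 0)) @ ic_vec
        wpred = pred @ ic_vec
        wtrue = (truth > 0) @ ic_vec
        covered = pred.any(axis=1)
        if covered.any():
            denom = wpred[covered]
            ratio = np.divide(wtp[covered], denom, out=np.zeros_like(denom), where=denom > 0)
            pr = float(np.mean(ratio))
        else:
            pr = 0.0
        denom_r = wtrue[has_truth]
        rc = float(
            np.mean(
                np.divide(wtp[has_truth], denom_r, out=np.zeros_like(denom_r), where=denom_r > 0)
            )
        )
        f = 2 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0
        if f > best:
            best, best_tau = f, float(tau)
    return best, best_tau


def aupr(scores: np.ndarray, truth: np.ndarray) -> float:
    """Micro-averaged area under the precision-recall curve.

    All (protein, term) cells are pooled and the area is the step-wise
    sum over the score-sorted curve.
    """
    scores, truth = _check_shapes(scores, truth)
    if not truth.any():
        raise ValueError("AUPR is undefined with zero positive cells")
    return float(average_precision_score(truth.ravel().astype(int), scores.ravel()))


@dataclass
class TermAUCReport:
    """Per-term ROC AUCs grouped into annotation-frequency bins."""

    term_auc: dict[str, float]
    bin_mean: dict[int, float]
    skipped: list[str]
    interval: int = 5
    max_count: int = 100


def term_auc_by_frequency(
    scores: np.ndarray,
    truth: np.ndarray,
    counts: Mapping[str, int],
    terms: Sequence[str],
    interval: int = 5,
    max_count: int = 100,
) -> TermAUCReport:
    """Mean per-term AUC in frequency bins (0,5], (5,10], ..., (95,100].

    Terms whose truth column is constant (all 0 or all 1) have no defined
    AUC and are reported as skipped; empty bins are absent from the
    result.
    """
    scores, truth = _check_shapes(scores, truth)
    term_auc: dict[str, float] = {}
    skipped: list[str] = []
    bins: dict[int, list[float]] = {}
    for j, t in enumerate(terms):
        col = truth[:, j]
        if col.min() == col.max():
            skipped.append(t)
            continue
        auc = float(roc_auc_score(col.astype(int), scores[:, j]))
        term_auc[t] = auc
        c = counts.get(t, 0)
        if 1 <= c <= max_count:
            b = int(np.ceil(c / interval))
            bins.setdefault(b, []).append(auc)
    bin_mean = {b: float(np.mean(v)) for b, v in sorted(bins.items())}
    return TermAUCReport(
        term_auc=term_auc, bin_mean=bin_mean, skipped=skipped,
        interval=interval, max_count=max_count,
    )


def auc_frequency_correlation(
    term_auc: Mapping[str, float], counts: Mapping[str, int]
) -> float:
    """Pearson correlation between per-term AUC and annotation frequency.

    Returns NaN (with a warning) when either variable has zero variance.
    """
    common = [t for t in term_auc if t in counts]
    if len(common) < 2:
        raise ValueError("need at least two terms with defined AUC and counts")
    x = np.array([term_auc[t] for t in common])
    y = np.array([float(counts[t]) for t in common])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("AUC-frequency correlation undefined: zero variance")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def propagate_scores(A: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Max-propagate prediction scores up the ontology.

    ``A`` is the ancestor-closure matrix (A[i, j] = 1 iff i is an
    ancestor of j or i = j); each term's propagated score is the maximum
    over its descendants (itself included), so score(ancestor) >=
    score(descendant) — predictions then respect the true-path rule like
    the closed truth does.
    """
    A = np.asarray(A) > 0
    scores = np.asarray(scores, float)
    out = np.empty_like(scores)
    for i in range(A.shape[0]):
        out[:, i] = scores[:, A[i]].max(axis=1)
    return out


@dataclass
class MetricReport:
    """Full evaluation summary for one prediction matrix."""

    fmax: float
    fmax_threshold: float
    weighted_fmax: float
    weighted_fmax_threshold: float
    smin: float
    smin_threshold: float
    aupr: float
    term_auc_bins: dict[int, float]
    auc_frequency_r: float
    n_proteins: int
    n_terms: int

    def to_dict(self) -> dict:
        return {
            "fmax": self.fmax,
            "fmax_threshold": self.fmax_threshold,
            "weighted_fmax": self.weighted_fmax,
            "weighted_fmax_threshold": self.weighted_fmax_threshold,
            "smin": self.smin,
            "smin_threshold": self.smin_threshold,
            "aupr": self.aupr,
            "term_auc_bins": {str(k): v for k, v in self.term_auc_bins.items()},
            "auc_frequency_r": self.auc_frequency_r,
            "n_proteins": self.n_proteins,
            "n_terms": self.n_terms,
        }


def evaluate_predictions(
    scores: np.ndarray,
    truth: np.ndarray,
    counts: Mapping[str, int],
    terms: Sequence[str],
    n_proteins_for_ic: int | None = None,
    A: np.ndarray | None = None,
    grid: float = DEFAULT_GRID,
) -> MetricReport:
    """One-call evaluation producing the full :class:`MetricReport`.

    ``counts`` are ancestor-closed annotation frequencies (typically from
    the training set) used both for information content and for the
    rare-term bins; when ``A`` is given, scores are max-propagated first.
    """
    scores, truth = _check_shapes(scores, truth)
    if A is not None:
        scores = propagate_scores(A, scores)
    n_ic = n_proteins_for_ic if n_proteins_for_ic is not None else truth.shape[0]
    full_counts = {t: counts.get(t, 0) for t in terms}
    ic = information_content(full_counts, n_ic)
    ic_vec = ic.as_array(terms)
    f, f_tau = fmax(scores, truth, grid)
    wf, wf_tau = weighted_fmax(scores, truth, ic_vec, grid)
    s, s_tau = smin(scores, truth, ic_vec, grid)
    report = term_auc_by_frequency(scores, truth, full_counts, terms)
    try:
        r = auc_frequency_correlation(
            report.term_auc, {t: c for t, c in full_counts.items() if c > 0}
        )
    except ValueError:
        r = float("nan")
    return MetricReport(
        fmax=f, fmax_threshold=f_tau,
        weighted_fmax=wf, weighted_fmax_threshold=wf_tau,
        smin=s, smin_threshold=s_tau,
        aupr=aupr(scores, truth),
        term_auc_bins=report.bin_mean,
        auc_frequency_r=r,
        n_proteins=scores.shape[0],
        n_terms=scores.shape[1],
    )
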