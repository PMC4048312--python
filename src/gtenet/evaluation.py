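"""Reconstruction evaluation: thresholding, ROC analysis, and
excitatory/inhibitory labeling of links and neurons.

Score matrices are turned into reconstructed networks by keeping the top
fraction of links.  Quality against the ground truth is summarized by ROC
curves (true-positive vs false-positive ratio over all thresholds).  To
label neuron types without a-priori information, GTE scores from the
inhibition-active (E+I) and inhibition-blocked (E-only) conditions are
combined: their sum highlights excitatory links (present in both), their
difference inhibitory links (present only with inhibition active);
neurons are then ranked by the difference between their putative
excitatory and inhibitory out-degrees and the top prior fraction is
labeled excitatory.  Labeling success is tested against a binomial chance
model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError, ValidationError
from .gte import GTEScoreMatrix
from .topology import EXCITATORY, INHIBITORY

__all__ = [
    "ROCCurve",
    "LabelingResult",
    "threshold_links",
    "roc_curve",
    "tpr_at_fpr",
    "threshold_at_fpr",
    "combine_conditions",
    "label_neurons",
    "labeling_pvalue",
    "expected_coincidences",
]


def _as_scores(scores) -> np.ndarray:
    if isinstance(scores, GTEScoreMatrix):
        return scores.scores
    return np.asarray(scores, dtype=float)


@dataclass
class ROCCurve:
    """ROC curve with thresholds descending from +inf; endpoints (0,0), (1,1)."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class LabelingResult:
    labels: np.ndarray            # +1 excitatory / -1 inhibitory per neuron
    degree_difference: np.ndarray  # d_i = outdeg_exc - outdeg_inh
    n_dual_links: int             # links scored both E and I, removed
    fraction_correct_exc: float | None = None
    fraction_correct_inh: float | None = None
    p_value_exc: float | None = None
    p_value_inh: float | None = None


def threshold_links(scores, link_fraction: float) -> np.ndarray:
    """Keep the top ``link_fraction`` of off-diagonal scores as links.

    Ties are broken deterministically by (score desc, source id asc,
    target id asc).
    """
    s = _as_scores(scores)
    if not 0 <= link_fraction <= 1:
        raise ParameterError("link_fraction must be in [0, 1]")
    n = s.shape[0]
    src, dst = np.where(~np.eye(n, dtype=bool))
    vals = s[src, dst]
    n_keep = int(round(link_fraction * len(vals)))
    order = np.lexsort((dst, src, -vals))
    adj = np.zeros((n, n), dtype=np.int8)
    keep = order[:n_keep]
    adj[src[keep], dst[keep]] = 1
    return adj


def roc_curve(scores, truth: np.ndarray) -> ROCCurve:
    """ROC of the score matrix against a binary ground-truth adjacency.

    Sweeps all distinct off-diagonal score values as thresholds:
    TPR = recovered true links / all true links, FPR = included non-links
    / all non-links (the diagonal is excluded from both).
    """
    s = _as_scores(scores)
    t = np.asarray(truth)
    if s.shape != t.shape:
        raise ValidationError("scores and truth must have the same shape")
    offdiag = ~np.eye(s.shape[0], dtype=bool)
    sv = s[offdiag]
    tv = t[offdiag].astype(bool)
    n_pos = int(tv.sum())
    n_neg = int((~tv).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ground truth is degenerate (all links or none)")
    order = np.argsort(-sv, kind="stable")
    sv_sorted = sv[order]
    tp = np.cumsum(tv[order])
    fp = np.cumsum(~tv[order])
    # collapse ties: curve points only where the threshold value changes
    distinct = np.r_[np.flatnonzero(np.diff(sv_sorted)), len(sv_sorted) - 1]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    thresholds = np.r_[np.inf, sv_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds, tpr, fpr, auc)


def tpr_at_fpr(curve: ROCCurve, fpr_target: float) -> float:
    """TPR linearly interpolated at the requested FPR."""
    if not 0 <= fpr_target <= 1:
        raise ParameterError("fpr_target must be in [0, 1]")
    return float(np.interp(fpr_target, curve.fpr, curve.tpr))


def threshold_at_fpr(scores, truth: np.ndarray, fpr_max: float = 0.05) -> np.ndarray:
    """Largest high-purity link set with false-positive ratio <= ``fpr_max``.

    Walks the ROC ordering and keeps the longest score-ranked prefix whose
    FPR stays within the bound (ground truth known, as in simulation).
    """
    s = _as_scores(scores)
    t = np.asarray(truth).astype(bool)
    n = s.shape[0]
    offdiag = ~np.eye(n, dtype=bool)
    src, dst = np.where(offdiag)
    vals = s[src, dst]
    tv = t[src, dst]
    n_neg = int((~tv).sum())
    order = np.lexsort((dst, src, -vals))
    fp = np.cumsum(~tv[order])
    ok = np.flatnonzero(fp / max(n_neg, 1) <= fpr_max)
    adj = np.zeros((n, n), dtype=np.int8)
    if len(ok):
        keep = order[: ok[-1] + 1]
        adj[src[keep], dst[keep]] = 1
    return adj


def combine_conditions(scores_ei, scores_eonly) -> tuple[np.ndarray, np.ndarray]:
    """Combine E+I and E-only GTE scores into putative E and I scores.

    Excitatory links are present in both conditions, so their scores add;
    inhibitory links exist only with inhibition active, so they stand out
    in the difference.  Only the rank ordering matters downstream.
    """
    ei = _as_scores(scores_ei)
    eo = _as_scores(scores_eonly)
    if ei.shape != eo.shape:
        raise ValidationError("score matrices must share neuron indexing")
    return ei + eo, ei - eo


def label_neurons(
    putative_exc: np.ndarray,
    putative_inh: np.ndarray,
    frac_excitatory: float,
    truth_types: np.ndarray | None = None,
    alpha: float = 0.05,
) -> LabelingResult:
    """Label neurons E/I from thresholded putative-E and putative-I subnets.

    Links present in both subnetworks (forbidden under Dale's principle)
    are removed first; each neuron is then ranked by
    ``d_i = outdeg_E(i) - outdeg_I(i)`` and the top ``frac_excitatory``
    fraction is labeled excitatory (ties broken by neuron id).  If the
    true types are supplied, per-class accuracies and upper-tail binomial
    p-values against the chance model are reported.
    """
    pe = np.asarray(putative_exc).astype(bool)
    pi = np.asarray(putative_inh).astype(bool)
    if pe.shape != pi.shape:
        raise ValidationError("subnetworks must have the same shape")
    dual = pe & pi
    pe = pe & ~dual
    pi = pi & ~dual
    d = pe.sum(axis=1).astype(int) - pi.sum(axis=1).astype(int)
    n = len(d)
    n_exc = int(round(frac_excitatory * n))
    order = np.lexsort((np.arange(n), -d))  # d desc, id asc
    labels = np.full(n, INHIBITORY, dtype=np.int8)
    labels[order[:n_exc]] = EXCITATORY
    result = LabelingResult(labels, d, int(dual.sum()))
    if truth_types is not None:
        truth_types = np.asarray(truth_types)
        e_mask = truth_types == EXCITATORY
        i_mask = ~e_mask
        n_e, n_i = int(e_mask.sum()), int(i_mask.sum())
        correct_e = int((labels[e_mask] == EXCITATORY).sum())
        correct_i = int((labels[i_mask] == INHIBITORY).sum())
        result.fraction_correct_exc = correct_e / n_e if n_e else np.nan
        result.fraction_correct_inh = correct_i / n_i if n_i else np.nan
        p_e, p_i = labeling_pvalue(correct_e, correct_i, n_e, n_i)
        result.p_value_exc = p_e
        result.p_value_inh = p_i
    return result


def labeling_pvalue(
    n_correct_exc: int,
    n_correct_inh: int,
    n_exc: int,
    n_inh: int,
    pooled_chance: bool = False,
) -> tuple[float, float]:
    """Binomial significance of E/I labeling accuracy, per class.

    Under random labeling that respects the known class fractions, a
    neuron of a class holding fraction q of the population is labeled
    correctly with probability q; the number of correct calls in a class
    of size N is then Binomial(N, q).  Returns the upper-tail
    probabilities of at least the observed number of correct calls for
    the excitatory and inhibitory classes.  With ``pooled_chance`` both
    classes use the pooled success probability ``f_E^2 + f_I^2``.
    """
    if not (0 <= n_correct_exc <= n_exc and 0 <= n_correct_inh <= n_inh):
        raise ParameterError("correct counts must not exceed class sizes")
    total = n_exc + n_inh
    if total == 0:
        raise ParameterError("empty population")
    f_e = n_exc / total
    f_i = n_inh / total
    if pooled_chance:
        q_e = q_i = f_e**2 + f_i**2
    else:
        q_e, q_i = f_e, f_i
    p_e = float(stats.binom.sf(n_correct_exc - 1, n_exc, q_e)) if n_exc else np.nan
    p_i = float(stats.binom.sf(n_correct_inh - 1, n_inh, q_i)) if n_inh else np.nan
    return p_e, p_i


def expected_coincidences(firing_rate: float, window: float, n_samples: int) -> float:
    """Expected chance same-window spike coincidences between two
    unconnected neurons: ``n_samples * (f * window)^2``."""
    if firing_rate < 0 or window <= 0 or n_samples < 0:
        raise ParameterError("arguments must be positive")
    return n_samples * (firing_rate * window) ** 2
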