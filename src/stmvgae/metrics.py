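"""External clustering-agreement metrics: ARI, NMI, homogeneity, purity.

Implemented from the contingency table directly (not delegated), so the
test suite can check them against an independent reference implementation.
All four are invariant to consistent relabeling of either partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .data import ValidationError

__all__ = ["MetricReport", "adjusted_rand_index",
           "normalized_mutual_information", "homogeneity_score", "purity",
           "evaluate"]


@dataclass
class MetricReport:
    ari: float
    nmi: float
    hs: float
    purity: float
    n_spots: int

    def as_dict(self) -> dict:
        return {"ari": self.ari, "nmi": self.nmi, "hs": self.hs,
                "purity": self.purity, "n_spots": self.n_spots}


def _contingency(truth, pred) -> np.ndarray:
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ValidationError("truth and pred must be equal-length vectors")
    if truth.size < 2:
        raise ValidationError("need at least 2 spots")
    _, ti = np.unique(truth, return_inverse=True)
    _, pi = np.unique(pred, return_inverse=True)
    m = sparse.coo_matrix((np.ones(truth.size), (ti, pi))).toarray()
    return m


def adjusted_rand_index(truth, pred) -> float:
    """Permutation-model-adjusted Rand index via pair counting."""
    m = _contingency(truth, pred)
    n = m.sum()

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_cells = comb2(m).sum()
    sum_rows = comb2(m.sum(axis=1)).sum()
    sum_cols = comb2(m.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_rows * sum_cols / total
    max_index = (sum_rows + sum_cols) / 2.0
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def normalized_mutual_information(truth, pred) -> float:
    """I(T;P) / mean(H(T), H(P)); 0 if one side is a single cluster
    (and the other is not), 1 if both are trivially identical."""
    m = _contingency(truth, pred)
    n = m.sum()
    ht = _entropy(m.sum(axis=1))
    hp = _entropy(m.sum(axis=0))
    if ht == 0.0 and hp == 0.0:
        return 1.0
    if ht == 0.0 or hp == 0.0:
        return 0.0
    pij = m / n
    outer = np.outer(m.sum(axis=1), m.sum(axis=0)) / (n * n)
    nz = pij > 0
    mi = float((pij[nz] * np.log(pij[nz] / outer[nz])).sum())
    return mi / ((ht + hp) / 2.0)


def homogeneity_score(truth, pred) -> float:
    """1 - H(T|P)/H(T); 1.0 when every predicted cluster is pure."""
    m = _contingency(truth, pred)
    n = m.sum()
    ht = _entropy(m.sum(axis=1))
    if ht == 0.0:
        return 1.0
    # H(T|P) = sum_p P(p) H(T | P=p)
    h_cond = 0.0
    for col in m.T:
        csum = col.sum()
        if csum > 0:
            h_cond += (csum / n) * _entropy(col)
    return float(1.0 - h_cond / ht)


def purity(truth, pred) -> float:
    """(1/n) * sum over predicted clusters of the largest class overlap."""
    m = _contingency(truth, pred)
    return float(m.max(axis=0).sum() / m.sum())


def evaluate(truth, pred) -> MetricReport:
    return MetricReport(
        ari=adjusted_rand_index(truth, pred),
        nmi=normalized_mutual_information(truth, pred),
        hs=homogeneity_score(truth, pred),
        purity=purity(truth, pred),
        n_spots=int(np.asarray(truth).size),
    )
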