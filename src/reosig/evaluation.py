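"""Classifier evaluation: confusion metrics, the sensitivity/specificity
F-score, vote-count ROC/AUC, and clustering-based assessment of
signature-disconfirmed samples.

The F-score used throughout is the harmonic mean of sensitivity and
specificity, ``2 * sens * spec / (sens + spec)`` — not the precision/recall
F1. MSI is the positive class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .io import MSI, MSS, ExpressionMatrix, LabelTable
from .reo import de_statistics

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_msi(self) -> int:
        return self.tp + self.fn

    @property
    def n_mss(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class Metrics:
    sensitivity: float
    specificity: float
    f_score: float
    auc: float = field(default=float("nan"))


def confusion(predictions: Sequence[str], truths: Sequence[str]) -> ConfusionMatrix:
    """Confusion counts with MSI as the positive class."""
    if len(predictions) != len(truths):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(truths)} truths"
        )
    if len(truths) == 0:
        raise ValueError("empty label sequences")
    unknown = {lab for lab in (*predictions, *truths) if lab not in (MSI, MSS)}
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    tp = fn = fp = tn = 0
    for pred, truth in zip(predictions, truths):
        if truth == MSI:
            tp += pred == MSI
            fn += pred == MSS
        else:
            fp += pred == MSI
            tn += pred == MSS
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def f_score(sensitivity: float, specificity: float) -> float:
    """Harmonic mean of sensitivity and specificity; 0 when both are 0."""
    if sensitivity + specificity == 0:
        return 0.0
    return 2 * sensitivity * specificity / (sensitivity + specificity)


def metrics_from_confusion(cm: ConfusionMatrix) -> Metrics:
    if cm.n_msi == 0 or cm.n_mss == 0:
        raise ValueError("both classes must be represented in the truth labels")
    sens = cm.tp / cm.n_msi
    spec = cm.tn / cm.n_mss
    return Metrics(sensitivity=sens, specificity=spec, f_score=f_score(sens, spec))


def roc_auc(scores: Sequence[float], truths: Sequence[str]) -> float:
    """AUC of the ROC swept over score thresholds (MSI = positive).

    Computed as the Mann-Whitney probability that a random MSI sample scores
    above a random MSS sample, with ties contributing 1/2 (midranks) —
    equal to the trapezoidal area under the empirical ROC curve.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truths)
    if len(s) != len(t):
        raise ValueError("scores and truths must be aligned")
    pos = t == MSI
    neg = t == MSS
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(s)
    n1, n2 = int(pos.sum()), int(neg.sum())
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n2))


def round_metric(x: float, places: int = 4) -> float:
    """Half-up rounding at the reporting precision."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def metrics_report(
    cms: dict[str, ConfusionMatrix],
    aucs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-dataset evaluation table (metrics rounded to 4 decimals)."""
    rows = []
    for tag, cm in cms.items():
        m = metrics_from_confusion(cm)
        rows.append(
            {
                "dataset": tag,
                "tp": cm.tp,
                "fn": cm.fn,
                "fp": cm.fp,
                "tn": cm.tn,
                "sensitivity": round_metric(m.sensitivity),
                "specificity": round_metric(m.specificity),
                "f_score": round_metric(m.f_score),
                "auc": round_metric(aucs[tag]) if aucs and tag in aucs else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def cluster_assessment(
    matrix: ExpressionMatrix,
    confirmed_labels: LabelTable,
    query_ids: Iterable[str],
    n_top: int = 100,
    fdr_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Which class do disputed samples cluster with?

    DE genes are computed between the signature-confirmed MSI and MSS
    samples (Student's t, BH FDR < ``fdr_cutoff``); on the top ``n_top``
    genes (ascending q, then p, then symbol) all samples are clustered by
    complete-linkage hierarchical clustering with Euclidean distance and the
    tree is cut into two clusters. Each cluster is labeled by the majority
    class of its confirmed members ("unassigned" on a tie or when a cluster
    has no confirmed member); each query sample is reported with the class
    of the cluster it joins.
    """
    query_ids = list(query_ids)
    missing = [q for q in query_ids if q not in matrix.data.columns]
    if missing:
        raise KeyError(f"query samples absent from matrix: {missing}")
    confirmed = [s for s in confirmed_labels.sample_ids]
    sub = matrix.subset_samples(confirmed)
    de = de_statistics(sub, confirmed_labels)
    de = de[de["q"] < fdr_cutoff]
    if de.empty:
        raise ValueError("no DE genes between confirmed classes at the FDR cutoff")
    if len(de) < n_top:
        logger.warning(
            "only %d DE genes available (requested top %d); using all", len(de), n_top
        )
    order = de.assign(gene=de.index).sort_values(
        ["q", "p", "gene"], kind="stable"
    )
    top_genes = order.index[:n_top].tolist()

    samples = matrix.sample_ids
    profile = matrix.data.loc[top_genes].T.to_numpy()  # samples x genes
    Z = linkage(profile, method="complete", metric="euclidean")
    assignment = fcluster(Z, t=2, criterion="maxclust")
    cluster_of = dict(zip(samples, assignment))

    cluster_class: dict[int, str] = {}
    for cl in (1, 2):
        members = [s for s in confirmed if cluster_of[s] == cl]
        n_msi = sum(confirmed_labels.status(s) == MSI for s in members)
        n_mss = len(members) - n_msi
        if not members or n_msi == n_mss:
            cluster_class[cl] = "unassigned"
        else:
            cluster_class[cl] = MSI if n_msi > n_mss else MSS
    return pd.DataFrame(
        {
            "sample_id": query_ids,
            "cluster": [int(cluster_of[q]) for q in query_ids],
            "cluster_class": [cluster_class[cluster_of[q]] for q in query_ids],
        }
    ).set_index("sample_id")
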