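"""Model/Results interface tying the discovery pipeline together.

``MsiSignatureModel`` holds a labeled training expression matrix and the
screening thresholds; ``fit()`` runs the full discovery pipeline

    DE screen -> pair screen (Fisher) -> redundancy removal -> FD filter
    -> vote-threshold selection

and returns an ``MsiSignatureResults`` carrying the fitted signature, the
per-stage counts, training-set diagnostics and a ``summary()`` table.
Prediction on new samples hangs off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .evaluation import (
    ConfusionMatrix,
    Metrics,
    confusion,
    metrics_from_confusion,
    roc_auc,
    round_metric,
)
from .io import ExpressionMatrix, LabelTable, read_expression_matrix, read_labels
from .reo import (
    PairStats,
    remove_redundant_pairs,
    screen_de_genes,
    select_candidate_pairs,
)
from .signature import (
    Signature,
    classify_matrix,
    filter_by_fd,
    select_vote_threshold,
)


class StageEmptyError(RuntimeError):
    """A discovery stage produced an empty gene/pair set."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} produced an empty set ({detail})")
        self.stage = stage


class MsiSignatureModel:
    """REO gene-pair signature discovery on a labeled training cohort.

    Parameters
    ----------
    matrix
        Training expression matrix (genes × samples, any monotone scale).
    labels
        MSI/MSS assignment for the training samples.
    de_fdr
        BH FDR cutoff for the Student's t differential-expression screen.
    pair_fdr
        BH FDR cutoff for the one-sided Fisher pair screen.
    fd_min
        Minimum frequency difference (FD) a pair must reach to enter the
        signature; 0.8 for the right-sided colon signature, 0.9 for the
        left-sided one.
    max_de_genes
        Optional cap on DE genes entering the all-pairs screen (top genes
        by t-test p-value), for desk-scale runs.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        labels: LabelTable,
        de_fdr: float = 0.01,
        pair_fdr: float = 0.01,
        fd_min: float = 0.8,
        max_de_genes: int | None = None,
    ):
        labels.check_against(matrix)
        self.matrix = matrix
        self.labels = labels
        self.de_fdr = de_fdr
        self.pair_fdr = pair_fdr
        self.fd_min = fd_min
        self.max_de_genes = max_de_genes

    @classmethod
    def from_files(
        cls,
        expression_path: str | Path,
        labels_path: str | Path,
        genes_in: str = "rows",
        **kwargs,
    ) -> "MsiSignatureModel":
        matrix = read_expression_matrix(expression_path, genes_in=genes_in)
        labels = read_labels(labels_path)
        # restrict to labeled samples so unlabeled columns are ignored
        matrix = matrix.subset_samples(
            [s for s in matrix.sample_ids if s in labels.labels]
        )
        return cls(matrix, labels, **kwargs)

    def fit(self) -> "MsiSignatureResults":
        """Run the discovery pipeline; deterministic given inputs and config."""
        de = screen_de_genes(
            self.matrix, self.labels, fdr_cutoff=self.de_fdr, max_genes=self.max_de_genes
        )
        if len(de) < 2:
            raise StageEmptyError(
                "screen_de_genes", f"{len(de)} genes at FDR<{self.de_fdr}"
            )
        candidates = select_candidate_pairs(
            self.matrix, self.labels, [d.gene_id for d in de], fdr_cutoff=self.pair_fdr
        )
        if not candidates:
            raise StageEmptyError(
                "select_candidate_pairs", f"0 pairs at FDR<{self.pair_fdr}"
            )
        nonredundant = remove_redundant_pairs(candidates)
        selected = filter_by_fd(nonredundant, self.fd_min)
        if not selected:
            raise StageEmptyError("filter_by_fd", f"0 pairs at FD>={self.fd_min}")

        provisional = Signature(
            pairs=[ps.genes for ps in selected], vote_threshold=1
        )
        votes_df = classify_matrix(self.matrix, provisional)
        vote_counts = votes_df["votes"].to_dict()
        k, per_k = select_vote_threshold(vote_counts, self.labels, len(selected))

        signature = Signature(
            pairs=[ps.genes for ps in selected],
            vote_threshold=k,
            metadata={
                "de_fdr": self.de_fdr,
                "pair_fdr": self.pair_fdr,
                "fd_min": self.fd_min,
                "n_de_genes": len(de),
                "n_candidate_pairs": len(candidates),
                "n_nonredundant_pairs": len(nonredundant),
                "n_selected_pairs": len(selected),
                "vote_threshold": k,
            },
        )
        return MsiSignatureResults(
            model=self,
            signature=signature,
            de_genes=de,
            candidate_pairs=candidates,
            nonredundant_pairs=nonredundant,
            selected_pairs=selected,
            per_k_metrics=per_k,
            training_votes=votes_df["votes"],
        )


@dataclass
class MsiSignatureResults:
    """Fitted signature plus training-set diagnostics."""

    model: MsiSignatureModel
    signature: Signature
    de_genes: list
    candidate_pairs: list[PairStats]
    nonredundant_pairs: list[PairStats]
    selected_pairs: list[PairStats]
    per_k_metrics: pd.DataFrame
    training_votes: pd.Series
    _training_pred: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def stage_counts(self) -> dict[str, int]:
        return {
            "de_genes": len(self.de_genes),
            "candidate_pairs": len(self.candidate_pairs),
            "nonredundant_pairs": len(self.nonredundant_pairs),
            "selected_pairs": len(self.selected_pairs),
            "vote_threshold": self.signature.vote_threshold,
        }

    def predict(
        self, matrix: ExpressionMatrix | None = None, missing_policy: str = "error"
    ) -> pd.DataFrame:
        """Per-sample votes and MSI/MSS calls (training matrix by default)."""
        if matrix is None:
            if self._training_pred is None:
                self._training_pred = classify_matrix(
                    self.model.matrix, self.signature
                )
            return self._training_pred
        return classify_matrix(matrix, self.signature, missing_policy)

    @property
    def training_confusion(self) -> ConfusionMatrix:
        pred = self.predict()
        truths = [self.model.labels.status(s) for s in pred.index]
        return confusion(pred["predicted_status"].tolist(), truths)

    @property
    def training_metrics(self) -> Metrics:
        m = metrics_from_confusion(self.training_confusion)
        pred = self.predict()
        truths = [self.model.labels.status(s) for s in pred.index]
        auc = roc_auc(pred["votes"].to_numpy(), truths)
        return Metrics(m.sensitivity, m.specificity, m.f_score, auc)

    def summary(self) -> str:
        """Human-readable fit report."""
        cm = self.training_confusion
        m = self.training_metrics
        lines = [
            "REO gene-pair MSI signature",
            "=" * 45,
            f"training samples        {cm.n_msi} MSI / {cm.n_mss} MSS",
            f"DE genes (FDR<{self.model.de_fdr:g})     {len(self.de_genes)}",
            f"candidate pairs         {len(self.candidate_pairs)}",
            f"after redundancy        {len(self.nonredundant_pairs)}",
            f"after FD>={self.model.fd_min:g}           {len(self.selected_pairs)}",
            f"vote threshold k        {self.signature.vote_threshold} of {self.signature.n_pairs}",
            "-" * 45,
            "pair (gene1 > gene2 votes MSI)      FD",
        ]
        for ps in self.selected_pairs:
            lines.append(f"  {ps.gene1:>12} > {ps.gene2:<12}    {ps.fd:8.4f}")
        lines += [
            "-" * 45,
            f"training sensitivity    {round_metric(m.sensitivity):.4f}",
            f"training specificity    {round_metric(m.specificity):.4f}",
            f"training F-score        {round_metric(m.f_score):.4f}",
            f"training AUC            {round_metric(m.auc):.4f}",
        ]
        return "\n".join(lines)
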