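"""Synthetic two-class expression data with planted REO structure.

The generator emulates the statistical situation the discovery pipeline
assumes: a cohort of MSI and MSS samples in which a small set of gene pairs
shows the pattern ``E_gene1 > E_gene2`` with class-dependent probability
(p_pattern_msi in MSI, p_pattern_mss in MSS), on top of a background of
unrelated genes. Planted genes are also mean-shifted between classes so
that they pass the differential-expression screen, as the real signature
genes do.

Expression values are log-normal: per-gene baselines on the log2 scale with
Gaussian noise, exponentiated to a positive measurement scale so that the
multiplicative degradation operator is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    MSI,
    MSS,
    ExpressionMatrix,
    LabelTable,
    write_expression_matrix,
    write_labels,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``n_genes`` is the total gene count; ``2 * n_planted_pairs`` of them are
    planted signature genes, the rest background. ``de_shift`` is the mean
    log2 shift of planted genes in MSI samples, in units of ``noise_sd``.
    """

    n_msi: int = 60
    n_mss: int = 60
    n_genes: int = 300
    n_planted_pairs: int = 10
    p_pattern_msi: float = 0.95
    p_pattern_mss: float = 0.05
    de_shift: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_pattern_msi", "p_pattern_mss"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.n_msi, self.n_mss, self.n_genes) < 1 or self.n_planted_pairs < 0:
            raise ValueError("sample and gene counts must be positive")
        if 2 * self.n_planted_pairs > self.n_genes:
            raise ValueError(
                f"2 * n_planted_pairs = {2 * self.n_planted_pairs} exceeds "
                f"n_genes = {self.n_genes}"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, LabelTable, list[tuple[str, str]]]:
    """Draw one labeled cohort; bit-identical for identical config.

    For each planted pair, the two gene values in a sample are drawn iid
    from the pair's (class-shifted) distribution, then assigned to
    (gene1, gene2) as (max, min) with the class's pattern probability and as
    (min, max) otherwise — so ``P(E_gene1 > E_gene2 | class)`` equals the
    configured probability exactly.

    Because that assignment hands gene2 the smaller draw in MSI and the
    larger one in MSS, it erodes gene2's between-class mean difference by
    ``2 (p_msi - p_mss) / sqrt(pi)`` noise SDs (the expected max of two iid
    Gaussians is ``sd / sqrt(pi)``). The pair-level class shift is raised by
    that amount so the disadvantaged gene still shifts by exactly
    ``de_shift`` SDs and both planted genes clear the DE screen as intended.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_msi + config.n_mss
    is_msi = np.zeros(n_samples, dtype=bool)
    is_msi[: config.n_msi] = True
    sample_ids = [f"MSI_{i+1:03d}" for i in range(config.n_msi)] + [
        f"MSS_{i+1:03d}" for i in range(config.n_mss)
    ]

    n_planted_genes = 2 * config.n_planted_pairs
    n_background = config.n_genes - n_planted_genes
    planted_pairs = [
        (f"P{m+1:03d}A", f"P{m+1:03d}B") for m in range(config.n_planted_pairs)
    ]
    background_genes = [f"G{i+1:04d}" for i in range(n_background)]

    log2 = np.empty((config.n_genes, n_samples))
    gene_ids: list[str] = []
    row = 0
    dilution = (
        2 * abs(config.p_pattern_msi - config.p_pattern_mss) / np.sqrt(np.pi)
    )
    pair_shift = (config.de_shift + dilution) * config.noise_sd
    shift = np.where(is_msi, pair_shift, 0.0)
    p_pattern = np.where(is_msi, config.p_pattern_msi, config.p_pattern_mss)
    for g1, g2 in planted_pairs:
        mu = rng.uniform(3.0, 9.0)
        draws = rng.normal(mu, config.noise_sd, size=(2, n_samples)) + shift
        hi = draws.max(axis=0)
        lo = draws.min(axis=0)
        pattern = rng.random(n_samples) < p_pattern
        log2[row] = np.where(pattern, hi, lo)
        log2[row + 1] = np.where(pattern, lo, hi)
        gene_ids += [g1, g2]
        row += 2
    for g in background_genes:
        mu = rng.uniform(3.0, 9.0)
        log2[row] = rng.normal(mu, config.noise_sd, size=n_samples)
        gene_ids.append(g)
        row += 1

    values = np.exp2(log2)
    matrix = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
    labels = LabelTable(
        {sid: (MSI if flag else MSS) for sid, flag in zip(sample_ids, is_msi)}
    )
    return matrix, labels, planted_pairs


def apply_monotone_distortion(matrix: ExpressionMatrix, seed: int) -> ExpressionMatrix:
    """Apply an independent strictly increasing transform to each sample.

    Each sample gets ``f(x) = a + b*x + c*x**3`` with b, c > 0 — a stand-in
    for arbitrary monotone scale differences between profiling runs. Rank
    order within every sample is preserved, so REO-based calls must not
    change.
    """
    rng = np.random.default_rng(seed)
    X = matrix.values.astype(float)
    n = matrix.n_samples
    a = rng.uniform(-5.0, 5.0, size=n)
    b = rng.uniform(0.1, 3.0, size=n)
    c = rng.uniform(0.01, 0.5, size=n)
    # scale x to unit magnitude per sample before cubing, for numeric headroom
    scale = np.abs(X).max(axis=0)
    scale[scale == 0] = 1.0
    Xs = X / scale
    out = a + b * Xs + c * Xs**3
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.gene_ids, columns=matrix.sample_ids)
    )


def apply_degradation(
    matrix: ExpressionMatrix,
    fraction_genes: float,
    attenuation_range: tuple[float, float] = (0.5, 0.9),
    seed: int = 0,
) -> ExpressionMatrix:
    """Attenuate a random subset of genes per sample (multiplicative loss).

    Mimics partial RNA degradation: in each sample, ``fraction_genes`` of
    the genes are multiplied by a factor drawn uniformly from
    ``attenuation_range``. Not rank-preserving — used to measure classifier
    stability under realistic signal loss.
    """
    if not 0 <= fraction_genes <= 1:
        raise ValueError(f"fraction_genes must be in [0, 1], got {fraction_genes}")
    lo, hi = attenuation_range
    if lo > hi:
        raise ValueError("attenuation_range must be (low, high) with low <= high")
    rng = np.random.default_rng(seed)
    X = matrix.values.astype(float).copy()
    n_genes, n_samples = X.shape
    n_hit = int(round(fraction_genes * n_genes))
    for j in range(n_samples):
        idx = rng.choice(n_genes, size=n_hit, replace=False)
        X[idx, j] *= rng.uniform(lo, hi, size=n_hit)
    return ExpressionMatrix(
        pd.DataFrame(X, index=matrix.gene_ids, columns=matrix.sample_ids)
    )


def write_simulation(
    out_dir: str | Path,
    matrix: ExpressionMatrix,
    labels: LabelTable,
    planted_pairs: list[tuple[str, str]],
    config: SimulationConfig,
) -> None:
    """Write the matrix/label TSVs plus a planted-truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(matrix, out / "expression.tsv")
    write_labels(labels, out / "labels.tsv")
    with (out / "planted_pairs.tsv").open("w") as fh:
        fh.write("gene1\tgene2\ttrue_p1\ttrue_p2\n")
        for g1, g2 in planted_pairs:
            fh.write(
                f"{g1}\t{g2}\t{config.p_pattern_msi}\t{config.p_pattern_mss}\n"
            )
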