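"""Core REO (relative expression ordering) statistics.

Signature discovery screens genes and gene pairs in four steps:

1. differential expression between MSI and MSS samples (two-sided Student's
   t-test, Benjamini-Hochberg FDR);
2. for every pair of DE genes, count how often the oriented pattern
   ``E_gene1 > E_gene2`` holds within each class and test whether it is more
   frequent in MSI with a one-sided Fisher exact test (BH FDR over all pairs);
3. score each pair by the frequency difference FD = p1 - p2, the difference
   between the within-class pattern frequencies;
4. remove redundant pairs so each gene appears in at most one pair, keeping
   the pair with the largest FD.

All statistics depend only on within-sample orderings, so any strictly
increasing per-sample transform of the expression values leaves them
unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import MSI, MSS, ExpressionMatrix, LabelTable

logger = logging.getLogger(__name__)

_PAIR_BLOCK = 256  # row block size for the all-pairs comparison


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    t_statistic: float
    p_value: float
    q_value: float


@dataclass(frozen=True)
class PairStats:
    """An oriented gene pair; the pattern ``E_gene1 > E_gene2`` votes MSI."""

    gene1: str
    gene2: str
    n1_pattern: int
    n1_total: int
    n2_pattern: int
    n2_total: int
    fisher_p: float
    fisher_q: float = float("nan")

    @property
    def p1(self) -> float:
        return self.n1_pattern / self.n1_total

    @property
    def p2(self) -> float:
        return self.n2_pattern / self.n2_total

    @property
    def fd(self) -> float:
        return self.p1 - self.p2

    @property
    def genes(self) -> tuple[str, str]:
        return (self.gene1, self.gene2)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-aligned with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _class_indices(matrix: ExpressionMatrix, labels: LabelTable) -> tuple[np.ndarray, np.ndarray]:
    labels.check_against(matrix)
    cols = pd.Index(matrix.sample_ids)
    msi = cols.get_indexer(labels.samples_with(MSI))
    mss = cols.get_indexer(labels.samples_with(MSS))
    return msi, mss


def de_statistics(matrix: ExpressionMatrix, labels: LabelTable) -> pd.DataFrame:
    """Per-gene two-sided Student's t statistics (equal variance) with BH q-values.

    Genes with zero variance in both classes get p = 1 (no evidence), not an
    error. Returns a DataFrame indexed by gene id with columns t, p, q.
    """
    msi, mss = _class_indices(matrix, labels)
    if len(msi) < 2 or len(mss) < 2:
        raise ValueError(
            f"each class needs >=2 samples (MSI: {len(msi)}, MSS: {len(mss)})"
        )
    X = matrix.values
    t, p = stats.ttest_ind(X[:, msi], X[:, mss], axis=1, equal_var=True)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        genes = np.asarray(matrix.gene_ids)[degenerate].tolist()
        logger.info("zero-variance genes assigned p=1: %s", genes)
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    q = bh_adjust(p)
    return pd.DataFrame({"t": t, "p": p, "q": q}, index=matrix.gene_ids)


def screen_de_genes(
    matrix: ExpressionMatrix,
    labels: LabelTable,
    fdr_cutoff: float = 0.01,
    max_genes: int | None = None,
) -> list[DEResult]:
    """Genes differentially expressed between MSI and MSS at BH FDR < cutoff.

    ``max_genes`` optionally caps the result to the top genes by p-value,
    which keeps the subsequent all-pairs screen desk-scale.
    """
    if not 0 < fdr_cutoff < 1:
        raise ValueError(f"fdr_cutoff must be in (0, 1), got {fdr_cutoff}")
    table = de_statistics(matrix, labels)
    kept = table[table["q"] < fdr_cutoff]
    if max_genes is not None and len(kept) > max_genes:
        kept = kept.sort_values(["p", "q"], kind="stable").iloc[:max_genes]
        kept = kept.loc[sorted(kept.index, key=table.index.get_loc)]
    return [
        DEResult(g, float(r["t"]), float(r["p"]), float(r["q"]))
        for g, r in kept.iterrows()
    ]


def pair_reo_counts(
    matrix: ExpressionMatrix, labels: LabelTable, gene1: str, gene2: str
) -> np.ndarray:
    """2x2 table of the pattern ``E_gene1 > E_gene2``: rows (MSI, MSS),
    columns (pattern, non-pattern). Ties count as non-pattern."""
    for g in (gene1, gene2):
        if g not in matrix.data.index:
            raise KeyError(f"gene {g!r} not present in expression matrix")
    msi, mss = _class_indices(matrix, labels)
    v1 = matrix.data.loc[gene1].to_numpy()
    v2 = matrix.data.loc[gene2].to_numpy()
    pattern = v1 > v2
    a = int(pattern[msi].sum())
    c = int(pattern[mss].sum())
    return np.array([[a, len(msi) - a], [c, len(mss) - c]])


def _check_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)) or np.any(arr < 0):
            raise ValueError("counts must be non-negative integers")
        arr = arr.astype(int)
    return arr


def fisher_exact_p(counts) -> float:
    """One-sided Fisher exact p-value that the pattern is more frequent in MSI.

    For the table [[a, b], [c, d]] (rows MSI, MSS; columns pattern,
    non-pattern) this is the upper hypergeometric tail P(X >= a) with
    population a+b+c+d, a+c pattern samples and a+b draws.
    """
    a, b = _check_counts(counts)[0]
    c, d = _check_counts(counts)[1]
    return float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def compute_fd(counts) -> float:
    """Frequency difference FD = p1 - p2 of the pattern between MSI and MSS."""
    arr = _check_counts(counts)
    n1, n2 = arr[0].sum(), arr[1].sum()
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must have at least one sample")
    return arr[0, 0] / n1 - arr[1, 0] / n2


def _pattern_count_matrix(X: np.ndarray) -> np.ndarray:
    """C[i, j] = number of columns with X[i] > X[j], computed in row blocks."""
    g = X.shape[0]
    C = np.empty((g, g), dtype=np.int64)
    for start in range(0, g, _PAIR_BLOCK):
        stop = min(start + _PAIR_BLOCK, g)
        C[start:stop] = (X[start:stop, None, :] > X[None, :, :]).sum(axis=2)
    return C


def select_candidate_pairs(
    matrix: ExpressionMatrix,
    labels: LabelTable,
    genes: list[str],
    fdr_cutoff: float = 0.01,
) -> list[PairStats]:
    """Screen all unordered pairs of ``genes`` for MSI-enriched REO patterns.

    Each pair is oriented so FD >= 0 (larger-FD orientation; lexicographic
    order on ties), tested one-sided by Fisher's exact test, and BH-adjusted
    across all tested pairs; pairs with q < ``fdr_cutoff`` are returned sorted
    by FD descending (ties: Fisher p ascending, then gene names).
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to form pairs")
    if len(set(genes)) != len(genes):
        raise ValueError("gene list contains duplicates")
    missing = [g for g in genes if g not in matrix.data.index]
    if missing:
        raise KeyError(f"genes not present in expression matrix: {missing}")
    msi, mss = _class_indices(matrix, labels)
    X = matrix.data.loc[genes].to_numpy()
    C1 = _pattern_count_matrix(X[:, msi])
    C2 = _pattern_count_matrix(X[:, mss])
    n1, n2 = len(msi), len(mss)

    iu, ju = np.triu_indices(len(genes), k=1)
    fd_fwd = C1[iu, ju] / n1 - C2[iu, ju] / n2
    fd_rev = C1[ju, iu] / n1 - C2[ju, iu] / n2
    # orient toward the MSI-enriched pattern; lexicographic gene order on ties
    gene_arr = np.asarray(genes)
    lex_fwd = gene_arr[iu] < gene_arr[ju]
    use_fwd = (fd_fwd > fd_rev) | ((fd_fwd == fd_rev) & lex_fwd)
    gi = np.where(use_fwd, iu, ju)
    gj = np.where(use_fwd, ju, iu)
    a = C1[gi, gj]
    c = C2[gi, gj]
    p = stats.hypergeom.sf(a - 1, n1 + n2, a + c, n1)
    q = bh_adjust(p)
    keep = q < fdr_cutoff
    pairs = [
        PairStats(
            gene1=genes[int(gi[k])],
            gene2=genes[int(gj[k])],
            n1_pattern=int(a[k]),
            n1_total=n1,
            n2_pattern=int(c[k]),
            n2_total=n2,
            fisher_p=float(p[k]),
            fisher_q=float(q[k]),
        )
        for k in np.nonzero(keep)[0]
    ]
    pairs.sort(key=lambda ps: (-ps.fd, ps.fisher_p, ps.gene1, ps.gene2))
    return pairs


def remove_redundant_pairs(pairs: list[PairStats]) -> list[PairStats]:
    """Keep each gene in at most one pair, preferring the largest FD.

    Greedy pass over pairs sorted by FD descending (ties: Fisher p ascending,
    then gene names); a pair is kept iff neither gene already occurs in a
    kept pair. Deterministic given the input set.
    """
    ordered = sorted(pairs, key=lambda ps: (-ps.fd, ps.fisher_p, ps.gene1, ps.gene2))
    used: set[str] = set()
    kept: list[PairStats] = []
    for ps in ordered:
        if ps.gene1 in used or ps.gene2 in used:
            continue
        kept.append(ps)
        used.update(ps.genes)
    return kept


def pair_stats_frame(pairs: list[PairStats]) -> pd.DataFrame:
    """Tabular view of pair statistics (one row per oriented pair)."""
    return pd.DataFrame(
        [
            {
                "gene1": ps.gene1,
                "gene2": ps.gene2,
                "n1_pattern": ps.n1_pattern,
                "n1_total": ps.n1_total,
                "n2_pattern": ps.n2_pattern,
                "n2_total": ps.n2_total,
                "p1": ps.p1,
                "p2": ps.p2,
                "fd": ps.fd,
                "fisher_p": ps.fisher_p,
                "fisher_q": ps.fisher_q,
            }
            for ps in pairs
        ],
        columns=[
            "gene1", "gene2", "n1_pattern", "n1_total", "n2_pattern",
            "n2_total", "p1", "p2", "fd", "fisher_p", "fisher_q",
        ],
    )


def write_pair_stats(pairs: list[PairStats], path) -> None:
    pair_stats_frame(pairs).to_csv(path, sep="\t", index=False)
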