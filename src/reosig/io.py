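"""Reading and writing expression matrices, probe maps, label tables and signatures.

Expression values may be on any monotone scale (raw intensity, log2, RSEM):
the classifiers in this package only use within-sample orderings, so no
normalisation is applied on load.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MSI = "MSI"
MSS = "MSS"

# Input status tokens are matched case-insensitively. MSI-L tumors are
# clinically managed like MSS and are grouped with MSS.
_STATUS_SYNONYMS = {
    "MSI": MSI,
    "MSI-H": MSI,
    "MSIH": MSI,
    "MSS": MSS,
    "MSI-L": MSS,
    "MSIL": MSS,
}


class LoadError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample numeric expression matrix.

    Thin wrapper around a pandas DataFrame (index = gene ids, columns =
    sample ids) guaranteeing unique identifiers and no missing values.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise LoadError(f"duplicate gene ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise LoadError(f"duplicate sample ids: {dups}")

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample(self, sample_id: str) -> dict[str, float]:
        """Return one sample's profile as a gene -> value mapping."""
        return self.data[sample_id].to_dict()

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])


@dataclass(frozen=True)
class ProbeMap:
    """Read-only probe -> gene(s) mapping; multi-mapped probes keep all targets."""

    mapping: Mapping[str, frozenset[str]]

    def genes_for(self, probe_id: str) -> frozenset[str]:
        return self.mapping.get(probe_id, frozenset())


@dataclass
class LabelTable:
    """Sample -> MSI/MSS assignment with input-token normalisation."""

    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, status in self.labels.items():
            if status not in (MSI, MSS):
                raise LoadError(
                    f"sample {sid!r}: status must be {MSI!r} or {MSS!r}, got {status!r}"
                )

    @classmethod
    def from_raw(cls, raw: Mapping[str, str]) -> "LabelTable":
        """Build from raw status tokens (MSI-H, msi-l, ...), normalising each."""
        return cls({sid: normalize_status(tok) for sid, tok in raw.items()})

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels)

    def status(self, sample_id: str) -> str:
        return self.labels[sample_id]

    def samples_with(self, status: str) -> list[str]:
        return [s for s, lab in self.labels.items() if lab == status]

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, name="status")

    def check_against(self, matrix: ExpressionMatrix) -> None:
        """Every labeled sample must exist in the companion matrix."""
        missing = [s for s in self.labels if s not in matrix.data.columns]
        if missing:
            raise LoadError(f"labeled samples absent from expression matrix: {missing}")


def normalize_status(token: str) -> str:
    key = token.strip().upper()
    if key not in _STATUS_SYNONYMS:
        raise LoadError(
            f"unknown MSI status token {token!r}; expected one of "
            f"{sorted(set(_STATUS_SYNONYMS))} (case-insensitive)"
        )
    return _STATUS_SYNONYMS[key]


def _infer_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_matrix(
    path: str | Path,
    delimiter: str | None = None,
    genes_in: str = "rows",
) -> ExpressionMatrix:
    """Load a delimited expression file into a genes × samples matrix.

    The first column holds row identifiers and the header row column
    identifiers. ``genes_in`` declares whether genes are in rows (default) or
    columns; the result is always genes × samples. Duplicate gene rows are
    averaged (same rule as probe collapsing); rows containing missing values
    are dropped with a warning.
    """
    if genes_in not in ("rows", "columns"):
        raise ValueError(f"genes_in must be 'rows' or 'columns', got {genes_in!r}")
    path = Path(path)
    if not path.exists():
        raise LoadError(f"expression file not found: {path}")
    sep = _infer_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if raw.shape[0] < 2 or raw.shape[1] < 2:
        raise LoadError(f"malformed header in {path.name}: need ids plus data")
    # build the frame by hand so duplicate header ids are not silently renamed
    df = pd.DataFrame(
        raw.iloc[1:, 1:].to_numpy(),
        index=pd.Index(raw.iloc[1:, 0].astype(str)),
        columns=pd.Index(raw.iloc[0, 1:].astype(str)),
    )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise LoadError(
            f"non-numeric cell in {path.name} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    if genes_in == "columns":
        numeric = numeric.T
    if numeric.columns.has_duplicates:
        dups = numeric.columns[numeric.columns.duplicated()].unique().tolist()
        raise LoadError(f"duplicate sample identifiers in {path.name}: {dups}")
    n_missing = int(numeric.isna().any(axis=1).sum())
    if n_missing:
        dropped = numeric.index[numeric.isna().any(axis=1)].tolist()
        logger.warning(
            "dropping %d gene row(s) with missing values: %s", n_missing, dropped
        )
        numeric = numeric.dropna(axis=0)
    if numeric.index.has_duplicates:
        numeric = numeric.groupby(level=0, sort=False).mean()
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(numeric)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    sep = _infer_delimiter(path, delimiter)
    matrix.data.to_csv(path, sep=sep, index_label="gene_id")


def read_probe_map(path: str | Path, delimiter: str = "\t") -> ProbeMap:
    """Two-column (probe_id, gene_id) file; repeated probe rows accumulate targets."""
    mapping: dict[str, set[str]] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(delimiter)
            if len(parts) != 2:
                raise LoadError(
                    f"{path.name}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            probe, gene = (p.strip() for p in parts)
            mapping.setdefault(probe, set())
            if gene:
                mapping[probe].add(gene)
    return ProbeMap({p: frozenset(g) for p, g in mapping.items()})


def collapse_probes(matrix: ExpressionMatrix, probe_map: ProbeMap) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    Probes mapping to no gene or to multiple genes are discarded; the
    expression of the probes retained for a gene is averaged per sample.
    """
    gene_for_probe: dict[str, str] = {}
    for probe in matrix.gene_ids:
        genes = probe_map.genes_for(probe)
        if len(genes) == 1:
            gene_for_probe[probe] = next(iter(genes))
    if not gene_for_probe:
        raise LoadError("no probe maps uniquely to a gene; collapsed matrix is empty")
    kept = matrix.data.loc[list(gene_for_probe)]
    collapsed = kept.groupby(
        kept.index.map(gene_for_probe.__getitem__), sort=True
    ).mean()
    collapsed.index.name = matrix.data.index.name
    return ExpressionMatrix(collapsed)


def read_labels(path: str | Path, delimiter: str = "\t") -> LabelTable:
    """Two-column (sample_id, status) file, header optional."""
    path = Path(path)
    raw: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split(delimiter)]
            if len(parts) != 2:
                raise LoadError(
                    f"{path.name}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            sid, tok = parts
            if lineno == 1 and tok.upper() not in _STATUS_SYNONYMS:
                continue  # header row
            if sid in raw:
                raise LoadError(f"{path.name}:{lineno}: duplicate sample id {sid!r}")
            raw[sid] = tok
    return LabelTable.from_raw(raw)


def write_labels(labels: LabelTable, path: str | Path, delimiter: str = "\t") -> None:
    with Path(path).open("w") as fh:
        fh.write(f"sample_id{delimiter}status\n")
        for sid, status in labels.labels.items():
            fh.write(f"{sid}{delimiter}{status}\n")
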