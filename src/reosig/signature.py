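"""Gene-pair signatures and the majority-vote MSI classifier.

A signature is an ordered list of oriented gene pairs plus a vote threshold
k: a sample is called MSI when at least k pairs show the MSI-associated
pattern ``E_gene1 > E_gene2`` within that sample. Because only within-sample
orderings enter the rule, the call is invariant to any strictly increasing
transform of a sample's expression values — the property that makes these
signatures robust to batch effects and normalisation choices.

The published 10-pair colon-cancer signature for right-sided tumors
(10-GPS, threshold 7 of 10) ships as a built-in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import math

import pandas as pd

from .evaluation import f_score
from .io import MSI, MSS, ExpressionMatrix, LabelTable
from .reo import PairStats

_10GPS_PAIRS: list[tuple[str, str]] = [
    ("HNRNPL", "CDC16"),
    ("MTA2", "VGF"),
    ("CALR", "SEC22B"),
    ("RASL11A", "CAB39L"),
    ("LYG1", "DHRS12"),
    ("STRN3", "TMEM192"),
    ("HPSE", "BCAS3"),
    ("PRPF39", "ATF6"),
    ("CCRN4L", "GRM8"),
    ("AMFR", "DUSP18"),
]


@dataclass
class Signature:
    """Oriented gene pairs plus the MSI vote threshold k."""

    pairs: list[tuple[str, str]]
    vote_threshold: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pairs = [tuple(p) for p in self.pairs]
        if not self.pairs:
            raise ValueError("signature must contain at least one pair")
        if not 1 <= self.vote_threshold <= len(self.pairs):
            raise ValueError(
                f"vote threshold {self.vote_threshold} outside 1..{len(self.pairs)}"
            )
        genes = [g for pair in self.pairs for g in pair]
        if len(set(genes)) != len(genes):
            raise ValueError("signature genes must be distinct across pairs")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> list[str]:
        return [g for pair in self.pairs for g in pair]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pairs": [list(p) for p in self.pairs],
            "vote_threshold": self.vote_threshold,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Signature":
        payload = json.loads(Path(path).read_text())
        return cls(
            pairs=[tuple(p) for p in payload["pairs"]],
            vote_threshold=int(payload["vote_threshold"]),
            metadata=payload.get("metadata", {}),
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Signature":
        """Two-column (gene1, gene2) TSV with a ``# vote_threshold: k`` header line."""
        pairs: list[tuple[str, str]] = []
        k: int | None = None
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "vote_threshold" in line:
                    k = int(line.split(":", 1)[1])
                continue
            g1, g2 = line.split("\t")
            if (g1, g2) == ("gene1", "gene2"):
                continue
            pairs.append((g1, g2))
        if k is None:
            raise ValueError("signature TSV missing '# vote_threshold: k' header")
        return cls(pairs=pairs, vote_threshold=k)


def builtin_10gps() -> Signature:
    """The published 10-gene-pair MSI signature for right-sided colon cancer."""
    return Signature(
        pairs=list(_10GPS_PAIRS),
        vote_threshold=7,
        metadata={"name": "10-GPS", "target": "right-sided colon cancer"},
    )


def filter_by_fd(pairs: Sequence[PairStats], fd_min: float) -> list[PairStats]:
    """Pairs with FD >= fd_min (inclusive), input order preserved."""
    if not 0 <= fd_min <= 1:
        raise ValueError(f"fd_min must be in [0, 1], got {fd_min}")
    return [ps for ps in pairs if ps.fd >= fd_min]


def count_votes(
    sample_expression: Mapping[str, float],
    signature: Signature,
    missing_policy: str = "error",
) -> tuple[int, int]:
    """MSI votes for one sample: pairs with strict value(gene1) > value(gene2).

    Under ``missing_policy="drop"`` pairs with an absent gene are excluded
    and ``pairs_used`` is reduced accordingly; under ``"error"`` any absent
    gene raises. Ties never vote.
    """
    if missing_policy not in ("error", "drop"):
        raise ValueError(f"missing_policy must be 'error' or 'drop', got {missing_policy!r}")
    absent = [g for g in signature.genes if g not in sample_expression]
    if absent and missing_policy == "error":
        raise KeyError(f"signature genes missing from sample: {absent}")
    votes = 0
    pairs_used = 0
    for g1, g2 in signature.pairs:
        if g1 not in sample_expression or g2 not in sample_expression:
            continue
        pairs_used += 1
        votes += sample_expression[g1] > sample_expression[g2]
    return votes, pairs_used


def effective_threshold(signature: Signature, pairs_used: int) -> int:
    """Vote threshold rescaled when pairs were dropped, preserving the vote
    fraction k/n: ceil(k * pairs_used / n), at least 1."""
    return max(1, math.ceil(signature.vote_threshold * pairs_used / signature.n_pairs))


def classify(
    sample_expression: Mapping[str, float],
    signature: Signature,
    missing_policy: str = "error",
) -> str:
    """MSI/MSS call for one sample by the majority-vote rule."""
    votes, pairs_used = count_votes(sample_expression, signature, missing_policy)
    if pairs_used == 0:
        raise ValueError("no usable signature pairs in sample")
    return MSI if votes >= effective_threshold(signature, pairs_used) else MSS


def classify_matrix(
    matrix: ExpressionMatrix,
    signature: Signature,
    missing_policy: str = "error",
) -> pd.DataFrame:
    """Per-sample votes, usable pairs and predicted status for a whole matrix."""
    rows = []
    for sid in matrix.sample_ids:
        profile = matrix.sample(sid)
        votes, used = count_votes(profile, signature, missing_policy)
        if used == 0:
            raise ValueError(f"no usable signature pairs in sample {sid!r}")
        status = MSI if votes >= effective_threshold(signature, used) else MSS
        rows.append(
            {"sample_id": sid, "votes": votes, "pairs_used": used, "predicted_status": status}
        )
    return pd.DataFrame(rows).set_index("sample_id")


def select_vote_threshold(
    vote_counts: Mapping[str, int],
    labels: LabelTable,
    n_pairs: int,
) -> tuple[int, pd.DataFrame]:
    """Choose the vote threshold k maximising the sensitivity/specificity
    F-score on training votes.

    Evaluates every k in 1..n_pairs with the rule "MSI iff votes >= k" and
    returns the F-maximising k (ties broken toward larger k, the more
    specific classifier) together with the per-k metric table.
    """
    sample_ids = list(vote_counts)
    truths = [labels.status(s) for s in sample_ids]
    n_msi = sum(t == MSI for t in truths)
    n_mss = len(truths) - n_msi
    if n_msi == 0 or n_mss == 0:
        raise ValueError("vote-threshold selection requires both classes")
    rows = []
    for k in range(1, n_pairs + 1):
        tp = sum(vote_counts[s] >= k for s, t in zip(sample_ids, truths) if t == MSI)
        fp = sum(vote_counts[s] >= k for s, t in zip(sample_ids, truths) if t == MSS)
        sens = tp / n_msi
        spec = (n_mss - fp) / n_mss
        rows.append(
            {
                "k": k,
                "tp": tp,
                "fn": n_msi - tp,
                "fp": fp,
                "tn": n_mss - fp,
                "sensitivity": sens,
                "specificity": spec,
                "f_score": f_score(sens, spec),
            }
        )
    table = pd.DataFrame(rows).set_index("k")
    best_f = table["f_score"].max()
    best_k = int(table.index[table["f_score"] == best_f].max())
    return best_k, table
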