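"""Drug feature encoding and drug-drug similarity matrices.

Each drug is described, per modality (chemical substructure keys, targets,
enzymes, pathways), by a finite set of opaque feature tokens.  Tokens are
encoded as binary indicator vectors over a per-modality vocabulary, and the
N x N drug-drug similarity matrix of a modality is the pairwise Jaccard (or
cosine) similarity of those bit vectors.  Similarity rows, not raw bit
vectors, are what the downstream classifier consumes: they compress a sparse
high-dimensional fingerprint into a dense N-vector of relationships to every
other drug in the panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical modality names, in conventional report order.
MODALITIES = ("substructure", "target", "enzyme", "pathway")


@dataclass
class DrugFeatureTable:
    """Ordered drugs with per-(drug, modality) token sets.

    Parameters
    ----------
    drugs
        Ordered, unique drug identifiers.  Row order of every downstream
        matrix follows this list.
    modalities
        Ordered modality names (non-empty).
    tokens
        Mapping ``(drug, modality) -> frozenset of token strings``.  Missing
        entries are treated as empty sets.
    """

    drugs: list[str]
    modalities: list[str]
    tokens: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.drugs)) != len(self.drugs):
            raise ValueError("drug identifiers must be unique")
        if not self.modalities:
            raise ValueError("modality list must be non-empty")

    def token_set(self, drug: str, modality: str) -> frozenset[str]:
        return self.tokens.get((drug, modality), frozenset())

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    def drug_index(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.drugs)}

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "DrugFeatureTable":
        """Build from a long table with columns drug_id, modality, token."""
        required = {"drug_id", "modality", "token"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"feature table missing columns: {sorted(missing)}")
        drugs = list(dict.fromkeys(frame["drug_id"].astype(str)))
        modalities = sorted(set(frame["modality"].astype(str)))
        tokens: dict[tuple[str, str], set[str]] = {}
        for drug, modality, token in frame[["drug_id", "modality", "token"]].itertuples(index=False):
            tokens.setdefault((str(drug), str(modality)), set()).add(str(token))
        frozen = {k: frozenset(v) for k, v in tokens.items()}
        return cls(drugs=drugs, modalities=modalities, tokens=frozen)

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            (drug, modality, token)
            for (drug, modality), toks in sorted(self.tokens.items())
            for token in sorted(toks)
        ]
        return pd.DataFrame(rows, columns=["drug_id", "modality", "token"])


def read_feature_table(path: str | Path) -> DrugFeatureTable:
    """Read a drug-feature file (TSV/CSV; one token per row)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, dtype=str)
    return DrugFeatureTable.from_long_frame(frame)


def write_feature_table(table: DrugFeatureTable, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table.to_long_frame().to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class FeatureVocabulary:
    """Deterministic (lexicographic) token ordering for one modality."""

    modality: str
    tokens: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.tokens)

    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tokens)}


@dataclass
class BitMatrix:
    """N x V binary presence matrix for one modality."""

    drugs: list[str]
    modality: str
    values: np.ndarray  # (N, V) uint8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("bit matrix must be 2-D")
        if self.values.shape[0] != len(self.drugs):
            raise ValueError("row count must match drug count")


@dataclass
class SimilarityMatrix:
    """Symmetric N x N drug-drug similarity in [0, 1] for one modality."""

    drugs: list[str]
    modality: str
    values: np.ndarray  # (N, N) float64
    metric: str = "jaccard"

    def row(self, drug: str) -> np.ndarray:
        return self.values[self.drugs.index(drug)]


def build_vocabulary(table: DrugFeatureTable, modality: str) -> FeatureVocabulary:
    """Sorted union of all token sets observed for ``modality``.

    The vocabulary size is the bit-vector dimension of the modality (e.g.
    808 substructure keys / 1162 targets / 202 enzymes / 957 pathways in the
    public 572-drug reference dataset).
    """
    if modality not in table.modalities:
        raise ValueError(
            f"unknown modality {modality!r}; valid modalities: {sorted(table.modalities)}"
        )
    union: set[str] = set()
    for drug in table.drugs:
        union |= table.token_set(drug, modality)
    return FeatureVocabulary(modality=modality, tokens=tuple(sorted(union)))


def encode_bit_matrix(table: DrugFeatureTable, vocab: FeatureVocabulary) -> BitMatrix:
    """Encode token sets as an N x V {0,1} matrix.

    Tokens absent from the vocabulary are ignored with a logged warning
    (they can occur when a vocabulary from one drug panel is applied to
    another).
    """
    index = vocab.index()
    values = np.zeros((table.n_drugs, vocab.size), dtype=np.uint8)
    unknown = 0
    for i, drug in enumerate(table.drugs):
        for token in table.token_set(drug, vocab.modality):
            j = index.get(token)
            if j is None:
                unknown += 1
            else:
                values[i, j] = 1
    if unknown:
        logger.warning(
            "%d token occurrences not in the %s vocabulary were ignored",
            unknown,
            vocab.modality,
        )
    return BitMatrix(drugs=list(table.drugs), modality=vocab.modality, values=values)


def similarity_matrix(bits: BitMatrix, metric: str = "jaccard") -> SimilarityMatrix:
    """Pairwise drug-drug similarity of bit-vector rows.

    Jaccard: |row_i AND row_k| / |row_i OR row_k|.  Cosine: dot product over
    the product of Euclidean norms.  Pairs in which both rows are all-zero
    share no evidence, so their similarity is defined as 0; this keeps the
    whole matrix inside [0, 1] (0/0 is otherwise undefined).
    """
    if metric not in ("jaccard", "cosine"):
        raise ValueError(f"unknown metric {metric!r}; choose 'jaccard' or 'cosine'")
    x = bits.values.astype(np.float64)
    inter = x @ x.T  # co-occurrence counts (= dot products for 0/1 data)
    if metric == "jaccard":
        sizes = x.sum(axis=1)
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    else:
        norms = np.sqrt(np.diag(inter))
        denom = norms[:, None] * norms[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(denom > 0, inter / np.where(denom > 0, denom, 1.0), 0.0)
    values = np.clip(values, 0.0, 1.0)
    # exact symmetry despite float rounding
    values = (values + values.T) / 2.0
    return SimilarityMatrix(
        drugs=list(bits.drugs), modality=bits.modality, values=values, metric=metric
    )


def encode_all(
    table: DrugFeatureTable,
    modalities: Sequence[str] | None = None,
    metric: str = "jaccard",
) -> dict[str, SimilarityMatrix]:
    """Vocabulary -> bit matrix -> similarity matrix for each modality."""
    chosen = list(modalities) if modalities is not None else list(table.modalities)
    out: dict[str, SimilarityMatrix] = {}
    for modality in chosen:
        vocab = build_vocabulary(table, modality)
        bits = encode_bit_matrix(table, vocab)
        out[modality] = similarity_matrix(bits, metric=metric)
    return out


def write_bit_matrix(bits: BitMatrix, vocab: FeatureVocabulary, path: str | Path) -> None:
    """Round-trippable delimited text: header row = vocabulary tokens."""
    frame = pd.DataFrame(bits.values, index=bits.drugs, columns=list(vocab.tokens))
    frame.to_csv(path, sep="\t", index_label="drug_id")


def read_bit_matrix(path: str | Path, modality: str) -> tuple[BitMatrix, FeatureVocabulary]:
    frame = pd.read_csv(path, sep="\t", index_col="drug_id")
    vocab = FeatureVocabulary(modality=modality, tokens=tuple(frame.columns))
    bits = BitMatrix(
        drugs=[str(d) for d in frame.index],
        modality=modality,
        values=frame.to_numpy(dtype=np.uint8),
    )
    return bits, vocab


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(sim.values, index=sim.drugs, columns=sim.drugs)
    frame.to_csv(path, sep="\t", index_label="drug_id")


def read_similarity_matrix(path: str | Path, modality: str, metric: str = "jaccard") -> SimilarityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="drug_id")
    return SimilarityMatrix(
        drugs=[str(d) for d in frame.index],
        modality=modality,
        values=frame.to_numpy(dtype=np.float64),
        metric=metric,
    )
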