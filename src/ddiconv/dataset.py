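"""Interaction records: loading, deduplication, pair vectors, CV folds.

An interaction record is an unordered drug pair plus the integer class of
the pharmacological event the pair produces (multi-class, not binary
detection).  Raw exports typically list each pair in both orientations, so
deduplication over unordered pairs roughly halves the record count (74,528
raw -> 37,264 unique in the public reference dataset).
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .features import DrugFeatureTable, SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionRecord:
    drug_a: str
    drug_b: str
    event: int

    def unordered_key(self) -> tuple[str, str]:
        return (self.drug_a, self.drug_b) if self.drug_a <= self.drug_b else (self.drug_b, self.drug_a)


def load_interactions(
    path: str | Path,
    feature_table: DrugFeatureTable | None = None,
    n_events: int | None = None,
) -> list[InteractionRecord]:
    """Read delimited interaction rows (drug_a, drug_b, event).

    Rows referencing drugs absent from ``feature_table`` are dropped with a
    logged count; malformed rows or out-of-range event labels raise with the
    offending line number.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, dtype={"drug_a": str, "drug_b": str})
    missing = {"drug_a", "drug_b", "event"} - set(frame.columns)
    if missing:
        raise ValueError(f"interaction file missing columns: {sorted(missing)}")

    records: list[InteractionRecord] = []
    known = set(feature_table.drugs) if feature_table is not None else None
    dropped = 0
    for pos, row in enumerate(frame.itertuples(index=False)):
        line_no = pos + 2  # header is line 1
        try:
            event = int(row.event)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"line {line_no}: event label {row.event!r} is not an integer") from exc
        if event < 0 or (n_events is not None and event >= n_events):
            raise ValueError(f"line {line_no}: event label {event} outside [0, {n_events})")
        a, b = str(row.drug_a), str(row.drug_b)
        if a == b:
            raise ValueError(f"line {line_no}: self-interaction {a!r}")
        if known is not None and (a not in known or b not in known):
            dropped += 1
            continue
        records.append(InteractionRecord(a, b, event))
    if dropped:
        logger.warning("dropped %d interaction rows referencing unknown drugs", dropped)
    return records


def write_interactions(records: Sequence[InteractionRecord], path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.DataFrame(
        [(r.drug_a, r.drug_b, r.event) for r in records],
        columns=["drug_a", "drug_b", "event"],
    )
    frame.to_csv(path, sep=sep, index=False)


def load_interactions_sqlite(
    path: str | Path,
    table: str = "extraction",
    columns: tuple[str, str, str] = ("drugA", "drugB", "mechanism"),
) -> pd.DataFrame:
    """Adapter for SQLite interaction distributions ("event.db"-style).

    Returns the raw long frame with canonical column names; event labels are
    whatever the source stores (often strings) and must be mapped to dense
    integers by the caller before use.
    """
    with sqlite3.connect(str(path)) as conn:
        frame = pd.read_sql_query(f"SELECT * FROM {table}", conn)
    a, b, e = columns
    return frame.rename(columns={a: "drug_a", b: "drug_b", e: "event"})[
        ["drug_a", "drug_b", "event"]
    ]


def deduplicate_pairs(records: Iterable[InteractionRecord]) -> list[InteractionRecord]:
    """One record per unordered pair; the first occurrence wins.

    A later record for the same unordered pair with a different event label
    is logged as a conflict and discarded.
    """
    seen: dict[tuple[str, str], int] = {}
    out: list[InteractionRecord] = []
    conflicts = 0
    for rec in records:
        key = rec.unordered_key()
        if key not in seen:
            seen[key] = rec.event
            out.append(rec)
        elif seen[key] != rec.event:
            conflicts += 1
    if conflicts:
        logger.warning("%d duplicate pairs carried conflicting event labels; kept first", conflicts)
    return out


def pair_vectors(
    records: Sequence[InteractionRecord],
    sim: SimilarityMatrix,
    augment_symmetric: bool = False,
) -> np.ndarray:
    """Per-record input vectors: similarity row of drug_a ++ row of drug_b.

    Each row has length 2N (N = panel size).  With ``augment_symmetric`` the
    (b, a) orientation is appended as an extra row per record, doubling the
    row count; labels must then be duplicated by the caller
    (see :func:`labels`).
    """
    index = {d: i for i, d in enumerate(sim.drugs)}
    rows = []
    for rec in records:
        try:
            ia, ib = index[rec.drug_a], index[rec.drug_b]
        except KeyError as exc:
            raise KeyError(f"drug {exc.args[0]!r} not indexed in similarity matrix") from exc
        rows.append(np.concatenate([sim.values[ia], sim.values[ib]]))
        if augment_symmetric:
            rows.append(np.concatenate([sim.values[ib], sim.values[ia]]))
    n = len(sim.drugs)
    return np.asarray(rows, dtype=np.float64).reshape(-1, 2 * n)


def labels(records: Sequence[InteractionRecord], augment_symmetric: bool = False) -> np.ndarray:
    y = np.array([r.event for r in records], dtype=np.int64)
    return np.repeat(y, 2) if augment_symmetric else y


def stratified_kfold(
    records: Sequence[InteractionRecord] | np.ndarray,
    k: int,
    seed: int = 0,
) -> np.ndarray:
    """Deterministic stratified fold assignment (record -> fold index).

    Per-event proportions are preserved within +-1 record per fold.  Classes
    with fewer than ``k`` members are spread round-robin over folds (with a
    logged warning), starting at a class-dependent offset so small classes
    do not all pile into fold 0.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if isinstance(records, np.ndarray):
        y = np.asarray(records, dtype=np.int64)
    else:
        y = np.array([r.event for r in records], dtype=np.int64)
    n = y.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds record count {n}")
    rng = np.random.default_rng(seed)
    folds = np.full(n, -1, dtype=np.int64)
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        if idx.size < k:
            logger.warning("event %d has %d < k=%d records; distributing round-robin", cls, idx.size, k)
        folds[idx] = (np.arange(idx.size) + offset) % k
        offset += idx.size % k  # rotate start so remainders spread evenly
    return folds


@dataclass
class PairDataset:
    """Deduplicated records plus per-modality pair matrices and fold labels."""

    records: list[InteractionRecord]
    n_events: int
    pair_matrices: dict[str, np.ndarray]  # modality -> (n_records, 2N)
    folds: np.ndarray  # (n_records,)

    def __post_init__(self) -> None:
        n = len(self.records)
        for modality, mat in self.pair_matrices.items():
            if mat.shape[0] != n:
                raise ValueError(f"{modality} pair matrix rows != record count")
        if self.folds.shape[0] != n:
            raise ValueError("fold assignment length != record count")

    @property
    def y(self) -> np.ndarray:
        return np.array([r.event for r in self.records], dtype=np.int64)

    @property
    def modalities(self) -> list[str]:
        return list(self.pair_matrices)

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train indices, test indices) for one held-out fold."""
        test = np.flatnonzero(self.folds == fold)
        train = np.flatnonzero(self.folds != fold)
        return train, test

    def inputs(self, idx: np.ndarray, modalities: Sequence[str] | None = None) -> list[np.ndarray]:
        mods = list(modalities) if modalities is not None else self.modalities
        return [self.pair_matrices[m][idx] for m in mods]


def assemble_dataset(
    records: Sequence[InteractionRecord],
    sims: dict[str, SimilarityMatrix],
    k: int = 5,
    seed: int = 0,
    n_events: int | None = None,
) -> PairDataset:
    """Deduplicate, vectorize against every modality, and assign folds."""
    unique = deduplicate_pairs(records)
    if n_events is None:
        n_events = int(max(r.event for r in unique)) + 1
    mats = {m: pair_vectors(unique, sim) for m, sim in sims.items()}
    folds = stratified_kfold(unique, k=k, seed=seed)
    return PairDataset(records=unique, n_events=n_events, pair_matrices=mats, folds=folds)
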