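"""Synthetic drug panels and interaction tables with planted event rules.

The generator emulates, at desk scale, the statistical shape that makes the
public 572-drug / 65-event benchmark learnable: pharmacological *drug
families*.  Drugs are assigned to equal-size families; each modality carries
its own archetype token set per family, and a drug's token set in a modality
is the archetype of its *modality view* — the drug's family for informative
modalities (with a small outlier rate emulating modality-specific
annotation noise), or an independent grouping for non-informative ones.
Annotation sharing within families mirrors real data, where drugs of one
class list the same targets, enzymes and pathways.

Event labels follow a linear-prototype rule: one prototype weight vector per
event class over the informative modalities' vocabularies, and a pair's true
event is the argmax of the prototype scores on the pair's combined token
counts.  The prototypes are constructed (by a least-norm solve against the
archetype matrix) so that every family has a planted preferred event class
of fixed strength, assigned round-robin over classes; which of the two
drugs' preferred classes wins a given pair is decided by the prototypes'
Gaussian cross-terms.  This keeps the event histogram close to uniform while
the rule stays a genuine argmax of prototype scores on token counts.
Observed labels flip to a uniformly random other class with the configured
noise probability, so the returned oracle labeler scores ~(1 - noise)
against observed labels — the ceiling any model can reach.  Labels depend on
the informative modalities only: a model trained on a non-informative
modality can do no better than chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import InteractionRecord, write_interactions
from .features import MODALITIES, DrugFeatureTable, write_feature_table

logger = logging.getLogger(__name__)


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset.

    ``n_families`` should be a multiple of ``n_events`` so every event class
    is the preferred class of the same number of families (a balanced event
    histogram); ``view_noise`` is the per-drug probability that one
    informative modality mislabels the drug's family.
    """

    n_drugs: int = 120
    vocab_sizes: dict[str, int] = field(
        default_factory=lambda: {"substructure": 160, "target": 240, "enzyme": 40, "pathway": 200}
    )
    token_prob: float = 0.05
    n_events: int = 8
    n_pairs: int = 900
    noise: float = 0.1
    informative: tuple[str, ...] = ("substructure", "target", "pathway")
    n_families: int = 8
    view_noise: float = 0.03
    pref_strength: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 2:
            raise ValueError("n_events must be >= 2")
        if not 0.0 <= self.noise < 1.0:
            raise ValueError("noise must be in [0, 1)")
        if not self.informative:
            raise ValueError("at least one informative modality is required")
        unknown = set(self.informative) - set(self.vocab_sizes)
        if unknown:
            raise ValueError(f"informative modalities without vocabularies: {sorted(unknown)}")
        if self.n_families < 2:
            raise ValueError("need at least 2 families")
        if self.n_families % self.n_events:
            logger.warning(
                "n_families=%d is not a multiple of n_events=%d; the event histogram will be uneven",
                self.n_families,
                self.n_events,
            )

    @property
    def modalities(self) -> list[str]:
        return [m for m in MODALITIES if m in self.vocab_sizes] + sorted(
            set(self.vocab_sizes) - set(MODALITIES)
        )


@dataclass
class OracleLabeler:
    """Closure over the planted prototypes; recovers true (noise-free) labels."""

    drugs: list[str]
    informative_bits: np.ndarray  # (N, sum of informative vocab sizes)
    prototypes: np.ndarray  # (E, same width)

    def label(self, drug_a: str, drug_b: str) -> int:
        ia, ib = self.drugs.index(drug_a), self.drugs.index(drug_b)
        counts = self.informative_bits[ia] + self.informative_bits[ib]
        return int((self.prototypes @ counts).argmax())

    def labels(self, records: Sequence[InteractionRecord]) -> np.ndarray:
        index = {d: i for i, d in enumerate(self.drugs)}
        ia = np.array([index[r.drug_a] for r in records], dtype=np.intp)
        ib = np.array([index[r.drug_b] for r in records], dtype=np.intp)
        counts = self.informative_bits[ia] + self.informative_bits[ib]
        return (counts @ self.prototypes.T).argmax(axis=1)

    def accuracy(self, records: Sequence[InteractionRecord]) -> float:
        """Agreement with observed labels — the ceiling any model can reach."""
        observed = np.array([r.event for r in records])
        return float((self.labels(records) == observed).mean())


def _equal_groups(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Random assignment of n items to k groups of (near-)equal size."""
    return rng.permutation(np.arange(n) % k)


def generate(config: SynthConfig) -> tuple[DrugFeatureTable, list[InteractionRecord], OracleLabeler]:
    """Sample a drug panel, planted-rule interactions, and the oracle.

    Fully reproducible per ``config.seed``.  Raises if ``n_pairs`` exceeds
    the number of distinct unordered pairs.
    """
    capacity = config.n_drugs * (config.n_drugs - 1) // 2
    if config.n_pairs > capacity:
        raise ValueError(f"n_pairs={config.n_pairs} exceeds unordered-pair capacity {capacity}")
    rng = np.random.default_rng(config.seed)
    drugs = [f"D{i:04d}" for i in range(config.n_drugs)]
    families = _equal_groups(rng, config.n_drugs, config.n_families)
    preferred = np.arange(config.n_families) % config.n_events

    bits: dict[str, np.ndarray] = {}
    prototype_blocks: dict[str, np.ndarray] = {}
    tokens: dict[tuple[str, str], frozenset[str]] = {}
    for modality in config.modalities:
        size = config.vocab_sizes[modality]
        archetypes = (rng.random((config.n_families, size)) < config.token_prob).astype(np.float64)
        # least-norm prototype solve needs full row rank; give empty archetypes one token
        for k in np.flatnonzero(archetypes.sum(axis=1) == 0):
            archetypes[k, rng.integers(0, size)] = 1.0
        if modality in config.informative:
            view = families.copy()
            outliers = rng.random(config.n_drugs) < config.view_noise
            view[outliers] = rng.integers(0, config.n_families, int(outliers.sum()))
            # family-level scores: fixed preferred-class strength, Gaussian cross-terms
            scores = rng.standard_normal((config.n_families, config.n_events))
            scores[np.arange(config.n_families), preferred] = config.pref_strength
            prototype_blocks[modality] = np.linalg.pinv(archetypes) @ scores  # (V, E)
        else:
            view = _equal_groups(rng, config.n_drugs, config.n_families)
        mat = archetypes[view].astype(np.uint8)
        bits[modality] = mat
        names = [f"{modality[:3]}_{j:04d}" for j in range(size)]
        for i, drug in enumerate(drugs):
            present = frozenset(names[j] for j in np.flatnonzero(mat[i]))
            if present:
                tokens[(drug, modality)] = present
    table = DrugFeatureTable(drugs=drugs, modalities=config.modalities, tokens=tokens)

    informative = [m for m in config.modalities if m in config.informative]
    inf_bits = np.concatenate([bits[m] for m in informative], axis=1).astype(np.float64)
    prototypes = np.concatenate([prototype_blocks[m] for m in informative], axis=0).T  # (E, V_inf)
    oracle = OracleLabeler(drugs=drugs, informative_bits=inf_bits, prototypes=prototypes)

    iu, ju = np.triu_indices(config.n_drugs, k=1)
    chosen = rng.choice(capacity, size=config.n_pairs, replace=False)
    ia, ib = iu[chosen], ju[chosen]
    counts = inf_bits[ia] + inf_bits[ib]
    true_events = (counts @ prototypes.T).argmax(axis=1)

    flip = rng.random(config.n_pairs) < config.noise
    observed = true_events.copy()
    if flip.any():
        # uniform over the other n_events - 1 classes
        shift = rng.integers(1, config.n_events, size=int(flip.sum()))
        observed[flip] = (true_events[flip] + shift) % config.n_events

    records = [
        InteractionRecord(drugs[a], drugs[b], int(e))
        for a, b, e in zip(ia.tolist(), ib.tolist(), observed.tolist())
    ]
    return table, records, oracle


#: Named desk-scale study conditions.  ``medium`` is the benchmark scale used
#: by the learnability and multimodality experiments: 400 drugs, 20 events,
#: 20 families, 3 informative modalities, 10% label noise, 8000 unique pairs
#: (~10% pair density; the real benchmark's is ~23%).
FIXTURE_SCALES: dict[str, SynthConfig] = {
    "tiny": SynthConfig(
        n_drugs=20,
        vocab_sizes={"substructure": 40, "target": 60, "enzyme": 15, "pathway": 50},
        token_prob=0.12,
        n_events=3,
        n_pairs=100,
        noise=0.0,
        n_families=3,
        view_noise=0.0,
    ),
    "small": SynthConfig(
        n_drugs=120,
        vocab_sizes={"substructure": 160, "target": 240, "enzyme": 40, "pathway": 200},
        token_prob=0.06,
        n_events=8,
        n_pairs=900,
        noise=0.1,
        n_families=8,
        view_noise=0.03,
    ),
    "medium": SynthConfig(
        n_drugs=400,
        vocab_sizes={"substructure": 560, "target": 800, "enzyme": 140, "pathway": 660},
        token_prob=0.05,
        n_events=20,
        n_pairs=8000,
        noise=0.1,
        n_families=20,
        view_noise=0.03,
    ),
}


def make_fixture(
    scale: str,
    out_dir: str | Path,
    seed: int | None = None,
) -> tuple[dict[str, Path], SynthConfig, OracleLabeler]:
    """Write a named-scale dataset to disk in the canonical delimited formats.

    Returns the file paths, the configuration used, and the oracle labeler.
    """
    try:
        config = FIXTURE_SCALES[scale]
    except KeyError:
        raise ValueError(f"unknown scale {scale!r}; choose from {sorted(FIXTURE_SCALES)}") from None
    if seed is not None:
        config = replace(config, seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table, records, oracle = generate(config)
    paths = {
        "features": out_dir / "drug_features.tsv",
        "interactions": out_dir / "interactions.tsv",
    }
    write_feature_table(table, paths["features"])
    write_interactions(records, paths["interactions"])
    logger.info(
        "wrote %s fixture (%d drugs, %d pairs) to %s", scale, config.n_drugs, config.n_pairs, out_dir
    )
    return paths, config, oracle
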