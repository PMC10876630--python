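"""Experiment runners: cross-validation, feature ablation, grid, comparison.

These drive the reporting tables: per-feature-set ablation over all
non-empty modality subsets, the (dense-block count x activation) grid, and
the model-versus-baseline comparison with paired t-tests and one-way ANOVA
across shared CV folds.
"""

from __future__ import annotations

import itertools
import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .baselines import BaselineConfig, build_baseline
from .dataset import PairDataset
from .metrics import ALPHA, METRIC_COLUMNS, EvalReport, anova_oneway, evaluate_fold, paired_t_test
from .model import ModelConfig, MultimodalConvNet, SubmodelSpec, default_config

logger = logging.getLogger(__name__)

#: Desk-scale training protocol: few epochs with a decaying learning rate,
#: no validation split (see docs/methods.md).
DESK_PROTOCOL = dict(epochs=12, batch_size=128, lr_decay=0.85, early_stopping_patience=None)

#: Single-letter feature-set labels in conventional report order.
MODALITY_LETTERS = {"substructure": "S", "target": "T", "enzyme": "E", "pathway": "P"}

#: Fixed ablation row order for the four canonical modalities.
CANONICAL_SUBSET_ORDER = (
    ("S",), ("T",), ("E",), ("P",),
    ("S", "T"), ("S", "E"), ("S", "P"), ("T", "P"), ("T", "E"), ("P", "E"),
    ("S", "P", "E"), ("S", "T", "E"), ("S", "T", "P"), ("T", "P", "E"),
    ("S", "T", "E", "P"),
)


def feature_subsets(modalities: Sequence[str]) -> list[tuple[str, ...]]:
    """Every non-empty subset of the available modalities (2^m - 1 rows).

    When the four canonical modalities are all present the fixed report
    order above is used; otherwise subsets are ordered by size then
    lexicographically.
    """
    modalities = list(modalities)
    if set(modalities) == set(MODALITY_LETTERS):
        by_letter = {v: k for k, v in MODALITY_LETTERS.items()}
        return [tuple(by_letter[l] for l in letters) for letters in CANONICAL_SUBSET_ORDER]
    subsets = []
    for size in range(1, len(modalities) + 1):
        subsets.extend(itertools.combinations(sorted(modalities), size))
    return subsets


def subset_label(subset: Sequence[str]) -> str:
    return " + ".join(MODALITY_LETTERS.get(m, m[:1].upper()) for m in subset)


def cross_validate(
    dataset: PairDataset,
    model_factory: Callable[[], object],
    modalities: Sequence[str] | None = None,
    folds: Sequence[int] | None = None,
    label: str = "model",
    f1_averaging: str = "macro",
    seed: int | None = None,
) -> EvalReport:
    """Train/evaluate one model per held-out fold; returns the per-fold report.

    ``model_factory`` builds a fresh unfitted model exposing
    ``fit(list_of_matrices, y)`` and ``predict_proba(list_of_matrices)`` —
    both the fused conv net and every baseline satisfy this.
    """
    mods = list(modalities) if modalities is not None else dataset.modalities
    fold_ids = list(folds) if folds is not None else sorted(np.unique(dataset.folds).tolist())
    report = EvalReport(model_label=label, feature_label=subset_label(mods), seed=seed)
    y = dataset.y
    for fold in fold_ids:
        train_idx, test_idx = dataset.split(fold)
        model = model_factory()
        model.fit(dataset.inputs(train_idx, mods), y[train_idx])
        proba = model.predict_proba(dataset.inputs(test_idx, mods))
        report.add(evaluate_fold(y[test_idx], proba, dataset.n_events, f1_averaging))
    return report


def conv_model_factory(
    dataset: PairDataset,
    modalities: Sequence[str],
    seed: int = 0,
    **config_overrides,
) -> Callable[[], MultimodalConvNet]:
    """Factory for the fused model on a dataset's geometry."""
    n_drugs = dataset.pair_matrices[list(dataset.modalities)[0]].shape[1] // 2
    def make() -> MultimodalConvNet:
        config = default_config(
            modalities, n_drugs=n_drugs, n_events=dataset.n_events, seed=seed, **config_overrides
        )
        return MultimodalConvNet(config)
    return make


def run_ablation(
    dataset: PairDataset,
    seed: int = 0,
    folds: Sequence[int] | None = None,
    similarity_label: str = "Jaccard",
    **config_overrides,
) -> tuple[pd.DataFrame, list[EvalReport]]:
    """Train/evaluate every non-empty modality subset (15 rows for 4 modalities)."""
    if len(dataset.modalities) < 2:
        raise ValueError("ablation needs at least 2 modalities")
    reports = []
    rows = []
    for subset in feature_subsets(dataset.modalities):
        factory = conv_model_factory(dataset, subset, seed=seed, **config_overrides)
        report = cross_validate(dataset, factory, subset, folds=folds, label=subset_label(subset), seed=seed)
        reports.append(report)
        rows.append({"Set of Features": subset_label(subset), "Similarity Matrices": similarity_label, **report.mean()})
        logger.info("ablation %-14s ACC=%.4f", subset_label(subset), rows[-1]["ACC"])
    return pd.DataFrame(rows), reports


def run_grid(
    dataset: PairDataset,
    layers_grid: Sequence[int] = (2, 3, 4),
    input_activations: Sequence[str] = ("tanh",),
    dense_activations: Sequence[str] = ("tanh", "elu", "relu"),
    seed: int = 0,
    folds: Sequence[int] | None = None,
    similarity_label: str = "Jaccard",
    **config_overrides,
) -> pd.DataFrame:
    """Cross-product over (dense-block count, conv activation, dense activation).

    Dense widths for L blocks follow the halving ladder 1024, 512, 256, 128
    truncated to L entries.
    """
    cells = list(itertools.product(layers_grid, input_activations, dense_activations))
    if not cells:
        raise ValueError("empty hyperparameter grid")
    ladder = (1024, 512, 256, 128)
    rows = []
    for n_layers, i_fun, d_fun in cells:
        if not 1 <= n_layers <= len(ladder):
            raise ValueError(f"dense-block count {n_layers} outside 1..{len(ladder)}")
        overrides = dict(config_overrides)
        overrides["submodel_overrides"] = {
            **config_overrides.get("submodel_overrides", {}),
            "dense_sizes": ladder[:n_layers],
            "conv_activation": i_fun,
            "dense_activation": d_fun,
        }
        factory = conv_model_factory(dataset, dataset.modalities, seed=seed, **overrides)
        report = cross_validate(
            dataset, factory, folds=folds, label=f"{n_layers}/{i_fun}/{d_fun}", seed=seed
        )
        rows.append(
            {
                "Layers": n_layers,
                "I-Fun": i_fun,
                "D-Fun": d_fun,
                "Similarity Matrices": similarity_label,
                **report.mean(),
            }
        )
        logger.info("grid %d/%s/%s ACC=%.4f", n_layers, i_fun, d_fun, rows[-1]["ACC"])
    return pd.DataFrame(rows)


def run_comparison(
    dataset: PairDataset,
    baseline_kinds: Sequence[str] = ("random_forest", "knn", "logistic_regression"),
    seed: int = 0,
    folds: Sequence[int] | None = None,
    alpha: float = ALPHA,
    **config_overrides,
) -> tuple[pd.DataFrame, pd.DataFrame, list[EvalReport]]:
    """Fused model vs baselines on shared folds, with significance tests.

    Returns (metric table, significance table, per-fold reports).  The
    significance table holds, per metric, the paired t-test of the fused
    model against each baseline and the one-way ANOVA across all models.
    """
    factory = conv_model_factory(dataset, dataset.modalities, seed=seed, **config_overrides)
    reports = [cross_validate(dataset, factory, folds=folds, label="fused_conv", seed=seed)]
    lengths = {m: dataset.pair_matrices[m].shape[1] for m in dataset.modalities}
    for kind in baseline_kinds:
        config = BaselineConfig(kind=kind, seed=seed)
        def make(config=config):
            return build_baseline(config, lengths, dataset.n_events)
        reports.append(cross_validate(dataset, make, folds=folds, label=kind, seed=seed))

    table = pd.DataFrame(
        [{"Method": r.model_label, **r.mean()} for r in reports]
    )

    sig_rows = []
    main = reports[0]
    for metric in METRIC_COLUMNS:
        groups = [r.column(metric) for r in reports]
        if all(len(g) >= 2 for g in groups):
            f, p_anova = anova_oneway(*groups)
        else:
            f, p_anova = np.nan, np.nan
        for other in reports[1:]:
            if len(main.rows) >= 2:
                t, p = paired_t_test(main.column(metric), other.column(metric))
            else:
                t, p = np.nan, np.nan
            sig_rows.append(
                {
                    "metric": metric,
                    "comparison": f"fused_conv vs {other.model_label}",
                    "t": t,
                    "p_t": p,
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                    "F_anova": f,
                    "p_anova": p_anova,
                }
            )
    return table, pd.DataFrame(sig_rows), reports
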