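"""Per-drug support-vector regression of IC50 and drug prioritization.

Each drug gets its own epsilon-SVR fit from a selected gene list of one
feature type (or of hybrid features — standardized concatenation of several
types). The regression target is log10 IC50 by default: μM potencies span
several orders of magnitude, and the log transform keeps the epsilon tube
meaningful across that range. Model quality is the Pearson correlation
between pooled out-of-fold predictions and observed values under seeded
k-fold cross-validation. Ranking drugs for a query genomic profile sorts
predicted IC50 ascending (most potent first); the probabilistic drug
calculator instead sums the stored resistant/sensitive alteration
frequencies of the query's genes, which works even when the query covers
only a handful of genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .core_data import (
    AlignedDataset,
    BINARY_TYPES,
    DataError,
    FeatureMatrix,
)
from .feature_selection import FeatureSubset, cfs_select, f_stepping
from .response_stats import BiasResult


class ModelWarning(UserWarning):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """SVR and evaluation settings.

    kernel/C/epsilon follow the common SVR defaults (linear kernel,
    C=1, epsilon=0.1); ``target_transform`` is ``"log10"`` or
    ``"identity"``; ``missing_policy`` at prediction time is ``"error"``
    (strict) or ``"fill"`` (training column mean for continuous genes, 0 for
    binary).
    """

    kernel: str = "linear"
    C: float = 1.0
    epsilon: float = 0.1
    gamma: str | float = "scale"
    target_transform: str = "log10"
    missing_policy: str = "error"
    k_folds: int = 5

    def __post_init__(self) -> None:
        if self.target_transform not in ("log10", "identity"):
            raise ValueError("target_transform must be 'log10' or 'identity'")
        if self.missing_policy not in ("error", "fill"):
            raise ValueError("missing_policy must be 'error' or 'fill'")


DEFAULT_CONFIG = ModelConfig()


@dataclass
class DrugModel:
    """A fitted per-drug regressor plus everything needed to apply it."""

    drug: str
    feature_type: str
    genes: list[str]
    regressor: SVR
    target_transform: str
    train_means: pd.Series
    seed: int
    cv_pcc: float | None = None
    config: ModelConfig = field(default_factory=ModelConfig)

    def transform_target(self, y: np.ndarray) -> np.ndarray:
        return np.log10(y) if self.target_transform == "log10" else y

    def inverse_transform(self, y: np.ndarray) -> np.ndarray:
        return 10.0 ** y if self.target_transform == "log10" else y


@dataclass
class PriorityRanking:
    """Drugs ordered by predicted IC50 (ascending; rank 1 = most potent)."""

    entries: list[tuple[str, float, int]]  # (drug, predicted μM IC50, rank)
    unscored: list[tuple[str, str]] = field(default_factory=list)
    profile_id: str = ""


@dataclass
class CalculatorScore:
    """Per-drug resistant/sensitive alteration frequencies of query genes."""

    drug: str
    per_gene: dict[str, tuple[float, float] | None]  # gene -> (f_res, f_sen)
    sum_res: float
    sum_sen: float


# ---------------------------------------------------------------------------
# Hybrid features
# ---------------------------------------------------------------------------

def build_hybrid(matrices: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Concatenate ≥2 feature types over their shared cell lines.

    Continuous blocks are standardized to zero mean, unit variance (constant
    columns are dropped with a warning); binary blocks stay 0/1. Columns are
    prefixed by feature type ("expression:TP53") so symbols stay unique.
    """
    if len(matrices) < 2:
        raise DataError("hybrid features need at least two matrices")
    shared = set(matrices[0].cell_lines)
    for m in matrices[1:]:
        shared &= set(m.cell_lines)
    if not shared:
        raise DataError("no shared cell lines across the matrices")
    cells = sorted(shared)
    blocks = []
    for m in matrices:
        block = m.values.loc[cells].copy()
        if m.feature_type not in BINARY_TYPES:
            sd = block.std(ddof=0)
            constant = sd.index[sd == 0].tolist()
            if constant:
                warnings.warn(
                    f"dropping zero-variance {m.feature_type} columns: "
                    f"{constant}", ModelWarning, stacklevel=2,
                )
                block = block.drop(columns=constant)
                sd = sd.drop(constant)
            block = (block - block.mean()) / sd
        block.columns = [f"{m.feature_type}:{g}" for g in block.columns]
        blocks.append(block)
    values = pd.concat(blocks, axis=1)
    return FeatureMatrix(
        feature_type="hybrid", values=values,
        scale_note="binary 0/1 + standardized continuous blocks",
    )


# ---------------------------------------------------------------------------
# Training and evaluation
# ---------------------------------------------------------------------------

def _design(
    dataset: AlignedDataset, drug: str, feature_type: str, genes: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    if feature_type not in dataset.matrices:
        raise KeyError(f"no {feature_type!r} matrix in dataset")
    matrix = dataset.matrices[feature_type]
    missing = [g for g in genes if g not in matrix.values.columns]
    if missing:
        raise KeyError(f"genes absent from {feature_type} matrix: {missing}")
    cells = dataset.cells_for(feature_type, drug)
    frame = matrix.values.loc[cells, list(genes)]
    y = dataset.response.ic50.loc[cells, drug].to_numpy(dtype=float)
    return frame.to_numpy(dtype=float), y, frame


def _make_svr(config: ModelConfig) -> SVR:
    return SVR(kernel=config.kernel, C=config.C, epsilon=config.epsilon,
               gamma=config.gamma)


def train_drug_model(
    dataset: AlignedDataset,
    drug: str,
    feature_type: str,
    genes: Sequence[str],
    config: ModelConfig = DEFAULT_CONFIG,
    seed: int = 0,
) -> DrugModel:
    """Fit an epsilon-SVR for one drug on the listed genes.

    Requires ≥10 cell lines with both the feature type and an IC50. The
    target is transformed per ``config.target_transform`` before fitting;
    constant targets and constant gene columns are unlearnable and raise.
    """
    X, y, frame = _design(dataset, drug, feature_type, genes)
    if X.shape[0] < 10:
        raise DataError(
            f"only {X.shape[0]} usable cells for {drug!r}/{feature_type!r}; "
            "need at least 10"
        )
    if np.ptp(y) == 0:
        raise DataError(f"constant IC50 target for {drug!r}")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [g for g, s in zip(genes, sd) if s == 0]
        raise DataError(f"constant gene column(s) for {drug!r}: {bad}")
    model = DrugModel(
        drug=drug, feature_type=feature_type, genes=list(genes),
        regressor=_make_svr(config), target_transform=config.target_transform,
        train_means=frame.mean(), seed=seed, config=config,
    )
    model.regressor.fit(X, model.transform_target(y))
    return model


def cross_validate(
    dataset: AlignedDataset,
    drug: str,
    feature_type: str,
    genes: Sequence[str],
    config: ModelConfig = DEFAULT_CONFIG,
    k_folds: int | None = None,
    seed: int = 0,
) -> float:
    """Pooled out-of-fold Pearson r between predicted and observed IC50.

    Folds are shuffled with the given seed, so the score is reproducible.
    The correlation is computed on the transformed scale the model fits.
    """
    X, y, _ = _design(dataset, drug, feature_type, genes)
    k = k_folds if k_folds is not None else config.k_folds
    if k < 2 or k > X.shape[0]:
        raise DataError(f"k_folds={k} invalid for {X.shape[0]} cells")
    t = np.log10(y) if config.target_transform == "log10" else y
    preds = np.empty_like(t)
    for train_idx, test_idx in KFold(
        n_splits=k, shuffle=True, random_state=seed
    ).split(X):
        svr = _make_svr(config)
        svr.fit(X[train_idx], t[train_idx])
        preds[test_idx] = svr.predict(X[test_idx])
    return float(stats.pearsonr(preds, t).statistic)


def cv_evaluator(
    dataset: AlignedDataset,
    drug: str,
    feature_type: str,
    config: ModelConfig = DEFAULT_CONFIG,
    seed: int = 0,
):
    """Evaluator closure for F-stepping: gene list → seeded CV Pearson r."""
    def evaluate(genes: list[str]) -> float:
        try:
            return cross_validate(
                dataset, drug, feature_type, genes, config=config, seed=seed
            )
        except DataError:
            return -np.inf
    return evaluate


def select_and_train(
    dataset: AlignedDataset,
    drug: str,
    feature_type: str,
    config: ModelConfig = DEFAULT_CONFIG,
    seed: int = 0,
    run_f_stepping: bool = True,
) -> tuple[DrugModel, FeatureSubset]:
    """Full pipeline for one drug: CFS → (optional) F-stepping → SVR.

    Returns the fitted model (with ``cv_pcc`` set from seeded k-fold CV) and
    the selected subset with its decision history.
    """
    matrix = dataset.matrices[feature_type]
    cells = dataset.cells_for(feature_type, drug)
    sub_matrix = FeatureMatrix(
        feature_type=feature_type, values=matrix.values.loc[cells],
        scale_note=matrix.scale_note,
    )
    y_uM = dataset.response.ic50.loc[cells, drug]
    target = np.log10(y_uM) if config.target_transform == "log10" else y_uM
    subset = cfs_select(sub_matrix, target)
    if not subset.genes:
        raise DataError(f"CFS selected no genes for {drug!r}/{feature_type!r}")
    if run_f_stepping and len(subset.genes) > 1:
        subset = f_stepping(
            subset, sub_matrix, target,
            evaluator=cv_evaluator(dataset, drug, feature_type, config, seed),
        )
    model = train_drug_model(
        dataset, drug, feature_type, subset.genes, config=config, seed=seed
    )
    model.cv_pcc = cross_validate(
        dataset, drug, feature_type, subset.genes, config=config, seed=seed
    )
    return model, subset


# ---------------------------------------------------------------------------
# Prediction, prioritization, calculator
# ---------------------------------------------------------------------------

def predict_ic50(model: DrugModel, profile: Mapping[str, float]) -> float:
    """Predict IC50 (μM) for a query genomic profile.

    The profile must supply every model gene; with
    ``missing_policy="fill"`` absent continuous genes default to the
    training-set mean and absent binary genes to 0.
    """
    missing = [g for g in model.genes if g not in profile]
    if missing:
        if model.config.missing_policy == "error":
            raise KeyError(f"profile missing required genes: {missing}")
        binary = model.feature_type in BINARY_TYPES
        filled = {g: (0.0 if binary else float(model.train_means[g]))
                  for g in missing}
    else:
        filled = {}
    x = np.array([[float(profile.get(g, filled.get(g))) for g in model.genes]])
    pred = model.inverse_transform(model.regressor.predict(x))
    return float(pred[0])


def prioritize(
    models: Sequence[DrugModel],
    profile: Mapping[str, float],
    profile_id: str = "query",
) -> PriorityRanking:
    """Rank drugs for a profile by ascending predicted IC50.

    Drugs whose models cannot score the profile are returned in
    ``unscored`` with the reason, never silently dropped. Ties share the
    predicted value and break by drug name.
    """
    if not models:
        raise DataError("empty model bundle")
    scored: list[tuple[str, float]] = []
    unscored: list[tuple[str, str]] = []
    for model in models:
        try:
            scored.append((model.drug, predict_ic50(model, profile)))
        except (KeyError, DataError) as exc:
            unscored.append((model.drug, str(exc)))
    scored.sort(key=lambda t: (t[1], t[0]))
    entries = [(drug, pred, rank) for rank, (drug, pred) in
               enumerate(scored, start=1)]
    return PriorityRanking(entries=entries, unscored=unscored,
                           profile_id=profile_id)


def drug_calculator(
    query_genes: Sequence[str],
    bias_tables: Mapping[str, Mapping[str, BiasResult] | Sequence[BiasResult]],
) -> list[CalculatorScore]:
    """Probabilistic per-gene contribution scores for each drug.

    For every drug, look up each query gene's resistant/sensitive alteration
    fractions in the precomputed bias table (built at the 0.5 μM threshold)
    and sum them; genes absent from a drug's table contribute null entries
    and nothing to the sums.
    """
    out = []
    for drug in sorted(bias_tables):
        table = bias_tables[drug]
        lookup: Mapping[str, BiasResult]
        if isinstance(table, Mapping):
            lookup = table
        else:
            lookup = {r.gene: r for r in table}
        per_gene: dict[str, tuple[float, float] | None] = {}
        sum_res = sum_sen = 0.0
        for gene in query_genes:
            r = lookup.get(gene)
            if r is None:
                per_gene[gene] = None
            else:
                per_gene[gene] = (r.f_res, r.f_sen)
                sum_res += r.f_res
                sum_sen += r.f_sen
        out.append(CalculatorScore(drug=drug, per_gene=per_gene,
                                   sum_res=sum_res, sum_sen=sum_sen))
    return out


# ---------------------------------------------------------------------------
# Text serialization (audit-able model bundles)
# ---------------------------------------------------------------------------

def write_model(model: DrugModel, path) -> None:
    """Serialize a fitted linear-kernel model as a plain-text bundle.

    Records drug, feature type, transform, gene list, per-gene weights and
    the intercept, so predictions are auditable without binary formats.
    Only linear kernels have an explicit weight vector to export.
    """
    if model.config.kernel != "linear":
        raise DataError("text export supports linear-kernel models only")
    coef = model.regressor.coef_.ravel()
    lines = [
        f"#drug\t{model.drug}",
        f"#feature_type\t{model.feature_type}",
        f"#target_transform\t{model.target_transform}",
        f"#intercept\t{float(model.regressor.intercept_[0])!r}",
        f"#cv_pcc\t{'' if model.cv_pcc is None else repr(float(model.cv_pcc))}",
        f"#seed\t{model.seed}",
        "gene\tweight\ttrain_mean",
    ]
    for g, w in zip(model.genes, coef):
        lines.append(f"{g}\t{float(w)!r}\t{float(model.train_means[g])!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
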