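"""Composite pathogenicity models.

Per-variant effect scores from several component models are assembled
into a feature matrix (optionally alongside extra numeric features such
as a conservation score), missing cells — variants a component could
not score — are mean-imputed from the training data, and a logistic
regression head combines the columns into a single pathogenicity score.
Evaluation follows the field's convention: stratified k-fold
cross-validated auROC, plus incremental prefix evaluation showing what
each added component contributes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .models import LinearModel
from .variant_effects import EffectScoreRecord, Variant


@dataclass
class EnsembleModel:
    component_names: list[str]
    imputation_values: np.ndarray
    head: LinearModel
    l2: float = 1.0

    def predict(self, X: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64).copy()
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            for j in range(X.shape[1]):
                X[mask[:, j], j] = self.imputation_values[j]
        return self.head.predict(X)


# ---------------------------------------------------------------------------
# feature assembly


def _collapse_scores(records: list[EffectScoreRecord], scoring: str) -> dict[tuple, float]:
    """Per variant key, keep the score of largest magnitude (sign kept)
    across regions/outputs; unscored records yield no entry."""
    best: dict[tuple, float] = {}
    for rec in records:
        if not rec.scored or scoring not in rec.scores:
            continue
        val = rec.scores[scoring]
        cur = best.get(rec.variant.key)
        if cur is None or abs(val) > abs(cur):
            best[rec.variant.key] = val
    return best


def assemble_feature_matrix(
    score_tables: list[list[EffectScoreRecord]],
    variants: list[Variant],
    extra_features: dict[str, dict[tuple, float]] | None = None,
    scoring: str = "DIFF",
) -> tuple[np.ndarray, np.ndarray]:
    """Build the (n_variants, n_components [+ extras]) design matrix.

    Cells a component did not score hold 0.0 as a placeholder and are
    flagged in the returned binary ``missing_mask``; imputation happens
    at fit time from training data only.
    """
    n = len(variants)
    columns = [_collapse_scores(tbl, scoring) for tbl in score_tables]
    extra_items = list((extra_features or {}).items())
    K = len(columns) + len(extra_items)
    X = np.zeros((n, K), dtype=np.float64)
    mask = np.zeros((n, K), dtype=bool)
    for i, v in enumerate(variants):
        for j, col in enumerate(columns):
            if v.key in col:
                X[i, j] = col[v.key]
            else:
                mask[i, j] = True
        for j, (_, feat) in enumerate(extra_items, start=len(columns)):
            if v.key in feat:
                X[i, j] = feat[v.key]
            else:
                mask[i, j] = True
    return X, mask


# ---------------------------------------------------------------------------
# fitting and evaluation


def _impute(X: np.ndarray, mask: np.ndarray, means: np.ndarray) -> np.ndarray:
    X = X.copy()
    for j in range(X.shape[1]):
        X[mask[:, j], j] = means[j]
    return X


def _column_means(X: np.ndarray, mask: np.ndarray, names=None) -> np.ndarray:
    means = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        obs = ~mask[:, j]
        if not obs.any():
            name = names[j] if names else f"column {j}"
            raise ValueError(f"feature {name!r} has no observed values to impute from")
        means[j] = X[obs, j].mean()
    return means


def fit_logistic_ensemble(
    X: np.ndarray,
    mask: np.ndarray,
    labels: np.ndarray,
    l2: float = 1.0,
    seed: int = 0,
    component_names: list[str] | None = None,
) -> EnsembleModel:
    """Mean-impute masked cells and fit the L2-penalised logistic head."""
    from .models import fit_head_on_activations

    X = np.asarray(X, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    labels = np.asarray(labels).ravel()
    if component_names is None:
        component_names = [f"component{j + 1}" for j in range(X.shape[1])]
    means = _column_means(X, mask, component_names)
    head = fit_head_on_activations(_impute(X, mask, means), labels, l2=l2, seed=seed)
    return EnsembleModel(
        component_names=list(component_names),
        imputation_values=means,
        head=head,
        l2=l2,
    )


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann–Whitney statistic with
    average ranks for ties."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auROC requires both classes")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _make_folds(labels: np.ndarray, k: int, seed: int):
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros_like(labels), labels))
    for train_idx, test_idx in folds:
        if np.unique(labels[train_idx]).size < 2 or np.unique(labels[test_idx]).size < 2:
            raise ValueError(
                "a fold contains a single class after stratification; use a smaller k"
            )
    return folds


def cross_validated_auroc(
    X: np.ndarray,
    mask: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    seed: int = 0,
    l2: float = 1.0,
) -> tuple[list[float], float]:
    """Stratified k-fold CV; imputation means are computed on each
    training fold only so no test information leaks into the fit."""
    X = np.asarray(X, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    labels = np.asarray(labels).ravel()
    folds = _make_folds(labels, k, seed)
    per_fold: list[float] = []
    for train_idx, test_idx in folds:
        model = fit_logistic_ensemble(
            X[train_idx], mask[train_idx], labels[train_idx], l2=l2, seed=seed
        )
        scores = model.predict(X[test_idx], mask[test_idx])
        per_fold.append(auroc(scores, labels[test_idx]))
    return per_fold, float(np.mean(per_fold))


def incremental_component_eval(
    component_names: list[str],
    X: np.ndarray,
    mask: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    seed: int = 0,
    l2: float = 1.0,
) -> list[float]:
    """Mean CV auROC for each prefix of the component list (components
    added one at a time, in order), reusing the same folds throughout."""
    X = np.asarray(X, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    labels = np.asarray(labels).ravel()
    folds = _make_folds(labels, k, seed)
    out: list[float] = []
    for m in range(1, len(component_names) + 1):
        Xm, Mm = X[:, :m], mask[:, :m]
        per_fold = []
        for train_idx, test_idx in folds:
            model = fit_logistic_ensemble(
                Xm[train_idx], Mm[train_idx], labels[train_idx], l2=l2, seed=seed,
                component_names=component_names[:m],
            )
            per_fold.append(auroc(model.predict(Xm[test_idx], Mm[test_idx]), labels[test_idx]))
        out.append(float(np.mean(per_fold)))
    return out


def fraction_unscored(
    score_tables: list[list[EffectScoreRecord]], variants: list[Variant]
) -> list[float]:
    """Per component, the fraction of variants with no score (either
    flagged unscored or absent from the table entirely)."""
    fracs = []
    for tbl in score_tables:
        scored_keys = {r.variant.key for r in tbl if r.scored}
        n_unscored = sum(1 for v in variants if v.key not in scored_keys)
        fracs.append(n_unscored / len(variants) if variants else 0.0)
    return fracs


# ---------------------------------------------------------------------------
# TSV IO for score tables and labels


def write_score_table(records: list[EffectScoreRecord], path: str | os.PathLike,
                      scoring: str = "DIFF") -> None:
    rows = []
    for r in records:
        rows.append({
            "chrom": r.variant.chrom, "pos": r.variant.pos,
            "ref": r.variant.ref, "alt": r.variant.alt,
            "score": r.scores.get(scoring, np.nan) if r.scored else np.nan,
            "scored": int(r.scored),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_score_table(path: str | os.PathLike, model_name: str = "",
                     scoring: str = "DIFF") -> list[EffectScoreRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        v = Variant(str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        if int(row["scored"]):
            records.append(EffectScoreRecord(
                v, model_name, scores={scoring: float(row["score"])}, scored=True))
        else:
            records.append(EffectScoreRecord(v, model_name, scored=False))
    return records


def read_label_table(path: str | os.PathLike) -> tuple[list[Variant], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    variants = [
        Variant(str(r["chrom"]), int(r["pos"]), str(r["ref"]), str(r["alt"]))
        for _, r in df.iterrows()
    ]
    return variants, df["label"].to_numpy(dtype=int)
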