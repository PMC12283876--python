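"""Early identification of subgroup members from first-visit data only.

Longitudinal follow-up is expensive and often unavailable, so membership in
the behaviorally defined subgroups is predicted from a man's *first* visit:
demographics plus the behaviors recorded that day. Because subgroups are
nested (a subgroup may contain sub-subgroups), one binary member/non-member
random forest is trained per subgroup rather than a single multiclass model.
Accuracy is estimated by stratified k-fold cross-validation under a fixed
seed; impurity-decrease feature importances are averaged over folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ClassifierConfig",
    "prepare_first_visit_table",
    "train_subgroup_classifiers",
    "feature_importances",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierConfig:
    n_folds: int = 5
    n_trees: int = 500
    seed: int = 0
    class_weight: str | None = None  # e.g. "balanced"
    max_depth: int | None = None


def prepare_first_visit_table(
    table: pd.DataFrame, min_valid: int = 2000, id_col: str = "man_id"
) -> pd.DataFrame:
    """Complete-case first-visit feature matrix.

    Accepts either a one-row-per-man table or a raw visit table (reduced to
    the earliest visit per man when ``visit_date`` is present). Features with
    fewer than ``min_valid`` valid records are dropped, then men with any
    missing retained feature are dropped; categorical features are one-hot
    encoded with levels in sorted order. Returns a frame indexed by man id.
    """
    df = table.copy()
    if "visit_date" in df.columns:
        df = (
            df.sort_values([id_col, "visit_date"], kind="mergesort")
            .groupby(id_col, sort=True)
            .first()
            .reset_index()
        )
        df = df.drop(columns=["visit_date"])
    df = df.drop(columns=[c for c in ("hiv_diagnosis_date",) if c in df.columns])
    df = df.set_index(id_col)

    keep = [c for c in df.columns if df[c].notna().sum() >= min_valid]
    dropped = sorted(set(df.columns) - set(keep))
    if dropped:
        log.info("dropping %d features below %d valid records: %s",
                 len(dropped), min_valid, dropped)
    if not keep:
        raise ValueError(
            f"no feature has >= {min_valid} valid first-visit records"
        )
    df = df[keep].dropna(axis=0, how="any")

    cat = [c for c in df.columns if df[c].dtype == object]
    if cat:
        df = pd.get_dummies(df, columns=cat, dtype=float)
    df = df[sorted(df.columns)]
    return df.astype(float)


def _subgroup_seed(seed: int, index: int) -> int:
    return (seed * 1_000_003 + 7919 * index + 1) % (2**31 - 1)


def train_subgroup_classifiers(
    features: pd.DataFrame,
    membership: dict[str, list[str]] | pd.DataFrame,
    config: ClassifierConfig | None = None,
) -> dict:
    """Cross-validated one-vs-rest random forests, one per subgroup.

    ``membership`` maps subgroup label -> member man-ids (or a boolean frame
    indexed by man id). Subgroups with fewer than ``2 * n_folds`` members (or
    non-members) are skipped with a warning. The report is a plain dict,
    JSON-serializable and byte-reproducible under a fixed seed.
    """
    config = config or ClassifierConfig()
    if isinstance(membership, pd.DataFrame):
        membership = {
            c: list(membership.index[membership[c].astype(bool)])
            for c in membership.columns
        }
    X = features.to_numpy(dtype=float)
    report: dict = {
        "config": {
            "n_folds": config.n_folds,
            "n_trees": config.n_trees,
            "seed": config.seed,
            "class_weight": config.class_weight,
            "max_depth": config.max_depth,
        },
        "features": list(features.columns),
        "subgroups": {},
    }
    for s_idx, (label, members) in enumerate(sorted(membership.items())):
        y = features.index.isin(members).astype(int)
        n_pos, n_neg = int(y.sum()), int((1 - y).sum())
        if min(n_pos, n_neg) < 2 * config.n_folds:
            log.warning(
                "subgroup %s skipped: %d members / %d non-members "
                "(need >= %d each)", label, n_pos, n_neg, 2 * config.n_folds,
            )
            report["subgroups"][label] = {
                "skipped": True, "n_members": n_pos, "n_non_members": n_neg}
            continue
        sub_seed = _subgroup_seed(config.seed, s_idx)
        skf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=sub_seed
        )
        fold_acc: list[float] = []
        importances = np.zeros(X.shape[1])
        conf = np.zeros((2, 2), dtype=int)
        correct = 0
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            clf = RandomForestClassifier(
                n_estimators=config.n_trees,
                random_state=sub_seed + fold,
                class_weight=config.class_weight,
                max_depth=config.max_depth,
                n_jobs=1,
            )
            clf.fit(X[tr], y[tr])
            pred = clf.predict(X[te])
            fold_acc.append(float((pred == y[te]).mean()))
            correct += int((pred == y[te]).sum())
            for t, p in zip(y[te], pred):
                conf[t, p] += 1
            importances += clf.feature_importances_
        importances /= config.n_folds
        total = importances.sum()
        if total > 0:
            importances = importances / total
        ranked = sorted(
            zip(features.columns, importances), key=lambda kv: (-kv[1], kv[0])
        )
        report["subgroups"][label] = {
            "skipped": False,
            "n_members": n_pos,
            "n_non_members": n_neg,
            "majority_rate": max(n_pos, n_neg) / (n_pos + n_neg),
            "fold_accuracy": fold_acc,
            "accuracy": correct / len(y),
            "confusion": {
                "tn": int(conf[0, 0]), "fp": int(conf[0, 1]),
                "fn": int(conf[1, 0]), "tp": int(conf[1, 1]),
            },
            "importances": [[f, float(w)] for f, w in ranked],
        }
    return report


def feature_importances(report: dict, subgroup: str) -> list[tuple[str, float]]:
    """Ranked (feature, normalized importance) pairs for one subgroup."""
    try:
        entry = report["subgroups"][subgroup]
    except KeyError:
        raise KeyError(f"unknown subgroup {subgroup!r}") from None
    if entry.get("skipped"):
        raise ValueError(f"subgroup {subgroup!r} was skipped during training")
    return [(f, w) for f, w in entry["importances"]]
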