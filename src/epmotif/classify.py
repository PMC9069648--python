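"""Motif-pair feature encoding and L1-penalized EP-pair classification.

Each EP pair is described by a 4n+1 vector: for each of the n motif pairs,
the occurrence counts of the enhancer-side motif in the enhancer and in the
promoter, and of the promoter-side motif in each region, plus the class
label. An L1-penalized logistic classifier ("lasso") is evaluated under
stratified 10-fold cross-validation, reporting precision, recall and F1 for
the positive class and the motif pairs with nonzero coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.metrics import precision_recall_fscore_support

from .motifs import MotifOccurrence
from .pair_discovery import MotifPair

logger = logging.getLogger(__name__)

N_FOLDS = 10
DEFAULT_PENALTY_GRID = (0.01, 0.1, 1.0, 10.0)


@dataclass
class FeatureMatrix:
    """Per-EP-pair motif-pair occurrence counts plus labels.

    ``X`` has 4 columns per motif pair in deterministic (name-sorted)
    order; ``columns`` encodes ``motifpair/member/region``.
    """

    X: np.ndarray
    y: np.ndarray  # 1 = positive, 0 = negative
    columns: list[str]
    row_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns, index=self.row_ids)
        df["label"] = self.y
        return df


@dataclass
class CVReport:
    """Cross-validation outcome: per-fold and mean positive-class metrics."""

    fold_precision: list[float]
    fold_recall: list[float]
    fold_f1: list[float]
    mean_precision: float
    mean_recall: float
    mean_f1: float
    selected_pairs: list[str]
    n_selected: int
    seed: int
    C: float  # inverse regularization strength of the final refit
    n_folds: int = N_FOLDS
    extras: dict = field(default_factory=dict)


def _count_hits(occs: Sequence[MotifOccurrence], motif: str) -> int:
    # raw counts, both strands
    return sum(1 for o in occs if o.motif_name == motif)


def build_features(
    ep_items: Sequence[tuple[str, str, str, int]],
    motif_pairs: Sequence[MotifPair],
    occurrences: Mapping[str, Sequence[MotifOccurrence]],
) -> FeatureMatrix:
    """Build the 4n+1 feature matrix.

    ``ep_items`` rows are ``(ep_id, enh_seq_id, prom_seq_id, label)``; the
    sequence IDs must key into ``occurrences`` (scanner output on the exact
    sequences of the pairs). Column order is deterministic: motif pairs
    sorted by (motif_E, motif_P) name.
    """
    pairs = sorted(motif_pairs, key=lambda p: (p.motif_E, p.motif_P))
    motifs_needed = {p.motif_E for p in pairs} | {p.motif_P for p in pairs}
    scanned = {o.motif_name for occs in occurrences.values() for o in occs}
    # a motif may legitimately have zero hits overall only if it was scanned;
    # we cannot distinguish that from "never scanned", so only fail when no
    # occurrence of the motif exists anywhere and the caller gave a registry
    missing = motifs_needed - scanned
    if missing and not occurrences:
        raise ValueError(f"motif pairs reference unscanned motifs: {sorted(missing)}")

    columns = []
    for p in pairs:
        tag = f"{p.motif_E}|{p.motif_P}"
        columns += [
            f"{tag}/E-motif/enh", f"{tag}/E-motif/prom",
            f"{tag}/P-motif/enh", f"{tag}/P-motif/prom",
        ]
    X = np.zeros((len(ep_items), 4 * len(pairs)), dtype=np.int64)
    y = np.zeros(len(ep_items), dtype=np.int64)
    row_ids = []
    for r, (ep_id, enh_id, prom_id, label) in enumerate(ep_items):
        if enh_id not in occurrences or prom_id not in occurrences:
            raise KeyError(f"EP item {ep_id} has unscanned sequences")
        enh_occ, prom_occ = occurrences[enh_id], occurrences[prom_id]
        for c, p in enumerate(pairs):
            X[r, 4 * c + 0] = _count_hits(enh_occ, p.motif_E)
            X[r, 4 * c + 1] = _count_hits(prom_occ, p.motif_E)
            X[r, 4 * c + 2] = _count_hits(enh_occ, p.motif_P)
            X[r, 4 * c + 3] = _count_hits(prom_occ, p.motif_P)
        y[r] = int(label)
        row_ids.append(ep_id)
    return FeatureMatrix(X, y, columns, row_ids)


def cross_validate(
    features: FeatureMatrix,
    penalty_grid: Sequence[float] = DEFAULT_PENALTY_GRID,
    seed: int = 0,
    n_folds: int = N_FOLDS,
    standardize: bool = False,
) -> CVReport:
    """Stratified k-fold CV of an L1 logistic classifier.

    The inverse-regularization strength C is chosen by an inner grid search
    on each training split; metrics are for the positive class. The
    selected motif pairs come from a final refit on all data.
    """
    X, y = features.X.astype(float), features.y
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd

    def make_model() -> GridSearchCV:
        base = LogisticRegression(l1_ratio=1.0, solver="liblinear", max_iter=2000)
        inner = StratifiedKFold(3, shuffle=True, random_state=seed)
        return GridSearchCV(base, {"C": list(penalty_grid)}, cv=inner, scoring="f1")

    outer = StratifiedKFold(n_folds, shuffle=True, random_state=seed)
    prec, rec, f1 = [], [], []
    for train, test in outer.split(X, y):
        model = make_model()
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        p, r, f, _ = precision_recall_fscore_support(
            y[test], pred, average="binary", pos_label=1, zero_division=0
        )
        prec.append(float(p))
        rec.append(float(r))
        f1.append(float(f))

    final = make_model().fit(X, y)
    coefs = final.best_estimator_.coef_.ravel()
    selected = sorted(
        {features.columns[i].split("/")[0] for i in np.nonzero(coefs)[0]}
    )
    return CVReport(
        prec, rec, f1,
        float(np.mean(prec)), float(np.mean(rec)), float(np.mean(f1)),
        selected, len(selected), seed, float(final.best_params_["C"]), n_folds,
    )


def cross_condition_eval(
    motif_pairs_from_a: Sequence[MotifPair],
    ep_items_b: Sequence[tuple[str, str, str, int]],
    occurrences_b: Mapping[str, Sequence[MotifOccurrence]],
    penalty_grid: Sequence[float] = DEFAULT_PENALTY_GRID,
    seed: int = 0,
) -> CVReport:
    """Evaluate condition A's motif pairs on condition B's EP pairs.

    Features are built from A's discovered pairs over B's scanned
    sequences, then cross-validated on B. With A = B this reduces to
    ``cross_validate``.
    """
    if not motif_pairs_from_a:
        raise ValueError("no motif pairs from the source condition")
    scanned_b = {o.motif_name for occs in occurrences_b.values() for o in occs}
    shared = {p.motif_E for p in motif_pairs_from_a} | {
        p.motif_P for p in motif_pairs_from_a
    }
    if not (shared & scanned_b):
        raise ValueError("no shared motifs between conditions")
    feats = build_features(ep_items_b, motif_pairs_from_a, occurrences_b)
    report = cross_validate(feats, penalty_grid, seed)
    report.extras["transfer"] = True
    return report
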