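"""Evaluation harnesses: link-prediction MAP with subject-aware
cross-validation, group classification from connectivity / hierarchy
features, and per-subnetwork radius summaries.

Cross-validation folds are formed over *subjects*, never sessions, so
both recordings of a participant always land in the same fold and the
validation sets stay uncontaminated.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .connectivity import ConnectivityMatrix
from .models import (EmbeddingResult, HgcnConfig, shallow_poincare_fit,
                     train_model)

__all__ = [
    "SUBNETWORK_ORDER", "SubnetworkMap", "make_folds",
    "mean_average_precision", "link_prediction_experiment",
    "subnetwork_radii", "build_features", "classify",
]

SUBNETWORK_ORDER = ("pDMN", "aDMN", "DAN", "FPN", "VN", "VAN", "SN", "SMN")


class SubnetworkMap:
    """ROI label -> functional subnetwork assignment.

    The bundled default is an approximate AAL-90 assignment with
    subnetwork sizes 10/6/6/10/10/14/10/2 (pDMN, aDMN, DAN, FPN, VN, VAN,
    SN, SMN) and the remaining 22 ROIs unassigned; it is an editable TSV
    meant to be replaced when an exact table is available.
    """

    def __init__(self, mapping: dict[str, str]):
        bad = {v for v in mapping.values()} - set(SUBNETWORK_ORDER) - {"unassigned"}
        if bad:
            raise ValueError(f"unknown subnetwork labels: {sorted(bad)}")
        self.mapping = dict(mapping)
        self.roi_names = list(mapping)

    @classmethod
    def from_tsv(cls, path) -> "SubnetworkMap":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    @classmethod
    def default(cls, n_rois: int = 90) -> "SubnetworkMap":
        ref = (importlib.resources.files("hyperbrain")
               / "data" / "subnetworks_aal90.tsv")
        with importlib.resources.as_file(ref) as path:
            sm = cls.from_tsv(path)
        if n_rois == 90:
            return sm
        # smaller node sets (tests, scaled-down fixtures): truncate
        return cls({roi: sm.mapping[roi] for roi in sm.roi_names[:n_rois]})

    def subnetwork_of(self, roi: str) -> str:
        return self.mapping.get(roi, "unassigned")

    def rois_in(self, subnetwork: str) -> list[str]:
        return [r for r, s in self.mapping.items() if s == subnetwork]

    def sizes(self) -> dict[str, int]:
        return {s: len(self.rois_in(s)) for s in SUBNETWORK_ORDER}


# ---------------------------------------------------------------------------
# folds and MAP
# ---------------------------------------------------------------------------

def make_folds(records, k: int = 5, seed: int = 0) -> dict[str, int]:
    """Partition *subjects* into k near-equal folds (sessions follow their
    subject).  Deterministic given the seed."""
    subjects = sorted({r.subject_id for r in records})
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds the {len(subjects)} subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    folds = {}
    for pos, idx in enumerate(order):
        folds[subjects[idx]] = pos % k
    return folds


def _average_precision(scores_row, truth_row, self_idx):
    candidates = [j for j in range(len(scores_row)) if j != self_idx]
    true_set = {j for j in candidates if truth_row[j]}
    if not true_set:
        return None
    # descending score, deterministic tie-break by node index
    ranked = sorted(candidates, key=lambda j: (-scores_row[j], j))
    hits = 0
    ap = 0.0
    for rank, j in enumerate(ranked, start=1):
        if j in true_set:
            hits += 1
            ap += hits / rank
    return ap / len(true_set)


def mean_average_precision(scores: np.ndarray, truth: np.ndarray) -> float:
    """Mean over nodes of the average precision of each node's true
    neighbors in its score-ranked candidate list (all other nodes)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    n = truth.shape[0]
    if scores.shape != (n, n) or truth.shape != (n, n):
        raise ValueError("scores and truth must be square and equal shape")
    aps = [_average_precision(scores[i], truth[i], i) for i in range(n)]
    aps = [a for a in aps if a is not None]
    if not aps:
        raise ValueError("no node has a true neighbor; MAP undefined")
    return float(np.mean(aps))


def link_prediction_experiment(graphs: dict, records, models=("hgcn", "gcn"),
                               dims=(2, 3), k: int = 5, seed: int = 0,
                               base_config: HgcnConfig | None = None,
                               shallow_epochs: int = 300) -> pd.DataFrame:
    """MAP table for each model and output dimension D.

    For the inductive models (``hgcn``, ``hgcn_fixed``, ``gcn``) a model is
    trained per fold on the training subjects' graphs and each held-out
    graph's full adjacency is scored; the shallow ``poincare`` baseline is
    transductive and fitted directly on every held-out graph.  MAP values
    are averaged over held-out graphs pooled across folds.
    """
    base = base_config or HgcnConfig()
    folds = make_folds(records, k=k, seed=seed)
    keyed = [(r.subject_id, r.session) for r in records]
    table = pd.DataFrame(index=list(models), columns=list(dims), dtype=float)
    for model_name in models:
        for D in dims:
            maps = []
            for fold in range(k):
                train_keys = [key for r, key in zip(records, keyed)
                              if folds[r.subject_id] != fold]
                val_keys = [key for r, key in zip(records, keyed)
                            if folds[r.subject_id] == fold]
                if not val_keys:
                    continue
                if model_name == "poincare":
                    for key in val_keys:
                        g = graphs[key]
                        emb = shallow_poincare_fit(g, dim=D, seed=seed,
                                                   epochs=shallow_epochs)
                        scores = _shallow_scores(emb)
                        maps.append(mean_average_precision(scores, g.adjacency))
                    continue
                cfg = replace(base, output_dim=D, seed=seed,
                              model="gcn" if model_name == "gcn" else "hgcn",
                              curvature_mode=("fixed" if model_name == "hgcn_fixed"
                                              else base.curvature_mode))
                model = train_model([graphs[key] for key in train_keys], cfg)
                for key in val_keys:
                    g = graphs[key]
                    maps.append(mean_average_precision(
                        model.decode_probabilities(g), g.adjacency))
            table.loc[model_name, D] = float(np.mean(maps))
    return table


def _shallow_scores(emb: EmbeddingResult) -> np.ndarray:
    from . import geometry as geo
    X = emb.coords
    d = geo.dist_arcosh(X[:, None, :], X[None, :, :], 1.0)
    return 1.0 / (np.exp(d ** 2 - 2.0) + 1.0)


# ---------------------------------------------------------------------------
# hierarchy features and classification
# ---------------------------------------------------------------------------

def subnetwork_radii(embedding: EmbeddingResult, subnet_map: SubnetworkMap
                     ) -> np.ndarray:
    """Mean node radius per subnetwork, in the fixed order
    pDMN, aDMN, DAN, FPN, VN, VAN, SN, SMN.  Unassigned ROIs are excluded;
    an empty subnetwork yields NaN with a warning."""
    by_name = dict(zip(embedding.roi_names, embedding.radii))
    out = np.empty(len(SUBNETWORK_ORDER))
    for i, net in enumerate(SUBNETWORK_ORDER):
        rois = [r for r in subnet_map.rois_in(net) if r in by_name]
        if not rois:
            warnings.warn(f"subnetwork {net} has no embedded ROIs", RuntimeWarning)
            out[i] = np.nan
        else:
            out[i] = float(np.mean([by_name[r] for r in rois]))
    return out


def build_features(records, conns: dict, embeddings: dict,
                   subnet_map: SubnetworkMap, kind: str = "combined"):
    """Per-subject feature matrix from pre-intervention sessions only.

    kind='plv': strict lower triangle of the PLV matrix, row-major
    (4005 values for 90 ROIs); 'radius': the 8 subnetwork mean radii;
    'combined': their concatenation (4013 values).

    Returns (X, y, subject_ids) with y the group labels.
    """
    if kind not in ("plv", "radius", "combined"):
        raise ValueError("kind must be 'plv', 'radius' or 'combined'")
    rows, labels, sids = [], [], []
    seen = set()
    for r in records:
        if r.session != "pre" or r.subject_id in seen:
            continue
        seen.add(r.subject_id)
        key = (r.subject_id, "pre")
        feats = []
        if kind in ("plv", "combined"):
            if key not in conns:
                warnings.warn(f"missing pre-session PLV for {r.subject_id}; skipped",
                              RuntimeWarning)
                continue
            conn = conns[key]
            vals = conn.values if isinstance(conn, ConnectivityMatrix) else np.asarray(conn)
            il, jl = np.tril_indices(vals.shape[0], -1)   # row-major strict lower triangle
            feats.append(vals[il, jl])
        if kind in ("radius", "combined"):
            if key not in embeddings:
                warnings.warn(f"missing pre-session embedding for {r.subject_id}; "
                              "skipped", RuntimeWarning)
                continue
            feats.append(subnetwork_radii(embeddings[key], subnet_map))
        rows.append(np.concatenate(feats))
        labels.append(r.group)
        sids.append(r.subject_id)
    return np.vstack(rows), np.asarray(labels), sids


def classify(features: np.ndarray, labels, seed: int = 0, gamma: float = 0.1,
             C: float = 10.0, k: int = 5) -> dict:
    """Stratified k-fold RBF-kernel SVM; Macro F1 and AUC-ROC from pooled
    out-of-fold predictions/decision scores."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes are required")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty(y.shape, dtype=y.dtype)
    scores = np.empty(y.shape[0])
    per_fold = []
    for tr, te in skf.split(X, y):
        clf = SVC(kernel="rbf", gamma=gamma, C=C)
        clf.fit(X[tr], y[tr])
        y_pred[te] = clf.predict(X[te])
        dec = clf.decision_function(X[te])
        # decision_function is oriented toward clf.classes_[1]
        scores[te] = dec if clf.classes_[1] == classes[1] else -dec
        per_fold.append(float(f1_score(y[te], y_pred[te], average="macro")))
    return {
        "macro_f1": float(f1_score(y, y_pred, average="macro")),
        "auc_roc": float(roc_auc_score(y == classes[1], scores)),
        "per_fold_macro_f1": per_fold,
    }
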