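"""High-level orchestration used by the examples, the CLI and the
acceptance script: cohort-level thresholding, encoder training on a
balanced subject subset, and per-subject subnetwork radius extraction.
"""

from __future__ import annotations

import numpy as np

from .connectivity import DEFAULT_THRESHOLD, threshold_to_graph
from .evaluation import SubnetworkMap, subnetwork_radii
from .models import HgcnConfig, train_model

__all__ = ["threshold_cohort", "train_cohort_encoder",
           "cohort_radius_features"]


def threshold_cohort(conns: dict, threshold: float = DEFAULT_THRESHOLD) -> dict:
    """Threshold every connectivity matrix of a cohort store."""
    return {key: threshold_to_graph(c, threshold) for key, c in conns.items()}


def train_cohort_encoder(records, graphs: dict, config: HgcnConfig | None = None,
                         n_train_per_group: int = 2, session: str = "pre"):
    """Train one inductive encoder on a small balanced subject subset.

    The first ``n_train_per_group`` subjects of each group contribute
    their ``session`` graph; every other graph is embedded purely by
    inference.  Returns the trained model.
    """
    config = config or HgcnConfig()
    train_keys, counts = [], {}
    for r in records:
        if r.session != session:
            continue
        if counts.get(r.group, 0) < n_train_per_group:
            counts[r.group] = counts.get(r.group, 0) + 1
            train_keys.append((r.subject_id, r.session))
    return train_model([graphs[k] for k in train_keys], config)


def cohort_radius_features(records, graphs: dict, model,
                           subnet_map: SubnetworkMap | None = None,
                           session: str = "pre"):
    """Per-subject subnetwork mean radii from one session.

    Returns ``(X, y, subject_ids)`` with X of shape [n_subjects x 8]
    in the fixed subnetwork order.
    """
    subnet_map = subnet_map or SubnetworkMap.default()
    X, y, sids = [], [], []
    seen = set()
    for r in records:
        if r.session != session or r.subject_id in seen:
            continue
        seen.add(r.subject_id)
        emb = model.embed(graphs[(r.subject_id, session)])
        X.append(subnetwork_radii(emb, subnet_map))
        y.append(r.group)
        sids.append(r.subject_id)
    return np.vstack(X), np.asarray(y), sids
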