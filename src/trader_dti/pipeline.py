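"""Dataset construction and the train/predict workflow for interaction
prediction.

Each known drug-target pair becomes a labeled row of eight pair descriptors
derived from the two similarity matrices and the interaction table.  The
default feature map for a pair (d, t):

1-3. max, second-max and mean drug similarity of d to the drugs already
     known to interact with t;
4-6. max, second-max and mean target similarity of t to the targets already
     known to interact with d;
7.   interaction degree of d (excluding t), normalized by the target count;
8.   interaction degree of t (excluding d), normalized by the drug count.

The pair under construction is never its own evidence (leave-self-out), so
features carry no label leakage; empty evidence sets contribute zeros.  The
feature builder is a pluggable callable so alternative descriptor sets can
be swapped in without touching training.

Training wraps the Trader optimizer around the network's RMSE objective;
prediction scores every non-interacting candidate pair and emits the pairs
the model calls positive, ranked by score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ann import MLPSpec, forward_batch, rmse_objective
from .similarity import SimilarityMatrix
from .trader import TraderConfig, run

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionTable",
    "build_features",
    "feature_columns",
    "build_dataset",
    "sample_negatives",
    "enumerate_candidates",
    "TrainedModel",
    "train_anntr",
    "predict_new",
    "DEFAULT_TRAINING",
]

#: default optimizer configuration for network training
DEFAULT_TRAINING = TraderConfig(
    population_size=40,
    num_traders=4,
    max_iterations=300,
    bounds=(-10.0, 10.0),
    seed=0,
)


@dataclass
class InteractionTable:
    """Deduplicated known-positive pairs with per-drug / per-target indices."""

    pairs: frozenset
    by_drug: dict
    by_target: dict

    @classmethod
    def from_pairs(cls, pairs) -> "InteractionTable":
        seen = set()
        by_drug: dict = {}
        by_target: dict = {}
        for d, t in pairs:
            d, t = str(d), str(t)
            if (d, t) in seen:
                continue
            seen.add((d, t))
            by_drug.setdefault(d, set()).add(t)
            by_target.setdefault(t, set()).add(d)
        return cls(frozenset(seen), by_drug, by_target)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "InteractionTable":
        return cls.from_pairs(zip(df["drug_id"], df["target_id"]))

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.pairs), columns=["drug_id", "target_id"])


def _evidence_stats(sims: list[float]) -> tuple[float, float, float]:
    """(max, second-max, mean); empty slots are 0 by convention."""
    if not sims:
        return 0.0, 0.0, 0.0
    s = sorted(sims, reverse=True)
    second = s[1] if len(s) > 1 else 0.0
    return float(s[0]), float(second), float(np.mean(s))


def build_features(
    d: str,
    t: str,
    drug_sim: SimilarityMatrix,
    target_sim: SimilarityMatrix,
    known: InteractionTable,
) -> np.ndarray:
    """Eight pair descriptors for (d, t); the pair itself is excluded from
    every evidence set."""
    if d not in drug_sim:
        raise KeyError(f"unknown drug id {d!r}")
    if t not in target_sim:
        raise KeyError(f"unknown target id {t!r}")
    ev_drugs = [d2 for d2 in known.by_target.get(t, ()) if d2 != d]
    ev_targets = [t2 for t2 in known.by_drug.get(d, ()) if t2 != t]
    dmax, dsecond, dmean = _evidence_stats([drug_sim.loc(d, d2) for d2 in ev_drugs])
    tmax, tsecond, tmean = _evidence_stats([target_sim.loc(t, t2) for t2 in ev_targets])
    deg_d = len(ev_targets) / len(target_sim.ids)
    deg_t = len(ev_drugs) / len(drug_sim.ids)
    return np.array([dmax, dsecond, dmean, tmax, tsecond, tmean, deg_d, deg_t])


def feature_columns(df: pd.DataFrame) -> list[str]:
    """The feature columns of a dataset frame (named f1, f2, ...)."""
    return [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]


def sample_negatives(
    known: InteractionTable,
    drug_ids,
    target_ids,
    n: int,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Sample ``n`` non-interacting pairs uniformly without replacement."""
    pool = [
        (str(d), str(t))
        for d in drug_ids
        for t in target_ids
        if (str(d), str(t)) not in known.pairs
    ]
    if n > len(pool):
        raise ValueError(f"cannot sample {n} negatives from {len(pool)} candidates")
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in idx]


def build_dataset(
    drug_sim: SimilarityMatrix,
    target_sim: SimilarityMatrix,
    known: InteractionTable,
    split: float = 0.8,
    seed: int = 0,
    negative_ratio: float = 0.0,
    feature_builder=build_features,
) -> pd.DataFrame:
    """Featureize the known positives (one row per pair, label 1) into a
    dataset with a seeded train/test split.

    ``negative_ratio > 0`` additionally samples that ratio of non-interacting
    pairs as label-0 rows (1.0 gives balanced classes for two-class
    evaluation; the default 0 yields the positives-only dataset).
    """
    if len(known) == 0:
        raise ValueError("interaction table is empty")
    if not 0.0 < split <= 1.0:
        raise ValueError("split fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = [(d, t, 1) for d, t in sorted(known.pairs)]
    if negative_ratio > 0:
        n_neg = int(round(negative_ratio * len(rows)))
        rows += [
            (d, t, 0)
            for d, t in sample_negatives(known, drug_sim.ids, target_sim.ids, n_neg, rng)
        ]
    records = []
    for d, t, label in rows:
        feats = feature_builder(d, t, drug_sim, target_sim, known)
        records.append((d, t, *feats, label))
    n_feat = len(records[0]) - 3
    cols = ["drug_id", "target_id", *[f"f{i + 1}" for i in range(n_feat)], "label"]
    df = pd.DataFrame(records, columns=cols)
    n_train = int(round(split * len(df)))
    order = rng.permutation(len(df))
    tag = np.empty(len(df), dtype=object)
    tag[order[:n_train]] = "train"
    tag[order[n_train:]] = "test"
    df["split"] = tag
    return df


def enumerate_candidates(drug_ids, target_ids, known: InteractionTable):
    """Yield every (drug, target) pair absent from the known set."""
    if not len(drug_ids) or not len(target_ids):
        raise ValueError("drug and target id lists must be non-empty")
    for d in drug_ids:
        for t in target_ids:
            pair = (str(d), str(t))
            if pair not in known.pairs:
                yield pair


@dataclass
class TrainedModel:
    """A trained predictor: architecture, flat weights, final training RMSE,
    and the optimizer's convergence history."""

    spec: MLPSpec
    weights: np.ndarray
    rmse: float
    history: np.ndarray
    trader_config: TraderConfig

    def scores(self, features: np.ndarray) -> np.ndarray:
        return forward_batch(self.spec, self.weights, features)


def train_anntr(
    dataset: pd.DataFrame,
    spec: MLPSpec | None = None,
    trader_cfg: TraderConfig | None = None,
) -> TrainedModel:
    """Train the network on a dataset frame by minimizing RMSE with Trader.

    All rows of ``dataset`` are used; slice the train split first if the
    frame carries one.  The optimizer's bounds come from its config.
    """
    spec = spec or MLPSpec()
    cfg = trader_cfg or DEFAULT_TRAINING
    cols = feature_columns(dataset)
    if len(cols) != spec.layer_sizes[0]:
        raise ValueError(
            f"dataset has {len(cols)} features but the network expects "
            f"{spec.layer_sizes[0]} inputs"
        )
    X = dataset[cols].to_numpy(dtype=float)
    y = dataset["label"].to_numpy(dtype=float)
    objective = rmse_objective(spec, X, y, bounds=cfg.bounds)
    best, history = run(cfg, objective)
    return TrainedModel(spec, best.variables, best.objective_value, history, cfg)


def predict_new(
    model: TrainedModel,
    candidates,
    drug_sim: SimilarityMatrix,
    target_sim: SimilarityMatrix,
    known: InteractionTable,
    feature_builder=build_features,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Score candidate pairs and return the predicted interactions
    (label 1), sorted by score descending with a stable id tie-break.
    ``keep_all`` retains the negative calls too."""
    records = []
    for d, t in candidates:
        feats = feature_builder(d, t, drug_sim, target_sim, known)
        score = float(model.scores(feats[None, :])[0])
        records.append((d, t, score, 1 if score >= model.spec.threshold else 0))
    df = pd.DataFrame(records, columns=["drug_id", "target_id", "score", "label"])
    if not keep_all:
        df = df[df["label"] == 1]
    df = df.sort_values(
        ["score", "drug_id", "target_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return df
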