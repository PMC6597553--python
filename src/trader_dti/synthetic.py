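"""Seeded generators for fingerprints, sequences and interactions.

The generator plants a block (cluster) structure: drugs and targets are
partitioned into latent co-interaction blocks, each block owns a prototype
fingerprint and a prototype amino-acid sequence, members are noisy copies of
their block prototype, and interactions are Bernoulli with a high
within-block and low cross-block probability.  This emulates the structure
the real pipeline assumes — pharmacologically similar drugs tending to share
targets with mutually homologous sequences — so every stage is testable
without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pipeline import InteractionTable
from .similarity import FingerprintTable

__all__ = ["SyntheticWorldConfig", "World", "generate_world", "make_fixture", "FIXTURES"]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Defaults give the standard study world: 60 drugs and 40 targets in 3
    blocks, 200 binary molecular properties with skewed column frequencies,
    9 in 10 within-block pairs interacting versus 1 in 20 across blocks."""

    n_drugs: int = 60
    n_targets: int = 40
    n_properties: int = 200
    n_blocks: int = 3
    within_block_prob: float = 0.9
    cross_block_prob: float = 0.05
    fingerprint_noise: float = 0.05
    seq_length_range: tuple[int, int] = (60, 100)
    mutation_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("need at least one block")
        if min(self.n_drugs, self.n_targets) < self.n_blocks:
            raise ValueError("every block needs at least one drug and one target")
        for p in (
            self.within_block_prob,
            self.cross_block_prob,
            self.fingerprint_noise,
            self.mutation_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.within_block_prob <= self.cross_block_prob:
            raise ValueError(
                "within_block_prob must exceed cross_block_prob (planted signal)"
            )
        lo, hi = self.seq_length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid sequence length range")


@dataclass
class World:
    fingerprints: FingerprintTable
    sequences: dict
    interactions: InteractionTable
    drug_blocks: dict
    target_blocks: dict
    config: SyntheticWorldConfig


def _blocks(ids, n_blocks) -> dict:
    return {
        i: b for b, chunk in enumerate(np.array_split(np.asarray(ids), n_blocks))
        for i in chunk
    }


def generate_world(cfg: SyntheticWorldConfig) -> World:
    """Generate a complete seeded world (deterministic given the config)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    drug_ids = [f"D{i + 1:03d}" for i in range(cfg.n_drugs)]
    target_ids = [f"T{i + 1:03d}" for i in range(cfg.n_targets)]
    drug_blocks = _blocks(drug_ids, cfg.n_blocks)
    target_blocks = _blocks(target_ids, cfg.n_blocks)

    # column base rates drawn once -> frequency-skewed properties
    col_rates = rng.beta(1.0, 4.0, cfg.n_properties)
    proto_fp = rng.random((cfg.n_blocks, cfg.n_properties)) < col_rates
    fp = np.empty((cfg.n_drugs, cfg.n_properties))
    for i, d in enumerate(drug_ids):
        flips = rng.random(cfg.n_properties) < cfg.fingerprint_noise
        fp[i] = np.where(flips, ~proto_fp[drug_blocks[d]], proto_fp[drug_blocks[d]])
    fingerprints = FingerprintTable(drug_ids, fp)

    lo, hi = cfg.seq_length_range
    proto_seq = [
        rng.choice(_AA, size=int(rng.integers(lo, hi + 1))) for _ in range(cfg.n_blocks)
    ]
    sequences = {}
    for t in target_ids:
        seq = proto_seq[target_blocks[t]].copy()
        mutate = rng.random(seq.size) < cfg.mutation_rate
        seq[mutate] = rng.choice(_AA, size=int(mutate.sum()))
        sequences[t] = "".join(seq)

    pairs = []
    for d in drug_ids:
        for t in target_ids:
            p = (
                cfg.within_block_prob
                if drug_blocks[d] == target_blocks[t]
                else cfg.cross_block_prob
            )
            if rng.random() < p:
                pairs.append((d, t))
    if not pairs:
        raise ValueError("generated world has no interactions; raise the probabilities")
    return World(
        fingerprints,
        sequences,
        InteractionTable.from_pairs(pairs),
        drug_blocks,
        target_blocks,
        cfg,
    )


def _xor_fixture() -> pd.DataFrame:
    """The four-row XOR truth table as a two-feature dataset frame."""
    rows = [
        ("x00", "y00", 0.0, 0.0, 0),
        ("x01", "y01", 0.0, 1.0, 1),
        ("x10", "y10", 1.0, 0.0, 1),
        ("x11", "y11", 1.0, 1.0, 0),
    ]
    df = pd.DataFrame(rows, columns=["drug_id", "target_id", "f1", "f2", "label"])
    df["split"] = "train"
    return df


# hand-enumerable micro world: 4 drugs x 3 targets over 6 binary properties
_TINY_FP = np.array(
    [
        [1, 1, 0, 0, 1, 0],  # dA
        [1, 1, 0, 0, 0, 0],  # dB
        [0, 0, 1, 1, 0, 0],  # dC
        [0, 0, 1, 0, 0, 1],  # dD
    ],
    dtype=float,
)
_TINY_SEQS = {
    "tX": "MKVLAAGDTE",
    "tY": "MKVLAAGDSE",
    "tZ": "WWPCHHRRQN",
}
_TINY_PAIRS = [("dA", "tX"), ("dB", "tX"), ("dA", "tY"), ("dC", "tZ"), ("dD", "tZ")]


def _tiny4x3_fixture() -> World:
    cfg = SyntheticWorldConfig(
        n_drugs=4, n_targets=3, n_properties=6, n_blocks=2, seed=0
    )
    return World(
        FingerprintTable(["dA", "dB", "dC", "dD"], _TINY_FP.copy()),
        dict(_TINY_SEQS),
        InteractionTable.from_pairs(_TINY_PAIRS),
        {"dA": 0, "dB": 0, "dC": 1, "dD": 1},
        {"tX": 0, "tY": 0, "tZ": 1},
        cfg,
    )


FIXTURES = {"xor": _xor_fixture, "tiny4x3": _tiny4x3_fixture}


def make_fixture(name: str):
    """Return a tiny deterministic canned dataset/world by name."""
    try:
        return FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; registered: {sorted(FIXTURES)}"
        ) from None
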