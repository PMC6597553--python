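"""Similarity kernels feeding the interaction-prediction pipeline.

Drug-drug similarity is a weighted cosine over pharmacological fingerprint
vectors, ``SIM(D, D') = sum(W F F') / (sqrt(sum(W F^2)) sqrt(sum(W F'^2)))``,
where each feature weight decays with how common the feature is across the
drug panel: ``W_i = exp(-d_i^2 / (sigma^2 h^2))`` with ``d_i`` the nonzero
count of column i, ``sigma`` the population standard deviation of all the
``d_k``, and ``h = 0.1``.  At that ``h`` the kernel concentrates almost all
weight on the rarest features.

Target-target similarity is the normalized Smith-Waterman score
``SW(a, b) / sqrt(SW(a, a) * SW(b, b))`` of two amino-acid sequences,
computed with Biopython's local pairwise aligner (BLOSUM62 with gap
open 10 / extend 0.5 by default; a simple match/mismatch scheme is available
for hand-checkable tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

__all__ = [
    "FingerprintTable",
    "WeightVector",
    "SimilarityMatrix",
    "compute_weights",
    "drug_similarity",
    "drug_similarity_matrix",
    "SWScheme",
    "blosum62_scheme",
    "simple_scheme",
    "sw_normalized",
    "build_similarity_matrix",
    "target_similarity_matrix",
]


@dataclass
class FingerprintTable:
    """Drugs x molecular-property matrix of non-negative feature values."""

    drug_ids: list
    matrix: np.ndarray
    property_names: list | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.drug_ids):
            raise ValueError("matrix must be (n_drugs, n_properties)")
        if np.any(self.matrix < 0):
            raise ValueError("fingerprint values must be non-negative")
        if self.property_names is None:
            self.property_names = [f"p{j}" for j in range(self.matrix.shape[1])]

    def column_frequencies(self) -> np.ndarray:
        """d_i: number of drugs with a nonzero value in column i."""
        return np.count_nonzero(self.matrix, axis=0).astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.drug_ids, columns=self.property_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FingerprintTable":
        return cls(list(df.index), df.to_numpy(dtype=float), list(df.columns))


@dataclass
class WeightVector:
    """Per-feature weights with the statistics they were derived from.

    ``log_weights`` carries ``-d_i^2 / (sigma^2 h^2)`` exactly; at small h
    the exponentials underflow for all but the rarest features, so the
    cosine kernel works in log space (the cosine is invariant to a constant
    rescaling of the weights, so this changes nothing mathematically).
    """

    weights: np.ndarray
    sigma: float
    h: float
    log_weights: np.ndarray | None = None

    def __post_init__(self):
        if self.log_weights is None:
            with np.errstate(divide="ignore"):
                self.log_weights = np.log(np.asarray(self.weights, dtype=float))


def compute_weights(freqs, h: float = 0.1) -> WeightVector:
    """Feature weights ``W_i = exp(-d_i^2 / (sigma^2 h^2))``.

    ``sigma`` is the population standard deviation of the frequency vector.
    If every frequency is equal (``sigma == 0``) the formula degenerates and
    all weights are set to 1 with a warning.
    """
    d = np.asarray(freqs, dtype=float)
    if np.any(d < 0):
        raise ValueError("frequencies must be non-negative")
    sigma = float(np.std(d))
    if sigma == 0.0:
        logger.warning(
            "all feature frequencies equal (sigma = 0); weight formula is "
            "degenerate, using unit weights"
        )
        return WeightVector(np.ones_like(d), sigma, h, np.zeros_like(d))
    lw = -(d**2) / (sigma**2 * h**2)
    with np.errstate(under="ignore"):
        w = np.exp(lw)
    return WeightVector(w, sigma, h, lw)


def drug_similarity(F, F_prime, W: WeightVector | np.ndarray, names=("first", "second")) -> float:
    """Weighted cosine similarity of two fingerprint vectors, in [0, 1] for
    non-negative inputs and exactly 1 for identical vectors.

    Evaluated in log-weight space: each vector's terms are rescaled by the
    largest weight on its support before exponentiation, which cancels in
    the cosine ratio but keeps the sums representable at small ``h``.
    """
    F = np.asarray(F, dtype=float)
    Fp = np.asarray(F_prime, dtype=float)
    if isinstance(W, WeightVector):
        lw = np.asarray(W.log_weights, dtype=float)
    else:
        with np.errstate(divide="ignore"):
            lw = np.log(np.asarray(W, dtype=float))
    if F.shape != Fp.shape or F.shape != lw.shape:
        raise ValueError("fingerprints and weights must have equal lengths")
    if np.array_equal(F, Fp):
        return 1.0
    sup_a = (F != 0) & (lw > -np.inf)
    sup_b = (Fp != 0) & (lw > -np.inf)
    if not sup_a.any() or not sup_b.any():
        bad = names[0] if not sup_a.any() else names[1]
        raise ValueError(f"drug {bad!r} has zero weighted norm; similarity undefined")
    ma = float(lw[sup_a].max())
    mb = float(lw[sup_b].max())
    with np.errstate(under="ignore"):
        na = float(np.sqrt(np.sum(np.exp(lw - ma) * F * F)))
        nb = float(np.sqrt(np.sum(np.exp(lw - mb) * Fp * Fp)))
        num = float(np.sum(np.exp(lw - 0.5 * (ma + mb)) * F * Fp))
    return num / (na * nb)


@dataclass
class SimilarityMatrix:
    """Square, symmetric, identifier-indexed similarity matrix."""

    ids: list
    values: np.ndarray

    def __post_init__(self):
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match the identifier list")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix is not symmetric to 1e-9")
        self._index = {x: i for i, x in enumerate(self.ids)}
        if len(self._index) != n:
            raise ValueError("duplicate identifiers")

    def loc(self, a, b) -> float:
        try:
            return float(self.values[self._index[a], self._index[b]])
        except KeyError as err:
            raise KeyError(f"unknown identifier {err.args[0]!r}") from None

    def __contains__(self, item) -> bool:
        return item in self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SimilarityMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("similarity matrix rows and columns must carry the same ids")
        return cls(list(df.index), df.to_numpy(dtype=float))


def build_similarity_matrix(items: dict, kernel: Callable) -> SimilarityMatrix:
    """Apply a symmetric kernel over unordered pairs once, mirror, set the
    diagonal to 1.  ``items`` maps identifier -> object fed to the kernel."""
    ids = list(items)
    if len(ids) < 2:
        raise ValueError("need at least 2 items")
    n = len(ids)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                s = float(kernel(items[ids[i]], items[ids[j]]))
            except Exception as err:
                raise RuntimeError(
                    f"kernel failed on pair ({ids[i]!r}, {ids[j]!r}): {err}"
                ) from err
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(ids, values)


def drug_similarity_matrix(
    table: FingerprintTable, W: WeightVector | None = None, h: float = 0.1
) -> SimilarityMatrix:
    """Vectorized weighted-cosine matrix over a fingerprint table.  Weights
    default to :func:`compute_weights` on the table's own column
    frequencies."""
    if W is None:
        W = compute_weights(table.column_frequencies(), h=h)
    lw = np.asarray(W.log_weights, dtype=float)
    F = table.matrix
    # per-drug rescale by the largest log-weight on its support (cancels in
    # the cosine ratio, prevents underflow at small h)
    support = (F != 0) & (lw > -np.inf)
    if np.any(~support.any(axis=1)):
        bad = table.drug_ids[int(np.argmax(~support.any(axis=1)))]
        raise ValueError(f"drug {bad!r} has zero weighted norm; similarity undefined")
    m = np.where(support, lw, -np.inf).max(axis=1)
    with np.errstate(under="ignore"):
        A = F * np.exp(0.5 * (lw[None, :] - m[:, None]))
        G = A @ A.T
        norms = np.sqrt(np.diag(G))
    values = G / np.outer(norms, norms)
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2.0  # enforce exact symmetry
    return SimilarityMatrix(table.drug_ids, values)


_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SWScheme:
    """Smith-Waterman scoring scheme: a substitution matrix name or a simple
    match/mismatch pair, plus affine gap penalties (positive magnitudes)."""

    matrix: str | None = "BLOSUM62"
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        if self.matrix is not None:
            aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        else:
            # explicit matrix so X scores 0 against everything
            alphabet = _AA + "X"
            m = substitution_matrices.Array(alphabet, dims=2)
            for a in _AA:
                for b in _AA:
                    m[a, b] = self.match if a == b else self.mismatch
            aligner.substitution_matrix = m
        aligner.open_gap_score = -abs(self.gap_open)
        aligner.extend_gap_score = -abs(self.gap_extend)
        return aligner


def blosum62_scheme(gap_open: float = 10.0, gap_extend: float = 0.5) -> SWScheme:
    return SWScheme("BLOSUM62", gap_open=gap_open, gap_extend=gap_extend)


def simple_scheme(match: float = 1.0, mismatch: float = -1.0, gap: float = 1.0) -> SWScheme:
    """Match/mismatch scoring with a linear gap penalty (open == extend)."""
    return SWScheme(None, match=match, mismatch=mismatch, gap_open=gap, gap_extend=gap)


def sw_normalized(seq_a: str, seq_b: str, scheme: SWScheme | None = None) -> float:
    """Normalized local-alignment similarity
    ``SW(a, b) / sqrt(SW(a, a) * SW(b, b))``; 1 for identical sequences."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    scheme = scheme or blosum62_scheme()
    aligner = scheme.aligner()
    saa = aligner.score(seq_a, seq_a)
    sbb = aligner.score(seq_b, seq_b)
    if saa <= 0 or sbb <= 0:
        raise ValueError("self-alignment score is non-positive; cannot normalize")
    sab = max(aligner.score(seq_a, seq_b), 0.0)
    return float(sab / np.sqrt(saa * sbb))


def target_similarity_matrix(
    sequences: dict, scheme: SWScheme | None = None
) -> SimilarityMatrix:
    """Normalized Smith-Waterman matrix over a dict of id -> sequence, with
    self-alignment scores computed once per sequence."""
    ids = list(sequences)
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    scheme = scheme or blosum62_scheme()
    aligner = scheme.aligner()
    for tid, seq in sequences.items():
        if not seq:
            raise ValueError(f"target {tid!r} has an empty sequence")
    self_scores = {tid: aligner.score(s, s) for tid, s in sequences.items()}
    for tid, s in self_scores.items():
        if s <= 0:
            raise ValueError(f"target {tid!r}: self-alignment score is non-positive")
    n = len(ids)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sab = max(aligner.score(sequences[ids[i]], sequences[ids[j]]), 0.0)
            values[i, j] = values[j, i] = sab / np.sqrt(
                self_scores[ids[i]] * self_scores[ids[j]]
            )
    return SimilarityMatrix(ids, values)
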