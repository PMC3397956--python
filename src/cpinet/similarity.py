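"""Chemical, protein and shared-partner (SAR) similarity measures.

Chemical-chemical similarity operates on fixed-length binary fingerprints
(MACCS keys by default, 166 bits) with four classical metrics defined from
the bit counts a (shared on-bits), b (on only in x), c (on only in y) and
the vector length n:

========== =============================
Tanimoto   a / (a + b + c)
Cosine     a / sqrt((a + b)(a + c))
Forbes     a n / ((a + b)(a + c))
Russell-Rao a / n
========== =============================

Tanimoto, Cosine and Russell-Rao lie in [0, 1]; Forbes may exceed 1.
Protein-protein similarity is the Smith-Waterman local-alignment score
normalized as ``SW(i,j) / sqrt(SW(i,i) SW(j,j))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import TYPE_CHECKING, Mapping

import numpy as np

from .errors import DataError

if TYPE_CHECKING:  # pragma: no cover
    from .network import BipartiteNetwork

METRICS = ("tanimoto", "cosine", "forbes", "russell_rao")


@dataclass(frozen=True)
class FingerprintSet:
    """Binary fingerprints of common length, indexed by compound id."""

    ids: tuple[str, ...]
    bits: np.ndarray  # shape (n_compounds, n_bits), entries in {0, 1}

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 2 or bits.shape[0] != len(self.ids):
            raise DataError("fingerprint matrix shape does not match id list")
        if not np.isin(bits, (0, 1)).all():
            raise DataError("fingerprint entries must be 0 or 1")
        if len(set(self.ids)) != len(self.ids):
            raise DataError("duplicate fingerprint ids")
        object.__setattr__(self, "bits", bits)

    @cached_property
    def index(self) -> dict[str, int]:
        return {cid: i for i, cid in enumerate(self.ids)}

    def vector(self, cid: str) -> np.ndarray:
        return self.bits[self.index[cid]]

    def subset(self, ids) -> "FingerprintSet":
        idx = [self.index[c] for c in ids]
        return FingerprintSet(ids=tuple(ids), bits=self.bits[idx])


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric, non-negative pairwise similarity with labelled axes."""

    ids: tuple[str, ...]
    values: np.ndarray
    metric_name: str = "unknown"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if vals.shape != (n, n):
            raise DataError("similarity matrix must be square and match ids")
        if not np.allclose(vals, vals.T, atol=1e-9):
            raise DataError("similarity matrix must be symmetric")
        if (vals < 0).any():
            raise DataError("similarity values must be non-negative")
        object.__setattr__(self, "values", vals)

    @cached_property
    def index(self) -> dict[str, int]:
        return {i: k for k, i in enumerate(self.ids)}

    def value(self, i: str, j: str) -> float:
        return float(self.values[self.index[i], self.index[j]])

    def reorder(self, ids) -> "SimilarityMatrix":
        """Restrict/permute to the given ids (error if any is missing)."""
        try:
            idx = [self.index[i] for i in ids]
        except KeyError as exc:
            raise DataError(f"id {exc.args[0]!r} missing from similarity matrix") from exc
        return SimilarityMatrix(
            ids=tuple(ids),
            values=self.values[np.ix_(idx, idx)],
            metric_name=self.metric_name,
        )


def binary_similarity(x, y, metric: str = "tanimoto") -> float:
    """Similarity of two equal-length binary vectors under one metric.

    Pairs where the shared-bit count a is zero (including two all-zero
    vectors) score 0 under every metric: no evidence of similarity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("fingerprints must be 1-d vectors of equal length")
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    a = float(x @ y)
    if a == 0.0:
        return 0.0
    n = float(x.size)
    on_x = float(x.sum())  # a + b
    on_y = float(y.sum())  # a + c
    if metric == "tanimoto":
        return a / (on_x + on_y - a)
    if metric == "cosine":
        return a / np.sqrt(on_x * on_y)
    if metric == "forbes":
        return a * n / (on_x * on_y)
    return a / n  # russell_rao


def pairwise_similarity_matrix(fps: FingerprintSet, metric: str = "tanimoto") -> SimilarityMatrix:
    """All-pairs binary similarity, symmetric by construction."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if len(fps.ids) == 0:
        raise DataError("empty fingerprint set")
    X = fps.bits.astype(float)
    n_bits = X.shape[1]
    shared = X @ X.T  # a
    on = X.sum(axis=1)  # a + b per row
    with np.errstate(divide="ignore", invalid="ignore"):
        if metric == "tanimoto":
            denom = on[:, None] + on[None, :] - shared
            vals = shared / denom
        elif metric == "cosine":
            vals = shared / np.sqrt(on[:, None] * on[None, :])
        elif metric == "forbes":
            vals = shared * n_bits / (on[:, None] * on[None, :])
        else:  # russell_rao
            vals = shared / n_bits
    vals = np.where(shared == 0, 0.0, vals)
    vals = np.nan_to_num(vals, nan=0.0, posinf=0.0)
    vals = 0.5 * (vals + vals.T)  # exact symmetry against float noise
    return SimilarityMatrix(ids=fps.ids, values=vals, metric_name=metric)


def maccs_fingerprints(smiles: Mapping[str, str]) -> FingerprintSet:
    """166-bit MACCS keys from SMILES via the chemistry toolkit.

    Unparseable SMILES raise :class:`DataError` naming the compound.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import MACCSkeys

    RDLogger.DisableLog("rdApp.*")
    ids = tuple(smiles)
    rows = []
    for cid in ids:
        mol = Chem.MolFromSmiles(smiles[cid])
        if mol is None:
            raise DataError(f"cannot parse SMILES for chemical {cid!r}")
        fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 always unset
        arr = np.zeros(167, dtype=np.uint8)
        for b in fp.GetOnBits():
            arr[b] = 1
        rows.append(arr[1:])
    return FingerprintSet(ids=ids, bits=np.vstack(rows))


def sequence_similarity_matrix(
    sequences: Mapping[str, str],
    *,
    substitution_matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> SimilarityMatrix:
    """Normalized Smith-Waterman similarity for all sequence pairs.

    value(i, j) = SW(i, j) / sqrt(SW(i, i) * SW(j, j)) with local alignment
    under the given substitution matrix and affine gap penalties; the
    diagonal is exactly 1.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    if not sequences:
        raise DataError("no sequences given")
    ids = tuple(sequences)
    for pid in ids:
        if not sequences[pid]:
            raise DataError(f"empty sequence for protein {pid!r}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(substitution_matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    n = len(ids)
    raw = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            raw[i, j] = raw[j, i] = aligner.score(sequences[ids[i]], sequences[ids[j]])
    self_scores = np.diag(raw).copy()
    if (self_scores <= 0).any():
        raise DataError("non-positive self-alignment score; check sequences")
    vals = raw / np.sqrt(self_scores[:, None] * self_scores[None, :])
    np.fill_diagonal(vals, 1.0)
    vals = np.clip(0.5 * (vals + vals.T), 0.0, None)
    return SimilarityMatrix(
        ids=ids,
        values=vals,
        metric_name=f"smith_waterman/{substitution_matrix}/open{gap_open}/ext{gap_extend}",
    )


def sar_similarity(network: "BipartiteNetwork", side: str, i: str, j: str) -> float:
    """Tanimoto overlap of two nodes' interaction-partner sets.

    For two chemicals (``side="chemical"``) this is
    ``N_ij / (k_i + k_j - N_ij)`` where ``N_ij`` counts proteins bound by
    both and ``k`` are their degrees; ``side="protein"`` mirrors it over
    shared ligands.
    """
    if side == "chemical":
        idx = network.chemical_index
        rows = network.adjacency
    elif side == "protein":
        idx = network.protein_index
        rows = network.adjacency.T
    else:
        raise ValueError("side must be 'chemical' or 'protein'")
    if i not in idx:
        raise KeyError(f"unknown {side} id {i!r}")
    if j not in idx:
        raise KeyError(f"unknown {side} id {j!r}")
    xi = rows[idx[i]]
    xj = rows[idx[j]]
    shared = float(xi @ xj)
    k_i = float(xi.sum())
    k_j = float(xj.sum())
    if k_i < 1 or k_j < 1:
        raise DataError("sar_similarity requires both nodes to have degree >= 1")
    return shared / (k_i + k_j - shared)
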