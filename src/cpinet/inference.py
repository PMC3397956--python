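"""The five link-prediction scorers on the bipartite CPI network.

All three diffusion methods share the same two-step mass-diffusion scheme.
For a query chemical the initial resource sits on its interacting proteins;
each protein then distributes its resource to its neighbouring chemicals,
and each chemical redistributes what it received back to its neighbouring
proteins.  The final resource on proteins the chemical is not yet linked to
is the prediction score.  In matrix form, with adjacency A, protein degrees
D_p and chemical degrees D_c,

    F = A  D_p^-1 A^T  D_c^-1 A          (NBI)

Resource is conserved: the i-th row of F sums to the degree (or weighted
strength) of chemical i.

* EWNBI replaces A by the potency-weighted matrix V = W^lambda (elementwise
  on edges) everywhere, so allocation is proportional to edge weight;
  lambda = 0 recovers NBI, lambda = 1 is the fully potency-weighted method,
  and 0 < lambda < 1 damps strong edges relative to weak ones.
* NWNBI keeps the binary initial resource but allocates to neighbours
  proportionally to (receiver degree)^beta instead of equally; beta = 0
  recovers NBI, positive beta strengthens hub influence, negative beta
  weakens it.

DBSI and TBSI are similarity-weighted averages of known interaction
profiles over chemical-structure and protein-sequence similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError
from .io import RankedPrediction
from .network import BipartiteNetwork
from .similarity import FingerprintSet, SimilarityMatrix, binary_similarity

DIRECTIONS = ("targets_for_chemical", "chemicals_for_protein")


@dataclass(frozen=True)
class ScoreMatrix:
    """Predicted scores for all chemical-protein pairs of one network."""

    chemical_ids: tuple[str, ...]
    protein_ids: tuple[str, ...]
    scores: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (len(self.chemical_ids), len(self.protein_ids)):
            raise DataError("score matrix shape does not match id lists")
        if not np.isfinite(s).all():
            raise DataError("scores must be finite")
        if (s < 0).any():
            raise DataError("scores must be non-negative")
        object.__setattr__(self, "scores", s)


def _safe_divide(num: np.ndarray, denom: np.ndarray) -> np.ndarray:
    """Elementwise num/denom with 0 where denom is 0."""
    out = np.zeros_like(num, dtype=float)
    np.divide(num, denom, out=out, where=denom != 0)
    return out


def _two_step_scores(resource: np.ndarray, m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    # resource: (n_chem, n_prot) initial resource per query chemical;
    # m1: (n_prot, n_chem) protein->chemical allocation, row-stochastic;
    # m2: (n_chem, n_prot) chemical->protein allocation, row-stochastic.
    return resource @ m1 @ m2


def nbi_scores(network: BipartiteNetwork) -> ScoreMatrix:
    """Unweighted network-based inference (equal split at both steps)."""
    a = network.adjacency
    if a.size == 0:
        raise DataError("empty network")
    k_c = a.sum(axis=1)
    k_p = a.sum(axis=0)
    if (k_c == 0).any() or (k_p == 0).any():
        warnings.warn(
            "network contains zero-degree nodes; their scores are all zero",
            stacklevel=2,
        )
    m1 = _safe_divide(a.T, k_p[:, None])
    m2 = _safe_divide(a, k_c[:, None])
    return ScoreMatrix(
        network.chemical_ids,
        network.protein_ids,
        _two_step_scores(a, m1, m2),
        method="nbi",
        params={},
    )


def ewnbi_scores(network: BipartiteNetwork, lam: float = 1.0) -> ScoreMatrix:
    """Edge-weighted NBI: resource and allocation follow w^lambda.

    lambda = 0 reproduces :func:`nbi_scores` exactly; lambda = 1 weights
    each edge by its potency.  Intermediate and negative lambda values tune
    the relative influence of strong versus weak interactions.
    """
    a = network.adjacency
    if a.size == 0:
        raise DataError("empty network")
    if lam == 0:
        v = a
    else:
        on_edges = a == 1
        if (network.weights[on_edges] <= 0).any():
            raise DataError(
                "edge-weighted diffusion with lambda != 0 requires positive "
                "edge weights (potency > 0)"
            )
        v = np.zeros_like(a)
        v[on_edges] = network.weights[on_edges] ** lam
    s_c = v.sum(axis=1)
    s_p = v.sum(axis=0)
    m1 = _safe_divide(v.T, s_p[:, None])
    m2 = _safe_divide(v, s_c[:, None])
    return ScoreMatrix(
        network.chemical_ids,
        network.protein_ids,
        _two_step_scores(v, m1, m2),
        method="ewnbi",
        params={"lambda": lam},
    )


def nwnbi_scores(
    network: BipartiteNetwork, beta: float = 0.0, apply_at: str = "both"
) -> ScoreMatrix:
    """Node-weighted NBI: allocation proportional to (receiver degree)^beta.

    The initial resource is the binary profile, as in NBI.  At each
    diffusion step a node splits its resource among its neighbours in
    proportion to the neighbour's degree raised to ``beta`` (normalized over
    those neighbours), rather than equally.  ``apply_at`` selects where the
    preferential allocation acts: ``"step1"`` (protein -> chemical),
    ``"step2"`` (chemical -> protein) or ``"both"`` (default).  beta = 0
    reproduces :func:`nbi_scores` exactly for every choice.
    """
    if apply_at not in ("step1", "step2", "both"):
        raise ValueError("apply_at must be 'step1', 'step2' or 'both'")
    a = network.adjacency
    if a.size == 0:
        raise DataError("empty network")
    k_c = a.sum(axis=1)
    k_p = a.sum(axis=0)

    def preferential(adj: np.ndarray, receiver_degree: np.ndarray) -> np.ndarray:
        # adj: (n_senders, n_receivers); weight each receiver by degree^beta
        with np.errstate(divide="ignore"):
            pref = np.where(receiver_degree > 0, receiver_degree, 1.0) ** beta
        weighted = adj * pref[None, :]
        return _safe_divide(weighted, weighted.sum(axis=1, keepdims=True))

    if apply_at in ("step1", "both"):
        m1 = preferential(a.T, k_c)
    else:
        m1 = _safe_divide(a.T, k_p[:, None])
    if apply_at in ("step2", "both"):
        m2 = preferential(a, k_p)
    else:
        m2 = _safe_divide(a, k_c[:, None])
    return ScoreMatrix(
        network.chemical_ids,
        network.protein_ids,
        _two_step_scores(a, m1, m2),
        method="nwnbi",
        params={"beta": beta, "apply_at": apply_at},
    )


def dbsi_scores(network: BipartiteNetwork, chem_sim: SimilarityMatrix) -> ScoreMatrix:
    """Chemical-similarity inference.

    score(i, j) = sum_{l != i} S_c(i, l) a_lj / sum_{l != i} S_c(i, l); a
    similarity-weighted average of the other chemicals' link profiles (0
    when chemical i has zero similarity to every other chemical).
    """
    sim = chem_sim.reorder(network.chemical_ids)
    s = sim.values.copy()
    np.fill_diagonal(s, 0.0)  # exclude self: known links must not self-predict
    denom = s.sum(axis=1, keepdims=True)
    scores = _safe_divide(s @ network.adjacency, denom)
    return ScoreMatrix(
        network.chemical_ids,
        network.protein_ids,
        scores,
        method="dbsi",
        params={"metric": chem_sim.metric_name},
    )


def tbsi_scores(network: BipartiteNetwork, prot_sim: SimilarityMatrix) -> ScoreMatrix:
    """Protein-similarity inference, the mirror of :func:`dbsi_scores`.

    score(i, j) = sum_{k != j} S_g(j, k) a_ik / sum_{k != j} S_g(j, k).
    """
    sim = prot_sim.reorder(network.protein_ids)
    s = sim.values.copy()
    np.fill_diagonal(s, 0.0)
    denom = s.sum(axis=1)  # per protein j
    scores = _safe_divide(network.adjacency @ s.T, denom[None, :])
    return ScoreMatrix(
        network.chemical_ids,
        network.protein_ids,
        scores,
        method="tbsi",
        params={"metric": prot_sim.metric_name},
    )


def score_network(
    network: BipartiteNetwork,
    method: str,
    *,
    beta: float = 0.0,
    lam: float = 1.0,
    apply_at: str = "both",
    chem_sim: SimilarityMatrix | None = None,
    prot_sim: SimilarityMatrix | None = None,
) -> ScoreMatrix:
    """Dispatch to one of the five scorers by name."""
    if method == "nbi":
        return nbi_scores(network)
    if method == "nwnbi":
        return nwnbi_scores(network, beta=beta, apply_at=apply_at)
    if method == "ewnbi":
        return ewnbi_scores(network, lam=lam)
    if method == "dbsi":
        if chem_sim is None:
            raise DataError("dbsi requires a chemical similarity matrix")
        return dbsi_scores(network, chem_sim)
    if method == "tbsi":
        if prot_sim is None:
            raise DataError("tbsi requires a protein similarity matrix")
        return tbsi_scores(network, prot_sim)
    raise ValueError(f"unknown method {method!r}")


def virtual_profile(
    novel_fp: np.ndarray,
    training_fps: FingerprintSet,
    network: BipartiteNetwork,
) -> tuple[str, np.ndarray]:
    """Adopt the link profile of the most similar training compound.

    For a compound absent from the network, find the training chemical with
    the highest Tanimoto similarity to its fingerprint (ties broken by
    lexicographically smallest chemical id) and return that chemical's id
    together with a copy of its adjacency row, to serve as the novel
    compound's initial diffusion resource.
    """
    novel = np.asarray(novel_fp, dtype=float)
    if novel.sum() == 0:
        raise DataError("novel compound fingerprint is all-zero")
    best_id = None
    best_sim = -1.0
    for cid in network.chemical_ids:
        sim = binary_similarity(novel, training_fps.vector(cid), "tanimoto")
        if sim > best_sim or (sim == best_sim and (best_id is None or cid < best_id)):
            best_sim = sim
            best_id = cid
    assert best_id is not None
    row = network.adjacency[network.chemical_index[best_id]].copy()
    return best_id, row


def rank_candidates(
    scores: ScoreMatrix,
    network: BipartiteNetwork,
    direction: str = "targets_for_chemical",
    top_L: int | None = None,
    query_ids: Sequence[str] | None = None,
) -> list[RankedPrediction]:
    """Rank each query's unconnected counterparts by descending score.

    Known (training) pairs are excluded from the candidate queue.  Ties are
    broken by ascending candidate id so output is deterministic.  ``top_L``
    truncates each per-query list.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if top_L is not None and top_L < 1:
        raise ValueError("top_L must be >= 1")
    if direction == "targets_for_chemical":
        mat = scores.scores
        adj = network.adjacency
        queries, candidates = scores.chemical_ids, scores.protein_ids
    else:
        mat = scores.scores.T
        adj = network.adjacency.T
        queries, candidates = scores.protein_ids, scores.chemical_ids
    qindex = {q: i for i, q in enumerate(queries)}
    if query_ids is None:
        query_ids = queries
    out: list[RankedPrediction] = []
    cand_arr = np.array(candidates)
    for q in query_ids:
        if q not in qindex:
            raise DataError(f"unknown query id {q!r}")
        qi = qindex[q]
        free = adj[qi] == 0
        ids = cand_arr[free]
        vals = mat[qi][free]
        order = np.lexsort((ids, -vals))  # descending score, ascending id
        if top_L is not None:
            order = order[:top_L]
        for rank, k in enumerate(order, start=1):
            out.append(RankedPrediction(q, str(ids[k]), rank, float(vals[k])))
    return out
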