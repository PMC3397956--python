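"""Cross-validation and external-validation protocols with recall, recall
enhancement and AUC.

The benchmark protocol is 10-fold cross-validation over interaction pairs,
repeated 10 times with independent random splits.  Within a repetition the
model is trained on nine folds, the tenth is held out, and every query node
(chemical or protein, depending on direction) receives a ranked queue of all
its unconnected counterparts.  Metrics:

* recall@L - fraction of held-out links appearing within the top L of their
  query's queue;
* recall enhancement ER = R * N / L - recall relative to the expected recall
  of a random top-L list among N candidates;
* AUC - per query, the probability that a held-out link outscores a random
  non-link candidate (ties credit 0.5), averaged over assessable queries.

Held-out links whose chemical or protein lost every training link in the
split cannot be predicted by construction and are excluded from assessment
(they are counted in ``EvalReport.n_excluded_links``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .errors import DataError
from .inference import (
    DIRECTIONS,
    ScoreMatrix,
    score_network,
    virtual_profile,
)
from .network import BipartiteNetwork
from .similarity import FingerprintSet, SimilarityMatrix, binary_similarity

Pair = tuple[str, str]


@dataclass(frozen=True)
class CVSplit:
    """Assignment of every known interaction pair to one of n folds."""

    assignments: dict[Pair, int]  # fold indices 1..n_folds
    n_folds: int
    seed: int

    def fold_pairs(self, fold: int) -> list[Pair]:
        return [p for p, f in self.assignments.items() if f == fold]


@dataclass(frozen=True)
class EvalReport:
    """Aggregated performance of one method under one protocol."""

    method: str
    direction: str
    L: int
    recall: float
    recall_sd: float
    er: float
    er_sd: float
    auc: float
    auc_sd: float
    n_repetitions: int
    n_candidates_total: int
    n_excluded_links: int = 0
    seeds: tuple[int, ...] = ()
    params: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "direction": self.direction,
            "L": self.L,
            "recall": self.recall,
            "recall_sd": self.recall_sd,
            "er": self.er,
            "er_sd": self.er_sd,
            "auc": self.auc,
            "auc_sd": self.auc_sd,
            "n_repetitions": self.n_repetitions,
            "n_candidates_total": self.n_candidates_total,
            "n_excluded_links": self.n_excluded_links,
            "seeds": list(self.seeds),
            "params": self.params,
        }


def make_cv_splits(network: BipartiteNetwork, n_folds: int = 10, seed: int = 0) -> CVSplit:
    """Uniform random partition of the known pairs into balanced folds.

    Fold sizes differ by at most one; the assignment is reproducible from
    the seed.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    pairs = network.edges()
    if n_folds > len(pairs):
        raise ValueError("n_folds exceeds the number of interaction pairs")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    assignments = {
        pairs[idx]: (pos % n_folds) + 1 for pos, idx in enumerate(order)
    }
    return CVSplit(assignments=assignments, n_folds=n_folds, seed=seed)


def recall_at_L(
    ranked: Mapping[str, Sequence[str]],
    test_links: Iterable[Pair],
    L: int,
) -> float:
    """Fraction of test links within the top L of their query's list.

    ``ranked`` maps query id to its candidate ids in rank order.  Test links
    whose query has no list are not assessable and are excluded from the
    denominator (they should have been excluded upstream).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    hits = 0
    assessable = 0
    for query, candidate in test_links:
        if query not in ranked:
            continue
        assessable += 1
        if candidate in list(ranked[query])[:L]:
            hits += 1
    if assessable == 0:
        return 0.0
    return hits / assessable


def recall_enhancement(recall: float, n_candidates_total: int, L: int) -> float:
    """ER = recall * N / L: enhancement over a random top-L list among N."""
    if L < 1:
        raise ValueError("L must be >= 1")
    return recall * n_candidates_total / L


def auc_ranking(
    scores: Mapping[str, Mapping[str, float]],
    test_links: Iterable[Pair],
    mode: str = "per_query_mean",
) -> float:
    """Ranking AUC of test links against non-link candidates.

    ``scores`` maps query id -> {candidate id: score} over that query's
    candidate queue.  Per query, AUC = (n1 + 0.5 n2) / n over all (test
    link, non-link) score comparisons, where n1 counts wins and n2 ties.
    ``mode="per_query_mean"`` (default) averages per-query AUCs;
    ``mode="pooled"`` pools the comparisons across queries.
    """
    if mode not in ("per_query_mean", "pooled"):
        raise ValueError("mode must be 'per_query_mean' or 'pooled'")
    by_query: dict[str, set[str]] = {}
    for q, c in test_links:
        by_query.setdefault(q, set()).add(c)
    per_query: list[float] = []
    pooled_num = 0.0
    pooled_den = 0.0
    for q, positives in by_query.items():
        if q not in scores:
            continue
        cand = scores[q]
        pos = np.array([cand[c] for c in positives if c in cand])
        neg = np.array([v for c, v in cand.items() if c not in positives])
        if pos.size == 0 or neg.size == 0:
            continue
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        num = wins + 0.5 * ties
        den = pos.size * neg.size
        per_query.append(num / den)
        pooled_num += num
        pooled_den += den
    if not per_query:
        raise DataError("no assessable query for AUC")
    if mode == "pooled":
        return pooled_num / pooled_den
    return float(np.mean(per_query))


def _pos_neg_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


def _rank_of(scores: np.ndarray, ids: np.ndarray, k: int) -> int:
    """1-based rank of element k under descending score, id tie-break."""
    s_k = scores[k]
    higher = int((scores > s_k).sum())
    tied_before = int(((scores == s_k) & (ids < ids[k])).sum())
    return 1 + higher + tied_before


def _evaluate_fold(
    training: BipartiteNetwork,
    test_pairs: Sequence[Pair],
    scorer: Callable[[BipartiteNetwork], ScoreMatrix],
    direction: str,
    L: int,
) -> tuple[int, int, list[tuple[float, float]], int]:
    """Score one training network and assess its held-out links.

    Returns (hits, assessable, per-query (auc_numerator, n_comparisons)
    pairs, excluded links).
    """
    with warnings.catch_warnings():
        # masking strands nodes by design; their links are excluded below
        warnings.filterwarnings("ignore", message=".*zero-degree.*")
        score_matrix = scorer(training)
    if direction == "targets_for_chemical":
        mat = score_matrix.scores
        adj = training.adjacency
        qindex = training.chemical_index
        cindex = training.protein_index
        cand_ids = np.array(training.protein_ids)
        oriented = [(c, p) for c, p in test_pairs]
    else:
        mat = score_matrix.scores.T
        adj = training.adjacency.T
        qindex = training.protein_index
        cindex = training.chemical_index
        cand_ids = np.array(training.chemical_ids)
        oriented = [(p, c) for c, p in test_pairs]

    q_deg = adj.sum(axis=1)
    c_deg = adj.sum(axis=0)

    by_query: dict[str, list[str]] = {}
    excluded = 0
    for q, c in oriented:
        # a link is unassessable when either endpoint lost all training links
        if q_deg[qindex[q]] == 0 or c_deg[cindex[c]] == 0:
            excluded += 1
            continue
        by_query.setdefault(q, []).append(c)

    hits = 0
    assessable = 0
    aucs: list[tuple[float, float]] = []
    for q, positives in by_query.items():
        qi = qindex[q]
        free = adj[qi] == 0  # candidate queue: everything but training links
        vals = mat[qi][free]
        ids = cand_ids[free]
        pos_mask = np.isin(ids, positives)
        # recall: rank each test link within the full candidate queue
        for k in np.flatnonzero(pos_mask):
            assessable += 1
            if _rank_of(vals, ids, k) <= L:
                hits += 1
        pos = vals[pos_mask]
        neg = vals[~pos_mask]
        if pos.size and neg.size:
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            aucs.append((wins + 0.5 * ties, pos.size * neg.size))
    return hits, assessable, aucs, excluded


def _make_scorer(
    method: str | Callable[[BipartiteNetwork], ScoreMatrix],
    params: Mapping | None,
    chem_sim: SimilarityMatrix | None,
    prot_sim: SimilarityMatrix | None,
) -> tuple[Callable[[BipartiteNetwork], ScoreMatrix], str, dict]:
    if callable(method):
        return method, getattr(method, "__name__", "custom"), dict(params or {})
    p = dict(params or {})

    def scorer(net: BipartiteNetwork) -> ScoreMatrix:
        return score_network(
            net,
            method,
            beta=p.get("beta", 0.0),
            lam=p.get("lambda", 1.0),
            apply_at=p.get("apply_at", "both"),
            chem_sim=chem_sim,
            prot_sim=prot_sim,
        )

    return scorer, method, p


def run_cv_experiment(
    network: BipartiteNetwork,
    method: str | Callable[[BipartiteNetwork], ScoreMatrix] = "nbi",
    *,
    params: Mapping | None = None,
    direction: str = "targets_for_chemical",
    L: int = 5,
    n_folds: int = 10,
    n_repetitions: int = 10,
    seed: int = 0,
    chem_sim: SimilarityMatrix | None = None,
    prot_sim: SimilarityMatrix | None = None,
    auc_mode: str = "per_query_mean",
) -> EvalReport:
    """Repeated k-fold cross-validation of one method on one network.

    Each repetition draws a fresh random split from a seed derived
    deterministically from ``seed``; recall (hence ER) and AUC are
    accumulated over the repetition's folds and the report carries
    mean +/- sd across repetitions.  ``auc_mode="per_query_mean"``
    (default) averages per-query AUCs; ``auc_mode="pooled"`` pools the
    score comparisons across queries (sensitivity analysis).
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if auc_mode not in ("per_query_mean", "pooled"):
        raise ValueError("auc_mode must be 'per_query_mean' or 'pooled'")
    scorer, method_name, method_params = _make_scorer(method, params, chem_sim, prot_sim)
    master = np.random.default_rng(seed)
    rep_seeds = tuple(int(s) for s in master.integers(0, 2**31 - 1, size=n_repetitions))
    n_candidates = (
        network.n_proteins if direction == "targets_for_chemical" else network.n_chemicals
    )
    recalls, ers, mean_aucs = [], [], []
    total_excluded = 0
    for rep_seed in rep_seeds:
        split = make_cv_splits(network, n_folds=n_folds, seed=rep_seed)
        hits = assessable = 0
        rep_aucs: list[tuple[float, float]] = []
        for fold in range(1, n_folds + 1):
            test_pairs = split.fold_pairs(fold)
            training = network.mask_pairs(test_pairs)
            h, a, aucs, excl = _evaluate_fold(training, test_pairs, scorer, direction, L)
            hits += h
            assessable += a
            rep_aucs.extend(aucs)
            total_excluded += excl
        recall = hits / assessable if assessable else 0.0
        recalls.append(recall)
        ers.append(recall_enhancement(recall, n_candidates, L))
        if not rep_aucs:
            mean_aucs.append(float("nan"))
        elif auc_mode == "pooled":
            mean_aucs.append(sum(n for n, _ in rep_aucs) / sum(d for _, d in rep_aucs))
        else:
            mean_aucs.append(float(np.mean([n / d for n, d in rep_aucs])))
    return EvalReport(
        method=method_name,
        direction=direction,
        L=L,
        recall=float(np.mean(recalls)),
        recall_sd=float(np.std(recalls, ddof=1)) if len(recalls) > 1 else 0.0,
        er=float(np.mean(ers)),
        er_sd=float(np.std(ers, ddof=1)) if len(ers) > 1 else 0.0,
        auc=float(np.nanmean(mean_aucs)),
        auc_sd=float(np.nanstd(mean_aucs, ddof=1)) if len(mean_aucs) > 1 else 0.0,
        n_repetitions=n_repetitions,
        n_candidates_total=n_candidates,
        n_excluded_links=total_excluded,
        seeds=rep_seeds,
        params=method_params,
    )


def external_validation(
    training_network: BipartiteNetwork,
    external_pairs: Sequence[Pair],
    external_fps: FingerprintSet,
    training_fps: FingerprintSet,
    method: str = "nbi",
    *,
    params: Mapping | None = None,
    L: int = 20,
    prot_sim: SimilarityMatrix | None = None,
) -> EvalReport:
    """Prioritize targets for compounds absent from the training network.

    Each external compound receives a virtual interaction profile - the
    adjacency row of its most Tanimoto-similar training compound - which
    serves as its initial diffusion resource in an augmented network (or as
    its link profile for TBSI).  DBSI scores the compound directly from its
    fingerprint similarities to training compounds.  The compound is then
    ranked against *all* proteins (it has no true training links to mask)
    and assessed against its known external links at cutoff ``L``.
    """
    if not external_pairs:
        raise DataError("empty external validation set")
    p = dict(params or {})
    protein_index = training_network.protein_index
    by_compound: dict[str, list[str]] = {}
    n_excluded = 0
    for cid, pid in external_pairs:
        if cid in training_network.chemical_index:
            raise DataError(f"external compound {cid!r} present in training network")
        if pid not in protein_index:
            n_excluded += 1
            continue
        by_compound.setdefault(cid, []).append(pid)

    train_sub = training_fps.subset(training_network.chemical_ids)
    prot_ids = np.array(training_network.protein_ids)
    hits = 0
    assessable = 0
    aucs: list[float] = []
    for cid, true_targets in by_compound.items():
        try:
            fp = external_fps.vector(cid)
        except KeyError:
            n_excluded += len(true_targets)
            continue
        if fp.sum() == 0:
            n_excluded += len(true_targets)
            continue
        row_scores = _score_external_compound(
            cid, fp, training_network, train_sub, method, p, prot_sim
        )
        pos_mask = np.isin(prot_ids, true_targets)
        for k in np.flatnonzero(pos_mask):
            assessable += 1
            if _rank_of(row_scores, prot_ids, k) <= L:
                hits += 1
        pos = row_scores[pos_mask]
        neg = row_scores[~pos_mask]
        if pos.size and neg.size:
            aucs.append(_pos_neg_auc(pos, neg))
    if assessable == 0:
        raise DataError("no assessable external link")
    recall = hits / assessable
    n_candidates = training_network.n_proteins
    return EvalReport(
        method=method if isinstance(method, str) else "custom",
        direction="targets_for_chemical",
        L=L,
        recall=recall,
        recall_sd=0.0,
        er=recall_enhancement(recall, n_candidates, L),
        er_sd=0.0,
        auc=float(np.mean(aucs)) if aucs else float("nan"),
        auc_sd=0.0,
        n_repetitions=1,
        n_candidates_total=n_candidates,
        n_excluded_links=n_excluded,
        params=dict(p),
    )


def _score_external_compound(
    cid: str,
    fp: np.ndarray,
    network: BipartiteNetwork,
    training_fps: FingerprintSet,
    method: str,
    params: Mapping,
    prot_sim: SimilarityMatrix | None,
) -> np.ndarray:
    """Score all proteins for one novel compound."""
    if method == "dbsi":
        sims = np.array(
            [
                binary_similarity(fp, training_fps.vector(c), params.get("metric", "tanimoto"))
                for c in network.chemical_ids
            ]
        )
        denom = sims.sum()
        if denom == 0:
            return np.zeros(network.n_proteins)
        return sims @ network.adjacency / denom

    proxy_id, row = virtual_profile(fp, training_fps, network)
    if method == "tbsi":
        if prot_sim is None:
            raise DataError("tbsi requires a protein similarity matrix")
        s = prot_sim.reorder(network.protein_ids).values.copy()
        np.fill_diagonal(s, 0.0)
        denom = s.sum(axis=1)
        out = np.zeros(network.n_proteins)
        np.divide(s @ row, denom, out=out, where=denom != 0)
        return out

    # diffusion methods: append the virtual compound and run the scorer
    proxy_w = network.weights[network.chemical_index[proxy_id]]
    aug = BipartiteNetwork(
        chemical_ids=network.chemical_ids + (cid,),
        protein_ids=network.protein_ids,
        adjacency=np.vstack([network.adjacency, row[None, :]]),
        weights=np.vstack([network.weights, proxy_w[None, :]]),
        allow_isolated=True,
    )
    scores = score_network(
        aug,
        method,
        beta=params.get("beta", 0.0),
        lam=params.get("lambda", 1.0),
        apply_at=params.get("apply_at", "both"),
    )
    return scores.scores[-1]


def prune_similar(
    external_fps: FingerprintSet,
    training_fps: FingerprintSet,
    fraction: float = 0.5,
) -> FingerprintSet:
    """Remove the externally most training-similar compounds (stress test).

    Each external compound's maximum Tanimoto similarity to the training set
    is computed; the top ``fraction`` by that value (ties broken by id) are
    removed and the remainder returned.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    max_sims = []
    for cid in external_fps.ids:
        fp = external_fps.vector(cid)
        best = max(
            binary_similarity(fp, training_fps.bits[i], "tanimoto")
            for i in range(len(training_fps.ids))
        )
        max_sims.append((cid, best))
    n_remove = int(np.floor(fraction * len(max_sims) + 0.5))
    doomed = {
        cid
        for cid, _ in sorted(max_sims, key=lambda t: (-t[1], t[0]))[:n_remove]
    }
    keep = [cid for cid in external_fps.ids if cid not in doomed]
    return external_fps.subset(keep)


def sweep_parameter(
    network: BipartiteNetwork,
    method: str,
    grid: Sequence[float],
    *,
    direction: str = "targets_for_chemical",
    L: int = 5,
    n_folds: int = 10,
    n_repetitions: int = 10,
    seed: int = 0,
    chem_sim: SimilarityMatrix | None = None,
    prot_sim: SimilarityMatrix | None = None,
) -> dict[float, EvalReport]:
    """Cross-validate over a grid of beta (nwnbi) or lambda (ewnbi) values.

    All grid points share the same master seed, so the splits are paired and
    differences along the curve are attributable to the parameter alone.
    """
    if method not in ("nwnbi", "ewnbi"):
        raise ValueError("sweep_parameter supports methods 'nwnbi' and 'ewnbi'")
    if len(grid) == 0:
        raise ValueError("parameter grid is empty")
    key = "beta" if method == "nwnbi" else "lambda"
    out: dict[float, EvalReport] = {}
    for value in grid:
        out[float(value)] = run_cv_experiment(
            network,
            method,
            params={key: float(value)},
            direction=direction,
            L=L,
            n_folds=n_folds,
            n_repetitions=n_repetitions,
            seed=seed,
            chem_sim=chem_sim,
            prot_sim=prot_sim,
        )
    return out
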