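"""Curation filters, bipartite network construction and network statistics.

The bipartite chemical-protein interaction (CPI) network links chemical c_i
to protein p_j when a binding (Ki) or inhibition (IC50) measurement below
10 uM exists.  Each edge additionally carries a potency weight
``w = -log10(affinity / 100 uM)``, so a 10 uM interaction weighs 1 and a
1 nM interaction weighs 5.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DataError
from .io import InteractionRecord

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class BipartiteNetwork:
    """Bipartite CPI graph with binary adjacency and potency weights.

    ``adjacency[i, j] = 1`` iff chemical i interacts with protein j;
    ``weights`` is nonzero exactly where ``adjacency`` is 1.  Training
    networks must have every node connected; copies produced by
    cross-validation masking may contain isolated nodes and carry
    ``allow_isolated=True``.
    """

    chemical_ids: tuple[str, ...]
    protein_ids: tuple[str, ...]
    adjacency: np.ndarray
    weights: np.ndarray
    allow_isolated: bool = False

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if adj.shape != (len(self.chemical_ids), len(self.protein_ids)):
            raise DataError("adjacency shape does not match id lists")
        if w.shape != adj.shape:
            raise DataError("weights shape does not match adjacency")
        if not np.isin(adj, (0.0, 1.0)).all():
            raise DataError("adjacency entries must be 0 or 1")
        if ((w != 0) != (adj == 1)).any():
            raise DataError("weights must be nonzero exactly where adjacency is 1")
        if len(set(self.chemical_ids)) != len(self.chemical_ids):
            raise DataError("duplicate chemical ids")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise DataError("duplicate protein ids")
        if not self.allow_isolated:
            if adj.size == 0:
                raise DataError("empty network")
            if (adj.sum(axis=1) < 1).any():
                raise DataError("isolated chemical node in training network")
            if (adj.sum(axis=0) < 1).any():
                raise DataError("isolated protein node in training network")
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "weights", w)

    # -- basic accessors -------------------------------------------------
    @property
    def n_chemicals(self) -> int:
        return len(self.chemical_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_interactions(self) -> int:
        return int(self.adjacency.sum())

    @cached_property
    def chemical_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.chemical_ids)}

    @cached_property
    def protein_index(self) -> dict[str, int]:
        return {p: j for j, p in enumerate(self.protein_ids)}

    def chemical_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def protein_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)

    def edges(self) -> list[tuple[str, str]]:
        return [
            (self.chemical_ids[i], self.protein_ids[j])
            for i, j in np.argwhere(self.adjacency > 0)
        ]

    def mask_pairs(self, pairs: Iterable[tuple[str, str]]) -> "BipartiteNetwork":
        """Return a copy with the given (chemical, protein) links removed.

        The copy is flagged ``allow_isolated`` because masking can strand
        nodes; downstream evaluation accounts for those separately.
        """
        adj = self.adjacency.copy()
        w = self.weights.copy()
        for cid, pid in pairs:
            i = self.chemical_index[cid]
            j = self.protein_index[pid]
            adj[i, j] = 0.0
            w[i, j] = 0.0
        return BipartiteNetwork(
            self.chemical_ids, self.protein_ids, adj, w, allow_isolated=True
        )


@dataclass(frozen=True)
class NetworkStats:
    """Descriptive statistics of a CPI network (sparsity in percent)."""

    n_chemicals: int
    n_proteins: int
    n_interactions: int
    mean_chemical_degree: float
    mean_protein_degree: float
    sparsity_percent: float
    chemical_degree_histogram: dict[int, int] = field(default_factory=dict)
    protein_degree_histogram: dict[int, int] = field(default_factory=dict)

    @classmethod
    def from_counts(cls, n_chemicals: int, n_proteins: int, n_interactions: int) -> "NetworkStats":
        """Derive the mean degrees and sparsity implied by bare counts."""
        return cls(
            n_chemicals=n_chemicals,
            n_proteins=n_proteins,
            n_interactions=n_interactions,
            mean_chemical_degree=n_interactions / n_chemicals,
            mean_protein_degree=n_interactions / n_proteins,
            sparsity_percent=100.0 * n_interactions / (n_chemicals * n_proteins),
        )


@dataclass
class CurationReport:
    """How many records each curation criterion removed."""

    n_input: int = 0
    non_human: int = 0
    affinity_above_threshold: int = 0
    sequence_invalid: int = 0
    mw_out_of_range: int = 0
    duplicate_measurement: int = 0
    protein_under_connected: int = 0
    retained: int = 0

    @property
    def removed(self) -> int:
        return (
            self.non_human
            + self.affinity_above_threshold
            + self.sequence_invalid
            + self.mw_out_of_range
            + self.duplicate_measurement
            + self.protein_under_connected
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "non_human": self.non_human,
            "affinity_above_threshold": self.affinity_above_threshold,
            "sequence_invalid": self.sequence_invalid,
            "mw_out_of_range": self.mw_out_of_range,
            "duplicate_measurement": self.duplicate_measurement,
            "protein_under_connected": self.protein_under_connected,
            "retained": self.retained,
        }


def _is_valid_sequence(seq: str, min_length: int) -> bool:
    return len(seq) >= min_length and set(seq) <= STANDARD_RESIDUES


def _molecular_weight_and_organic(smiles: str) -> tuple[float, bool] | None:
    """Average molecular weight and carbon-presence from a SMILES string.

    Returns None if the SMILES cannot be parsed.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import Descriptors
        from rdkit import RDLogger

        RDLogger.DisableLog("rdApp.*")
    except ImportError:  # pragma: no cover - rdkit is a declared dependency
        return None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    has_carbon = any(atom.GetAtomicNum() == 6 for atom in mol.GetAtoms())
    return Descriptors.MolWt(mol), has_carbon


def apply_curation_filters(
    records: Sequence[InteractionRecord],
    sequences: Mapping[str, str],
    mol_weights: Mapping[str, float] | None = None,
    *,
    affinity_threshold_uM: float = 10.0,
    species: str | None = "human",
    min_sequence_length: int = 100,
    mw_range: tuple[float, float] = (100.0, 600.0),
    min_protein_degree: int = 3,
) -> tuple[list[InteractionRecord], CurationReport]:
    """Apply the curation criteria and report per-criterion removal counts.

    Record-level filters run first, in order: species, affinity strictly
    below the threshold, protein sequence valid (present, >= 100 standard
    residues), chemical organic with molecular weight in [100, 600] Da.
    Duplicate (chemical, protein) measurements then collapse to the single
    most potent (lowest affinity) record, and finally proteins left with
    fewer than ``min_protein_degree`` distinct active chemicals are dropped
    (applied once, not iterated).

    ``mol_weights`` overrides per-chemical molecular weights; otherwise they
    are computed from SMILES.  Chemicals whose weight cannot be determined
    (no mapping entry and no parseable SMILES) pass the weight filter
    unexamined.  Pass ``species=None`` to disable species filtering.
    """
    report = CurationReport(n_input=len(records))
    if len({r.affinity_type for r in records}) > 1:
        warnings.warn(
            "input mixes Ki and IC50 measurements; the benchmark networks "
            "are built per assay type",
            stacklevel=2,
        )

    mw_cache: dict[str, tuple[float, bool] | None] = {}

    def mw_organic(rec: InteractionRecord) -> tuple[float, bool] | None:
        cid = rec.chemical_id
        if mol_weights is not None and cid in mol_weights:
            return float(mol_weights[cid]), True
        if cid not in mw_cache:
            mw_cache[cid] = (
                _molecular_weight_and_organic(rec.smiles) if rec.smiles else None
            )
        return mw_cache[cid]

    survivors: list[InteractionRecord] = []
    for rec in records:
        if species is not None and rec.species.lower() != species.lower():
            report.non_human += 1
            continue
        if not rec.affinity_value < affinity_threshold_uM:
            report.affinity_above_threshold += 1
            continue
        seq = sequences.get(rec.protein_id)
        if seq is None or not _is_valid_sequence(seq, min_sequence_length):
            report.sequence_invalid += 1
            continue
        info = mw_organic(rec)
        if info is not None:
            mw, organic = info
            if not organic or not (mw_range[0] <= mw <= mw_range[1]):
                report.mw_out_of_range += 1
                continue
        survivors.append(rec)

    # collapse duplicate (chemical, protein) measurements: most potent wins
    best: dict[tuple[str, str], InteractionRecord] = {}
    for rec in survivors:
        key = (rec.chemical_id, rec.protein_id)
        prev = best.get(key)
        if prev is None or rec.affinity_value < prev.affinity_value:
            if prev is not None:
                report.duplicate_measurement += 1
            best[key] = rec
        else:
            report.duplicate_measurement += 1

    # protein-degree filter, applied once after all record-level filters
    degree: Counter[str] = Counter(pid for _cid, pid in best)
    retained = [
        rec for (cid, pid), rec in best.items() if degree[pid] >= min_protein_degree
    ]
    report.protein_under_connected += len(best) - len(retained)
    report.retained = len(retained)
    if not retained:
        raise DataError("curation removed every record: empty network")
    # keep a deterministic order independent of dict insertion history
    retained.sort(key=lambda r: (r.chemical_id, r.protein_id))
    return retained, report


def potency_to_weight(affinity_uM):
    """Potency weight ``-log10(affinity / 100 uM)`` (scalar or array).

    Curated interactions (affinity < 10 uM) map to weights > 1.  Affinities
    at or above 100 uM yield non-positive weights, which cannot occur after
    curation; a warning is emitted when they do.
    """
    affinity = np.asarray(affinity_uM, dtype=float)
    if (affinity <= 0).any():
        raise ValueError("affinity must be positive")
    w = -np.log10(affinity / 100.0)
    if (w <= 0).any():
        warnings.warn(
            "affinity >= 100 uM yields a non-positive potency weight; such "
            "records cannot pass curation",
            stacklevel=2,
        )
    return w if w.ndim else float(w)


def build_network(records: Sequence[InteractionRecord]) -> BipartiteNetwork:
    """Build the bipartite network from curated, deduplicated records.

    Node ids are ordered lexicographically so construction is deterministic
    and independent of record order.
    """
    if not records:
        raise DataError("cannot build a network from zero records")
    pairs = [(r.chemical_id, r.protein_id) for r in records]
    if len(set(pairs)) != len(pairs):
        raise DataError("duplicate (chemical, protein) pair; run curation first")
    chemical_ids = tuple(sorted({r.chemical_id for r in records}))
    protein_ids = tuple(sorted({r.protein_id for r in records}))
    cidx = {c: i for i, c in enumerate(chemical_ids)}
    pidx = {p: j for j, p in enumerate(protein_ids)}
    adj = np.zeros((len(chemical_ids), len(protein_ids)))
    w = np.zeros_like(adj)
    for rec in records:
        i, j = cidx[rec.chemical_id], pidx[rec.protein_id]
        adj[i, j] = 1.0
        w[i, j] = potency_to_weight(rec.affinity_value)
    return BipartiteNetwork(chemical_ids, protein_ids, adj, w)


def network_stats(network: BipartiteNetwork) -> NetworkStats:
    """Node counts, mean degrees, sparsity (%) and degree histograms."""
    base = NetworkStats.from_counts(
        network.n_chemicals, network.n_proteins, network.n_interactions
    )
    cdeg = network.chemical_degrees().astype(int)
    pdeg = network.protein_degrees().astype(int)
    return NetworkStats(
        n_chemicals=base.n_chemicals,
        n_proteins=base.n_proteins,
        n_interactions=base.n_interactions,
        mean_chemical_degree=base.mean_chemical_degree,
        mean_protein_degree=base.mean_protein_degree,
        sparsity_percent=base.sparsity_percent,
        chemical_degree_histogram=dict(sorted(Counter(cdeg.tolist()).items())),
        protein_degree_histogram=dict(sorted(Counter(pdeg.tolist()).items())),
    )


def records_from_network(network: BipartiteNetwork) -> list[InteractionRecord]:
    """Extract one record per edge (affinity back-derived from the weight)."""
    out = []
    for i, j in np.argwhere(network.adjacency > 0):
        affinity = 100.0 * 10.0 ** (-network.weights[i, j])
        out.append(
            InteractionRecord(
                chemical_id=network.chemical_ids[i],
                protein_id=network.protein_ids[j],
                affinity_type="Ki",
                affinity_value=affinity,
            )
        )
    return out
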