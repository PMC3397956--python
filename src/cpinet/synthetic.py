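"""Synthetic inputs: toy worked examples and block-structured random networks.

The random generator plants the kind of structure the inference methods
assume in real bioactivity data: chemicals and proteins fall into co-binding
communities (blocks), links are dense within a block and sparse between
blocks, fingerprints share block-specific bit patterns (so structural
similarity correlates with co-binding, the signal DBSI exploits) and protein
sequences share block-conserved segments (the signal TBSI exploits).
Potencies are drawn log-uniformly over the curated affinity window, so edge
weights span the same range as curated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError
from .network import BipartiteNetwork, potency_to_weight
from .similarity import FingerprintSet

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the block-model generator.

    Defaults give a 100 x 20 network in 4 blocks (25 chemicals x 5 proteins
    each) with a strong planted signal: within-block link probability 0.4
    against 0.01 between blocks.  Potencies span the curated affinity window
    0.001-10 uM, so potency weights lie in (1, 5].  A held-out fraction of
    chemicals (with all their links) is reserved for external-validation
    testing.
    """

    n_chemicals: int = 100
    n_proteins: int = 20
    n_blocks: int = 4
    within_block_link_prob: float = 0.4
    between_block_link_prob: float = 0.01
    potency_log_range: tuple[float, float] = (0.001, 10.0)  # uM
    fingerprint_length: int = 166
    bits_per_block: int = 24
    block_bit_on_prob: float = 0.9
    noise_bit_on_prob: float = 0.02
    sequence_length: int = 160
    conserved_segment_length: int = 70
    heldout_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.within_block_link_prob, self.between_block_link_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("link probabilities must be in [0, 1]")
        if self.within_block_link_prob < self.between_block_link_prob:
            raise ValueError(
                "within-block link probability must be >= between-block"
            )
        if self.n_blocks < 1 or self.n_chemicals < 1 or self.n_proteins < 1:
            raise ValueError("sizes must be positive")
        if self.n_blocks * self.bits_per_block > self.fingerprint_length:
            raise ValueError("bits_per_block * n_blocks exceeds fingerprint length")
        if not 0.0 <= self.heldout_fraction < 1.0:
            raise ValueError("heldout_fraction must be in [0, 1)")


def toy_network() -> BipartiteNetwork:
    """The fixed 2-chemical / 3-protein worked example with unit weights.

    c1 links p1 and p2; c2 links p2 and p3.  Unweighted NBI gives final
    resource (0.75, 1.0, 0.25) for c1, making p3 its single candidate.
    """
    adjacency = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]])
    return BipartiteNetwork(
        chemical_ids=("c1", "c2"),
        protein_ids=("p1", "p2", "p3"),
        adjacency=adjacency,
        weights=adjacency.copy(),
    )


def toy_weighted_network() -> BipartiteNetwork:
    """The toy network with potency weights c1-p1=2, c1-p2=1, c2-p2=1, c2-p3=1."""
    adjacency = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]])
    weights = np.array([[2.0, 1.0, 0.0], [0.0, 1.0, 1.0]])
    return BipartiteNetwork(
        chemical_ids=("c1", "c2"),
        protein_ids=("p1", "p2", "p3"),
        adjacency=adjacency,
        weights=weights,
    )


def _block_of(index: int, total: int, n_blocks: int) -> int:
    return (index * n_blocks) // total


def random_bipartite(
    config: GeneratorConfig,
) -> tuple[BipartiteNetwork, FingerprintSet, dict[str, str], list[tuple[str, str]]]:
    """Draw a block-structured network plus correlated fingerprints/sequences.

    Returns ``(network, fingerprints, sequences, held_out_pairs)``.  The
    fingerprint set covers *all* chemicals, including the held-out ones,
    whose true links are returned separately and never appear in the
    network.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_c, n_p, n_b = config.n_chemicals, config.n_proteins, config.n_blocks
    chem_ids = tuple(f"C{i:04d}" for i in range(n_c))
    prot_ids = tuple(f"P{j:03d}" for j in range(n_p))
    chem_block = np.array([_block_of(i, n_c, n_b) for i in range(n_c)])
    prot_block = np.array([_block_of(j, n_p, n_b) for j in range(n_p)])

    same_block = chem_block[:, None] == prot_block[None, :]
    prob = np.where(
        same_block, config.within_block_link_prob, config.between_block_link_prob
    )
    adjacency = (rng.random((n_c, n_p)) < prob).astype(float)

    # re-sample isolated nodes: link them to a random node of their block
    for _ in range(100):
        lonely_c = np.flatnonzero(adjacency.sum(axis=1) == 0)
        lonely_p = np.flatnonzero(adjacency.sum(axis=0) == 0)
        if lonely_c.size == 0 and lonely_p.size == 0:
            break
        for i in lonely_c:
            partners = np.flatnonzero(prot_block == chem_block[i])
            adjacency[i, rng.choice(partners)] = 1.0
        for j in lonely_p:
            partners = np.flatnonzero(chem_block == prot_block[j])
            adjacency[rng.choice(partners), j] = 1.0
    if (adjacency.sum(axis=1) == 0).any() or (adjacency.sum(axis=0) == 0).any():
        raise DataError("generator produced an empty node after bounded retries")

    lo, hi = config.potency_log_range
    affinities = 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=(n_c, n_p))
    weights = np.where(adjacency == 1, potency_to_weight(affinities), 0.0)

    # fingerprints: block-owned bits on with high probability, noise elsewhere
    bit_block = np.full(config.fingerprint_length, -1)
    for b in range(n_b):
        bit_block[b * config.bits_per_block : (b + 1) * config.bits_per_block] = b
    on_prob = np.where(
        bit_block[None, :] == chem_block[:, None],
        config.block_bit_on_prob,
        config.noise_bit_on_prob,
    )
    bits = (rng.random((n_c, config.fingerprint_length)) < on_prob).astype(np.uint8)
    # guarantee at least one on-bit per compound (all-zero fingerprints are invalid)
    for i in np.flatnonzero(bits.sum(axis=1) == 0):
        owned = np.flatnonzero(bit_block == chem_block[i])
        bits[i, rng.choice(owned)] = 1
    fingerprints = FingerprintSet(ids=chem_ids, bits=bits)

    # sequences: block-conserved segment inside random residues
    motifs = [
        "".join(rng.choice(AMINO_ACIDS, size=config.conserved_segment_length))
        for _ in range(n_b)
    ]
    sequences: dict[str, str] = {}
    for j, pid in enumerate(prot_ids):
        seq = rng.choice(AMINO_ACIDS, size=config.sequence_length)
        start = int(rng.integers(0, config.sequence_length - config.conserved_segment_length + 1))
        seq = "".join(seq)
        motif = motifs[prot_block[j]]
        sequences[pid] = seq[:start] + motif + seq[start + len(motif):]

    # hold out whole chemicals whose removal leaves every protein connected
    n_hold = int(config.heldout_fraction * n_c)
    held_out: list[int] = []
    if n_hold:
        col_deg = adjacency.sum(axis=0).copy()
        for i in rng.permutation(n_c):
            if len(held_out) == n_hold:
                break
            row = adjacency[i]
            if ((col_deg - row) >= 1).all():
                held_out.append(int(i))
                col_deg -= row
    held_mask = np.zeros(n_c, dtype=bool)
    held_mask[held_out] = True
    held_out_pairs = [
        (chem_ids[i], prot_ids[j])
        for i in sorted(held_out)
        for j in np.flatnonzero(adjacency[i] == 1)
    ]
    network = BipartiteNetwork(
        chemical_ids=tuple(np.array(chem_ids)[~held_mask]),
        protein_ids=prot_ids,
        adjacency=adjacency[~held_mask],
        weights=weights[~held_mask],
    )
    return network, fingerprints, sequences, held_out_pairs


def degenerate_cases() -> list[BipartiteNetwork]:
    """Small edge-case networks for the invariant suite (all <= 6 nodes).

    Single edge; one hub protein (star); duplicate-profile chemicals; a
    chain whose leaf becomes isolated once its only link is masked.
    """
    single = BipartiteNetwork(
        ("c1",), ("p1",), np.array([[1.0]]), np.array([[1.0]])
    )
    star_adj = np.ones((4, 1))
    star = BipartiteNetwork(
        ("c1", "c2", "c3", "c4"), ("p1",), star_adj, star_adj * 2.0
    )
    dup_adj = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 1.0, 1.0]])
    duplicates = BipartiteNetwork(
        ("c1", "c2", "c3"), ("p1", "p2", "p3"), dup_adj, dup_adj * 1.5
    )
    chain_adj = np.array([[1.0, 1.0], [0.0, 1.0]])
    chain = BipartiteNetwork(
        ("c1", "c2"), ("p1", "p2"), chain_adj, chain_adj * 3.0
    )
    return [single, star, duplicates, chain]
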