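"""Explicit edge-by-edge resource-passing simulator.

Independent oracle for the matrix-form diffusion scorers: walks the two
allocation steps per query chemical with Python dicts and per-edge shares.
Deliberately naive (quadratic loops) so it cannot share a defect with the
linear-algebra implementation it checks.
"""

import numpy as np


def simulate_two_step(network, *, lam=None, beta=None, apply_at="both"):
    """Return the full score matrix by explicit per-edge simulation.

    ``lam`` set -> edge-weighted diffusion with values w**lam (initial
    resource and allocation shares); ``beta`` set -> receiver-degree**beta
    preferential allocation at the steps named by ``apply_at``; neither ->
    plain equal-split diffusion.
    """
    adjacency = network.adjacency
    weights = network.weights
    n_chem, n_prot = adjacency.shape
    chem_deg = adjacency.sum(axis=1)
    prot_deg = adjacency.sum(axis=0)

    def edge_value(i, j):
        if lam is None:
            return 1.0
        return weights[i, j] ** lam

    scores = np.zeros((n_chem, n_prot))
    for q in range(n_chem):
        resource_p = {
            j: edge_value(q, j) if adjacency[q, j] == 1 else 0.0 for j in range(n_prot)
        }
        resource_c = {i: 0.0 for i in range(n_chem)}
        for j in range(n_prot):
            amount = resource_p[j]
            if amount == 0.0:
                continue
            neighbours = [i for i in range(n_chem) if adjacency[i, j] == 1]
            if not neighbours:
                continue
            if beta is not None and apply_at in ("step1", "both"):
                shares = np.array([chem_deg[i] ** beta for i in neighbours])
            elif lam is not None:
                shares = np.array([edge_value(i, j) for i in neighbours])
            else:
                shares = np.ones(len(neighbours))
            shares = shares / shares.sum()
            for i, share in zip(neighbours, shares):
                resource_c[i] += amount * share
        for i in range(n_chem):
            amount = resource_c[i]
            if amount == 0.0:
                continue
            neighbours = [j for j in range(n_prot) if adjacency[i, j] == 1]
            if not neighbours:
                continue
            if beta is not None and apply_at in ("step2", "both"):
                shares = np.array([prot_deg[j] ** beta for j in neighbours])
            elif lam is not None:
                shares = np.array([edge_value(i, j) for j in neighbours])
            else:
                shares = np.ones(len(neighbours))
            shares = shares / shares.sum()
            for j, share in zip(neighbours, shares):
                scores[q, j] += amount * share
    return scores
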