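"""Naive per-edge-loop evaluation of the message-passing model.

This mirrors the mathematical definition directly with Python dictionaries
and explicit loops over edges, neighbours, and atoms — no segment sums, no
reverse-edge arithmetic, no batching.  It exists as an independent oracle
for the vectorised implementation in :mod:`rxnbarrier.dmpnn` and is far
too slow for training.
"""

from __future__ import annotations

import numpy as np

from .dmpnn import ModelConfig, ModelState
from .reaction_graph import CondensedGraph


def _relu(v):
    return np.maximum(v, 0.0)


def naive_forward(
    cgr: CondensedGraph,
    atom_extras: np.ndarray | None,
    config: ModelConfig,
    state: ModelState,
) -> float:
    """Predicted barrier (kcal/mol) for one reaction, evaluated naively."""
    p = state.params
    n = cgr.n_atoms

    # per-atom auxiliary block
    proc = None
    if config.extra_route != "none" and atom_extras is not None and atom_extras.shape[1]:
        if config.extra_route == "route2_plain":
            proc = np.array(atom_extras, dtype=float)
        else:
            proc = np.stack([_relu(atom_extras[i] @ p["W_e"] + p["b_e"]) for i in range(n)])
            if config.extra_route == "route1_linear_relu_attention":
                d = config.extra_embed_dim
                q = np.stack([proc[i] @ p["W_q"] + p["b_q"] for i in range(n)])
                k = np.stack([proc[i] @ p["W_k"] + p["b_k"] for i in range(n)])
                v = np.stack([proc[i] @ p["W_v"] + p["b_v"] for i in range(n)])
                att_out = np.zeros_like(proc)
                for i in range(n):
                    scores = np.array([q[i] @ k[j] / np.sqrt(d) for j in range(n)])
                    scores = np.exp(scores - scores.max())
                    w = scores / scores.sum()
                    att_out[i] = sum(w[j] * v[j] for j in range(n))
                proc = proc + att_out

    x = {i: np.array(cgr.atom_features[i], dtype=float) for i in range(n)}
    if proc is not None and config.extra_placement == "before_mpnn":
        x = {i: np.concatenate([x[i], proc[i]]) for i in range(n)}

    # directed edges with bond features per undirected edge
    edges: list[tuple[int, int]] = []
    bond_of: dict[tuple[int, int], np.ndarray] = {}
    neighbours: dict[int, list[int]] = {i: [] for i in range(n)}
    for k_idx, (i, j) in enumerate(cgr.edge_list):
        for (a, b) in ((i, j), (j, i)):
            edges.append((a, b))
            bond_of[(a, b)] = np.array(cgr.bond_features[k_idx], dtype=float)
        neighbours[i].append(j)
        neighbours[j].append(i)

    h0 = {}
    for (v, w) in edges:
        e_vw = np.concatenate([x[v], bond_of[(v, w)]])
        h0[(v, w)] = e_vw @ p["W_i"] + p["b_i"]

    h = dict(h0)
    for _ in range(config.depth):
        new = {}
        for (v, w) in edges:
            msg = np.zeros(config.hidden_dim)
            for k in neighbours[v]:
                if k != w:
                    msg = msg + h[(k, v)]
            new[(v, w)] = _relu(h0[(v, w)] + msg @ p["W_h"] + p["b_h"])
        h = new

    hv = {}
    for v in range(n):
        inc = np.zeros(config.hidden_dim)
        for k in neighbours[v]:
            inc = inc + h[(k, v)]
        q = np.concatenate([x[v], inc])
        hv[v] = _relu(q @ p["W_o"] + p["b_o"])

    if proc is not None and config.extra_placement == "after_mpnn":
        hv = {v: np.concatenate([hv[v], proc[v]]) for v in range(n)}

    stacked = [hv[v] for v in range(n)]
    hm = sum(stacked) / n if config.pooling == "mean" else sum(stacked)
    if cgr.mol_extra.size:
        hm = np.concatenate([hm, cgr.mol_extra])

    out = hm
    for i in range(config.ffn_layers):
        out = out @ p[f"W_f{i}"] + p[f"b_f{i}"]
        if i < config.ffn_layers - 1:
            out = _relu(out)
    return float(out[0]) * state.target_std + state.target_mean
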