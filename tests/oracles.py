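"""Independent reference implementations used only to check the package.

Each oracle is written from the textbook definition of the quantity it
computes, deliberately sharing no code with the implementation under test.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy import linalg
from scipy.special import expit


def firth_logistic_oracle(y: np.ndarray, X: np.ndarray, tol: float = 1e-12, max_iter: int = 500) -> np.ndarray:
    """Firth-penalized logistic regression by plain Newton iteration.

    Modified score U*(b) = X'(y - mu + h (1/2 - mu)) with h the hat
    diagonals of W^{1/2} X (X'WX)^{-1} X' W^{1/2}.
    """
    b = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = expit(X @ b)
        w = mu * (1 - mu)
        WX = np.sqrt(w)[:, None] * X
        F = WX.T @ WX
        Finv = linalg.inv(F)
        h = np.einsum("ij,jk,ik->i", WX, Finv, WX)
        U = X.T @ (y - mu + h * (0.5 - mu))
        step = Finv @ U
        b = b + step
        if np.abs(step).max() < tol:
            break
    return b


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up, the brute-force way.

    Sort, scale p_(i) by m/i, then enforce monotonicity by a running
    minimum taken from the largest p downwards; cap at 1.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    running = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(running, 1.0)
    return adj


def patristic_oracle(tree) -> tuple[list[str], np.ndarray]:
    """Tip-tip path lengths via networkx all-pairs Dijkstra on the tree graph."""
    G = nx.Graph()
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            G.add_edge(id(node.parent_node), id(node), weight=node.edge.length or 0.0)
    leaves = tree.leaf_nodes()
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    D = np.zeros((n, n))
    for i, a in enumerate(leaves):
        lengths = nx.single_source_dijkstra_path_length(G, id(a))
        for j, b in enumerate(leaves):
            if i != j:
                D[i, j] = lengths[id(b)]
    return labels, D
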