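"""Phenotype similarity structures: correlation networks and NJ trees.

Two views of between-portrait similarity:

* the **correlation network** connects portrait pairs whose Pearson
  correlation exceeds a threshold (default 0.5); constant portraits
  have undefined correlation and are kept as isolated, flagged nodes.
* the **phenotype tree** is a neighbor-joining tree on the distance
  d(i, j) = 1 − r(i, j), so anti-correlated phenotypes are maximally
  distant.  The same operation serves all three resolution levels —
  individual samples, subtype means and PAT means — by feeding it the
  corresponding portrait list.  Negative NJ branch lengths are clamped
  to zero.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .som import Portrait

__all__ = ["correlation_network", "phenotype_tree", "tree_to_newick"]


def _correlation_matrix(portraits: list[Portrait]) -> tuple[np.ndarray, np.ndarray]:
    V = np.vstack([p.values for p in portraits])
    sd = V.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(V)
    return R, constant


def correlation_network(
    portraits: list[Portrait],
    threshold: float = 0.5,
    classes: dict | None = None,
) -> nx.Graph:
    """Graph with an edge wherever portrait correlation exceeds threshold.

    Node attributes: ``cls`` (optional class label) and ``constant``
    (True for flat portraits, which carry no edges).  Edge attribute
    ``weight`` holds the Pearson correlation.
    """
    if len(portraits) < 2:
        raise ValueError("at least two portraits required")
    if not -1.0 < threshold < 1.0:
        raise ValueError("threshold must be in (-1, 1)")
    ids = [p.sample_or_group_id for p in portraits]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate portrait ids")
    R, constant = _correlation_matrix(portraits)
    g = nx.Graph()
    for i, pid in enumerate(ids):
        g.add_node(
            pid,
            cls=(classes or {}).get(pid, ""),
            constant=bool(constant[i]),
        )
    for i in range(len(ids)):
        if constant[i]:
            continue
        for j in range(i + 1, len(ids)):
            if constant[j]:
                continue
            if R[i, j] > threshold:
                g.add_edge(ids[i], ids[j], weight=float(R[i, j]))
    return g


def phenotype_tree(mean_portraits: list[Portrait], metric: str = "correlation"):
    """Neighbor-joining tree over portraits.

    ``metric`` is ``"correlation"`` (d = 1 − Pearson r, default) or
    ``"euclidean"``.  Returns a :class:`skbio.TreeNode`; serialize with
    :func:`tree_to_newick`.
    """
    if len(mean_portraits) < 3:
        raise ValueError("neighbor joining needs at least three portraits")
    ids = [p.sample_or_group_id for p in mean_portraits]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate portrait ids")
    V = np.vstack([p.values for p in mean_portraits])
    if metric == "correlation":
        R, constant = _correlation_matrix(mean_portraits)
        if constant.any():
            flat = [ids[i] for i in np.flatnonzero(constant)]
            raise ValueError(f"constant portraits have no correlation: {flat}")
        D = 1.0 - R
    elif metric == "euclidean":
        diff = V[:, None, :] - V[None, :, :]
        D = np.sqrt((diff**2).sum(axis=2))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # enforce exact symmetry for skbio

    from skbio import DistanceMatrix
    from skbio.tree import nj

    tree = nj(DistanceMatrix(D, ids))
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        import logging

        logging.getLogger(__name__).info(
            "clamped %d negative NJ branch lengths to 0", clamped
        )
    return tree


def tree_to_newick(tree) -> str:
    import io

    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
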