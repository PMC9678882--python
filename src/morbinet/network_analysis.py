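"""Centrality description and fast-greedy community detection.

Edge weights enter all graph measures through their absolute value
(modularity is undefined for negative weights). Shortest-path measures use
edge length 1/|w|, so strong partial associations are short. Communities
are found by agglomerative greedy modularity optimization: starting from
singletons, repeatedly merge the community pair with the largest modularity
gain (ties broken lexicographically, making runs bit-reproducible), and
return the partition attaining the maximum recorded modularity. The
resulting communities are the "multimorbidity patterns" MP1..MPm, labelled
by decreasing size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from morbinet.mgm import MGMNetwork


def _abs_weights(network: Union[MGMNetwork, np.ndarray]) -> np.ndarray:
    w = network.weights if isinstance(network, MGMNetwork) else np.asarray(network, float)
    return np.abs(w)


def _node_names(network, p: int) -> list[str]:
    if isinstance(network, MGMNetwork):
        return network.node_names
    return [f"v{i + 1}" for i in range(p)]


def _graph(A: np.ndarray) -> nx.Graph:
    G = nx.Graph()
    p = A.shape[0]
    G.add_nodes_from(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            if A[i, j] > 0:
                G.add_edge(i, j, weight=A[i, j], length=1.0 / A[i, j])
    return G


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.full_like(x, np.nan)
    return (x - x.mean()) / sd


def centralities(network: Union[MGMNetwork, np.ndarray]) -> pd.DataFrame:
    """Degree, strength, closeness and betweenness per node, raw and z-scored.

    Degree counts incident edges; strength sums absolute weights. Closeness
    is 1 / (sum of shortest-path distances to reachable nodes), with
    unreachable pairs excluded; betweenness counts weighted shortest paths
    through the node with fractional credit for ties. Distances use edge
    length 1/|w|.
    """
    A = _abs_weights(network)
    p = A.shape[0]
    if p < 2:
        raise ValueError("need at least 2 nodes")
    G = _graph(A)
    degree = np.array([G.degree(i) for i in range(p)], dtype=float)
    strength = A.sum(axis=1)
    closeness = np.zeros(p)
    for i in range(p):
        dist = nx.single_source_dijkstra_path_length(G, i, weight="length")
        total = sum(d for j, d in dist.items() if j != i)
        closeness[i] = 1.0 / total if total > 0 else 0.0
    btw = nx.betweenness_centrality(G, weight="length", normalized=False)
    betweenness = np.array([btw[i] for i in range(p)])
    out = pd.DataFrame(
        {
            "node": np.arange(1, p + 1),
            "name": _node_names(network, p),
            "degree": degree,
            "strength": strength,
            "closeness": closeness,
            "betweenness": betweenness,
        }
    )
    for col in ("degree", "strength", "closeness", "betweenness"):
        out[f"z_{col}"] = _zscore(out[col].to_numpy())
    return out


def modularity(
    network: Union[MGMNetwork, np.ndarray], membership: Sequence[int]
) -> float:
    """Newman weighted modularity of a partition on absolute weights.

    Q = sum_ij [A_ij/(2m) - s_i s_j/(2m)^2] delta(c_i, c_j), with
    A = |weights|, s the node strengths and m the total edge weight.
    """
    A = _abs_weights(network)
    membership = np.asarray(membership)
    if membership.shape[0] != A.shape[0]:
        raise ValueError("membership must cover all nodes")
    m2 = A.sum()  # = 2m
    if m2 == 0:
        raise ValueError("modularity undefined for an empty graph")
    s = A.sum(axis=1)
    same = membership[:, None] == membership[None, :]
    return float((A[same].sum() / m2) - ((np.outer(s, s)[same]).sum() / m2**2))


@dataclass
class CommunityPartition:
    """A node partition with its modularity and the greedy merge history."""

    membership: np.ndarray  # community label per node, contiguous from 1
    modularity: float
    merge_history: list[tuple[int, int, float, float]] = field(default_factory=list)
    node_names: Optional[list[str]] = None

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.membership))

    def members(self, label: int) -> list[int]:
        return np.flatnonzero(self.membership == label).tolist()

    def sizes(self) -> dict[int, int]:
        labels, counts = np.unique(self.membership, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def fast_greedy_communities(
    network: Union[MGMNetwork, np.ndarray]
) -> CommunityPartition:
    """Agglomerative greedy modularity maximization (CNM).

    Start from singletons; at each step merge the community pair with the
    maximal modularity gain (ties: the lexicographically smallest pair of
    community representatives, a representative being the smallest member
    index); record Q after each merge; return the first partition attaining
    the maximum recorded Q. Isolated nodes stay singleton communities.
    """
    A = _abs_weights(network)
    p = A.shape[0]
    m2 = A.sum()
    if m2 == 0:
        raise ValueError("community detection needs at least one edge")
    # M[c][d] = sum over ordered pairs (i in c, j in d) of A_ij / (2m)
    M = A / m2
    a = M.sum(axis=1)
    comms: dict[int, list[int]] = {i: [i] for i in range(p)}
    active = sorted(comms)
    Q = float(np.trace(M) - (a @ a))
    best_Q = Q
    best_partition = {c: list(v) for c, v in comms.items()}
    history: list[tuple[int, int, float, float]] = []
    while len(active) > 1:
        # pairs are scanned in lexicographic order of representatives, so a
        # strict > keeps the lexicographically smallest pair on ties
        best_gain = -np.inf
        best_pair = None
        for ci_idx, c in enumerate(active):
            for d in active[ci_idx + 1 :]:
                gain = 2.0 * (M[c, d] - a[c] * a[d])
                if gain > best_gain + 1e-15:
                    best_gain = gain
                    best_pair = (c, d)
        c, d = best_pair
        # merge d into c (c < d keeps the smallest representative)
        M[c, :] += M[d, :]
        M[:, c] += M[:, d]
        M[d, :] = 0.0
        M[:, d] = 0.0
        a[c] += a[d]
        a[d] = 0.0
        comms[c].extend(comms[d])
        del comms[d]
        active.remove(d)
        Q += best_gain
        history.append((c, d, float(best_gain), float(Q)))
        if Q > best_Q + 1e-12:
            best_Q = Q
            best_partition = {k: list(v) for k, v in comms.items()}
    membership = np.zeros(p, dtype=int)
    # labels contiguous from 1, ordered by smallest member index
    for label, rep in enumerate(sorted(best_partition), start=1):
        membership[best_partition[rep]] = label
    names = _node_names(network, p)
    return CommunityPartition(
        membership=membership,
        modularity=float(modularity(A, membership)),
        merge_history=history,
        node_names=names,
    )


def label_patterns(
    partition: CommunityPartition, names: Optional[dict[str, str]] = None
) -> pd.DataFrame:
    """Map communities to multimorbidity-pattern labels MP1..MPm.

    Patterns are ordered by community size (descending), ties by smallest
    member index. Optional ``names`` maps MP labels to user-supplied
    pattern names.
    """
    sizes = partition.sizes()
    order = sorted(
        sizes,
        key=lambda label: (-sizes[label], min(partition.members(label))),
    )
    mp_of = {label: f"MP{rank}" for rank, label in enumerate(order, start=1)}
    rows = []
    for node in range(len(partition.membership)):
        label = int(partition.membership[node])
        mp = mp_of[label]
        rows.append(
            {
                "node": node + 1,
                "name": partition.node_names[node]
                if partition.node_names
                else f"v{node + 1}",
                "community": label,
                "pattern": mp,
                "pattern_name": (names or {}).get(mp, mp),
            }
        )
    return pd.DataFrame(rows)
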