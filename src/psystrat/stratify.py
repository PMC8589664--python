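"""From Mapper graph to patient groups A/B/C.

Connected components of the Mapper graph are the coarse structure; small
components (fewer distinct patients than a threshold) are excluded, and
their patients left unassigned.  If fewer components than the requested
number of groups survive, the largest component is split — an automated
stand-in for drawing a boundary on the graph by eye.  The default split
is a normalized-cut spectral bisection (sign of the Fiedler vector of the
shared-member-weighted graph Laplacian), which severs the narrow neck
between the two halves of the component.  Girvan-Newman edge-betweenness
removal is available as an alternative; on the dense, highly overlapping
graphs produced by high gain it tends to shave off peripheral nodes
instead of cutting the neck, so it is not the default.  Patients are then
labeled by majority vote over the nodes that contain them, with exact
ties left unassigned.

Group naming is data-anchored so labels are comparable across cohorts:
the group with the highest mean positive-factor score is B; of the
remaining two, the higher mean negative-factor score is C and the lower
is A (B = high positive/excited symptoms, C = high negative symptoms,
A = overall mild symptoms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .characterize import GROUP_LABELS, UNASSIGNED, wallwork_factors

logger = logging.getLogger(__name__)


@dataclass
class StratifyConfig:
    min_component_patients: int = 5
    n_groups: int = 3
    split_method: str = "spectral"  # or "edge_betweenness" / "manual"
    manual_cut: list[list] | None = None

    def __post_init__(self) -> None:
        if self.min_component_patients < 1:
            raise ValueError("min_component_patients must be >= 1")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.split_method not in ("spectral", "edge_betweenness", "manual"):
            raise ValueError(f"unknown split method {self.split_method!r}")


@dataclass
class GroupAssignment:
    """Patient -> group label plus the node provenance of each label."""

    labels: pd.Series  # index = patient row index, values in {A,B,C,unassigned}
    node_groups: dict = field(default_factory=dict)  # node -> group label
    provenance: dict = field(default_factory=dict)  # patient index -> contributing nodes
    excluded_nodes: set = field(default_factory=set)

    def counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()


def _component_patients(graph: nx.Graph, nodes) -> set[int]:
    patients: set[int] = set()
    for node in nodes:
        patients |= graph.nodes[node]["members"]
    return patients


def extract_components(graph: nx.Graph, min_component_patients: int = 5):
    """Connected components ordered by descending distinct-patient count.

    Returns ``(retained, excluded_nodes)`` where ``retained`` is a list of
    node sets and ``excluded_nodes`` the union of nodes in components with
    fewer distinct patients than the threshold.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = [set(c) for c in nx.connected_components(graph)]
    sized = [(len(_component_patients(graph, c)), sorted(c)[0], c) for c in comps]
    sized.sort(key=lambda t: (-t[0], t[1]))
    retained, excluded = [], set()
    for n_pat, _, comp in sized:
        if n_pat < min_component_patients:
            excluded |= comp
        else:
            retained.append(comp)
    return retained, excluded


def split_component(
    graph: nx.Graph,
    component: set,
    k: int,
    method: str = "spectral",
    manual_cut: list[list] | None = None,
) -> list[set]:
    """Partition one connected component's nodes into k groups of nodes."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(component):
        raise ValueError(f"cannot split {len(component)} nodes into {k} parts")
    if method == "manual":
        if manual_cut is None:
            raise ValueError("manual split requires manual_cut")
        parts = [set(map(tuple_if_list, p)) for p in manual_cut]
        union = set().union(*parts)
        if union != set(component) or sum(len(p) for p in parts) != len(union):
            raise ValueError("manual_cut is not a partition of the component")
        return parts
    if method == "spectral":
        parts = [set(component)]
        while len(parts) < k:
            parts.sort(key=lambda p: (-len(_component_patients(graph, p)), sorted(p)[0]))
            target = parts.pop(0)
            parts = _spectral_bisect(graph, target) + parts
        parts.sort(key=lambda p: (-len(_component_patients(graph, p)), sorted(p)[0]))
        return parts
    if method != "edge_betweenness":
        raise ValueError(f"unknown split method {method!r}")

    H = graph.subgraph(component).copy()
    while nx.number_connected_components(H) < k:
        order = _betweenness_order(H)
        # minimal prefix of the descending-betweenness order whose removal
        # reaches k components (bisection); recompute betweenness if even
        # removing every edge in this round is not enough
        lo, hi = 1, len(order)
        if _components_after_removal(H, order) < k:
            H.remove_edges_from(order)
            continue
        while lo < hi:
            mid = (lo + hi) // 2
            if _components_after_removal(H, order[:mid]) >= k:
                hi = mid
            else:
                lo = mid + 1
        H.remove_edges_from(order[:lo])
    parts = [set(c) for c in nx.connected_components(H)]
    parts.sort(key=lambda p: (-len(_component_patients(graph, p)), sorted(p)[0]))
    return parts


def _components_after_removal(H: nx.Graph, edges: list) -> int:
    G = H.copy()
    G.remove_edges_from(edges)
    return nx.number_connected_components(G)


def _betweenness_order(H: nx.Graph) -> list:
    """Edges sorted by descending exact betweenness (ties: lexicographically
    smallest edge first).  Large graphs go through igraph's C routine."""
    if H.number_of_edges() == 0:
        return []
    if H.number_of_nodes() <= 60:
        btw = nx.edge_betweenness_centrality(H)
        items = {tuple(sorted(e)): v for e, v in btw.items()}
    else:
        import igraph as ig

        nodes = sorted(H.nodes)
        index = {n: i for i, n in enumerate(nodes)}
        edges = [tuple(sorted(e)) for e in H.edges]
        g = ig.Graph(n=len(nodes), edges=[(index[u], index[v]) for u, v in edges])
        values = g.edge_betweenness()
        items = dict(zip(edges, values))
    return sorted(items, key=lambda e: (-items[e], e))


def _spectral_bisect(graph: nx.Graph, component: set) -> list[set]:
    """Normalized-cut bisection of one connected component.

    Computes the Fiedler vector of the symmetric normalized Laplacian of
    the shared-member-weighted subgraph and splits nodes by its sign
    (falling back to a median split if the sign split is degenerate).
    Deterministic: fixed eigensolver starting vector, dense solve on
    small components.
    """
    import scipy.sparse as sp
    import scipy.sparse.linalg as spl

    nodes = sorted(component)
    m = len(nodes)
    if m < 2:
        raise ValueError("cannot bisect a single-node component")
    if m == 2:
        return [{nodes[0]}, {nodes[1]}]
    idx = {n: i for i, n in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for u, v, d in graph.subgraph(component).edges(data=True):
        w = float(d.get("shared", 1))
        rows += [idx[u], idx[v]]
        cols += [idx[v], idx[u]]
        vals += [w, w]
    W = sp.csr_matrix((vals, (rows, cols)), shape=(m, m))
    deg = np.asarray(W.sum(axis=1)).ravel()
    dinv = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    L = sp.eye(m) - sp.diags(dinv) @ W @ sp.diags(dinv)
    if m <= 200:
        evals, evecs = np.linalg.eigh(L.toarray())
        fiedler = evecs[:, np.argsort(evals)[1]]
    else:
        v0 = np.ones(m) + 1e-3 * np.sin(np.arange(m))
        evals, evecs = spl.eigsh(L, k=2, sigma=-1e-5, which="LM", v0=v0)
        fiedler = evecs[:, np.argsort(evals)[1]]
    f = fiedler * dinv  # back to the random-walk eigenvector
    if f[np.argmax(np.abs(f))] < 0:
        f = -f
    side = f >= 0
    if side.all() or not side.any():
        side = f >= np.median(f)
    part1 = {nodes[i] for i in range(m) if side[i]}
    part2 = set(nodes) - part1
    if not part2:
        part1 = set(nodes[: m // 2])
        part2 = set(nodes[m // 2:])
    return [part1, part2]


def tuple_if_list(x):
    return tuple(x) if isinstance(x, list) else x


def name_groups(graph: nx.Graph, parts: list[set], symptoms: np.ndarray) -> dict:
    """Assign A/B/C names to node-set parts from their symptom profiles.

    B = highest mean positive-factor score; of the rest, C = higher mean
    negative-factor score, A = lower.  With more or fewer than three parts
    the remaining names are taken in order of descending positive score.
    """
    factors = wallwork_factors(np.asarray(symptoms, dtype=float))
    stats = []
    for part in parts:
        pats = sorted(_component_patients(graph, part))
        stats.append(
            (float(factors.loc[pats, "positive"].mean()), float(factors.loc[pats, "negative"].mean()))
        )
    order = sorted(range(len(parts)), key=lambda i: -stats[i][0])
    naming: dict[int, str] = {}
    if len(parts) == 3:
        naming[order[0]] = "B"
        rest = order[1:]
        rest.sort(key=lambda i: -stats[i][1])
        naming[rest[0]] = "C"
        naming[rest[1]] = "A"
    else:
        for rank, idx in enumerate(order):
            naming[idx] = GROUP_LABELS[rank] if rank < len(GROUP_LABELS) else f"G{rank}"
    node_groups = {}
    for idx, part in enumerate(parts):
        for node in part:
            node_groups[node] = naming[idx]
    return node_groups


def assign_patients(graph: nx.Graph, node_groups: dict) -> GroupAssignment:
    """Majority vote over a patient's containing nodes; ties unassigned."""
    n = graph.graph.get("n_patients")
    if n is None:
        n = len(_component_patients(graph, graph.nodes))
    votes: dict[int, dict[str, int]] = {}
    provenance: dict[int, list] = {}
    for node, data in graph.nodes(data=True):
        group = node_groups.get(node)
        for pat in data["members"]:
            provenance.setdefault(pat, []).append(node)
            if group is not None:
                votes.setdefault(pat, {}).setdefault(group, 0)
                votes[pat][group] += 1
    labels = pd.Series(UNASSIGNED, index=pd.RangeIndex(n), dtype=object)
    for pat, counts in votes.items():
        top = max(counts.values())
        winners = [g for g, c in counts.items() if c == top]
        if len(winners) == 1:
            labels[pat] = winners[0]
    excluded = {node for node in graph.nodes if node not in node_groups}
    return GroupAssignment(labels=labels, node_groups=dict(node_groups),
                           provenance=provenance, excluded_nodes=excluded)


def stratify(graph: nx.Graph, symptoms: np.ndarray, config: StratifyConfig | None = None) -> GroupAssignment:
    """Full stratification: components -> (splits) -> naming -> assignment."""
    config = config or StratifyConfig()
    retained, excluded = extract_components(graph, config.min_component_patients)
    if len(retained) > config.n_groups:
        logger.warning(
            "%d components retained but only %d groups requested; smallest %d excluded",
            len(retained), config.n_groups, len(retained) - config.n_groups,
        )
        for comp in retained[config.n_groups:]:
            excluded |= comp
        retained = retained[: config.n_groups]
    parts = list(retained)
    if config.split_method == "manual" and config.manual_cut is not None:
        # manual cut applies to the largest component
        largest = parts.pop(0)
        parts = split_component(graph, largest, len(config.manual_cut), "manual", config.manual_cut) + parts
    else:
        while len(parts) < config.n_groups:
            parts.sort(key=lambda p: -len(_component_patients(graph, p)))
            largest = parts.pop(0)
            parts = split_component(graph, largest, 2, config.split_method) + parts
    node_groups = name_groups(graph, parts, symptoms)
    assignment = assign_patients(graph, node_groups)
    assignment.excluded_nodes |= excluded
    return assignment


def boundary_nodes(graph: nx.Graph, node_groups: dict, a: str = "B", b: str = "C") -> list:
    """Nodes of groups a/b adjacent to the other group, in deterministic order."""
    out = []
    for node in sorted(n for n in graph.nodes if node_groups.get(n) in (a, b)):
        mine = node_groups[node]
        other = b if mine == a else a
        if any(node_groups.get(nb) == other for nb in graph.neighbors(node)):
            out.append(node)
    return out


def boundary_sensitivity(
    graph: nx.Graph,
    symptoms: np.ndarray,
    node_groups: dict,
    shift: int = 5,
    metrics=None,
) -> list[dict]:
    """Stability of group profiles under one-node boundary reassignments.

    Each entry flips one B/C boundary node to the other group, reassigns
    patients, and records the per-group factor-score means (plus any extra
    ``metrics(labels)`` output).  The first entry (``flipped=None``) is the
    unperturbed baseline.
    """
    factors = wallwork_factors(np.asarray(symptoms, dtype=float))

    def profile(labels: pd.Series) -> dict:
        out = {}
        for g in GROUP_LABELS:
            idx = labels.index[labels == g]
            if len(idx):
                out[g] = {f: float(factors.loc[idx, f].mean()) for f in factors.columns}
        return out

    base = assign_patients(graph, node_groups)
    rows = [{"flipped": None, "labels": base.labels, "profiles": profile(base.labels)}]
    if metrics is not None:
        rows[0]["metrics"] = metrics(base.labels)
    boundary = boundary_nodes(graph, node_groups)
    if not boundary:
        logger.warning("no B/C boundary found; sensitivity report is empty")
        return rows
    for node in boundary[:shift]:
        flipped = dict(node_groups)
        flipped[node] = "C" if node_groups[node] == "B" else "B"
        assign = assign_patients(graph, flipped)
        row = {"flipped": node, "labels": assign.labels, "profiles": profile(assign.labels)}
        if metrics is not None:
            row["metrics"] = metrics(assign.labels)
        rows.append(row)
    return rows
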