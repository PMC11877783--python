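"""VAF-constraint lineage-tree reconstruction.

A deliberately simplified reimplementation of the containment logic used by
longitudinal lineage-tree tools: variants are first partitioned by their exact
presence profile across samples, then merged by single linkage on per-sample
VAF distance; clusters are ordered into a rooted tree under the standard
containment condition (an ancestor's VAF must be at least each descendant's,
in every sample, up to a tolerance) with nearest-ancestor parent selection and
a per-parent sum-rule check over disjoint children. Constraint violations are
reported on the tree, never silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import networkx as nx
import pandas as pd

from .presence import Presence

ROOT = "ROOT"


@dataclass(frozen=True)
class VariantCluster:
    """A set of variants with one shared presence profile and tight VAFs.

    cluster_id is the lexicographically smallest member key; mean_vaf and
    presence are per-sample (sample name -> value).
    """

    cluster_id: str
    members: tuple[str, ...]
    mean_vaf: Mapping[str, float]
    presence: Mapping[str, Presence]

    @property
    def total_vaf(self) -> float:
        return sum(self.mean_vaf.values())

    def present_in(self, sample: str) -> bool:
        return self.presence[sample] is Presence.PRESENT


class _UnionFind:
    def __init__(self, items: Sequence[str]) -> None:
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller key becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def cluster_variants_by_vaf(
    vaf: pd.DataFrame,
    presence: pd.DataFrame,
    tol: float = 0.05,
) -> list[VariantCluster]:
    """Group variants by exact presence profile, then single-linkage on VAF.

    ``vaf`` and ``presence`` are variant-by-sample frames with identical
    indices/columns. Two variants join only if they share the full three-state
    presence profile and are connected through pairs whose maximum per-sample
    VAF distance is <= tol.
    """
    if not 0 < tol <= 0.2:
        raise ValueError(f"tol must be in (0, 0.2], got {tol}")
    if list(vaf.index) != list(presence.index) or list(vaf.columns) != list(presence.columns):
        raise ValueError("vaf and presence frames must be aligned")
    samples = list(vaf.columns)

    profiles: dict[tuple, list[str]] = {}
    for key in sorted(vaf.index):
        profile = tuple(Presence(presence.at[key, s]) for s in samples)
        profiles.setdefault(profile, []).append(key)

    clusters: list[VariantCluster] = []
    for profile, keys in profiles.items():
        uf = _UnionFind(keys)
        for a, b in combinations(keys, 2):
            dist = max(abs(vaf.at[a, s] - vaf.at[b, s]) for s in samples)
            if dist <= tol:
                uf.union(a, b)
        groups: dict[str, list[str]] = {}
        for k in keys:
            groups.setdefault(uf.find(k), []).append(k)
        for members in groups.values():
            members = tuple(sorted(members))
            mean_vaf = {s: float(vaf.loc[list(members), s].mean()) for s in samples}
            clusters.append(
                VariantCluster(
                    cluster_id=members[0],
                    members=members,
                    mean_vaf=mean_vaf,
                    presence=dict(zip(samples, profile)),
                )
            )
    return sorted(clusters, key=lambda c: c.cluster_id)


class MutationTree(Protocol):
    """Anything mapping mutations onto nodes of a rooted tree."""

    @property
    def mutation_nodes(self) -> Mapping[str, str]: ...

    def is_ancestor(self, node_a: str, node_b: str) -> bool: ...


class LineageTree:
    """Rooted cluster tree with a per-sample consistency report."""

    def __init__(
        self,
        graph: nx.DiGraph,
        clusters: Sequence[VariantCluster],
        tol: float,
        violations: list[dict],
    ) -> None:
        self.graph = graph
        self.clusters = {c.cluster_id: c for c in clusters}
        self.tol = tol
        self.violations = violations

    @property
    def is_consistent(self) -> bool:
        return not self.violations

    def parent(self, node: str) -> str | None:
        preds = list(self.graph.predecessors(node))
        return preds[0] if preds else None

    def children(self, node: str) -> list[str]:
        return sorted(self.graph.successors(node))

    @property
    def mutation_nodes(self) -> dict[str, str]:
        return {m: cid for cid, c in self.clusters.items() for m in c.members}

    def is_ancestor(self, node_a: str, node_b: str) -> bool:
        return node_a != node_b and nx.has_path(self.graph, node_a, node_b)

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {
                "parent": u,
                "child": v,
                "child_members": ",".join(self.clusters[v].members),
            }
            for u, v in sorted(self.graph.edges)
        ]
        return pd.DataFrame(rows, columns=["parent", "child", "child_members"])

    def _label(self, node: str) -> str:
        if node == ROOT:
            return ROOT
        return node.replace(":", "_").replace(">", "_").replace(",", "_").replace("(", "").replace(")", "")

    def _newick(self, node: str) -> str:
        kids = self.children(node)
        if not kids:
            return self._label(node)
        inner = ",".join(self._newick(k) for k in kids)
        return f"({inner}){self._label(node)}"

    def newick(self) -> str:
        return self._newick(ROOT) + ";"


def build_lineage_tree(
    clusters: Sequence[VariantCluster],
    tol: float = 0.05,
    root_vaf: float = 0.5,
) -> LineageTree:
    """Arrange clusters into a rooted tree under the containment condition.

    A cluster may parent another only if it is PRESENT wherever the child is
    PRESENT and its mean VAF is >= the child's minus tol in every sample.
    Among valid parents the nearest ancestor (smallest VAF excess summed over
    samples, ties broken lexicographically) wins; the germline root (VAF
    root_vaf everywhere) is always a candidate of last resort. After
    construction, containment and the pigeonhole sum rule
    (parent VAF + tol >= sum of children VAFs, per sample) are re-checked and
    violations reported on the returned tree.
    """
    if not clusters:
        raise ValueError("at least one cluster required")
    samples = list(next(iter(clusters)).mean_vaf)
    ordered = sorted(clusters, key=lambda c: (-c.total_vaf, c.cluster_id))

    graph = nx.DiGraph()
    graph.add_node(ROOT)
    violations: list[dict] = []

    placed: list[VariantCluster] = []
    for child in ordered:
        candidates: list[tuple[float, str]] = []
        for parent in placed:
            presence_ok = all(
                parent.present_in(s) for s in samples if child.present_in(s)
            )
            vaf_ok = all(
                parent.mean_vaf[s] >= child.mean_vaf[s] - tol for s in samples
            )
            if presence_ok and vaf_ok:
                excess = sum(parent.mean_vaf[s] - child.mean_vaf[s] for s in samples)
                candidates.append((excess, parent.cluster_id))
        root_ok = all(root_vaf >= child.mean_vaf[s] - tol for s in samples)
        if root_ok:
            candidates.append(
                (sum(root_vaf - child.mean_vaf[s] for s in samples), ROOT)
            )
        if candidates:
            _, parent_id = min(candidates)
        else:
            # no admissible parent at all: surface the infeasibility but keep
            # the node in the tree under the root so nothing is dropped
            parent_id = ROOT
            violations.append(
                {
                    "kind": "orphan",
                    "cluster": child.cluster_id,
                    "detail": "no parent satisfies containment; attached to root",
                }
            )
        graph.add_edge(parent_id, child.cluster_id)
        placed.append(child)

    by_id = {c.cluster_id: c for c in clusters}
    for node in graph.nodes:
        kids = [by_id[k] for k in graph.successors(node)]
        if not kids:
            continue
        for s in samples:
            parent_vaf = root_vaf if node == ROOT else by_id[node].mean_vaf[s]
            child_sum = sum(k.mean_vaf[s] for k in kids)
            if parent_vaf + tol < child_sum:
                violations.append(
                    {
                        "kind": "sum_rule",
                        "parent": node,
                        "sample": s,
                        "parent_vaf": parent_vaf,
                        "children_vaf_sum": child_sum,
                    }
                )
    return LineageTree(graph=graph, clusters=list(clusters), tol=tol, violations=violations)


def tree_concordance(inferred: MutationTree, truth: MutationTree) -> float:
    """Fraction of mutation pairs whose lineage relation agrees between trees.

    The relation of an ordered pair is one of: same node, ancestor, descendant,
    or neither (siblings/incomparable). Both trees must cover the same mutation
    set. A single-mutation tree has no pairs and scores 1.0.
    """
    keys_a = set(inferred.mutation_nodes)
    keys_b = set(truth.mutation_nodes)
    if keys_a != keys_b:
        raise ValueError(
            f"mutation sets differ: {sorted(keys_a ^ keys_b)[:5]}..."
            if keys_a ^ keys_b
            else "mutation sets differ"
        )

    def relation(tree: MutationTree, a: str, b: str) -> str:
        na, nb = tree.mutation_nodes[a], tree.mutation_nodes[b]
        if na == nb:
            return "same"
        if tree.is_ancestor(na, nb):
            return "ancestor"
        if tree.is_ancestor(nb, na):
            return "descendant"
        return "unrelated"

    pairs = list(combinations(sorted(keys_a), 2))
    if not pairs:
        return 1.0
    agree = sum(
        1 for a, b in pairs if relation(inferred, a, b) == relation(truth, a, b)
    )
    return agree / len(pairs)


def vaf_scatter(
    vaf: pd.DataFrame,
    sample_x: str,
    sample_y: str,
    categories: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Two-sample VAF scatter table (one row per variant), figure-ready.

    Mutations private to sample_x fall on the x-axis, private to sample_y on
    the y-axis, shared ones off-axis. Optionally annotates each point with its
    sharing category.
    """
    frame = pd.DataFrame(
        {
            "variant": vaf.index,
            "x_vaf": vaf[sample_x].to_numpy(),
            "y_vaf": vaf[sample_y].to_numpy(),
        }
    )
    frame["x_sample"] = sample_x
    frame["y_sample"] = sample_y
    if categories is not None:
        frame["category"] = frame["variant"].map(categories["category"]).fillna("")
    return frame
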