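"""Clustering, containment-tree construction, and pair-relation concordance."""

import pandas as pd
import pytest

from svztrace.lineage import (
    ROOT,
    build_lineage_tree,
    cluster_variants_by_vaf,
    tree_concordance,
    vaf_scatter,
)
from svztrace.presence import Presence, call_patient
from svztrace.sim import random_patient_spec, simulate_patient

S = ("SVZ", "PRIMARY", "RECURRENT")


def _frames(rows):
    """rows: key -> (vaf_triple, presence_triple as 'P'/'A'/'I')."""
    decode = {"P": Presence.PRESENT, "A": Presence.ABSENT, "I": Presence.INDETERMINATE}
    vaf = pd.DataFrame({s: {k: v[0][i] for k, v in rows.items()} for i, s in enumerate(S)})
    pres = pd.DataFrame(
        {s: {k: decode[v[1][i]].value for k, v in rows.items()} for i, s in enumerate(S)}
    )
    return vaf[list(S)], pres[list(S)]


class _TinyTree:
    """Hand-built rooted tree for oracle comparisons (node -> parent)."""

    def __init__(self, parents: dict, assignment: dict):
        self._parents = parents
        self.mutation_nodes = assignment

    def is_ancestor(self, a, b):
        cur = self._parents.get(b)
        while cur is not None:
            if cur == a:
                return True
            cur = self._parents.get(cur)
        return False


def test_identical_profiles_within_tol_merge():
    vaf, pres = _frames(
        {
            "v1": ((0.02, 0.40, 0.40), "PPP"),
            "v2": ((0.03, 0.42, 0.38), "PPP"),
            "v3": ((0.025, 0.44, 0.41), "PPP"),
        }
    )
    clusters = cluster_variants_by_vaf(vaf, pres, tol=0.05)
    assert len(clusters) == 1
    assert clusters[0].members == ("v1", "v2", "v3")


def test_disjoint_presence_profiles_never_merge():
    vaf, pres = _frames(
        {
            "v1": ((0.02, 0.40, 0.40), "PPP"),
            "v2": ((0.0, 0.40, 0.40), "APP"),
        }
    )
    assert len(cluster_variants_by_vaf(vaf, pres, tol=0.2)) == 2


def test_vaf_gap_splits_within_profile():
    vaf, pres = _frames(
        {
            "v1": ((0.0, 0.40, 0.0), "API"),
            "v2": ((0.0, 0.10, 0.0), "API"),
        }
    )
    assert len(cluster_variants_by_vaf(vaf, pres, tol=0.05)) == 2


def test_tol_validation():
    vaf, pres = _frames({"v1": ((0.1, 0.1, 0.1), "PPP")})
    with pytest.raises(ValueError):
        cluster_variants_by_vaf(vaf, pres, tol=0.5)


def test_gbm244_three_clusters_and_topology(gbm244_presence):
    """Worked example: trunk cluster parents the two sibling branch clusters."""
    presence = gbm244_presence
    clusters = cluster_variants_by_vaf(presence.vaf_frame(), presence.states_frame(), 0.05)
    assert len(clusters) == 3
    tree = build_lineage_tree(clusters, 0.05)
    assert tree.is_consistent
    trunk = next(c.cluster_id for c in clusters if c.present_in("SVZ"))
    branches = sorted(c.cluster_id for c in clusters if not c.present_in("SVZ"))
    assert tree.children(ROOT) == [trunk]
    assert tree.children(trunk) == branches


def test_single_cluster_hangs_off_root():
    vaf, pres = _frames({"v1": ((0.02, 0.40, 0.40), "PPP")})
    tree = build_lineage_tree(cluster_variants_by_vaf(vaf, pres, 0.05))
    assert sorted(tree.graph.edges) == [(ROOT, "v1")]
    assert tree.is_consistent


def test_crossing_vafs_become_siblings():
    """A > B in one sample and B > A in another (beyond tol): containment
    fails both ways, so both clusters sit under the root."""
    vaf, pres = _frames(
        {
            "va": ((0.0, 0.40, 0.10), "APP"),
            "vb": ((0.0, 0.10, 0.40), "APP"),
        }
    )
    tree = build_lineage_tree(cluster_variants_by_vaf(vaf, pres, 0.05), 0.05)
    assert sorted(tree.graph.edges) == [(ROOT, "va"), (ROOT, "vb")]


def test_sum_rule_violation_reported_not_repaired():
    """Two children whose VAFs sum past the parent trip the pigeonhole check."""
    vaf, pres = _frames(
        {
            "parent": ((0.0, 0.30, 0.30), "APP"),
            "kid_a": ((0.0, 0.28, 0.20), "APP"),
            "kid_b": ((0.0, 0.20, 0.28), "APP"),
        }
    )
    # force three clusters with a tiny tol
    clusters = cluster_variants_by_vaf(vaf, pres, tol=0.01)
    assert len(clusters) == 3
    tree = build_lineage_tree(clusters, tol=0.01)
    assert not tree.is_consistent
    assert any(v["kind"] == "sum_rule" for v in tree.violations)
    # nothing was dropped
    assert set(tree.mutation_nodes) == {"parent", "kid_a", "kid_b"}


def test_concordance_identical_trees():
    t = _TinyTree({"A": None, "B": "A"}, {"m1": "A", "m2": "A", "m3": "B"})
    assert tree_concordance(t, t) == 1.0


def test_concordance_star_vs_chain():
    """Chain root->A->B->C vs star root->{A,B,C}: every pair is
    ancestor-related in the chain and sibling in the star, so no pair agrees
    (enumeration over the 3 pairs)."""
    assignment = {"m1": "A", "m2": "B", "m3": "C"}
    chain = _TinyTree({"A": None, "B": "A", "C": "B"}, assignment)
    star = _TinyTree({"A": None, "B": None, "C": None}, assignment)
    assert tree_concordance(chain, star) == 0.0


def test_concordance_partial_agreement():
    """Chain A->B->C vs A->{B,C}: pairs (A,B) and (A,C) agree, (B,C) differs."""
    assignment = {"m1": "A", "m2": "B", "m3": "C"}
    chain = _TinyTree({"A": None, "B": "A", "C": "B"}, assignment)
    flat = _TinyTree({"A": None, "B": "A", "C": "A"}, assignment)
    assert tree_concordance(chain, flat) == pytest.approx(2 / 3)


def test_concordance_requires_matching_mutation_sets():
    a = _TinyTree({"A": None}, {"m1": "A"})
    b = _TinyTree({"A": None}, {"m2": "A"})
    with pytest.raises(ValueError):
        tree_concordance(a, b)


@pytest.mark.parametrize("pattern", ["svz_associated", "primary_associated"])
def test_noiseless_reconstruction_matches_truth(pattern):
    """On noiseless patients (>=3 mutations per clone) the inferred tree's
    pair relations reproduce the generating clone tree exactly."""
    for seed in range(10):
        spec = random_patient_spec(1000 + seed, pattern=pattern, noiseless=True)
        ds = simulate_patient(spec)
        presence = call_patient(ds.variants, spec.manifest)
        clusters = cluster_variants_by_vaf(
            presence.vaf_frame(), presence.states_frame(), 0.05
        )
        tree = build_lineage_tree(clusters, 0.05)
        assert tree.is_consistent
        assert tree_concordance(tree, ds.tree) == 1.0


def test_deterministic_given_identical_inputs(gbm244_presence):
    presence = gbm244_presence
    args = (presence.vaf_frame(), presence.states_frame(), 0.05)
    t1 = build_lineage_tree(cluster_variants_by_vaf(*args), 0.05)
    t2 = build_lineage_tree(cluster_variants_by_vaf(*args), 0.05)
    assert sorted(t1.graph.edges) == sorted(t2.graph.edges)
    assert t1.newick() == t2.newick()


def test_vaf_scatter_axes(gbm244_presence, gbm244_categories):
    vafs = gbm244_presence.vaf_frame()
    scatter = vaf_scatter(vafs, "SVZ", "PRIMARY", gbm244_categories)
    assert set(scatter.columns) >= {"variant", "x_vaf", "y_vaf", "category"}
    trunk = scatter[scatter["category"] == "SVZ_TUMOR_SHARED"]
    private = scatter[scatter["category"] == "PRIMARY_PRIVATE"]
    # trunk mutations sit off-axis (shared), primary-private on the y-axis
    assert (trunk["x_vaf"] > 0).all() and (trunk["y_vaf"] > 0).all()
    assert (private["x_vaf"] == 0).all() and (private["y_vaf"] > 0).all()
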