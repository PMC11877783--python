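"""Simulator contracts: VAF model, read sampling, truth labels, fixtures."""

from collections import Counter

import numpy as np
import pytest

from svztrace.categorize import MutationCategory
from svztrace.classify import RecurrencePattern
from svztrace.io import Role, write_variant_table, read_variant_table
from svztrace.presence import Presence, call_patient
from svztrace.sim import (
    Clone,
    Mutation,
    SampleDef,
    SimulationSpec,
    ccf_to_vaf,
    cohort_fixture,
    gbm244_preset,
    mutation_ccf,
    random_patient_spec,
    sample_reads,
    simulate_patient,
)


@pytest.mark.parametrize(
    "ccf,purity,expected",
    [(1.0, 1.0, 0.5), (0.0, 0.7, 0.0), (0.4, 0.6, 0.12)],
)
def test_ccf_to_vaf(ccf, purity, expected):
    assert ccf_to_vaf(ccf, purity) == pytest.approx(expected)


def test_ccf_to_vaf_rejects_out_of_range():
    with pytest.raises(ValueError):
        ccf_to_vaf(1.2, 0.5)
    with pytest.raises(ValueError):
        ccf_to_vaf(0.5, -0.1)


def test_sample_reads_noiseless():
    rng = np.random.default_rng(0)
    assert sample_reads(0.0, 1000, 0.0, rng, noiseless=True) == (0, 1000)
    assert sample_reads(0.25, 1000, 0.0, rng, noiseless=True) == (250, 1000)


def test_sample_reads_mean_matches_binomial_expectation():
    """Mean alt count over many draws sits within 3 s.e. of n*p with the
    miscall-adjusted success probability."""
    rng = np.random.default_rng(42)
    vaf, depth, err, n_draws = 0.25, 1000, 1e-3, 10_000
    draws = np.array(
        [sample_reads(vaf, depth, err, rng, fixed_depth=True)[0] for _ in range(n_draws)]
    )
    p = vaf * (1 - err) + (1 - vaf) * err / 3
    expected = depth * p  # 250.0 with the 249.75 + 0.25 error contributions
    se = np.sqrt(depth * p * (1 - p) / n_draws)
    assert abs(draws.mean() - expected) <= 3 * se


def test_poisson_depth_dispersion():
    rng = np.random.default_rng(1)
    depths = [sample_reads(0.1, 1000, 1e-3, rng)[1] for _ in range(2000)]
    assert np.std(depths) > 10  # Poisson, not fixed
    assert abs(np.mean(depths) - 1000) < 5


def test_simulation_determinism_and_noiseless_seed_independence():
    stochastic_a = simulate_patient(gbm244_preset(seed=7))
    stochastic_b = simulate_patient(gbm244_preset(seed=7))
    assert [v.counts for v in stochastic_a.variants] == [
        v.counts for v in stochastic_b.variants
    ]
    noiseless_a = simulate_patient(gbm244_preset(seed=1, noiseless=True))
    noiseless_b = simulate_patient(gbm244_preset(seed=2, noiseless=True))
    assert [v.counts for v in noiseless_a.variants] == [
        v.counts for v in noiseless_b.variants
    ]


def test_expected_vaf_identity():
    """Expected VAF of every simulated variant is 0.5 * purity * subtree CCF,
    reproduced exactly (after rounding) by noiseless counts."""
    spec = gbm244_preset(noiseless=True)
    ds = simulate_patient(spec)
    by_key = {m.key: m for m in spec.mutations}
    for rec in ds.variants:
        m = by_key[rec.key]
        for s in spec.samples:
            vaf = ccf_to_vaf(mutation_ccf(spec, s, m.mutation_id), s.purity)
            depth, alt = rec.counts[s.name]
            assert depth == s.mean_depth
            assert alt == round(s.mean_depth * vaf)


def test_trunk_only_spec_yields_all_shared():
    mutations = [Mutation(f"T{i}", "chr1", 1000 + i, "A", "G") for i in range(3)]
    spec = SimulationSpec(
        patient_id="TRUNK",
        clones=[Clone("trunk", None, tuple(m.mutation_id for m in mutations))],
        mutations=mutations,
        samples=[
            SampleDef("blood", Role.BLOOD, 0.0, 1000),
            SampleDef("svz", Role.SVZ, 0.05, 1000, {"trunk": 1.0}),
            SampleDef("primary", Role.PRIMARY, 0.8, 1000, {"trunk": 1.0}),
            SampleDef("recurrent", Role.RECURRENT, 0.8, 1000, {"trunk": 1.0}),
        ],
        noiseless=True,
    )
    ds = simulate_patient(spec)
    assert set(ds.truth_categories.values()) == {MutationCategory.SVZ_TUMOR_SHARED}


def test_spec_validation_rejects_bad_structures():
    m = [Mutation("a", "chr1", 1, "A", "G")]
    blood = SampleDef("blood", Role.BLOOD, 0.0, 100)
    svz = SampleDef("svz", Role.SVZ, 0.05, 100, {"c1": 1.0})
    primary = SampleDef("primary", Role.PRIMARY, 0.8, 100, {"c1": 1.0})
    good = [blood, svz, primary]
    with pytest.raises(ValueError):  # unknown parent
        SimulationSpec("P", [Clone("c1", "ghost", ("a",))], m, good).validate()
    with pytest.raises(ValueError):  # mutation in two clones
        SimulationSpec(
            "P", [Clone("c1", None, ("a",)), Clone("c2", "c1", ("a",))], m, good
        ).validate()
    with pytest.raises(ValueError):  # fractions not summing to 1
        SimulationSpec(
            "P",
            [Clone("c1", None, ("a",))],
            m,
            [blood, SampleDef("svz", Role.SVZ, 0.05, 100, {"c1": 0.5}), primary],
        ).validate()
    with pytest.raises(ValueError):  # impure blood
        SimulationSpec(
            "P",
            [Clone("c1", None, ("a",))],
            m,
            [SampleDef("blood", Role.BLOOD, 0.1, 100), svz, primary],
        ).validate()


def test_gbm244_preset_structure():
    spec = gbm244_preset()
    assert len(spec.clones) == 3  # trunk + two branches
    assert len(spec.mutations) == 12  # 2 drivers + 10 passengers
    assert sum(1 for m in spec.mutations if m.driver) == 2
    assert spec.sample(Role.BLOOD).purity == 0.0
    assert all(s.mean_depth == 1063 for s in spec.samples)


def test_gbm244_truth_labels(gbm244_noiseless):
    counts = Counter(c.value for c in gbm244_noiseless.truth_categories.values())
    assert counts == {"SVZ_TUMOR_SHARED": 2, "PRIMARY_PRIVATE": 5, "RECURRENT_PRIVATE": 5}
    assert gbm244_noiseless.truth_pattern.pattern is RecurrencePattern.SVZ_ASSOCIATED


@pytest.mark.parametrize("pattern,expected", [
    ("svz_associated", RecurrencePattern.SVZ_ASSOCIATED),
    ("primary_associated", RecurrencePattern.PRIMARY_ASSOCIATED),
])
def test_random_spec_truth_pattern_matches_request(pattern, expected):
    for seed in range(5):
        ds = simulate_patient(random_patient_spec(300 + seed, pattern=pattern))
        assert ds.truth_pattern.pattern is expected


def test_noiseless_truth_equals_pipeline_categories():
    """Oracle equivalence: on noiseless data at panel depth, categorize
    reproduces the simulator's generative truth for every variant."""
    from svztrace.categorize import categorize_patient

    for seed in range(8):
        for pattern in ("svz_associated", "primary_associated"):
            ds = simulate_patient(
                random_patient_spec(7000 + seed, pattern=pattern, noiseless=True)
            )
            presence = call_patient(ds.variants, ds.spec.manifest)
            table = categorize_patient(presence)
            got = {k: MutationCategory(r["category"]) for k, r in table.iterrows()}
            assert got == ds.truth_categories


def test_simulated_tables_roundtrip_through_io(tmp_path):
    ds = simulate_patient(gbm244_preset(seed=9))
    path = tmp_path / "t.tsv"
    write_variant_table(ds.variants, path)
    back = read_variant_table(path)
    assert {r.key: r.counts for r in back} == {r.key: r.counts for r in ds.variants}


class TestCohortFixture:
    def test_ten_patients(self, cohort):
        assert len(cohort) == 10

    def test_every_patient_has_a_trunk_variant(self, cohort):
        """A variant PRESENT across SVZ, primary and recurrent in every profile."""
        for patient in cohort:
            presence = call_patient(patient.variants, patient.manifest)
            assert any(
                all(
                    presence.state(k, role) is Presence.PRESENT
                    for role in (Role.SVZ, Role.PRIMARY, Role.RECURRENT)
                )
                for k in presence.somatic_keys
            ), patient.patient_id

    def test_gbm1938_three_trunk_shared_variants(self, cohort):
        patient = next(p for p in cohort if p.patient_id == "GBM-1938")
        presence = call_patient(patient.variants, patient.manifest)
        trunk = [
            k
            for k in presence.somatic_keys
            if all(
                presence.state(k, role) is Presence.PRESENT
                for role in (Role.SVZ, Role.PRIMARY, Role.RECURRENT)
            )
        ]
        genes = sorted(presence.variants[k].gene for k in trunk)
        assert genes == ["PDGFRA", "PTEN", "TERT"]

    def test_unknown_patients_blocked_by_indeterminate_calls(self, cohort):
        """Patients 2455/2437: every non-trunk variant is UNRESOLVED because a
        deciding tissue is INDETERMINATE."""
        from svztrace.categorize import categorize_patient

        for pid in ("GBM-2455", "GBM-2437"):
            patient = next(p for p in cohort if p.patient_id == pid)
            table = categorize_patient(call_patient(patient.variants, patient.manifest))
            non_trunk = table[table["category"] != "SVZ_TUMOR_SHARED"]
            assert (non_trunk["category"] == "UNRESOLVED").all()
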