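"""Dose scans, sequential and combination protocols, ensembles, aggregation."""

import numpy as np
import pytest

import rescomp as rc
from rescomp.sampling import MAX_CENTROID_DISTANCE

# sole-survivor communities found by scanning random equal-budget
# communities: the lone pre-antibiotic survivor is targeted and the
# richness path is strongly non-monotonic (verified by fine-grid scans)
THREE_CHANGE_R = np.array(
    [
        [0.47428468, 0.19739173, 0.32832359],
        [0.70668589, 0.09227226, 0.20104186],
        [0.74765471, 0.22941183, 0.02293347],
    ]
)
FOUR_CHANGE_R = np.array(
    [
        [2.81206203e-01, 2.29488850e-01, 4.89304947e-01],
        [1.03904495e-01, 1.75632342e-02, 8.78532271e-01],
        [1.71626015e-01, 7.44891534e-04, 8.27629094e-01],
    ]
)


def _community(R):
    return rc.Community(np.asarray(R), np.full(3, 1 / 3), 1.0)


class TestDoseScan:
    def test_target_coexisting_pre_antibiotic_changes_at_least_twice(self):
        # the targeted species is the sole pre-antibiotic survivor: a
        # non-target must emerge before the target dies, so the richness
        # changes at least twice on the way to the target's extinction
        for R in (THREE_CHANGE_R, FOUR_CHANGE_R):
            comm = _community(R)
            assert rc.coexisting_set(comm).survivors == (0,)
            res = rc.dose_scan(comm, [1.0, 0.0, 0.0], c_max=80.0, n_grid=401)
            assert not res.capped
            assert res.n_changes >= 2

    def test_non_monotonic_richness_path(self):
        # path passes 1 -> 2 -> 3 -> 2 -> 1 (4 changes), mirroring the
        # re-entrant coexistence seen when a dominant generalist is dosed
        comm = _community(FOUR_CHANGE_R)
        res = rc.dose_scan(comm, [1.0, 0.0, 0.0], c_max=80.0, n_grid=801)
        assert res.n_changes == 4
        rho_between = [
            len(
                rc.coexisting_set(
                    comm.with_death_rates([c, 0.0, 0.0])
                ).survivors
            )
            for c in np.concatenate([[0.0], res.change_points + 0.01])
        ]
        assert rho_between == [1, 2, 3, 2, 1]

    def test_change_points_refined(self):
        comm = _community(THREE_CHANGE_R)
        res = rc.dose_scan(comm, [1.0, 0.0, 0.0], c_max=80.0, n_grid=401,
                           resolution=1e-4)
        # each change point is localized: richness differs across +-resolution
        for cp in res.change_points:
            lo = rc.coexisting_set(
                comm.with_death_rates([cp - 2e-4, 0, 0])
            ).richness
            hi = rc.coexisting_set(
                comm.with_death_rates([cp + 2e-4, 0, 0])
            ).richness
            assert lo != hi

    def test_extinction_dose_is_refined(self):
        comm = _community(THREE_CHANGE_R)
        res = rc.dose_scan(comm, [1.0, 0.0, 0.0], c_max=80.0, n_grid=401)
        c = res.extinction_dose
        assert 0 in rc.coexisting_set(comm.with_death_rates([c - 2e-4, 0, 0])).survivors
        assert 0 not in rc.coexisting_set(comm.with_death_rates([c + 2e-4, 0, 0])).survivors

    def test_target_extinct_from_start(self):
        # species 1 is excluded without any antibiotic; dosing it changes
        # nothing, so no richness transitions are recorded
        R = np.array(
            [
                [1.31953615, 0.00588901],
                [0.29003918, 0.21615272],
                [0.34437003, 0.21350549],
            ]
        )
        comm = rc.Community(R, [0.5, 0.5], 1.0)
        assert 1 not in rc.coexisting_set(comm).survivors
        res = rc.dose_scan(comm, [0.0, 1.0, 0.0], c_max=5.0, n_grid=51)
        assert res.extinction_dose == 0.0
        assert res.n_changes == 0

    def test_capped_scan_flagged(self, two_specialists):
        # specialists never exclude each other, so the target survives any dose
        res = rc.dose_scan(two_specialists, [1.0, 0.0], c_max=3.0, n_grid=31)
        assert res.capped
        assert res.extinction_dose == np.inf

    def test_requires_positive_profile(self, two_specialists):
        with pytest.raises(ValueError):
            rc.dose_scan(two_specialists, [0.0, 0.0], c_max=1.0)


class TestSequentialTreatment:
    def test_symmetric_community_is_transitive(self):
        for d in (0.2, 0.5, 0.9):
            comm = rc.build_structured_community(
                rc.StructuredFamilySpec(0.3, 0.3, 0.4, d, d)
            )
            res = rc.sequential_treatment(comm, [d, 0, 0], [0, d, 0])
            assert res.delta_rho == 0
            assert res.mechanism == "transitive"

    def test_specialized_non_target_always_transitive(self):
        """A sufficiently specialized untargeted species cannot outcompete
        anyone, so the order of antibiotics never matters."""
        rng = np.random.default_rng(21)
        for _ in range(60):
            spec = rc.StructuredFamilySpec(
                rng.uniform(0.01, MAX_CENTROID_DISTANCE - 0.01),
                rng.uniform(0.01, MAX_CENTROID_DISTANCE - 0.01),
                rng.uniform(0.55, MAX_CENTROID_DISTANCE - 0.01),
                rng.uniform(0.01, 0.99),
                rng.uniform(0.01, 0.99),
            )
            comm = rc.build_structured_community(spec)
            res = rc.sequential_treatment(
                comm, [spec.d_1, 0, 0], [0, spec.d_2, 0]
            )
            assert res.delta_rho == 0

    def test_promotion_instance(self):
        # a generalist target is outcompeted under its antibiotic only while
        # the other target is present: order then decides the final richness
        comm = rc.build_structured_community(
            rc.StructuredFamilySpec(0.1, 0.35, 0.35, 0.3, 0.8)
        )
        res = rc.sequential_treatment(comm, [0.3, 0, 0], [0, 0.8, 0])
        assert res.delta_rho == 1
        assert res.mechanism == "promotion"
        assert res.order_AB_survivors == (2,)
        assert res.order_BA_survivors == (0, 2)
        a = res.context_flags["A"]
        b = res.context_flags["B"]
        assert a["extinct_in_full"] and not a["extinct_without_other_target"]
        assert b["extinct_in_full"] and b["extinct_without_other_target"]

    def test_neutralization_instance(self):
        # the second target survives its antibiotic only while the first
        # target is present to shield it
        comm = rc.build_structured_community(
            rc.StructuredFamilySpec(0.45, 0.55, 0.2, 0.3, 0.3)
        )
        res = rc.sequential_treatment(comm, [0.3, 0, 0], [0, 0.3, 0])
        assert res.delta_rho == 1
        assert res.mechanism == "neutralization"
        b = res.context_flags["B"]
        assert not b["extinct_in_full"] and b["extinct_without_other_target"]

    def test_delta_rho_zero_or_one_in_structured_family(self):
        rng = np.random.default_rng(22)
        for _ in range(200):
            spec = rc.StructuredFamilySpec(
                rng.uniform(0.01, MAX_CENTROID_DISTANCE - 0.01),
                rng.uniform(0.01, MAX_CENTROID_DISTANCE - 0.01),
                rng.uniform(0.01, MAX_CENTROID_DISTANCE - 0.01),
                rng.uniform(0.01, 0.99),
                rng.uniform(0.01, 0.99),
            )
            comm = rc.build_structured_community(spec)
            res = rc.sequential_treatment(
                comm, [spec.d_1, 0, 0], [0, spec.d_2, 0]
            )
            assert res.delta_rho in (0, 1)
            assert (res.mechanism == "transitive") == (res.delta_rho == 0)


class TestCombinationTreatment:
    def test_zero_doses_are_additive(self, symmetric_three):
        res = rc.combination_treatment(symmetric_three, [0, 0, 0], [0, 0, 0])
        assert res.classification == "additive"
        assert not res.extinct_A and not res.extinct_B and not res.extinct_AB
        assert np.isnan(res.d_min)

    def test_antagonism_instance(self):
        # symmetric targets with a specialized non-target: each antibiotic
        # alone kills its target, together the targets shield each other
        comm = rc.build_structured_community(
            rc.StructuredFamilySpec(0.15, 0.15, 0.45, 0.4, 0.4)
        )
        res = rc.combination_treatment(comm, [0.4, 0, 0], [0, 0.4, 0])
        assert res.extinct_A == {0}
        assert res.extinct_B == {1}
        assert res.extinct_AB == frozenset()
        assert res.rho_AB == 3 and res.rho_additive == 1
        assert res.classification == "antagonistic"
        assert res.d_min == pytest.approx(0.4)

    def test_synergism_instance(self):
        # distant targets with a generalist non-target: either antibiotic
        # alone preserves coexistence, together the non-target sweeps
        comm = rc.build_structured_community(
            rc.StructuredFamilySpec(0.73, 0.57, 0.18, 0.33, 0.24)
        )
        res = rc.combination_treatment(comm, [0.33, 0, 0], [0, 0.24, 0])
        assert not res.extinct_A and not res.extinct_B
        assert res.extinct_AB == {0, 1}
        assert res.classification == "synergistic"
        assert res.d_min == pytest.approx(0.24)

    def test_classification_invariants(self):
        rng = np.random.default_rng(23)
        sampler = rc.two_target_sampler()
        for _ in range(80):
            comm, A, B = sampler(rng)
            res = rc.combination_treatment(comm, A, B)
            if res.rho_AB < res.rho_additive:
                assert res.classification == "synergistic"
            elif res.rho_AB > res.rho_additive:
                assert res.classification == "antagonistic"
            else:
                assert res.classification == "additive"


class TestEnsembleScan:
    def test_empty_ensemble(self):
        res = rc.ensemble_scan(rc.two_target_sampler(), 0, seed=0)
        assert res.counts == {}
        assert res.n_total == 0

    def test_deterministic_given_seed(self):
        a = rc.ensemble_scan(rc.two_target_sampler(), 300, seed=17)
        b = rc.ensemble_scan(rc.two_target_sampler(), 300, seed=17)
        assert a.counts == b.counts

    def test_promotion_excludes_synergism_and_additivity(self):
        res = rc.ensemble_scan(
            rc.two_target_sampler(), 1500, seed=18, require_full_coexistence=True
        )
        assert res.counts.get(("promotion", "synergistic"), 0) == 0
        assert res.counts.get(("promotion", "additive"), 0) == 0
        assert res.counts.get(("promotion", "antagonistic"), 0) > 0

    def test_records_cover_full_table(self):
        res = rc.ensemble_scan(rc.two_target_sampler(), 50, seed=19)
        recs = res.to_records()
        assert len(recs) == 9
        assert sum(r["count"] for r in recs) + res.n_failed + res.n_unclassified == 50


class TestStructuredFamilyScan:
    def test_random_mode_reports_shares(self):
        out = rc.structured_family_scan(400, seed=24)
        c = out["counts"]
        assert c["failed"] == 0
        assert out["n_nonzero_delta_rho"] == c["promotion"] + c["neutralization"] + c["unclassified"]
        if out["n_nonzero_delta_rho"]:
            assert out["promotion_share"] + out["neutralization_share"] <= 1.0 + 1e-12

    def test_grid_mode_runs(self):
        out = rc.structured_family_scan(400, seed=0, mode="grid")
        assert out["n_samples"] >= 64


class TestAggregation:
    R4 = np.array(
        [
            [0.4, 0.3, 0.15, 0.15],
            [0.3, 0.4, 0.15, 0.15],
            [0.1, 0.1, 0.5, 0.3],
            [0.1, 0.1, 0.3, 0.5],
        ]
    )

    def test_single_member_group_is_identity(self):
        comm = rc.Community(self.R4, np.full(4, 0.25), 1.0)
        same = rc.aggregate_symmetric_species(comm, [2])
        np.testing.assert_allclose(same.R, comm.R)

    def test_merged_community_preserves_classification(self):
        comm4 = rc.Community(self.R4, np.full(4, 0.25), 1.0)
        comm3 = rc.aggregate_symmetric_species(comm4, [2, 3])
        assert comm3.m == 3 and comm3.p == 3
        for dose in (0.3, 0.6, 0.9, 1.5):
            r4 = rc.combination_treatment(
                comm4, [dose, 0, 0, 0], [0, dose, 0, 0]
            )
            r3 = rc.combination_treatment(comm3, [dose, 0, 0], [0, dose, 0])
            assert r4.classification == r3.classification

    def test_merged_steady_state_matches_ode(self):
        # merged species carries the group's combined abundance
        comm4 = rc.Community(self.R4, np.full(4, 0.25), 1.0,
                             death_rates=[0.2, 0.0, 0.0, 0.0])
        comm3 = rc.aggregate_symmetric_species(comm4, [2, 3])
        ss4 = rc.steady_state(comm4)
        ss3 = rc.steady_state(comm3)
        assert ss4.converged and ss3.converged
        np.testing.assert_allclose(
            ss3.abundances[:2], ss4.abundances[:2], atol=1e-6
        )
        assert ss3.abundances[2] == pytest.approx(
            ss4.abundances[2] + ss4.abundances[3], abs=1e-6
        )

    def test_asymmetry_raises(self):
        R = self.R4.copy()
        R[3, 2] = 0.45  # break the mirror symmetry
        comm = rc.Community(R, np.full(4, 0.25), 1.0)
        with pytest.raises(ValueError):
            rc.aggregate_symmetric_species(comm, [2, 3])

    def test_perturbed_symmetry_mostly_preserves_classification(self):
        """Classification under aggregation is robust to small (1%)
        perturbations of the symmetric structure."""
        rng = np.random.default_rng(25)
        agree = total = 0
        while total < 40:
            noise = rng.normal(0.0, 0.01, size=self.R4.shape)
            R = np.clip(self.R4 + self.R4 * noise, 1e-3, None)
            comm4 = rc.Community(R, np.full(4, 0.25), 1.0)
            try:
                comm3 = rc.aggregate_symmetric_species(comm4, [2, 3], tol=0.05)
            except ValueError:
                continue
            dose = float(rng.uniform(0.2, 1.2))
            r4 = rc.combination_treatment(comm4, [dose, 0, 0, 0], [0, dose, 0, 0])
            r3 = rc.combination_treatment(comm3, [dose, 0, 0], [0, dose, 0])
            total += 1
            agree += r4.classification == r3.classification
        assert agree / total >= 0.95
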