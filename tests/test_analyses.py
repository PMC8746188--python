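"""Edge bookkeeping, the three analysis families, and their covariate logic."""

import dataclasses

import numpy as np
import pytest

import clsm
from clsm.analyses import (
    AnalysisConfig,
    CovariateMode,
    EdgeFinding,
    EdgeIndexMap,
    critical_area_lesion_load,
    edge_vectorize,
    functional_edge_analysis,
    region_lsm,
    sc_residualize_fc,
    structural_edge_analysis,
)
from clsm.cohort import CohortConfig, CohortDataset, SubjectRecord, generate_cohort
from clsm.glm import PermutationConfig

from conftest import behavior_from_latent

PERM = PermutationConfig(n_perm=200, seed=0)


class TestEdgeIndexMap:
    def test_three_rois(self):
        emap = EdgeIndexMap(3)
        assert emap.pairs == [(0, 1), (0, 2), (1, 2)]
        m = np.array([[0, 5, 6], [5, 0, 7], [6, 7, 0]], float)
        np.testing.assert_array_equal(emap.vectorize(m), [5, 6, 7])

    def test_round_trip(self, rng):
        emap = EdgeIndexMap(7)
        m = rng.standard_normal((7, 7))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        np.testing.assert_allclose(emap.devectorize(emap.vectorize(m)), m, atol=1e-12)

    def test_round_trip_with_unit_diagonal(self, rng):
        emap = EdgeIndexMap(5)
        v = rng.standard_normal(emap.n_edges)
        m = emap.devectorize(v, diag=1.0)
        np.testing.assert_array_equal(np.diag(m), 1.0)
        np.testing.assert_allclose(emap.vectorize(m), v)

    def test_108_rois_give_5778_edges(self):
        assert EdgeIndexMap(108).n_edges == 5778

    def test_position_bijection(self):
        emap = EdgeIndexMap(9)
        for k, (i, j) in enumerate(emap.pairs):
            assert emap.position(i, j) == k
            assert emap.position(j, i) == k

    def test_asymmetric_rejected(self, rng):
        emap = EdgeIndexMap(4)
        m = rng.standard_normal((4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            edge_vectorize(m, emap)

    def test_diagonal_not_an_edge(self):
        with pytest.raises(ValueError, match="diagonal"):
            EdgeIndexMap(4).position(2, 2)


def _cohort_with_behavior(base: CohortDataset, latents) -> CohortDataset:
    subjects = tuple(
        dataclasses.replace(s, behavior=behavior_from_latent(lat))
        for s, lat in zip(base.subjects, latents)
    )
    return dataclasses.replace(base, subjects=subjects)


@pytest.fixture(scope="module")
def lesioned_cohort():
    cfg = CohortConfig(
        n_subjects=97,
        n_dorsal_left=3,
        n_ventral_per_hemi=4,
        n_timepoints=80,
        lesion_damage_prob=0.5,
    )
    return generate_cohort(cfg, seed=21)


class TestRegionLsm:
    def test_planted_roi_effect_recovered(self, lesioned_cohort):
        """Behavior = c - k * lesion(ROI_j) + noise with large k: ROI_j
        survives with negative z in >= 90% of seeded runs."""
        roi_j = 1
        hits = 0
        n_runs = 20
        rng = np.random.default_rng(5)
        for run in range(n_runs):
            latents = np.array(
                [
                    160.0 - 120.0 * s.lesion_load[roi_j] + rng.normal(0, 5)
                    for s in lesioned_cohort.subjects
                ]
            )
            cohort = _cohort_with_behavior(lesioned_cohort, latents)
            res = region_lsm(
                cohort, "avc", PermutationConfig(n_perm=300, seed=run)
            )
            name = cohort.parcellation.names[roi_j]
            if name in res.feature_ids:
                k = res.feature_ids.index(name)
                if res.survivors[k] and res.z[k] < 0:
                    hits += 1
        assert hits / n_runs >= 0.9

    def test_min_damage_rule_boundary(self, lesioned_cohort):
        loads = np.stack([s.lesion_load for s in lesioned_cohort.subjects])
        counts = (loads > 0).sum(axis=0)
        # pick thresholds bracketing an actual ROI's damage count
        target = int(counts[counts > 0].min())
        res_incl = region_lsm(lesioned_cohort, "avc", PERM, min_damage_subjects=target)
        res_excl = region_lsm(lesioned_cohort, "avc", PERM, min_damage_subjects=target + 1)
        names = np.array(lesioned_cohort.parcellation.names)
        boundary = set(names[counts == target])
        assert boundary <= set(res_incl.feature_ids)
        assert not (boundary & set(res_excl.feature_ids))

    def test_decreasing_threshold_never_drops_rois(self, lesioned_cohort):
        prev: set = set()
        for thresh in (40, 20, 10, 1):
            res = region_lsm(lesioned_cohort, "avc", PERM, min_damage_subjects=thresh)
            current = set(res.feature_ids)
            assert prev <= current
            prev = current

    def test_right_hemisphere_never_included(self, lesioned_cohort):
        res = region_lsm(lesioned_cohort, "avc", PERM, min_damage_subjects=1)
        right = {lesioned_cohort.parcellation.names[i]
                 for i in lesioned_cohort.parcellation.right_ids}
        assert not (right & set(res.feature_ids))

    def test_no_roi_passes_warns_and_returns_empty(self, lesioned_cohort):
        with pytest.warns(UserWarning, match="inclusion"):
            res = region_lsm(lesioned_cohort, "avc", PERM, min_damage_subjects=98)
        assert len(res.feature_ids) == 0
        assert res.n_survivors == 0


class TestStructuralEdgeAnalysis:
    def test_planted_sc_edge_ranks_first(self, lesioned_cohort):
        """Behavior driven by one structural edge: that edge tops |z|."""
        emap = EdgeIndexMap(lesioned_cohort.parcellation.n_rois)
        i, j = 2, 8
        rng = np.random.default_rng(17)
        fibers = np.array([s.structural[i, j] for s in lesioned_cohort.subjects])
        scale = 60.0 / max(fibers.std(), 1e-9)
        latents = 100.0 + scale * (fibers - fibers.mean()) + rng.normal(0, 5, len(fibers))
        cohort = _cohort_with_behavior(lesioned_cohort, latents)
        res, findings = structural_edge_analysis(cohort, "avc", PERM)
        k = emap.position(i, j)
        assert np.nanargmax(np.abs(res.z)) == k
        assert findings[0].roi_a == cohort.parcellation.names[i]
        assert findings[0].roi_b == cohort.parcellation.names[j]

    def test_identical_fiber_counts_all_flagged(self, small_cohort):
        const = small_cohort.subjects[0].structural
        subjects = tuple(
            dataclasses.replace(s, structural=const) for s in small_cohort.subjects
        )
        cohort = dataclasses.replace(small_cohort, subjects=subjects)
        res, findings = structural_edge_analysis(cohort, "avc", PERM)
        assert res.undefined.all()
        assert res.n_survivors == 0
        assert findings == []

    def test_findings_sorted_by_abs_z(self, lesioned_cohort):
        res, findings = structural_edge_analysis(
            lesioned_cohort, "avc", PermutationConfig(n_perm=100, alpha=0.5, seed=1)
        )
        zs = [abs(e.z) for e in findings]
        assert zs == sorted(zs, reverse=True)


class TestScResidualizeFc:
    def test_exact_affine_relation_vanishes(self, rng):
        sc = rng.standard_normal((30, 4))
        fc = 2.5 * sc + 1.0
        out = sc_residualize_fc(fc, sc)
        np.testing.assert_allclose(out, 0, atol=1e-9)

    def test_constant_sc_mean_centers(self, rng):
        fc = rng.standard_normal((25, 3))
        sc = np.full((25, 3), 7.0)
        out = sc_residualize_fc(fc, sc)
        np.testing.assert_allclose(out, fc - fc.mean(axis=0), atol=1e-12)

    def test_per_edge_normal_equations_oracle(self, rng):
        fc = rng.standard_normal((40, 6))
        sc = rng.standard_normal((40, 6))
        out = sc_residualize_fc(fc, sc)
        for e in range(6):
            x = np.column_stack([np.ones(40), sc[:, e]])
            oracle = fc[:, e] - x @ np.linalg.solve(x.T @ x, x.T @ fc[:, e])
            np.testing.assert_allclose(out[:, e], oracle, atol=1e-10)
            assert abs(out[:, e] @ sc[:, e]) < 1e-8

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="shape"):
            sc_residualize_fc(rng.standard_normal((10, 3)), rng.standard_normal((10, 4)))


class TestCriticalAreaLesionLoad:
    def test_zero_lesion(self, small_cohort):
        p = small_cohort.parcellation
        s = dataclasses.replace(
            small_cohort.subjects[0],
            lesion_load=np.zeros(p.n_rois),
            total_lesion_volume=0.0,
        )
        assert critical_area_lesion_load(s, [p.names[0]], p, 1000.0) == 0.0

    def test_summed_contributions(self, small_cohort):
        p = small_cohort.parcellation
        load = np.zeros(p.n_rois)
        load[[0, 1, 2, 3]] = [0.01, 0.02, 0.03, 0.04]
        s = dataclasses.replace(
            small_cohort.subjects[0], lesion_load=load,
            total_lesion_volume=float(load.sum() * 1000),
        )
        crit = [p.names[i] for i in range(4)]
        assert critical_area_lesion_load(s, crit, p, 1000.0) == pytest.approx(100.0)

    def test_lesion_outside_critical_area(self, small_cohort):
        p = small_cohort.parcellation
        load = np.zeros(p.n_rois)
        load[5] = 0.5
        s = dataclasses.replace(
            small_cohort.subjects[0], lesion_load=load, total_lesion_volume=500.0
        )
        assert critical_area_lesion_load(s, [p.names[0], p.names[1]], p, 1000.0) == 0.0

    def test_unknown_roi(self, small_cohort):
        with pytest.raises(ValueError, match="unknown ROI"):
            critical_area_lesion_load(
                small_cohort.subjects[0], ["bogus"], small_cohort.parcellation, 1000.0
            )

    def test_volume_mapping_form(self, small_cohort):
        p = small_cohort.parcellation
        load = np.zeros(p.n_rois)
        load[0] = 0.5
        s = dataclasses.replace(
            small_cohort.subjects[0], lesion_load=load, total_lesion_volume=500.0
        )
        vols = {p.names[0]: 2000.0}
        assert critical_area_lesion_load(s, [p.names[0]], p, vols) == pytest.approx(1000.0)


@pytest.fixture(scope="module")
def planted_fc_cohort():
    cfg = CohortConfig(
        n_subjects=97,
        n_dorsal_left=3,
        n_ventral_per_hemi=4,
        n_timepoints=150,
        planted_fc_edges=((1, 9, 60.0),),
        lesion_behavior_coef=0.004,
        lesion_damage_prob=0.4,
        noise_sd=6.0,
    )
    return generate_cohort(cfg, seed=11)


class TestFunctionalEdgeAnalysis:
    def _planted_index(self, cohort):
        emap = EdgeIndexMap(cohort.parcellation.n_rois)
        return emap.position(1, 9)

    @pytest.mark.parametrize("mode", ["LESION_VOLUME", "LESION_VOLUME_PLUS_SC"])
    def test_planted_edge_survives(self, planted_fc_cohort, mode):
        cfg = AnalysisConfig(covariate_mode=mode, permutation=PermutationConfig(n_perm=300, seed=4))
        res, findings = functional_edge_analysis(planted_fc_cohort, cfg)
        assert res.survivors[self._planted_index(planted_fc_cohort)]
        names = {(f.roi_a, f.roi_b) for f in findings}
        p = planted_fc_cohort.parcellation
        assert (p.names[1], p.names[9]) in names

    def test_critical_area_mode_runs(self, planted_fc_cohort):
        p = planted_fc_cohort.parcellation
        cfg = AnalysisConfig(
            covariate_mode="CRITICAL_AREAS_PLUS_SC",
            critical_rois=tuple(p.names[i] for i in p.ids_where(hemisphere="L", stream="ventral")[:4]),
            permutation=PermutationConfig(n_perm=300, seed=4),
        )
        res, _ = functional_edge_analysis(planted_fc_cohort, cfg)
        assert res.survivors[self._planted_index(planted_fc_cohort)]

    def test_critical_mode_requires_rois(self):
        with pytest.raises(ValueError, match="critical_rois"):
            AnalysisConfig(covariate_mode="CRITICAL_AREAS_PLUS_SC")

    def test_sc_rescaling_invariance_in_mode_b(self, planted_fc_cohort):
        """Affine rescaling of fiber counts leaves mode-(b) z-scores
        unchanged: residualization absorbs the scale."""
        cfg = AnalysisConfig(
            covariate_mode="LESION_VOLUME_PLUS_SC",
            permutation=PermutationConfig(n_perm=100, seed=2),
        )
        base, _ = functional_edge_analysis(planted_fc_cohort, cfg)
        scaled_subjects = []
        for s in planted_fc_cohort.subjects:
            m = 3.0 * s.structural
            scaled_subjects.append(dataclasses.replace(s, structural=m))
        scaled = dataclasses.replace(planted_fc_cohort, subjects=tuple(scaled_subjects))
        res, _ = functional_edge_analysis(scaled, cfg)
        np.testing.assert_allclose(res.z, base.z, atol=1e-8)

    def test_covariate_style_override(self, planted_fc_cohort):
        """Mode (b) with the covariate entered in the GLM instead of
        pre-residualized still recovers the planted edge."""
        cfg = AnalysisConfig(
            covariate_mode="LESION_VOLUME_PLUS_SC",
            covariate_as_regressor=True,
            permutation=PermutationConfig(n_perm=300, seed=4),
        )
        res, _ = functional_edge_analysis(planted_fc_cohort, cfg)
        assert res.survivors[self._planted_index(planted_fc_cohort)]

    def test_findings_reference_valid_rois_and_streams(self, planted_fc_cohort):
        cfg = AnalysisConfig(permutation=PermutationConfig(n_perm=100, alpha=0.5, seed=3))
        _, findings = functional_edge_analysis(planted_fc_cohort, cfg)
        p = planted_fc_cohort.parcellation
        assert findings, "expected some reported edges at alpha=0.5"
        for e in findings:
            a, b = p.index_of(e.roi_a), p.index_of(e.roi_b)
            assert a != b
        # survivor summaries can be filtered by hemisphere/stream labels
        left_ventral = {
            p.names[i] for i in p.ids_where(hemisphere="L", stream="ventral")
        }
        filtered = [
            e for e in findings if e.roi_a in left_ventral and e.roi_b in left_ventral
        ]
        assert isinstance(filtered, list)

    def test_behavior_selector(self, planted_fc_cohort):
        cfg = AnalysisConfig(
            behavior="spontaneous_speech",
            permutation=PermutationConfig(n_perm=100, seed=5),
        )
        res, _ = functional_edge_analysis(planted_fc_cohort, cfg)
        assert len(res.z) == EdgeIndexMap(planted_fc_cohort.parcellation.n_rois).n_edges

    def test_fisher_z_switch_runs(self, planted_fc_cohort):
        cfg = AnalysisConfig(
            fisher_z=True, permutation=PermutationConfig(n_perm=100, seed=6)
        )
        res, _ = functional_edge_analysis(planted_fc_cohort, cfg)
        assert np.isfinite(res.fwe_threshold)


class TestEdgeFinding:
    def test_self_edge_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            EdgeFinding("a", "a", 1.0, True)
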