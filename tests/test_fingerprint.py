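"""Motif-correlation scoring, threshold rules, fingerprint extraction, and
catalytic-site geometry."""

import numpy as np
import pytest

from allofret.entropy import CorrelationMatrix, ResidueTrajectory
from allofret.fingerprint import (FingerprintExtractor, MotifSpec,
                                  catalytic_geometry, compare_geometries,
                                  extract_fingerprint, motif_correlations,
                                  threshold_from_histogram)
from allofret.reference import ASYN_EXCLUSIVE_ALLOSTERIC_RESIDUES


def _matrix(ids, values):
    return CorrelationMatrix(residue_ids=np.asarray(ids, dtype=int),
                             values=np.asarray(values, dtype=float), lag=1,
                             normalized=True, window_summary=1)


def _planted_matrix(couplings, base=0.3, ids=None):
    """Matrix with chosen (residue, motif-residue) cells set high."""
    ids = list(range(218, 229)) + [150, 300, 320, 350] if ids is None else ids
    idx = {r: i for i, r in enumerate(ids)}
    v = np.full((len(ids), len(ids)), base)
    for (r, m), val in couplings.items():
        v[idx[r], idx[m]] = v[idx[m], idx[r]] = val
    return _matrix(ids, v)


class TestMotifCorrelations:
    def test_planted_maximum(self):
        corr = _planted_matrix({(350, 219): 0.95}, base=0.5)
        scores = motif_correlations(corr, aggregate="max")
        assert scores[350] == pytest.approx(0.95)
        assert 219 not in scores  # motif residues excluded from candidacy

    def test_all_sub_threshold(self):
        corr = _planted_matrix({}, base=0.5)
        scores = motif_correlations(corr, aggregate="max")
        assert all(s < 0.8 for s in scores.values())

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        ids = [219, 300, 301]
        v = rng.uniform(0, 1, (3, 3))
        v = 0.5 * (v + v.T)
        corr = _matrix(ids, v)
        motif = MotifSpec(motif_residue_ids=(219,), origin_residue_id=219)
        scores = motif_correlations(corr, motif, aggregate="max")
        for i, rid in enumerate(ids):
            if rid == 219:
                continue
            assert scores[rid] == pytest.approx(max(v[i, 0:1]))

    def test_missing_motif_residue_raises(self):
        corr = _matrix([300, 301], np.eye(2))
        with pytest.raises(KeyError, match="missing"):
            motif_correlations(corr)


class TestThreshold:
    def test_fixed_default(self):
        thr, experimental = threshold_from_histogram(mode="fixed")
        assert thr == 0.8 and not experimental

    def test_density_peak_rule_arithmetic(self):
        thr, experimental = threshold_from_histogram(
            mode="density_peak_rule", density=np.array([0.1, 2.2, 1.5]),
            axis_max=2.7)
        assert thr == pytest.approx(2.2 / 2.7)
        assert experimental

    def test_degenerate_distribution_flags(self):
        thr, experimental = threshold_from_histogram(
            np.full(100, 0.5), mode="density_peak_rule")
        assert thr == 1.0 and experimental


class TestExtractFingerprint:
    def test_planted_exclusive_set(self):
        bound = _planted_matrix({(300, 219): 0.95, (350, 222): 0.95,
                                 (320, 220): 0.9})
        free = _planted_matrix({(320, 220): 0.9})
        res = extract_fingerprint(bound, free, threshold=0.8, aggregate="max")
        assert res.exclusive_set == {300, 350}
        assert 320 in res.bound_set and 320 in res.free_set

    def test_identical_inputs_empty_exclusive(self):
        m = _planted_matrix({(300, 219): 0.95})
        res = extract_fingerprint(m, m, aggregate="max")
        assert res.exclusive_set == frozenset()

    def test_catalytic_domain_residue_excluded_by_range(self):
        bound = _planted_matrix({(150, 219): 0.95})
        free = _planted_matrix({})
        res = extract_fingerprint(bound, free, aggregate="max")
        assert 150 in res.bound_set
        assert 150 not in res.exclusive_set

    def test_threshold_nesting(self):
        rng = np.random.default_rng(1)
        ids = list(range(218, 229)) + list(range(280, 300))
        v = rng.uniform(0, 1, (len(ids), len(ids)))
        v = 0.5 * (v + v.T)
        bound, free = _matrix(ids, v), _matrix(ids, v * 0.5)
        prev = None
        for thr in np.arange(0.5, 0.96, 0.05):
            res = extract_fingerprint(bound, free, threshold=thr,
                                      aggregate="max")
            if prev is not None:
                assert res.bound_set <= prev.bound_set
                assert res.free_set <= prev.free_set
                assert res.exclusive_set <= prev.exclusive_set | prev.free_set
            prev = res

    def test_residue_set_mismatch_reports_difference(self):
        a = _planted_matrix({})
        b = _planted_matrix({}, ids=list(range(218, 229)) + [150, 300])
        with pytest.raises(ValueError, match="symmetric difference"):
            extract_fingerprint(a, b)

    def test_repeat_consensus_two_of_three(self):
        hit = _planted_matrix({(300, 219): 0.95})
        miss = _planted_matrix({})
        res = extract_fingerprint([hit, hit, miss], [miss, miss, miss],
                                  aggregate="max")
        assert 300 in res.exclusive_set
        res = extract_fingerprint([hit, miss, miss], [miss, miss, miss],
                                  aggregate="max")
        assert 300 not in res.exclusive_set

    def test_estimator_interface(self):
        bound = _planted_matrix({(300, 219): 0.95})
        free = _planted_matrix({})
        ext = FingerprintExtractor(aggregate="max").fit(bound, free)
        assert ext.exclusive_set_ == {300}
        assert ext.get_params()["threshold"] == 0.8


class TestReferenceResidueList:
    """The published aSyn-specific residue list is a format/range fixture."""

    def test_thirty_residues_in_hemopexin_range(self):
        motif = MotifSpec()
        ids = list(ASYN_EXCLUSIVE_ALLOSTERIC_RESIDUES.values())
        assert len(ids) == 30
        assert len(set(ids)) == 30
        assert all(motif.in_hemopexin(r) for r in ids)

    def test_names_match_ids(self):
        for name, rid in ASYN_EXCLUSIVE_ALLOSTERIC_RESIDUES.items():
            assert int(name[1:]) == rid


def _geometry_traj(frames, ids=(218, 219, 220)):
    coords = np.asarray(frames, dtype=float)
    return ResidueTrajectory(residue_ids=np.asarray(ids, dtype=int),
                             coords=coords)


MOTIF3 = MotifSpec(motif_residue_ids=(218, 219, 220), origin_residue_id=219)


class TestCatalyticGeometry:
    def test_static_structure_zero_spread(self):
        frame = [[0, 0, 0], [3, 0, 0], [0, 4, 0]]
        geo = catalytic_geometry(_geometry_traj([frame, frame]), MOTIF3)
        np.testing.assert_allclose(geo.pair_sd, 0.0)
        want = {(218, 219): 3.0, (218, 220): 4.0, (219, 220): 5.0}
        for pair, mean in zip(geo.motif_pairs, geo.pair_mean):
            assert mean == pytest.approx(want[pair])

    def test_origin_residue_at_zero(self):
        frame = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        geo = catalytic_geometry(_geometry_traj([frame, frame]), MOTIF3)
        origin_row = np.flatnonzero(geo.residue_ids == 219)[0]
        np.testing.assert_allclose(geo.mean_rel_position[origin_row], 0.0)

    def test_two_frame_translation_hand_computed(self):
        # residue 218 moves 1 A along x between the frames:
        # distances to 219 are 3 and 2 -> mean 2.5, SD 0.5
        f1 = [[0, 0, 0], [3, 0, 0], [0, 4, 0]]
        f2 = [[1, 0, 0], [3, 0, 0], [0, 4, 0]]
        geo = catalytic_geometry(_geometry_traj([f1, f2]), MOTIF3)
        i = geo.motif_pairs.index((218, 219))
        assert geo.pair_mean[i] == pytest.approx(2.5)
        assert geo.pair_sd[i] == pytest.approx(0.5)

    def test_all_atom_centroids(self):
        coords = np.zeros((2, 3, 3))
        traj = ResidueTrajectory(
            residue_ids=np.array([218, 219, 220]), coords=coords,
            atom_coords={
                218: np.tile(np.array([[0, 0, 0], [2, 0, 0]], dtype=float),
                             (2, 1, 1)),
                219: np.tile(np.array([[5.0, 0, 0]]), (2, 1, 1)),
                220: np.tile(np.array([[5.0, 3, 0]]), (2, 1, 1)),
            })
        geo = catalytic_geometry(traj, MOTIF3)
        i = geo.motif_pairs.index((218, 219))
        assert geo.pair_mean[i] == pytest.approx(4.0)  # centroid (1,0,0)
        assert geo.atom_mode == "all_atoms"


class TestCompareGeometries:
    @staticmethod
    def _geo(scale=1.0, shift218=0.0):
        f = np.array([[0 + shift218, 0, 0], [3, 0, 0], [0, 4, 0]]) * scale
        return catalytic_geometry(_geometry_traj([f, f]), MOTIF3)

    def test_identity(self):
        d = compare_geometries(self._geo(), self._geo())
        np.testing.assert_allclose(d["delta_mean"], 0.0)
        assert d["configuration_change_norm"] == 0.0

    def test_uniform_dilation(self):
        free, bound = self._geo(), self._geo(scale=1.1)
        d = compare_geometries(free, bound)
        np.testing.assert_allclose(d["delta_mean"], 0.1 * free.pair_mean)

    def test_single_residue_displacement_localized(self):
        d = compare_geometries(self._geo(), self._geo(shift218=0.5))
        for pair, delta in zip(self._geo().motif_pairs, d["delta_mean"]):
            if 218 in pair:
                assert abs(delta) > 0
            else:
                assert delta == pytest.approx(0.0)
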