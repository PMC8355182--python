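import numpy as np
import pandas as pd
import pytest

from oracles import (cross_corr_z_loop, fisher_z_loop, pairmate_score_loop,
                     scene_object_loop)
from remap_rsa import (PatternSet, SimConfig, ValidationError, align_scores,
                       cross_run_correlation, eligibility, fisher_z,
                       generate_dataset, lr_asymmetry, pairmate_score,
                       scene_object_scores, similarity_tensor)
from remap_rsa.pattern_similarity import (R_CLAMP, CrossRunMatrix,
                                          pairmate_scores_from_z)


class TestFisherZ:
    def test_fixed_point_and_closed_form(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
        assert fisher_z(-0.5) == -fisher_z(0.5)

    def test_boundary_clamped(self):
        assert fisher_z(1.0) == pytest.approx(np.arctanh(R_CLAMP))
        assert np.isfinite(fisher_z(-1.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.01)

    def test_vectorized_matches_scalar(self, rng):
        r = rng.uniform(-1, 1, 50)
        np.testing.assert_allclose(fisher_z(r), [fisher_z(v) for v in r])


def _pattern(catalog, values, round=1, phase="scene", region="HC"):
    ids = catalog.stimuli(phase)
    return PatternSet("p01", region, phase, round, ids, values)


class TestCrossRunCorrelation:
    def test_within_scan_forbidden(self, small_catalog, rng):
        a = _pattern(small_catalog, rng.standard_normal((8, 6)), round=2)
        b = _pattern(small_catalog, rng.standard_normal((8, 6)), round=2)
        with pytest.raises(ValidationError, match="within-scan"):
            cross_run_correlation(a, b)

    def test_zero_variance_row_names_stimulus(self, small_catalog, rng):
        vals = rng.standard_normal((8, 6))
        vals[3] = 2.5
        a = _pattern(small_catalog, vals, round=1)
        b = _pattern(small_catalog, rng.standard_normal((8, 6)), round=2)
        with pytest.raises(ValidationError, match=small_catalog.scene_ids[3]):
            cross_run_correlation(a, b)

    def test_self_correlation_hits_clamp(self, small_catalog, rng):
        vals = rng.standard_normal((8, 6))
        a = _pattern(small_catalog, vals, round=1)
        b = _pattern(small_catalog, vals, round=2)
        m = cross_run_correlation(a, b)
        np.testing.assert_allclose(np.diag(m.values), np.arctanh(R_CLAMP))

    def test_matches_per_pair_bruteforce(self, small_catalog, rng):
        A = rng.standard_normal((8, 5))
        B = rng.standard_normal((8, 5))
        m = cross_run_correlation(_pattern(small_catalog, A, round=1),
                                  _pattern(small_catalog, B, round=3))
        np.testing.assert_allclose(m.values, cross_corr_z_loop(A, B),
                                   atol=1e-10)


class TestPairmateScore:
    def _matrix(self, catalog, Z):
        ids = catalog.scene_ids
        return CrossRunMatrix("p01", "HC", "scene", 1, "scene", 2,
                              ids, ids, Z)

    def test_uniform_matrix_scores_zero(self, small_catalog):
        m = self._matrix(small_catalog, np.full((8, 8), 0.37))
        out = pairmate_score(m, small_catalog, 2)
        assert out["score"] == pytest.approx(0.0)

    def test_forced_arithmetic(self, small_catalog):
        Z = np.full((8, 8), 0.04)
        s1, s2 = small_catalog.scenes_of_pair(1)
        ids = small_catalog.scene_ids
        i1, i2 = ids.index(s1), ids.index(s2)
        Z[i1, i2] = Z[i2, i1] = 0.10
        out = pairmate_score(self._matrix(small_catalog, Z), small_catalog, 1)
        assert out["pairmate_sim"] == pytest.approx(0.10)
        assert out["non_pairmate_sim"] == pytest.approx(0.04)
        assert out["score"] == pytest.approx(0.06)

    def test_matches_exhaustive_enumeration(self, catalog, rng):
        Z = rng.standard_normal((36, 36))
        m = self._matrix(catalog, Z)
        ids = catalog.scene_ids
        for k in range(1, 19):
            s1, s2 = catalog.scenes_of_pair(k)
            pair, non, score = pairmate_score_loop(Z, ids, ids, s1, s2)
            out = pairmate_score(m, catalog, k)
            assert out["pairmate_sim"] == pytest.approx(pair, abs=1e-12)
            assert out["non_pairmate_sim"] == pytest.approx(non, abs=1e-12)
            assert out["score"] == pytest.approx(score, abs=1e-12)

    def test_vectorized_path_equals_scalar_path(self, catalog, rng):
        Z = rng.standard_normal((36, 36))
        ps, nps = pairmate_scores_from_z(Z)
        m = self._matrix(catalog, Z)
        for k in range(1, 19):
            out = pairmate_score(m, catalog, k)
            assert ps[k - 1] == pytest.approx(out["pairmate_sim"], abs=1e-12)
            assert nps[k - 1] == pytest.approx(out["non_pairmate_sim"],
                                               abs=1e-12)


def _aligned_setup(tiny_dataset):
    from remap_rsa import compute_learned_rounds
    ds = tiny_dataset.dataset
    lr = compute_learned_rounds(ds.trials, ds.catalog)
    tensor = similarity_tensor(ds, regions=["HC"])
    return ds, lr, tensor


class TestAlignScores:
    def test_round_pair_mapping(self):
        from remap_rsa.pattern_similarity import _alignment_round_pair
        # learned in round 4: IP={3,4}, pre-IP={2,3}, LR+2={4,6}
        assert _alignment_round_pair("IP", 4) == (3, 4)
        assert _alignment_round_pair("pre-IP", 4) == (2, 3)
        assert _alignment_round_pair("LR+2", 4) == (4, 6)
        assert _alignment_round_pair("LR-3", 4) == (1, 4)
        assert _alignment_round_pair("pre-IP", 2) is None
        assert _alignment_round_pair("LR+1", 6) is None

    def test_only_eligible_cells_present(self, tiny_dataset):
        ds, lr, tensor = _aligned_setup(tiny_dataset)
        aligned = align_scores(tensor, eligibility(lr), lr)
        merged = aligned.merge(lr, on=["participant", "pair_index"])
        assert merged["learned_round"].notna().all()
        ip = merged[merged["alignment"] == "IP"]
        assert (ip["learned_round"] >= 2).all()
        pre = merged[merged["alignment"] == "pre-IP"]
        assert (pre["learned_round"] >= 3).all()

    def test_scores_come_from_the_right_round_pair(self, tiny_dataset):
        ds, lr, tensor = _aligned_setup(tiny_dataset)
        aligned = align_scores(tensor, eligibility(lr), lr)
        lookup = tensor.set_index(
            ["participant", "pair_index", "round_i", "round_j"])["score"]
        lr_map = lr.set_index(["participant", "pair_index"])["learned_round"]
        for _, row in aligned[aligned["alignment"] == "IP"].iterrows():
            k = int(lr_map[(row["participant"], row["pair_index"])])
            assert row["score"] == lookup[
                (row["participant"], row["pair_index"], k - 1, k)]

    def test_missing_tensor_entry_is_error(self, tiny_dataset):
        ds, lr, tensor = _aligned_setup(tiny_dataset)
        cut = tensor[~((tensor["round_i"] == 1) & (tensor["round_j"] == 2))]
        if (lr["learned_round"] == 2).any():
            with pytest.raises(ValidationError, match="missing round pair"):
                align_scores(cut, eligibility(lr), lr)


class TestLrAsymmetry:
    def test_single_pair_learned_last_round_has_no_succeeding(self):
        aligned = pd.DataFrame({
            "participant": ["p"] * 3, "region": ["HC"] * 3,
            "pair_index": [1, 1, 1],
            "alignment": ["IP", "LR-2", "LR-3"],
            "score": [0.1, 0.2, 0.3]})
        out = lr_asymmetry(aligned)
        assert out.loc[0, "preceding_mean"] == pytest.approx(0.2)
        assert np.isnan(out.loc[0, "succeeding_mean"])

    def test_symmetric_scores_balance(self):
        recs = []
        for k, (pre, suc) in enumerate([(0.1, 0.1), (0.3, 0.3)], start=1):
            recs += [("p", "HC", k, "IP", pre), ("p", "HC", k, "LR+1", suc)]
        out = lr_asymmetry(pd.DataFrame(
            recs, columns=["participant", "region", "pair_index",
                           "alignment", "score"]))
        assert out.loc[0, "preceding_mean"] == out.loc[0, "succeeding_mean"]


class TestSceneObject:
    def test_identity_and_symmetry_constructions(self, small_catalog, rng):
        # scene patterns equal to their target object's pattern -> target
        # relative similarity near the clamp, competitor near baseline
        from remap_rsa.data_model import Dataset
        cat = small_catalog
        V = 24
        O = rng.standard_normal((8, V))
        obj_rows = {o: O[i] for i, o in enumerate(cat.object_ids)}
        patterns = {}
        scene_vals = np.stack([obj_rows[cat.assoc_object[s]]
                               for s in cat.scene_ids])
        for r in range(1, 7):
            patterns[("p01", "HC", "scene", r)] = PatternSet(
                "p01", "HC", "scene", r, cat.scene_ids, scene_vals)
        for r in (1, 6):
            patterns[("p01", "HC", "object", r)] = PatternSet(
                "p01", "HC", "object", r, cat.object_ids, O)
        trials = pd.DataFrame(
            [{"participant": "p01", "round": r, "scene_id": s,
              "choice": "target", "confidence": "high", "rt": 1.0}
             for r in range(1, 7) for s in cat.scene_ids])
        ds = Dataset(cat, patterns, trials)
        lr = pd.DataFrame({"participant": ["p01"] * 4,
                           "pair_index": [1, 2, 3, 4],
                           "learned_round": [3.0] * 4})
        out = scene_object_scores(ds, lr)
        t = out[out["relevance"] == "target"]["relative_similarity"]
        c = out[out["relevance"] == "competitor"]["relative_similarity"]
        assert (t > 5).all()          # clamped z minus finite baseline
        assert abs(c.mean()) < 1.0    # competitor near the baseline pool

    def test_matches_bruteforce_enumeration(self, tiny_config):
        sim = generate_dataset(tiny_config, with_recognition=False)
        ds = sim.dataset
        cat = ds.catalog
        from remap_rsa import compute_learned_rounds
        lr = compute_learned_rounds(ds.trials, ds.catalog)
        got = scene_object_scores(ds, lr, regions=["HC"])
        p = ds.participants[0]
        lr_of_pair = {
            int(r["pair_index"]):
                (None if pd.isna(r["learned_round"]) else int(r["learned_round"]))
            for _, r in lr[lr["participant"] == p].iterrows()}
        obj = (ds.pattern(p, "HC", "object", 1).reindexed(cat.object_ids)
               + ds.pattern(p, "HC", "object", 6).reindexed(cat.object_ids)) / 2
        obj_map = {o: obj[i] for i, o in enumerate(cat.object_ids)}
        scene_mats = {r: {s: ds.pattern(p, "HC", "scene", r).row(s)
                          for s in cat.scene_ids} for r in range(1, 7)}
        expect = scene_object_loop(scene_mats, obj_map, cat, lr_of_pair)
        sub = got[got["participant"] == p].set_index(
            ["pair_index", "state", "relevance"])["relative_similarity"]
        assert len(sub) == len(expect) > 0
        for key, val in expect.items():
            assert sub[key] == pytest.approx(val, abs=1e-10)


class TestInvariances:
    def test_voxel_permutation_leaves_tensor_unchanged(self, tiny_config, rng):
        sim = generate_dataset(tiny_config, with_recognition=False)
        ds = sim.dataset
        base = similarity_tensor(ds, regions=["HC"])
        perm = rng.permutation(tiny_config.n_voxels)
        shuffled = {key: PatternSet(ps.participant, ps.region, ps.phase,
                                    ps.round, ps.stimulus_ids,
                                    ps.values[:, perm])
                    for key, ps in ds.patterns.items()}
        from remap_rsa.data_model import Dataset
        ds2 = Dataset(ds.catalog, shuffled, ds.trials)
        out = similarity_tensor(ds2, regions=["HC"])
        pd.testing.assert_frame_equal(base, out)

    def test_affine_transform_of_one_row_is_invariant(self, tiny_config):
        sim = generate_dataset(tiny_config, with_recognition=False)
        ds = sim.dataset
        base = similarity_tensor(ds, regions=["HC"])
        key = ("p01", "HC", "scene", 1)
        vals = ds.patterns[key].values.copy()
        vals[5] = 3.0 * vals[5] + 11.0   # positive affine, one stimulus row
        patched = dict(ds.patterns)
        patched[key] = PatternSet(*key, ds.patterns[key].stimulus_ids, vals)
        from remap_rsa.data_model import Dataset
        out = similarity_tensor(Dataset(ds.catalog, patched, ds.trials),
                                regions=["HC"])
        pd.testing.assert_frame_equal(base, out)
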