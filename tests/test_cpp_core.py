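import numpy as np
import pandas as pd
import pytest

from cppsig.cpp_core import (
    CPPConfig,
    Feature,
    adjusted_auc,
    compute_feature_matrix,
    create_feature_space,
    positional_aggregation,
    prefilter,
    rank_features,
    redundancy_filter,
    run_cpp,
)
from cppsig.scales import AA_ORDER, Scale, ScaleSet
from cppsig.sequence_parts import ProteinEntry
from cppsig.splits import SplitSpec, enumerate_all
from cppsig.synthetic_data import positional_recall


def brute_force_adjusted_auc(test, ref):
    """All-pairs concordance count oracle (ties count 1/2)."""
    wins = sum((t > r) + 0.5 * (t == r) for t in test for r in ref)
    return wins / (len(test) * len(ref)) - 0.5


def toy_scaleset(n=3):
    rng = np.random.default_rng(5)
    scales = [
        Scale(f"s{i}", dict(zip(AA_ORDER, rng.random(20))), "cat", f"sub{i}")
        for i in range(n)
    ]
    return ScaleSet(scales)


class TestFeatureSpace:
    def test_product_counts(self):
        ss = toy_scaleset(4)
        splits = enumerate_all()[:5]
        feats = create_feature_space(["tmd", "tmd_c_jmd_c"], splits, ss)
        assert len(feats) == 2 * 5 * 4
        single = create_feature_space(["tmd"], splits[:1], ScaleSet(ss.scales[:1]))
        assert len(single) == 1

    def test_ids_stable_and_part_major(self):
        ss = toy_scaleset(2)
        splits = enumerate_all()[:2]
        a = create_feature_space(["tmd", "jmd_n_tmd_n"], splits, ss)
        b = create_feature_space(["tmd", "jmd_n_tmd_n"], splits, ss)
        assert [f.feature_id for f in a] == [f.feature_id for f in b]
        assert all(f.part_id == "tmd" for f in a[:4])

    def test_positions_on_reference_frame(self):
        ss = toy_scaleset(1)
        whole = SplitSpec(kind="segment", i_th=1, n_segments=1)
        (f,) = create_feature_space(["tmd_c_jmd_c"], [whole], ss)
        assert f.positions == tuple(range(21, 41))


class TestFeatureMatrix:
    def test_poly_leucine_whole_tmd(self):
        vals = {aa: 0.0 for aa in AA_ORDER}
        vals["L"] = 1.0
        ss = ScaleSet([Scale("lscale", vals)])
        entry = ProteinEntry(
            id="p", sequence="A" * 10 + "L" * 20 + "A" * 10, tmd_start=11, tmd_stop=30
        )
        whole = SplitSpec(kind="segment", i_th=1, n_segments=1)
        feats = create_feature_space(["tmd"], [whole], ss)
        M = compute_feature_matrix([entry], feats, ss)
        assert M.iloc[0, 0] == pytest.approx(1.0)

    def test_matches_handcomputed_toy(self):
        vals = {aa: i / 19 for i, aa in enumerate(AA_ORDER)}
        ss = ScaleSet([Scale("lin", vals)])
        seq = "ACDEFGHIKL" + "LIVFALIVFALIVFALIVFA" + "MNPQRSTVWY"
        entry = ProteinEntry(id="p", sequence=seq, tmd_start=11, tmd_stop=30)
        half1 = SplitSpec(kind="segment", i_th=1, n_segments=2)
        feats = create_feature_space(["tmd"], [half1], ss)
        M = compute_feature_matrix([entry], feats, ss)
        expected = np.mean([vals[c] for c in "LIVFALIVFA"])
        assert M.iloc[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_determinism(self, small_dataset, small_scaleset):
        entries, _, _ = small_dataset
        splits = enumerate_all()[:10]
        feats = create_feature_space(["tmd"], splits, small_scaleset)
        M1 = compute_feature_matrix(entries[:5], feats, small_scaleset)
        M2 = compute_feature_matrix(entries[:5], feats, small_scaleset)
        pd.testing.assert_frame_equal(M1, M2)

    def test_not_applicable_is_nan(self):
        ss = toy_scaleset(1)
        entry = ProteinEntry(
            id="p", sequence="A" * 10 + "L" * 20 + "A" * 10, tmd_start=11, tmd_stop=30
        )
        # span-15 pattern cannot fit the 10-residue TMD-C half
        pat = SplitSpec(kind="pattern", terminus="N", start_offset=1, steps=(4, 3, 4, 3))
        feats = create_feature_space(["tmd_c"], [pat], ss)
        M = compute_feature_matrix([entry], feats, ss)
        assert np.isnan(M.iloc[0, 0])


class TestAdjustedAUC:
    @pytest.mark.parametrize(
        "test,ref,expected",
        [
            ([0.9, 0.8, 0.7], [0.3, 0.2, 0.1], 0.5),
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([1, 3], [2, 4], -0.25),
        ],
    )
    def test_known_values(self, test, ref, expected):
        assert adjusted_auc(test, ref) == pytest.approx(expected)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            nt, nr = rng.integers(1, 9), rng.integers(1, 9)
            # discrete support makes ties frequent
            t = rng.integers(0, 5, nt).astype(float)
            r = rng.integers(0, 5, nr).astype(float)
            assert adjusted_auc(t, r) == pytest.approx(
                brute_force_adjusted_auc(t, r), abs=1e-12
            )

    def test_antisymmetry_and_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t, r = rng.random(6), rng.random(5)
            a = adjusted_auc(t, r)
            assert a == pytest.approx(-adjusted_auc(r, t), abs=1e-12)
            assert -0.5 <= a <= 0.5

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            adjusted_auc([], [1.0])


def make_stat_features(stats):
    """Features with preset statistics for filter/rank tests."""
    feats = []
    for i, st in enumerate(stats):
        f = Feature(
            feature_id=f"f{i:03d}",
            part_id="tmd",
            split_id=1,
            split=SplitSpec(kind="segment", i_th=1, n_segments=1),
            scale_id=st.get("scale_id", f"s{i}"),
            subcategory=st.get("subcategory", f"sub{i}"),
            positions=st.get("positions", (11, 12, 13, 14)),
        )
        f.mean_dif = st.get("mean_dif", 0.0)
        f.std_test = st.get("std_test", 0.1)
        f.adjusted_auc = st.get("adjusted_auc", 0.0)
        f.importance = st.get("importance", 0.0)
        feats.append(f)
    return feats


class TestPrefilter:
    def make_matrix(self, n_feats, test_std=0.05, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"T{i}" for i in range(10)] + [f"R{i}" for i in range(10)]
        cols = [f"f{i:03d}" for i in range(n_feats)]
        M = rng.normal(0.5, test_std, (20, n_feats)).clip(0, 1)
        return pd.DataFrame(M, index=ids, columns=cols)

    def test_top_k_by_absolute_mean_difference(self):
        M = self.make_matrix(200)
        M.loc[[f"T{i}" for i in range(10)], "f000"] += 0.0  # keep std small
        feats = make_stat_features([{} for _ in range(200)])
        for f in feats:
            f.feature_id = f.feature_id  # ids f000..f199 align with columns
        kept = prefilter(
            feats, M, [f"T{i}" for i in range(10)], [f"R{i}" for i in range(10)],
            CPPConfig(pct_pre_filter=0.05),
        )
        assert len(kept) == 10  # floor(0.05 * 200)
        worst_kept = min(abs(f.mean_dif) for f in kept)
        dropped = [f for f in feats if f not in kept and f.std_test <= 0.2]
        assert all(abs(f.mean_dif) <= worst_kept + 1e-12 for f in dropped)

    def test_high_test_std_dropped(self):
        M = self.make_matrix(20)
        noisy = M.copy()
        tids = [f"T{i}" for i in range(10)]
        noisy.loc[tids, "f000"] = np.linspace(0, 1, 10)  # std ~0.3 > 0.2
        feats = make_stat_features([{} for _ in range(20)])
        kept = prefilter(
            feats, noisy, tids, [f"R{i}" for i in range(10)], CPPConfig()
        )
        assert "f000" not in [f.feature_id for f in kept]
        assert feats[0].std_test > 0.2

    def test_overlapping_sets_rejected(self):
        M = self.make_matrix(5)
        feats = make_stat_features([{} for _ in range(5)])
        with pytest.raises(ValueError, match="disjoint"):
            prefilter(feats, M, ["T0"], ["T0", "R0"], CPPConfig())


class TestRankAndRedundancy:
    def test_rank_order_and_tiebreaks(self):
        feats = make_stat_features(
            [
                {"adjusted_auc": 0.3, "mean_dif": 0.1},
                {"adjusted_auc": -0.4, "mean_dif": 0.05},
                {"adjusted_auc": 0.3, "mean_dif": 0.2},
            ]
        )
        ranked = rank_features(feats)
        assert [f.feature_id for f in ranked] == ["f001", "f002", "f000"]

    def test_duplicate_rejected_disjoint_accepted(self):
        ss = toy_scaleset(3)
        feats = make_stat_features(
            [
                {"adjusted_auc": 0.5, "positions": (11, 12, 13, 14),
                 "scale_id": "s0", "subcategory": "sub0"},
                # exact positional duplicate, same subcategory -> rejected
                {"adjusted_auc": 0.4, "positions": (11, 12, 13, 14),
                 "scale_id": "s0", "subcategory": "sub0"},
                # same scale, disjoint positions -> accepted
                {"adjusted_auc": 0.3, "positions": (31, 32, 33, 34),
                 "scale_id": "s0", "subcategory": "sub0"},
            ]
        )
        out = redundancy_filter(feats, CPPConfig(), ss)
        assert [f.feature_id for f in out] == ["f000", "f002"]

    def test_n_filter_caps_output(self):
        ss = toy_scaleset(3)
        feats = make_stat_features(
            [
                {"adjusted_auc": 0.5 - i * 1e-3,
                 "positions": (11 + (i % 30),), "scale_id": f"s{i % 3}",
                 "subcategory": f"sub{i % 3}"}
                for i in range(60)
            ]
        )
        out = redundancy_filter(feats, CPPConfig(n_filter=15), ss)
        assert len(out) == 15
        assert out == feats[:15]  # non-redundant candidates kept in rank order

    def test_greedy_prefix_monotonicity(self):
        ss = toy_scaleset(3)
        rng = np.random.default_rng(9)
        feats = make_stat_features(
            [
                {"adjusted_auc": 0.5 - i * 1e-3,
                 "positions": tuple(sorted(rng.choice(range(11, 35), 4, replace=False))),
                 "scale_id": f"s{i % 3}", "subcategory": f"sub{i % 3}"}
                for i in range(40)
            ]
        )
        small = redundancy_filter(feats, CPPConfig(n_filter=5), ss)
        large = redundancy_filter(feats, CPPConfig(n_filter=12), ss)
        assert [f.feature_id for f in large][: len(small)] == [
            f.feature_id for f in small
        ]


class TestPositionalAggregation:
    def test_equal_share_and_conservation(self):
        feats = make_stat_features(
            [{"importance": 1.0, "positions": (11, 12, 13, 14), "mean_dif": 0.2}]
        )
        profile, fmap = positional_aggregation(feats)
        assert profile.loc[profile.position == 11, "importance"].item() == 0.25
        assert profile["importance"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_handbuilt_three_feature_toy(self):
        feats = make_stat_features(
            [
                {"importance": 0.6, "positions": (11, 12), "mean_dif": 0.1,
                 "subcategory": "A"},
                {"importance": 0.3, "positions": (12,), "mean_dif": -0.2,
                 "subcategory": "A"},
                {"importance": 0.1, "positions": (31, 32, 33, 34), "mean_dif": 0.3,
                 "subcategory": "B"},
            ]
        )
        profile, fmap = positional_aggregation(feats)
        by_pos = profile.set_index("position")["importance"]
        assert by_pos[11] == pytest.approx(0.3)
        assert by_pos[12] == pytest.approx(0.6)
        assert by_pos[31] == pytest.approx(0.025)
        assert profile["importance"].sum() == pytest.approx(1.0, abs=1e-9)
        row = fmap[(fmap.subcategory == "A") & (fmap.position == 12)]
        assert row["mean_dif"].item() == pytest.approx((0.1 - 0.2) / 2)


class TestRunCPP:
    def test_deterministic_reruns(self, small_dataset, small_scaleset):
        entries, _, _ = small_dataset
        test_ids = [e.id for e in entries if e.label.value == "positive"]
        ref_ids = [e.id for e in entries if e.label.value == "unlabeled"]
        cfg = CPPConfig(n_filter=20)
        r1 = run_cpp(entries, small_scaleset, test_ids, ref_ids, cfg)
        r2 = run_cpp(entries, small_scaleset, test_ids, ref_ids, cfg)
        assert [f.feature_id for f in r1.features] == [
            f.feature_id for f in r2.features
        ]
        pd.testing.assert_frame_equal(r1.matrix, r2.matrix)

    def test_planted_signature_recovered(self, small_cpp, small_dataset):
        _, truth, _ = small_dataset
        top = small_cpp.features[0]
        planted = truth.planted_union()
        assert set(top.positions) & planted
        assert positional_recall(small_cpp.features, truth, top=10) >= 0.6
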