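from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from sleepframe.enrichment import (
    ALL_FINGERPRINTS,
    CompoundLibrary,
    RankedList,
    annotation_statistic,
    collapse_per_compound,
    enrich_annotations,
    permutation_pvalue,
    rank_by_cosine,
    simulated_pvalue,
)
from sleepframe.synthetic_data import LibrarySimConfig, simulate_compound_library

QUERY = np.array([2.0, -1.0, 0.5, 1.5, -0.5, 1.0, 0.0, -2.0, 0.8, -0.3, 1.2, 0.4])


def library_from_vectors(vectors: dict[str, np.ndarray], annotations=None):
    rows = [
        [f"{cid}-r1", cid, *vec] for cid, vec in vectors.items()
    ]
    fp = pd.DataFrame(
        rows, columns=["fingerprint_id", "compound_id"] + [f"p{i+1}" for i in range(12)]
    )
    ann = {}
    if annotations:
        ann = {
            cls: pd.DataFrame(rows_, columns=["compound_id", "annotation_id"])
            for cls, rows_ in annotations.items()
        }
    return CompoundLibrary(fingerprints=fp, annotations=ann)


def ranked_from_cosines(cosines: dict[str, float]):
    table = pd.DataFrame(
        {
            "fingerprint_id": list(cosines),
            "compound_id": list(cosines),
            "cosine": list(cosines.values()),
        }
    ).sort_values("cosine", ascending=False).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return RankedList(table=table, mode="collapse")


class TestCollapse:
    def test_opposite_replicates_cancel(self):
        v = QUERY.copy()
        lib = library_from_vectors({"a": v})
        extra = lib.fingerprints.copy()
        extra.loc[1] = ["a-r2", "a", *(-v)]
        lib = CompoundLibrary(fingerprints=extra)
        out = collapse_per_compound(lib)
        assert len(out.fingerprints) == 1
        np.testing.assert_allclose(
            out.fingerprints[out.value_columns].to_numpy()[0], 0.0
        )

    def test_single_replicates_unchanged(self):
        lib = library_from_vectors({"a": QUERY, "b": -QUERY})
        out = collapse_per_compound(lib)
        pd.testing.assert_frame_equal(
            out.fingerprints[out.value_columns],
            lib.fingerprints[lib.value_columns],
        )

    def test_replicate_counting(self):
        cfg = LibrarySimConfig(n_compounds=100, replicates=3, seed=1)
        lib = simulate_compound_library(cfg, QUERY)
        assert len(collapse_per_compound(lib).fingerprints) == 100


class TestRanking:
    def test_query_itself_ranks_first(self):
        lib = library_from_vectors(
            {"q": QUERY, "other": np.roll(QUERY, 3), "anti": -QUERY}
        )
        ranked = rank_by_cosine(QUERY, lib)
        assert ranked.table.iloc[0]["compound_id"] == "q"
        assert ranked.table.iloc[0]["cosine"] == pytest.approx(1.0)
        assert ranked.table.iloc[-1]["compound_id"] == "anti"
        assert ranked.table.iloc[-1]["cosine"] == pytest.approx(-1.0)

    def test_hand_computed_order(self):
        a = np.zeros(12); a[0] = 1.0
        b = np.zeros(12); b[0] = 1.0; b[1] = 1.0
        c = np.zeros(12); c[1] = 1.0
        lib = library_from_vectors({"a": a, "b": b, "c": c})
        q = np.zeros(12); q[0] = 1.0
        ranked = rank_by_cosine(q, lib)
        assert list(ranked.table["compound_id"]) == ["a", "b", "c"]
        assert ranked.cosine_of("b") == pytest.approx(1 / np.sqrt(2))

    def test_all_mode_keeps_replicates(self):
        cfg = LibrarySimConfig(n_compounds=20, replicates=2, seed=2)
        lib = simulate_compound_library(cfg, QUERY)
        assert len(rank_by_cosine(QUERY, lib, mode=ALL_FINGERPRINTS).table) == 40

    def test_dimension_mismatch_rejected(self):
        lib = library_from_vectors({"a": QUERY})
        with pytest.raises(ValueError, match="entries"):
            rank_by_cosine(np.ones(5), lib)


class TestAnnotationStatistic:
    def test_sum_of_absolute_cosines(self):
        ranked = ranked_from_cosines({"a": 0.5, "b": -0.5, "c": 0.5, "d": -0.5, "e": 0.1})
        n, s = annotation_statistic(ranked, {"a", "b", "c", "d"})
        assert (n, s) == (4, pytest.approx(2.0))

    def test_single_negative_member(self):
        ranked = ranked_from_cosines({"a": -0.7, "b": 0.2})
        n, s = annotation_statistic(ranked, {"a"})
        assert (n, s) == (1, pytest.approx(0.7))

    def test_whole_library(self):
        cos = {"a": 0.3, "b": -0.4, "c": 0.1}
        ranked = ranked_from_cosines(cos)
        _, s = annotation_statistic(ranked, set(cos))
        assert s == pytest.approx(sum(abs(v) for v in cos.values()))

    def test_empty_intersection_rejected(self):
        ranked = ranked_from_cosines({"a": 0.3})
        with pytest.raises(ValueError):
            annotation_statistic(ranked, {"zzz"})


class TestPermutationPvalue:
    def test_count_over_b_convention(self):
        # the reported convention: 1470 larger draws of 100,000 -> 0.0147,
        # printed to two significant figures as 0.015
        p = simulated_pvalue(1470, 100_000)
        assert p == 0.0147
        assert f"{p:.2g}" == "0.015"
        assert simulated_pvalue(1470, 100_000, plus_one=True) == pytest.approx(
            1471 / 100_001
        )

    def test_degenerate_equal_cosines_give_p_zero(self):
        # every draw sums to exactly n·c; strict '>' yields count 0
        ranked = ranked_from_cosines({f"c{i}": 0.5 for i in range(10)})
        res = permutation_pvalue(ranked, n=4, s_observed=2.0, b=1000, seed=0)
        assert res.count_larger == 0 and res.p_value == 0.0

    def test_matches_exhaustive_enumeration(self):
        cos = {"a": 0.9, "b": -0.6, "c": 0.3, "d": -0.2, "e": 0.1, "f": 0.05}
        ranked = ranked_from_cosines(cos)
        n, b = 2, 40_000
        s_obs = 0.9 + 0.6  # members a, b
        res = permutation_pvalue(ranked, n, s_obs, b=b, seed=1)
        sums = [
            abs(cos[x]) + abs(cos[y]) for x, y in combinations(cos, 2)
        ]
        p_exact = sum(s > s_obs for s in sums) / len(sums)
        mc_err = 3 * np.sqrt(max(p_exact, 1 / b) * (1 - p_exact) / b)
        assert abs(res.p_value - p_exact) <= mc_err

    def test_invariant_to_library_reordering(self):
        cos = {"a": 0.9, "b": -0.6, "c": 0.3, "d": -0.2, "e": 0.1}
        r1 = ranked_from_cosines(cos)
        r2 = ranked_from_cosines(dict(reversed(list(cos.items()))))
        p1 = permutation_pvalue(r1, 2, 1.0, b=5000, seed=3).p_value
        p2 = permutation_pvalue(r2, 2, 1.0, b=5000, seed=3).p_value
        assert p1 == p2

    def test_n_out_of_range_rejected(self):
        ranked = ranked_from_cosines({"a": 0.5, "b": 0.1})
        with pytest.raises(ValueError):
            permutation_pvalue(ranked, 3, 0.5, b=100, seed=0)


class TestEnrichment:
    def test_two_sidedness_under_query_negation(self):
        cfg = LibrarySimConfig(n_compounds=60, annotation_rate=0.6, seed=4)
        lib = simulate_compound_library(cfg, QUERY)
        r_pos = rank_by_cosine(QUERY, lib)
        r_neg = rank_by_cosine(-QUERY, lib)
        e_pos = enrich_annotations(r_pos, lib, "target", b=2000, seed=5)
        e_neg = enrich_annotations(r_neg, lib, "target", b=2000, seed=5)
        merged = e_pos.merge(e_neg, on="annotation_id", suffixes=("_p", "_n"))
        np.testing.assert_allclose(merged["statistic_p"], merged["statistic_n"])
        np.testing.assert_allclose(merged["p_value_p"], merged["p_value_n"])

    def test_mixed_sign_members_sum_by_magnitude(self):
        ranked = ranked_from_cosines({"a": 0.4, "b": -0.4, "c": 0.4, "d": -0.4})
        n, s = annotation_statistic(ranked, {"a", "b", "c", "d"})
        assert s == pytest.approx(4 * 0.4)

    def test_inflating_member_cosines_never_increases_p(self):
        base = {"a": 0.5, "b": -0.3, "c": 0.2, "d": 0.1, "e": -0.05,
                "f": 0.15, "g": -0.25, "h": 0.35}
        members = {"a", "b"}
        previous_p = None
        for inflate in (1.0, 1.5, 2.0):
            cos = {k: (v * inflate if k in members else v) for k, v in base.items()}
            ranked = ranked_from_cosines(cos)
            n, s = annotation_statistic(ranked, members)
            p = permutation_pvalue(ranked, n, s, b=20_000, seed=6).p_value
            if previous_p is not None:
                assert p <= previous_p + 1e-12
            previous_p = p

    def test_planted_annotation_attains_minimum_p(self):
        wins = 0
        for s in range(5):
            cfg = LibrarySimConfig(
                n_compounds=100, planted_class="pathway",
                planted_annotation="PWY001", planted_members=10, effect=3.0,
                seed=40 + s,
            )
            lib = simulate_compound_library(cfg, QUERY)
            ranked = rank_by_cosine(QUERY, lib)
            res = enrich_annotations(ranked, lib, "pathway", b=5000, seed=s)
            planted_p = res.loc[res["annotation_id"] == "PWY001", "p_value"].iloc[0]
            wins += planted_p == res["p_value"].min()
        assert wins >= 4

    def test_unknown_class_rejected(self):
        lib = library_from_vectors({"a": QUERY})
        ranked = rank_by_cosine(QUERY, lib)
        with pytest.raises(ValueError):
            enrich_annotations(ranked, lib, "colour", b=10, seed=0)

    def test_unannotated_compounds_are_deleted_from_pool(self):
        vecs = {f"c{i}": np.roll(QUERY, i) for i in range(6)}
        lib = library_from_vectors(
            vecs, {"target": [("c0", "T1"), ("c1", "T1"), ("c2", "T2")]}
        )
        ranked = rank_by_cosine(QUERY, lib)
        res = enrich_annotations(ranked, lib, "target", b=500, seed=0)
        # the pool is the 3 annotated compounds; a 3-member annotation would
        # exhaust it, so T1's draws come from exactly those cosines
        assert set(res["annotation_id"]) == {"T1", "T2"}
        assert res.loc[res["annotation_id"] == "T1", "n"].iloc[0] == 2


class TestLibraryRoundTrip:
    def test_csv_round_trip(self, tmp_path):
        cfg = LibrarySimConfig(n_compounds=10, replicates=2, seed=9)
        lib = simulate_compound_library(cfg, QUERY)
        fp_path = tmp_path / "lib.csv"
        lib.to_csv(fp_path, annotation_dir=tmp_path)
        back = CompoundLibrary.from_csv(
            fp_path,
            {cls: tmp_path / f"annotations_{cls}.csv" for cls in lib.annotations},
        )
        pd.testing.assert_frame_equal(back.fingerprints, lib.fingerprints)
        for cls in lib.annotations:
            pd.testing.assert_frame_equal(back.annotations[cls], lib.annotations[cls])
        assert back.shortlisted.equals(lib.shortlisted.astype(bool))
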