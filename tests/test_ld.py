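"""LD grouping: r2 semantics, the greedy algorithm, and a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from rhizogwas.genotypes import GenotypeMatrix
from rhizogwas.ld import (
    annotate_groups,
    build_groups,
    group_of_variant,
    pairwise_r2,
    seed_set,
)

from conftest import toy_matrix


class TestPairwiseR2:
    def test_identical_columns(self):
        x = np.array([0, 1, 0, 1, 1.0])
        assert pairwise_r2(x, x) == pytest.approx(1.0)

    def test_complement_is_perfect_ld(self):
        x = np.array([0, 1, 0, 1, 1.0])
        assert pairwise_r2(x, 1 - x) == pytest.approx(1.0)

    def test_orthogonal_table(self):
        assert pairwise_r2(np.array([0, 0, 1, 1.0]),
                           np.array([0, 1, 0, 1.0])) == pytest.approx(0.0)

    def test_constant_on_complete_set_is_zero_by_contract(self):
        x = np.array([1, 1, 1, np.nan])
        y = np.array([0, 1, 0, 1.0])
        assert pairwise_r2(x, y) == 0.0

    def test_fewer_than_two_complete_pairs_undefined(self):
        x = np.array([1, np.nan, np.nan])
        y = np.array([np.nan, 1, 0.0])
        assert np.isnan(pairwise_r2(x, y))


def brute_force_grouping(dosage, ids, threshold):
    """Independent reimplementation of the greedy procedure from the
    full pairwise r2 matrix."""
    p = dosage.shape[1]
    r2 = np.full((p, p), np.nan)
    for i in range(p):
        for j in range(p):
            r2[i, j] = pairwise_r2(dosage[:, i], dosage[:, j])
    maf = []
    nmiss = []
    for j in range(p):
        col = dosage[:, j]
        obs = col[~np.isnan(col)]
        f = obs.mean() if len(obs) else np.nan
        maf.append(min(f, 1 - f) if len(obs) else -1)
        nmiss.append(np.isnan(col).sum())
    order = sorted(range(p), key=lambda j: (-maf[j], nmiss[j], j))
    ungrouped = set(range(p))
    groups, singles = [], []
    for j in order:
        if j not in ungrouped:
            continue
        ungrouped.discard(j)
        hits = [k for k in sorted(ungrouped)
                if not np.isnan(r2[j, k]) and r2[j, k] >= threshold]
        if hits:
            for k in hits:
                ungrouped.discard(k)
            groups.append((ids[j], frozenset(ids[k] for k in [j] + hits)))
        else:
            singles.append(ids[j])
    return groups, singles


class TestBuildGroups:
    def test_three_identical_columns_one_group(self):
        G = toy_matrix({"a": [0, 1, 1, 0], "b": [0, 1, 1, 0],
                        "c": [1, 0, 0, 1]})
        res = build_groups(G, 0.95)
        assert len(res.groups) == 1
        assert set(res.groups[0].member_ids) == {"a", "b", "c"}  # complement too
        assert res.ungrouped_ids == []

    def test_orthogonal_columns_all_ungrouped(self):
        G = toy_matrix({"a": [0, 0, 1, 1], "b": [0, 1, 0, 1]})
        res = build_groups(G, 0.95)
        assert res.groups == []
        assert set(res.ungrouped_ids) == {"a", "b"}

    def test_chain_grouping_is_seed_relative(self):
        """A~B and B~C above threshold but A~C below: the greedy pass
        seeds at A (highest MAF), groups B with it, and leaves C
        ungrouped."""
        n = 100
        a = np.zeros(n)
        a[:50] = 1
        b = a.copy()
        b[0] = 0  # 49 carriers
        c = b.copy()
        c[1] = 0  # 48 carriers
        thr = 0.95
        assert pairwise_r2(a, b) >= thr and pairwise_r2(b, c) >= thr
        assert pairwise_r2(a, c) < thr
        G = toy_matrix({"A": a, "B": b, "C": c})
        res = build_groups(G, thr)
        assert len(res.groups) == 1
        assert res.groups[0].seed_id == "A"
        assert set(res.groups[0].member_ids) == {"A", "B"}
        assert res.ungrouped_ids == ["C"]
        assert seed_set(res) == ["A", "C"]

    def test_matches_brute_force_oracle(self, small_panel):
        rng = np.random.default_rng(5)
        for rep in range(5):
            cols = rng.choice(small_panel.n_variants, size=30, replace=False)
            sub = small_panel.take_variants(np.sort(cols))
            ids = sub.variants["id"].tolist()
            for thr in (0.95, 0.80):
                res = build_groups(sub, thr)
                exp_groups, exp_singles = brute_force_grouping(
                    sub.dosage, ids, thr)
                got = [(g.seed_id, frozenset(g.member_ids))
                       for g in res.groups]
                assert got == exp_groups
                assert res.ungrouped_ids == exp_singles

    def test_membership_property_and_partition(self, small_panel):
        sub = small_panel.take_variants(np.arange(60))
        res = build_groups(sub, 0.9)
        all_ids = set(sub.variants["id"])
        seen = set(res.ungrouped_ids)
        for g in res.groups:
            assert len(g.member_ids) >= 2
            assert not seen.intersection(g.member_ids)
            seen.update(g.member_ids)
            for m in g.member_ids:
                r2 = pairwise_r2(sub.column(g.seed_id), sub.column(m))
                assert r2 >= 0.9
        assert seen == all_ids
        # disjoint member sets
        sizes = sum(len(g.member_ids) for g in res.groups)
        assert sizes + len(res.ungrouped_ids) == len(all_ids)

    def test_lower_threshold_never_more_ungrouped(self, small_panel):
        sub = small_panel.take_variants(np.arange(80))
        n95 = len(build_groups(sub, 0.95).ungrouped_ids)
        n80 = len(build_groups(sub, 0.80).ungrouped_ids)
        assert n80 <= n95

    def test_deterministic(self, small_panel):
        sub = small_panel.take_variants(np.arange(50))
        a = build_groups(sub, 0.9)
        b = build_groups(sub, 0.9)
        assert [g.member_ids for g in a.groups] == [g.member_ids
                                                    for g in b.groups]


class TestAnnotateGroups:
    def test_spanned_distance_single_replicon(self):
        G = toy_matrix({"a": [0, 1, 1, 0], "b": [0, 1, 1, 0]})
        G.variants.loc[:, "position"] = pd.array([100, 600], dtype="Int64")
        res = annotate_groups(build_groups(G, 0.95), G)
        assert res.groups[0].spanned_bp == 500
        assert res.groups[0].composition == "snp_only"

    def test_cross_replicon_group_has_no_span(self):
        G = toy_matrix({"a": [0, 1, 1, 0], "b": [0, 1, 1, 0]})
        G.variants.loc[1, "replicon"] = "pSymA"
        res = annotate_groups(build_groups(G, 0.95), G)
        assert res.groups[0].spanned_bp is None

    def test_mixed_composition(self):
        G = toy_matrix({"s1": [0, 1, 1, 0], "s2": [0, 1, 1, 0],
                        "p1": [0, 1, 1, 0]})
        G.variants.loc[2, "vtype"] = "PAV"
        res = annotate_groups(build_groups(G, 0.95), G)
        assert res.groups[0].composition == "mixed"

    def test_group_map_covers_universe(self, small_panel):
        sub = small_panel.take_variants(np.arange(40))
        res = build_groups(sub, 0.9)
        gmap = group_of_variant(res)
        assert set(gmap) == set(sub.variants["id"])


def test_seed_set_counts():
    G = toy_matrix({
        "a": [0, 1, 1, 0, 1, 0], "b": [0, 1, 1, 0, 1, 0],
        "c": [1, 1, 0, 0, 0, 1], "d": [1, 1, 0, 0, 0, 1],
        "e": [0, 0, 1, 1, 0, 1],
    })
    res = build_groups(G, 0.95)
    assert len(seed_set(res)) == len(res.groups) + len(res.ungrouped_ids)
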