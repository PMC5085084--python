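"""Band matrix construction, Dice/Nei-Li similarity, UPGMA, and
polymorphism accounting."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from msapseq.landscape import (
    BandMatrix,
    build_band_matrix,
    dice_similarity,
    polymorphic_percent,
    polymorphism_accounting,
    round_half_up,
    similarity_matrix,
    upgma_tree,
)

from oracles import dice_by_counting, upgma_cophenetic


class TestBandMatrix:
    def test_identical_spectra_identical_rows(self):
        bands = [("I", "MSP", 100), ("I", "HPA", 100), ("II", "MSP", 230)]
        bm = build_band_matrix({"s1": bands, "s2": list(bands)})
        assert (bm.row("s1") == bm.row("s2")).all()
        assert len(bm.bands) == 3

    def test_binning_merges_nearby_sizes(self):
        bm = build_band_matrix(
            {"s1": [("I", "MSP", 200)], "s2": [("I", "MSP", 200.4)]}, bin_width=1
        )
        assert len(bm.bands) == 1 and bm.data.to_numpy().sum() == 2

    def test_channels_are_separate_columns(self):
        bm = build_band_matrix({"s1": [("I", "MSP", 100), ("I", "HPA", 100)]})
        assert len(bm.bands) == 2

    def test_empty_spectrum_all_zero_row(self):
        bm = build_band_matrix({"s1": [("I", "MSP", 100)], "s2": []})
        assert bm.row("s2").sum() == 0

    def test_non_binary_cells_rejected(self):
        df = pd.DataFrame([[0, 2]], index=["s"], columns=["I:MSP:1", "I:MSP:2"])
        with pytest.raises(ValueError):
            BandMatrix(df)


class TestDiceSimilarity:
    def test_identity_gives_one(self):
        assert dice_similarity([1, 0, 1], [1, 0, 1]).S == 1.0

    def test_worked_example(self):
        r = dice_similarity([1, 1, 1, 0], [1, 1, 0, 1])
        assert (r.a, r.b, r.c) == (2, 1, 1)
        assert r.S == pytest.approx(4 / 6)
        assert r.distance == pytest.approx(1 - 4 / 6)

    def test_disjoint_supports_zero(self):
        assert dice_similarity([1, 0], [0, 1]).S == 0.0

    def test_shared_absences_ignored(self):
        base = dice_similarity([1, 1, 0], [1, 0, 1]).S
        padded = dice_similarity([1, 1, 0, 0, 0], [1, 0, 1, 0, 0]).S
        assert base == padded

    def test_all_absent_undefined(self):
        with pytest.raises(ValueError):
            dice_similarity([0, 0], [0, 0])

    def test_symmetric_random_rows(self, rng):
        for _ in range(20):
            x = rng.integers(0, 2, size=30)
            y = rng.integers(0, 2, size=30)
            if not (x.any() or y.any()):
                continue
            assert dice_similarity(x, y).S == dice_similarity(y, x).S


class TestPolymorphicPercent:
    def test_boundaries(self):
        assert polymorphic_percent(1.0) == 0.0
        assert polymorphic_percent(0.0) == 100.0

    def test_strictly_decreasing(self):
        grid = np.linspace(0, 1, 101)
        vals = [polymorphic_percent(s) for s in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_round_trip_against_direct_counting(self, rng):
        """Inverting the Dice coefficient recovers (b+c)/(a+b+c)."""
        for _ in range(50):
            x = rng.integers(0, 2, size=200)
            y = rng.integers(0, 2, size=200)
            r = dice_similarity(x, y)
            direct = 100 * (r.b + r.c) / (r.a + r.b + r.c)
            assert polymorphic_percent(r.S) == pytest.approx(direct, rel=1e-10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            polymorphic_percent(1.2)


class TestSimilarityMatrix:
    def test_duplicate_rows_give_unit_offdiagonal(self):
        bm = build_band_matrix(
            {"a": [("I", "MSP", 10)], "b": [("I", "MSP", 10)], "c": [("I", "MSP", 20)]}
        )
        sim = similarity_matrix(bm)
        assert sim.loc["a", "b"] == 1.0
        assert sim.loc["a", "c"] == 0.0
        assert np.allclose(np.diag(sim), 1.0)

    def test_matches_bruteforce_recount(self, rng):
        data = rng.integers(0, 2, size=(10, 50))
        data[:, 0] = 1  # avoid undefined pairs
        df = pd.DataFrame(
            data,
            index=[f"s{i}" for i in range(10)],
            columns=[f"I:MSP:{j}" for j in range(50)],
        )
        sim = similarity_matrix(BandMatrix(df))
        for i in range(10):
            for j in range(i + 1, 10):
                assert sim.iloc[i, j] == pytest.approx(
                    dice_by_counting(data[i], data[j]), rel=1e-12
                )
                assert sim.iloc[i, j] == sim.iloc[j, i]


def _dist_df(labels, fn):
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = fn(labels[i], labels[j])
    return pd.DataFrame(d, index=labels, columns=labels)


def _patristic(newick):
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda a, b: pdm.patristic_distance(taxa[a], taxa[b])


class TestUpgma:
    def test_three_leaf_hand_example(self):
        dd = _dist_df(
            ["A", "B", "C"], lambda x, y: 0.2 if {x, y} == {"A", "B"} else 0.6
        )
        tree = upgma_tree(dd)
        assert tree.newick == "((A:0.1,B:0.1):0.2,C:0.3);"

    def test_all_zero_distances_merge_at_zero(self):
        dd = _dist_df(["A", "B", "C"], lambda x, y: 0.0)
        tree = upgma_tree(dd)
        assert set(tree.heights) == {0.0}

    def test_reconstructs_ultrametric_exactly(self, rng):
        """On ultrametric input the UPGMA cophenetic distances equal the
        input distances."""
        for _ in range(5):
            # random ultrametric: random binary merge tree with growing heights
            labels = [f"L{i}" for i in range(8)]
            heights = np.sort(rng.uniform(0.05, 1.0, size=7))
            clusters = [[l] for l in labels]
            coph = {}
            for h in heights:
                i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
                for a in clusters[i]:
                    for b in clusters[j]:
                        coph[frozenset((a, b))] = 2 * h
                clusters[i] = clusters[i] + clusters[j]
                del clusters[j]
            dd = _dist_df(labels, lambda x, y: coph[frozenset((x, y))])
            tree = upgma_tree(dd)
            dist = _patristic(tree.newick)
            for a in labels:
                for b in labels:
                    if a != b:
                        assert dist(a, b) == pytest.approx(dd.loc[a, b], abs=1e-9)

    def test_agrees_with_oracle_and_scipy_on_random_input(self, rng):
        labels = [f"L{i}" for i in range(7)]
        m = rng.uniform(0.1, 1.0, size=(7, 7))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        dd = pd.DataFrame(m, index=labels, columns=labels)
        tree = upgma_tree(dd)
        dist = _patristic(tree.newick)
        oracle = upgma_cophenetic(
            {frozenset((a, b)): dd.loc[a, b] for a in labels for b in labels if a != b},
            labels,
        )
        for key, val in oracle.items():
            a, b = sorted(key)
            assert dist(a, b) == pytest.approx(val, abs=1e-9)
        # scipy average-linkage cophenetic distances as a second check
        coph = squareform(cophenet(linkage(squareform(m), method="average")))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert dist(a, b) == pytest.approx(coph[i, j], abs=1e-9)

    def test_pair_structure_first_split_separates_cultivars(self, small_experiment):
        """Two cultivar pairs with small within-pair distances segregate
        into their pair clusters before pairs join."""
        from msapseq.landscape import build_band_matrix, similarity_matrix

        spectra = small_experiment.sample_spectra()
        bm = build_band_matrix(spectra)
        sim = similarity_matrix(bm)
        tree = upgma_tree(1.0 - sim)
        dist = _patristic(tree.newick)
        p1 = [s for s in bm.samples if s.startswith("P1_")]
        p2 = [s for s in bm.samples if s.startswith("P2_")]
        max_within = max(
            max(dist(a, b) for a in p1 for b in p1 if a != b),
            max(dist(a, b) for a in p2 for b in p2 if a != b),
        )
        min_between = min(dist(a, b) for a in p1 for b in p2)
        assert max_within < min_between

    def test_asymmetric_input_rejected(self):
        dd = pd.DataFrame(
            [[0, 0.1], [0.3, 0]], index=["A", "B"], columns=["A", "B"]
        )
        with pytest.raises(ValueError):
            upgma_tree(dd)


def _matrix_from_rows(rows):
    samples = list(rows)
    cols = sorted({k for r in rows.values() for k in r})
    df = pd.DataFrame(
        [[rows[s].get(c, 0) for c in cols] for s in samples],
        index=samples,
        columns=cols,
    )
    return BandMatrix(df)


GROUPS = {
    "p1_std_1": ("1", "standard"),
    "p1_std_2": ("1", "standard"),
    "p1_som_1": ("1", "somaclone"),
    "p1_som_2": ("1", "somaclone"),
    "p2_std_1": ("2", "standard"),
    "p2_som_1": ("2", "somaclone"),
}


class TestPolymorphismAccounting:
    def test_gain_in_one_pair(self):
        band = "I:HPA:100"
        rows = {s: {band: 1 if "p1_som" in s else 0} | {"I:HPA:1": 1} for s in GROUPS}
        acc = polymorphism_accounting(_matrix_from_rows(rows), GROUPS)
        assert acc.table.loc[("I", "HPA"), "one_gained"] == 1
        assert acc.total_within_both() == 0

    def test_gain_in_both_pairs(self):
        band = "I:HPA:100"
        rows = {s: {band: 1 if "_som" in s else 0} | {"I:HPA:1": 1} for s in GROUPS}
        acc = polymorphism_accounting(_matrix_from_rows(rows), GROUPS)
        assert acc.table.loc[("I", "HPA"), "both_gained"] == 1
        assert acc.combos_with_within_both() == ["I"]

    def test_replicate_inconsistency_ignored(self):
        band = "I:HPA:100"
        rows = {s: {band: 0, "I:HPA:1": 1} for s in GROUPS}
        rows["p1_som_1"][band] = 1  # only one of two somaclone replicates
        acc = polymorphism_accounting(_matrix_from_rows(rows), GROUPS)
        assert acc.table["total"].sum() == 0

    def test_no_polymorphism_all_zero(self):
        rows = {s: {"I:HPA:1": 1, "II:MSP:2": 1} for s in GROUPS}
        acc = polymorphism_accounting(_matrix_from_rows(rows), GROUPS)
        assert acc.table["total"].sum() == 0

    def test_scope_partition_and_conservation(self, small_experiment):
        """Each polymorphic band lands in exactly one scope and totals add."""
        from msapseq.landscape import build_band_matrix

        spectra = small_experiment.sample_spectra()
        bm = build_band_matrix(spectra)
        groups = {
            s: (s.split("_")[0], "standard" if "_standard_" in s else "somaclone")
            for s in bm.samples
        }
        acc = polymorphism_accounting(bm, groups)
        t = acc.table
        assert (
            t["total"]
            == t[["one_gained", "one_lost", "both_gained", "both_lost", "both_mixed"]].sum(
                axis=1
            )
        ).all()
        assert len(acc.band_scope) == t["total"].sum()

    def test_unknown_sample_rejected(self):
        rows = {s: {"I:HPA:1": 1} for s in GROUPS}
        with pytest.raises(ValueError):
            polymorphism_accounting(
                _matrix_from_rows(rows), {**GROUPS, "ghost": ("1", "standard")}
            )


def test_round_half_up_at_printed_precision():
    assert round_half_up(0.99785, 4) == 0.9979
    assert round_half_up(2.3304, 2) == 2.33
    assert round_half_up(0.425, 2) == 0.43


class TestSimilarityProperties:
    """Property-based checks of the Dice coefficient and its inversion."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    rows = st.lists(st.integers(0, 1), min_size=1, max_size=60)

    @given(x=rows, y=rows)
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_similarity_bounds_and_inversion(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if not any(x) and not any(y):
            return
        r = dice_similarity(x, y)
        assert 0.0 <= r.S <= 1.0
        assert (r.S == 1.0) == (x == y)
        direct = 100 * (r.b + r.c) / (r.a + r.b + r.c)
        assert polymorphic_percent(r.S) == pytest.approx(direct, rel=1e-10)
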