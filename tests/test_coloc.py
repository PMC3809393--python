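"""Two-channel matching, overlap fractions, interfocal distances and
category counts, checked against hand arithmetic and a brute-force
assignment oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gamfoci._rng import child_rng
from gamfoci.coloc import (
    ColocConfig,
    category_counts,
    colocalization_fraction,
    green_per_red,
    interfocal_summary,
    match_foci,
)
from gamfoci.simulate import (
    CopyModel,
    FocusPairGeometry,
    simulate_cut_foci,
    simulate_focus_pairs,
)


def calls_df(rows):
    return pd.DataFrame(rows, columns=["cell_id", "channel", "x_um", "y_um"])


class TestMatchFoci:
    def test_coincident_pair_is_1to1_at_zero_distance(self):
        m = match_foci(calls_df([("a", "green", 1.0, 1.0), ("a", "red", 1.0, 1.0)]))
        assert m.cells["ratio_class"].tolist() == ["1:1"]
        assert m.pairs["distance_um"].iloc[0] == 0.0

    def test_one_green_two_red_yields_near_and_far(self):
        # distances 0.57 and 0.84 um from the green focus
        m = match_foci(
            calls_df(
                [
                    ("a", "green", 1.0, 1.0),
                    ("a", "red", 1.57, 1.0),
                    ("a", "red", 1.0, 1.84),
                ]
            )
        )
        assert m.cells["ratio_class"].tolist() == ["1:2"]
        near = m.pairs.loc[m.pairs["kind"] == "1:2-near", "distance_um"].iloc[0]
        far = m.pairs.loc[m.pairs["kind"] == "1:2-far", "distance_um"].iloc[0]
        assert near == pytest.approx(0.57)
        assert far == pytest.approx(0.84)
        assert near <= far

    def test_empty_channel_cell_excluded_and_counted(self):
        m = match_foci(
            calls_df([("a", "green", 1.0, 1.0),
                      ("b", "green", 0.5, 0.5), ("b", "red", 0.5, 0.5)])
        )
        assert m.n_excluded == 1
        assert m.cells["cell_id"].tolist() == ["b"]

    def test_matching_equals_brute_force_assignment(self):
        # oracle: minimum-total-distance assignment by explicit enumeration
        rng = child_rng(9, "brute_force")
        for trial in range(30):
            n_g = int(rng.integers(1, 7))
            n_r = int(rng.integers(1, 7))
            g = rng.uniform(0, 3, size=(n_g, 2))
            r = rng.uniform(0, 3, size=(n_r, 2))
            rows = [("c", "green", x, y) for x, y in g] + [
                ("c", "red", x, y) for x, y in r
            ]
            m = match_foci(calls_df(rows))
            # a 1:2 cell reports the assignment pair (near) plus the far
            # distance; only assignment pairs enter the oracle comparison
            matched = m.pairs[m.pairs["kind"] != "1:2-far"]
            got = np.sort(matched["distance_um"].to_numpy())

            k = min(n_g, n_r)
            best = None
            big, small = (g, r) if n_g >= n_r else (r, g)
            for perm in itertools.permutations(range(len(big)), k):
                d = np.linalg.norm(small - big[list(perm)], axis=1)
                if best is None or d.sum() < best.sum():
                    best = d
            assert got == pytest.approx(np.sort(best))

    def test_swapping_channels_preserves_1to1_distances(self):
        rows = [("a", "green", 0.1, 0.2), ("a", "red", 0.3, 0.4),
                ("b", "green", 1.0, 1.0), ("b", "red", 1.1, 0.9)]
        m1 = match_foci(calls_df(rows))
        m2 = match_foci(calls_df(rows), green_channel="red", red_channel="green")
        assert m1.pairs["distance_um"].tolist() == pytest.approx(
            m2.pairs["distance_um"].tolist()
        )


class TestColocalizationFraction:
    def test_all_zero_distances_full_overlap(self):
        rows = [(f"c{i}", ch, 1.0, 1.0) for i in range(5) for ch in ("green", "red")]
        pct, _ = colocalization_fraction(match_foci(calls_df(rows)))
        assert pct == 100.0

    def test_hand_count_eight_of_ten(self):
        rows = []
        for i in range(8):
            rows += [(f"c{i}", "green", 1.0, 1.0), (f"c{i}", "red", 1.05, 1.0)]
        for i in range(8, 10):
            rows += [(f"c{i}", "green", 1.0, 1.0), (f"c{i}", "red", 1.30, 1.0)]
        pct, sem = colocalization_fraction(
            match_foci(calls_df(rows)), ColocConfig(overlap_threshold_um=0.2)
        )
        assert pct == pytest.approx(80.0)
        assert sem == pytest.approx(100 * math.sqrt(0.8 * 0.2 / 10))

    def test_generator_at_zero_distance_fully_overlapped(self):
        calls = simulate_focus_pairs(0.0, FocusPairGeometry(), 200, seed=1)
        pct, _ = colocalization_fraction(
            match_foci(calls), ColocConfig(overlap_threshold_um=0.05)
        )
        assert pct == 100.0

    def test_monotone_in_threshold(self):
        calls = simulate_focus_pairs(55.0, FocusPairGeometry(), 500, seed=2)
        m = match_foci(calls)
        pcts = [
            colocalization_fraction(m, ColocConfig(overlap_threshold_um=t))[0]
            for t in (0.05, 0.1, 0.2, 0.4, 0.8)
        ]
        assert all(a <= b for a, b in zip(pcts, pcts[1:]))

    def test_sem_across_experiments(self):
        rows = []
        for i in range(6):
            rows += [(f"c{i}", "green", 1.0, 1.0), (f"c{i}", "red", 1.0, 1.0)]
        labels = {f"c{i}": i % 2 for i in range(6)}
        pct, sem = colocalization_fraction(match_foci(calls_df(rows)),
                                           experiments=labels)
        assert pct == 100.0 and sem == 0.0

    def test_no_1to1_cells_rejected(self):
        m = match_foci(calls_df([("a", "green", 0, 0), ("a", "red", 0, 0),
                                 ("a", "red", 1, 1)]))
        with pytest.raises(ValueError):
            colocalization_fraction(m)


class TestInterfocalSummary:
    def test_single_pair_mean_is_distance(self):
        m = match_foci(calls_df([("a", "green", 0.0, 0.0), ("a", "red", 0.3, 0.4)]))
        s = interfocal_summary(m)
        assert s.mean_distance_1to1 == pytest.approx(0.5)
        assert s.mean_distance_near is None and s.mean_distance_far is None

    def test_hand_means_per_class(self):
        rows = [
            ("a", "green", 0.0, 0.0), ("a", "red", 0.1, 0.0),       # 1:1 d=0.1
            ("b", "green", 0.0, 0.0), ("b", "red", 0.3, 0.0),       # 1:1 d=0.3
            ("c", "green", 0.0, 0.0), ("c", "red", 0.2, 0.0),       # 1:2
            ("c", "red", 0.0, 0.6),
        ]
        s = interfocal_summary(match_foci(calls_df(rows)))
        assert s.mean_distance_1to1 == pytest.approx(0.2)
        assert s.mean_distance_near == pytest.approx(0.2)
        assert s.mean_distance_far == pytest.approx(0.6)
        assert s.counts["1:1"] == 2 and s.counts["1:2"] == 1

    def test_mean_1to1_distance_monotone_in_genomic_separation(self):
        geom = FocusPairGeometry()
        means = []
        for g in (10.0, 80.0, 2400.0):
            calls = simulate_focus_pairs(g, geom, 2000, seed=4)
            means.append(interfocal_summary(match_foci(calls)).mean_distance_1to1)
        assert means[0] <= means[1] <= means[2]


class TestCategoryCounts:
    def test_identical_sets_all_both(self):
        a = pd.DataFrame({"x_um": [0.0, 1.0], "y_um": [0.0, 1.0]})
        out = category_counts(a, a.copy())
        assert out.both_pct == 100.0
        assert out.a_only_pct == 0.0 and out.b_only_pct == 0.0

    def test_disjoint_sets_split_proportionally(self):
        a = pd.DataFrame({"x_um": [0.0, 0.0, 0.0], "y_um": [0.0, 5.0, 10.0]})
        b = pd.DataFrame({"x_um": [20.0], "y_um": [0.0]})
        out = category_counts(a, b)
        assert out.both_pct == 0.0
        assert out.a_only_pct == pytest.approx(75.0)
        assert out.b_only_pct == pytest.approx(25.0)

    def test_hand_count_four_coincident_of_ten_each(self):
        # 10 A and 10 B foci, 4 coincident pairs: pooled denominator
        # 10+10-4 = 16 gives both = 25%; per-channel denominator gives
        # 4/10 = 40% of each channel matched
        ax = [float(i) for i in range(10)]
        bx = [float(i) for i in range(4)] + [float(i) + 100 for i in range(4, 10)]
        a = pd.DataFrame({"x_um": ax, "y_um": 0.0})
        b = pd.DataFrame({"x_um": bx, "y_um": 0.0})
        out = category_counts(a, b)
        assert out.n_matched == 4
        assert out.both_pct == pytest.approx(100 * 4 / 16)
        per = category_counts(a, b, denominator="per_channel")
        assert per.both_pct_a == pytest.approx(40.0)
        assert per.both_pct_b == pytest.approx(40.0)

    def test_symmetry_under_channel_swap(self):
        rng = child_rng(3, "cat_sym")
        a = pd.DataFrame({"x_um": rng.uniform(0, 5, 12), "y_um": rng.uniform(0, 5, 12)})
        b = pd.DataFrame({"x_um": rng.uniform(0, 5, 7), "y_um": rng.uniform(0, 5, 7)})
        ab = category_counts(a, b)
        ba = category_counts(b, a)
        assert ab.both_pct == pytest.approx(ba.both_pct)
        assert ab.a_only_pct == pytest.approx(ba.b_only_pct)
        assert ab.b_only_pct == pytest.approx(ba.a_only_pct)

    def test_percentages_sum_to_hundred(self):
        rng = child_rng(4, "cat_sum")
        a = pd.DataFrame({"x_um": rng.uniform(0, 3, 9), "y_um": rng.uniform(0, 3, 9)})
        b = pd.DataFrame({"x_um": rng.uniform(0, 3, 5), "y_um": rng.uniform(0, 3, 5)})
        out = category_counts(a, b)
        assert out.both_pct + out.a_only_pct + out.b_only_pct == pytest.approx(100.0)

    def test_both_empty_rejected(self):
        empty = pd.DataFrame(columns=["x_um", "y_um"])
        with pytest.raises(ValueError):
            category_counts(empty, empty)


class TestGreenPerRed:
    def test_equal_counts_unity(self):
        assert green_per_red([1, 2, 1], [1, 2, 1]) == 1.0

    def test_exact_ratio(self):
        assert green_per_red([82], [100]) == pytest.approx(0.82)

    def test_detection_thinning_recovers_efficiency(self):
        # fully cut, fully labelled chromosomes: green = Binomial(red, p)
        model = CopyModel(copies={2: 0.5, 4: 0.5}, cut_prob=1.0)
        n = 20000
        green = simulate_cut_foci(model, p=0.82, n_cells=n, seed=8)
        red = simulate_cut_foci(model, p=1.0, n_cells=n, seed=8)
        ratio = green_per_red(green, red)
        se = math.sqrt(0.82 * 0.18 / red.sum())
        assert abs(ratio - 0.82) <= 3 * se

    def test_no_red_rejected(self):
        with pytest.raises(ValueError):
            green_per_red([1, 2], [0, 0])
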