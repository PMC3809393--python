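"""Generator correctness: branching traces, dose-response thinning,
copy-number cutting, pair geometry, image rendering, determinism."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gamfoci.simulate import (
    CopyModel,
    FocusPairGeometry,
    ImageScene,
    SimParams,
    render_image,
    simulate_cut_foci,
    simulate_dose_response,
    simulate_focus_pairs,
    simulate_microcolony,
)

FAST_GROWTH = ((0.0, 1.0),)  # constant 1 h interdivision time


class TestSimParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"r": -0.1},
            {"r": 1.5},
            {"p": math.nan},
            {"b": -1.0},
            {"y": math.inf},
            {"tau_schedule": ((0.0, 0.0),)},
            {"tau_schedule": ((1.0, 1.0),)},
            {"tau_schedule": ((0.0, 1.0), (0.5, 2.0), (0.5, 3.0))},
            {"seed": -1},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimParams(**kwargs)

    def test_tau_schedule_lookup(self):
        p = SimParams(tau_schedule=((0.0, 1.0), (9.0, 12.0)))
        assert p.tau_at(0.0) == 1.0
        assert p.tau_at(8.99) == 1.0
        assert p.tau_at(9.0) == 12.0
        assert p.next_boundary(0.0) == 9.0
        assert p.next_boundary(9.0) == math.inf


class TestMicrocolony:
    def test_zero_rate_gives_zero_foci(self):
        tr = simulate_microcolony(SimParams(r=0.0, p=1.0, seed=3), t_end=12.0)
        assert (tr.frames["cum_foci"] == 0).all()
        tr.validate()

    def test_forced_absorption_arrests_at_two_cells(self):
        for seed in range(5):
            tr = simulate_microcolony(
                SimParams(r=1.0, p=1.0, arrest_on_focus=True,
                          tau_schedule=FAST_GROWTH, seed=seed),
                t_end=50.0,
            )
            assert tr.n_divisions == 1
            assert int(tr.frames["n_cells"].iloc[-1]) == 2
            assert tr.n_foci == 1
            tr.validate()

    def test_conservation_invariant_across_seeds(self):
        for seed in range(8):
            tr = simulate_microcolony(
                SimParams(r=0.05, p=0.71, seed=seed), t_end=20.0, max_cells=60
            )
            tr.validate()
            assert (tr.frames["n_cells"] == 1 + tr.frames["cum_divisions"]).all()

    def test_foci_per_division_matches_bernoulli_thinning(self):
        # one Bernoulli(q) focus per division: colony-mean foci/divisions
        # must agree with q within Monte-Carlo error.  Arrest is disabled so
        # every colony reaches a fixed division count and the expectation is
        # exactly q (the per-division Bernoulli enumeration oracle).
        q = 0.0145
        params_proto = dict(r=q, p=1.0, arrest_on_focus=False,
                            tau_schedule=FAST_GROWTH)
        f = []
        for seed in range(1500):
            tr = simulate_microcolony(
                SimParams(seed=seed, **params_proto), t_end=60.0, max_cells=101
            )
            assert tr.n_divisions >= 100
            f.append(tr.n_foci / tr.n_divisions)
        f = np.asarray(f)
        se = f.std(ddof=1) / math.sqrt(len(f))
        assert abs(f.mean() - q) <= 3 * se

    def test_arrested_cells_never_divide_again(self):
        tr = simulate_microcolony(
            SimParams(r=0.3, p=1.0, arrest_on_focus=True, tau_schedule=FAST_GROWTH,
                      seed=11),
            t_end=12.0,
        )
        tr.validate(arrest_on_focus=True)  # raises on violation

    def test_fixed_seed_reproducible(self):
        a = simulate_microcolony(SimParams(seed=7), t_end=15.0, max_cells=80)
        b = simulate_microcolony(SimParams(seed=7), t_end=15.0, max_cells=80)
        pd.testing.assert_frame_equal(a.frames, b.frames)
        pd.testing.assert_frame_equal(a.events, b.events)

    def test_bad_t_end_rejected(self):
        with pytest.raises(ValueError):
            simulate_microcolony(SimParams(), t_end=0.0)


class TestDoseResponse:
    def test_zero_yield_zero_background(self):
        t = simulate_dose_response(SimParams(y=0.0, b=0.0, seed=1), [0, 50, 140], 200)
        assert (t["mean_foci"] == 0).all()

    def test_poisson_mean_recovered_without_thinning(self):
        y, d, n = 0.05, 100.0, 20000
        t = simulate_dose_response(SimParams(y=y, p=1.0, b=0.0, seed=2), [d], n)
        se = t["sd_foci"].iloc[0] / math.sqrt(n)
        assert abs(t["mean_foci"].iloc[0] - y * d) <= 3 * se

    def test_thinned_mean_with_background(self):
        # closed form: b + p*y*D = 0.043 + 0.71*0.031*140 = 3.124
        params = SimParams(y=0.031, p=0.71, b=0.043, seed=5)
        t = simulate_dose_response(params, [140.0], 10000)
        se = t["sd_foci"].iloc[0] / math.sqrt(10000)
        assert abs(t["mean_foci"].iloc[0] - 3.1241) <= 3 * se

    def test_thinning_moments(self):
        # detected = Binomial(Poisson(yD), p) + Bernoulli(b):
        # mean = p*y*D + b ; var = p*y*D + b*(1-b)
        params = SimParams(y=0.031, p=0.71, b=0.043, seed=9)
        d, n = 100.0, 20000
        t = simulate_dose_response(params, [d], n)
        mean_th = 0.71 * 0.031 * d + 0.043
        var_th = 0.71 * 0.031 * d + 0.043 * (1 - 0.043)
        mean_se = math.sqrt(var_th / n)
        var_se = var_th * math.sqrt(2.0 / (n - 1))  # normal-approx SE of a variance
        assert abs(t["mean_foci"].iloc[0] - mean_th) <= 3 * mean_se
        assert abs(t["sd_foci"].iloc[0] ** 2 - var_th) <= 4 * var_se

    def test_empty_doses_rejected(self):
        with pytest.raises(ValueError):
            simulate_dose_response(SimParams(), [], 10)
        with pytest.raises(ValueError):
            simulate_dose_response(SimParams(), [0.0], 0)


class TestCutFoci:
    def test_single_copy_always_one_focus(self):
        m = CopyModel(copies={1: 1.0}, cut_prob=1.0)
        counts = simulate_cut_foci(m, p=1.0, n_cells=500, seed=1)
        assert (counts == 1).all()

    def test_two_copies_always_multifocus(self):
        m = CopyModel(copies={2: 1.0}, cut_prob=1.0)
        counts = simulate_cut_foci(m, p=1.0, n_cells=500, seed=2)
        assert (counts > 1).all()

    def test_multifocus_fraction_matches_exact_enumeration(self):
        # oracle: exact mixture over copy number of Binomial(c, cut*p)
        cut, p = 0.8, 0.8
        pe = cut * p
        exact = 0.5 * sum(
            1 - stats.binom.pmf(0, c, pe) - stats.binom.pmf(1, c, pe) for c in (2, 4)
        )
        m = CopyModel(copies={2: 0.5, 4: 0.5}, cut_prob=cut)
        counts = simulate_cut_foci(m, p=p, n_cells=50000, seed=3)
        frac = (counts > 1).mean()
        se = math.sqrt(exact * (1 - exact) / 50000)
        assert abs(frac - exact) <= 3 * se

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            CopyModel(copies={2: 0.5, 4: 0.4}, cut_prob=0.5)
        with pytest.raises(ValueError):
            CopyModel(copies={0: 1.0}, cut_prob=0.5)


class TestFocusPairs:
    def test_zero_genomic_distance_overlaps(self):
        calls = simulate_focus_pairs(0.0, FocusPairGeometry(), 50, seed=1)
        wide = calls.pivot(index="cell_id", columns="channel", values=["x_um", "y_um"])
        d = np.hypot(
            wide[("x_um", "green")] - wide[("x_um", "red")],
            wide[("y_um", "green")] - wide[("y_um", "red")],
        )
        assert np.allclose(d, 0.0)

    def test_plateau_mean_recovered(self):
        geom = FocusPairGeometry(plateau_um=0.57, halfsat_kb=35.0)
        calls = simulate_focus_pairs(2400.0, geom, 10000, seed=2)
        wide = calls.pivot(index="cell_id", columns="channel", values=["x_um", "y_um"])
        d = np.hypot(
            wide[("x_um", "green")] - wide[("x_um", "red")],
            wide[("y_um", "green")] - wide[("y_um", "red")],
        ).to_numpy()
        se = d.std(ddof=1) / math.sqrt(len(d))
        assert abs(d.mean() - 0.57) <= 3 * se

    def test_mean_displacement_monotone_in_genomic_distance(self):
        geom = FocusPairGeometry()
        means = []
        for g in (10.0, 55.0, 80.0):
            calls = simulate_focus_pairs(g, geom, 4000, seed=3)
            wide = calls.pivot(index="cell_id", columns="channel",
                               values=["x_um", "y_um"])
            means.append(
                float(
                    np.hypot(
                        wide[("x_um", "green")] - wide[("x_um", "red")],
                        wide[("y_um", "green")] - wide[("y_um", "red")],
                    ).mean()
                )
            )
        assert means[0] <= means[1] <= means[2]

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            simulate_focus_pairs(-1.0, FocusPairGeometry(), 10, seed=0)


class TestRenderImage:
    def test_empty_scene_all_zero(self):
        scene = ImageScene(shape=(16, 16), pixel_size_um=0.1, spots=(), background=0.0)
        img = render_image(scene, seed=1)
        assert (img == 0).all()

    def test_brightest_pixel_near_spot_center(self):
        scene = ImageScene(
            shape=(32, 32), pixel_size_um=0.1,
            spots=((1.5, 1.6, 1000.0, 0.2),), background=10.0,
        )
        hits = 0
        for seed in range(200):
            img = render_image(scene, seed=seed)
            r, c = np.unravel_index(np.argmax(img), img.shape)
            if abs(r - 16) <= 1 and abs(c - 15) <= 1:
                hits += 1
        assert hits >= 198  # >= 99% of seeds

    def test_total_photon_count_matches_gaussian_integral(self):
        amp, sigma, px, bg = 500.0, 0.2, 0.1, 5.0
        scene = ImageScene(
            shape=(64, 64), pixel_size_um=px,
            spots=((3.2, 3.2, amp, sigma),), background=bg,
        )
        expected = bg * 64 * 64 + amp * 2 * math.pi * (sigma / px) ** 2
        totals = [render_image(scene, seed=s).sum() for s in range(50)]
        se = np.std(totals, ddof=1) / math.sqrt(len(totals))
        assert abs(np.mean(totals) - expected) <= 3 * se

    def test_spot_outside_field_rejected(self):
        with pytest.raises(ValueError):
            ImageScene(shape=(16, 16), pixel_size_um=0.1,
                       spots=((5.0, 0.5, 100.0, 0.2),))

    def test_fixed_seed_reproducible(self):
        scene = ImageScene(shape=(16, 16), pixel_size_um=0.1,
                           spots=((0.8, 0.8, 100.0, 0.2),), background=3.0)
        assert (render_image(scene, 4) == render_image(scene, 4)).all()
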