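"""Permutation test, bootstrap, and the four selection criteria."""

import numpy as np
import pytest

from evlock import curves, inference as inf
from evlock import simulate as sim

CLASSES = ("POScorr", "LURfalse")
NOISE = sim.NoiseSpec(ar1_coeff=0.3, white_sd=1.0, amp_jitter_sigma=0.0)


def effect_tensor(seed, n_per_class=150, n_regions=8, effect_region=7,
                  effect=0.8):
    """Null windows everywhere except an HRF-shaped bump in one region."""
    knots = sim.template_knots(sim.ResponseTemplate("r", "x"))
    means_a = np.zeros((n_regions, 12))
    means_b = np.zeros((n_regions, 12))
    means_b[effect_region] = effect * knots
    return sim.sample_trials(
        {CLASSES[0]: means_a, CLASSES[1]: means_b},
        {CLASSES[0]: n_per_class, CLASSES[1]: n_per_class},
        NOISE, seed,
    )


class TestPermutationCriticalValue:
    def test_deterministic_given_seed(self):
        t = sim.sample_null_trials({c: 40 for c in CLASSES}, 5, NOISE, 0)
        a = inf.permutation_critical_value(t, CLASSES, (0, 5), 100, seed=9)
        b = inf.permutation_critical_value(t, CLASSES, (0, 5), 100, seed=9)
        assert a.critical_value == b.critical_value
        np.testing.assert_array_equal(
            a.null_max_distribution, b.null_max_distribution
        )

    def test_nearest_rank_quantile_convention(self):
        vals = np.arange(1.0, 101.0)
        assert inf._nearest_rank_quantile(vals, 0.95) == 95.0
        assert inf._nearest_rank_quantile(vals, 0.5) == 50.0

    def test_injected_effect_exceeds_critical(self):
        """A strong one-region contrast clears the max-statistic threshold."""
        detected = 0
        for r in range(10):
            t = effect_tensor(seed=100 + r)
            res = inf.permutation_critical_value(
                t, CLASSES, (0, 5), n_perm=200, seed=r
            )
            areas = inf.delta_area_by_region(t, CLASSES, (0, 5))
            detected += int(areas.iloc[7] > res.critical_value)
        assert detected >= 9

    def test_requires_two_trials_per_class(self):
        t = sim.sample_null_trials({CLASSES[0]: 1, CLASSES[1]: 40}, 3, NOISE, 0)
        with pytest.raises(ValueError):
            inf.permutation_critical_value(t, CLASSES, (0, 5), 100)

    def test_raising_quantile_never_enlarges_selection(self):
        t = effect_tensor(seed=3, effect=0.35)
        areas = inf.delta_area_by_region(t, CLASSES, (0, 5))
        selected = []
        for q in (0.8, 0.9, 0.95, 0.99):
            res = inf.permutation_critical_value(
                t, CLASSES, (0, 5), n_perm=200, quantile=q, seed=1
            )
            selected.append(set(areas.index[areas > res.critical_value]))
        for small, large in zip(selected[1:], selected[:-1]):
            assert small <= large


class TestBootstrap:
    def test_zero_noise_bootstrap_degenerates(self):
        knots = sim.template_knots(sim.ResponseTemplate("r", "x"))
        t = sim.sample_trials(
            {c: knots[None, :] for c in CLASSES},
            {c: 30 for c in CLASSES},
            sim.NoiseSpec.none(), 0,
        )
        res = inf.bootstrap_observables(
            t, CLASSES, inf.area_observable(CLASSES, "R000", (0, 5)),
            n_boot=50, seed=0,
        )
        assert res.boot_std < 1e-6
        assert not res.z_defined or not np.isfinite(res.z)

    def test_deterministic_given_seed(self):
        t = effect_tensor(seed=5)
        fn = inf.area_observable(CLASSES, "R007", (0, 5))
        a = inf.bootstrap_observables(t, CLASSES, fn, n_boot=50, seed=4)
        b = inf.bootstrap_observables(t, CLASSES, fn, n_boot=50, seed=4)
        assert a.boot_std == b.boot_std and a.boot_mean == b.boot_mean

    def test_alternative_numerator_stored(self):
        t = effect_tensor(seed=6)
        res = inf.bootstrap_observables(
            t, CLASSES, inf.area_observable(CLASSES, "R007", (0, 5)),
            n_boot=50, seed=0,
        )
        assert res.z == res.point_estimate / res.boot_std
        assert res.z_boot_mean == res.boot_mean / res.boot_std


class TestSelectionLogic:
    def make_curve_pair(self, shift=0.0, amp_b=1.0):
        base = sim.ResponseTemplate("r", "a", dip_amplitude=-0.15)
        ka = sim.template_knots(base)
        kb = amp_b * sim.template_knots(
            sim.ResponseTemplate("r", "a", onset_shift=shift,
                                 dip_amplitude=-0.15)
        )
        times = np.arange(-2.0, 10.0)
        return (curves.interpolate(times, ka), curves.interpolate(times, kb))

    def test_area_selection_boundary_cases(self):
        """Regions sit exactly around the study's critical value 0.5453:
        above is selected, at-or-below is not, monotone curves never are."""
        criteria = inf.SelectionCriteria(maxima_window=(1, 5), area_window=(0, 5))
        strong = self.make_curve_pair(amp_b=0.0)  # flat B: large area but no B max
        pair = self.make_curve_pair(amp_b=0.4)

        curves_by_region = {"hit": pair, "flatB": strong}
        table = inf.select_area_regions(
            curves_by_region, critical=0.01, criteria=criteria,
            region_sizes={"hit": 100, "flatB": 100},
        )
        assert bool(table.loc["hit", "selected"])
        assert not bool(table.loc["flatB", "selected"])  # no in-window max for B

        # exact threshold comparisons: dArea must strictly exceed critical
        area = table.loc["hit", "delta_area"]
        just_below = inf.select_area_regions(
            {"hit": pair}, critical=area, criteria=criteria
        )
        assert not bool(just_below.loc["hit", "selected"])

    def test_small_region_excluded_by_size(self):
        criteria = inf.SelectionCriteria()
        pair = self.make_curve_pair(amp_b=0.4)
        table = inf.select_area_regions(
            {"tiny": pair}, critical=0.01, criteria=criteria,
            region_sizes={"tiny": 9},
        )
        assert not bool(table.loc["tiny", "selected"])

    def test_delay_criteria_hand_computed(self):
        """z > 2, sigma < 0.15, range > 0.1 applied to constructed rows."""
        from evlock.observables import Chord, EdgeDelay

        criteria = inf.SelectionCriteria()
        chord = Chord(0.0, 0.0, 3.0, 1.0)

        def edge(mean, sigma, rng_):
            return EdgeDelay("leading", mean, sigma, rng_, True, chord, chord)

        def boot(point, std):
            return inf.BootstrapResult(point, std, point, 100, 0, 0)

        import pandas as pd

        area_table = pd.DataFrame(
            {"size": 100, "delta_area": 0.9, "has_maxima": True,
             "size_ok": True, "selected": True},
            index=pd.Index(["ok", "lowz", "wide", "narrow"], name="region"),
        )
        delays = {
            "ok": edge(0.64, 0.10, 0.5),
            "lowz": edge(0.30, 0.10, 0.5),
            "wide": edge(0.64, 0.20, 0.5),     # sigma 0.2 >= 0.15 -> excluded
            "narrow": edge(0.64, 0.10, 0.05),  # range 0.05 <= 0.1 -> excluded
        }
        boots = {
            "ok": boot(0.64, 0.2),    # z = 3.2
            "lowz": boot(0.30, 0.2),  # z = 1.5
            "wide": boot(0.64, 0.2),
            "narrow": boot(0.64, 0.2),
        }
        table = inf.select_delay_regions(area_table, delays, boots, criteria)
        assert bool(table.loc["ok", "selected"])
        assert not bool(table.loc["lowz", "selected"])
        assert not bool(table.loc["wide", "selected"])
        assert not bool(table.loc["narrow", "selected"])

    def test_irrelevant_region_never_delay_selected(self):
        import pandas as pd
        from evlock.observables import Chord, EdgeDelay

        criteria = inf.SelectionCriteria()
        area_table = pd.DataFrame(
            {"size": 100, "delta_area": 0.2, "has_maxima": True,
             "size_ok": True, "selected": False},
            index=pd.Index(["r"], name="region"),
        )
        chord = Chord(0.0, 0.0, 3.0, 1.0)
        delays = {"r": EdgeDelay("leading", 1.0, 0.01, 0.9, True, chord, chord)}
        boots = {"r": inf.BootstrapResult(1.0, 0.1, 1.0, 100, 0, 0)}
        table = inf.select_delay_regions(area_table, delays, boots, criteria)
        assert not bool(table.loc["r", "selected"])
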