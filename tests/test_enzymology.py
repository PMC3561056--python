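"""Initial rates, dose-response fitting, funnel filters and selectivity stats."""

import numpy as np
import pandas as pd
import pytest

from synlethnet.enzymology import (
    KineticTrace,
    counterscreen_filter,
    fit_ic50,
    initial_rate,
    lipinski_filter,
    percent_inhibition,
    screen_funnel,
    selectivity_test,
    traces_from_frame,
)
from synlethnet.simdata import (
    CompoundSpec,
    KineticSimConfig,
    simulate_counterscreen,
    simulate_kinetic_screen,
)


def trace(times, rfu, conc=0.0):
    return KineticTrace("CPD", conc, times, rfu)


class TestInitialRate:
    def test_exact_line(self):
        est = initial_rate(trace([0, 1, 2], [0, 10, 20]))
        assert est.slope == pytest.approx(10.0)
        assert est.r_squared == pytest.approx(1.0)

    def test_constant_trace_zero_slope(self):
        est = initial_rate(trace([0, 1, 2, 3], [5, 5, 5, 5]))
        assert est.slope == pytest.approx(0.0)

    def test_slope_on_curved_trace_matches_closed_form_ols(self):
        """Full-window OLS on a saturating trace equals the cov/var closed form;
        an early window recovers the t->0 tangent k * f_max within 15%."""
        t = np.arange(0, 10.5, 0.5)
        rfu = 1000 * (1 - np.exp(-0.05 * t))
        est = initial_rate(trace(t, rfu))
        oracle = np.sum((t - t.mean()) * (rfu - rfu.mean())) / np.sum((t - t.mean()) ** 2)
        assert est.slope == pytest.approx(oracle, rel=1e-9)
        # curvature pulls the full-window slope ~20% below the tangent ...
        assert est.slope == pytest.approx(39.21, abs=0.01)
        # ... while a short leading window tracks the tangent closely
        early = initial_rate(trace(t, rfu), window_fraction=0.3)
        assert early.slope == pytest.approx(50.0, rel=0.15)

    def test_window_fraction_recovers_tangent_better(self):
        t = np.arange(0, 10.25, 0.25)
        rfu = 1000 * (1 - np.exp(-0.2 * t))
        full = initial_rate(trace(t, rfu))
        early = initial_rate(trace(t, rfu), window_fraction=0.2)
        assert abs(early.slope - 200.0) < abs(full.slope - 200.0)
        assert early.window[1] <= 2.0 + 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            trace([0, 1], [0, 1])
        with pytest.raises(ValueError, match="at least 3"):
            initial_rate(trace([0, 1, 9, 10], [0, 1, 2, 3]), window_fraction=0.3)


class TestPercentInhibition:
    @pytest.mark.parametrize("slope, expected", [(0.0, 100.0), (50.0, 0.0), (25.0, 50.0)])
    def test_reference_points(self, slope, expected):
        vehicle = initial_rate(trace([0, 1, 2], [0, 50, 100]))
        est = initial_rate(trace([0, 1, 2], [0, slope, 2 * slope]))
        assert percent_inhibition(est, vehicle) == pytest.approx(expected)

    def test_degenerate_vehicle_rejected(self):
        vehicle = initial_rate(trace([0, 1, 2], [100, 50, 0]))
        with pytest.raises(ValueError, match="degenerate vehicle"):
            percent_inhibition(vehicle, vehicle)

    def test_antitone_in_slope(self):
        vehicle = initial_rate(trace([0, 1, 2], [0, 50, 100]))
        pcts = [
            percent_inhibition(initial_rate(trace([0, 1, 2], [0, s, 2 * s])), vehicle)
            for s in np.linspace(0, 60, 13)
        ]
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))

    def test_stimulation_capped_at_100_but_not_below(self):
        vehicle = initial_rate(trace([0, 1, 2], [0, 50, 100]))
        boosted = initial_rate(trace([0, 1, 2], [0, 80, 160]))
        assert percent_inhibition(boosted, vehicle) == pytest.approx(-60.0)


def four_pl(c, bottom, top, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


class TestFitIC50:
    doses = np.array([1e-8, 3.16e-8, 1e-7, 3.16e-7, 1e-6, 3.16e-6, 1e-5, 3.16e-5])

    def test_noiseless_self_consistency(self):
        act = four_pl(self.doses, 0.0, 100.0, 1e-6, 1.0)
        fit = fit_ic50(self.doses, act)
        assert fit.converged
        assert fit.ic50 == pytest.approx(1e-6, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)
        assert fit.top == pytest.approx(100.0, abs=1e-4)
        assert fit.bottom == pytest.approx(0.0, abs=1e-4)

    def test_unit_rescaling_equivariance(self):
        act = four_pl(self.doses, 2.0, 98.0, 5e-7, 1.3)
        fit_molar = fit_ic50(self.doses, act)
        fit_micromolar = fit_ic50(self.doses * 1e6, act)
        assert fit_micromolar.ic50 == pytest.approx(fit_molar.ic50 * 1e6, rel=1e-6)
        assert fit_micromolar.hill == pytest.approx(fit_molar.hill, rel=1e-6)

    def test_flat_series_flagged_not_raised(self):
        fit = fit_ic50(self.doses, np.full_like(self.doses, 100.0))
        assert (not fit.converged) or (not fit.ic50_in_range)

    def test_noisy_recovery_within_20_percent_mostly(self):
        """5%-noise 8-point series from a 500 nM compound: quick version."""
        ok = 0
        n = 100
        truth = four_pl(self.doses, 0.0, 100.0, 5e-7, 1.0)
        for seed in range(n):
            rng = np.random.default_rng(seed)
            act = truth * (1.0 + rng.normal(0, 0.05, self.doses.size))
            fit = fit_ic50(self.doses, act)
            ok += fit.converged and abs(fit.ic50 - 5e-7) / 5e-7 <= 0.20
        assert ok / n >= 0.90

    def test_input_validation(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_ic50([1e-6, 2e-6, 3e-6], [90, 50, 10])
        with pytest.raises(ValueError, match="> 0"):
            fit_ic50([0.0, 1e-6, 2e-6, 3e-6], [100, 90, 50, 10])


class TestFilters:
    def test_counterscreen_removes_persistent_inhibition(self):
        retained = counterscreen_filter(
            ["art", "real"], {"art": 75.0, "real": 5.0}, threshold=50.0
        )
        assert retained == ["real"]

    def test_counterscreen_missing_entry_names_compound(self):
        with pytest.raises(ValueError, match="orphan"):
            counterscreen_filter(["orphan"], {})

    @pytest.mark.parametrize(
        "mw, clogp, hbd, hba, passes, violation",
        [
            (300.0, 2.0, 2, 4, True, ""),
            (650.0, 2.0, 2, 4, False, "mw"),
            (300.0, 6.5, 2, 4, False, "clogp"),
            (300.0, 2.0, 6, 4, False, "hbd"),
            (300.0, 2.0, 2, 11, False, "hba"),
            (499.9, 5.0, 5, 10, True, ""),  # boundary conventions
            (500.0, 5.0, 5, 10, False, "mw"),  # MW bound is strict
        ],
    )
    def test_rule_of_five(self, mw, clogp, hbd, hba, passes, violation):
        df = pd.DataFrame(
            [{"compound_id": "X", "mw": mw, "clogp": clogp, "hbd": hbd, "hba": hba}]
        )
        out = lipinski_filter(df)
        assert bool(out.loc[0, "passes"]) is passes
        assert violation in out.loc[0, "violations"]

    def test_missing_descriptor_rejected(self):
        with pytest.raises(ValueError, match="clogp"):
            lipinski_filter(pd.DataFrame([{"compound_id": "X", "mw": 1.0, "hbd": 0, "hba": 0}]))
        bad = pd.DataFrame(
            [{"compound_id": "X", "mw": np.nan, "clogp": 1.0, "hbd": 0, "hba": 0}]
        )
        with pytest.raises(ValueError, match="X"):
            lipinski_filter(bad)


class TestSelectivity:
    def test_identical_groups_not_significant(self):
        res = selectivity_test({"wt": [90, 100, 110], "mut": [90, 100, 110]})
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert not res.pairwise["significant"].any()

    def test_separated_groups_flagged(self, rng):
        a = 100 + rng.normal(0, 0.5, 10)
        b = 50 + rng.normal(0, 0.5, 10)
        res = selectivity_test({"wt": a, "ko": b})
        assert res.pairwise.loc[0, "p_adj"] < 1e-3
        assert res.pairwise.loc[0, "mean_diff"] == pytest.approx(50.0, abs=1.0)

    def test_only_shifted_group_pairs_flagged(self, rng):
        groups = {
            "wt": 100 + rng.normal(0, 1, 8),
            "het": 100 + rng.normal(0, 1, 8),
            "ko": 60 + rng.normal(0, 1, 8),
        }
        res = selectivity_test(groups)
        flagged = res.pairwise[res.pairwise["significant"]]
        assert len(flagged) == 2
        assert all("ko" in {r.group_a, r.group_b} for r in flagged.itertuples())

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2 genotypes"):
            selectivity_test({"wt": [1, 2, 3]})
        with pytest.raises(ValueError, match="replicates"):
            selectivity_test({"wt": [1, 2], "ko": [3]})

    def test_tukey_matches_statsmodels(self, rng):
        """Cross-check adjusted p-values against an independent implementation."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = {
            "wt": 100 + rng.normal(0, 5, 6),
            "het": 92 + rng.normal(0, 5, 6),
            "ko": 70 + rng.normal(0, 5, 6),
        }
        res = selectivity_test(groups)
        values = np.concatenate([groups[g] for g in groups])
        labels = np.repeat(list(groups), [len(groups[g]) for g in groups])
        sm = pairwise_tukeyhsd(values, labels)
        sm_p = {
            frozenset((str(row[0]), str(row[1]))): float(p)
            for row, p in zip(sm.summary().data[1:], sm.pvalues)
        }
        for r in res.pairwise.itertuples():
            assert r.p_adj == pytest.approx(sm_p[frozenset((r.group_a, r.group_b))], abs=1e-6)


class TestScreenFunnel:
    def test_noiseless_funnel_keeps_exactly_druglike_true_inhibitors(self):
        compounds = (
            CompoundSpec("inh-good", 1e-6),
            CompoundSpec("inh-greasy", 2e-6),        # true inhibitor, fails rule of five
            CompoundSpec("art-quench", 5e-7, 1.0, True),
            CompoundSpec("inactive", 1e-2),
        )
        cfg = KineticSimConfig(
            f_max=1000.0, k_uninhibited=0.05, baseline=20.0, noise_sd=0.0,
            compounds=compounds, seed=0,
        )
        dose = 1e-5
        traces = simulate_kinetic_screen(cfg, [0.0, dose])
        counter = simulate_counterscreen(cfg, dose)
        descriptors = pd.DataFrame(
            [
                {"compound_id": "inh-good", "mw": 350.0, "clogp": 2.0, "hbd": 1, "hba": 4},
                {"compound_id": "inh-greasy", "mw": 620.0, "clogp": 6.2, "hbd": 1, "hba": 4},
                {"compound_id": "art-quench", "mw": 380.0, "clogp": 3.0, "hbd": 2, "hba": 5},
                {"compound_id": "inactive", "mw": 300.0, "clogp": 1.0, "hbd": 1, "hba": 3},
            ]
        )
        funnel = screen_funnel(traces, counter, descriptors, screening_conc=dose)
        assert set(funnel.primary_hits) == {"inh-good", "inh-greasy", "art-quench"}
        assert set(funnel.after_counterscreen) == {"inh-good", "inh-greasy"}
        assert funnel.final_hits == ["inh-good"]

    def test_traces_from_frame_groups_by_compound_and_dose(self):
        cfg = KineticSimConfig(compounds=(CompoundSpec("A", 1e-6), CompoundSpec("B", 1e-6)))
        traces = simulate_kinetic_screen(cfg, [0.0, 1e-6])
        parsed = traces_from_frame(traces)
        assert {(t.compound_id, t.conc) for t in parsed} == {
            ("A", 0.0), ("A", 1e-6), ("B", 0.0), ("B", 1e-6),
        }
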