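"""Subtype calling, Kaplan-Meier, logrank, two-group Cox and the
best-cutoff metagene scan."""

import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as lifelines_logrank

import emstate as es
from emstate.errors import ScanDomainError, StratumEmptyError, UndefinedStatisticError


def make_cohort(times, events, markers=None, genes=None):
    n = len(times)
    data = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "time": times,
            "event": events,
            "ESR": (markers or {}).get("ESR", np.full(n, 100.0)),
            "HER2": (markers or {}).get("HER2", np.full(n, 100.0)),
            "MKI67": (markers or {}).get("MKI67", np.full(n, 100.0)),
        }
    )
    gene_cols = ()
    if genes is not None:
        for name, vals in genes.items():
            data[name] = vals
        gene_cols = tuple(genes)
    return es.SurvivalCohort(data=data, gene_columns=gene_cols)


class TestCallSubtypes:
    def bimodal(self, high_mask, lo=16.0, hi=512.0):
        return np.where(high_mask, hi, lo).astype(float)

    def test_stgallen_mapping(self, rng):
        n = 40
        esr_hi = np.arange(n) < 20
        her2_hi = np.arange(n) % 2 == 0
        mki = np.where(np.arange(n) % 4 < 2, 400.0, 10.0)
        cohort = make_cohort(
            rng.uniform(1, 100, n),
            rng.integers(0, 2, n),
            markers={
                "ESR": self.bimodal(esr_hi) * rng.lognormal(0, 0.05, n),
                "HER2": self.bimodal(her2_hi) * rng.lognormal(0, 0.05, n),
                "MKI67": mki,
            },
        )
        calls = es.call_subtypes(cohort)
        for i in range(n):
            sub = calls["subtype"].iloc[i]
            if esr_hi[i] and her2_hi[i]:
                assert sub == "luminal_B"
            elif not esr_hi[i] and not her2_hi[i]:
                assert sub == "basal"
            elif not esr_hi[i] and her2_hi[i]:
                assert sub == "HER2pos"
            else:
                assert sub in ("luminal_A", "luminal_B")
        # ESR+/HER2-: MKI67 split decides A vs B
        lum = calls[(calls["esr_pos"]) & (~calls["her2_pos"])]
        assert set(lum["subtype"]) == {"luminal_A", "luminal_B"}

    def test_planted_bimodal_marker_agreement(self):
        cohort, truth = es.simulate_survival_cohort(
            es.SurvSimConfig(n_patients=500, seed=5)
        )
        calls = es.call_subtypes(cohort, random_state=0)
        for marker, col in (("ESR", "esr_pos"), ("HER2", "her2_pos")):
            agreement = (
                calls[col].values == truth.marker_high[marker].values
            ).mean()
            assert agreement >= 0.95

    def test_subtype_total_and_deterministic(self):
        cohort, _ = es.simulate_survival_cohort(es.SurvSimConfig(n_patients=200, seed=3))
        a = es.call_subtypes(cohort, random_state=1)
        b = es.call_subtypes(cohort, random_state=1)
        assert set(a["subtype"]) <= {"luminal_A", "luminal_B", "basal", "HER2pos"}
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_patients_rejected(self):
        cohort = make_cohort([1.0] * 10, [1] * 10)
        with pytest.raises(ValueError, match="20"):
            es.call_subtypes(cohort)


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        km = es.km_estimate([3.0, 5.0, 7.0], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_single_subject_drops_to_zero(self):
        km = es.km_estimate([5.0], [1])
        assert km.loc[km["time"] == 5.0, "survival"].iloc[0] == 0.0

    def test_five_subject_hand_computed_oracle(self):
        km = es.km_estimate([1.0, 2.0, 3.0, 4.0, 5.0], [1, 1, 0, 1, 1])
        expected = {1.0: 0.8, 2.0: 0.6, 4.0: 0.3, 5.0: 0.0}
        lookup = dict(zip(km["time"], km["survival"]))
        for t, s in expected.items():
            assert lookup[t] == pytest.approx(s)

    def test_equals_empirical_survival_without_censoring(self, rng):
        times = rng.integers(1, 30, 50).astype(float)
        km = es.km_estimate(times, np.ones(50, dtype=int))
        for t, s in zip(km["time"], km["survival"]):
            assert s == pytest.approx((times > t).mean())

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            es.km_estimate([-1.0, 2.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t, e = [1.0, 2.0, 3.0], [1, 0, 1]
        stat, p = es.logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_label_swap_symmetry(self, rng):
        ta, tb = rng.uniform(1, 20, 15), rng.uniform(1, 20, 12)
        ea, eb = rng.integers(0, 2, 15), rng.integers(0, 2, 12)
        assert es.logrank_test(ta, ea, tb, eb) == es.logrank_test(tb, eb, ta, ea)

    def test_agrees_with_lifelines_under_ties(self, rng):
        for _ in range(5):
            ta = rng.integers(1, 12, 30).astype(float)
            tb = rng.integers(1, 12, 25).astype(float)
            ea, eb = rng.integers(0, 2, 30), rng.integers(0, 2, 25)
            stat, p = es.logrank_test(ta, ea, tb, eb)
            ref = lifelines_logrank(ta, tb, ea, eb)
            assert stat == pytest.approx(ref.test_statistic, abs=1e-9)
            assert p == pytest.approx(ref.p_value, abs=1e-12)

    @pytest.mark.parametrize(
        "ta, ea, tb, eb",
        [
            ([1, 3, 5, 7, 9], [1, 1, 1, 0, 1], [2, 4, 6, 8, 10], [1, 1, 0, 1, 1]),
            ([1, 2, 3, 4, 5], [1, 1, 1, 1, 1], [6, 7, 8, 9, 10], [1, 1, 1, 1, 0]),
        ],
    )
    def test_matches_exhaustive_permutation_oracle(self, ta, ea, tb, eb):
        """Analytic chi-square p vs the exact permutation distribution of the
        statistic on 10-subject toys (asymptotic approximation tolerance)."""
        ta, tb = np.asarray(ta, float), np.asarray(tb, float)
        ea, eb = np.asarray(ea), np.asarray(eb)
        stat_obs, p_chi = es.logrank_test(ta, ea, tb, eb)
        t_all = np.concatenate([ta, tb])
        e_all = np.concatenate([ea, eb])
        perm_stats = []
        for idx in itertools.combinations(range(10), 5):
            mask = np.zeros(10, dtype=bool)
            mask[list(idx)] = True
            try:
                s, _ = es.logrank_test(
                    t_all[mask], e_all[mask], t_all[~mask], e_all[~mask]
                )
            except UndefinedStatisticError:
                s = 0.0
            perm_stats.append(s)
        p_perm = np.mean(np.asarray(perm_stats) >= stat_obs - 1e-12)
        assert p_chi == pytest.approx(p_perm, abs=0.1)

    def test_all_censored_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            es.logrank_test([1.0, 2.0], [0, 0], [1.0, 3.0], [0, 0])


class TestCoxTwoGroup:
    def test_exchangeable_groups_give_unit_hr(self):
        t, e = [1.0, 2.0, 3.0, 4.0], [1, 1, 0, 1]
        res = es.cox_two_group(t, e, t, e)
        assert res.hr == pytest.approx(1.0, abs=1e-6)
        assert res.ci_low < 1.0 < res.ci_high

    def test_matches_breslow_grid_oracle_on_toy(self):
        th, eh = [2.0, 4.0, 4.0], [1, 1, 0]
        tl, el = [1.0, 3.0, 5.0], [1, 0, 1]
        res = es.cox_two_group(th, eh, tl, el)

        def breslow_loglik(beta):
            t = np.array(th + tl)
            e = np.array(eh + el)
            x = np.array([1, 1, 1, 0, 0, 0])
            ll = 0.0
            for u in np.unique(t[e == 1]):
                at_risk = t >= u
                d = int(((t == u) & (e == 1)).sum())
                s = int(((t == u) & (e == 1) & (x == 1)).sum())
                ll += s * beta - d * np.log(np.sum(np.exp(beta * x[at_risk])))
            return ll

        grid = np.arange(-3.0, 3.0, 1e-4)
        beta_grid = grid[np.argmax([breslow_loglik(b) for b in grid])]
        assert res.beta == pytest.approx(beta_grid, abs=1e-4)

    def test_agrees_with_lifelines_without_ties(self, rng):
        th = np.sort(rng.uniform(1, 100, 30))
        tl = np.sort(rng.uniform(1, 100, 30)) + 1e-4
        eh = rng.integers(0, 2, 30)
        el = rng.integers(0, 2, 30)
        if eh.sum() == 0 or el.sum() == 0:
            pytest.skip("degenerate draw")
        res = es.cox_two_group(th, eh, tl, el)
        df = pd.DataFrame(
            {
                "t": np.concatenate([th, tl]),
                "e": np.concatenate([eh, el]),
                "x": [1] * 30 + [0] * 30,
            }
        )
        fitter = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert res.beta == pytest.approx(fitter.params_["x"], abs=1e-5)
        assert res.se == pytest.approx(fitter.standard_errors_["x"], abs=1e-5)

    def test_single_event_score_test_equals_logrank(self):
        """With exactly one event the Cox score statistic at beta=0 and the
        logrank chi-square coincide."""
        th, eh = np.array([4.0, 6.0]), np.array([1, 0])
        tl, el = np.array([5.0, 7.0, 8.0]), np.array([0, 0, 0])
        # risk set at t=4: all 5 subjects, 2 in the high group
        r1, r0, d = 2.0, 3.0, 1.0
        mu = r1 / (r1 + r0)
        score_stat = (1.0 - d * mu) ** 2 / (d * mu * (1 - mu))
        stat, _ = es.logrank_test(th, eh, tl, el)
        assert stat == pytest.approx(score_stat)

    def test_no_events_in_one_group_non_estimable(self):
        res = es.cox_two_group([1.0, 2.0], [0, 0], [1.0, 2.0], [1, 1])
        assert not res.estimable and res.ci_high == np.inf

    def test_no_events_at_all_rejected(self):
        with pytest.raises(ValueError):
            es.cox_two_group([1.0], [0], [2.0], [0])

    def test_planted_two_group_hr_mean_recovery(self):
        """Two cohorts whose baseline hazards differ 2-fold plant HR=2."""
        hrs = []
        for rep in range(10):
            high, _ = es.simulate_survival_cohort(
                es.SurvSimConfig(n_patients=300, baseline_hazard=0.02, seed=31000 + 2 * rep)
            )
            low, _ = es.simulate_survival_cohort(
                es.SurvSimConfig(n_patients=300, baseline_hazard=0.01, seed=31001 + 2 * rep)
            )
            res = es.cox_two_group(
                high.data["time"], high.data["event"], low.data["time"], low.data["event"]
            )
            hrs.append(res.hr)
        assert np.mean(hrs) == pytest.approx(2.0, abs=0.25)


class TestBestCutoffScan:
    def test_constant_scores_rejected(self):
        with pytest.raises(ScanDomainError):
            es.best_cutoff_scan(
                np.ones(40), np.arange(1, 41, dtype=float), np.ones(40, dtype=int)
            )

    def test_separated_risk_groups_cut_between_supports(self, rng):
        n = 100
        scores = np.concatenate([rng.uniform(0, 1, 50), rng.uniform(3, 4, 50)])
        times = np.concatenate(
            [rng.exponential(100, 50), rng.exponential(10, 50)]
        )
        events = np.ones(n, dtype=int)
        res = es.best_cutoff_scan(scores, times, events)
        # selected split separates the planted groups exactly: the cutoff is
        # at or above the low support and below the high support
        assert scores[:50].max() - 1e-12 <= res.cutoff < 3.0
        assert (scores > res.cutoff).sum() == 50
        assert res.hr > 1.0

    def test_planted_positive_loghr_gives_hr_above_one(self):
        n_above = 0
        for rep in range(50):
            cohort, truth = es.simulate_survival_cohort(
                es.SurvSimConfig(n_patients=600, log_hr=0.5, seed=41000 + rep)
            )
            sig = es.GeneSignature("M", truth.gene_names, source="sim")
            res = es.best_cutoff_scan(
                es.metagene(cohort, sig).values,
                cohort.data["time"].values,
                cohort.data["event"].values,
            )
            n_above += res.hr > 1.0
        assert n_above >= 45  # >= 90% of replicates

    def test_null_scan_p_is_optimistic(self):
        """With no planted effect the nominal minimum-p is anti-conservative:
        substantially more than 5% of null scans reach p < 0.05 — the reason
        results carry the selection_optimism flag."""
        n_sig = 0
        n_rep = 200
        for rep in range(n_rep):
            cohort, truth = es.simulate_survival_cohort(
                es.SurvSimConfig(n_patients=600, log_hr=0.0, seed=52000 + rep)
            )
            sig = es.GeneSignature("M", truth.gene_names, source="sim")
            res = es.best_cutoff_scan(
                es.metagene(cohort, sig).values,
                cohort.data["time"].values,
                cohort.data["event"].values,
            )
            assert res.selection_optimism
            n_sig += res.p < 0.05
        assert n_sig / n_rep > 0.05

    def test_permutation_adjusted_p_corrects_selection(self):
        """The adjusted p exceeds the optimistic nominal p under the null,
        and stays small when the planted effect is real."""
        null_cohort, t0 = es.simulate_survival_cohort(
            es.SurvSimConfig(n_patients=200, log_hr=0.0, seed=55011)
        )
        sig = es.GeneSignature("M", t0.gene_names, source="sim")
        null_res = es.best_cutoff_scan(
            es.metagene(null_cohort, sig).values,
            null_cohort.data["time"].values,
            null_cohort.data["event"].values,
            adjust_p_permutations=99,
            random_state=1,
        )
        assert null_res.p_adjusted is not None
        assert null_res.p_adjusted > null_res.p

        effect_cohort, t1 = es.simulate_survival_cohort(
            es.SurvSimConfig(n_patients=200, log_hr=1.0, seed=55012)
        )
        effect_res = es.best_cutoff_scan(
            es.metagene(effect_cohort, sig).values,
            effect_cohort.data["time"].values,
            effect_cohort.data["event"].values,
            adjust_p_permutations=99,
            random_state=1,
        )
        assert effect_res.p_adjusted == pytest.approx(0.01)  # 1/(99+1)

    def test_group_sizes_respect_minimum_fraction(self):
        cohort, truth = es.simulate_survival_cohort(
            es.SurvSimConfig(n_patients=200, log_hr=0.3, seed=7)
        )
        sig = es.GeneSignature("M", truth.gene_names, source="sim")
        res = es.best_cutoff_scan(
            es.metagene(cohort, sig).values,
            cohort.data["time"].values,
            cohort.data["event"].values,
            min_group_frac=0.1,
        )
        assert res.n_high >= 20 and res.n_low >= 20
        assert res.n_high + res.n_low == 200


class TestSignatureSurvival:
    def run_with_loghr(self, log_hr, seed=61):
        cohort, truth = es.simulate_survival_cohort(
            es.SurvSimConfig(n_patients=600, log_hr=log_hr, seed=seed)
        )
        sig = es.GeneSignature("M", truth.gene_names, source="sim")
        return es.signature_survival(cohort, [sig]), sig, cohort

    def test_protective_metagene_reports_hr_below_one(self):
        table, _, _ = self.run_with_loghr(-0.7)
        assert table["hr"].iloc[0] < 1.0

    def test_harmful_metagene_reports_hr_above_one(self):
        table, _, _ = self.run_with_loghr(0.7)
        assert table["hr"].iloc[0] > 1.0

    def test_composite_of_identical_signatures_is_idempotent(self):
        table, sig, cohort = self.run_with_loghr(0.5)
        composite = es.signature_survival(cohort, [(sig, sig)])
        assert composite["hr"].iloc[0] == pytest.approx(table["hr"].iloc[0])
        assert composite["cutoff"].iloc[0] == pytest.approx(table["cutoff"].iloc[0])

    def test_subtype_filter_runs_and_restricts_n(self):
        cohort, truth = es.simulate_survival_cohort(
            es.SurvSimConfig(n_patients=800, log_hr=0.5, seed=13)
        )
        sig = es.GeneSignature("M", truth.gene_names, source="sim")
        table = es.signature_survival(cohort, [sig], subtype_filter="basal")
        assert table["n_high"].iloc[0] + table["n_low"].iloc[0] < 800

    def test_empty_stratum_error_lists_available(self):
        # every ESR-negative patient is HER2-positive: no basal tumors
        rng = np.random.default_rng(1)
        n = 60
        esr_high = np.arange(n) >= 30
        cohort = make_cohort(
            rng.uniform(1, 50, n),
            rng.integers(0, 2, n),
            markers={
                "ESR": np.where(esr_high, 512.0, 16.0) * rng.lognormal(0, 0.05, n),
                "HER2": np.where(~esr_high, 512.0, 16.0) * rng.lognormal(0, 0.05, n),
                "MKI67": rng.lognormal(5, 1, n),
            },
            genes={"SIG000": rng.normal(0, 1, n)},
        )
        with pytest.raises(StratumEmptyError, match="available"):
            es.signature_survival(
                cohort,
                [es.GeneSignature("M", ("SIG000",), source="sim")],
                subtype_filter="basal",
            )
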