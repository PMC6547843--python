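import dataclasses

import numpy as np
import pandas as pd
import pytest

from oracles import holm_oracle, splitplot_ss_oracle
from phenorep.anova import (
    DegenerateInputError,
    IncompleteRepeatedError,
    fit_splitplot,
    fit_splitplot_repeated,
    holm_adjust,
    posthoc_strain_within_time,
    posthoc_time_within_strain,
)
from phenorep.cohort import (
    base_measures,
    cohort_frame,
    default_params,
    generate_cohort,
    simulate_measures,
)

from conftest import make_balanced_design


class TestDegreesOfFreedom:
    def test_balanced_design_df(self, table, cohort, catalogue):
        """2 strains x 8 cages x 3 times, 48 animals: classical strata df."""
        res = fit_splitplot(table, cohort, catalogue[0])
        assert res.term("strain").df == 1
        assert res.term("cage(strain)").df == 14
        assert res.term("time").df == 2
        assert res.term("time:strain").df == 2
        assert res.term("residual").df == 28
        assert sum(t.df for t in res.terms) == res.n_animals - 1

    def test_dropout_design_df_2_27(self, dropout_table, dropout_cohort, catalogue):
        """With the single dropout (47 animals) the interaction is F(2, 27)."""
        res = fit_splitplot(dropout_table, dropout_cohort, catalogue[0])
        inter = res.term("time:strain")
        assert (inter.df, inter.df_den) == (2, 27)
        assert res.term("strain").df_den == 14
        assert sum(t.df for t in res.terms) == 46

    def test_repeated_df_accounting(self, dropout_table, dropout_cohort, catalogue):
        lm = next(s for s in catalogue if s.repeated)
        res = fit_splitplot_repeated(dropout_table, dropout_cohort, lm)
        assert sum(t.df for t in res.terms) == 2 * 47 - 1
        assert res.term("trial:time:strain").df_den == 27  # mirrors printed stats
        pooled = fit_splitplot_repeated(
            dropout_table, dropout_cohort, lm, trial_error="pooled"
        )
        assert pooled.term("trial:time:strain").df_den == 41


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_balanced_ss_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_cages = int(rng.integers(2, 6))
        records, tab, spec = make_balanced_design(n_cages, rng)
        res = fit_splitplot(tab, records, spec)
        df = cohort_frame(records).assign(
            value=tab.set_index("animal_id").value.reindex(
                [r.animal_id for r in records]
            ).to_numpy()
        )
        expected = splitplot_ss_oracle(df)
        for term, ss in expected.items():
            assert res.term(term).ss == pytest.approx(ss, rel=1e-8, abs=1e-10)

    def test_balanced_type3_equals_sequential(self):
        """On balanced data the drop-term SS partition is exhaustive: the
        term SS plus residual recover the total sum of squares."""
        rng = np.random.default_rng(5)
        records, tab, spec = make_balanced_design(4, rng)
        res = fit_splitplot(tab, records, spec)
        y = tab.value.to_numpy()
        total = ((y - y.mean()) ** 2).sum()
        assert sum(t.ss for t in res.terms) == pytest.approx(total, rel=1e-10)

    def test_repeated_balanced_matches_brute_force(self):
        """Two-trial toy: between-animal SS from trial means x2, within SS
        from trial differences / 2, checked against direct partitions."""
        rng = np.random.default_rng(8)
        records, tab, spec = make_balanced_design(2, rng)
        spec = dataclasses.replace(spec, repeated=True, trial=1)
        t1 = tab.assign(trial=1.0)
        t2 = tab.assign(trial=2.0, value=rng.normal(size=len(tab)))
        full = pd.concat([t1, t2], ignore_index=True)
        res = fit_splitplot_repeated(full, records, spec)
        wide = full.pivot_table(index="animal_id", columns="trial", values="value")
        order = [r.animal_id for r in records]
        means = wide.mean(axis=1).reindex(order).to_numpy()
        diffs = (wide[2.0] - wide[1.0]).reindex(order).to_numpy()
        df_means = cohort_frame(records).assign(value=means)
        between = splitplot_ss_oracle(df_means)
        for term in ("strain", "cage(strain)", "time", "time:strain"):
            assert res.term(term).ss == pytest.approx(2 * between[term], rel=1e-8)
        assert res.term("residual(between)").ss == pytest.approx(
            2 * between["residual"], rel=1e-8
        )
        # within-animal stratum against a direct partition of the diffs
        df_d = cohort_frame(records).assign(value=diffs)
        within = splitplot_ss_oracle(df_d)
        assert res.term("trial").ss == pytest.approx(
            len(diffs) * diffs.mean() ** 2 / 2, rel=1e-8
        )
        assert res.term("trial:strain").ss == pytest.approx(
            within["strain"] / 2, rel=1e-8
        )
        assert res.term("trial:time:strain").ss == pytest.approx(
            within["time:strain"] / 2, rel=1e-8
        )
        assert res.term("trial:cage(strain)").ss == pytest.approx(
            within["cage(strain)"] / 2, rel=1e-8
        )

    def test_splitplot_matches_R_aov(self, tmp_path):
        """Independent cross-check: R's aov with an Error(cage) stratum on
        the same balanced data reproduces our F statistics."""
        import json
        import subprocess

        rng = np.random.default_rng(17)
        records, tab, spec = make_balanced_design(3, rng)
        df = cohort_frame(records).assign(
            value=tab.set_index("animal_id").value.reindex(
                [r.animal_id for r in records]
            ).to_numpy()
        )
        csv = tmp_path / "toy.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            """
            d <- read.csv(commandArgs(TRUE)[1])
            d$strain <- factor(d$strain); d$time_group <- factor(d$time_group)
            d$cage_id <- factor(d$cage_id)
            m <- summary(aov(value ~ strain * time_group + Error(cage_id), data = d))
            wp <- m[["Error: cage_id"]][[1]]
            sp <- m[["Error: Within"]][[1]]
            cat(jsonlite::toJSON(list(
              f_strain = wp["strain", "F value"],
              f_time = sp["time_group", "F value"],
              f_inter = sp["strain:time_group", "F value"]
            ), auto_unbox = TRUE, digits = 12))
            """
        )
        out = subprocess.run(
            ["Rscript", str(script), str(csv)], capture_output=True, text=True
        )
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)
        res = fit_splitplot(tab, records, spec)
        assert res.term("strain").f == pytest.approx(ref["f_strain"], rel=1e-6)
        assert res.term("time").f == pytest.approx(ref["f_time"], rel=1e-6)
        assert res.term("time:strain").f == pytest.approx(ref["f_inter"], rel=1e-6)


class TestDegenerateInputs:
    def test_constant_data_flagged(self, cohort, catalogue):
        spec = catalogue[0]
        tab = pd.DataFrame(
            {
                "animal_id": [r.animal_id for r in cohort],
                "measure_id": spec.base_id,
                "trial": np.nan,
                "value": 1.0,
                "raw_value": 1.0,
            }
        )
        res = fit_splitplot(tab, cohort, spec)
        assert res.flagged
        assert all(t.ss == 0 for t in res.terms)
        assert np.isnan(res.term("time:strain").f)

    def test_missing_value_rejected(self, table, cohort, catalogue):
        spec = catalogue[0]
        short = table[table.animal_id != cohort[0].animal_id]
        with pytest.raises(DegenerateInputError):
            fit_splitplot(short, cohort, spec)

    def test_missing_trial_rejected(self, table, cohort, catalogue):
        lm = next(s for s in catalogue if s.repeated)
        broken = table[~((table.measure_id == lm.base_id) & (table.trial == 2.0)
                         & (table.animal_id == cohort[0].animal_id))]
        with pytest.raises(IncompleteRepeatedError):
            fit_splitplot_repeated(broken, cohort, lm)

    def test_repeated_requires_repeated_spec(self, table, cohort, catalogue):
        with pytest.raises(ValueError):
            fit_splitplot_repeated(table, cohort, catalogue[0])
        with pytest.raises(ValueError):
            fit_splitplot(table, cohort, next(s for s in catalogue if s.repeated))


class TestTrialEffectRecovery:
    def test_zero_trial_effect_zero_noise(self, cohort, catalogue):
        params = default_params(0)
        lm = next(s for s in catalogue if s.repeated)
        params = dataclasses.replace(
            params, cage_sd=0.0, residual_sd=1e-300, animal_sd=0.0,
            trial_effect={lm.base_id: 0.0},
        )
        tab = simulate_measures(cohort, params, catalogue)
        res = fit_splitplot_repeated(tab, cohort, lm)
        assert res.term("trial").ss == pytest.approx(0.0, abs=1e-15)

    def test_trial_contrast_recovered(self, cohort, catalogue):
        """The estimated trial-2 shift matches the generating theta."""
        lm = next(s for s in catalogue if s.repeated)
        params = dataclasses.replace(
            default_params(0), animal_sd=0.0, trial_effect={lm.base_id: -0.8}
        )
        estimates = []
        for k in range(30):
            p = dataclasses.replace(params, seed=900 + k)
            tab = simulate_measures(cohort, p, catalogue)
            rows = tab[tab.measure_id == lm.base_id]
            wide = rows.pivot_table(index="animal_id", columns="trial", values="value")
            estimates.append((wide[2.0] - wide[1.0]).mean())
        # SE of the mean over 30 studies ~ sqrt(2)/sqrt(48*30) ~ 0.04
        assert np.mean(estimates) == pytest.approx(-0.8, abs=0.12)


class TestHolm:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.04, 0.03], [0.03, 0.06, 0.06]),
            ([0.2], [0.2]),
            ([0.5, 0.5, 0.5], [1.0, 1.0, 1.0]),
        ],
    )
    def test_worked_examples(self, p, expected):
        assert holm_adjust(p) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_literal_stepdown(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 15)).tolist()
        adjusted = holm_adjust(p)
        assert adjusted == pytest.approx(holm_oracle(p))
        assert np.all(adjusted >= np.asarray(p) - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.2, 1.3])


class TestPostHoc:
    def test_time_varying_contrast_flags_morning_not_afternoon(
        self, cohort, catalogue
    ):
        """delta = (d, d, 0): morning/noon contrasts significant after
        Holm in most simulated studies, afternoon rarely."""
        spec = catalogue[0]
        flags = {"morning": 0, "noon": 0, "afternoon": 0}
        n_sims = 25
        for k in range(n_sims):
            p = default_params(seed=1300 + k)
            tab = simulate_measures(cohort, p, [spec])
            res = fit_splitplot(tab, cohort, spec)
            for c in posthoc_strain_within_time(res, tab, cohort, spec):
                if c.significant:
                    flags[c.description.split()[-1]] += 1
        assert flags["morning"] / n_sims > 0.5
        assert flags["noon"] / n_sims > 0.5
        assert flags["afternoon"] / n_sims < 0.25

    def test_identical_strains_rarely_flagged(self, cohort, catalogue):
        """Type-I control: with delta = 0 the per-measure family flags a
        contrast in at most ~ alpha of null studies."""
        spec = catalogue[1]
        n_flagged = 0
        n_sims = 40
        for k in range(n_sims):
            p = default_params(seed=2200 + k, delta=0.0, constant_delta=True)
            tab = simulate_measures(cohort, p, [spec])
            res = fit_splitplot(tab, cohort, spec)
            comps = posthoc_strain_within_time(res, tab, cohort, spec)
            n_flagged += any(c.significant for c in comps)
        assert n_flagged / n_sims <= 0.15

    def test_holm_monotone_and_antisymmetric_estimates(
        self, table, cohort, catalogue
    ):
        spec = catalogue[0]
        res = fit_splitplot(table, cohort, spec)
        comps = posthoc_strain_within_time(res, table, cohort, spec)
        assert len(comps) == 3
        for c in comps:
            assert c.p_holm >= c.p_raw - 1e-15

    def test_time_within_strain_families(self, table, cohort, catalogue):
        spec = catalogue[0]
        res = fit_splitplot(table, cohort, spec)
        comps = posthoc_time_within_strain(res, table, cohort, spec)
        assert len(comps) == 6
        assert all(c.p_holm >= c.p_raw - 1e-15 for c in comps if c.p_holm == c.p_holm)
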