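"""Benchmarking statistics: formulas, identities, and library cross-checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stancestrength.cohort import CohortGenConfig, DEFAULT_N_PER_STRATUM, generate_cohort
from stancestrength.protocol import DIRECTION_CODES
from stancestrength.stats import (
    StatsError,
    build_normative_table,
    deficit_score,
    f_from_ss,
    games_howell,
    independent_t,
    one_way_anova,
    partial_eta_squared,
    percent_difference,
    two_way_anova,
)


class TestPercentDifference:
    @pytest.mark.parametrize(
        "m1,m2,expected",
        [
            (1.8504, 1.3659, 35.47),  # young-adult male advantage, direction A
            (2.3039, 1.6909, 36.25),  # middle-aged male advantage, direction D2
        ],
    )
    def test_printed_group_means(self, m1, m2, expected):
        assert round(percent_difference(m1, m2), 2) == expected

    def test_identity_and_zero_reference(self):
        assert percent_difference(3.3, 3.3) == 0.0
        with pytest.raises(StatsError):
            percent_difference(1.0, 0.0)


def pooled_t_oracle(x1, x2):
    """Student's pooled-variance t computed from the textbook formula."""
    n1, n2 = len(x1), len(x2)
    sp2 = ((n1 - 1) * np.var(x1, ddof=1) + (n2 - 1) * np.var(x2, ddof=1)) / (n1 + n2 - 2)
    return (np.mean(x1) - np.mean(x2)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


class TestIndependentT:
    def test_matches_formula_oracle(self, rng):
        x1, x2 = rng.normal(2.3, 0.4, 17), rng.normal(1.7, 0.5, 17)
        res = independent_t(x1, x2, variant="student")
        assert res.t == pytest.approx(pooled_t_oracle(x1, x2), rel=1e-12)
        assert res.df == 32  # n1 + n2 - 2
        assert res.p == pytest.approx(2 * sps.t.sf(abs(res.t), 32), rel=1e-12)
        assert res.pct_diff == pytest.approx(
            percent_difference(x1.mean(), x2.mean()), rel=1e-12
        )

    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = independent_t(x, x)
        assert res.t == 0.0 and res.p == 1.0

    def test_antisymmetry(self, rng):
        x1, x2 = rng.normal(2, 1, 12), rng.normal(3, 1, 15)
        a, b = independent_t(x1, x2), independent_t(x2, x1)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_welch_variant(self, rng):
        x1, x2 = rng.normal(2, 0.2, 10), rng.normal(2.5, 1.5, 30)
        res = independent_t(x1, x2, variant="welch")
        ref = sps.ttest_ind(x1, x2, equal_var=False)
        assert res.t == pytest.approx(float(ref.statistic))
        assert res.df < len(x1) + len(x2) - 2  # Welch df shrinks

    def test_degenerate_rejected(self):
        with pytest.raises(StatsError):
            independent_t([1.0, 1.0], [1.0, 1.0])


class TestOneWayAnova:
    def test_two_groups_f_equals_t_squared(self, rng):
        x1, x2 = rng.normal(2, 0.5, 14), rng.normal(2.4, 0.5, 11)
        rows = one_way_anova([x1, x2])
        t = pooled_t_oracle(x1, x2)
        assert rows[0].f == pytest.approx(t**2, rel=1e-9)

    def test_matches_scipy(self, rng):
        groups = [rng.normal(m, 0.4, n) for m, n in [(2.0, 18), (1.9, 17), (1.5, 15)]]
        rows = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert rows[0].f == pytest.approx(float(ref.statistic), rel=1e-12)
        assert rows[0].p == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_identical_groups_zero_f(self):
        x = np.array([1.0, 2.0, 3.0])
        rows = one_way_anova([x, x, x])
        assert rows[0].ss == pytest.approx(0.0, abs=1e-12)
        assert rows[0].f == pytest.approx(0.0, abs=1e-12)

    def test_null_f_near_one_on_average(self, rng):
        fs = []
        for _ in range(200):
            groups = [rng.normal(2.0, 0.5, 12) for _ in range(3)]
            fs.append(one_way_anova(groups)[0].f)
        # E[F(2, 33)] = 33/31 ~= 1.065; 0.25 is ~3 standard errors at 200 reps
        assert float(np.mean(fs)) == pytest.approx(33 / 31, abs=0.25)

    def test_degenerate_inputs(self):
        with pytest.raises(StatsError):
            one_way_anova([[1.0, 2.0]])
        with pytest.raises(StatsError):
            one_way_anova([[1.0, 1.0], [1.0, 1.0]])


class TestGamesHowell:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 2.5])
        pairs = games_howell([x, x + 0.0, x], labels=list("abc"))
        for p in pairs:
            assert p.mean_diff == 0.0
            assert p.p_adj > 0.99

    def test_k2_equals_welch_t(self, rng):
        """With two groups, the studentized-range p equals the Welch t-test p."""
        x1, x2 = rng.normal(2, 0.6, 13), rng.normal(2.7, 1.1, 19)
        pair = games_howell([x1, x2])[0]
        welch = independent_t(x1, x2, variant="welch")
        assert pair.q == pytest.approx(abs(welch.t) * np.sqrt(2), rel=1e-12)
        assert pair.p_adj == pytest.approx(welch.p, abs=1e-6)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        groups = [rng.normal(2.0, 0.5, 12), rng.normal(2.6, 1.0, 17), rng.normal(2.1, 0.7, 9)]
        mine = games_howell(groups, labels=list("abc"))
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": ["a"] * 12 + ["b"] * 17 + ["c"] * 9,
            }
        )
        ref = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        for mine_pair, (_, ref_row) in zip(mine, ref.iterrows()):
            assert {mine_pair.group_i, mine_pair.group_j} == {ref_row["A"], ref_row["B"]}
            assert abs(mine_pair.mean_diff) == pytest.approx(abs(ref_row["diff"]), rel=1e-9)
            assert mine_pair.se == pytest.approx(ref_row["se"], rel=1e-9)
            assert mine_pair.df_welch == pytest.approx(ref_row["df"], rel=1e-9)
            assert mine_pair.p_adj == pytest.approx(ref_row["pval"], abs=1e-6)

    def test_shifted_group_detected(self):
        detected = 0
        null_ok = 0
        n_rep = 60
        rng = np.random.default_rng(2024)
        for _ in range(n_rep):
            a = rng.normal(2.0, 0.4, 15)
            b = rng.normal(2.0, 0.4, 15)
            c = rng.normal(3.2, 0.4, 15)  # large shift
            pairs = {(p.group_i, p.group_j): p for p in games_howell([a, b, c], list("abc"))}
            if pairs[("a", "c")].p_adj < 0.05 and pairs[("b", "c")].p_adj < 0.05:
                detected += 1
            if pairs[("a", "b")].p_adj > 0.05:
                null_ok += 1
        assert detected >= 0.95 * n_rep
        assert null_ok >= 0.80 * n_rep

    def test_zero_variance_pair_rejected(self):
        with pytest.raises(StatsError):
            games_howell([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])


class TestTwoWayAnova:
    @staticmethod
    def _cells(rng, n_fn=lambda: 8, means=None):
        cells = {}
        for a in ("male", "female"):
            for b in ("G25", "G45", "G65"):
                mu = means[(a, b)] if means else 2.0 + 0.4 * (a == "male") - 0.3 * (b == "G65")
                cells[(a, b)] = rng.normal(mu, 0.4, n_fn())
        return cells

    def test_additive_zero_noise_interaction_is_zero(self):
        means = {
            (a, b): 2.0 + (0.5 if a == "male" else 0.0) + {"G25": 0, "G45": -0.2, "G65": -0.6}[b]
            for a in ("male", "female")
            for b in ("G25", "G45", "G65")
        }
        cells = {k: np.full(6, v) + np.tile([-0.1, 0.1], 3) for k, v in means.items()}
        rows = {r.source: r for r in two_way_anova(cells)}
        assert rows["interaction"].ss == pytest.approx(0.0, abs=1e-9)

    def test_balanced_decomposition_sums_to_total(self, rng):
        cells = self._cells(rng)
        rows = two_way_anova(cells)
        y = np.concatenate(list(cells.values()))
        ss_total = float(((y - y.mean()) ** 2).sum())
        assert sum(r.ss for r in rows) == pytest.approx(ss_total, abs=1e-9)

    def test_error_df_at_published_n(self, rng):
        # 99 analysed participants in 6 cells (men 19/17/15; the published
        # per-group female counts sum higher than the stated 48 — this uses
        # a 48-women split consistent with the error df of 93)
        ns = iter([19, 17, 15, 18, 17, 13])
        cells = self._cells(rng, n_fn=lambda: next(ns))
        rows = {r.source: r for r in two_way_anova(cells)}
        assert rows["error"].df == 93
        assert rows["gender"].df == 1
        assert rows["age_group"].df == 2
        assert rows["interaction"].df == 2

    def test_matches_statsmodels_type2_unbalanced(self, rng):
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        cells = self._cells(rng, n_fn=lambda: int(rng.integers(5, 12)))
        rows = {r.source: r for r in two_way_anova(cells)}
        records = [
            {"y": v, "A": a, "B": b} for (a, b), arr in cells.items() for v in arr
        ]
        ref = anova_lm(smf.ols("y ~ C(A) * C(B)", pd.DataFrame(records)).fit(), typ=2)
        assert rows["gender"].ss == pytest.approx(ref.loc["C(A)", "sum_sq"], rel=1e-9)
        assert rows["age_group"].ss == pytest.approx(ref.loc["C(B)", "sum_sq"], rel=1e-9)
        assert rows["interaction"].ss == pytest.approx(ref.loc["C(A):C(B)", "sum_sq"], rel=1e-9)
        assert rows["error"].ss == pytest.approx(ref.loc["Residual", "sum_sq"], rel=1e-9)
        assert rows["gender"].f == pytest.approx(ref.loc["C(A)", "F"], rel=1e-9)
        assert rows["gender"].p == pytest.approx(ref.loc["C(A)", "PR(>F)"], rel=1e-6)

    def test_empty_cell_rejected(self, rng):
        cells = self._cells(rng)
        del cells[("male", "G65")]
        with pytest.raises(StatsError):
            two_way_anova(cells)


class TestSsHelpers:
    def test_f_from_ss_printed_rows(self):
        # direction A gender row and direction B age row of the published table
        assert f_from_ss(3.64, 1, 8.47, 93) == pytest.approx(39.97, rel=0.005)
        assert f_from_ss(6.85, 2, 14.05, 93) == pytest.approx(22.671, rel=0.005)
        assert f_from_ss(0.0, 2, 5.0, 50) == 0.0

    def test_partial_eta_squared_printed_rows(self):
        assert partial_eta_squared(3.64, 8.47) == pytest.approx(0.301, abs=0.0005)
        assert partial_eta_squared(6.28, 10.73) == pytest.approx(0.369, abs=0.0005)
        assert partial_eta_squared(0.0, 5.0) == 0.0

    def test_guards(self):
        with pytest.raises(StatsError):
            f_from_ss(1.0, 1, 0.0, 10)
        with pytest.raises(StatsError):
            partial_eta_squared(0.0, 0.0)
        with pytest.raises(StatsError):
            partial_eta_squared(-1.0, 1.0)


class TestNormativeTable:
    def test_zero_sd_table_equals_configured_means(self):
        cfg = CohortGenConfig(
            seed=2,
            n_per_stratum={k: 3 for k in DEFAULT_N_PER_STRATUM},
            direction_sd={d: 0.0 for d in DIRECTION_CODES},
        )
        table = build_normative_table(generate_cohort(cfg))
        for (sex, grp, d), summary in table.entries.items():
            assert summary.mean == pytest.approx(cfg.cell_mean(sex, grp, d))
            assert summary.sd == pytest.approx(0.0, abs=1e-12)

    def test_stochastic_recovery_of_anchor_means(self):
        """Generator defaults: the normative table's young-adult direction-A
        means land within 2 SE of the anchors (1.85 male, 1.37 female)."""
        cfg = CohortGenConfig(seed=7, n_per_stratum={("male", "G25"): 60, ("female", "G25"): 60})
        table = build_normative_table(generate_cohort(cfg))
        for sex, anchor in [("male", 1.8504), ("female", 1.3659)]:
            s = table.get(sex, "G25", "A")
            assert abs(s.mean - anchor) <= 2 * s.sd / np.sqrt(s.n)

    def test_single_participant_stratum_warns_and_omits(self):
        cfg = CohortGenConfig(seed=3, n_per_stratum={("male", "G25"): 2, ("female", "G25"): 2})
        cohort = generate_cohort(cfg)
        with pytest.warns(UserWarning, match="omitted"):
            table = build_normative_table(cohort[:3])  # one lone female
        assert ("female", "G25", "A") not in table.entries
        assert ("male", "G25", "A") in table.entries

    def test_dataframe_schema(self):
        cfg = CohortGenConfig(seed=4, n_per_stratum={("male", "G25"): 3, ("female", "G25"): 3})
        df = build_normative_table(generate_cohort(cfg)).to_dataframe()
        assert list(df.columns) == [
            "sex", "age_group", "direction", "n", "mean_n_per_kg", "sd_n_per_kg",
        ]
        assert len(df) == 12  # 2 strata x 6 directions


class TestDeficitScore:
    def _table_and_patient(self, seed=5):
        cfg = CohortGenConfig(seed=seed, n_per_stratum={("male", "G25"): 10, ("female", "G25"): 10})
        cohort = generate_cohort(cfg)
        return build_normative_table(cohort), cohort[0]

    def test_patient_at_norm_mean(self):
        table, patient = self._table_and_patient()
        sex, grp = patient.participant.stratum
        for d in DIRECTION_CODES:
            patient.relative[d] = table.get(sex, grp, d).mean
        report = deficit_score(patient, table)
        for d in DIRECTION_CODES:
            assert report.directions[d]["z"] == pytest.approx(0.0, abs=1e-12)
            assert report.directions[d]["pct_deficit"] == pytest.approx(0.0, abs=1e-9)
            assert report.directions[d]["pct_of_norm"] == pytest.approx(100.0)

    def test_deficit_against_printed_anchor(self):
        """A patient at the young women's mean scores -26.18% against the
        young men's direction-A norm of 1.8504 N/kg."""
        assert round(percent_difference(1.3659, 1.8504), 2) == -26.18

    def test_z_definition(self):
        table, patient = self._table_and_patient()
        sex, grp = patient.participant.stratum
        report = deficit_score(patient, table)
        for d in DIRECTION_CODES:
            s = table.get(sex, grp, d)
            assert report.directions[d]["z"] == pytest.approx(
                (patient.relative[d] - s.mean) / s.sd
            )

    def test_missing_stratum_hint(self):
        table, patient = self._table_and_patient()
        table.entries = {
            k: v for k, v in table.entries.items() if k[0] != patient.participant.sex
        }
        with pytest.raises(StatsError, match="nearest"):
            deficit_score(patient, table)
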