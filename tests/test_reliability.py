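"""CV, ICC, repeated-measures GLM and correlation statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from octavld import (
    CohortSpec,
    correlate,
    cv_of_sample,
    cv_percent,
    icc,
    pairwise_cv,
    pairwise_emm,
    rm_glm,
    simulate_cohort,
)

# ---------------------------------------------------------------------------
# independent oracles


def icc_oracle(y, model="ICC2"):
    """Mean squares by explicit loops, then the variance-component ratio."""
    y = np.asarray(y, float)
    n, k = y.shape
    gm = y.mean()
    ss_rows = ss_cols = ss_tot = 0.0
    for i in range(n):
        ss_rows += k * (y[i].mean() - gm) ** 2
    for j in range(k):
        ss_cols += n * (y[:, j].mean() - gm) ** 2
    for i in range(n):
        for j in range(k):
            ss_tot += (y[i, j] - gm) ** 2
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    if model == "ICC2":
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return (msr - mse) / (msr + (k - 1) * mse)


def split_plot_oracle(df):
    """Hand sums-of-squares decomposition for a balanced two-group design.

    Returns F statistics for the within effects (tested against their
    subject-interaction error strata) and the between-group effect.
    """
    eyes = sorted(df["eye_id"].unique())
    devs = list(pd.unique(df["device"]))
    locs = list(pd.unique(df["location"]))
    groups = {e: df[df.eye_id == e]["al_group"].iloc[0] for e in eyes}
    glevels = sorted(set(groups.values()))
    a, b, N, G = len(devs), len(locs), len(eyes), len(glevels)

    y = {}
    for _, r in df.iterrows():
        y[(r.eye_id, r.device, r.location)] = r.vld

    def mean(eye=None, dev=None, loc=None, grp=None):
        vals = [
            v
            for (e, d, l), v in y.items()
            if (eye is None or e == eye)
            and (dev is None or d == dev)
            and (loc is None or l == loc)
            and (grp is None or groups[e] == grp)
        ]
        return np.mean(vals)

    m = mean()
    ss_dev = N * b * sum((mean(dev=d) - m) ** 2 for d in devs)
    ss_dev_err = b * sum(
        (mean(eye=e, dev=d) - mean(dev=d, grp=groups[e]) - mean(eye=e) + mean(grp=groups[e])) ** 2
        for e in eyes
        for d in devs
    )
    F_dev = (ss_dev / (a - 1)) / (ss_dev_err / ((a - 1) * (N - G)))

    ss_loc = N * a * sum((mean(loc=l) - m) ** 2 for l in locs)
    ss_loc_err = a * sum(
        (mean(eye=e, loc=l) - mean(loc=l, grp=groups[e]) - mean(eye=e) + mean(grp=groups[e])) ** 2
        for e in eyes
        for l in locs
    )
    F_loc = (ss_loc / (b - 1)) / (ss_loc_err / ((b - 1) * (N - G)))

    ss_int = N * sum(
        (mean(dev=d, loc=l) - mean(dev=d) - mean(loc=l) + m) ** 2 for d in devs for l in locs
    )
    ss_int_err = sum(
        (
            y[(e, d, l)]
            - mean(dev=d, loc=l, grp=groups[e])
            - mean(eye=e, dev=d)
            - mean(eye=e, loc=l)
            + mean(dev=d, grp=groups[e])
            + mean(loc=l, grp=groups[e])
            + mean(eye=e)
            - mean(grp=groups[e])
        )
        ** 2
        for e in eyes
        for d in devs
        for l in locs
    )
    F_int = (ss_int / ((a - 1) * (b - 1))) / (ss_int_err / ((a - 1) * (b - 1) * (N - G)))

    ng = N // G
    ss_grp = a * b * ng * sum((mean(grp=g) - m) ** 2 for g in glevels)
    ss_subj = a * b * sum((mean(eye=e) - mean(grp=groups[e])) ** 2 for e in eyes)
    F_grp = (ss_grp / (G - 1)) / (ss_subj / (N - G))
    return {"instrument": F_dev, "location": F_loc, "instrument x location": F_int, "al_group": F_grp}


# ---------------------------------------------------------------------------
# CV


class TestCV:
    @pytest.mark.parametrize(
        "mean, sd, expected_int",
        [(20.1, 3.4, 17), (19.8, 4.4, 22), (18.8, 1.9, 10), (21.9, 2.0, 9)],
    )
    def test_reference_cells_round_to_printed_integers(self, mean, sd, expected_int):
        assert round(cv_percent(mean, sd)) == expected_int

    def test_zero_sd_gives_zero(self):
        assert cv_percent(5.0, 0.0) == 0.0

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            cv_percent(0.0, 1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(1.0, 100.0), min_size=3, max_size=20),
        st.floats(0.1, 10.0),
    )
    def test_scale_invariance(self, values, factor):
        v = np.asarray(values)
        if v.std(ddof=1) == 0 or v.mean() <= 0:
            return
        assert cv_of_sample(v * factor) == pytest.approx(cv_of_sample(v), rel=1e-9)


class TestPairwiseCV:
    def test_identical_vectors_zero(self):
        r = pairwise_cv([10.0, 12.0, 14.0], [10.0, 12.0, 14.0])
        assert r.mean_cv_percent == 0.0 and r.sd_cv_percent == 0.0

    def test_hand_computed_pair(self):
        # (10, 30): sd = 20/sqrt(2) = 14.142, mean = 20 -> CV = 70.71%
        r = pairwise_cv([10.0, 10.0], [30.0, 30.0])
        assert r.mean_cv_percent == pytest.approx(100 * (20 / np.sqrt(2)) / 20, rel=1e-9)

    def test_scale_invariant(self):
        a = np.array([10.0, 20.0, 15.0])
        b = np.array([12.0, 18.0, 19.0])
        r1 = pairwise_cv(a, b)
        r2 = pairwise_cv(3 * a, 3 * b)
        assert r1.mean_cv_percent == pytest.approx(r2.mean_cv_percent, rel=1e-12)
        assert r1.sd_cv_percent == pytest.approx(r2.sd_cv_percent, rel=1e-12)

    def test_nonpositive_pair_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            r = pairwise_cv([10.0, 0.0], [30.0, 0.0])
        assert r.n == 1


class TestICC:
    def test_duplicated_column_gives_one(self):
        col = np.array([3.0, 5.0, 9.0, 2.0, 7.0])
        res = icc(np.column_stack([col, col]))
        assert res.estimate == pytest.approx(1.0)

    def test_offset_ladder_matches_hand_value(self):
        # rows (1,2)...(5,6): MSB=5, MSJ=2.5, MSE=0 -> ICC2 = 5/6
        y = np.array([[1, 2], [2, 3], [3, 4], [4, 5], [5, 6]], float)
        res = icc(y)
        assert res.estimate == pytest.approx(5.0 / 6.0, abs=1e-12)
        assert res.estimate == pytest.approx(icc_oracle(y), abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(0, 50), min_size=2, max_size=2),
            min_size=8,
            max_size=8,
        )
    )
    def test_matches_mean_squares_oracle(self, rows):
        y = np.asarray(rows, float)
        if np.allclose(y, y.mean()):
            return
        for model in ("ICC2", "ICC3"):
            assert icc(y, model).estimate == pytest.approx(icc_oracle(y, model), abs=1e-10)

    def test_null_monte_carlo_near_zero(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, size=(500, 2))
        assert abs(icc(y).estimate) < 0.1

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(1)
        y = rng.normal(10, 2, size=(20, 2)) + rng.normal(0, 2, size=(20, 1))
        res = icc(y)
        assert res.ci_low <= res.estimate <= res.ci_high
        assert -1 <= res.ci_low and res.ci_high <= 1

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        y = rng.normal(10, 2, size=(15, 3)) + rng.normal(0, 1.5, size=(15, 1))
        df = pd.DataFrame(
            {
                "t": np.repeat(np.arange(15), 3),
                "r": np.tile(np.arange(3), 15),
                "s": y.ravel(),
            }
        )
        table = pg.intraclass_corr(df, targets="t", raters="r", ratings="s")
        for mine, theirs in (("ICC2", "ICC(A,1)"), ("ICC3", "ICC(C,1)")):
            res = icc(y, mine)
            row = table[table.Type == theirs].iloc[0]
            assert res.estimate == pytest.approx(row.ICC, abs=1e-10)
            assert res.ci_low == pytest.approx(row.CI95[0], abs=5e-3)
            assert res.ci_high == pytest.approx(row.CI95[1], abs=5e-3)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            icc(np.full((5, 2), 7.0))


class TestRMGLM:
    @staticmethod
    def toy_table(n_eyes=6, seed=3, grouped=True, **spec_kw):
        spec = CohortSpec(n_eyes=n_eyes, seed=seed, **spec_kw)
        df = simulate_cohort(spec)
        df = df[df["scan"] == 1].copy()
        if grouped:
            # deterministic balanced groups for oracle comparability
            eyes = sorted(df["eye_id"].unique())
            gmap = {e: (1 if i < len(eyes) // 2 else 2) for i, e in enumerate(eyes)}
            df["al_group"] = df["eye_id"].map(gmap)
        return df

    def test_matches_hand_ss_oracle_with_groups(self):
        df = self.toy_table()
        res = rm_glm(df)
        oracle = split_plot_oracle(df)
        got = dict(zip(res.anova["effect"], res.anova["F"]))
        for effect, F in oracle.items():
            assert got[effect] == pytest.approx(F, rel=1e-8), effect

    def test_matches_statsmodels_without_groups(self):
        sm = pytest.importorskip("statsmodels.stats.anova")
        df = self.toy_table(grouped=False)
        res = rm_glm(df, between=None)
        table = sm.AnovaRM(
            df, depvar="vld", subject="eye_id", within=["device", "location"]
        ).fit().anova_table
        got = dict(zip(res.anova["effect"], res.anova["F"]))
        assert got["instrument"] == pytest.approx(table.loc["device", "F Value"], rel=1e-8)
        assert got["location"] == pytest.approx(table.loc["location", "F Value"], rel=1e-8)
        assert got["instrument x location"] == pytest.approx(
            table.loc["device:location", "F Value"], rel=1e-8
        )

    def test_pure_device_effect_degenerate(self):
        # exact additive device effect, zero residual
        rows = []
        for e in range(4):
            for di, d in enumerate("ABCD"):
                for l in ("s", "n", "i", "t"):
                    rows.append(
                        {"eye_id": f"e{e}", "device": d, "location": l, "vld": 10.0 + di}
                    )
        res = rm_glm(pd.DataFrame(rows), between=None)
        got = {r["effect"]: r for _, r in res.anova.iterrows()}
        assert np.isinf(got["instrument"]["F"]) and got["instrument"]["p"] == 0.0
        assert got["location"]["F"] == 0.0 and got["location"]["p"] == 1.0

    def test_permuting_eye_labels_leaves_F_unchanged(self):
        df = self.toy_table(grouped=False)
        res1 = rm_glm(df, between=None)
        relabel = {e: f"z{i}" for i, e in enumerate(sorted(df.eye_id.unique())[::-1])}
        df2 = df.assign(eye_id=df.eye_id.map(relabel))
        res2 = rm_glm(df2, between=None)
        assert np.allclose(res1.anova["F"], res2.anova["F"])

    def test_incomplete_eyes_dropped_with_warning(self):
        df = self.toy_table(grouped=False)
        df = df[~((df.eye_id == df.eye_id.iloc[0]) & (df.device == "Spectralis"))]
        with pytest.warns(UserWarning, match="dropped"):
            res = rm_glm(df, between=None)
        assert res.n_complete == 5

    def test_duplicate_scans_rejected(self):
        spec = CohortSpec(n_eyes=4, seed=0)
        df = simulate_cohort(spec)  # both scans present
        with pytest.raises(ValueError, match="scan"):
            rm_glm(df)

    def test_emm_device_is_mean_of_cells(self):
        df = self.toy_table()
        res = rm_glm(df)
        assert np.allclose(res.emm_device.values, res.emm_cells.mean(axis=1).values)


class TestPairwiseEMM:
    def test_antisymmetric(self):
        df = TestRMGLM.toy_table()
        comp = pairwise_emm(rm_glm(df))
        for _, r in comp.iterrows():
            mirror = comp[
                (comp.factor == r.factor)
                & (comp.level_1 == r.level_2)
                & (comp.level_2 == r.level_1)
            ].iloc[0]
            assert mirror.difference == pytest.approx(-r.difference, abs=1e-12)
            assert mirror.p == pytest.approx(r.p, abs=1e-12)

    def test_null_differences_and_calibrated_p(self):
        zero_dev = {d: 0.0 for d in ("A", "B", "C", "D")}
        pvals, diffs = [], []
        for s in range(60):
            df = simulate_cohort(
                CohortSpec(
                    n_eyes=10,
                    seed=s,
                    device_offsets=zero_dev,
                    sigma_between=1.0,
                    sigma_within=1.0,
                )
            )
            comp = pairwise_emm(rm_glm(df[df.scan == 1], between=None))
            dev = comp[comp.factor == "instrument"]
            pvals.extend(dev.p)
            diffs.extend(dev.difference)
        assert abs(np.mean(diffs)) < 0.1
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert 0.005 < frac < 0.15  # near-nominal type-I rate

    def test_simulated_offsets_recovered(self):
        spec = CohortSpec(n_eyes=200, seed=7)
        df = simulate_cohort(spec)
        comp = pairwise_emm(rm_glm(df[df.scan == 1]))
        offs = spec.device_offsets
        for _, r in comp[comp.factor == "instrument"].iterrows():
            true_diff = offs[r.level_1] - offs[r.level_2]
            assert abs(r.difference - true_diff) < 3 * r.se + 1e-9


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = correlate(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r2, _ = correlate(x, -x)
        assert r2 == pytest.approx(-1.0)

    def test_hand_formula_on_five_points(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        r, p = correlate(x, y)
        assert r == pytest.approx(num / den, abs=1e-12)
        assert 0 <= p <= 1

    def test_spearman_monotone(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r, _ = correlate(x, np.exp(x), method="spearman")
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [1.0, 2.0])
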