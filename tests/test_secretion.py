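import numpy as np
import pandas as pd
import pytest

from sevmir import io, normalize, secretion

from conftest import make_sheet


def make_ci(frame: pd.DataFrame) -> secretion.CorrelationInput:
    f = frame.copy()
    for cond in ("Q", "SIPS"):
        if f"extra_ct_{cond}" not in f:
            f[f"extra_ct_{cond}"] = 40.0 - np.log2(f[f"extra_au_{cond}"] / 10.0)
    return secretion.CorrelationInput(frame=f)


class TestAuTransform:
    def test_anchor(self):
        assert secretion.au_transform(40.0) == 10.0

    def test_one_cycle_doubles(self):
        assert secretion.au_transform(39.0) == pytest.approx(20.0)

    def test_ct_30(self):
        assert secretion.au_transform(30.0) == pytest.approx(10_240.0)

    def test_nd_rejected(self):
        with pytest.raises(io.ValidationError):
            secretion.au_transform(float("nan"))

    def test_efficiency_changes_base(self):
        # 90% efficiency: base 1.9
        assert secretion.au_transform(39.0, efficiency=0.9) == pytest.approx(19.0)

    def test_monotone_decreasing(self):
        cts = np.linspace(20, 40, 50)
        au = secretion.au_transform(cts)
        assert (np.diff(au) < 0).all()


class TestCorrelationFilter:
    def build(self):
        # 8 miRNAs engineered so steps remove 2 (low quartile both), 1
        # (TPM zero), 1 (ND) -> counts [8, 6, 5, 4]
        ids = [f"m{i}" for i in range(1, 9)]
        tpm = pd.DataFrame(
            {
                "n1": [1, 2, 0, 300, 300, 400, 500, 600],
                "n2": [1, 2, 400, 300, 300, 400, 500, 600],
            },
            index=ids, dtype=float,
        )
        ct = pd.DataFrame(
            {
                "q1": [39.0, 39.0, 25.0, 26.0, 27.0, 25.5, 24.0, 23.0],
                "q2": [39.0, 39.0, 25.0, np.nan, 27.0, 25.5, 24.0, 23.0],
            },
            index=ids,
        )
        tpm_norm = normalize.NormalizedMatrix(tpm, scheme="tpm")
        ct_norm = normalize.NormalizedMatrix(ct, scheme="per_cell_ct")
        return ids, tpm_norm, ct_norm

    def test_step_counts(self):
        ids, tpm, ct = self.build()
        report = secretion.correlation_filter(ids, tpm, ct)
        assert report.step_counts == [8, 6, 5, 4]
        assert report.kept == ["m5", "m6", "m7", "m8"]

    def test_identity_when_nothing_filtered(self):
        ids = [f"m{i}" for i in range(6)]
        tpm = normalize.NormalizedMatrix(
            pd.DataFrame({"n1": [100.0 + i for i in range(6)]}, index=ids), scheme="tpm"
        )
        ct = normalize.NormalizedMatrix(
            pd.DataFrame({"q1": [25.0 + 0.1 * i for i in range(6)]}, index=ids),
            scheme="per_cell_ct",
        )
        report = secretion.correlation_filter(ids, tpm, ct)
        # quartile step drops only miRNAs low on BOTH platforms; here
        # TPM-low and Ct-low sets coincide, so the bottom quartile goes
        assert report.step_counts[0] == 6
        assert len(report.kept) >= 4

    def test_or_rule_stricter_than_and(self):
        ids, tpm, ct = self.build()
        and_report = secretion.correlation_filter(ids, tpm, ct, quartile_rule="and")
        or_report = secretion.correlation_filter(ids, tpm, ct, quartile_rule="or")
        assert set(or_report.kept) <= set(and_report.kept)


class TestRankScores:
    def test_identical_ranks_zero(self):
        frame = pd.DataFrame(
            {
                "intra_Q": [300.0, 200, 100],
                "intra_SIPS": [300.0, 200, 100],
                "extra_au_Q": [30.0, 20, 10],
                "extra_au_SIPS": [30.0, 20, 10],
            },
            index=["A", "B", "C"],
        )
        out = secretion.rank_scores(make_ci(frame))
        assert (out["drank_Q"] == 0).all()
        assert (out["ddrank"] == 0).all()

    def test_hand_ranks(self):
        # intra ranks A,B,C = 1,2,3 in both conditions; extra Q same,
        # extra SIPS reversed -> ddrank A=-2, B=0, C=+2
        frame = pd.DataFrame(
            {
                "intra_Q": [300.0, 200, 100],
                "intra_SIPS": [300.0, 200, 100],
                "extra_au_Q": [30.0, 20, 10],
                "extra_au_SIPS": [10.0, 20, 30],
            },
            index=["A", "B", "C"],
        )
        out = secretion.rank_scores(make_ci(frame))
        assert out["ddrank"].to_dict() == {"A": -2.0, "B": 0.0, "C": 2.0}

    def test_tie_rule_average(self):
        frame = pd.DataFrame(
            {
                "intra_Q": [300.0, 200, 100],
                "intra_SIPS": [300.0, 200, 100],
                "extra_au_Q": [20.0, 20.0, 10],
                "extra_au_SIPS": [30.0, 20, 10],
            },
            index=["A", "B", "C"],
        )
        out = secretion.rank_scores(make_ci(frame))
        assert out.at["A", "rank_extra_Q"] == 1.5
        assert out.at["B", "rank_extra_Q"] == 1.5

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            {
                "intra_Q": rng.lognormal(3, 1, 20),
                "intra_SIPS": rng.lognormal(3, 1, 20),
                "extra_au_Q": rng.lognormal(5, 1, 20),
                "extra_au_SIPS": rng.lognormal(5, 1, 20),
            },
            index=[f"m{i}" for i in range(20)],
        )
        base = secretion.rank_scores(make_ci(frame))
        for transform in (np.log, np.sqrt, lambda x: 3 * x + 1, lambda x: x**3):
            out = secretion.rank_scores(make_ci(frame.apply(transform)))
            pd.testing.assert_series_equal(out["ddrank"], base["ddrank"])


class TestRatioScores:
    def test_hand_arithmetic(self):
        # intra constant; extra AU doubles in SIPS for X, halves for Y:
        # vesicular/intracellular quotients raw {X: 2, Y: 0.5}, mean 1.25,
        # normalized {X: 1.6, Y: 0.4}
        frame = pd.DataFrame(
            {
                "intra_Q": [100.0, 100.0],
                "intra_SIPS": [100.0, 100.0],
                "extra_au_Q": [40.0, 40.0],
                "extra_au_SIPS": [80.0, 20.0],
            },
            index=["X", "Y"],
        )
        out = secretion.ratio_scores(make_ci(frame))
        assert out.at["X", "ddratio_raw"] == pytest.approx(2.0, abs=1e-12)
        assert out.at["Y", "ddratio_raw"] == pytest.approx(0.5, abs=1e-12)
        assert out.at["X", "ddratio"] == pytest.approx(1.6, abs=1e-12)
        assert out.at["Y", "ddratio"] == pytest.approx(0.4, abs=1e-12)

    def test_no_condition_difference_gives_ones(self):
        rng = np.random.default_rng(1)
        intra = rng.lognormal(3, 1, 10)
        au = rng.lognormal(5, 1, 10)
        frame = pd.DataFrame(
            {"intra_Q": intra, "intra_SIPS": intra, "extra_au_Q": au, "extra_au_SIPS": au},
            index=[f"m{i}" for i in range(10)],
        )
        out = secretion.ratio_scores(make_ci(frame))
        assert np.allclose(out["ddratio"], 1.0, atol=1e-12)

    def test_mean_normalization_identity(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(
            {
                "intra_Q": rng.lognormal(3, 1, 50),
                "intra_SIPS": rng.lognormal(3, 1, 50),
                "extra_au_Q": rng.lognormal(5, 1, 50),
                "extra_au_SIPS": rng.lognormal(5, 1, 50),
            },
            index=[f"m{i}" for i in range(50)],
        )
        out = secretion.ratio_scores(make_ci(frame))
        assert np.nanmean(out["ddratio"]) == pytest.approx(1.0, abs=1e-9)

    def test_zero_denominator_flagged_and_excluded(self):
        frame = pd.DataFrame(
            {
                "intra_Q": [100.0, 0.0, 100.0],
                "intra_SIPS": [100.0, 100.0, 100.0],
                "extra_au_Q": [40.0, 40.0, 40.0],
                "extra_au_SIPS": [80.0, 80.0, 20.0],
            },
            index=["X", "bad", "Y"],
        )
        out = secretion.ratio_scores(make_ci(frame))
        assert np.isnan(out.at["bad", "ddratio"])
        assert out.at["X", "ddratio"] == pytest.approx(1.6, abs=1e-12)


class TestSymmetry:
    def swapped(self, frame):
        out = frame.rename(
            columns={
                "intra_Q": "intra_SIPS", "intra_SIPS": "intra_Q",
                "extra_au_Q": "extra_au_SIPS", "extra_au_SIPS": "extra_au_Q",
                "extra_ct_Q": "extra_ct_SIPS", "extra_ct_SIPS": "extra_ct_Q",
            }
        )
        return out

    def frame(self):
        rng = np.random.default_rng(5)
        return make_ci(
            pd.DataFrame(
                {
                    "intra_Q": rng.lognormal(3, 1, 30),
                    "intra_SIPS": rng.lognormal(3, 1, 30),
                    "extra_au_Q": rng.lognormal(5, 1, 30),
                    "extra_au_SIPS": rng.lognormal(5, 1, 30),
                },
                index=[f"m{i}" for i in range(30)],
            )
        ).frame

    def test_condition_swap_negates_ddrank(self):
        f = self.frame()
        a = secretion.rank_scores(make_ci(f))
        b = secretion.rank_scores(make_ci(self.swapped(f)))
        assert np.allclose(a["ddrank"], -b["ddrank"], atol=0)

    def test_condition_swap_reciprocates_ddratio_raw(self):
        f = self.frame()
        a = secretion.ratio_scores(make_ci(f))
        b = secretion.ratio_scores(make_ci(self.swapped(f)))
        assert np.allclose(a["ddratio_raw"] * b["ddratio_raw"], 1.0, rtol=1e-12)


class TestClassify:
    def test_all_identical_all_neutral(self):
        scores = pd.DataFrame({"ddrank": np.zeros(10), "ddratio": np.ones(10)})
        labels = secretion.classify_selective(scores)
        assert (labels == "neutral").all()

    def test_planted_extremes_labeled(self):
        scores = pd.DataFrame(
            {
                "ddrank": [-10.0, 0, 0, 0, 0, 0, 0, 10.0],
                "ddratio": [0.1, 1, 1, 1, 1, 1, 1, 5.0],
            },
            index=[f"m{i}" for i in range(8)],
        )
        labels = secretion.classify_selective(scores)
        assert labels["m7"] == "secreted"
        assert labels["m0"] == "retained"
        assert (labels.drop(["m0", "m7"]) == "neutral").all()

    def test_concordance_required(self):
        # high ddrank but median ddratio -> neutral
        scores = pd.DataFrame(
            {
                "ddrank": [-5.0, -2, -1, 0, 1, 2, 5, 20.0],
                "ddratio": [0.2, 0.8, 0.9, 1.0, 1.0, 1.1, 1.8, 1.0],
            },
            index=[f"m{i}" for i in range(8)],
        )
        labels = secretion.classify_selective(scores)
        assert labels["m7"] == "neutral"

    def test_too_few_raises(self):
        scores = pd.DataFrame({"ddrank": [1.0, 2], "ddratio": [1.0, 2]})
        with pytest.raises(io.ValidationError):
            secretion.classify_selective(scores)


class TestConcordance:
    def test_monotone_relation_rho_one(self):
        rng = np.random.default_rng(0)
        ddrank = rng.normal(size=30)
        scores = pd.DataFrame({"ddrank": ddrank, "ddratio": np.exp(ddrank)},
                              index=[f"m{i}" for i in range(30)])
        conc = secretion.method_concordance(scores, k=5)
        assert conc.rho == pytest.approx(1.0)
        assert conc.top_secreted_overlap == 5
        assert conc.top_retained_overlap == 5

    def test_reversed_rho_minus_one(self):
        rng = np.random.default_rng(0)
        ddrank = rng.normal(size=30)
        scores = pd.DataFrame({"ddrank": ddrank, "ddratio": -ddrank},
                              index=[f"m{i}" for i in range(30)])
        assert secretion.method_concordance(scores).rho == pytest.approx(-1.0)

    def test_constant_vector_undefined(self):
        scores = pd.DataFrame({"ddrank": np.arange(10.0), "ddratio": np.ones(10)})
        conc = secretion.method_concordance(scores)
        assert np.isnan(conc.rho)


class TestBuildCorrelationInput:
    def test_pools_donors_and_days(self):
        rows, ct_cols, tpm_cols = [], {}, {}
        for donor in ("d1", "d2"):
            for cond in ("Q", "SIPS"):
                for day in ("D7", "D21"):
                    qid, nid = f"{donor}_{cond}_{day}_EV", f"{donor}_{cond}_{day}_IC"
                    rows.append((qid, donor, cond, day, 1e6, "qpcr"))
                    rows.append((nid, donor, cond, day, 1e6, "ngs"))
                    ct_cols[qid] = {"m1": 30.0 if cond == "Q" else 28.0}
                    tpm_cols[nid] = {"m1": 100.0}
        sheet = make_sheet(rows)
        ct = normalize.NormalizedMatrix(pd.DataFrame(ct_cols), scheme="per_cell_ct")
        tpm = normalize.NormalizedMatrix(pd.DataFrame(tpm_cols), scheme="tpm")
        qs = sheet.subset(list(ct.values.columns))
        ns = sheet.subset(list(tpm.values.columns))
        ci = secretion.build_correlation_input(["m1"], tpm, ct, ns, qs)
        assert ci.frame.at["m1", "extra_ct_Q"] == pytest.approx(30.0)
        assert ci.frame.at["m1", "extra_au_SIPS"] == pytest.approx(
            secretion.au_transform(28.0)
        )
        assert ci.frame.at["m1", "intra_Q"] == pytest.approx(100.0)
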