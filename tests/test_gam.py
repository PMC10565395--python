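import subprocess

import numpy as np
import pandas as pd
import pytest

from tidegate.gam import BinomialGAM, ModelSpec, Smooth, aicc, aicc_rank
from tidegate.residency import build_presence
from tidegate.tables import (
    build_intraday_table,
    build_roaming_table,
    build_seasonal_table,
)


class TestAICc:
    def test_formula_value(self):
        assert aicc(50.0, 2, 100) == pytest.approx(50.1237, abs=5e-5)

    def test_blows_up_at_saturation(self):
        assert aicc(10.0, 99, 100) == float("inf")
        assert aicc(10.0, 120, 100) == float("inf")

    def test_exceeds_aic_for_positive_k(self):
        assert aicc(100.0, 3, 50) > 100.0


def _logistic_month_data(n=3000, seed=0, amplitude=1.2, n_tags=10):
    rng = np.random.default_rng(seed)
    month = rng.integers(1, 13, n)
    tag = rng.integers(0, n_tags, n).astype(str)
    tag_eff = rng.normal(0, 0.4, n_tags)
    eta = amplitude * np.sin(2 * np.pi * (month - 9) / 12) - 0.2
    eta = eta + tag_eff[tag.astype(int)]
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
    return pd.DataFrame(
        {"detected": y, "month": month, "noise": rng.uniform(0, 1, n), "tag_id": tag}
    )


@pytest.fixture(scope="module")
def month_fit():
    df = _logistic_month_data()
    spec = ModelSpec(
        "m",
        "detected",
        (
            Smooth("month", basis="cc", df=6, bounds=(0.5, 12.5)),
            Smooth("noise", basis="ps", df=6),
        ),
        random="tag",
    )
    return BinomialGAM(spec, df).fit()


class TestFitting:
    def test_recovers_seasonal_peak(self, month_fit):
        # truth peaks where sin(2 pi (m-9)/12) = 1, i.e. month 12
        grid = np.arange(1, 13)
        sv = month_fit.smooth_values("s(month)", grid)
        assert grid[int(np.argmax(sv))] in (11, 12, 1)

    def test_cyclic_smooth_is_periodic(self, month_fit):
        a = month_fit.smooth_values("s(month)", np.array([0.6]))
        b = month_fit.smooth_values("s(month)", np.array([12.6]))
        assert a[0] == pytest.approx(b[0], abs=1e-9)

    def test_null_covariate_penalized_to_linear_floor(self, month_fit):
        # the 2nd-derivative penalty cannot shrink the linear component, so
        # an uninformative covariate ends at ~1 effective df, not more
        assert month_fit.edf_by_term["s(noise)"] < 1.15

    def test_random_intercepts_absorb_tag_variance(self, month_fit):
        assert month_fit.edf_by_term["random(tag_id)"] > 2.0

    def test_constant_response_flagged_degenerate(self):
        df = _logistic_month_data(n=300, seed=1)
        df["detected"] = 0
        spec = ModelSpec(
            "flat", "detected", (Smooth("month", basis="cc", df=5, bounds=(0.5, 12.5)),)
        )
        fit = BinomialGAM(spec, df).fit()
        assert fit.degenerate

    def test_summary_mentions_terms(self, month_fit):
        text = month_fit.summary()
        assert "s(month)" in text and "AICc" in text


class TestRanking:
    def test_identical_fits_delta_zero(self, month_fit):
        table = aicc_rank({"a": month_fit, "b": month_fit})
        assert table["delta_aicc"].tolist() == [0.0, 0.0]

    def test_better_model_ranks_first(self):
        df = _logistic_month_data(n=2000, seed=2)
        month = Smooth("month", basis="cc", df=6, bounds=(0.5, 12.5))
        with_month = BinomialGAM(ModelSpec("with", "detected", (month,)), df).fit()
        intercept_only = BinomialGAM(ModelSpec("none", "detected", ()), df).fit()
        table = aicc_rank({"with": with_month, "none": intercept_only})
        assert table.iloc[0]["model"] == "with"
        assert table.iloc[1]["delta_aicc"] > 10

    def test_degenerate_fit_excluded(self):
        df = _logistic_month_data(n=300, seed=3)
        flat = df.copy()
        flat["detected"] = 1
        spec = ModelSpec("s", "detected", ())
        good = BinomialGAM(spec, df).fit()
        bad = BinomialGAM(spec, flat).fit()
        with pytest.warns(UserWarning, match="degenerate"):
            table = aicc_rank({"good": good, "bad": bad})
        assert table["model"].tolist() == ["good"]


class TestSexByFactorInteraction:
    def test_male_only_tide_height_ordering_recovered(self):
        rng = np.random.default_rng(5)
        n = 6000
        sex = rng.choice(["female", "male"], n)
        tide = rng.choice(["low", "intermediate", "high"], n)
        shift = {"low": -0.8, "intermediate": 0.0, "high": 0.8}
        eta = -0.5 + np.where(
            sex == "male", np.array([shift[t] for t in tide]), 0.0
        )
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        df = pd.DataFrame({"detected": y, "sex": sex, "tide_height_class": tide})
        spec = ModelSpec(
            "tide",
            "detected",
            (),
            ("sex", "tide_height_class", "tide_height_class:sex"),
        )
        fit = BinomialGAM(spec, df).fit()
        probe = pd.DataFrame(
            {
                "sex": ["male"] * 3 + ["female"] * 3,
                "tide_height_class": ["high", "intermediate", "low"] * 2,
            }
        )
        eta_hat = fit.predict(probe, linear=True)
        male_hi, male_mid, male_lo = eta_hat[:3]
        female = eta_hat[3:]
        assert male_hi > male_mid > male_lo
        assert np.ptp(female) < 0.3  # flat for females


class TestModelTables:
    def _presence(self, config, det_factory):
        det = det_factory(
            [
                ("2020-01-01 10:00:00", "A", "R1"),
                ("2020-01-03 10:00:00", "A", "R1"),
                ("2020-01-03 14:30:00", "A", "R2"),
                ("2020-01-02 09:00:00", "B", "R3"),
            ]
        )
        return det, build_presence(det, config)

    def test_seasonal_rows_end_at_last_detection(self, config, det_factory, tags):
        det, p = self._presence(config, det_factory)
        table = build_seasonal_table(p, tags)
        assert len(table[table.tag_id == "A"]) == 3  # days 1..3
        assert len(table[table.tag_id == "B"]) == 2  # days 1..2
        a = table[table.tag_id == "A"].set_index("day")["detected"]
        assert a.loc[pd.Timestamp("2020-01-01")] == 1
        assert a.loc[pd.Timestamp("2020-01-02")] == 0

    def test_roaming_rows_only_present_days(self, config, det_factory, tags):
        det, p = self._presence(config, det_factory)
        table = build_roaming_table(p, tags, n_receivers=5)
        a = table[table.tag_id == "A"].set_index("day")
        assert len(a) == 2
        assert a.loc[pd.Timestamp("2020-01-03"), "visited"] == 2
        assert (table["visited"] <= table["n_receivers"]).all()

    def test_roaming_props_defined(self, config, det_factory, tags):
        det, p = self._presence(config, det_factory)
        table = build_roaming_table(p, tags, n_receivers=5)
        day1 = table[table.day == pd.Timestamp("2020-01-01")].iloc[0]
        assert day1["prop_f"] == pytest.approx(1.0)  # the only female detected

    def test_intraday_24_rows_per_present_day(self, config, det_factory, tags):
        det, p = self._presence(config, det_factory)
        table = build_intraday_table(det, p, tags)
        a = table[table.tag_id == "A"]
        assert len(a) == 2 * 24  # two present days
        hit = a[(a.day == pd.Timestamp("2020-01-03")) & (a.hour == 14)]
        assert hit["detected"].iloc[0] == 1
        miss = a[(a.day == pd.Timestamp("2020-01-03")) & (a.hour == 15)]
        assert miss["detected"].iloc[0] == 0

    def test_binomial_trials_model_runs(self, config, det_factory, tags):
        det, p = self._presence(config, det_factory)
        table = build_roaming_table(p, tags, n_receivers=5)
        spec = ModelSpec(
            "roam", "visited", (), ("sex",), trials="n_receivers"
        )
        fit = BinomialGAM(spec, table).fit()
        assert np.isfinite(fit.aicc)


class TestAgainstMgcv:
    def test_cyclic_binomial_fit_matches_mgcv(self, tmp_path):
        """Independent oracle: mgcv's gam() on the same data and formula."""
        df = _logistic_month_data(n=2500, seed=7, n_tags=1)
        df.to_csv(tmp_path / "d.csv", index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            """
            suppressMessages(library(mgcv))
            d <- read.csv(commandArgs(TRUE)[1])
            m <- gam(detected ~ s(month, bs='cc', k=6), family=binomial,
                     knots=list(month=c(0.5, 12.5)), data=d, method='GCV.Cp')
            grid <- data.frame(month=1:12)
            cat(predict(m, grid, type='response'), sep='\\n')
            """
        )
        out = subprocess.run(
            ["Rscript", str(script), str(tmp_path / "d.csv")],
            capture_output=True,
            text=True,
            check=True,
        )
        mgcv_pred = np.array([float(x) for x in out.stdout.split()])
        spec = ModelSpec(
            "m", "detected", (Smooth("month", basis="cc", df=6, bounds=(0.5, 12.5)),)
        )
        fit = BinomialGAM(spec, df).fit()
        ours = fit.predict(pd.DataFrame({"month": np.arange(1, 13)}))
        assert np.sqrt(np.mean((ours - mgcv_pred) ** 2)) < 0.03
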