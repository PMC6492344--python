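import numpy as np
import pandas as pd
import pytest

import lymphomap as lm
from lymphomap.survival import (
    NoEventsError,
    fit_cox,
    km_estimate,
    pairwise_cox,
    prognostic_map,
)


def partial_loglik_grid(time, status, x, betas):
    """Brute-force Breslow=Efron (no ties) partial log-likelihood curve."""
    time = np.asarray(time, float)
    x = np.asarray(x, float)
    lls = []
    for b in betas:
        ll = 0.0
        for i in np.flatnonzero(status):
            risk = time >= time[i]
            ll += b * x[i] - np.log(np.sum(np.exp(b * x[risk])))
        lls.append(ll)
    return np.array(lls)


class TestFitCox:
    def test_matches_bruteforce_grid_tiny_fixture(self):
        """On a no-tie 6-subject fixture the Newton coefficient agrees
        with an exhaustive 1-D partial-likelihood grid search to 1e-4."""
        time = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        status = [1, 1, 0, 1, 1, 1]
        x = [1.0, 0.0, 1.0, 0.0, 1.0, 0.0]
        res = fit_cox(time, status, x)
        betas = np.linspace(-4, 4, 160001)
        lls = partial_loglik_grid(time, status, x, betas)
        assert abs(res.coef[0] - betas[np.argmax(lls)]) < 1e-4

    def test_matches_lifelines(self, rng):
        """Independent cross-check against lifelines on tied data."""
        from lifelines import CoxPHFitter

        n = 120
        x = rng.integers(0, 2, n).astype(float)
        time = np.ceil(rng.exponential(5 / np.exp(0.5 * x)))  # induces ties
        status = (rng.random(n) < 0.8).astype(int)
        res = fit_cox(time, status, x)
        df = pd.DataFrame({"T": time, "E": status, "x": x})
        cph = CoxPHFitter().fit(df, duration_col="T", event_col="E")
        assert res.coef[0] == pytest.approx(cph.params_["x"], abs=1e-6)
        assert res.se[0] == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_null_covariate_hr_near_one(self, rng):
        n = 800
        time = rng.exponential(1.0, n)
        status = np.ones(n, dtype=int)
        x = rng.integers(0, 2, n).astype(float)
        res = fit_cox(time, status, x)
        assert 0.85 < res.hr[0] < 1.18

    def test_planted_beta_recovered(self):
        cfg = lm.SimulationConfig(
            n_genes=40,
            n_modules=2,
            genes_per_module=10,
            class_definitions=[
                ("hi", frozenset("AB"), 300),
                ("lo", frozenset("B"), 300),
            ],
            module_betas={"A": np.log(2.0)},
            censor_rate=0.0,
            seed=3,
        )
        _, truth = lm.simulate_expression(cfg)
        ann = lm.simulate_survival(truth, cfg)
        x = (ann["class"] == "hi").to_numpy(dtype=float)
        res = fit_cox(ann["time"], ann["status"], x)
        assert 1.7 < res.hr[0] < 2.35

    def test_zero_events_raises(self):
        with pytest.raises(NoEventsError):
            fit_cox([1, 2, 3], [0, 0, 0], [0.0, 1.0, 0.5])

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            fit_cox([1, 2, 3], [1, 1, 0], [1.0, 1.0, 1.0])

    def test_separation_flagged(self):
        # events strictly precede all censoring in group 1 -> monotone
        time = [1, 2, 3, 10, 11, 12]
        status = [1, 1, 1, 0, 0, 0]
        x = [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]
        res = fit_cox(time, status, x)
        assert not res.converged
        assert "monotone-likelihood" in res.flags

    def test_label_swap_inverts_hr(self, rng):
        n = 100
        time = rng.exponential(1, n)
        status = rng.integers(0, 2, n)
        status[0] = 1
        x = rng.integers(0, 2, n).astype(float)
        a = fit_cox(time, status, x)
        b = fit_cox(time, status, 1.0 - x)
        assert a.hr[0] == pytest.approx(1 / b.hr[0], rel=1e-6)
        assert a.p[0] == pytest.approx(b.p[0], rel=1e-6)


class TestKaplanMeier:
    def test_all_events_hand_product(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        lookup = dict(zip(km["time"], km["survival"]))
        assert lookup[0.0] == 1.0
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)

    def test_no_events_flat_at_one(self):
        km = km_estimate([5.0, 6.0, 7.0], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_censored_mix_hand_computed(self):
        # events at 1 (5 at risk) and 4 (3 at risk); censored at 2 and 5
        km = km_estimate([1, 2, 4, 5, 6], [1, 0, 1, 0, 1])
        lookup = dict(zip(km["time"], km["survival"]))
        assert lookup[1.0] == pytest.approx(4 / 5)
        assert lookup[4.0] == pytest.approx(4 / 5 * 2 / 3)
        assert lookup[6.0] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(1.0, 50)
        km = km_estimate(t, np.ones(50, dtype=int))
        for time, surv in zip(km["time"], km["survival"]):
            assert surv == pytest.approx((t > time).mean())


class TestPairwise:
    def make_ann(self, rng, n=200, beta=0.0):
        group = rng.integers(0, 2, n)
        time = rng.exponential(1.0 / np.exp(beta * group))
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "class": np.where(group == 1, "g2", "g1"),
                "time": time,
                "status": 1,
                "chemotherapy": rng.integers(0, 2, n),
                "rituximab": rng.integers(0, 2, n),
            }
        )

    def test_identical_strata_null(self, rng):
        ann = self.make_ann(rng)
        strata = ann.set_index("sample_id")["class"]
        table = pairwise_cox(ann, strata)
        assert len(table) == 1
        assert 0.8 < table.iloc[0]["hr"] < 1.25

    def test_planted_hr_recovered_and_pair_count(self, rng):
        ann = self.make_ann(rng, n=600, beta=0.7)
        strata = ann.set_index("sample_id")["class"]
        table = pairwise_cox(ann, strata, adjust=True)
        assert table.iloc[0]["hr"] == pytest.approx(np.exp(0.7), rel=0.25)
        assert bool(table.iloc[0]["significant"])
        # adjusted fit close to unadjusted (therapy independent of hazard)
        assert table.iloc[0]["hr_adjusted"] == pytest.approx(
            table.iloc[0]["hr"], rel=0.15
        )
        # k strata -> k(k-1)/2 rows
        ann3 = ann.copy()
        ann3.loc[ann3.index[:100], "class"] = "g3"
        t3 = pairwise_cox(ann3, ann3.set_index("sample_id")["class"])
        assert len(t3) == 3


class TestPrognosticMap:
    def test_constant_portraits_all_undefined(self, rng):
        portraits = {
            f"s{i}": lm.Portrait(
                sample_or_group_id=f"s{i}",
                values=np.zeros(9),
                grid_rows=3,
                grid_cols=3,
            )
            for i in range(60)
        }
        ann = pd.DataFrame(
            {
                "sample_id": list(portraits),
                "time": rng.exponential(1, 60),
                "status": 1,
            }
        )
        hr_map = prognostic_map(portraits, ann)
        assert not hr_map.defined.any()
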