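"""Overload thresholds/classification, mixed model, density and correlation stats."""

import itertools
import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ycquant.calibration import calcium_to_ratio
from ycquant.glmm import MixedLogit, SeparationError
from ycquant.stats import (
    OverloadThresholds,
    check_normality,
    classify_overload,
    compare_density,
    compute_thresholds,
    correlate_density_ratio,
    fit_overload_model,
)
from ycquant.synthetic import CohortConfig, simulate_measurement_tables


def _meas(dend, spine=None):
    spine = dend if spine is None else spine
    return pd.DataFrame(
        {
            "roi_id": [f"d{i}" for i in range(len(dend))] + [f"s{i}" for i in range(len(spine))],
            "animal_id": "a1",
            "genotype": "control",
            "compartment": ["dendrite"] * len(dend) + ["spine"] * len(spine),
            "mean_ratio": list(dend) + list(spine),
        }
    )


class TestComputeThresholds:
    def test_linear_interpolation_percentile(self):
        """1..100 has 95th percentile 95.05 under linear interpolation."""
        vals = np.arange(1.0, 101.0)
        thr = compute_thresholds(_meas(vals))
        assert thr.thr_dend == pytest.approx(95.05)
        assert thr.thr_spine == pytest.approx(95.05)

    def test_constant_input(self):
        thr = compute_thresholds(_meas([1.7] * 25))
        assert thr.thr_dend == 1.7

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(1.7, 0.3, 100)
        shuffled = vals.copy()
        rng.shuffle(shuffled)
        assert compute_thresholds(_meas(vals)) == compute_thresholds(_meas(shuffled))

    def test_matches_percentile_oracle_on_synthetic_cohort(self):
        m, _ = simulate_measurement_tables(CohortConfig(seed=5))
        ctl = m[m["genotype"] == "control"]
        thr = compute_thresholds(ctl)
        for comp, got in (("dendrite", thr.thr_dend), ("spine", thr.thr_spine)):
            vals = np.sort(ctl.loc[ctl["compartment"] == comp, "mean_ratio"].to_numpy())
            # independent linear-interpolation percentile: h = (n-1)q
            h = (len(vals) - 1) * 0.95
            lo = int(math.floor(h))
            oracle = vals[lo] + (h - lo) * (vals[lo + 1] - vals[lo])
            assert got == pytest.approx(oracle, abs=1e-9)

    def test_insufficient_compartment(self):
        with pytest.raises(ValueError, match="spine"):
            compute_thresholds(_meas(np.linspace(1, 2, 30), spine=[1.5] * 5))


class TestClassifyOverload:
    @pytest.mark.parametrize("n", [40, 100, 4655])
    def test_self_classification_near_five_percent(self, n):
        """Thresholds from a control set classify ~5% of that same set as
        overloaded, up to percentile discreteness."""
        rng = np.random.default_rng(n)
        m = _meas(rng.normal(1.69, 0.27, n), spine=rng.normal(1.76, 0.33, n))
        thr = compute_thresholds(m)
        _, frac = classify_overload(m, thr)
        for row in frac.itertuples(index=False):
            assert math.floor(0.05 * n) / n <= row.fraction <= math.ceil(0.05 * n) / n

    def test_tie_is_not_overloaded(self):
        thr = OverloadThresholds(thr_dend=1.8, thr_spine=1.9)
        m = _meas([1.8, 1.8000001], spine=[1.9])
        out, _ = classify_overload(m, thr)
        assert list(out["overload"]) == [False, True, False]

    def test_mixture_fraction_recovered(self):
        """A 20% high-calcium subpopulation in tau yields an overload fraction
        near 20% + the baseline 5%, within ±3 points at n=2000."""
        import dataclasses

        cfg = dataclasses.replace(
            CohortConfig(seed=9),
            overload_fraction_tau=0.20,
            dendrites_per_volume=200, volumes_per_animal=1,
            n_control_animals=6, n_tau_animals=10,
        )
        m, _ = simulate_measurement_tables(cfg)
        thr = compute_thresholds(m[m["genotype"] == "control"])
        dend = m[m["compartment"] == "dendrite"]
        _, frac = classify_overload(dend, thr)
        tau_frac = float(
            frac.loc[(frac["genotype"] == "tau") & (frac["compartment"] == "dendrite"),
                     "fraction"].iloc[0]
        )
        tau_dend = dend[dend["genotype"] == "tau"]
        assert len(tau_dend) >= 2000
        # generator truth: fraction of tau structures whose noiseless ratio
        # exceeds the same threshold
        r_true = np.array([calcium_to_ratio(c) for c in tau_dend["true_calcium_nM"]])
        truth = float((r_true > thr.thr_dend).mean())
        assert truth > 0.10  # the mixture creates a real elevated subpopulation
        assert tau_frac == pytest.approx(truth, abs=0.03)


class TestMixedLogitModel:
    def _clustered_data(self, rng, n_animals=15, n_obs=100, sigma=0.5, beta=0.8):
        y, x, g = [], [], []
        for i in range(n_animals):
            u = rng.normal(0, sigma)
            tau = 1.0 if i >= 6 else 0.0
            eta = -2.2 + beta * tau + u
            y.append((rng.random(n_obs) < 1 / (1 + np.exp(-eta))).astype(float))
            x.append(np.full(n_obs, tau))
            g.append(np.full(n_obs, i))
        return map(np.concatenate, (y, x, g))

    def test_matches_lme4_glmer(self, tmp_path):
        """Gauss-Hermite ML agrees with lme4::glmer (nAGQ=25) on coefficients,
        standard errors and the random-intercept SD."""
        rng = np.random.default_rng(42)
        y, x, g = self._clustered_data(rng)
        res = MixedLogit(y, np.column_stack([np.ones_like(y), x]), g).fit()
        csv = tmp_path / "d.csv"
        np.savetxt(csv, np.column_stack([y, x, g]), delimiter=",", header="y,x,g", comments="")
        rscript = textwrap.dedent(
            f"""
            d <- read.csv("{csv}")
            suppressMessages(library(lme4))
            m <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=25)
            co <- summary(m)$coefficients
            cat(co[,1], co[,2], sqrt(unlist(VarCorr(m))), sep="\\n")
            """
        )
        proc = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        b0, b1, se0, se1, sigma = map(float, proc.stdout.strip().splitlines()[-5:])
        assert res.params == pytest.approx([b0, b1], abs=2e-3)
        assert res.bse == pytest.approx([se0, se1], abs=2e-3)
        assert res.sigma == pytest.approx(sigma, abs=5e-3)

    def test_all_identical_outcomes_separation(self):
        with pytest.raises(SeparationError):
            fit_overload_model(
                np.zeros(40), np.array(["control"] * 20 + ["tau"] * 20),
                np.repeat([f"a{i}" for i in range(4)], 10),
            )

    def test_single_animal_group_rejected(self):
        rng = np.random.default_rng(1)
        flags = rng.random(30) < 0.3
        with pytest.raises(ValueError, match="control"):
            fit_overload_model(
                flags, np.array(["control"] * 10 + ["tau"] * 20),
                np.array(["a1"] * 10 + ["b1"] * 10 + ["b2"] * 10),
            )

    def test_power_against_strong_overload_difference(self):
        """5% vs 25% overload across 15 animals is detected nearly always."""
        rej = 0
        n_rep = 30
        for rep in range(n_rep):
            rng = np.random.default_rng(50_000 + rep)
            y, x, g = [], [], []
            for i in range(15):
                p = 0.25 if i >= 6 else 0.05
                y.append((rng.random(300) < p).astype(float))
                x.append(np.full(300, "tau" if i >= 6 else "control"))
                g.append(np.full(300, i))
            gc = fit_overload_model(np.concatenate(y), np.concatenate(x), np.concatenate(g))
            rej += gc.p_value < 0.05
        assert rej / n_rep >= 0.9


class TestCheckNormality:
    def test_normal_samples_rarely_rejected(self):
        ok = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            _, p = check_normality(rng.normal(size=100))
            ok += p > 0.05
        assert ok >= 90

    def test_exponential_samples_usually_rejected(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            _, p = check_normality(rng.exponential(size=100))
            hits += p < 0.05
        assert hits >= 90

    def test_out_of_range_n(self):
        with pytest.raises(ValueError):
            check_normality([1.0, 2.0])


def _density_records(per_animal_means, genotype):
    rows = []
    for a, m in enumerate(per_animal_means):
        rows.append(
            {
                "dendrite_id": f"{genotype}{a}_d0", "animal_id": f"{genotype}{a}",
                "genotype": genotype, "length_um": 30.0, "n_spines": 9,
                "density_per_um": m, "parent_ratio": 1.7, "included": True,
            }
        )
    return pd.DataFrame(rows)


class TestCompareDensity:
    def test_identical_groups(self):
        rec = pd.concat(
            [_density_records([0.5, 0.6, 0.7], "control"), _density_records([0.5, 0.6, 0.7], "tau")]
        )
        out = compare_density(rec)
        assert out.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert out.percent_reduction == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_student_t(self):
        """3v3 comparison equals the pooled-variance t formula exactly."""
        ctl, tau = [0.58, 0.62, 0.66], [0.40, 0.44, 0.42]
        out = compare_density(
            pd.concat([_density_records(ctl, "control"), _density_records(tau, "tau")])
        )
        n1, n2 = 3, 3
        m1, m2 = np.mean(tau), np.mean(ctl)
        sp2 = ((n1 - 1) * np.var(tau, ddof=1) + (n2 - 1) * np.var(ctl, ddof=1)) / (n1 + n2 - 2)
        t_ref = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        p_ref = 2 * sps.t.sf(abs(t_ref), n1 + n2 - 2)
        assert out.t_statistic == pytest.approx(t_ref, abs=1e-12)
        assert out.p_value == pytest.approx(p_ref, abs=1e-12)
        assert out.percent_reduction == pytest.approx(100 * (1 - m1 / m2), abs=1e-12)

    def test_small_group_rejected(self):
        rec = pd.concat([_density_records([0.6], "control"), _density_records([0.4, 0.5], "tau")])
        with pytest.raises(ValueError, match="control"):
            compare_density(rec)

    def test_recovers_injected_reduction(self):
        """6 control vs 9 tau animals with a true 30% reduction: the
        estimated reduction is unbiased and the t-test nearly always fires."""
        import dataclasses

        hits, ests = 0, []
        n_rep = 60
        for rep in range(n_rep):
            cfg = dataclasses.replace(
                CohortConfig(seed=70_000 + rep), dendrites_per_volume=1
            )
            _, rec = simulate_measurement_tables(cfg)
            out = compare_density(rec)
            hits += out.p_value < 0.05
            ests.append(out.percent_reduction)
        assert hits / n_rep >= 0.9
        assert abs(np.mean(ests) - 30.0) <= 8.0


class TestCorrelateDensityRatio:
    def _rec(self, ratio, density):
        return pd.DataFrame(
            {
                "dendrite_id": [f"d{i}" for i in range(len(ratio))],
                "animal_id": "a", "genotype": "tau",
                "length_um": 30.0, "n_spines": 9,
                "density_per_um": density, "parent_ratio": ratio, "included": True,
            }
        )

    def test_exact_line(self):
        r = np.linspace(1.4, 2.2, 10)
        out = correlate_density_ratio(self._rec(r, 2 * r))
        assert out.r_squared == pytest.approx(1.0)
        assert out.spearman_rho == pytest.approx(1.0)

    def test_null_r_squared_scale(self):
        """Independent density and ratio: E[R^2] = 1/(n-1), and Spearman p
        stays above 0.05 in most replicates."""
        n, reps = 60, 500
        r2s, p_ok = [], 0
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            out = correlate_density_ratio(
                self._rec(rng.normal(1.7, 0.2, n), rng.normal(0.5, 0.1, n))
            )
            r2s.append(out.r_squared)
            p_ok += out.p_value > 0.05
        assert np.mean(r2s) == pytest.approx(1 / (n - 1), abs=0.006)
        assert p_ok / reps >= 0.9

    def test_spearman_matches_rank_permutation_bruteforce(self):
        """Exact Spearman rho via the rank formula on n=8 distinct values."""
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(size=8)
        out = correlate_density_ratio(self._rec(1.5 + 0.1 * x, 0.5 + 0.05 * y))
        rx = np.argsort(np.argsort(1.5 + 0.1 * x))
        ry = np.argsort(np.argsort(0.5 + 0.05 * y))
        d = rx - ry
        rho_ref = 1 - 6 * (d**2).sum() / (8 * (8**2 - 1))
        assert out.spearman_rho == pytest.approx(rho_ref, abs=1e-12)
        # exact permutation p-value: fraction of rank permutations at least
        # as extreme in |rho|
        n_extreme = 0
        total = 0
        for perm in itertools.permutations(range(8)):
            dd = rx - np.array(perm)
            rho_p = 1 - 6 * (dd**2).sum() / (8 * 63)
            n_extreme += abs(rho_p) >= abs(rho_ref) - 1e-12
            total += 1
        assert out.p_value == pytest.approx(n_extreme / total, abs=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate_density_ratio(self._rec(np.full(5, 1.7), np.linspace(0.3, 0.7, 5)))
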