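"""Exact conditional count test, normalization front-ends, BH, RNA-seq DE."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cutrun_delta.differential import (
    NormalizationSpec,
    bh_fdr,
    binomial_enrichment_library_sizes,
    estimate_overdispersion,
    exact_count_test,
    median_of_ratios_size_factors,
    rnaseq_de,
    spikein_library_sizes,
)
from cutrun_delta.io_formats import CountTable


def table(rows, samples, library_sizes=None, features=None):
    counts = pd.DataFrame(
        rows,
        index=pd.Index(features or [f"f{i}" for i in range(len(rows))], name="feature_id"),
        columns=samples,
    )
    lib = pd.Series(library_sizes, index=samples, dtype=float) if library_sizes else None
    return CountTable(counts, lib)


def conditional_binomial_oracle(y_a: int, n: int, pi0: float) -> float:
    """Exhaustive two-sided minimum-likelihood conditional binomial p."""
    pmf = [math.comb(n, j) * pi0**j * (1 - pi0) ** (n - j) for j in range(n + 1)]
    obs = pmf[y_a]
    return min(sum(q for q in pmf if q <= obs * (1 + 1e-8)), 1.0)


class TestBH:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_degenerate(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0]), [1.0, 1.0])
        np.testing.assert_allclose(bh_fdr([0.37]), [0.37])
        assert bh_fdr([]).size == 0


class TestSpikeinSizes:
    def test_passthrough(self):
        spec = spikein_library_sizes({"a": 1000, "b": 1000, "c": 500, "d": 500})
        assert spec.mode == "spikein"
        assert spec.library_sizes.tolist() == [1000.0, 1000.0, 500.0, 500.0]

    def test_zero_spike_fatal_with_guidance(self):
        with pytest.raises(ValueError, match="enriched-regions"):
            spikein_library_sizes({"a": 1000, "b": 0})

    def test_global_spike_scaling_leaves_results_unchanged(self):
        """The conditional test depends on library sizes only through ratios."""
        t = table([[30, 25, 10, 8], [5, 6, 7, 8]], ["c1", "c2", "k1", "k2"])
        r1 = exact_count_test(t, ["c1", "c2"], ["k1", "k2"],
                              spikein_library_sizes({"c1": 100, "c2": 120, "k1": 90, "k2": 110}))
        r2 = exact_count_test(t, ["c1", "c2"], ["k1", "k2"],
                              spikein_library_sizes({"c1": 1000, "c2": 1200, "k1": 900, "k2": 1100}))
        np.testing.assert_allclose(r1["pvalue"], r2["pvalue"])
        np.testing.assert_allclose(r1["log2fc"], r2["log2fc"])


class TestBinomialEnrichment:
    def test_upper_tail_example(self):
        """k_s=30 of N_s=1000 vs k_c=10 of N_c=1000: p0 = 10.5/1000.5."""
        p0 = 10.5 / 1000.5
        expected = float(stats.binom.sf(29, 1000, p0))
        # independent check by direct summation
        brute = sum(
            math.comb(1000, j) * p0**j * (1 - p0) ** (1000 - j) for j in range(30, 1001)
        )
        assert expected == pytest.approx(brute, rel=1e-9)
        t = table([[30, 10, 10]], ["s", "igg", "input"],
                  library_sizes={"s": 1000, "igg": 1000, "input": 1000})
        # single gene: BH leaves p unchanged; significant iff p <= cut
        norm, common = binomial_enrichment_library_sizes(
            t, ["s"], ["igg", "input"], fdr_cut=expected + 1e-12
        )
        assert common == ["f0"] and norm.library_sizes["s"] == 30.0

    def test_zero_count_never_significant(self):
        t = table([[0, 10, 10], [500, 10, 10]], ["s", "igg", "input"],
                  library_sizes={"s": 1000, "igg": 1000, "input": 1000})
        norm, common = binomial_enrichment_library_sizes(t, ["s"], ["igg", "input"])
        assert common == ["f1"]

    def test_sample_identical_to_control_yields_nothing(self):
        """Calibration: a mark sample that IS the control produces no
        significant gene bodies (fatal empty-set diagnostic)."""
        rng = np.random.default_rng(21)
        k = rng.poisson(50, size=400)
        t = table(np.column_stack([k, k, k]).tolist(), ["s", "igg", "input"],
                  library_sizes={"s": k.sum() * 2, "igg": k.sum() * 2, "input": k.sum() * 2},
                  features=[f"g{i}" for i in range(400)])
        with pytest.raises(ValueError, match="significant"):
            binomial_enrichment_library_sizes(t, ["s"], ["igg", "input"])


class TestExactCountTest:
    def run_single(self, y_a, y_b, L_a=1000.0, L_b=1000.0, rho=0.0):
        t = table([[y_a, y_b]], ["A", "B"], library_sizes={"A": L_a, "B": L_b})
        res = exact_count_test(t, ["A"], ["B"], rho=rho)
        return res.iloc[0]

    def test_symmetric_null_p_one(self):
        assert self.run_single(5, 5)["pvalue"] == 1.0

    def test_extreme_split_binomial_p(self):
        row = self.run_single(0, 10)
        assert row["pvalue"] == pytest.approx(2 * 0.5**10, rel=1e-12)

    def test_empty_feature(self):
        row = self.run_single(0, 0)
        assert row["pvalue"] == 1.0 and row["log2fc"] == 0.0

    def test_log2fc_pseudocount_direction(self):
        row = self.run_single(40, 10)
        assert row["log2fc"] == pytest.approx(np.log2(10.5 / 40.5))

    def test_matches_enumeration_oracle_up_to_n50(self):
        """rho=0 p-values equal exhaustive conditional-binomial enumeration
        for every (y_a, n) with n <= 50, at equal and unequal library sizes."""
        for L_a, L_b in [(1000.0, 1000.0), (2000.0, 1000.0)]:
            pi0 = L_a / (L_a + L_b)
            for n in range(0, 51):
                rows = [[y_a, n - y_a] for y_a in range(n + 1)]
                t = table(rows, ["A", "B"], library_sizes={"A": L_a, "B": L_b})
                res = exact_count_test(t, ["A"], ["B"], rho=0.0)
                for y_a, p in zip(range(n + 1), res["pvalue"]):
                    assert p == pytest.approx(
                        conditional_binomial_oracle(y_a, n, pi0), rel=1e-9
                    ), (y_a, n, pi0)

    def test_single_replicate_rho_warning(self):
        t = table([[5, 9]], ["A", "B"])
        with pytest.warns(UserWarning, match="single replicate"):
            exact_count_test(t, ["A"], ["B"])

    def test_null_calibration_rejection_rate(self):
        """On gamma-Poisson null data (2 vs 2, 2000 features) the rejection
        rate at p < 0.05 stays in the binomial 99% band [0.03, 0.07]."""
        rng = np.random.default_rng(2024)
        n_feat = 2000
        mu = rng.uniform(30, 300, n_feat)
        s = np.array([1.0, 1.2, 0.9, 1.1])
        phi = 0.1
        lam = rng.gamma(1.0 / phi, phi * np.outer(mu, s))
        counts = rng.poisson(lam)
        t = table(counts.tolist(), ["c1", "c2", "k1", "k2"],
                  library_sizes=dict(zip(["c1", "c2", "k1", "k2"], s * 1e6)),
                  features=[f"g{i}" for i in range(n_feat)])
        res = exact_count_test(t, ["c1", "c2"], ["k1", "k2"])
        rate = float((res["pvalue"] < 0.05).mean())
        assert 0.03 <= rate <= 0.07, rate


class TestOverdispersionEstimator:
    def test_poisson_data_rho_near_zero(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.poisson(100, size=(2000, 4)), columns=["a", "b", "c", "d"]
        )
        rho = estimate_overdispersion(
            counts, {"A": ["a", "b"], "B": ["c", "d"]},
            pd.Series(1.0, index=["a", "b", "c", "d"]),
        )
        assert rho < 0.002

    def test_overdispersed_data_rho_positive(self):
        rng = np.random.default_rng(4)
        phi = 0.1
        mu = 200.0
        lam = rng.gamma(1 / phi, phi * mu, size=(2000, 4))
        counts = pd.DataFrame(rng.poisson(lam), columns=["a", "b", "c", "d"])
        rho = estimate_overdispersion(
            counts, {"A": ["a", "b"], "B": ["c", "d"]},
            pd.Series(1.0, index=["a", "b", "c", "d"]),
        )
        # pair-level rho for NB shape 1/phi: 1/(2/phi + 1)
        assert rho == pytest.approx(1 / (2 / phi + 1), rel=0.15)


class TestRnaseqDE:
    def test_low_count_filter_rule(self):
        counts = [[9, 9, 9, 9, 9, 9, 9, 9, 9],
                  [9, 9, 12, 9, 9, 9, 9, 9, 9],
                  [100, 110, 90, 100, 95, 105, 98, 102, 101]]
        samples = [f"{c}_r{i}" for c in ("ctrl", "sg2", "sg3") for i in (1, 2, 3)]
        t = table(counts, samples, features=["low", "edge", "ok"])
        cond = {s: s.rsplit("_", 1)[0] for s in samples}
        out = rnaseq_de(t, cond, "ctrl", ["sg2", "sg3"])
        assert set(out["filtered"].feature_ids) == {"edge", "ok"}

    def test_identical_samples_null(self):
        counts = np.tile([[50], [80], [200]], (1, 6)).tolist()
        samples = [f"{c}_r{i}" for c in ("ctrl", "sg2") for i in (1, 2, 3)]
        t = table(counts, samples, features=["a", "b", "c"])
        cond = {s: s.rsplit("_", 1)[0] for s in samples}
        out = rnaseq_de(t, cond, "ctrl", ["sg2"])
        res = out["contrasts"]["sg2"]
        assert (res["pvalue"] == 1.0).all()
        assert np.allclose(out["size_factors"], out["size_factors"].iloc[0])

    def test_both_guides_rule(self):
        """A gene down in only one guide is not a DEG."""
        rng = np.random.default_rng(8)
        base = rng.poisson(400, size=(50, 9))
        samples = [f"{c}_r{i}" for c in ("ctrl", "sg2", "sg3") for i in (1, 2, 3)]
        base[0, 3:6] //= 8  # down in sg2 only
        base[1, 3:9] //= 8  # down in both
        t = table(base.tolist(), samples, features=[f"g{i}" for i in range(50)])
        cond = {s: s.rsplit("_", 1)[0] for s in samples}
        out = rnaseq_de(t, cond, "ctrl", ["sg2", "sg3"])
        assert "g1" in out["deg_down"] and "g0" not in out["deg_down"]

    def test_median_of_ratios_excludes_zeros(self):
        counts = pd.DataFrame({"a": [10, 0, 100], "b": [20, 50, 200]})
        sf = median_of_ratios_size_factors(counts)
        # only rows without zeros enter; both surviving genes have ratio
        # (1/sqrt(2), sqrt(2)) scaled
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
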