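import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from trnamod import calling
from trnamod.calling import (
    BetaNull,
    CallingConfig,
    CallingError,
    adjust_pvalues,
    classify_confidence,
    fit_background,
    mi_frequency,
    position_pvalue,
    read_identity,
)

from conftest import make_coverage


def counts(a=0, c=0, g=0, t=0, d=0):
    return {"A": a, "C": c, "G": g, "T": t, "-": d}


def brute_force_mi(count_map, ref):
    """Independent recount: enumerate every read; deletions are
    non-reference calls and contribute to coverage."""
    reads = [b for b, n in count_map.items() for _ in range(n)]
    if not reads:
        return math.nan
    return sum(r != ref for r in reads) / len(reads)


class TestMiFrequency:
    @pytest.mark.parametrize("cnt,ref,expected", [
        (counts(a=5, c=3, g=90, t=2), "G", 0.10),
        (counts(a=100), "A", 0.0),
        (counts(g=40, d=60), "G", 0.60),  # deletions count as misreads
        (counts(t=97, c=3), "U", 0.03),   # U accepted for T
    ])
    def test_examples(self, cnt, ref, expected):
        assert mi_frequency(cnt, ref) == pytest.approx(expected)
        assert mi_frequency(cnt, ref) == pytest.approx(
            brute_force_mi(cnt, ref.replace("U", "T")))

    def test_zero_coverage_is_explicit_marker(self):
        assert math.isnan(mi_frequency(counts(), "A"))

    def test_unknown_base_rejected(self):
        with pytest.raises(CallingError):
            mi_frequency(counts(a=1), "X")

    @given(st.lists(st.integers(0, 500), min_size=5, max_size=5),
           st.sampled_from("ACGT"))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_recount(self, vals, ref):
        cnt = dict(zip("ACGT-", vals))
        expected = brute_force_mi(cnt, ref)
        got = mi_frequency(cnt, ref)
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected)


class TestReadIdentity:
    def test_even_split(self):
        comp = read_identity(counts(a=50, g=50))
        assert comp == {"A": 0.5, "C": 0, "G": 0.5, "T": 0, "-": 0}

    def test_all_reference_is_unit_vector(self):
        comp = read_identity(counts(c=120))
        assert comp["C"] == 1.0 and sum(comp.values()) == 1.0

    def test_deletion_fraction(self):
        comp = read_identity(counts(g=40, d=60))
        assert comp["-"] == pytest.approx(0.6)
        assert sum(comp.values()) == pytest.approx(1.0)


def make_null(alpha, beta, q75=0.05):
    return BetaNull(ref_base="G", alpha=alpha, beta=beta,
                    pseudo_mismatch=alpha, pseudo_match=beta,
                    threshold_q75=q75)


class TestPositionPvalue:
    def test_uniform_null(self):
        # Beta(1,1) null: upper-tail mass above MI=0.3 is 0.7
        null = make_null(1.0, 1.0)
        p = position_pvalue(counts(g=70, a=30), "G", null)
        assert p == pytest.approx(0.7)

    def test_zero_mi_gives_p_one(self):
        assert position_pvalue(counts(g=100), "G", make_null(2, 50)) == 1.0

    @pytest.mark.parametrize("alpha,beta,x", [
        (2, 50, 0.25), (1.5, 30, 0.1), (0.8, 5, 0.5), (4, 300, 0.02),
    ])
    def test_matches_quadrature_oracle(self, alpha, beta, x):
        """Tail probability agrees with adaptive quadrature of the beta
        density over [x, 1] to 1e-9."""
        oracle, err = integrate.quad(
            lambda v: stats.beta.pdf(v, alpha, beta), x, 1,
            epsabs=1e-12, limit=200)
        assert err < 1e-10
        n = round(x * 1000)
        p = position_pvalue(counts(g=1000 - n, a=n), "G",
                            make_null(alpha, beta))
        assert p == pytest.approx(oracle, abs=1e-9)

    def test_posterior_exceedance_mode(self):
        # closed form: P(latent MI < q75 | counts) under the beta posterior
        null = make_null(2.0, 50.0, q75=0.04)
        p = position_pvalue(counts(g=90, a=10), "G", null,
                            mode="posterior-exceedance")
        expected = stats.beta.cdf(0.04, 10 + 2.0, 90 + 50.0)
        assert p == pytest.approx(expected)

    @given(st.integers(0, 200))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_mi(self, mismatches):
        """For a fixed null, p is non-increasing in MI (both modes)."""
        null = make_null(2, 50, q75=0.05)
        cov = 200
        for mode in ("null-tail", "posterior-exceedance"):
            p_lo = position_pvalue(counts(g=cov - mismatches, a=mismatches),
                                   "G", null, mode=mode)
            more = min(mismatches + 10, cov)
            p_hi = position_pvalue(counts(g=cov - more, a=more), "G", null,
                                   mode=mode)
            assert p_hi <= p_lo + 1e-12

    def test_invalid_null_rejected(self):
        with pytest.raises(CallingError):
            make_null(-1.0, 5.0)


class TestFitBackground:
    def test_method_of_moments_recovers_beta(self):
        """10,000 draws from Beta(2, 50): recovered alpha in [1.6, 2.4] and
        beta in [40, 60]."""
        rng = np.random.default_rng(11)
        mi = rng.beta(2, 50, size=10_000)
        cov = 1000
        rows = [("sp", f"t{i}", "10", "G",
                 round(m * cov), 0, cov - round(m * cov), 0, 0)
                for i, m in enumerate(mi)]
        coverage = make_coverage(rows)
        nulls = fit_background(coverage, None)
        assert 1.6 <= nulls["G"].alpha <= 2.4
        assert 40 <= nulls["G"].beta <= 60

    def test_constant_input_triggers_fallback(self):
        rows = [("sp", f"t{i}", "10", "G", 0, 0, 100, 0, 0)
                for i in range(40)]
        with pytest.warns(UserWarning, match="degenerate"):
            nulls = fit_background(make_coverage(rows), None)
        assert nulls["G"].fallback

    def test_too_few_sites_rejected(self):
        rows = [("sp", f"t{i}", "10", "G", 1, 0, 99, 0, 0) for i in range(5)]
        with pytest.raises(CallingError, match="background fitting"):
            fit_background(make_coverage(rows), None)

    def test_known_sites_excluded_from_fit(self):
        rng = np.random.default_rng(5)
        quiet = [("sp", f"t{i}", "10", "G", *_noisy(rng, 0.01), 0)
                 for i in range(50)]
        hot = [("sp", f"h{i}", "10", "G", 600, 0, 400, 0, 0)
               for i in range(20)]
        known = pd.DataFrame(
            [{"species": "sp", "trna": f"h{i}", "position": "10",
              "code": "m22G", "source": "known"} for i in range(20)])
        with_excl = fit_background(make_coverage(quiet + hot), known)
        without = fit_background(make_coverage(quiet + hot), None)
        assert with_excl["G"].mean < 0.05 < without["G"].mean

    def test_gc_background_exceeds_at_on_synthetic_default(self, scenario):
        """G/C backgrounds run hotter than A/U, so their 75th-percentile
        thresholds are larger — the base-specific ordering the thresholds
        exist for."""
        nulls = fit_background(
            scenario["coverage"][scenario["coverage"]["species"] == "hyper_A"],
            scenario["truth"])
        assert nulls["G"].threshold_q75 > nulls["A"].threshold_q75
        assert nulls["C"].threshold_q75 > nulls["T"].threshold_q75
        for null in nulls.values():
            assert 0 < null.mean < null.threshold_q75 * 2


def _noisy(rng, mean):
    cov = 1000
    k = rng.binomial(cov, mean)
    return (k, 0, cov - k, 0)


def reference_bh(pvals):
    """Textbook Benjamini-Hochberg step-up, written independently."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, p[idx] * m / rank)
        adjusted[idx] = val
        prev = val
    return adjusted


class TestAdjustPvalues:
    def test_hand_computed_example(self):
        # m=4: each p_i * 4/i clamps to 0.04
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_test_unchanged(self):
        assert adjust_pvalues([0.5]).tolist() == [0.5]

    def test_empty_input(self):
        assert len(adjust_pvalues([])) == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(CallingError):
            adjust_pvalues([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_dominating(self, pvals):
        out = adjust_pvalues(pvals)
        assert np.all(out >= np.asarray(pvals) - 1e-12)
        assert np.all(out <= 1.0 + 1e-12)

    def test_matches_independent_reference(self):
        """BH output equals an independently written step-up on 1,000
        random p-vectors."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 30))
            assert np.allclose(adjust_pvalues(p), reference_bh(p),
                               atol=1e-12)


class TestClassifyConfidence:
    @pytest.mark.parametrize("base,mi,p_adj,expected", [
        ("G", 0.12, 0.001, "high"),
        ("G", 0.08, 0.001, "moderate"),
        ("A", 0.06, 0.01, "high"),
        ("A", 0.06, 0.30, "none"),
        ("U", 0.04, 0.001, "moderate"),
        ("C", 0.50, 0.049, "high"),
    ])
    def test_examples(self, base, mi, p_adj, expected):
        assert classify_confidence(base, mi, p_adj) == expected

    def test_exhaustive_boundary_grid(self):
        """Full grid of (base class, MI above/at/below threshold, p
        above/at/below 0.05); ties at the MI threshold are moderate, ties
        at p = 0.05 are not significant."""
        for base, thr in [("G", 0.10), ("C", 0.10), ("A", 0.05),
                          ("T", 0.05), ("U", 0.05)]:
            for mi, above in [(thr + 0.01, True), (thr, False),
                              (thr - 0.01, False)]:
                for p_adj, sig in [(0.049, True), (0.05, False),
                                   (0.051, False)]:
                    expected = ("high" if sig and above
                                else "moderate" if sig else "none")
                    assert classify_confidence(base, mi, p_adj) == expected

    def test_unknown_base_rejected(self):
        with pytest.raises(CallingError):
            classify_confidence("N", 0.5, 0.01)


class TestCallModifications:
    def test_low_and_no_coverage_markers(self, scenario):
        coverage = scenario["coverage"].copy()
        cols = ["count_a", "count_c", "count_g", "count_t", "count_del"]
        coverage.loc[0, cols] = [2, 0, 3, 0, 0]   # below min_coverage
        coverage.loc[1, cols] = [0, 0, 0, 0, 0]   # no reads at all
        keys = coverage.loc[[0, 1], ["species", "trna", "position"]]
        calls = calling.call_modifications(coverage, scenario["truth"])
        calls = keys.merge(calls, on=["species", "trna", "position"])
        assert calls.loc[0, "confidence"] == "low-coverage"
        assert calls.loc[1, "confidence"] == "no-coverage"
        assert math.isnan(calls.loc[1, "mi_frequency"])

    def test_high_calls_satisfy_their_definition(self, scenario_calls):
        high = scenario_calls[scenario_calls["confidence"] == "high"]
        assert len(high) > 0
        thr = high["ref_base"].map(calling.DEFAULT_MI_THRESHOLDS)
        assert (high["p_adjusted"] < 0.05).all()
        assert (high["mi_frequency"] > thr).all()

    def test_identity_composition_sums_to_one(self, scenario_calls):
        covered = scenario_calls[scenario_calls["coverage"] > 0]
        total = covered[["frac_a", "frac_c", "frac_g", "frac_t",
                         "frac_del"]].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_posterior_exceedance_mode_runs(self, scenario):
        cfg = CallingConfig(pvalue_mode="posterior-exceedance")
        sub = scenario["coverage"]
        sub = sub[sub["species"] == "hyper_A"]
        calls = calling.call_modifications(sub, scenario["truth"], cfg)
        tested = calls[calls["p_value"].notna()]
        assert len(tested) and tested["p_value"].between(0, 1).all()
        # strong sites must still be recovered in this mode
        assert (calls["confidence"] == "high").sum() > 50
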