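"""Differential expression, correlation screens, co-mutation and Cox screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import minimize_scalar

from epicrosstalk.core import ExpressionMatrix
from epicrosstalk.regulators import default_regulators
from epicrosstalk.stats import (
    comutation_test,
    correlate_with_regulators,
    cox_screen,
    cox_univariate,
    differential_expression,
    regulator_coexpression,
)

from .oracles import fisher_two_sided_enumeration


def _matrix(values: np.ndarray, gene_ids=None, sample_ids=None) -> pd.DataFrame:
    g = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    s = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=g, columns=s)


class TestDifferentialExpression:
    def test_identical_values_give_zero_fc_and_no_pass(self):
        v = _matrix(np.tile(np.arange(10, dtype=float), (4, 1)))
        recs = differential_expression(v, [f"s{j}" for j in range(5)], [f"s{j}" for j in range(5, 10)])
        for r in recs:
            assert r.log2fc == pytest.approx(
                v.iloc[0, :5].mean() - v.iloc[0, 5:].mean()
            )
        # constant within each group and equal means -> p = 1 convention
        const = _matrix(np.full((2, 10), 5.0))
        recs = differential_expression(const, [f"s{j}" for j in range(5)], [f"s{j}" for j in range(5, 10)])
        assert all(r.p_value == 1.0 and not r.passes for r in recs)

    def test_planted_shift_passes(self, rng):
        v = rng.normal(8, 0.3, size=(5, 40))
        v[0, :20] += 2.0
        recs = differential_expression(_matrix(v), [f"s{j}" for j in range(20)], [f"s{j}" for j in range(20, 40)])
        assert recs[0].passes and recs[0].log2fc == pytest.approx(2.0, abs=0.5)
        assert not any(r.passes for r in recs[1:])

    def test_antisymmetry_under_group_swap(self, rng):
        v = _matrix(rng.normal(size=(20, 16)))
        a = [f"s{j}" for j in range(8)]
        b = [f"s{j}" for j in range(8, 16)]
        fwd = differential_expression(v, a, b)
        rev = differential_expression(v, b, a)
        for f, r in zip(fwd, rev):
            assert f.log2fc == pytest.approx(-r.log2fc, abs=1e-12)
            assert f.p_value == pytest.approx(r.p_value, rel=1e-12)

    def test_group_overlap_rejected(self, rng):
        v = _matrix(rng.normal(size=(3, 10)))
        with pytest.raises(ValueError, match="disjoint"):
            differential_expression(v, ["s0", "s1", "s2"], ["s2", "s3", "s4"])

    def test_bh_adjustment_monotone_in_p_rank(self, rng):
        v = _matrix(rng.normal(size=(200, 12)))
        recs = differential_expression(v, [f"s{j}" for j in range(6)], [f"s{j}" for j in range(6, 12)])
        df = pd.DataFrame([(r.p_value, r.p_adj) for r in recs], columns=["p", "q"])
        df = df.sort_values("p")
        assert (df["q"].diff().dropna() >= -1e-15).all()
        assert (df["q"] <= 1).all() and (df["q"] >= df["p"] - 1e-15).all()


class TestCorrelationScreens:
    def test_self_correlation_is_one(self, rng):
        regs = default_regulators()
        v = rng.normal(size=(2, 50))
        m = _matrix(np.vstack([v[0], v[0], v[1]]), gene_ids=["target", "METTL3", "FTO"])
        recs = correlate_with_regulators(m, ["target"], regs)
        rec = next(r for r in recs if r.regulator_id == "METTL3")
        assert rec.rho == pytest.approx(1.0)
        assert rec.passes

    def test_planted_correlation_flagged(self, default_cohort):
        m = default_cohort.expression
        design = default_cohort.design
        targets = [t for t, _r, _s in design.corr_pairs]
        recs = correlate_with_regulators(m, targets)
        by_pair = {(r.gene_id, r.regulator_id): r for r in recs}
        for target, reg, sign in design.corr_pairs:
            rec = by_pair[(target, reg)]
            assert rec.passes and sign * rec.rho > 0.3

    def test_independent_targets_rarely_flagged(self, rng):
        regs = default_regulators()
        hits = 0
        for rep in range(20):
            r2 = np.random.default_rng(rep)
            rows = [r2.normal(size=200) for _ in range(23)]
            m = _matrix(np.vstack(rows), gene_ids=["target"] + regs.m6a)
            recs = correlate_with_regulators(m, ["target"], regs)
            hits += any(r.passes for r in recs)
        assert hits / 20 < 0.1

    def test_constant_gene_dropped_with_warning(self, rng):
        regs = default_regulators()
        m = _matrix(
            np.vstack([np.full(30, 3.0), rng.normal(size=30)]),
            gene_ids=["flat", "METTL3"],
        )
        with pytest.warns(UserWarning, match="constant"):
            recs = correlate_with_regulators(m, ["flat"], regs)
        assert recs == []

    def test_coexpression_excludes_self_and_flags_duplicates(self, rng):
        regs = default_regulators()
        base = rng.normal(size=(43, 60))
        ids = regs.all
        m = _matrix(base, gene_ids=ids)
        # duplicate HDAC1 into HDAC2 -> rho = 1
        m.loc["HDAC2"] = m.loc["HDAC1"]
        recs = regulator_coexpression(m, regs)
        assert not any(r.gene_id == r.regulator_id for r in recs)
        dup = next(r for r in recs if {r.gene_id, r.regulator_id} == {"HDAC1", "HDAC2"})
        assert dup.rho == pytest.approx(1.0) and dup.passes

    def test_planted_coexpression_block_all_flagged(self, rng):
        regs = default_regulators()
        n = 200
        z = rng.normal(size=n)
        rows = {}
        for g in regs.all:
            rows[g] = rng.normal(size=n)
        for g in ("METTL3", "METTL14", "WTAP"):  # r ~ 0.7 block
            rows[g] = 0.84 * z + np.sqrt(1 - 0.84**2) * rng.normal(size=n)
        m = _matrix(np.vstack([rows[g] for g in regs.all]), gene_ids=regs.all)
        recs = regulator_coexpression(m, regs)
        block = {
            frozenset((a, b))
            for a in ("METTL3", "METTL14", "WTAP")
            for b in ("METTL3", "METTL14", "WTAP")
            if a < b
        }
        flagged = {
            frozenset((r.gene_id, r.regulator_id)) for r in recs if r.passes
        }
        assert block <= flagged


class TestComutation:
    def test_hand_computed_extreme_table(self):
        muts = {f"s{i}": frozenset(["A", "B"]) for i in range(10)}
        muts.update({f"t{i}": frozenset() for i in range(10)})
        (rec,) = comutation_test(muts, ["A", "B"])
        assert rec.direction == "co_occurrence"
        assert rec.p_value == pytest.approx(2 / 184756, rel=1e-9)  # 2 / C(20,10)
        assert rec.passes

    def test_perfect_anticorrelation_is_mutual_exclusivity(self):
        muts = {f"s{i}": frozenset(["A"]) for i in range(8)}
        muts.update({f"t{i}": frozenset(["B"]) for i in range(8)})
        (rec,) = comutation_test(muts, ["A", "B"])
        assert rec.direction == "mutual_exclusivity"
        assert not rec.passes

    def test_degenerate_gene_gives_p_one(self):
        muts = {f"s{i}": frozenset(["A", "B"]) if i < 5 else frozenset(["B"]) for i in range(10)}
        (rec,) = comutation_test(muts, ["A", "B"])  # B mutated in all samples
        assert rec.degenerate and rec.p_value == 1.0

    def test_matches_enumeration_oracle_small_n(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 31))
            xa = rng.random(n) < rng.uniform(0.2, 0.8)
            xb = rng.random(n) < rng.uniform(0.2, 0.8)
            muts = {
                f"s{i}": frozenset(
                    (["A"] if xa[i] else []) + (["B"] if xb[i] else [])
                )
                for i in range(n)
            }
            (rec,) = comutation_test(muts, ["A", "B"])
            if rec.degenerate:
                continue
            expected = fisher_two_sided_enumeration(rec.n11, rec.n10, rec.n01, rec.n00)
            assert rec.p_value == pytest.approx(expected, abs=1e-12)

    def test_counts_partition_samples(self, rng):
        n = 40
        muts = {f"s{i}": frozenset(np.array(["A", "B", "C"])[rng.random(3) < 0.4]) for i in range(n)}
        for rec in comutation_test(muts, ["A", "B", "C"]):
            assert rec.n11 + rec.n10 + rec.n01 + rec.n00 == n


class TestCox:
    def _sim(self, n, beta, rng):
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-beta * x))
        c = rng.exponential(2.0, size=n)
        return x, np.minimum(t, c), (t <= c).astype(int)

    def test_matches_partial_likelihood_grid_oracle(self, rng):
        x, t, e = self._sim(60, 0.8, rng)

        def neg_breslow_ll(beta):
            ll = 0.0
            for i in np.flatnonzero(e):
                risk = t >= t[i]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return -ll

        res = minimize_scalar(neg_breslow_ll, bounds=(-5, 5), method="bounded")
        coef, _se, _p, conv = cox_univariate(x, t, e)
        assert conv
        assert coef == pytest.approx(res.x, abs=1e-4)

    def test_matches_lifelines_on_tie_free_data(self, rng):
        from lifelines import CoxPHFitter

        x, t, e = self._sim(120, 0.5, rng)
        df = pd.DataFrame({"x": x, "t": t, "e": e})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        coef, se, p, conv = cox_univariate(x, t, e)
        assert conv
        assert coef == pytest.approx(cph.params_["x"], abs=1e-4)
        assert se == pytest.approx(cph.standard_errors_["x"], rel=1e-3)

    def test_screen_passes_planted_gene_and_excludes_constant(self, rng):
        n = 200
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-x))
        e = np.ones(n, dtype=int)
        values = pd.DataFrame(
            {f"s{i}": [x[i], 5.0, rng.normal()] for i in range(n)},
            index=["risky", "flat", "noise"],
        )
        meta = pd.DataFrame(
            {"os_time": t, "os_event": e}, index=[f"s{i}" for i in range(n)]
        )
        m = ExpressionMatrix(values, meta)
        with pytest.warns(UserWarning, match="constant"):
            res = cox_screen(m, ["risky", "flat", "noise"])
        assert "flat" not in res.index
        assert bool(res.loc["risky", "passes"])
        assert res.loc["risky", "coefficient"] == pytest.approx(1.0, abs=0.3)
        assert not bool(res.loc["noise", "passes"])

    def test_no_events_is_not_converged(self):
        coef, se, p, conv = cox_univariate(
            np.arange(5.0), np.arange(1.0, 6.0), np.zeros(5)
        )
        assert not conv and p == 1.0
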