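"""Birth-death shift likelihood, rjMCMC behaviour and posterior summaries."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import poisson

from paleodiv import synthgen
from paleodiv.phylo_core import mrca, parse_tree, set_ages_from_lengths
from paleodiv.shiftbd import (
    Priors,
    PosteriorSample,
    Regime,
    Shift,
    ShiftConfig,
    TreeIndex,
    bd_loglik,
    posterior_rtt,
    rjmcmc_run,
    rtt_curve,
    shift_summary,
)


def ode_loglik(index: TreeIndex, config: ShiftConfig) -> float:
    """Independent oracle: numerically integrate the E/D equations.

    Same propagation scheme (tip conditions, node joins, survival
    conditioning) but each branch segment is integrated with an adaptive
    ODE solver instead of the closed form.
    """
    by_branch = {}
    for s in config.shifts:
        by_branch.setdefault(s.node, []).append(s)
    for lst in by_branch.values():
        lst.sort(key=lambda s: s.age)

    r_bottom = [None] * index.n
    stack = [index.root]
    while stack:
        v = stack.pop()
        if v == index.root:
            r_bottom[v] = config.root_regime
        else:
            br = by_branch.get(v)
            r_bottom[v] = br[0].regime if br else r_bottom[index.parent[v]]
        stack.extend(index.children[v])

    def integrate(e0, logd0, lam, mu, t0, t1):
        if t1 - t0 <= 0:
            return e0, logd0

        def rhs(_, y):
            e, d = y
            return [
                mu - (lam + mu) * e + lam * e * e,
                -(lam + mu) * d + 2 * lam * e * d,
            ]

        sol = solve_ivp(rhs, (t0, t1), [e0, 1.0], rtol=1e-10, atol=1e-12)
        e1, dratio = sol.y[0][-1], sol.y[1][-1]
        return e1, logd0 + math.log(dratio)

    e_arr = [0.0] * index.n
    d_arr = [0.0] * index.n
    for v in range(index.n):
        if index.is_tip[v]:
            e, logd = 1.0 - index.f[v], math.log(index.f[v])
        else:
            c0, c1 = index.children[v]
            e = e_arr[c0]
            logd = d_arr[c0] + d_arr[c1] + math.log(r_bottom[v].lam)
        if v == index.root:
            return logd - 2.0 * math.log(1.0 - e)
        p = index.parent[v]
        t = index.age[v]
        br = by_branch.get(v, [])
        lam, mu = r_bottom[v].lam, r_bottom[v].mu
        for k, s in enumerate(br):
            e, logd = integrate(e, logd, lam, mu, t, s.age)
            t = s.age
            nxt = br[k + 1].regime if k + 1 < len(br) else r_bottom[p]
            lam, mu = nxt.lam, nxt.mu
        e, logd = integrate(e, logd, lam, mu, t, index.age[p])
        e_arr[v], d_arr[v] = e, logd


class TestLikelihood:
    def test_two_tip_yule_closed_form(self):
        tree = parse_tree("(A:7.5,B:7.5);")
        set_ages_from_lengths(tree)
        idx = TreeIndex(tree, 1.0)
        lam = 0.23
        got = bd_loglik(idx, ShiftConfig(Regime(lam, 0.0)))
        assert got == pytest.approx(math.log(lam) - 2 * lam * 7.5, abs=1e-10)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_yule_formula_any_tree(self, seed):
        tree, _ = synthgen.simulate_bd_tree(lam=0.15, ntips=30, seed=seed)
        idx = TreeIndex(tree, 1.0)
        lam = 0.11
        got = bd_loglik(idx, ShiftConfig(Regime(lam, 0.0)))
        want = (idx.n_tips - 1) * math.log(lam) - lam * idx.total_length
        assert got == pytest.approx(want, abs=1e-9)

    def test_sampling_continuity_at_one(self):
        tree, _ = synthgen.simulate_bd_tree(lam=0.1, ntips=20, seed=5)
        cfg = ShiftConfig(Regime(0.12, 0.03))
        a = bd_loglik(TreeIndex(tree, 1.0), cfg)
        b = bd_loglik(TreeIndex(tree, 1.0 - 1e-9), cfg)
        assert abs(a - b) < 1e-6

    def test_polytomy_rejected(self):
        tree = parse_tree("(A:1,B:1,C:1);")
        set_ages_from_lengths(tree)
        with pytest.raises(Exception, match="binary"):
            TreeIndex(tree, 1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_ode_integration_constant_rate(self, seed):
        """Closed-form propagation vs adaptive ODE oracle, random trees."""
        rng = np.random.default_rng(seed)
        ntips = int(rng.integers(5, 50))
        lam0 = float(rng.uniform(0.05, 0.3))
        tree, _ = synthgen.simulate_bd_tree(lam=lam0, ntips=ntips, seed=seed)
        f = float(rng.uniform(0.3, 1.0))
        idx = TreeIndex(tree, f)
        lam = float(rng.uniform(0.05, 0.5))
        mu = float(rng.uniform(0.0, lam * 0.9))
        cfg = ShiftConfig(Regime(lam, mu))
        assert bd_loglik(idx, cfg) == pytest.approx(
            ode_loglik(idx, cfg), abs=1e-6
        )

    def test_matches_ode_integration_with_shifts(self):
        tree, _ = synthgen.simulate_bd_tree(lam=0.1, ntips=25, seed=40)
        idx = TreeIndex(tree, 0.8)
        # put shifts on two branches, at mid-age
        cand = [
            v for v in range(idx.n)
            if v != idx.root and idx.dur[v] > 1.0
        ][:2]
        shifts = tuple(
            Shift(v, (idx.age[v] + idx.age[idx.parent[v]]) / 2,
                  Regime(0.3, 0.05))
            for v in cand
        )
        cfg = ShiftConfig(Regime(0.1, 0.02), shifts)
        assert bd_loglik(idx, cfg) == pytest.approx(
            ode_loglik(idx, cfg), abs=1e-6
        )

    def test_equal_rates_limit(self):
        """lambda == mu uses the r -> 0 branch of the closed form."""
        tree, _ = synthgen.simulate_bd_tree(lam=0.1, ntips=15, seed=60)
        idx = TreeIndex(tree, 0.9)
        cfg = ShiftConfig(Regime(0.1, 0.1))
        assert bd_loglik(idx, cfg) == pytest.approx(
            ode_loglik(idx, cfg), abs=1e-6
        )

    def test_invalid_shift_age_rejected(self):
        tree, _ = synthgen.simulate_bd_tree(lam=0.1, ntips=10, seed=2)
        idx = TreeIndex(tree, 1.0)
        v = next(v for v in range(idx.n) if v != idx.root)
        bad = ShiftConfig(
            Regime(0.1, 0.0),
            (Shift(v, idx.age[idx.parent[v]] + 1.0, Regime(0.2, 0.0)),),
        )
        with pytest.raises(ValueError, match="outside"):
            bd_loglik(idx, bad)


class TestRjmcmc:
    def test_store_and_burnin_counts(self):
        tree, _ = synthgen.simulate_bd_tree(lam=0.1, ntips=10, seed=3)
        samples = rjmcmc_run(tree, generations=2000, store=200,
                             burnin_fraction=0.1, seed=1)
        assert len(samples) == 180  # 200 stored minus 10% burn-in

    def test_reproducible_given_seed(self):
        tree, _ = synthgen.simulate_bd_tree(lam=0.1, ntips=10, seed=3)
        a = rjmcmc_run(tree, generations=1000, store=100, seed=7)
        b = rjmcmc_run(tree, generations=1000, store=100, seed=7)
        assert [s.loglik for s in a] == [s.loglik for s in b]

    def test_prior_recovery_poisson_shift_count(self):
        """With the likelihood disabled the shift count is Poisson."""
        tree, _ = synthgen.simulate_bd_tree(lam=0.1, ntips=20, seed=9)
        gamma = 1.0
        samples = rjmcmc_run(
            tree, generations=60000, store=10000, burnin_fraction=0.1,
            seed=5, prior_only=True, priors=Priors(expected_shifts=gamma),
        )
        ks = np.array([s.config.n_shifts for s in samples])
        kmax = 6
        obs = np.bincount(np.minimum(ks, kmax), minlength=kmax + 1)
        probs = poisson.pmf(np.arange(kmax), gamma)
        probs = np.append(probs, 1 - probs.sum())
        exp = probs * len(ks)
        # merge sparse cells to keep the chi-square valid
        keep = exp >= 5
        chi2 = float(((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum())
        from scipy.stats import chi2 as chi2_dist

        p = 1 - chi2_dist.cdf(chi2, df=keep.sum() - 1)
        assert p > 0.01

    def test_yule_parameter_recovery_single_tree(self):
        tree, _ = synthgen.simulate_bd_tree(lam=0.1, ntips=100, seed=11)
        samples = rjmcmc_run(tree, generations=6000, store=600, seed=7)
        lams = np.array([s.config.root_regime.lam for s in samples])
        assert abs(lams.mean() - 0.1) < 0.02  # within 20% of truth
        ks = np.array([s.config.n_shifts for s in samples])
        assert np.bincount(ks).argmax() == 0


class TestShiftSummary:
    def _fake_samples(self, node, hit_fraction, n=200, root=Regime(0.1, 0.0)):
        out = []
        for i in range(n):
            shifts = ()
            if i < hit_fraction * n:
                shifts = (Shift(node, 1.0, Regime(0.5, 0.0)),)
            out.append(PosteriorSample(ShiftConfig(root, shifts), 0.0, 0.0, i))
        return out

    def test_empty_sample_list_rejected(self, yule50):
        with pytest.raises(ValueError):
            shift_summary([], yule50)

    def test_zero_shift_posterior_empty_report(self, yule50):
        idx = TreeIndex(yule50, 1.0)
        samples = self._fake_samples(node=0, hit_fraction=0.0)
        rep = shift_summary(samples, idx)
        assert rep.significant == []

    def test_bayes_factor_matches_hand_calculation(self, yule50):
        idx = TreeIndex(yule50, 1.0)
        # pick a branch subtending >= 5 tips, long enough to see
        node = max(
            (v for v in range(idx.n)
             if v != idx.root and idx.ntips_below[v] >= 5),
            key=lambda v: idx.dur[v],
        )
        gamma = 1.0
        # shift ages must lie inside the branch
        mid = (idx.age[node] + idx.age[idx.parent[node]]) / 2
        samples = []
        for i in range(200):
            shifts = ()
            if i < 160:  # 80% marginal
                shifts = (Shift(int(node), float(mid), Regime(0.5, 0.0)),)
            samples.append(
                PosteriorSample(ShiftConfig(Regime(0.1, 0.0), shifts), 0, 0, i)
            )
        rep = shift_summary(samples, idx, expected_shifts=gamma)
        row = next(r for r in rep.rows if r["node"] == node)
        prior = 1 - math.exp(-gamma * idx.dur[node] / idx.total_length)
        expected_bf = (0.8 / 0.2) / (prior / (1 - prior))
        assert row["marginal"] == pytest.approx(0.8)
        assert row["bayes_factor"] == pytest.approx(expected_bf, rel=1e-9)
        assert rep.rows[0]["node"] == node

    def test_min_clade_size_filter(self, yule50):
        idx = TreeIndex(yule50, 1.0)
        rep = shift_summary(
            self._fake_samples(node=0, hit_fraction=0.0), idx,
            min_clade_size=5,
        )
        assert all(r["n_tips"] >= 5 for r in rep.rows)


class TestRttCurve:
    def test_single_regime_constant_curve(self, yule50):
        idx = TreeIndex(yule50, 1.0)
        cfg = ShiftConfig(Regime(0.17, 0.0))
        curve = rtt_curve(idx, cfg)
        assert np.allclose(curve.rate, 0.17)
        assert curve.age[1] - curve.age[0] == pytest.approx(0.1)

    def test_step_at_shift_age_hand_check(self):
        tree = parse_tree("((A:10,B:10):10,(C:10,D:10):10);")
        set_ages_from_lengths(tree)
        idx = TreeIndex(tree, 1.0)
        node_a = next(i for i in range(idx.n) if idx.label[i] == "A")
        cfg = ShiftConfig(
            Regime(0.1, 0.0), (Shift(node_a, 5.0, Regime(1.0, 0.0)),)
        )
        curve = rtt_curve(idx, cfg)
        # below 5 Ma: four branches, one at 1.0 -> mean 0.325
        i2 = int(round(2.0 / 0.1))
        i7 = int(round(7.0 / 0.1))
        i15 = int(round(15.0 / 0.1))
        assert curve.rate[i2] == pytest.approx((1.0 + 3 * 0.1) / 4)
        assert curve.rate[i7] == pytest.approx(0.1)
        assert curve.rate[i15] == pytest.approx(0.1)

    def test_grid_spans_clade_origin_to_present(self, yule50):
        idx = TreeIndex(yule50, 1.0)
        cfg = ShiftConfig(Regime(0.1, 0.0))
        curve = rtt_curve(idx, cfg)
        assert curve.age[0] == 0.0
        assert curve.age[-1] < idx.age[idx.root]
        assert idx.age[idx.root] - curve.age[-1] <= 0.1 + 1e-9

    def test_clade_restriction(self, yule50):
        labels = sorted(l.taxon.label for l in yule50.leaf_nodes())[:4]
        node = mrca(yule50, set(labels))
        tips = {l.taxon.label for l in node.leaf_iter()}
        curves = posterior_rtt(
            yule50,
            [PosteriorSample(ShiftConfig(Regime(0.2, 0.0)), 0, 0, 0)],
            frozenset(tips),
        )
        assert curves[0].age[-1] < node.age

    def test_posterior_mean_linearity(self, yule50):
        """Mean of per-sample curves equals curve of pointwise means."""
        idx = TreeIndex(yule50, 1.0)
        rng = np.random.default_rng(4)
        samples = [
            PosteriorSample(
                ShiftConfig(Regime(float(rng.uniform(0.05, 0.3)), 0.0)), 0, 0, i
            )
            for i in range(20)
        ]
        curves = posterior_rtt(idx, samples)
        mat = np.array([c.rate for c in curves])
        mean_lam = np.mean([s.config.root_regime.lam for s in samples])
        assert np.allclose(mat.mean(axis=0), mean_lam)
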