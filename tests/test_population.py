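import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import replitrack as rt
from replitrack.population import MIN_PAIRS_FOR_MIXTURE, _em_once


def foci_frame(rel_positions, length_um=4.0, cell_id=1, frame=0):
    return pd.DataFrame(dict(
        frame=frame, cell_id=cell_id, rel_pos=rel_positions,
        length_um=length_um))


class TestPairSeparations:
    def test_two_foci_separation_arithmetic(self):
        pairs = rt.pair_separations(foci_frame([0.30, 0.50]))
        assert len(pairs) == 1
        assert pairs.rel_sep.iloc[0] == pytest.approx(0.20)
        assert pairs.sep_um.iloc[0] == pytest.approx(0.80)

    def test_single_focus_gives_no_pairs(self):
        assert len(rt.pair_separations(foci_frame([0.5]))) == 0

    def test_three_foci_give_three_pairs(self):
        assert len(rt.pair_separations(foci_frame([0.2, 0.5, 0.8]))) == 3

    def test_empty_input(self):
        assert len(rt.pair_separations(pd.DataFrame(
            columns=["frame", "cell_id", "rel_pos", "length_um"]))) == 0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=0, max_size=6))
    def test_pair_count_and_bounds(self, positions):
        pairs = rt.pair_separations(foci_frame(positions))
        n = len(positions)
        assert len(pairs) == n * (n - 1) // 2
        if len(pairs):
            assert ((pairs.rel_sep >= 0) & (pairs.rel_sep <= 1)).all()


ORACLE_MIX = dict(w=(0.8, 0.2), mu=(0.20, 0.45), sd=(0.05, 0.07))


def sample_oracle(n, seed=0):
    rng = np.random.default_rng(seed)
    comp = rng.random(n) < ORACLE_MIX["w"][0]
    x = np.where(comp,
                 rng.normal(ORACLE_MIX["mu"][0], ORACLE_MIX["sd"][0], n),
                 rng.normal(ORACLE_MIX["mu"][1], ORACLE_MIX["sd"][1], n))
    return np.abs(x)


class TestFitMixture:
    def test_recovers_known_mixture(self):
        x = sample_oracle(10000, seed=1)
        mix = rt.fit_mixture(x, seed=1)
        assert mix.mu_low == pytest.approx(0.20, abs=0.01)
        assert mix.mu_high == pytest.approx(0.45, abs=0.01)
        assert mix.w_low == pytest.approx(0.8, abs=0.03)
        assert mix.w_low + mix.w_high == pytest.approx(1.0)

    def test_two_point_masses(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([0.2 + rng.normal(0, 1e-3, 60),
                            0.45 + rng.normal(0, 1e-3, 40)])
        mix = rt.fit_mixture(x, seed=2)
        assert mix.mu_low == pytest.approx(0.20, abs=0.002)
        assert mix.mu_high == pytest.approx(0.45, abs=0.002)
        assert mix.w_low == pytest.approx(0.6, abs=0.02)

    def test_insufficient_data_raises(self):
        with pytest.raises(ValueError, match="50"):
            rt.fit_mixture(np.full(MIN_PAIRS_FOR_MIXTURE - 1, 0.2))

    def test_em_never_decreases_loglikelihood(self):
        x = sample_oracle(500, seed=3)
        mu = np.array([0.1, 0.5])
        sd = np.array([0.1, 0.1])
        w = np.array([0.5, 0.5])
        lls = []
        for _ in range(40):
            mu, sd, w, ll, _, ok = _em_once(x, mu, sd, w, max_iter=1)
            lls.append(ll)
        diffs = np.diff(lls)
        assert (diffs >= -1e-9).all()

    def test_agrees_with_sklearn_reference(self):
        sklearn = pytest.importorskip("sklearn.mixture")
        x = sample_oracle(4000, seed=4)
        mix = rt.fit_mixture(x, seed=4)
        gm = sklearn.GaussianMixture(2, tol=1e-8, n_init=3, random_state=0)
        gm.fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        ref_mu = gm.means_.ravel()[order]
        assert mix.mu_low == pytest.approx(ref_mu[0], abs=0.005)
        assert mix.mu_high == pytest.approx(ref_mu[1], abs=0.005)
        # average log-likelihood per sample matches the reference fit
        assert mix.loglik / len(x) == pytest.approx(
            gm.score(x[:, None]), abs=1e-3)


def oracle_mixture():
    return rt.SeparationMixture(
        mu_low=0.20, sd_low=0.05, w_low=0.8,
        mu_high=0.45, sd_high=0.07, w_high=0.2,
        loglik=0.0, n_iter=0, n_samples=0)


class TestClassifyPairs:
    def test_posterior_matches_closed_form(self):
        mix = oracle_mixture()
        x = 0.18
        from scipy.stats import norm
        lo = 0.8 * norm.pdf(x, 0.20, 0.05)
        hi = 0.2 * norm.pdf(x, 0.45, 0.07)
        assert mix.posterior_low(x) == pytest.approx(lo / (lo + hi))

    def test_low_separation_labeled_resolved(self):
        pairs = rt.pair_separations(foci_frame([0.40, 0.58]))  # sep 0.18
        cl = rt.classify_pairs(pairs, oracle_mixture())
        assert cl.label.iloc[0] == "resolved_sisters"
        assert cl.accepted.iloc[0]

    def test_high_separation_labeled_high(self):
        pairs = rt.pair_separations(foci_frame([0.25, 0.70]))  # sep 0.45
        cl = rt.classify_pairs(pairs, oracle_mixture())
        assert cl.label.iloc[0] == "high_separation"
        assert not cl.accepted.iloc[0]

    def test_three_foci_greedy_accepts_single_best_pair(self):
        # separations {0.15, 0.44, 0.59}: only the 0.15 pair is low
        pairs = rt.pair_separations(foci_frame([0.11, 0.26, 0.70]))
        cl = rt.classify_pairs(pairs, oracle_mixture())
        assert cl.accepted.sum() == 1
        assert cl.loc[cl.accepted, "rel_sep"].iloc[0] == pytest.approx(0.15)

    def test_accepted_pairs_are_disjoint(self, small_run):
        for (_, _), grp in small_run.classified[
                small_run.classified.accepted].groupby(["frame", "cell_id"]):
            ids = grp[["i", "j"]].to_numpy().ravel()
            assert len(ids) == len(set(ids))

    def test_matches_exhaustive_matching_oracle(self, small_run):
        """Greedy acceptance equals brute-force maximum disjoint matching
        (most pairs, then highest posterior sum) on all <=4-focus cells."""
        cl = small_run.classified
        nfoci = small_run.foci.groupby(["frame", "cell_id"]).size()
        checked = 0
        for (frame, cell), grp in cl.groupby(["frame", "cell_id"]):
            if nfoci.get((frame, cell), 0) > 4:
                continue
            cands = grp[grp.posterior_low > 0.5]
            best = set()
            best_key = (0, 0.0)
            items = list(cands.itertuples())
            for r in range(len(items), -1, -1):
                for combo in itertools.combinations(items, r):
                    ids = [f for p in combo for f in (p.i, p.j)]
                    if len(ids) != len(set(ids)):
                        continue
                    key = (len(combo), sum(p.posterior_low for p in combo))
                    if key > best_key:
                        best_key = key
                        best = {p.Index for p in combo}
            got = set(grp[grp.accepted].index)
            assert got == best, (frame, cell)
            checked += 1
        assert checked > 100


class TestCountFactories:
    def _counts(self, rel_positions, mixture=None):
        foci = foci_frame(rel_positions)
        pairs = rt.pair_separations(foci)
        cl = rt.classify_pairs(pairs, mixture or oracle_mixture())
        return rt.count_factories(foci, cl)

    def test_single_focus_is_one_colocalized_pair(self):
        counts = self._counts([0.5])
        assert counts.n_coloc.iloc[0] == 1
        assert counts.n_resolved.iloc[0] == 0

    def test_resolved_pair_counts_once(self):
        counts = self._counts([0.40, 0.58])
        assert counts.n_coloc.iloc[0] == 0
        assert counts.n_resolved.iloc[0] == 1

    def test_four_foci_one_resolved_pair_two_coloc(self):
        # one tight pair + two isolated foci far apart
        counts = self._counts([0.10, 0.28, 0.60, 0.95])
        assert counts.n_foci.iloc[0] == 4
        assert counts.n_resolved.iloc[0] == 1
        assert counts.n_coloc.iloc[0] == 2

    def test_inconsistent_pair_reference_raises(self):
        foci = foci_frame([0.40, 0.58])
        pairs = rt.pair_separations(foci)
        cl = rt.classify_pairs(pairs, oracle_mixture())
        cl.loc[:, "i"] = 999
        with pytest.raises(ValueError, match="missing"):
            rt.count_factories(foci, cl)

    def test_conservation_on_every_frame(self, small_run):
        c = small_run.counts
        assert (c.n_foci == c.n_coloc + 2 * c.n_resolved).all()
        assert (c.n_coloc >= 0).all()

    def test_zero_focus_cell_frames_included_but_pairless(self, small_run):
        zero = small_run.counts[small_run.counts.n_foci == 0]
        assert len(zero) > 0
        assert (zero.n_coloc == 0).all() and (zero.n_resolved == 0).all()


class TestColocalizationFraction:
    def test_all_single_focus_cells_give_one(self):
        counts = pd.DataFrame(dict(n_foci=[1, 1], n_resolved=[0, 0],
                                   n_coloc=[1, 1]))
        assert rt.colocalization_fraction(counts) == 1.0

    def test_no_pairs_raises(self):
        counts = pd.DataFrame(dict(n_foci=[0], n_resolved=[0], n_coloc=[0]))
        with pytest.raises(ValueError):
            rt.colocalization_fraction(counts)


class TestConditionalPositionDensity:
    def test_columns_are_stochastic(self, small_run):
        M, pos_e, len_e = rt.conditional_position_density(
            small_run.foci.rel_pos, small_run.foci.length_um)
        sums = M.sum(axis=0)
        nonzero = sums > 0
        assert nonzero.any()
        assert np.allclose(sums[nonzero], 1.0)

    def test_point_mass_at_midcell(self):
        M, pos_e, len_e = rt.conditional_position_density(
            np.full(50, 0.5), np.full(50, 4.0))
        nz_rows = np.nonzero(M.sum(axis=1))[0]
        assert len(nz_rows) == 1
        assert pos_e[nz_rows[0]] <= 0.5 <= pos_e[nz_rows[0] + 1]


class TestPatternFrequencies:
    def test_single_cell_single_focus(self):
        counts = pd.DataFrame(dict(frame=[0], cell_id=[1], n_foci=[1],
                                   n_resolved=[0], n_coloc=[1],
                                   length_um=[3.0]))
        tab = rt.pattern_frequencies(counts)
        assert tab.loc["1_focus", "overall"] == 1.0

    def test_columns_sum_to_one(self, small_run):
        tab = rt.pattern_frequencies(small_run.counts)
        assert np.allclose(tab.sum(axis=0), 1.0)

    def test_two_focus_probability_rises_with_length(self, small_run):
        from scipy.stats import spearmanr
        counts = small_run.counts
        edges = np.arange(3.0, counts.length_um.max() + 0.5, 0.5)
        binned = pd.cut(counts.length_um, edges)
        g = counts.assign(two=(counts.n_foci >= 2)).groupby(
            binned, observed=True)
        p2 = g.two.mean()[g.size() >= 50].dropna()
        rho = spearmanr(np.arange(len(p2)), p2.to_numpy()).statistic
        assert rho > 0

    def test_zero_focus_cells_peak_at_intermediate_lengths(self, small_run):
        counts = small_run.counts
        edges = np.arange(3.0, counts.length_um.max() + 0.5, 0.5)
        binned = pd.cut(counts.length_um, edges)
        g = counts.assign(z=(counts.n_foci == 0)).groupby(
            binned, observed=True)
        p0 = g.z.mean()[g.size() >= 30].dropna().to_numpy()
        peak = int(np.argmax(p0))
        assert 0 < peak < len(p0) - 1
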