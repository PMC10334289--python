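"""PWF fitting and Wallenius-based category enrichment."""

import numpy as np
import pytest
from scipy import stats

from dipsig.enrichment import category_test, enrich_all, fit_pwf, uniform_pwf
from dipsig.io import CategoryMap, GeneSet
from dipsig.setstats import Universe


def build_genes(n, seed=0, min_len=500, max_len=50_000):
    rng = np.random.default_rng(seed)
    ids = [f"g{i}" for i in range(n)]
    lengths = rng.integers(min_len, max_len, size=n).astype(float)
    return ids, lengths


class TestFitPwf:
    def test_flat_selection_gives_flat_weights(self):
        ids, lengths = build_genes(5000, seed=0)
        rng = np.random.default_rng(1)
        sel = rng.random(5000) < 0.2  # independent of length
        pwf = fit_pwf(sel, lengths, ids)
        rate = sel.mean()
        # every bin within 3 binomial sigma of the global rate
        sigma = np.sqrt(rate * (1 - rate) / (5000 / 20))
        assert np.abs(pwf.bin_weights - rate).max() < 3 * sigma

    def test_length_proportional_selection_recovered_monotone(self):
        ids, lengths = build_genes(5000, seed=2)
        rng = np.random.default_rng(3)
        prob = lengths / lengths.max()
        sel = rng.random(5000) < prob
        pwf = fit_pwf(sel, lengths, ids)
        assert (np.diff(pwf.bin_weights) >= -1e-12).all()
        rho = stats.spearmanr(pwf.weights, lengths).statistic
        assert rho > 0.9

    def test_single_bin_constant_weight(self):
        ids, lengths = build_genes(100, seed=4)
        sel = np.zeros(100, dtype=bool)
        sel[:30] = True
        pwf = fit_pwf(sel, lengths, ids, n_bins=1)
        assert np.allclose(pwf.weights, 0.3)

    def test_no_contrast_rejected(self):
        ids, lengths = build_genes(10)
        with pytest.raises(ValueError):
            fit_pwf(np.ones(10, bool), lengths, ids)
        with pytest.raises(ValueError):
            fit_pwf(np.zeros(10, bool), lengths, ids)


def weighted_mc_tail(n_universe, cat_idx, n_sel, weights, x_obs, n_draws, seed):
    """MC oracle: weighted sampling without replacement via Gumbel keys."""
    rng = np.random.default_rng(seed)
    logw = np.log(weights)
    hits = 0
    chunk = 2000
    done = 0
    cat_mask = np.zeros(n_universe, dtype=bool)
    cat_mask[cat_idx] = True
    while done < n_draws:
        k = min(chunk, n_draws - done)
        gumbel = -np.log(-np.log(rng.random((k, n_universe))))
        keys = logw[None, :] + gumbel
        top = np.argpartition(-keys, n_sel - 1, axis=1)[:, :n_sel]
        hits += int((cat_mask[top].sum(axis=1) >= x_obs).sum())
        done += k
    return hits / n_draws


class TestCategoryTest:
    def test_uniform_weights_reduce_to_central_hypergeometric(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(10, 200))
            ids = [f"g{i}" for i in range(n)]
            u = Universe(frozenset(ids))
            pwf = uniform_pwf(ids, rate=float(rng.uniform(0.05, 0.95)))
            n_sel = int(rng.integers(1, n))
            n_cat = int(rng.integers(1, n))
            sel = GeneSet("s", frozenset(rng.choice(ids, n_sel, replace=False)))
            cat = frozenset(rng.choice(ids, n_cat, replace=False))
            if cat == u.genes:
                continue
            res = category_test(sel, cat, u, pwf)
            x = len(sel.genes & cat)
            p_central = stats.hypergeom.sf(x - 1, n, n_cat, n_sel)
            assert abs(res.p_value - p_central) < 1e-10

    def test_category_equals_universe_p_one(self):
        ids = [f"g{i}" for i in range(20)]
        u = Universe(frozenset(ids))
        res = category_test(GeneSet("s", frozenset(ids[:5])), frozenset(ids), u, uniform_pwf(ids))
        assert res.p_value == 1.0

    def test_length_bias_makes_confounded_category_less_significant(self):
        # long genes selected preferentially; category made of long genes
        n = 400
        ids = [f"g{i}" for i in range(n)]
        lengths = np.linspace(1000, 50_000, n)
        rng = np.random.default_rng(6)
        prob = 0.5 * lengths / lengths.max()
        sel_mask = rng.random(n) < prob
        pwf = fit_pwf(sel_mask, lengths, ids)
        u = Universe(frozenset(ids))
        sel = GeneSet("s", frozenset(np.array(ids)[sel_mask]))
        cat_idx = np.arange(n - 60, n)  # the 60 longest genes
        cat = frozenset(np.array(ids)[cat_idx])
        res = category_test(sel, cat, u, pwf)
        x = len(sel.genes & cat)
        p_central = stats.hypergeom.sf(x - 1, n, 60, len(sel))
        assert res.odds > 1
        assert res.p_value > p_central

    def test_wallenius_matches_weighted_mc_oracle(self):
        n = 60
        ids = [f"g{i}" for i in range(n)]
        lengths = np.linspace(1000, 20_000, n)
        rng = np.random.default_rng(7)
        sel_mask = rng.random(n) < 0.5 * lengths / lengths.max()
        pwf = fit_pwf(sel_mask, lengths, ids)
        u = Universe(frozenset(ids))
        n_sel = 15
        sel = GeneSet("s", frozenset(rng.choice(ids, n_sel, replace=False)))
        cat_idx = np.arange(40, 60)
        cat = frozenset(np.array(ids)[cat_idx])
        res = category_test(sel, cat, u, pwf)
        # oracle draws with two-group weights implied by the odds parameter
        w = np.ones(n)
        w[cat_idx] = res.odds
        x = len(sel.genes & cat)
        p_mc = weighted_mc_tail(n, cat_idx, n_sel, w, x, n_draws=100_000, seed=8)
        sigma = np.sqrt(res.p_value * (1 - res.p_value) / 100_000)
        assert abs(res.p_value - p_mc) < 3 * sigma + 1e-3

    def test_wallenius_pmf_sums_to_one(self):
        n, n_cat, n_sel, odds = 80, 25, 30, 2.5
        support = np.arange(0, min(n_cat, n_sel) + 1)
        pmf = stats.nchypergeom_wallenius.pmf(support, n, n_cat, n_sel, odds)
        assert abs(pmf.sum() - 1.0) < 1e-8

    def test_empty_category_rejected(self):
        ids = ["g0", "g1"]
        u = Universe(frozenset(ids))
        with pytest.raises(ValueError):
            category_test(GeneSet("s", frozenset(["g0"])), frozenset(), u, uniform_pwf(ids))


class TestEnrichAll:
    def _setup(self, seed=9):
        rng = np.random.default_rng(seed)
        n = 5000
        ids = [f"g{i}" for i in range(n)]
        lengths = rng.integers(500, 20_000, n).astype(float)
        u = Universe(frozenset(ids))
        return rng, ids, lengths, u

    def test_planted_category_ranks_first(self):
        rng, ids, lengths, u = self._setup()
        planted = set(rng.choice(ids, 200, replace=False))
        # 80% of a 100-gene selection comes from the planted category
        sel_genes = set(rng.choice(sorted(planted), 80, replace=False)) | set(
            rng.choice(sorted(set(ids) - planted), 20, replace=False)
        )
        sel = GeneSet("sel", frozenset(sel_genes))
        cats = {"planted": ("planted", frozenset(planted))}
        for i in range(9):
            cats[f"null{i}"] = (f"null{i}", frozenset(rng.choice(ids, 200, replace=False)))
        cmap = CategoryMap(cats)
        flags = np.array([g in sel_genes for g in ids])
        pwf = fit_pwf(flags, lengths, ids)
        table = enrich_all(sel, cmap, u, pwf)
        assert table.iloc[0]["category_id"] == "planted"
        assert bool(table.iloc[0]["significant"])

    def test_single_category_q_equals_p(self):
        rng, ids, lengths, u = self._setup(10)
        sel = GeneSet("sel", frozenset(rng.choice(ids, 50, replace=False)))
        cmap = CategoryMap({"c": ("c", frozenset(rng.choice(ids, 100, replace=False)))})
        table = enrich_all(sel, cmap, u, uniform_pwf(ids))
        assert table["qval"].iloc[0] == table["pval"].iloc[0]

    def test_empty_gene_set_all_p_one(self):
        rng, ids, lengths, u = self._setup(11)
        sel = GeneSet("sel", frozenset())
        cmap = CategoryMap({"c": ("c", frozenset(ids[:100]))})
        table = enrich_all(sel, cmap, u, uniform_pwf(ids))
        assert (table["pval"] == 1.0).all()

    def test_null_selection_type_one_control(self):
        rng, ids, lengths, u = self._setup(12)
        fracs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            sel = GeneSet("sel", frozenset(r.choice(ids, 100, replace=False)))
            cats = {
                f"c{i}": (f"c{i}", frozenset(r.choice(ids, 150, replace=False))) for i in range(20)
            }
            table = enrich_all(sel, CategoryMap(cats), u, uniform_pwf(ids))
            fracs.append((table["pval"] < 0.05).mean())
        assert np.mean(fracs) <= 0.065
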