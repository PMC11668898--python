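"""NB Wald DE, BH adjustment, DEG intersection, and ORA exactness."""

import math

import numpy as np
import pandas as pd
import pytest

from radres.diffexpr import (
    CountsMatrix,
    intersect_common_degs,
    nb_wald_de,
    ora_enrich,
    read_counts,
    read_de_table,
    select_degs,
    size_factors,
    write_counts,
    write_de_table,
)
from radres.synth import PlantedGene, sim_counts


def bh_oracle(pvals):
    """Independent Benjamini-Hochberg implementation (step-up, literal)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


def make_cm(counts, n_rr=3, n_wt=3, cell_line="CL1"):
    genes = [f"g{i}" for i in range(counts.shape[0])]
    samples = [f"rr{i}" for i in range(n_rr)] + [f"wt{i}" for i in range(n_wt)]
    meta = pd.DataFrame(
        {"cell_line": cell_line, "phenotype": ["RR"] * n_rr + ["WT"] * n_wt},
        index=pd.Index(samples, name="sample_id"),
    )
    return CountsMatrix(pd.DataFrame(counts, index=genes, columns=samples), meta)


class TestNbWaldDe:
    def test_flat_gene_has_no_effect_and_high_p(self, rng):
        # every gene constant across samples: size factors are exactly 1,
        # so a gene with identical counts in both groups has log2fc 0, p 1
        counts = np.tile(rng.integers(20, 200, size=(50, 1)), (1, 6))
        de = nb_wald_de(make_cm(counts))
        assert np.abs(de["log2fc"]).max() < 1e-9
        assert de["p"].min() > 0.99

    def test_bh_adjustment_matches_independent_oracle(self, rng):
        counts = rng.poisson(rng.lognormal(5, 1, size=(200, 1)) * np.ones((200, 6)))
        de = nb_wald_de(make_cm(counts))
        np.testing.assert_allclose(
            de["p_adj"].to_numpy(), bh_oracle(de["p"].to_numpy()), atol=1e-12
        )
        assert (de["p_adj"] >= de["p"] - 1e-15).all()

    def test_bh_oracle_hand_example(self):
        np.testing.assert_allclose(
            bh_oracle([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_planted_gene_power(self):
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            mats, _ = sim_counts(
                n_genes=400, n_per_group=3, n_cell_lines=1,
                planted=[PlantedGene("G00007", 2.0, True)],
                dispersion=0.05, seed=seed,
            )
            de = nb_wald_de(mats["CL1"])
            hits += de.loc["G00007", "p_adj"] < 0.05
        assert hits >= 0.9 * n_seeds

    def test_missing_phenotype_rejected(self, rng):
        counts = rng.poisson(50, size=(10, 4))
        cm = make_cm(counts, n_rr=4, n_wt=0)
        with pytest.raises(ValueError, match="WT"):
            nb_wald_de(cm)

    def test_size_factors_track_library_scaling(self, rng):
        base = rng.poisson(rng.lognormal(5, 1, size=(300, 1)) * np.ones((300, 4))) + 1
        scaled = base * np.array([1, 2, 4, 1])
        sf = size_factors(pd.DataFrame(scaled))
        ratios = (sf / sf.iloc[0]).to_numpy()
        np.testing.assert_allclose(ratios, [1, 2, 4, 1], rtol=0.05)


class TestDegSelection:
    def test_strict_alpha_boundary(self):
        de = pd.DataFrame(
            {"log2fc": [1.0, -1.0, 2.0], "p": [0.01, 0.01, 0.02],
             "p_adj": [0.049, 0.05, 0.051]},
            index=["a", "b", "c"],
        )
        assert select_degs(de) == {"a": "up"}

    def test_zero_fold_change_excluded_and_signs_correct(self):
        de = pd.DataFrame(
            {"log2fc": [0.0, -2.0, 0.5], "p": [1e-4] * 3, "p_adj": [1e-3] * 3},
            index=["z", "d", "u"],
        )
        assert select_degs(de) == {"d": "down", "u": "up"}

    def test_empty_results(self):
        de = pd.DataFrame(columns=["log2fc", "p", "p_adj"])
        assert select_degs(de) == {}


class TestIntersection:
    def test_direction_conflict_removes_gene(self):
        sets = {"A": {"g1": "up", "g2": "down"}, "B": {"g1": "up", "g2": "up"}}
        common = intersect_common_degs(sets)
        assert common.genes == {"g1": "up"}
        assert (common.n_up, common.n_down) == (1, 0)

    def test_scope_order_independent(self):
        sets = {
            "A": {"g1": "up", "g2": "down"},
            "B": {"g1": "up", "g2": "down"},
            "C": {"g1": "up"},
        }
        a = intersect_common_degs(sets, scope=["A", "B", "C"])
        b = intersect_common_degs(sets, scope=["C", "B", "A"])
        assert a.genes == b.genes

    def test_fc_threshold_fraction(self):
        sets = {"A": {"g1": "up", "g2": "up"}, "B": {"g1": "up", "g2": "up"}}
        tables = {
            cl: pd.DataFrame({"log2fc": [2.0, 0.5]}, index=["g1", "g2"])
            for cl in ("A", "B")
        }
        common = intersect_common_degs(sets, de_tables=tables, fc_threshold=1.0)
        assert common.frac_above_fc == pytest.approx(0.5)

    def test_empty_scope_rejected(self):
        with pytest.raises(ValueError, match="scope"):
            intersect_common_degs({"A": {}}, scope=[])


class TestOra:
    def exact_tail(self, N, K, n, k):
        """Exact hypergeometric upper tail by combinatorial enumeration."""
        return sum(
            math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(n, K) + 1)
        ) / math.comb(N, n)

    def test_p_matches_exact_enumeration_small_universes(self, rng):
        for _ in range(25):
            N = int(rng.integers(10, 31))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = {f"g{i}" for i in range(N)}
            term = set(rng.choice(sorted(universe), size=K, replace=False))
            selected = set(rng.choice(sorted(universe), size=n, replace=False))
            res = ora_enrich(selected, universe, {"T": term}, min_size=1)
            k = len(term & selected)
            assert res.loc["T", "p"] == pytest.approx(
                self.exact_tail(N, K, n, k), abs=1e-12
            )

    def test_small_terms_excluded(self):
        universe = {f"g{i}" for i in range(100)}
        sets = {"small": {f"g{i}" for i in range(19)},
                "ok": {f"g{i}" for i in range(20)}}
        res = ora_enrich(set(list(universe)[:10]), universe, sets, min_size=20)
        assert "small" not in res.index and "ok" in res.index

    def test_rich_factor_uses_listed_term_size(self):
        universe = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(20)}
        selected = {f"g{i}" for i in range(5)}  # 5 of the 20 listed
        res = ora_enrich(selected, universe, {"T": term}, min_size=1)
        assert res.loc["T", "rich_factor"] == pytest.approx(0.25)

    def test_fdr_matches_bh_oracle(self, rng):
        universe = {f"g{i}" for i in range(60)}
        sets = {
            f"T{t}": set(rng.choice(sorted(universe), size=25, replace=False))
            for t in range(8)
        }
        selected = set(rng.choice(sorted(universe), size=15, replace=False))
        res = ora_enrich(selected, universe, sets, min_size=1)
        np.testing.assert_allclose(
            res["fdr"].to_numpy(), bh_oracle(res["p"].to_numpy()), atol=1e-12
        )

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            ora_enrich({"x"}, {"a"}, {})


class TestGlobalNull:
    def test_near_zero_discoveries_without_planted_genes(self):
        fracs = []
        for seed in range(5):
            mats, _ = sim_counts(n_genes=1000, n_per_group=3, n_cell_lines=1,
                                 planted=[], dispersion=0.05, seed=seed)
            de = nb_wald_de(mats["CL1"])
            fracs.append((de["p_adj"] < 0.05).mean())
        assert np.mean(fracs) < 0.005


def test_counts_and_de_table_roundtrip(tmp_path, rng):
    mats, _ = sim_counts(n_genes=50, n_per_group=2, n_cell_lines=1, seed=1)
    cm = mats["CL1"]
    write_counts(cm, tmp_path / "counts.tsv", tmp_path / "meta.tsv")
    back = read_counts(tmp_path / "counts.tsv", tmp_path / "meta.tsv")
    assert (back.counts == cm.counts).all().all()
    assert (back.meta["phenotype"] == cm.meta["phenotype"]).all()

    de = nb_wald_de(cm)
    write_de_table(de, tmp_path / "de.tsv")
    back_de = read_de_table(tmp_path / "de.tsv")
    np.testing.assert_allclose(back_de["log2fc"], de["log2fc"], atol=1e-12)
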