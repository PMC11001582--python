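"""Differential abundance, over-representation, regulator scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from helpers import bh_stepup_oracle, hypergeom_tail_oracle, welch_t_oracle
from neurophen import synthdata
from neurophen.proteomics import (
    AbundanceTable,
    GeneSetCollection,
    RegulatorNetwork,
    enrich_sets,
    regulator_enrichment,
    welch_de,
)


def make_table(rows: dict, groups: dict) -> AbundanceTable:
    data = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    data.columns = list(groups)
    return AbundanceTable(data=data, groups=pd.Series(groups), min_valid_per_group=2)


GROUPS_44 = {"a1": "A", "a2": "A", "a3": "A", "a4": "A",
             "b1": "B", "b2": "B", "b3": "B", "b4": "B"}


class TestWelchDe:
    def test_identical_groups(self):
        t = make_table({"p1": [1, 2, 3, 4, 1, 2, 3, 4]}, GROUPS_44)
        row = welch_de(t, "A", "B").loc["p1"]
        assert row["t_stat"] == 0.0
        assert row["p"] == 1.0
        assert row["q"] == 1.0
        assert not row["significant"]

    def test_matches_textbook_oracle(self):
        t = make_table({"p1": [1, 2, 3, 4, 3, 4, 5, 6]}, GROUPS_44)
        row = welch_de(t, "A", "B").loc["p1"]
        t_o, df_o, p_o = welch_t_oracle([1, 2, 3, 4], [3, 4, 5, 6])
        assert row["t_stat"] == pytest.approx(t_o, abs=1e-10)
        assert row["df"] == pytest.approx(df_o, abs=1e-10)
        assert row["p"] == pytest.approx(p_o, abs=1e-10)
        assert row["log2fc"] == pytest.approx(2.0)

    def test_matches_scipy_on_random_pairs(self, rng):
        # dual route: vectorised implementation vs scipy's Welch test
        for _ in range(300):
            na, nb = rng.integers(3, 8, size=2)
            a = rng.normal(0, rng.uniform(0.5, 3), size=na)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=nb)
            rows = {"p": list(a) + list(b)}
            groups = {f"a{i}": "A" for i in range(na)} | {f"b{i}": "B" for i in range(nb)}
            row = welch_de(make_table(rows, groups), "A", "B").loc["p"]
            ref = stats.ttest_ind(b, a, equal_var=False)
            assert abs(row["p"] - ref.pvalue) < 1e-12
            assert row["t_stat"] == pytest.approx(ref.statistic, abs=1e-12)

    def test_bh_is_exact_stepup(self, rng):
        t, _ = synthdata.gen_proteome(n_proteins=400, frac_de=0.2, seed=4)
        de = welch_de(t, "WT", "GR400")
        np.testing.assert_allclose(de["q"].to_numpy(),
                                   bh_stepup_oracle(de["p"].to_numpy()), atol=1e-12)

    def test_bh_example_all_equal(self):
        np.testing.assert_allclose(bh_stepup_oracle([0.01, 0.02, 0.03, 0.04]), 0.04)
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        np.testing.assert_allclose(q, 0.04)

    def test_missing_values_excluded(self, caplog):
        rows = {
            "tested": [1, 2, 3, 4, 5, 6, 7, 8],
            "sparse": [1, np.nan, np.nan, np.nan, 5, 6, 7, 8],
        }
        t = make_table(rows, GROUPS_44)
        de = welch_de(t, "A", "B", min_valid_per_group=3)
        assert list(de.index) == ["tested"]

    def test_zero_variance_equal_means(self):
        t = make_table({"p1": [5, 5, 5, 5, 5, 5, 5, 5]}, GROUPS_44)
        row = welch_de(t, "A", "B").loc["p1"]
        assert row["t_stat"] == 0.0 and row["p"] == 1.0

    def test_zero_variance_unequal_means_flagged(self):
        t = make_table({"p1": [5, 5, 5, 5, 7, 7, 7, 7]}, GROUPS_44)
        row = welch_de(t, "A", "B").loc["p1"]
        assert row["degenerate"]
        assert row["p"] == np.finfo(float).tiny

    def test_group_size_validation(self):
        with pytest.raises(ValueError, match="< 2"):
            make_table({"p": [1, 2, 3]}, {"a1": "A", "a2": "A", "b1": "B"})


class TestEnrichSets:
    def universe(self, n=20):
        return [f"g{i}" for i in range(n)]

    def test_set_equal_to_universe_is_uninformative(self):
        uni = self.universe()
        coll = GeneSetCollection(sets={"all": frozenset(uni)}, universe=frozenset(uni))
        out = enrich_sets(uni[:7], coll)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_perfect_overlap_closed_form(self):
        uni = self.universe(20)
        coll = GeneSetCollection(sets={"s": frozenset(uni[:5])}, universe=frozenset(uni))
        out = enrich_sets(uni[:5], coll)
        assert out.loc[0, "p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_zero_overlap_omitted(self):
        uni = self.universe(20)
        coll = GeneSetCollection(sets={"s": frozenset(uni[:5])}, universe=frozenset(uni))
        out = enrich_sets(uni[10:15], coll)
        assert len(out) == 0

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(100):
            N = int(rng.integers(8, 26))
            uni = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            members = list(rng.choice(uni, size=K, replace=False))
            query = list(rng.choice(uni, size=n, replace=False))
            k = len(set(members) & set(query))
            if k == 0:
                continue
            coll = GeneSetCollection(sets={"s": frozenset(members)}, universe=frozenset(uni))
            out = enrich_sets(query, coll)
            assert out.loc[0, "p"] == pytest.approx(
                hypergeom_tail_oracle(N, K, n, k), rel=1e-10
            )

    def test_empty_query_rejected(self):
        coll = GeneSetCollection(sets={"s": frozenset(["g1"])}, universe=frozenset(["g1"]))
        with pytest.raises(ValueError, match="significant|empty"):
            enrich_sets([], coll)

    def test_unmapped_ids_dropped_with_warning(self, caplog):
        uni = self.universe(10)
        coll = GeneSetCollection(sets={"s": frozenset(uni[:5])}, universe=frozenset(uni))
        out = enrich_sets(uni[:3] + ["NOT_A_GENE"], coll)
        assert out.loc[0, "query_size"] == 3

    def test_case_folding(self):
        coll = GeneSetCollection(sets={"s": frozenset(["Col6a1", "TGFB1"])},
                                 universe=frozenset(["COL6A1", "tgfb1", "actb"]))
        out = enrich_sets(["col6a1"], coll)
        assert out.loc[0, "overlap"] == 1

    def test_ecm_truth_recovered_across_seeds(self):
        hits = 0
        for seed in range(5):
            table, truth = synthdata.gen_proteome(
                n_proteins=1000, frac_de=0.1, frac_ecm=0.1, ecm_de_odds=8.0, seed=seed
            )
            de = welch_de(table, "WT", "GR400")
            up = de.index[de["significant"] & (de["log2fc"] > 0)]
            sets = synthdata.make_gene_sets(truth, seed=seed)
            out = enrich_sets(up, sets).set_index("set")
            if out.loc["ECM", "q"] < 0.05:
                hits += 1
        assert hits == 5


class TestRegulatorEnrichment:
    def de_frame(self, lfc: dict, p: dict) -> pd.DataFrame:
        ids = list(lfc)
        return pd.DataFrame(
            {"log2fc": [lfc[i] for i in ids], "p": [p[i] for i in ids],
             "q": [p[i] for i in ids], "significant": [p[i] < 0.05 for i in ids]},
            index=ids,
        )

    def test_all_consistent_targets_z_two(self):
        lfc = {f"t{i}": 2.0 for i in range(4)} | {f"x{i}": 0.0 for i in range(16)}
        p = {k: (0.001 if k.startswith("t") else 0.9) for k in lfc}
        net = RegulatorNetwork(targets={"REG": [(f"t{i}", 1) for i in range(4)]})
        out = regulator_enrichment(self.de_frame(lfc, p), net).set_index("regulator")
        assert out.loc["REG", "z"] == pytest.approx(2.0)
        assert out.loc["REG", "overlap"] == 4

    def test_balanced_signs_z_zero(self):
        lfc = {"u1": 2.0, "u2": 2.0, "d1": -2.0, "d2": -2.0} | {
            f"x{i}": 0.0 for i in range(16)
        }
        p = {k: (0.001 if not k.startswith("x") else 0.9) for k in lfc}
        net = RegulatorNetwork(targets={"REG": [(t, 1) for t in ("u1", "u2", "d1", "d2")]})
        out = regulator_enrichment(self.de_frame(lfc, p), net).set_index("regulator")
        assert out.loc["REG", "z"] == pytest.approx(0.0)

    def test_no_overlap_reported_inert(self):
        lfc = {"a": 2.0} | {f"x{i}": 0.0 for i in range(10)}
        p = {k: (0.001 if k == "a" else 0.9) for k in lfc}
        net = RegulatorNetwork(targets={"REG": [("x0", 1), ("x1", 1)]})
        out = regulator_enrichment(self.de_frame(lfc, p), net).set_index("regulator")
        assert out.loc["REG", "p"] == 1.0
        assert np.isnan(out.loc["REG", "z"])

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        lfc = {f"t{i}": 2.0 for i in range(3)} | {f"x{i}": 0.0 for i in range(17)}
        p = {k: (0.001 if k.startswith("t") else 0.9) for k in lfc}
        net = RegulatorNetwork(targets={"REG": [("t0", 0), ("t1", 0), ("x0", 0), ("x1", 0)]})
        out = regulator_enrichment(self.de_frame(lfc, p), net).set_index("regulator")
        # N=20 tested, K=4 targets, n=3 in input, k=2 overlap
        assert out.loc["REG", "p"] == pytest.approx(hypergeom_tail_oracle(20, 4, 3, 2), rel=1e-9)

    def test_fold_change_window_is_linear_scale(self):
        # |linear FC| >= 1.5 means |log2fc| >= log2(1.5) ~ 0.585
        lfc = {"in": 0.6, "out": 0.5} | {f"x{i}": 0.0 for i in range(10)}
        p = {k: (0.001 if k in ("in", "out") else 0.9) for k in lfc}
        net = RegulatorNetwork(targets={"REG": [("in", 1), ("out", 1)]})
        out = regulator_enrichment(self.de_frame(lfc, p), net).set_index("regulator")
        assert out.loc["REG", "overlap"] == 1

    def test_driver_recovered_on_synthetic_data(self):
        table, truth = synthdata.gen_proteome(
            n_proteins=1000, frac_de=0.1, frac_ecm=0.1, ecm_de_odds=8.0,
            up_fraction=1.0, seed=6,
        )
        de = welch_de(table, "WT", "GR400")
        net = synthdata.make_regulator_network(truth, seed=6)
        out = regulator_enrichment(de, net)
        assert out.iloc[0]["regulator"] == "DRIVER"
        assert out.set_index("regulator").loc["DRIVER", "z"] > 2


class TestGmtIo:
    def test_round_trip(self, tmp_path):
        from neurophen.io import write_gmt

        path = tmp_path / "sets.gmt"
        write_gmt({"s1": ["g1", "g2"], "s2": ["g2", "g3", "g4"]}, path)
        coll = GeneSetCollection.from_gmt(path, universe=["g1", "g2", "g3", "g4"])
        assert coll.sets["s1"] == frozenset({"g1", "g2"})
        assert coll.sets["s2"] == frozenset({"g2", "g3", "g4"})

    def test_regulator_sign_suffixes(self, tmp_path):
        path = tmp_path / "reg.gmt"
        path.write_text("REG\tdesc\tCOL6A1+\tTGFB2-\tMYSTERY\n")
        net = RegulatorNetwork.from_gmt(path)
        assert dict(net.targets["REG"]) == {"col6a1": 1, "tgfb2": -1, "mystery": 0}

    def test_empty_sets_dropped(self, caplog):
        coll = GeneSetCollection(
            sets={"keep": frozenset(["g1"]), "drop": frozenset(["absent"])},
            universe=frozenset(["g1", "g2"]),
        )
        assert "drop" not in coll.sets


class TestFdrBehaviour:
    def test_null_yields_almost_no_discoveries(self):
        called = []
        for seed in range(5):
            table, _ = synthdata.gen_proteome(n_proteins=1000, frac_de=0.0, seed=seed)
            de = welch_de(table, "WT", "GR400")
            called.append(int(de["significant"].sum()))
        assert np.mean(called) <= 1.0

    def test_spiked_power_and_fdr(self):
        fdps, powers = [], []
        for seed in range(5):
            table, truth = synthdata.gen_proteome(
                n_proteins=1000, frac_de=0.1, lfc_location=1.5, seed=seed
            )
            de = welch_de(table, "WT", "GR400")
            hits = de["significant"].to_numpy()
            true = truth.de_flags
            fdps.append((hits & ~true).sum() / max(hits.sum(), 1))
            powers.append((hits & true).sum() / true.sum())
        assert np.mean(fdps) <= 0.08
        assert np.mean(powers) >= 0.8
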