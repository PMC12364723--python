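"""Instrument selection: p-value filter, LD clumping, F-statistic."""

import numpy as np
import pandas as pd
import pytest

from medimr.instruments import (IVConfig, LDMatrix, clump, f_statistic,
                                filter_f, filter_pvalue, select_instruments)
from conftest import mk_records


class TestPvalueFilter:
    @pytest.mark.parametrize("pval,kept", [
        (4.9e-6, True),   # strictly below the default threshold
        (5.0e-6, False),  # boundary: strict inequality rejects
        (1e-9, True),
    ])
    def test_strict_threshold(self, pval, kept):
        df = mk_records([{"pval": pval}])
        assert (len(filter_pvalue(df)) == 1) is kept

    def test_stringent_threshold_nests(self, rng):
        """The 5e-8 sensitivity selection is a subset of the 5e-6 one."""
        df = mk_records([{"snp": f"s{i}", "pval": p}
                         for i, p in enumerate(10.0 ** rng.uniform(-12, -4, 200))])
        loose = set(filter_pvalue(df, 5e-6)["snp"])
        strict = set(filter_pvalue(df, 5e-8)["snp"])
        assert strict <= loose


class TestFStatistic:
    def test_direct_arithmetic(self):
        assert f_statistic(0.1, 0.02) == pytest.approx(25.0)
        assert f_statistic(0.0, 0.3) == 0.0

    def test_boundary_just_above_ten_retained(self):
        df = mk_records([{"beta": 0.1, "se": 0.0316227},  # F = 10.00004
                         {"snp": "rs2", "beta": 0.1, "se": 0.032}])  # F = 9.77
        kept = filter_f(df, min_f=10.0)
        assert list(kept["snp"]) == ["rs1"]

    def test_mean_f_of_retained_at_least_ten(self, rng):
        df = mk_records([{"snp": f"s{i}", "beta": b, "se": 0.02}
                         for i, b in enumerate(rng.normal(0, 0.1, 100))])
        kept = filter_f(df)
        assert kept["f_stat"].mean() >= 10.0


def brute_force_clump(df, ld, r2_max, window_kb):
    """Independent reference: set-based elimination, no incremental state."""
    order = df.sort_values(["pval", "chrom", "pos", "snp"]).reset_index(drop=True)
    alive = set(order["snp"])
    kept = []
    for _, row in order.iterrows():
        if row["snp"] not in alive:
            continue
        kept.append(row["snp"])
        for _, other in order.iterrows():
            if other["snp"] == row["snp"] or other["snp"] not in alive:
                continue
            if other["chrom"] != row["chrom"]:
                continue
            if abs(other["pos"] - row["pos"]) > window_kb * 1000:
                continue
            r2 = ld.r2(row["snp"], other["snp"])
            if r2 is None or r2 >= r2_max:
                alive.discard(other["snp"])
        alive.discard(row["snp"])
    return kept


class TestClump:
    def test_single_snp_retained(self):
        df = mk_records([{}])
        kept, _ = clump(df, LDMatrix.identity(df["snp"]))
        assert len(kept) == 1

    def test_lower_pvalue_wins_within_window(self):
        df = mk_records([
            {"snp": "a", "pos": 1_000_000, "pval": 1e-10},
            {"snp": "b", "pos": 1_050_000, "pval": 1e-8},
        ])
        ld = LDMatrix(["a", "b"], np.array([[1.0, np.sqrt(0.5)],
                                            [np.sqrt(0.5), 1.0]]))
        kept, audit = clump(df, ld)
        assert list(kept["snp"]) == ["a"]
        assert audit.set_index("snp").loc["b", "action"] == "dropped"

    def test_outside_window_both_kept(self):
        df = mk_records([
            {"snp": "a", "pos": 1_000_000, "pval": 1e-10},
            {"snp": "b", "pos": 1_000_000 + 10_500_000 * 1000 // 1000, "pval": 1e-8},
        ])
        df.loc[1, "pos"] = 1_000_000 + 10_500 * 1000  # 10,500 kb apart
        ld = LDMatrix(["a", "b"], np.array([[1.0, 0.99], [0.99, 1.0]]))
        kept, _ = clump(df, ld)
        assert set(kept["snp"]) == {"a", "b"}

    def test_missing_ld_is_conservative(self):
        df = mk_records([
            {"snp": "a", "pos": 1_000_000, "pval": 1e-10},
            {"snp": "b", "pos": 1_100_000, "pval": 1e-8},
        ])
        kept, audit = clump(df, LDMatrix.identity(["a"]))  # b unknown to panel
        assert list(kept["snp"]) == ["a"]
        assert "missing_ld" in audit.set_index("snp").loc["b", "reason"]

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_and_order_invariant(self, trial, rng):
        r = np.random.default_rng(1000 + trial)
        n = int(r.integers(5, 200))
        snps = [f"s{i}" for i in range(n)]
        df = mk_records([{"snp": s,
                          "chrom": str(r.integers(1, 3)),
                          "pos": int(r.integers(1, 5_000_000)),
                          "pval": float(10.0 ** r.uniform(-12, -5))}
                         for s in snps])
        corr = r.uniform(-1, 1, (n, n))
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)
        ld = LDMatrix(snps, corr)
        r2_max, window = 0.1, 500
        kept, _ = clump(df, ld, r2_max=r2_max, window_kb=window)
        assert list(kept["snp"]) == brute_force_clump(df, ld, r2_max, window)
        shuffled = df.sample(frac=1.0, random_state=trial).reset_index(drop=True)
        kept2, _ = clump(shuffled, ld, r2_max=r2_max, window_kb=window)
        assert list(kept2["snp"]) == list(kept["snp"])
        # post-condition: retained SNPs pairwise below the r2 limit in-window
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                a, b = kept.iloc[i], kept.iloc[j]
                if a["chrom"] == b["chrom"] and abs(a["pos"] - b["pos"]) <= window * 1000:
                    assert ld.r2(a["snp"], b["snp"]) < r2_max


class TestSelectInstruments:
    def test_audit_covers_every_snp_once(self, rng):
        df = mk_records([{"snp": f"s{i}",
                          "pos": 1_000_000 + i * 1000,
                          "beta": float(rng.normal(0, 0.05)),
                          "se": 0.01,
                          "pval": float(10.0 ** rng.uniform(-9, -3))}
                         for i in range(50)])
        result = select_instruments(df, LDMatrix.identity(df["snp"]))
        assert sorted(result.audit["snp"]) == sorted(df["snp"])
        assert set(result.audit["reason"]) <= {"pval", "clumped", "weak", "instrument"}
        retained = set(result.records["snp"])
        assert retained == set(result.audit.loc[result.audit["action"] == "retained", "snp"])
        # every retained SNP satisfies every filter
        assert (result.records["pval"] < 5e-6).all()
        assert (f_statistic(result.records["beta"], result.records["se"]) >= 10).all()

    def test_ivconfig_roundtrip(self):
        iv = IVConfig(pval=5e-8)
        df = mk_records([{"pval": 1e-9}, {"snp": "rs2", "pval": 1e-7}])
        assert iv.select(df, LDMatrix.identity(df["snp"])).n_snp == 1


class TestLDMatrix:
    def test_from_genotypes_pearson_r2(self, rng):
        g = rng.integers(0, 3, size=(200, 3)).astype(float)
        dosages = pd.DataFrame(g, columns=["a", "b", "c"])
        ld = LDMatrix.from_genotypes(dosages)
        expected = np.corrcoef(g[:, 0], g[:, 1])[0, 1] ** 2
        assert ld.r2("a", "b") == pytest.approx(expected)
        assert ld.r2("a", "zzz") is None

    def test_file_roundtrip(self, tmp_path):
        ld = LDMatrix(["x", "y"], np.array([[1.0, 0.3], [0.3, 1.0]]))
        p = tmp_path / "ld.txt"
        ld.to_file(p)
        back = LDMatrix.from_file(p)
        assert back.r2("x", "y") == pytest.approx(0.09)
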