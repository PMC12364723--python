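"""I/O, validation, allele harmonization, and nearest-gene mapping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medimr.sumstats import (SumstatsError, harmonize, nearest_gene, read_bed,
                             read_sumstats, validate_sumstats, write_sumstats)
from conftest import mk_records


class TestReadSumstats:
    def test_well_formed_file_round_trips(self, tmp_path):
        df = mk_records([{}, {"snp": "rs2", "pos": 2000}, {"snp": "rs3", "pos": 3000}])
        path = tmp_path / "x.tsv"
        write_sumstats(df, path)
        got, report = read_sumstats(path)
        assert report.n_read == 3 and report.n_dropped == 0
        pd.testing.assert_frame_equal(got[df.columns], df)

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        df = mk_records([
            {},
            {"se": 0.0},            # nonpositive SE
            {"eaf": 1.5},           # impossible frequency
            {"ea": "AT"},           # not a single base
        ])
        path = tmp_path / "x.tsv"
        write_sumstats(df, path)
        got, report = read_sumstats(path)
        assert report.n_kept == 1 and report.n_dropped == 3
        assert set(report.drops["reason"]) == {
            "nonpositive_se", "eaf_out_of_range", "invalid_allele"}

    def test_or_scale_stores_log_odds(self, tmp_path):
        df = mk_records([{"beta": 1.0}, {"beta": 2.0}])  # OR column
        path = tmp_path / "x.tsv"
        write_sumstats(df, path)
        got, _ = read_sumstats(path, or_scale=True)
        assert got["beta"].iloc[0] == 0.0
        assert got["beta"].iloc[1] == pytest.approx(np.log(2.0))

    def test_missing_column_is_fatal(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("SNP\tCHR\nrs1\t1\n")
        with pytest.raises(SumstatsError, match="missing mandatory column"):
            read_sumstats(path)

    def test_missing_se_imputed_from_beta_and_p(self):
        df = mk_records([{"beta": 0.1, "pval": 0.05}])
        df.loc[0, "se"] = np.nan
        kept, drops = validate_sumstats(df)
        assert len(kept) == 1 and kept["se_imputed"].iloc[0]
        # |beta| / z where z = PhiInv(1 - p/2) = 1.95996...
        assert kept["se"].iloc[0] == pytest.approx(0.1 / 1.959964, rel=1e-5)


class TestHarmonize:
    def test_allele_swap_flips_outcome_beta(self):
        exp = mk_records([{"ea": "A", "oa": "G", "beta": 0.10}])
        out = mk_records([{"ea": "G", "oa": "A", "beta": -0.05, "eaf": 0.7}])
        h = harmonize(exp, out)
        assert h.n_snp == 1
        assert h.df["gamma_y"].iloc[0] == pytest.approx(0.05)
        assert bool(h.df["flipped_y"].iloc[0])

    def test_palindromic_snp_removed(self):
        exp = mk_records([{"ea": "A", "oa": "T"}, {"snp": "rs2"}])
        out = mk_records([{"ea": "A", "oa": "T"}, {"snp": "rs2"}])
        h = harmonize(exp, out)
        assert h.n_snp == 1
        assert h.audit.set_index("snp").loc["rs1", "reason"] == "palindromic"
        cg = harmonize(mk_records([{"ea": "C", "oa": "G"}, {"snp": "rs2"}]),
                       mk_records([{"ea": "C", "oa": "G"}, {"snp": "rs2"}]))
        assert "rs1" not in set(cg.df["snp"])

    def test_irreconcilable_alleles_removed(self):
        exp = mk_records([{"ea": "A", "oa": "G"}, {"snp": "rs2", "ea": "A", "oa": "G"}])
        out = mk_records([{"ea": "A", "oa": "C"}, {"snp": "rs2", "ea": "A", "oa": "G"}])
        h = harmonize(exp, out)
        assert h.n_snp == 1
        assert "irreconcilable_y" in set(h.audit["reason"])

    def test_strand_flip_reconciled_and_flagged(self):
        exp = mk_records([{"ea": "A", "oa": "G", "beta": 0.1}])
        out = mk_records([{"ea": "T", "oa": "C", "beta": 0.2}])  # complement strand
        h = harmonize(exp, out)
        assert h.n_snp == 1
        assert h.df["gamma_y"].iloc[0] == pytest.approx(0.2)
        assert bool(h.df["strand_y"].iloc[0])

    def test_empty_intersection_warns_not_raises(self):
        exp = mk_records([{}])
        out = mk_records([{}]).assign(snp="rs999")
        with pytest.warns(UserWarning, match="empty SNP intersection"):
            h = harmonize(exp, out)
        assert h.n_snp == 0

    def test_idempotent(self):
        exp = mk_records([{"ea": "A", "oa": "G", "beta": 0.1},
                          {"snp": "rs2", "ea": "C", "oa": "T", "beta": -0.2}])
        out = mk_records([{"ea": "G", "oa": "A", "beta": 0.3},
                          {"snp": "rs2", "ea": "T", "oa": "C", "beta": 0.4}])
        h1 = harmonize(exp, out)
        e2, o2 = h1.to_frames()
        h2 = harmonize(e2, o2)
        pd.testing.assert_frame_equal(
            h1.df[["snp", "gamma_x", "gamma_y"]],
            h2.df[["snp", "gamma_x", "gamma_y"]])
        assert not h2.df["flipped_y"].any()

    def test_sign_flip_symmetry(self, rng):
        """Flipping a record's alleles and negating beta leaves the
        harmonized set unchanged."""
        exp = mk_records([{"ea": "A", "oa": "G", "beta": 0.1},
                          {"snp": "rs2", "ea": "C", "oa": "A", "beta": 0.2}])
        out = mk_records([{"ea": "A", "oa": "G", "beta": 0.5, "eaf": 0.4},
                          {"snp": "rs2", "ea": "C", "oa": "A", "beta": -0.1}])
        flipped = out.copy()
        flipped.loc[0, ["ea", "oa"]] = ["G", "A"]
        flipped.loc[0, "beta"] = -out.loc[0, "beta"]
        flipped.loc[0, "eaf"] = 1 - out.loc[0, "eaf"]
        a = harmonize(exp, out).df
        b = harmonize(exp, flipped).df
        pd.testing.assert_frame_equal(a[["snp", "gamma_x", "gamma_y"]],
                                      b[["snp", "gamma_x", "gamma_y"]])

    def test_three_way_mediator_alignment(self):
        exp = mk_records([{"ea": "A", "oa": "G", "beta": 0.1}])
        out = mk_records([{"ea": "A", "oa": "G", "beta": 0.2}])
        med = mk_records([{"ea": "G", "oa": "A", "beta": 0.3}])
        h = harmonize(exp, out, mediator=med)
        assert h.has_mediator
        assert h.df["gamma_m"].iloc[0] == pytest.approx(-0.3)


def brute_force_nearest(pos, genes):
    """Exhaustive distance scan used as the independent oracle."""
    pos0 = pos - 1
    best = None
    for _, g in genes.iterrows():
        if g["start"] <= pos0 < g["end"]:
            d = 0
        elif pos0 < g["start"]:
            d = g["start"] - pos0
        else:
            d = pos0 - g["end"] + 1
        key = (d, g["start"], g["gene_id"])
        if best is None or key < best:
            best = key
    return best[2], best[0]


class TestNearestGene:
    GENES = pd.DataFrame({
        "chrom": ["1", "1", "2"],
        "start": [1000, 9000, 500],
        "end": [2000, 9500, 800],
        "gene_id": ["A", "B", "C"],
    })

    def test_overlap_distance_zero(self):
        hit = nearest_gene("1", 1500, self.GENES)
        assert hit.gene_id == "A" and hit.distance == 0

    def test_intergenic_picks_nearer_edge(self):
        # 3 kb past gene A's end, 5 kb before gene B's start
        hit = nearest_gene("1", 5000, self.GENES)
        assert hit.gene_id == "A"
        assert hit.distance == 3000  # downstream: positive sign

    def test_upstream_distance_is_negative(self):
        hit = nearest_gene("1", 500, self.GENES)  # pos0 499, gene starts at 1000
        assert hit.gene_id == "A" and hit.distance == -501

    def test_exact_tie_breaks_by_smaller_start(self):
        genes = pd.DataFrame({"chrom": ["1", "1"], "start": [100, 300],
                              "end": [151, 351], "gene_id": ["Z", "Y"]})
        pos0 = 225  # Z: 225-151+1 = 75; Y: 300-225 = 75 -> exact tie
        hit = nearest_gene("1", pos0 + 1, genes)
        assert hit.gene_id == "Z"

    def test_unmapped_chromosome(self):
        assert not nearest_gene("17", 1000, self.GENES).mapped

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(st.integers(min_value=1, max_value=200_000), st.integers(0, 2**31 - 1))
    def test_agrees_with_exhaustive_scan(self, pos, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 60))
        starts = np.sort(r.integers(0, 150_000, n))
        lengths = r.integers(1, 5000, n)
        genes = pd.DataFrame({"chrom": "1", "start": starts,
                              "end": starts + lengths,
                              "gene_id": [f"g{i}" for i in range(n)]})
        hit = nearest_gene("1", pos, genes)
        gid, d = brute_force_nearest(pos, genes)
        assert hit.gene_id == gid and abs(hit.distance) == d


def test_read_bed_rejects_inverted_interval(tmp_path):
    p = tmp_path / "g.bed"
    p.write_text("1\t500\t400\tbad\n")
    with pytest.raises(SumstatsError):
        read_bed(p)
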