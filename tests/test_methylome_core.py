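"""Coverage parsing, tiling, quantification and pseudo-bulking."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from oocyte_multiomics import methylome as me


def make_cell(rows, cell_id="c", group="g", context=None):
    sites = pd.DataFrame(rows, columns=me.SITE_COLUMNS)
    return me.CellMethylome(cell_id, group, sites, context)


class TestReadCoverage:
    def test_single_line(self, tmp_path):
        p = tmp_path / "c.cov"
        p.write_text("chr1\t100\t100\t50.0\t1\t1\n")
        cell = me.read_coverage(p)
        row = cell.sites.iloc[0]
        assert (row["chrom"], row["pos"], row["meth"], row["unmeth"]) == ("chr1", 100, 1, 1)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "c.cov"
        p.write_text("")
        assert me.read_coverage(p).n_cpgs_covered == 0

    def test_three_line_fixture(self, tmp_path):
        p = tmp_path / "c.cov"
        p.write_text(
            "chr1\t100\t100\t100.0\t2\t0\n"
            "chr1\t200\t200\t0.0\t0\t3\n"
            "chr2\t50\t50\t25.0\t1\t3\n"
        )
        cell = me.read_coverage(p)
        assert cell.n_cpgs_covered == 3
        assert cell.sites["meth"].sum() == 3
        assert cell.sites["unmeth"].sum() == 6

    def test_malformed_line_number(self, tmp_path):
        p = tmp_path / "c.cov"
        p.write_text("chr1\t100\t100\t50.0\t1\t1\nchr1\tx\t200\t0.0\t0\t1\n")
        with pytest.raises(me.CoverageParseError, match="line 2"):
            me.read_coverage(p)

    def test_wrong_column_count(self, tmp_path):
        p = tmp_path / "c.cov"
        p.write_text("chr1\t100\t1\t1\n")
        with pytest.raises(me.CoverageParseError, match="6"):
            me.read_coverage(p)

    def test_roundtrip(self, tmp_path):
        cell = make_cell([("chr1", 100, 2, 1), ("chr2", 5, 0, 4)])
        p = tmp_path / "c.cov"
        me.write_coverage(cell, p)
        back = me.read_coverage(p, cell_id="c", group="g")
        pd.testing.assert_frame_equal(back.sites, cell.sites)

    def test_zero_call_site_rejected(self, tmp_path):
        p = tmp_path / "c.cov"
        p.write_text("chr1\t100\t100\t0.0\t0\t0\n")
        with pytest.raises(me.CoverageParseError):
            me.read_coverage(p)


class TestBuildTiles:
    def test_250_cpgs_two_tiles(self):
        pos = np.arange(1, 251) * 10
        ts = me.build_tiles({"chr1": pos})
        assert ts.n_tiles == 2
        assert ts.tiles["start"].tolist() == [10, 1010]
        assert ts.tiles["end"].tolist() == [1000, 2000]

    def test_exactly_100(self):
        pos = np.arange(10, 1001, 10)
        ts = me.build_tiles({"chr1": pos})
        assert ts.n_tiles == 1
        assert (ts.tiles.iloc[0]["start"], ts.tiles.iloc[0]["end"]) == (10, 1000)

    def test_99_cpgs_no_tile(self):
        assert me.build_tiles({"chr1": np.arange(1, 100)}).n_tiles == 0

    def test_unsorted_raises(self):
        with pytest.raises(ValueError, match="chr1"):
            me.build_tiles({"chr1": np.array([5, 3, 10] * 40)})

    def test_tiling_conservation(self):
        # every reference CpG in at most one tile; tile CpG total = 100 x tiles
        rng = np.random.default_rng(0)
        pos = np.unique(rng.integers(1, 100_000, 730))
        ts = me.build_tiles({"chr1": pos})
        n_in_tiles = sum(
            ((pos >= s) & (pos <= e)).sum()
            for s, e in zip(ts.tiles["start"], ts.tiles["end"])
        )
        assert n_in_tiles == 100 * ts.n_tiles


class TestQuantifyTiles:
    def make_tileset(self):
        return me.build_tiles({"chr1": np.arange(1, 101) * 10})

    @pytest.mark.parametrize(
        "meth, unmeth, min_calls, expected",
        [(15, 15, 30, 50.0), (15, 14, 30, np.nan), (3, 2, 5, 60.0)],
    )
    def test_thresholds(self, meth, unmeth, min_calls, expected):
        ts = self.make_tileset()
        counts = me.TileCounts(np.array([meth]), np.array([unmeth]))
        pct = me.quantify_tiles(ts, counts, min_calls)
        if np.isnan(expected):
            assert np.isnan(pct[0])
        else:
            assert pct[0] == expected

    def test_min_calls_validated(self):
        ts = self.make_tileset()
        with pytest.raises(ValueError):
            me.quantify_tiles(ts, me.TileCounts(np.array([1]), np.array([1])), 0)


class TestOracleEquivalence:
    def test_tile_counts_match_bruteforce(self):
        """count_calls equals per-site summation on random sparse fixtures."""
        rng = np.random.default_rng(42)
        pos = np.arange(1, 501) * 7  # 5 tiles
        ts = me.build_tiles({"chr1": pos})
        for _ in range(20):
            n = rng.integers(10, 200)
            picked = rng.choice(pos, size=n, replace=False)
            meth = rng.integers(0, 3, n)
            unmeth = rng.integers(0, 3, n)
            keep = meth + unmeth > 0
            sites = pd.DataFrame(
                {"chrom": "chr1", "pos": picked[keep],
                 "meth": meth[keep], "unmeth": unmeth[keep]}
            )
            got = ts.count_calls(sites)
            for t in range(ts.n_tiles):
                lo, hi = ts.tiles["start"][t], ts.tiles["end"][t]
                mask = (sites["pos"] >= lo) & (sites["pos"] <= hi)
                assert got.meth[t] == sites.loc[mask, "meth"].sum()
                assert got.unmeth[t] == sites.loc[mask, "unmeth"].sum()

    def test_region_quantification_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        sites = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], 300),
                "pos": rng.integers(1, 5000, 300),
                "meth": rng.integers(0, 4, 300),
                "unmeth": rng.integers(1, 4, 300),
            }
        )
        cell = me.CellMethylome("c", "g", sites)
        regions = me.RegionSet(pd.DataFrame(
            [("chr1", 100, 2000, "r1", "CGI", False),
             ("chr2", 500, 4500, "r2", "gDMR", False)],
            columns=me.RegionSet.COLUMNS,
        ))
        out = me.quantify_regions(regions, cell, min_calls=1).set_index("name")
        for _, reg in regions.table.iterrows():
            mask = (
                (sites["chrom"] == reg["chrom"])
                & (sites["pos"] >= reg["start"])
                & (sites["pos"] <= reg["end"])
            )
            m, u = sites.loc[mask, "meth"].sum(), sites.loc[mask, "unmeth"].sum()
            assert out.loc[reg["name"], "percent"] == pytest.approx(
                100 * m / (m + u)
            )


class TestPseudobulk:
    def test_two_cells_one_site(self):
        a = make_cell([("chr1", 100, 1, 0)])
        b = make_cell([("chr1", 100, 0, 1)], cell_id="b")
        bulk = me.pseudobulk([a, b])
        assert bulk.sites.iloc[0][["meth", "unmeth"]].tolist() == [1, 1]

    def test_single_cell_identity(self):
        a = make_cell([("chr1", 100, 2, 1), ("chr2", 5, 0, 3)])
        bulk = me.pseudobulk([a])
        merged = bulk.sites.sort_values(["chrom", "pos"]).reset_index(drop=True)
        orig = a.sites.sort_values(["chrom", "pos"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, orig)

    def test_ten_cell_column_sums(self, meth_sim):
        _, cells, _, _, _ = meth_sim
        bulk = me.pseudobulk(cells, "WT")
        wt = [c for c in cells if c.group == "WT"]
        assert bulk.sites["meth"].sum() == sum(c.sites["meth"].sum() for c in wt)
        assert bulk.sites["unmeth"].sum() == sum(c.sites["unmeth"].sum() for c in wt)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            me.pseudobulk([], "WT")


class TestSegmentDomains:
    def tileset4(self):
        return me.build_tiles({"chr1": np.arange(1, 401) * 10})

    def test_two_domains(self):
        ts = self.tileset4()
        doms = me.segment_domains(ts, np.array([10.0, 20.0, 80.0, 90.0]))
        t = doms.table
        assert t["region_class"].tolist() == ["hypo_domain", "hyper_domain"]
        assert t.iloc[0]["start"] == ts.tiles.iloc[0]["start"]
        assert t.iloc[0]["end"] == ts.tiles.iloc[1]["end"]
        assert t.iloc[1]["end"] == ts.tiles.iloc[3]["end"]

    def test_mid_tile_breaks_run(self):
        ts = self.tileset4()
        doms = me.segment_domains(ts, np.array([10.0, 50.0, 10.0, np.nan]))
        assert doms.table["region_class"].tolist() == ["hypo_domain", "hypo_domain"]
        assert len(doms) == 2

    def test_boundary_25_is_hypo(self):
        ts = self.tileset4()
        doms = me.segment_domains(ts, np.array([25.0, np.nan, 75.0, np.nan]))
        assert doms.table["region_class"].tolist() == ["hypo_domain", "hyper_domain"]

    def test_chromosome_break(self):
        ts = me.build_tiles(
            {"chr1": np.arange(1, 101) * 10, "chr2": np.arange(1, 101) * 10}
        )
        doms = me.segment_domains(ts, np.array([10.0, 10.0]))
        assert len(doms) == 2  # runs never span chromosomes


class TestChiSquare:
    def test_uniform_table(self):
        chi2, p = me.chi_square_2x2(10, 10, 10, 10)
        assert chi2 == 0
        assert p == pytest.approx(1.0)

    def test_known_table(self):
        chi2, p = me.chi_square_2x2(30, 10, 10, 30)
        assert chi2 == pytest.approx(20.0)
        assert p == pytest.approx(7.744e-6, rel=1e-3)

    def test_degenerate_margin(self):
        with pytest.raises(ValueError, match="margin"):
            me.chi_square_2x2(0, 0, 5, 5)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 500, 4)
            chi2, p = me.chi_square_2x2(a, b, c, d)
            ref = chi2_contingency([[a, b], [c, d]], correction=False)
            assert chi2 == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-8, abs=1e-300)


class TestQuantifyRegions:
    def region(self):
        return me.RegionSet(pd.DataFrame(
            [("chr1", 1, 1000, "r", "gDMR", False)], columns=me.RegionSet.COLUMNS
        ))

    def test_below_min_calls_missing(self):
        cell = make_cell([("chr1", 10, 9, 10)])  # 19 calls
        out = me.quantify_regions(self.region(), cell, min_calls=20)
        assert np.isnan(out["percent"].iloc[0])

    def test_pooled_percent(self):
        cell = make_cell([("chr1", 10, 10, 10)])
        out = me.quantify_regions(self.region(), cell, min_calls=20)
        assert out["percent"].iloc[0] == 50.0

    def test_no_overlap_missing(self):
        cell = make_cell([("chr2", 10, 10, 10)])
        out = me.quantify_regions(self.region(), cell, min_calls=1)
        assert np.isnan(out["percent"].iloc[0])
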