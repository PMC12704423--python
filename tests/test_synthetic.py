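"""Generator correctness: determinism, moment agreement, truth completeness."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from oocyte_multiomics import methylome as me, proteomics as pr
from oocyte_multiomics.synthetic import (
    ExpressionSimSpec,
    MethylomeSimSpec,
    PlantedRegion,
    ProteomeSimSpec,
    simulate_counts,
    simulate_methylomes,
    simulate_proteome,
)

from conftest import small_methylome_spec


class TestDeterminism:
    def test_methylomes_identical_for_same_seed(self, tmp_path):
        spec = small_methylome_spec(seed=7, n_cells_per_group=1)
        out = []
        for run in range(2):
            cells, _, _ = simulate_methylomes(spec)
            path = tmp_path / f"run{run}.cov"
            me.write_coverage(cells[0], path)
            out.append(path.read_bytes())
        assert out[0] == out[1]

    def test_proteome_identical_for_same_seed(self):
        spec = ProteomeSimSpec(n_proteins=50, seed=3, missing_rate=0.1)
        a, _ = simulate_proteome(spec)
        b, _ = simulate_proteome(spec)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_counts_identical_for_same_seed(self):
        spec = ExpressionSimSpec(n_genes=100, n_markers_per_set=5, seed=3)
        a, _ = simulate_counts(spec)
        b, _ = simulate_counts(spec)
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestMethylomeMoments:
    def test_pure_oocyte_chh_summary(self):
        """With no contamination the mCHH summary is a binomial draw around
        the oocyte expectation (0.06) over >= 1e5 calls."""
        spec = small_methylome_spec(seed=13, n_cells_per_group=1)
        cells, _, _ = simulate_methylomes(spec)
        n = spec.non_cpg_sites
        sd = np.sqrt(0.06 * 0.94 / n)
        for cell in cells:
            assert abs(cell.context.mchh / 100 - 0.06) < 3 * sd

    def test_half_somatic_mixture_chh(self):
        """f=0.5 with somatic mCHH 0.005 gives the mixture mean
        (0.06 + 0.005)/2 = 0.0325."""
        spec = small_methylome_spec(seed=14, n_cells_per_group=1,
                                    contamination_fraction=0.5)
        cells, _, _ = simulate_methylomes(spec)
        p = 0.0325
        sd = np.sqrt(p * (1 - p) / spec.non_cpg_sites)
        assert abs(cells[0].context.mchh / 100 - p) < 3 * sd

    def test_domain_levels_converge(self, meth_sim):
        """Pooled WT methylation of hyper/hypo domain sites approaches the
        specified levels within 3 binomial SDs."""
        spec, cells, regions, ts, _ = meth_sim
        bulk = me.pseudobulk(cells, "WT")
        for cls, level in (("hyper_domain", spec.p_hyper), ("hypo_domain", spec.p_hypo)):
            # exclude domains containing CGI/gDMR overrides: pool all and
            # allow the small contamination of overridden sites via margin
            q = me.quantify_regions(regions.subset(cls), bulk, min_calls=1)
            calls = q["calls"].sum()
            observed = (q["percent"] * q["calls"]).sum() / calls / 100
            sd = np.sqrt(level * (1 - level) / calls)
            assert abs(observed - level) < 3 * sd + 0.02  # override margin

    def test_x_cgis_hypomethylated_in_oocyte(self, meth_sim):
        spec, cells, regions, _, _ = meth_sim
        bulk = me.pseudobulk(cells, "WT")
        q = me.quantify_regions(regions.subset("CGI", x_only=True), bulk, min_calls=10)
        assert (q["percent"].dropna() < 10).all()


class TestMethylomeValidation:
    @pytest.mark.parametrize(
        "field, value, match",
        [
            ("p_hyper", 1.5, "p_hyper"),
            ("coverage_rate", -1, "coverage_rate"),
            ("n_cells_per_group", 0, "n_cells_per_group"),
            ("hypo_block_tiles", 0, "block lengths"),
            ("contamination_fraction", 1.2, "contamination_fraction"),
        ],
    )
    def test_invalid_field_named(self, field, value, match):
        spec = small_methylome_spec(**{field: value})
        with pytest.raises(ValueError, match=match):
            spec.validate()

    def test_gdmr_outside_chromosomes(self):
        bad = PlantedRegion("g", "chr99", 0, 10)
        spec = small_methylome_spec(gdmrs=(bad,))
        with pytest.raises(ValueError, match="chr99"):
            spec.validate()


class TestProteomeSim:
    def test_zero_planted_shifts_tail_count(self):
        """Expected number of |log2FC| > 0.5 under the null follows the
        normal tail: 2 N Phi(-0.5 / (sd sqrt(2/n)))."""
        spec = ProteomeSimSpec(n_proteins=3000, seed=8)
        mat, _ = simulate_proteome(spec)
        fc = pr.group_log2fc(pr.log2_transform(mat), "WT", "KO")
        sd_fc = spec.sd * np.sqrt(2 / spec.n_samples_per_group)
        p_tail = 2 * norm.sf(0.5 / sd_fc)
        expected = spec.n_proteins * p_tail
        observed = int((fc.abs() > 0.5).sum())
        band = 3 * np.sqrt(spec.n_proteins * p_tail * (1 - p_tail))
        assert abs(observed - expected) <= band + 1

    def test_no_missing_when_rate_zero(self):
        mat, _ = simulate_proteome(ProteomeSimSpec(n_proteins=100, seed=1))
        assert not mat.values.isna().any(axis=None)

    def test_missing_rate_realised(self):
        mat, _ = simulate_proteome(
            ProteomeSimSpec(n_proteins=2000, missing_rate=0.3, seed=2)
        )
        frac = mat.values.isna().to_numpy().mean()
        assert frac == pytest.approx(0.3, abs=0.02)

    def test_invalid_fields(self):
        with pytest.raises(ValueError, match="missing_rate"):
            ProteomeSimSpec(missing_rate=1.0).validate()
        with pytest.raises(ValueError, match="sd"):
            ProteomeSimSpec(sd=-0.1).validate()

    def test_unknown_planted_protein(self):
        spec = ProteomeSimSpec(n_proteins=10, planted_effects=[("nope", "KO", 1.0)])
        with pytest.raises(ValueError, match="nope"):
            simulate_proteome(spec)


class TestExpressionSim:
    def test_marker_mean_ratio(self):
        """10x SN-marker multiplier yields an SN/NSN marker expression ratio
        near 10 (negative-binomial means scale linearly)."""
        spec = ExpressionSimSpec(
            seed=6, n_cells={("NSN", "WT"): 30, ("SN", "WT"): 30}
        )
        cm, _ = simulate_counts(spec)
        sn_cells = cm.cells.index[cm.cells["stage"] == "SN"]
        nsn_cells = cm.cells.index[cm.cells["stage"] == "NSN"]
        sn_markers = spec.sn_markers()
        ratio = (
            cm.counts.loc[sn_markers, sn_cells].to_numpy().mean()
            / cm.counts.loc[sn_markers, nsn_cells].to_numpy().mean()
        )
        assert ratio == pytest.approx(10.0, rel=0.1)

    def test_empty_stage_not_emitted(self):
        spec = ExpressionSimSpec(
            seed=1, n_cells={("NSN", "WT"): 3, ("SN", "WT"): 0}
        )
        cm, _ = simulate_counts(spec)
        assert (cm.cells["stage"] == "SN").sum() == 0

    def test_invalid_dispersion(self):
        with pytest.raises(ValueError, match="dispersion"):
            ExpressionSimSpec(dispersion=0.0).validate()


class TestTruthCompleteness:
    def test_methylome_truth_matches_spec(self, meth_sim):
        spec, cells, _, _, truth = meth_sim
        assert set(truth.cells["cell_id"]) == {c.cell_id for c in cells}
        assert list(truth.regions["name"]) == [g.name for g in spec.gdmrs]
        assert not truth.regions["name"].duplicated().any()
        planted = truth.regions.set_index("name")["planted_delta_pp"]
        assert (planted.loc[[g.name for g in spec.gdmrs if g.ko_delta > 0]] < 0).all()

    def test_proteome_truth_one_row_per_effect(self):
        effects = [("P00001", "KO", -2.0), ("P00002", "KO", 1.0)]
        _, truth = simulate_proteome(
            ProteomeSimSpec(n_proteins=10, planted_effects=effects, seed=0)
        )
        assert len(truth.features) == 2
        assert set(truth.features["feature_id"]) == {"P00001", "P00002"}

    def test_counts_truth_one_row_per_effect(self):
        _, truth = simulate_counts(
            ExpressionSimSpec(seed=0, planted_de=[("gene_0001", 2.0)])
        )
        assert truth.features["feature_id"].tolist() == ["gene_0001"]
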