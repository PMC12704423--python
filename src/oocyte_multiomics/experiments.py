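"""Canned validation experiments over the synthetic generators.

Each function runs one self-contained, seeded experiment -- the same ones the
test suite and the acceptance script report -- and returns plain dictionaries
of measured quantities. Problem sizes are desk-scale: large enough for the
statistical properties under test, small enough to run in seconds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import expression as ex
from . import methylome as me
from . import proteomics as pr
from .datasets import load_epimod_abundance, load_scmc_abundance
from .synthetic import (
    ExpressionSimSpec,
    MethylomeSimSpec,
    simulate_counts,
    simulate_methylomes,
)

__all__ = [
    "table_proteomics_summary",
    "null_dmr_fdp",
    "planted_recovery",
    "contamination_screen_flags",
    "staging_accuracy",
]


def table_proteomics_summary() -> dict[str, float]:
    """Headline numbers from the packaged SCMC / epigenetic-modifier tables.

    Fold changes are Hom (knockout) or Het vs the WT reference; percentages
    are of the WT level; reductions are 100 minus that.
    """
    scmc = pr.log2_transform(load_scmc_abundance())
    epi = pr.log2_transform(load_epimod_abundance())
    fc_hom = pr.group_log2fc(scmc, "WT", "Hom")
    fc_het = pr.group_log2fc(scmc, "WT", "Het")
    epi_test = pr.differential_test(epi, "WT", "Hom")
    scmc_test = pr.differential_test(scmc, "WT", "Hom")
    return {
        "nalp5_log2fc_hom_vs_wt": float(fc_hom["NALP5"]),
        "nalp5_log2fc_het_vs_wt": float(fc_het["NALP5"]),
        "nalp5_percent_of_wt_hom": float(pr.percent_of_reference(fc_hom["NALP5"])),
        "nalp5_percent_of_wt_het": float(pr.percent_of_reference(fc_het["NALP5"])),
        "dnmt3l_percent_reduction": float(epi_test.loc["DNM3L", "percent_reduction"]),
        "uhrf1_percent_reduction": float(epi_test.loc["UHRF1", "percent_reduction"]),
        "tle6_percent_reduction": float(scmc_test.loc["TLE6", "percent_reduction"]),
        "ooep_percent_reduction": float(scmc_test.loc["OOEP", "percent_reduction"]),
        "dnmt1_abs_log2fc": float(abs(epi_test.loc["DNMT1", "log2fc"])),
        "dnmt1_significant": float(epi_test.loc["DNMT1", "significant"]),
    }


def null_dmr_fdp(
    n_tiles: int = 1000,
    n_reps: int = 20,
    calls_per_group: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Realised false-discovery proportion of tile DMR calling under the null.

    Each replicate draws a bimodal genome (half tiles at 5%, half at 90%
    true methylation) with identical truth in both groups, binomial calls at
    ``calls_per_group`` per tile and group, and runs the chi-square + BH +
    delta pipeline. All discoveries are false, so per-replicate
    FDP = V / max(R, 1).
    """
    rng = np.random.default_rng(seed)
    ts = me.build_tiles({"chr1": (np.arange(n_tiles * 100) + 1) * 10})
    truth_p = np.where(np.arange(n_tiles) % 2 == 0, 0.05, 0.90)
    fdps = []
    for _ in range(n_reps):
        ma = rng.binomial(calls_per_group, truth_p)
        mb = rng.binomial(calls_per_group, truth_p)
        res = me.call_dmrs(
            ts,
            me.TileCounts(ma, calls_per_group - ma),
            me.TileCounts(mb, calls_per_group - mb),
        )
        n_sig = int(res["significant"].sum())
        fdps.append(n_sig / max(n_sig, 1))
    return {
        "mean_fdp": float(np.mean(fdps)),
        "n_tiles": n_tiles,
        "n_reps": n_reps,
    }


def planted_recovery(seed: int = 0) -> dict[str, float]:
    """Recover the planted knockout effects at the default study conditions.

    Runs the full-size default methylome simulation: measures the median
    global methylation difference against the value the planting implies
    (~-5 pp), checks that the three planted -30 pp gDMRs (and only those)
    are called significant at dense coverage, and that a sparse-coverage
    rerun is suppressed by the >100 calls/kb filter.
    """
    spec = MethylomeSimSpec(seed=seed)
    cells, regions, truth = simulate_methylomes(spec)
    ts = me.build_tiles(spec.cpg_positions())

    per_cell = me.global_methylation(cells, ts, min_calls=5)
    diff, p = me.compare_global_methylation(per_cell, *spec.groups)

    bulk_wt = me.pseudobulk(cells, spec.groups[0])
    bulk_ko = me.pseudobulk(cells, spec.groups[1])
    gd = me.test_gdmrs(
        regions.subset("gDMR"), bulk_wt, bulk_ko, group_labels=spec.groups
    ).set_index("name")
    planted = truth.regions.set_index("name")["planted_delta_pp"]
    planted_names = planted.index[planted < 0]
    null_names = planted.index[planted == 0]

    sparse_spec = MethylomeSimSpec(seed=seed + 1, coverage_rate=12_000,
                                   n_cells_per_group=3)
    s_cells, s_regions, _ = simulate_methylomes(sparse_spec)
    s_gd = me.test_gdmrs(
        s_regions.subset("gDMR"),
        me.pseudobulk(s_cells, sparse_spec.groups[0]),
        me.pseudobulk(s_cells, sparse_spec.groups[1]),
    )

    return {
        "global_median_difference_pp": float(diff),
        "expected_global_difference_pp": float(
            truth.extras["expected_global_difference_pp"]
        ),
        "global_welch_p": float(p),
        "n_cells_per_group": spec.n_cells_per_group,
        "planted_gdmrs_called": int(gd.loc[planted_names, "significant"].sum()),
        "n_planted_gdmrs": int(len(planted_names)),
        "null_gdmrs_called": int(gd.loc[null_names, "significant"].sum()),
        "mean_planted_gdmr_delta_pp": float(gd.loc[planted_names, "delta"].mean()),
        "sparse_gdmrs_called": int(s_gd["significant"].sum()),
        "sparse_max_calls_per_kb": float(
            s_gd[["calls_per_kb_A", "calls_per_kb_B"]].to_numpy().max()
        ),
    }


def contamination_screen_flags(
    fractions=(0.0, 0.25, 0.5),
    n_reps: int = 20,
    seed: int = 0,
) -> dict[str, object]:
    """Mean number of flagged contamination criteria per mixing fraction.

    Each replicate simulates one small-genome cell per group at the given
    somatic mixing fraction and screens it; reported per fraction is the mean
    count (over replicates and cells) of criteria returning ``contaminated``,
    plus the fraction of cells retained.
    """
    flag_means, retained_frac = [], []
    for k, f in enumerate(fractions):
        flags, retained = [], []
        for rep in range(n_reps):
            spec = MethylomeSimSpec(
                n_autosomes=2,
                cpg_per_chromosome=4_000,
                coverage_rate=6_000,
                n_cells_per_group=1,
                contamination_fraction=f,
                seed=seed + 1000 * k + rep,
            )
            cells, regions, _ = simulate_methylomes(spec)
            ts = me.build_tiles(spec.cpg_positions())
            _, report = me.screen_cells(cells, regions, ts, min_cpgs=3_000)
            crit = report[["x_cgi", "context", "bimodality"]]
            flags.extend((crit == "contaminated").sum(axis=1).tolist())
            retained.extend(report["retained"].tolist())
        flag_means.append(float(np.mean(flags)))
        retained_frac.append(float(np.mean(retained)))
    return {
        "fractions": list(fractions),
        "mean_flags": flag_means,
        "retained_fraction": retained_frac,
        "n_reps": n_reps,
    }


def staging_accuracy(seed: int = 0) -> dict[str, float]:
    """Stage-call accuracy on simulated NSN/SN cells.

    Well-separated condition: 10x marker multipliers (the default), where
    every call should be correct. Weak separation: 1.5x multipliers, where
    calls may fall back to ambiguous but must never flip stage.
    """
    spec = ExpressionSimSpec(seed=seed)
    cm, _ = simulate_counts(spec)
    st = ex.stage_cells(cm, spec.nsn_markers(), spec.sn_markers())
    accuracy = float((st["stage"] == cm.cells["stage"]).mean())

    weak = ExpressionSimSpec(seed=seed + 1, marker_multiplier=1.5)
    wcm, _ = simulate_counts(weak)
    wst = ex.stage_cells(wcm, weak.nsn_markers(), weak.sn_markers())
    called = wst["stage"] != "ambiguous"
    wrong = int((wst.loc[called, "stage"] != wcm.cells.loc[called, "stage"]).sum())
    return {
        "accuracy_well_separated": accuracy,
        "n_cells": len(st),
        "weak_separation_wrong_calls": wrong,
        "weak_separation_ambiguous": int((~called).sum()),
    }
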