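"""Differential protein abundance for label-free oocyte proteomes.

The substrate is a matrix of raw DIA intensities (proteins x samples) with a
sample -> genotype design. The workflow mirrors a standard Perseus-style
pipeline: log2-transform, per-group means on the log scale, two-sample t-test
per protein, Benjamini-Hochberg adjustment across the tested family, and a
significance call at FDR < 0.1 combined with |log2FC| > 0.5. Fold changes are
differences of per-group mean log2 intensities (never the log of mean raw
intensities), so a log2FC of -8.47 corresponds to 0.3% of the reference level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AbundanceMatrix",
    "load_abundance_tsv",
    "log2_transform",
    "group_log2fc",
    "percent_of_reference",
    "format_percent",
    "differential_test",
    "standardize_for_heatmap",
    "correlate_log2fc",
]


@dataclass
class AbundanceMatrix:
    """Proteins x samples intensity matrix with a group design.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with one column per sample. Missing
        intensities are NaN. On the raw scale all present values must be
        strictly positive.
    design
        Series mapping every sample (column) to a group label, e.g.
        ``WT``/``Het``/``Hom``.
    log_scale
        Whether ``values`` already holds log2 intensities.
    """

    values: pd.DataFrame
    design: pd.Series = field(repr=False)
    log_scale: bool = False

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples without a group in the design: {missing}")
        self.design = self.design.loc[self.values.columns]
        if not self.log_scale:
            bad = (self.values <= 0).any(axis=None)
            if bad:
                prot, samp = _first_nonpositive(self.values)
                raise ValueError(
                    f"non-positive raw intensity for protein {prot!r}, sample {samp!r}"
                )

    def samples_in(self, group: str) -> list[str]:
        hit = list(self.design.index[self.design == group])
        if not hit:
            raise KeyError(f"no samples with group {group!r}")
        return hit


def _first_nonpositive(values: pd.DataFrame) -> tuple[str, str]:
    mask = values <= 0
    for samp in values.columns:
        col = mask[samp]
        if col.any():
            return str(col.idxmax()), str(samp)
    raise AssertionError("no non-positive value found")


def load_abundance_tsv(matrix_path, design_path) -> AbundanceMatrix:
    """Read a protein x sample TSV (first column protein id) plus a
    two-column sample->group design TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col=0).iloc[:, 0]
    return AbundanceMatrix(values=values.astype(float), design=design)


def log2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Replace every present intensity by log2(intensity); NaN preserved."""
    if matrix.log_scale:
        raise ValueError("matrix is already on the log2 scale")
    return AbundanceMatrix(
        values=np.log2(matrix.values), design=matrix.design, log_scale=True
    )


def _require_log(matrix: AbundanceMatrix) -> None:
    if not matrix.log_scale:
        raise ValueError("expected a log2-scale matrix; call log2_transform first")


def group_log2fc(
    logmat: AbundanceMatrix, reference_group: str, test_group: str
) -> pd.Series:
    """Per-protein log2 fold change: mean log2 intensity over the test group
    minus the mean over the reference group (NaN intensities ignored)."""
    _require_log(logmat)
    ref = logmat.values[logmat.samples_in(reference_group)].mean(axis=1)
    tst = logmat.values[logmat.samples_in(test_group)].mean(axis=1)
    fc = tst - ref
    fc.name = f"log2fc_{test_group}_vs_{reference_group}"
    return fc


def percent_of_reference(log2fc):
    """2**log2fc x 100: the test-group level as a percentage of reference."""
    return 2.0 ** np.asarray(log2fc, dtype=float) * 100.0


def format_percent(pct: float) -> str:
    """Report percentages at 1 d.p. below 10% and as integers above."""
    if not np.isfinite(pct):
        raise ValueError("cannot format a non-finite percentage")
    return f"{pct:.1f}" if pct < 10 else f"{pct:.0f}"


def differential_test(
    logmat: AbundanceMatrix,
    reference_group: str,
    test_group: str,
    fdr_threshold: float = 0.1,
    fc_threshold: float = 0.5,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test per protein with BH adjustment over the tested family.

    Proteins with fewer than two present values in either group are flagged
    ``testable=False``, carry NaN statistics and are excluded from the BH
    family. ``significant`` requires q < ``fdr_threshold`` and
    |log2fc| > ``fc_threshold`` (both strict). Student's equal-variance t is
    the default (the Perseus convention); set ``equal_var=False`` for Welch.
    """
    _require_log(logmat)
    ref_cols = logmat.samples_in(reference_group)
    tst_cols = logmat.samples_in(test_group)
    ref = logmat.values[ref_cols]
    tst = logmat.values[tst_cols]

    testable = (ref.notna().sum(axis=1) >= 2) & (tst.notna().sum(axis=1) >= 2)
    fc = tst.mean(axis=1) - ref.mean(axis=1)

    out = pd.DataFrame(index=logmat.values.index)
    out["log2fc"] = fc.where(testable)
    out["percent_of_reference"] = percent_of_reference(out["log2fc"])
    out["percent_reduction"] = 100.0 - out["percent_of_reference"]
    out["t_statistic"] = np.nan
    out["p_value"] = np.nan
    out["q_value"] = np.nan

    idx = out.index[testable]
    if len(idx):
        res = stats.ttest_ind(
            tst.loc[idx], ref.loc[idx], axis=1, equal_var=equal_var,
            nan_policy="omit",
        )
        out.loc[idx, "t_statistic"] = res.statistic
        out.loc[idx, "p_value"] = res.pvalue
        out.loc[idx, "q_value"] = multipletests(
            out.loc[idx, "p_value"].to_numpy(), method="fdr_bh"
        )[1]

    out["significant"] = (
        (out["q_value"] < fdr_threshold) & (out["log2fc"].abs() > fc_threshold)
    ).fillna(False)
    out["testable"] = testable
    return out


def standardize_for_heatmap(logmat: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Standardize a log2 matrix for heatmap display.

    ``center_rows``: subtract each row's mean (relative abundance per protein).
    ``dataset_zscore_then_row_center``: subtract the global mean of the whole
    matrix and divide by the global variance across all values, then subtract
    each row's (post-scaling) mean -- the convention used when placing several
    datasets on one colour scale.
    """
    if mode == "center_rows":
        return logmat.sub(logmat.mean(axis=1), axis=0)
    if mode == "dataset_zscore_then_row_center":
        flat = logmat.to_numpy(dtype=float)
        var = np.nanvar(flat)
        if var == 0:
            raise ValueError("zero variance across the dataset; cannot standardize")
        scaled = (logmat - np.nanmean(flat)) / var
        return scaled.sub(scaled.mean(axis=1), axis=0)
    raise ValueError(f"unknown mode {mode!r}")


def correlate_log2fc(fc_a, fc_b) -> tuple[float, float]:
    """Pearson correlation between two fold-change vectors.

    Accepts aligned arrays or index-aligned Series; restricted to the pairs
    where both values are finite. Requires at least 3 such pairs.
    """
    if isinstance(fc_a, pd.Series) and isinstance(fc_b, pd.Series):
        shared = fc_a.index.intersection(fc_b.index)
        a = fc_a.loc[shared].to_numpy(dtype=float)
        b = fc_b.loc[shared].to_numpy(dtype=float)
    else:
        a = np.asarray(fc_a, dtype=float)
        b = np.asarray(fc_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("fold-change vectors must be paired")
    keep = np.isfinite(a) & np.isfinite(b)
    if keep.sum() < 3:
        raise ValueError("need at least 3 finite fold-change pairs")
    r, p = stats.pearsonr(a[keep], b[keep])
    return float(r), float(p)
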