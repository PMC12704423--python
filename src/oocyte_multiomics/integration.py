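"""Cross-omic integration: set-overlap significance and paired fold changes.

Overlap between differentially expressed genes and differentially abundant
proteins is assessed with an upper-tail hypergeometric test over a declared
universe (by default, the features detected in both omics layers). Paired
transcript/protein log2 fold changes are tabulated through a one-to-one
gene <-> protein mapping and correlated with Pearson's r.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .proteomics import correlate_log2fc

__all__ = ["FeatureMap", "OverlapResult", "hypergeometric_overlap", "paired_fc_scatter"]


@dataclass
class FeatureMap:
    """One-to-one pairs of (gene id, protein id)."""

    pairs: pd.DataFrame  # columns: gene_id, protein_id

    def __post_init__(self) -> None:
        p = self.pairs[["gene_id", "protein_id"]].reset_index(drop=True)
        if p["gene_id"].duplicated().any() or p["protein_id"].duplicated().any():
            raise ValueError("mapping must be one-to-one on the mapped subset")
        self.pairs = p

    @classmethod
    def from_tsv(cls, path) -> "FeatureMap":
        return cls(pd.read_csv(path, sep="\t", names=["gene_id", "protein_id"], header=0))


@dataclass(frozen=True)
class OverlapResult:
    universe: int
    size_a: int
    size_b: int
    overlap: int
    p_value: float


def hypergeometric_overlap(
    set_a: set, set_b: set, universe: set, tail: str = "upper"
) -> OverlapResult:
    """P(X >= k) for the overlap k of two sets drawn from a finite universe.

    X ~ Hypergeometric(N=|universe|, K=|A|, n=|B|). Both sets must be subsets
    of the universe. ``tail='lower'`` gives the depletion probability
    P(X <= k) instead.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    n_univ, k_a, n_b = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    if tail == "upper":
        p = float(stats.hypergeom.sf(k - 1, n_univ, k_a, n_b))
    elif tail == "lower":
        p = float(stats.hypergeom.cdf(k, n_univ, k_a, n_b))
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    return OverlapResult(n_univ, k_a, n_b, k, p)


def paired_fc_scatter(
    deg_records: pd.DataFrame,
    dap_records: pd.DataFrame,
    feature_map: FeatureMap,
) -> tuple[pd.DataFrame, float, float]:
    """Pair transcript and protein log2 fold changes via the feature map.

    ``deg_records`` is indexed by gene id with columns ``log2fc`` and
    ``significant``; ``dap_records`` likewise by protein id. Returns the
    paired table (gene_id, protein_id, rna_log2fc, protein_log2fc,
    both_significant) plus the Pearson r and p over the finite pairs
    (>= 3 pairs required).
    """
    rows = []
    for gene, prot in feature_map.pairs.itertuples(index=False):
        if gene in deg_records.index and prot in dap_records.index:
            rows.append(
                dict(
                    gene_id=gene,
                    protein_id=prot,
                    rna_log2fc=float(deg_records.at[gene, "log2fc"]),
                    protein_log2fc=float(dap_records.at[prot, "log2fc"]),
                    both_significant=bool(deg_records.at[gene, "significant"])
                    and bool(dap_records.at[prot, "significant"]),
                )
            )
    table = pd.DataFrame(rows)
    if len(table) < 3:
        raise ValueError("need >= 3 mapped fold-change pairs")
    r, p = correlate_log2fc(
        table["rna_log2fc"].to_numpy(), table["protein_log2fc"].to_numpy()
    )
    return table, r, p
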