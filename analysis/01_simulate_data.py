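#!/usr/bin/env python
"""Generate the seeded synthetic datasets used by the downstream analyses.

Emits, under results/synthetic/: the region annotation (BED), the simulation
ground truth (JSON), one example per-cell coverage file (Bismark dialect),
and the proteome / count matrices (TSV). The methylome cells themselves are
regenerated on demand by the later scripts (the generators are pure
functions of spec + seed), so the bulky per-cell site tables are not stored.
"""

from pathlib import Path

from oocyte_multiomics import methylome as me
from oocyte_multiomics.synthetic import (
    ExpressionSimSpec,
    MethylomeSimSpec,
    ProteomeSimSpec,
    simulate_counts,
    simulate_methylomes,
    simulate_proteome,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20260929


def main() -> None:
    mspec = MethylomeSimSpec(seed=SEED)
    cells, regions, truth = simulate_methylomes(mspec)
    regions.to_bed(OUT / "regions.bed")
    truth.to_json(OUT / "methylome_truth.json")
    me.write_coverage(cells[0], OUT / f"{cells[0].cell_id}.cov")
    print(f"methylomes: {len(cells)} cells, "
          f"{cells[0].n_cpgs_covered:,} CpGs covered in {cells[0].cell_id}; "
          f"{len(regions)} annotated regions "
          f"(expected global KO deficit "
          f"{truth.extras['expected_global_difference_pp']:+.2f} pp)")

    pspec = ProteomeSimSpec(
        seed=SEED + 1,
        planted_effects=[(f"P{i + 1:05d}", "KO", -1.5) for i in range(20)]
        + [(f"P{i + 1:05d}", "KO", 1.0) for i in range(20, 30)],
    )
    matrix, ptruth = simulate_proteome(pspec)
    matrix.values.to_csv(OUT / "proteome_raw.tsv", sep="\t")
    matrix.design.rename("group").to_csv(OUT / "proteome_design.tsv", sep="\t")
    ptruth.to_json(OUT / "proteome_truth.json")
    print(f"proteome: {pspec.n_proteins} proteins x {matrix.values.shape[1]} "
          f"samples, {len(ptruth.features)} planted shifts")

    espec = ExpressionSimSpec(
        seed=SEED + 2,
        planted_de=[(f"gene_{i + 1:04d}", -1.5) for i in range(20)]
        + [(f"gene_{i + 1:04d}", 1.5) for i in range(20, 30)],
    )
    cm, etruth = simulate_counts(espec)
    cm.counts.to_csv(OUT / "counts.tsv", sep="\t")
    cm.cells.to_csv(OUT / "cell_metadata.tsv", sep="\t")
    etruth.to_json(OUT / "counts_truth.json")
    print(f"transcriptome: {espec.n_genes} genes x {cm.counts.shape[1]} cells, "
          f"{len(etruth.features)} planted shifts")


if __name__ == "__main__":
    main()
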