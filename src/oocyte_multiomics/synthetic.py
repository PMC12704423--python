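"""Seeded synthetic data generators with planted ground truth.

Three generators emulate the statistical structure the analysis assumes:

* ``simulate_methylomes`` -- sparse per-cell CpG methylomes on a small
  genome (5 autosomes + X by default) with the bimodal oocyte domain
  layout (hypermethylated blocks near 90%, hypomethylated blocks near 5%),
  hypomethylated X-chromosome CpG islands, elevated non-CpG methylation,
  imprinted gDMRs, a unimodal somatic contaminant profile mixed in at the
  read level, and planted knockout effects (a global deficit on
  hypermethylated domains and gDMR-specific hypomethylation).
* ``simulate_proteome`` -- log-normal protein intensities with planted
  per-group log2 shifts and optional missingness.
* ``simulate_counts`` -- negative-binomial transcriptomes with NSN/SN
  marker modules and planted knockout effects.

Every generator is a pure function of its spec (which includes the seed) and
returns a :class:`SimTruth` recording each planted effect exactly once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .methylome import CellMethylome, ContextSummary, RegionSet, SITE_COLUMNS
from .proteomics import AbundanceMatrix

__all__ = [
    "SimTruth",
    "ContextParams",
    "PlantedRegion",
    "MethylomeSimSpec",
    "simulate_methylomes",
    "ProteomeSimSpec",
    "simulate_proteome",
    "ExpressionSimSpec",
    "simulate_counts",
]


def _check_fraction(name: str, value: float, upper_open: bool = False) -> None:
    hi_ok = value < 1 if upper_open else value <= 1
    if not (0 <= value and hi_ok):
        raise ValueError(f"{name} must lie in [0, 1{')' if upper_open else ']'}: got {value}")


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0: got {value}")


@dataclass
class SimTruth:
    """Ground truth emitted by every simulator.

    ``cells``: per-cell group / stage / contamination fraction.
    ``regions``: planted per-region methylation effects.
    ``features``: planted per-protein or per-gene log2 shifts.
    ``extras``: derived scalar expectations (e.g. the expected global
    methylation difference implied by the planted deficit).
    """

    cells: pd.DataFrame
    regions: pd.DataFrame
    features: pd.DataFrame
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "cells": self.cells.to_dict(orient="records"),
            "regions": self.regions.to_dict(orient="records"),
            "features": self.features.to_dict(orient="records"),
            "extras": self.extras,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Methylome simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContextParams:
    """Expected methylated fraction per cytosine context for one cell type.

    For the somatic profile ``mcpg`` is the genome-wide CpG site-level used
    to draw somatic reads (unimodal). For the oocyte profile the realised
    CpG level is determined by the domain layout, so ``mcpg`` is the nominal
    genome-wide expectation only; ``mchg``/``mchh`` parameterise the non-CpG
    summary draws for both profiles.
    """

    mcpg: float
    mchg: float
    mchh: float

    def validate(self, prefix: str) -> None:
        for f in ("mcpg", "mchg", "mchh"):
            _check_fraction(f"{prefix}.{f}", getattr(self, f))


@dataclass(frozen=True)
class PlantedRegion:
    """A gDMR: ``n_cpgs`` reference CpGs starting at ``cpg_index`` on
    ``chrom``, methylated at ``wt_level`` in wild-type oocytes and at
    ``wt_level - ko_delta`` in knockouts."""

    name: str
    chrom: str
    cpg_index: int
    n_cpgs: int
    wt_level: float = 0.85
    ko_delta: float = 0.0


def _auto_gdmrs(spec: "MethylomeSimSpec") -> tuple[PlantedRegion, ...]:
    """Place up to 10 gDMRs inside hypermethylated blocks (one per block per
    autosome); the first 3 carry the planted -30 pp knockout effect, matching
    the study's finding of 3 hypomethylated gDMRs."""
    period = spec.hypo_block_tiles + spec.hyper_block_tiles
    n_blocks = spec.tiles_per_chromosome // period
    out: list[PlantedRegion] = []
    i = 0
    for block in range(n_blocks):
        for a in range(spec.n_autosomes):
            if i >= 10:
                return tuple(out)
            tile = block * period + spec.hypo_block_tiles
            out.append(
                PlantedRegion(
                    name=f"gDMR-{i + 1:02d}",
                    chrom=f"chr{a + 1}",
                    cpg_index=tile * 100 + 30,
                    n_cpgs=40,
                    wt_level=0.85,
                    ko_delta=0.30 if i < 3 else 0.0,
                )
            )
            i += 1
    return tuple(out)


@dataclass
class MethylomeSimSpec:
    """Conditions for the single-cell methylome generator.

    The genome is ``n_autosomes`` autosomes plus one X chromosome, each with
    ``cpg_per_chromosome`` reference CpGs spaced ``cpg_spacing`` bp apart.
    100-CpG tiles alternate hypomethylated blocks (``hypo_block_tiles`` tiles
    at ``p_hypo``) and hypermethylated blocks (``hyper_block_tiles`` at
    ``p_hyper``); the default 6/4 split yields a genome-wide oocyte mCpG just
    under 40%. Knockout cells lose ``global_ko_delta`` from hypermethylated
    block levels (0.125 under the default layout induces a ~5 pp deficit in
    the mean-of-tiles global methylation) and each planted gDMR additionally
    drops by its own ``ko_delta``. Contamination mixes somatic reads in at
    the stated per-cell fraction, shifting CpG sites, the context summary and
    X-CGI methylation jointly.
    """

    n_autosomes: int = 5
    x_chrom: str = "chrX"
    cpg_per_chromosome: int = 20_000
    cpg_spacing: int = 50
    hypo_block_tiles: int = 6
    hyper_block_tiles: int = 4
    p_hypo: float = 0.05
    p_hyper: float = 0.90
    gdmrs: Sequence[PlantedRegion] | None = None  # auto-placed when None
    global_ko_delta: float = 0.125
    n_cells_per_group: int = 10
    groups: tuple[str, str] = ("WT", "KO")
    coverage_rate: float = 50_000.0  # expected covered CpGs per cell
    mean_reads_per_site: float = 2.0  # zero-truncated Poisson mean parameter
    oocyte_context: ContextParams = ContextParams(mcpg=0.38, mchg=0.05, mchh=0.06)
    somatic_context: ContextParams = ContextParams(mcpg=0.70, mchg=0.005, mchh=0.005)
    x_cgi_oocyte: float = 0.02
    x_cgi_somatic: float = 0.40
    contamination_fraction: float | Sequence[float] = 0.0
    non_cpg_sites: int = 150_000  # CHG and CHH calls per cell for the summary
    n_cgis_per_autosome_band: int = 1  # one hypo- and one hyper-domain CGI each
    n_x_cgis: int = 6
    cgi_cpgs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gdmrs is None:
            self.gdmrs = _auto_gdmrs(self)

    # -- derived geometry ---------------------------------------------------

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_autosomes)] + [self.x_chrom]

    @property
    def tiles_per_chromosome(self) -> int:
        return self.cpg_per_chromosome // 100

    def cpg_positions(self) -> dict[str, np.ndarray]:
        pos = (np.arange(self.cpg_per_chromosome, dtype=np.int64) + 1) * self.cpg_spacing
        return {c: pos.copy() for c in self.chromosomes}

    def validate(self) -> None:
        for name in ("p_hypo", "p_hyper", "global_ko_delta",
                     "x_cgi_oocyte", "x_cgi_somatic"):
            _check_fraction(name, getattr(self, name))
        self.oocyte_context.validate("oocyte_context")
        self.somatic_context.validate("somatic_context")
        if self.hypo_block_tiles < 1 or self.hyper_block_tiles < 1:
            raise ValueError("block lengths (hypo_block_tiles/hyper_block_tiles) must be >= 1")
        if self.n_cells_per_group < 1:
            raise ValueError("n_cells_per_group must be >= 1")
        _check_positive("coverage_rate", self.coverage_rate)
        _check_positive("mean_reads_per_site", self.mean_reads_per_site)
        for g in self.gdmrs:
            if g.chrom not in self.chromosomes:
                raise ValueError(f"gdmrs: region {g.name} on undeclared chromosome {g.chrom}")
            if g.cpg_index < 0 or g.cpg_index + g.n_cpgs > self.cpg_per_chromosome:
                raise ValueError(f"gdmrs: region {g.name} outside the CpG map")
            _check_fraction(f"gdmrs[{g.name}].wt_level", g.wt_level)
            if not 0 <= g.wt_level - g.ko_delta <= 1:
                raise ValueError(f"gdmrs: {g.name} knockout level outside [0, 1]")
        for f in np.atleast_1d(np.asarray(self.contamination_fraction, dtype=float)):
            _check_fraction("contamination_fraction", float(f))

    def contamination_per_cell(self) -> np.ndarray:
        n = 2 * self.n_cells_per_group
        f = np.asarray(self.contamination_fraction, dtype=float)
        if f.ndim == 0:
            return np.full(n, float(f))
        if len(f) != n:
            raise ValueError(
                f"contamination_fraction: expected scalar or length {n}, got {len(f)}"
            )
        return f


def _tile_labels(spec: MethylomeSimSpec) -> np.ndarray:
    """Per-tile True where hypermethylated, for one chromosome."""
    period = spec.hypo_block_tiles + spec.hyper_block_tiles
    t = np.arange(spec.tiles_per_chromosome)
    return (t % period) >= spec.hypo_block_tiles


def _site_levels(spec: MethylomeSimSpec):
    """Per-chromosome site-level methylation for the three profiles
    (oocyte WT, oocyte KO, somatic) plus the CGI/gDMR region table."""
    n = spec.cpg_per_chromosome
    hyper_tiles = _tile_labels(spec)
    hyper_sites = np.repeat(hyper_tiles, 100)
    pad = n - len(hyper_sites)
    if pad > 0:  # trailing CpGs beyond full tiles keep the hypo level
        hyper_sites = np.concatenate([hyper_sites, np.zeros(pad, dtype=bool)])

    base = np.where(hyper_sites, spec.p_hyper, spec.p_hypo)
    ko_base = np.where(
        hyper_sites, np.clip(spec.p_hyper - spec.global_ko_delta, 0, 1), spec.p_hypo
    )

    wt: dict[str, np.ndarray] = {}
    ko: dict[str, np.ndarray] = {}
    som: dict[str, np.ndarray] = {}
    regions: list[dict] = []
    pos0 = spec.cpg_spacing  # position of CpG index 0

    def span(i0: int, n_cpgs: int) -> tuple[int, int]:
        return pos0 + i0 * spec.cpg_spacing, pos0 + (i0 + n_cpgs - 1) * spec.cpg_spacing

    tiles_per = spec.tiles_per_chromosome
    for chrom in spec.chromosomes:
        wt[chrom] = base.copy()
        ko[chrom] = ko_base.copy()
        som[chrom] = np.full(n, spec.somatic_context.mcpg)

        is_x = chrom == spec.x_chrom
        if is_x:
            cgi_tiles = np.linspace(2, tiles_per - 3, spec.n_x_cgis).astype(int)
        else:
            # one CGI in a hypomethylated block, one in a hypermethylated block
            period = spec.hypo_block_tiles + spec.hyper_block_tiles
            cgi_tiles = np.array([2, 2 + spec.hypo_block_tiles + period])[
                : 2 * spec.n_cgis_per_autosome_band
            ]
        for k, tile in enumerate(cgi_tiles):
            i0 = int(tile) * 100 + 35
            start, end = span(i0, spec.cgi_cpgs)
            sl = slice(i0, i0 + spec.cgi_cpgs)
            if is_x:
                wt[chrom][sl] = spec.x_cgi_oocyte
                ko[chrom][sl] = spec.x_cgi_oocyte
                som[chrom][sl] = spec.x_cgi_somatic
            regions.append(
                dict(chrom=chrom, start=start, end=end,
                     name=f"CGI_{chrom}_{k + 1}", region_class="CGI", is_x=is_x)
            )

    for g in spec.gdmrs:
        sl = slice(g.cpg_index, g.cpg_index + g.n_cpgs)
        wt[g.chrom][sl] = g.wt_level
        ko[g.chrom][sl] = g.wt_level - g.ko_delta
        start, end = span(g.cpg_index, g.n_cpgs)
        regions.append(
            dict(chrom=g.chrom, start=start, end=end, name=g.name,
                 region_class="gDMR", is_x=g.chrom == spec.x_chrom)
        )

    # true domain annotation (merged blocks), for domain-restricted DMR tests
    period = spec.hypo_block_tiles + spec.hyper_block_tiles
    for chrom in spec.chromosomes:
        for b in range(int(np.ceil(tiles_per / period))):
            t0 = b * period
            hypo_end_tile = min(t0 + spec.hypo_block_tiles, tiles_per) - 1
            if t0 <= hypo_end_tile:
                start, _ = span(t0 * 100, 1)
                _, end = span(hypo_end_tile * 100 + 99, 1)
                regions.append(dict(chrom=chrom, start=start, end=end,
                                    name=f"hypo_{chrom}_{b}",
                                    region_class="hypo_domain", is_x=chrom == spec.x_chrom))
            h0 = t0 + spec.hypo_block_tiles
            hyper_end_tile = min(h0 + spec.hyper_block_tiles, tiles_per) - 1
            if h0 < tiles_per:
                start, _ = span(h0 * 100, 1)
                _, end = span(hyper_end_tile * 100 + 99, 1)
                regions.append(dict(chrom=chrom, start=start, end=end,
                                    name=f"hyper_{chrom}_{b}",
                                    region_class="hyper_domain", is_x=chrom == spec.x_chrom))

    return wt, ko, som, pd.DataFrame(regions)


def _zero_truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    k = rng.poisson(lam, size)
    zero = k == 0
    while zero.any():
        k[zero] = rng.poisson(lam, int(zero.sum()))
        zero = k == 0
    return k


def simulate_methylomes(
    spec: MethylomeSimSpec,
) -> tuple[list[CellMethylome], RegionSet, SimTruth]:
    """Draw per-cell sparse CpG methylomes under the spec's conditions.

    Each reference CpG is covered independently with probability
    ``coverage_rate / total_sites``; read depth at a covered site is
    zero-truncated Poisson. Each read comes from the somatic profile with the
    cell's contamination probability, else from the (genotype-specific)
    oocyte profile, and is methylated at the profile's site level. Context
    summaries: mCpG is the realised methylated fraction of the cell's CpG
    calls; mCHG/mCHH are binomial draws over ``non_cpg_sites`` calls at the
    contamination-mixed expected fractions.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    wt_p, ko_p, som_p, region_table = _site_levels(spec)
    positions = spec.cpg_positions()
    chroms = spec.chromosomes
    n_per = spec.cpg_per_chromosome
    total_sites = n_per * len(chroms)
    p_cov = min(spec.coverage_rate / total_sites, 1.0)
    fracs = spec.contamination_per_cell()

    ooc = {spec.groups[0]: wt_p, spec.groups[1]: ko_p}
    cells: list[CellMethylome] = []
    cell_rows = []
    idx = 0
    for group in spec.groups:
        for j in range(spec.n_cells_per_group):
            f = float(fracs[idx])
            frames = []
            meth_total = 0
            depth_total = 0
            for chrom in chroms:
                covered = np.flatnonzero(rng.random(n_per) < p_cov)
                depth = _zero_truncated_poisson(
                    rng, spec.mean_reads_per_site, len(covered)
                )
                n_som = rng.binomial(depth, f)
                meth = rng.binomial(n_som, som_p[chrom][covered]) + rng.binomial(
                    depth - n_som, ooc[group][chrom][covered]
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": positions[chrom][covered],
                            "meth": meth,
                            "unmeth": depth - meth,
                        }
                    )
                )
                meth_total += int(meth.sum())
                depth_total += int(depth.sum())
            mcpg = 100.0 * meth_total / max(depth_total, 1)
            p_chg = (1 - f) * spec.oocyte_context.mchg + f * spec.somatic_context.mchg
            p_chh = (1 - f) * spec.oocyte_context.mchh + f * spec.somatic_context.mchh
            mchg = 100.0 * rng.binomial(spec.non_cpg_sites, p_chg) / spec.non_cpg_sites
            mchh = 100.0 * rng.binomial(spec.non_cpg_sites, p_chh) / spec.non_cpg_sites
            cell_id = f"{group}_{j:02d}"
            cells.append(
                CellMethylome(
                    cell_id,
                    group,
                    pd.concat(frames, ignore_index=True)[SITE_COLUMNS],
                    ContextSummary(mcpg, mchg, mchh),
                )
            )
            cell_rows.append(
                dict(cell_id=cell_id, group=group, stage="", contamination=f)
            )
            idx += 1

    regions = RegionSet(region_table)
    # expected global (mean-of-tiles) difference implied by the planting
    tiled = slice(0, spec.tiles_per_chromosome * 100)
    exp_wt = np.mean([wt_p[c][tiled].reshape(-1, 100).mean(axis=1) for c in chroms])
    exp_ko = np.mean([ko_p[c][tiled].reshape(-1, 100).mean(axis=1) for c in chroms])
    truth = SimTruth(
        cells=pd.DataFrame(cell_rows),
        regions=pd.DataFrame(
            [
                dict(name=g.name, chrom=g.chrom, wt_level=g.wt_level,
                     planted_delta_pp=-100.0 * g.ko_delta)
                for g in spec.gdmrs
            ]
        ),
        features=pd.DataFrame(columns=["feature_id", "group", "log2_shift"]),
        extras={
            "expected_global_difference_pp": float(100.0 * (exp_ko - exp_wt)),
            "p_cov": p_cov,
        },
    )
    return cells, regions, truth


# ---------------------------------------------------------------------------
# Proteome simulation
# ---------------------------------------------------------------------------


@dataclass
class ProteomeSimSpec:
    """Log-normal proteome: log2 intensity = baseline + planted group shift
    + Normal(0, sd). Baselines are drawn once per protein from
    Uniform(baseline_range) under the spec seed unless given explicitly."""

    n_proteins: int = 3000
    n_samples_per_group: int = 4
    groups: tuple[str, ...] = ("WT", "KO")
    baseline_range: tuple[float, float] = (15.0, 25.0)
    baseline_log2_mean: np.ndarray | None = None  # per protein, optional
    sd: float | np.ndarray = 0.25  # per protein or scalar
    planted_effects: Sequence[tuple[str, str, float]] = ()  # (protein, group, shift)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.n_samples_per_group < 2:
            raise ValueError("n_samples_per_group must be >= 2")
        if np.any(np.asarray(self.sd) < 0):
            raise ValueError("sd must be >= 0")
        _check_fraction("missing_rate", self.missing_rate, upper_open=True)

    def protein_ids(self) -> list[str]:
        return [f"P{i + 1:05d}" for i in range(self.n_proteins)]


def simulate_proteome(spec: ProteomeSimSpec) -> tuple[AbundanceMatrix, SimTruth]:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    proteins = spec.protein_ids()
    pidx = {p: i for i, p in enumerate(proteins)}
    if spec.baseline_log2_mean is not None:
        baseline = np.asarray(spec.baseline_log2_mean, dtype=float)
        if len(baseline) != spec.n_proteins:
            raise ValueError("baseline_log2_mean length must equal n_proteins")
    else:
        baseline = rng.uniform(*spec.baseline_range, spec.n_proteins)
    sd = np.broadcast_to(np.asarray(spec.sd, dtype=float), (spec.n_proteins,))

    shift = {g: np.zeros(spec.n_proteins) for g in spec.groups}
    for prot, grp, delta in spec.planted_effects:
        if prot not in pidx:
            raise ValueError(f"planted_effects: unknown protein {prot!r}")
        if grp not in shift:
            raise ValueError(f"planted_effects: unknown group {grp!r}")
        shift[grp][pidx[prot]] += delta

    cols, data, design = [], [], {}
    for grp in spec.groups:
        mu = baseline + shift[grp]
        for k in range(spec.n_samples_per_group):
            samp = f"{grp}{k + 1}"
            log2 = rng.normal(mu, sd)
            data.append(2.0 ** log2)
            cols.append(samp)
            design[samp] = grp
    values = pd.DataFrame(np.column_stack(data), index=proteins, columns=cols)
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = values.mask(mask)

    truth = SimTruth(
        cells=pd.DataFrame(columns=["cell_id", "group", "stage", "contamination"]),
        regions=pd.DataFrame(columns=["name", "planted_delta_pp"]),
        features=pd.DataFrame(
            [dict(feature_id=p, group=g, log2_shift=d)
             for p, g, d in spec.planted_effects]
        ),
    )
    return AbundanceMatrix(values=values, design=pd.Series(design)), truth


# ---------------------------------------------------------------------------
# Transcriptome simulation
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSimSpec:
    """Negative-binomial transcriptome with NSN/SN marker modules.

    Counts ~ NB(mean x stage multiplier x 2**planted shift, dispersion).
    Stage multipliers apply to the matching marker module (SN markers are
    ``marker_multiplier``-fold up in SN cells, NSN markers in NSN cells).
    Planted shifts apply in knockout cells of both stages. The default cell
    layout mirrors the study's post-QC design: 4 WT + 4 KO NSN cells and
    6 WT + 2 KO SN cells.
    """

    n_genes: int = 2000
    n_markers_per_set: int = 20
    marker_multiplier: float = 10.0
    mean_log2_range: tuple[float, float] = (1.0, 8.0)
    marker_base_mean: float = 50.0
    dispersion: float = 0.1
    n_cells: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("NSN", "WT"): 4, ("NSN", "KO"): 4, ("SN", "WT"): 6, ("SN", "KO"): 2,
        }
    )
    planted_de: Sequence[tuple[str, float]] = ()  # (gene, log2 shift in KO)
    ko_group: str = "KO"
    seed: int = 0

    def validate(self) -> None:
        if np.any(np.asarray(self.dispersion) <= 0):
            raise ValueError("dispersion must be > 0")
        _check_positive("marker_multiplier", self.marker_multiplier)
        _check_positive("marker_base_mean", self.marker_base_mean)
        for key, n in self.n_cells.items():
            if n < 0:
                raise ValueError(f"n_cells[{key}] must be >= 0")

    def nsn_markers(self) -> list[str]:
        return [f"NSN_mk_{i + 1:02d}" for i in range(self.n_markers_per_set)]

    def sn_markers(self) -> list[str]:
        return [f"SN_mk_{i + 1:02d}" for i in range(self.n_markers_per_set)]

    def gene_ids(self) -> list[str]:
        n_other = self.n_genes - 2 * self.n_markers_per_set
        if n_other < 0:
            raise ValueError("n_genes smaller than the two marker modules")
        return (
            self.nsn_markers()
            + self.sn_markers()
            + [f"gene_{i + 1:04d}" for i in range(n_other)]
        )


def simulate_counts(spec: ExpressionSimSpec) -> tuple[CountMatrix, SimTruth]:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    gidx = {g: i for i, g in enumerate(genes)}
    n_mark = spec.n_markers_per_set

    base = np.empty(len(genes))
    base[: 2 * n_mark] = spec.marker_base_mean
    base[2 * n_mark:] = 2.0 ** rng.uniform(*spec.mean_log2_range, len(genes) - 2 * n_mark)

    ko_shift = np.zeros(len(genes))
    for gene, delta in spec.planted_de:
        if gene not in gidx:
            raise ValueError(f"planted_de: unknown gene {gene!r}")
        ko_shift[gidx[gene]] += delta

    disp = np.broadcast_to(np.asarray(spec.dispersion, dtype=float), (len(genes),))
    r = 1.0 / disp

    cols, data, meta = [], [], []
    for (stage, genotype), n in spec.n_cells.items():
        mult = np.ones(len(genes))
        if stage == "NSN":
            mult[:n_mark] = spec.marker_multiplier
        elif stage == "SN":
            mult[n_mark: 2 * n_mark] = spec.marker_multiplier
        mu = base * mult
        if genotype == spec.ko_group:
            mu = mu * 2.0 ** ko_shift
        for k in range(n):
            cell = f"{stage}_{genotype}_{k:02d}"
            counts = rng.negative_binomial(r, r / (r + mu))
            data.append(counts)
            cols.append(cell)
            meta.append(dict(cell_id=cell, group=genotype, stage=stage))
    if not cols:
        raise ValueError("n_cells sums to zero; nothing to simulate")
    counts = pd.DataFrame(
        np.column_stack(data).astype(np.int64), index=genes, columns=cols
    )
    cells = pd.DataFrame(meta).set_index("cell_id")

    truth = SimTruth(
        cells=cells.reset_index().assign(contamination=0.0),
        regions=pd.DataFrame(columns=["name", "planted_delta_pp"]),
        features=pd.DataFrame(
            [dict(feature_id=g, group=spec.ko_group, log2_shift=d)
             for g, d in spec.planted_de]
        ),
    )
    return CountMatrix(counts=counts, cells=cells), truth
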