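"""Single-cell bisulfite (scPBAT) methylome analysis.

Per-cell CpG calls (Bismark coverage dialect, 1-based) are the input unit.
The workflow: read-count QC and a three-criterion somatic-contamination
screen (X-chromosome CpG-island methylation, cytosine-context ratios,
bimodality of 100-CpG tile methylation), pseudo-bulking of retained cells,
quantification over contiguous 100-CpG tiles and annotated regions,
segmentation into hypo-/hypermethylated domains, and chi-square differential
methylation with Benjamini-Hochberg adjustment.

Oocyte methylomes are bimodal -- hypermethylated domains near 75-100% and
hypomethylated domains near 0-25% -- with unusually high non-CpG (CHG/CHH)
methylation and hypomethylated X-chromosome CpG islands; somatic contaminants
break all three signatures at once, which is what the screen exploits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContextSummary",
    "CellMethylome",
    "TileSet",
    "TileCounts",
    "RegionSet",
    "CoverageParseError",
    "read_coverage",
    "write_coverage",
    "qc_read_filter",
    "qc_x_cgi",
    "qc_context",
    "qc_bimodality",
    "screen_cells",
    "pseudobulk",
    "build_tiles",
    "quantify_tiles",
    "segment_domains",
    "chi_square_2x2",
    "call_dmrs",
    "quantify_regions",
    "test_gdmrs",
    "filter_hyper_cgis",
    "global_methylation",
    "compare_global_methylation",
]

SITE_COLUMNS = ["chrom", "pos", "meth", "unmeth"]


class ContextSummary(NamedTuple):
    """Aligner-reported methylated-cytosine percentages per context."""

    mcpg: float
    mchg: float
    mchh: float


@dataclass
class CellMethylome:
    """CpG site calls for one cell (or one pseudo-bulked group)."""

    cell_id: str
    group: str
    sites: pd.DataFrame = field(repr=False)
    context: ContextSummary | None = None

    def __post_init__(self) -> None:
        self.sites = self.sites[SITE_COLUMNS].reset_index(drop=True)
        if len(self.sites):
            bad = (
                (self.sites["meth"] < 0)
                | (self.sites["unmeth"] < 0)
                | (self.sites["meth"] + self.sites["unmeth"] < 1)
            )
            if bad.any():
                raise ValueError(
                    f"cell {self.cell_id!r}: invalid counts at row {int(bad.idxmax())}"
                )
        if self.context is not None and not all(
            0 <= v <= 100 for v in self.context
        ):
            raise ValueError(f"cell {self.cell_id!r}: context percentages outside [0,100]")

    @property
    def n_cpgs_covered(self) -> int:
        return len(self.sites)

    @property
    def total_calls(self) -> int:
        return int((self.sites["meth"] + self.sites["unmeth"]).sum())


class CoverageParseError(ValueError):
    pass


def read_coverage(
    path,
    cell_id: str | None = None,
    group: str = "",
    context: ContextSummary | None = None,
) -> CellMethylome:
    """Parse a Bismark-style coverage file.

    Tab-separated, six columns: chrom, start, end, methylation percentage,
    methylated count, unmethylated count; 1-based positions. The percentage
    column is ignored and recomputed from the counts downstream.
    """
    name = cell_id if cell_id is not None else str(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=None, dtype=str, comment=None)
    except pd.errors.EmptyDataError:
        empty = pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                              zip(SITE_COLUMNS, [str, np.int64, np.int64, np.int64])})
        return CellMethylome(name, group, empty, context)
    if raw.shape[1] != 6:
        raise CoverageParseError(
            f"{path}: expected 6 tab-separated columns, found {raw.shape[1]}"
        )
    numeric = raw[[1, 4, 5]].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        raise CoverageParseError(f"{path}: malformed line {int(bad.idxmax()) + 1}")
    sites = pd.DataFrame(
        {
            "chrom": raw[0].to_numpy(),
            "pos": numeric[1].astype(np.int64).to_numpy(),
            "meth": numeric[4].astype(np.int64).to_numpy(),
            "unmeth": numeric[5].astype(np.int64).to_numpy(),
        }
    )
    try:
        return CellMethylome(name, group, sites, context)
    except ValueError as exc:
        raise CoverageParseError(f"{path}: {exc}") from exc


def write_coverage(cell: CellMethylome, path) -> None:
    """Emit the Bismark coverage dialect (start == end == CpG position)."""
    s = cell.sites
    total = (s["meth"] + s["unmeth"]).to_numpy()
    pct = np.where(total > 0, 100.0 * s["meth"].to_numpy() / np.maximum(total, 1), 0.0)
    out = pd.DataFrame(
        {
            0: s["chrom"],
            1: s["pos"],
            2: s["pos"],
            3: np.round(pct, 6),
            4: s["meth"],
            5: s["unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------


@dataclass
class RegionSet:
    """Named annotated intervals (CGIs, gDMRs, hypo/hyper domains).

    Intervals are stored 1-based inclusive; BED input (0-based half-open) is
    converted on read. ``region_class`` is one of ``CGI``, ``gDMR``,
    ``hypo_domain``, ``hyper_domain``; ``is_x`` flags X-chromosome regions.
    """

    table: pd.DataFrame  # chrom, start, end, name, region_class, is_x

    COLUMNS = ["chrom", "start", "end", "name", "region_class", "is_x"]

    def __post_init__(self) -> None:
        t = self.table[self.COLUMNS].reset_index(drop=True)
        if (t["end"] < t["start"]).any():
            raise ValueError("region end precedes start")
        gdmr = t[t["region_class"] == "gDMR"]
        if gdmr["name"].duplicated().any():
            raise ValueError("gDMR names must be unique")
        self.table = t

    def subset(self, region_class: str, x_only: bool = False) -> "RegionSet":
        t = self.table[self.table["region_class"] == region_class]
        if x_only:
            t = t[t["is_x"]]
        return RegionSet(t.copy())

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_bed(cls, path, x_chroms: Sequence[str] = ("chrX", "X")) -> "RegionSet":
        """Read `chrom  start  end  name  class` BED (0-based half-open)."""
        t = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "region_class"],
        )
        t["start"] = t["start"].astype(np.int64) + 1  # to 1-based inclusive
        t["end"] = t["end"].astype(np.int64)
        t["is_x"] = t["chrom"].isin(list(x_chroms))
        return cls(t)

    def to_bed(self, path) -> None:
        t = self.table.copy()
        t["start"] = t["start"] - 1
        t[["chrom", "start", "end", "name", "region_class"]].to_csv(
            path, sep="\t", header=False, index=False
        )


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------


class TileCounts(NamedTuple):
    """Aggregated per-tile methylated/unmethylated call counts for one entity."""

    meth: np.ndarray
    unmeth: np.ndarray

    @property
    def calls(self) -> np.ndarray:
        return self.meth + self.unmeth


class TileSet:
    """Ordered, non-overlapping windows of exactly 100 consecutive reference
    CpGs per chromosome; trailing partial windows are dropped.

    Tile spans run from the first to the last contained CpG position
    (1-based inclusive).
    """

    TILE_CPGS = 100

    def __init__(self, cpg_map: dict[str, np.ndarray], tile_cpgs: int | None = None):
        if tile_cpgs is not None:
            self.TILE_CPGS = int(tile_cpgs)
        self._pos: dict[str, np.ndarray] = {}
        self._offset: dict[str, int] = {}
        records = []
        offset = 0
        for chrom, pos in cpg_map.items():
            pos = np.asarray(pos, dtype=np.int64)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"CpG positions on {chrom} are not strictly increasing")
            n_tiles = len(pos) // self.TILE_CPGS
            tiled = pos[: n_tiles * self.TILE_CPGS]
            self._pos[chrom] = tiled
            self._offset[chrom] = offset
            for i in range(n_tiles):
                block = tiled[i * self.TILE_CPGS : (i + 1) * self.TILE_CPGS]
                records.append((chrom, int(block[0]), int(block[-1])))
            offset += n_tiles
        self.n_tiles = offset
        self.tiles = pd.DataFrame(records, columns=["chrom", "start", "end"])

    def count_calls(self, sites: pd.DataFrame) -> TileCounts:
        """Sum a cell's (or pseudo-bulk's) calls into tiles; sites absent from
        the reference CpG map or in dropped trailing windows are ignored."""
        meth = np.zeros(self.n_tiles, dtype=np.int64)
        unmeth = np.zeros(self.n_tiles, dtype=np.int64)
        for chrom, sub in sites.groupby("chrom", sort=False):
            tiled = self._pos.get(chrom)
            if tiled is None or not len(tiled):
                continue
            pos = sub["pos"].to_numpy()
            i = np.searchsorted(tiled, pos)
            ok = (i < len(tiled)) & (tiled[np.minimum(i, len(tiled) - 1)] == pos)
            tile = self._offset[chrom] + i[ok] // self.TILE_CPGS
            np.add.at(meth, tile, sub["meth"].to_numpy()[ok])
            np.add.at(unmeth, tile, sub["unmeth"].to_numpy()[ok])
        return TileCounts(meth, unmeth)


def build_tiles(cpg_map: dict[str, np.ndarray], tile_cpgs: int = 100) -> TileSet:
    """Build the 100-CpG tile map from sorted reference CpG positions."""
    return TileSet(cpg_map, tile_cpgs=tile_cpgs)


def quantify_tiles(
    tileset: TileSet, counts: TileCounts, min_calls: int = 30
) -> np.ndarray:
    """Pooled percent methylation per tile; NaN where calls < ``min_calls``."""
    if min_calls < 1:
        raise ValueError("min_calls must be >= 1")
    total = counts.calls.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * counts.meth / total
    pct[total < min_calls] = np.nan
    return pct


# ---------------------------------------------------------------------------
# QC screen
# ---------------------------------------------------------------------------


def qc_read_filter(cell: CellMethylome, min_cpgs: int = 600_000) -> bool:
    """Coverage filter: pass iff at least ``min_cpgs`` CpGs are covered."""
    return cell.n_cpgs_covered >= min_cpgs


def _pooled_percent(sites: pd.DataFrame) -> tuple[float, int]:
    calls = int((sites["meth"] + sites["unmeth"]).sum())
    if calls == 0:
        return float("nan"), 0
    return 100.0 * float(sites["meth"].sum()) / calls, calls


def _sites_in_regions(sites: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    keep = []
    for chrom, sub in sites.groupby("chrom", sort=False):
        reg = regions[regions["chrom"] == chrom]
        if reg.empty:
            continue
        pos = sub["pos"].to_numpy()
        mask = np.zeros(len(sub), dtype=bool)
        for start, end in zip(reg["start"], reg["end"]):
            mask |= (pos >= start) & (pos <= end)
        keep.append(sub[mask])
    if not keep:
        return sites.iloc[0:0]
    return pd.concat(keep)


def qc_x_cgi(
    cell: CellMethylome, regions: RegionSet, max_percent: float = 10.0
) -> tuple[float, str]:
    """Criterion 1: pooled methylation over X-chromosome CpG islands.

    Contaminated iff the pooled percentage strictly exceeds ``max_percent``
    (oocyte X CGIs are hypomethylated; somatic ones are not). With zero calls
    over X CGIs the verdict is ``untestable``.
    """
    x_cgis = regions.subset("CGI", x_only=True)
    hit = _sites_in_regions(cell.sites, x_cgis.table)
    pct, calls = _pooled_percent(hit)
    if calls == 0:
        return float("nan"), "untestable"
    return pct, ("contaminated" if pct > max_percent else "pass")


def qc_context(
    cell: CellMethylome,
    max_mcpg: float = 40.0,
    min_mchg: float = 3.0,
    min_mchh: float = 4.0,
) -> str:
    """Criterion 2: cytosine-context ratios from the aligner QC summary.

    Oocytes show mCpG < 40%, mCHG > 3% and mCHH > 4% (all strict); somatic
    DNA has high mCpG and near-zero non-CpG methylation.
    """
    if cell.context is None:
        return "untestable"
    c = cell.context
    ok = (c.mcpg < max_mcpg) and (c.mchg > min_mchg) and (c.mchh > min_mchh)
    return "pass" if ok else "contaminated"


def qc_bimodality(
    cell: CellMethylome,
    tileset: TileSet,
    min_calls: int = 5,
    min_informative: int = 50,
    max_mid: float = 0.20,
    min_low: float = 0.05,
    min_high: float = 0.05,
) -> tuple[float, str]:
    """Criterion 3: bimodality of the per-cell 100-CpG tile histogram.

    Over tiles with >= ``min_calls`` calls, the fractions of tiles at <= 25%
    (low), >= 75% (high) and in between (mid) are computed; a normal oocyte
    peaks at 0% and 100%, so the cell passes iff mid <= ``max_mid`` and both
    tails hold at least ``min_low``/``min_high`` of tiles. Fewer than
    ``min_informative`` informative tiles -> ``untestable``.
    """
    pct = quantify_tiles(tileset, tileset.count_calls(cell.sites), min_calls)
    pct = pct[np.isfinite(pct)]
    if len(pct) < min_informative:
        return float("nan"), "untestable"
    low = float(np.mean(pct <= 25))
    high = float(np.mean(pct >= 75))
    mid = 1.0 - low - high
    ok = (mid <= max_mid) and (low >= min_low) and (high >= min_high)
    return mid, ("pass" if ok else "contaminated")


def screen_cells(
    cells: Iterable[CellMethylome],
    regions: RegionSet,
    tileset: TileSet,
    min_cpgs: int = 600_000,
    bimodality_min_calls: int = 5,
) -> tuple[list[CellMethylome], pd.DataFrame]:
    """Apply the read-count filter and all three contamination criteria.

    A cell is retained iff the read filter passes and every contamination
    criterion passes; ``untestable`` criteria exclude the cell conservatively.
    Cells failing the read filter are not evaluated for contamination
    (criteria reported as ``not_tested``). Returns the retained cells and a
    per-cell report with each criterion's value and verdict.
    """
    retained: list[CellMethylome] = []
    rows = []
    for cell in cells:
        reads_ok = qc_read_filter(cell, min_cpgs)
        row: dict[str, object] = {
            "cell_id": cell.cell_id,
            "group": cell.group,
            "n_cpgs_covered": cell.n_cpgs_covered,
            "read_filter": "pass" if reads_ok else "fail",
        }
        if reads_ok:
            x_pct, x_status = qc_x_cgi(cell, regions)
            ctx_status = qc_context(cell)
            mid, bim_status = qc_bimodality(
                cell, tileset, min_calls=bimodality_min_calls
            )
            keep = all(s == "pass" for s in (x_status, ctx_status, bim_status))
        else:
            x_pct, mid = float("nan"), float("nan")
            x_status = ctx_status = bim_status = "not_tested"
            keep = False
        row.update(
            x_cgi_percent=x_pct,
            x_cgi=x_status,
            context=ctx_status,
            mid_fraction=mid,
            bimodality=bim_status,
            retained=keep,
        )
        rows.append(row)
        if keep:
            retained.append(cell)
    return retained, pd.DataFrame(rows)


def pseudobulk(cells: Sequence[CellMethylome], group: str | None = None) -> CellMethylome:
    """Sum per-site calls across cells (optionally restricted to one group)."""
    use = [c for c in cells if group is None or c.group == group]
    if not use:
        raise ValueError(f"no cells to pseudo-bulk (group={group!r})")
    merged = (
        pd.concat([c.sites for c in use], ignore_index=True)
        .groupby(["chrom", "pos"], as_index=False, sort=True)[["meth", "unmeth"]]
        .sum()
    )
    label = group if group is not None else use[0].group
    return CellMethylome(f"pseudobulk_{label}", label, merged[SITE_COLUMNS])


# ---------------------------------------------------------------------------
# Domains and differential methylation
# ---------------------------------------------------------------------------


def segment_domains(
    tileset: TileSet,
    percents: np.ndarray,
    hypo_band: tuple[float, float] = (0.0, 25.0),
    hyper_band: tuple[float, float] = (75.0, 100.0),
) -> RegionSet:
    """Merge consecutive informative tiles into hypo-/hypermethylated domains.

    Bands are closed intervals as conventionally printed (0-25% and 75-100%);
    runs break at chromosome boundaries, missing tiles, or mid-range tiles.
    """
    t = tileset.tiles
    labels = np.full(len(t), "", dtype=object)
    finite = np.isfinite(percents)
    labels[finite & (percents >= hypo_band[0]) & (percents <= hypo_band[1])] = "hypo_domain"
    labels[finite & (percents >= hyper_band[0]) & (percents <= hyper_band[1])] = "hyper_domain"

    records = []
    counter = 0
    i = 0
    chroms = t["chrom"].to_numpy()
    while i < len(t):
        lab = labels[i]
        if lab == "":
            i += 1
            continue
        j = i
        while j + 1 < len(t) and labels[j + 1] == lab and chroms[j + 1] == chroms[i]:
            j += 1
        counter += 1
        records.append(
            dict(
                chrom=chroms[i],
                start=int(t["start"].iloc[i]),
                end=int(t["end"].iloc[j]),
                name=f"{lab}_{counter}",
                region_class=lab,
                is_x=False,
            )
        )
        i = j + 1
    cols = RegionSet.COLUMNS
    return RegionSet(pd.DataFrame(records, columns=cols))


def chi_square_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) for the table
    [[a, b], [c, d]], via the closed form N(ad-bc)^2 / product of margins."""
    counts = np.array([a, b, c, d], dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    n = counts.sum()
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("degenerate margin: a row or column sums to zero")
    chi2 = n * (a * d - b * c) ** 2 / margins
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def _chi2_vectorized(ma, ua, mb, ub):
    ma, ua, mb, ub = (np.asarray(x, dtype=float) for x in (ma, ua, mb, ub))
    n = ma + ua + mb + ub
    margins = (ma + ua) * (mb + ub) * (ma + mb) * (ua + ub)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = n * (ma * ub - ua * mb) ** 2 / margins
    chi2 = np.where(margins > 0, chi2, 0.0)
    return chi2, stats.chi2.sf(chi2, df=1)


def _tiles_within(tileset: TileSet, regions: RegionSet) -> np.ndarray:
    """Boolean mask of tiles fully contained in some region of ``regions``."""
    mask = np.zeros(tileset.n_tiles, dtype=bool)
    t = tileset.tiles
    for chrom, reg in regions.table.groupby("chrom"):
        sel = t["chrom"] == chrom
        if not sel.any():
            continue
        reg = reg.sort_values("start")
        starts = reg["start"].to_numpy()
        ends = reg["end"].to_numpy()
        ts = t.loc[sel, "start"].to_numpy()
        te = t.loc[sel, "end"].to_numpy()
        idx = np.searchsorted(starts, ts, side="right") - 1
        ok = (idx >= 0) & (ends[np.maximum(idx, 0)] >= te)
        mask[np.flatnonzero(sel.to_numpy())[ok]] = True
    return mask


def call_dmrs(
    tileset: TileSet,
    counts_a: TileCounts,
    counts_b: TileCounts,
    alpha: float = 0.05,
    min_diff: float = 25.0,
    min_calls: int = 30,
    domain_filter: RegionSet | None = None,
    group_labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Per-tile chi-square differential methylation between two pseudo-bulks.

    Tiles must meet ``min_calls`` in both groups (and, if ``domain_filter``
    is given, lie fully within a hypo-/hypermethylated domain) to enter the
    BH family. ``significant`` requires q < ``alpha`` and |delta| strictly
    > ``min_diff`` percentage points (delta = %B - %A).
    """
    pct_a = quantify_tiles(tileset, counts_a, min_calls)
    pct_b = quantify_tiles(tileset, counts_b, min_calls)
    tested = np.isfinite(pct_a) & np.isfinite(pct_b)
    if domain_filter is not None:
        tested &= _tiles_within(tileset, domain_filter)

    la, lb = group_labels
    out = tileset.tiles.copy()
    out[f"percent_{la}"] = pct_a
    out[f"percent_{lb}"] = pct_b
    out["delta"] = pct_b - pct_a
    out[f"calls_{la}"] = counts_a.calls
    out[f"calls_{lb}"] = counts_b.calls
    out["tested"] = tested
    out["chi2"] = np.nan
    out["p"] = np.nan
    out["q"] = np.nan
    if tested.any():
        chi2, p = _chi2_vectorized(
            counts_a.meth[tested], counts_a.unmeth[tested],
            counts_b.meth[tested], counts_b.unmeth[tested],
        )
        out.loc[tested, "chi2"] = chi2
        out.loc[tested, "p"] = p
        out.loc[tested, "q"] = multipletests(p, method="fdr_bh")[1]
    out["significant"] = (
        (out["q"] < alpha) & (out["delta"].abs() > min_diff)
    ).fillna(False)
    return out


def quantify_regions(
    regions: RegionSet, bulk: CellMethylome, min_calls: int = 20
) -> pd.DataFrame:
    """Pooled percent methylation per region; NaN below ``min_calls``.

    Also reports calls per kilobase of region length (1-based inclusive
    span), used by the gDMR coverage filter.
    """
    if min_calls < 1:
        raise ValueError("min_calls must be >= 1")
    rows = []
    for _, reg in regions.table.iterrows():
        sub = bulk.sites[
            (bulk.sites["chrom"] == reg["chrom"])
            & (bulk.sites["pos"] >= reg["start"])
            & (bulk.sites["pos"] <= reg["end"])
        ]
        meth = int(sub["meth"].sum())
        unmeth = int(sub["unmeth"].sum())
        calls = meth + unmeth
        length_kb = (reg["end"] - reg["start"] + 1) / 1000.0
        rows.append(
            dict(
                name=reg["name"],
                chrom=reg["chrom"],
                start=reg["start"],
                end=reg["end"],
                region_class=reg["region_class"],
                meth=meth,
                unmeth=unmeth,
                calls=calls,
                calls_per_kb=calls / length_kb,
                percent=(100.0 * meth / calls) if calls >= min_calls else np.nan,
            )
        )
    return pd.DataFrame(rows)


def test_gdmrs(
    gdmrs: RegionSet,
    bulk_a: CellMethylome,
    bulk_b: CellMethylome,
    alpha: float = 0.05,
    min_diff: float = 25.0,
    min_calls: int = 20,
    min_density: float = 100.0,
    density_mode: str = "both",
    group_labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Chi-square differential methylation of germline DMRs.

    Quantification requires ``min_calls`` calls per gDMR; significance
    additionally requires the region to be highly covered, strictly more than
    ``min_density`` calls/kb in both groups (``density_mode='both'``, the
    default) or in at least one (``'either'``).
    """
    if density_mode not in ("both", "either"):
        raise ValueError("density_mode must be 'both' or 'either'")
    qa = quantify_regions(gdmrs, bulk_a, min_calls)
    qb = quantify_regions(gdmrs, bulk_b, min_calls)
    la, lb = group_labels
    out = qa[["name", "chrom", "start", "end"]].copy()
    out[f"percent_{la}"] = qa["percent"]
    out[f"percent_{lb}"] = qb["percent"]
    out["delta"] = qb["percent"] - qa["percent"]
    out[f"calls_{la}"] = qa["calls"]
    out[f"calls_{lb}"] = qb["calls"]
    out[f"calls_per_kb_{la}"] = qa["calls_per_kb"]
    out[f"calls_per_kb_{lb}"] = qb["calls_per_kb"]
    tested = qa["percent"].notna() & qb["percent"].notna()
    out["tested"] = tested
    out["chi2"] = np.nan
    out["p"] = np.nan
    out["q"] = np.nan
    if tested.any():
        chi2, p = _chi2_vectorized(
            qa.loc[tested, "meth"], qa.loc[tested, "unmeth"],
            qb.loc[tested, "meth"], qb.loc[tested, "unmeth"],
        )
        out.loc[tested, "chi2"] = chi2
        out.loc[tested, "p"] = p
        out.loc[tested, "q"] = multipletests(p, method="fdr_bh")[1]
    dense_a = qa["calls_per_kb"] > min_density
    dense_b = qb["calls_per_kb"] > min_density
    dense = (dense_a & dense_b) if density_mode == "both" else (dense_a | dense_b)
    out["covered"] = dense
    out["significant"] = (
        (out["q"] < alpha) & (out["delta"].abs() > min_diff) & dense
    ).fillna(False)
    return out


def filter_hyper_cgis(
    cgis: RegionSet,
    percent_a: pd.Series,
    percent_b: pd.Series,
    threshold: float = 75.0,
) -> RegionSet:
    """Keep CpG islands methylated strictly above ``threshold`` percent in at
    least one of the two groups (percent Series indexed by CGI name)."""
    names = cgis.table["name"]
    keep = (
        percent_a.reindex(names).to_numpy() > threshold
    ) | (percent_b.reindex(names).to_numpy() > threshold)
    return RegionSet(cgis.table[np.nan_to_num(keep, nan=False).astype(bool)].copy())


def global_methylation(
    cells: Sequence[CellMethylome], tileset: TileSet, min_calls: int = 5
) -> pd.DataFrame:
    """Per-cell global methylation: the unweighted mean percent methylation
    of all informative (>= ``min_calls`` calls) 100-CpG tiles.

    Cells with zero informative tiles are excluded with a warning.
    """
    rows = []
    for cell in cells:
        pct = quantify_tiles(tileset, tileset.count_calls(cell.sites), min_calls)
        pct = pct[np.isfinite(pct)]
        if len(pct) == 0:
            warnings.warn(
                f"cell {cell.cell_id!r} has no informative tiles; excluded",
                stacklevel=2,
            )
            continue
        rows.append(
            dict(
                cell_id=cell.cell_id,
                group=cell.group,
                n_informative_tiles=len(pct),
                global_percent=float(pct.mean()),
            )
        )
    return pd.DataFrame(rows)


def compare_global_methylation(
    per_cell: pd.DataFrame, group_a: str, group_b: str
) -> tuple[float, float]:
    """Welch t-test on per-cell global methylation between two groups.

    Returns (difference of group medians, B minus A, in percentage points;
    Welch two-sided p-value). Requires >= 2 cells per group.
    """
    a = per_cell.loc[per_cell["group"] == group_a, "global_percent"].to_numpy()
    b = per_cell.loc[per_cell["group"] == group_b, "global_percent"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 cells per group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = float(stats.ttest_ind(b, a, equal_var=False).pvalue)
    if np.isnan(p):  # both groups constant: no evidence unless means differ
        p = 1.0 if np.isclose(b.mean(), a.mean()) else 0.0
    return float(np.median(b) - np.median(a)), p
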