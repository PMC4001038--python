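"""Barcoded mutant-pool fitness from tag hybridization intensities.

Each mutant carries a TagModule with two unique barcodes (uptag, downtag)
whose array hybridization intensity is a proxy for strain abundance. Strain
fitness is the difference of mean log2 tag intensities, END minus START, of
one pooled growth competition — equivalently log2 of the fold change in
relative strain abundance. The pipeline then excludes low-START strains,
median-centres each pool, averages strains into gene fitness, removes
chromosomal-position trends with a running median, re-centres the mode at
zero, and reports two data-quality correlations (shared-strain and
same-operon adjacent-gene).
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .genome_annotation import GenomeAnnotation

logger = logging.getLogger(__name__)

STRAIN_FITNESS_COLUMNS = ["strain_id", "pool", "fitness", "start_mean", "included"]
DEFAULT_POSITION_WINDOW = 251
KDE_GRID_POINTS = 512


@dataclass
class IntensityTable:
    """Per-tag log2 hybridization intensities for one sample (condition + phase)."""

    sample_id: str
    intensities: pd.Series  # index tag_id, values log2 intensity

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            raise ValueError(f"{self.sample_id}: duplicate tag_id")
        if not np.isfinite(self.intensities.to_numpy(dtype=float)).all():
            raise ValueError(f"{self.sample_id}: non-finite intensity")

    def __len__(self) -> int:
        return len(self.intensities)


@dataclass(frozen=True)
class QualityReport:
    """Pool-agreement diagnostics for one condition.

    ``strain_correlation``: Pearson r of fitness for strains measured in both
    pools. ``operon_correlation``: Pearson r of gene fitness between adjacent
    same-operon genes. Either is None (undefined) with fewer than 3 pairs.
    Strong jackpot selection — a few strains dominating the culture — drives
    both down because most strains never get to grow.
    """

    strain_correlation: Optional[float]
    n_strain_pairs: int
    operon_correlation: Optional[float]
    n_operon_pairs: int

    def to_dict(self) -> dict:
        return {
            "strain_correlation": self.strain_correlation,
            "n_strain_pairs": self.n_strain_pairs,
            "operon_correlation": self.operon_correlation,
            "n_operon_pairs": self.n_operon_pairs,
        }


def strain_pools(pools: str) -> tuple[int, ...]:
    """Parse the strains-table ``pools`` field ('1', '2' or '1;2')."""
    return tuple(int(p) for p in str(pools).split(";") if p)


def strain_fitness(
    start: Mapping[int, IntensityTable],
    end: Mapping[int, IntensityTable],
    strains: pd.DataFrame,
) -> pd.DataFrame:
    """Per-strain, per-pool fitness = mean END log2 intensity − mean START.

    ``start``/``end`` map pool number -> IntensityTable. For each strain and
    each pool it belongs to, every tag (uptag and/or downtag) present in both
    that pool's START and END samples contributes; tag intensities are
    averaged within each sample before differencing. Strains with no tag
    measured in a pool's samples are dropped from that pool with a logged
    reason.
    """
    rows = []
    for pool, start_tab in start.items():
        if pool not in end:
            raise ValueError(f"pool {pool} present in START but not END")
        end_tab = end[pool]
        s_int, e_int = start_tab.intensities, end_tab.intensities
        for rec in strains.itertuples(index=False):
            if pool not in strain_pools(rec.pools):
                continue
            tags = [t for t in (rec.uptag_id, rec.downtag_id) if t in s_int.index and t in e_int.index]
            if not tags:
                logger.info(
                    "strain %s: no tag measured in pool %d START+END; excluded",
                    rec.strain_id,
                    pool,
                )
                continue
            start_mean = float(s_int[tags].mean())
            end_mean = float(e_int[tags].mean())
            rows.append(
                {
                    "strain_id": rec.strain_id,
                    "pool": pool,
                    "fitness": end_mean - start_mean,
                    "start_mean": start_mean,
                    "included": True,
                }
            )
    return pd.DataFrame(rows, columns=STRAIN_FITNESS_COLUMNS)


def filter_low_start(records: pd.DataFrame, theta: float) -> pd.DataFrame:
    """Exclude strains whose mean START log2 intensity falls below ``theta``.

    Low-START strains have unreliable ratios (their START signal is mostly
    background); they are retained in the table with ``included = False``.
    """
    out = records.copy()
    out["included"] = out["included"] & (out["start_mean"] >= theta)
    n_in, n_out = int(out["included"].sum()), int((~out["included"]).sum())
    logger.info("low-START filter at theta=%.3f: %d kept, %d excluded", theta, n_in, n_out)
    if n_in == 0:
        raise ValueError("empty pool: every strain excluded by the low-START filter")
    return out


def background_theta(start: Mapping[int, IntensityTable], quantile: float = 0.05) -> float:
    """Default low-START threshold: a low quantile of all START intensities."""
    allvals = np.concatenate([t.intensities.to_numpy(dtype=float) for t in start.values()])
    return float(np.quantile(allvals, quantile))


def normalize_strain_median(records: pd.DataFrame) -> pd.DataFrame:
    """Centre each pool's included strain-fitness distribution at median 0.

    Done separately per pool: the two pools are hybridized and amplified
    independently, so each carries its own multiplicative offset.
    """
    out = records.copy()
    for pool, grp in out.groupby("pool"):
        inc = grp.loc[grp["included"], "fitness"]
        if inc.empty:
            raise ValueError(f"pool {pool}: no included strains to normalize")
        out.loc[grp.index, "fitness"] = grp["fitness"] - float(inc.median())
    return out


def gene_fitness(
    records: pd.DataFrame,
    strains: pd.DataFrame,
    condition: str = "",
) -> pd.DataFrame:
    """Gene fitness ("mean log ratio"): unweighted mean over included strain
    measurements carrying an insertion in the gene, pools combined.

    Strains mapped to intergenic regions are aggregated per intergenic label
    and flagged so reports can separate them from genic calls.
    """
    merged = records.loc[records["included"]].merge(
        strains[["strain_id", "feature"]], on="strain_id", how="left"
    )
    grouped = (
        merged.groupby("feature")["fitness"].agg(["mean", "size"]).reset_index()
    )
    out = pd.DataFrame(
        {
            "gene_id": grouped["feature"],
            "fitness": grouped["mean"],
            "n_strains": grouped["size"].astype(int),
            "intergenic": grouped["feature"].str.startswith("intergenic:"),
        }
    )
    out["condition"] = condition
    return out.sort_values("gene_id", ignore_index=True)


def _kde_mode(values: np.ndarray, grid_points: int = KDE_GRID_POINTS) -> float:
    """Mode of a sample: argmax of a Gaussian KDE (Silverman bandwidth) on a
    fixed grid spanning the data. Deterministic, hence testable."""
    if len(values) < 2 or np.ptp(values) == 0:
        return float(values[0]) if len(values) else 0.0
    kde = stats.gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), grid_points)
    return float(grid[np.argmax(kde(grid))])


def normalize_position_mode(
    gene_records: pd.DataFrame,
    annotation: GenomeAnnotation,
    window: int = DEFAULT_POSITION_WINDOW,
) -> pd.DataFrame:
    """Remove chromosomal-position trends, then re-centre the mode at zero.

    Step 1: subtract a running median of gene fitness over a centred window
    of ``window`` genes in chromosome order (truncated at chromosome edges).
    The running median tracks broad positional biases — copy-number and
    replication-origin effects — while staying insensitive to isolated
    high-fitness outliers. Step 2: subtract the KDE mode so the typical
    (neutral) gene scores exactly 0. Intergenic rows receive only the mode
    shift.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    out = gene_records.copy()
    order = {gid: i for i, gid in enumerate(annotation.gene_ids)}
    chrom_of = {g.gene_id: g.chrom for g in annotation}
    genic = out[~out["intergenic"] & out["gene_id"].isin(order)].copy()
    if len(genic) < 3:
        warnings.warn("fewer than 3 genes: skipping position normalization")
    else:
        genic["_order"] = genic["gene_id"].map(order)
        genic["_chrom"] = genic["gene_id"].map(chrom_of)
        genic = genic.sort_values("_order")
        for _, grp in genic.groupby("_chrom"):
            run_med = (
                grp["fitness"]
                .rolling(window, center=True, min_periods=1)
                .median()
            )
            out.loc[grp.index, "fitness"] = grp["fitness"] - run_med
    mode = _kde_mode(out["fitness"].to_numpy(dtype=float))
    out["fitness"] = out["fitness"] - mode
    return out


def quality_metrics(
    records: pd.DataFrame,
    gene_records: pd.DataFrame,
    annotation: GenomeAnnotation,
    min_pairs: int = 3,
) -> QualityReport:
    """Shared-strain and same-operon adjacent-gene Pearson correlations."""
    inc = records.loc[records["included"]]
    wide = inc.pivot_table(index="strain_id", columns="pool", values="fitness")
    shared = wide.dropna()
    if shared.shape[1] == 2 and len(shared) >= min_pairs:
        r_strain = float(stats.pearsonr(shared[1], shared[2]).statistic)
        n_strain = len(shared)
    else:
        r_strain, n_strain = None, len(shared) if shared.shape[1] == 2 else 0

    fit = gene_records.set_index("gene_id")["fitness"]
    pairs = [
        (a, b)
        for a, b in annotation.adjacent_operon_pairs()
        if a in fit.index and b in fit.index
    ]
    if len(pairs) >= min_pairs:
        av = np.array([fit[a] for a, _ in pairs])
        bv = np.array([fit[b] for _, b in pairs])
        r_operon = float(stats.pearsonr(av, bv).statistic)
    else:
        r_operon = None
    return QualityReport(r_strain, n_strain, r_operon, len(pairs))


def run_barseq(
    start: Mapping[int, IntensityTable],
    end: Mapping[int, IntensityTable],
    strains: pd.DataFrame,
    annotation: GenomeAnnotation,
    theta: Optional[float] = None,
    window: int = DEFAULT_POSITION_WINDOW,
    condition: str = "",
    normalize: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, QualityReport]:
    """Full pool pipeline: strain fitness -> filters -> normalizations ->
    gene fitness -> quality metrics. ``theta=None`` uses the background
    quantile default; ``normalize=False`` skips all centring steps (useful
    for noise-free oracle comparisons)."""
    records = strain_fitness(start, end, strains)
    if theta is None:
        theta = background_theta(start)
    records = filter_low_start(records, theta)
    if normalize:
        records = normalize_strain_median(records)
    genes = gene_fitness(records, strains, condition=condition)
    if normalize:
        genes = normalize_position_mode(genes, annotation, window=window)
    quality = quality_metrics(records, genes, annotation)
    return records, genes, quality


def read_intensity_tsv(path: str | os.PathLike) -> dict[tuple[int, str], IntensityTable]:
    """Read the long-format intensity TSV (tag_id, pool, phase, log2_intensity)
    into IntensityTables keyed by (pool, phase)."""
    df = pd.read_csv(path, sep="\t", dtype={"tag_id": str, "pool": int, "phase": str})
    out = {}
    for (pool, phase), grp in df.groupby(["pool", "phase"]):
        series = pd.Series(
            grp["log2_intensity"].to_numpy(dtype=float), index=grp["tag_id"].to_numpy()
        )
        out[(int(pool), str(phase))] = IntensityTable(f"pool{pool}_{phase}", series)
    return out


def write_intensity_tsv(
    tables: Mapping[tuple[int, str], IntensityTable], path: str | os.PathLike
) -> None:
    frames = []
    for (pool, phase), tab in sorted(tables.items()):
        frames.append(
            pd.DataFrame(
                {
                    "tag_id": tab.intensities.index,
                    "pool": pool,
                    "phase": phase,
                    "log2_intensity": tab.intensities.to_numpy(dtype=float),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
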