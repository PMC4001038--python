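"""Pooled growth-competition simulator with known ground truth.

Generates every input the two fitness pipelines consume: a synthetic genome
with operon structure, a two-pool barcoded mutant library, a dense random
transposon insertion library, deterministic exponential growth competition,
log-normally noisy barcode-array intensities, and multinomially sampled
sequencing reads. Every strain's true relative growth rate is recorded so
parameter-recovery tests can compare pipeline output against truth.

Growth model: strain i with relative rate rho_i (1 = neutral) grows for D
reference doublings, a_i = x_i(0) * 2^(rho_i * D); END abundances are the
renormalized a_i. Under strong positive selection a handful of strains can
take over the culture — the jackpot effect seen when a few resistant
mutants predominate.

Randomness: one master seed; every sub-generator derives an independent
stream keyed by a fixed label, so components are reproducible in isolation.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .genome_annotation import Gene, GenomeAnnotation, map_position
from .barseq_fitness import IntensityTable
from .tnle_fitness import InsertionTable

STRAIN_COLUMNS = [
    "strain_id",
    "chrom",
    "position",
    "feature",
    "pools",
    "uptag_id",
    "downtag_id",
    "true_rate",
]


def _rng(seed: int, *key: str | int) -> np.random.Generator:
    """Independent deterministic stream for (master seed, component key)."""
    words = [int(seed) & 0x7FFFFFFF]
    for k in key:
        if isinstance(k, str):
            words.append(zlib.crc32(k.encode()) & 0x7FFFFFFF)
        else:
            words.append(int(k) & 0x7FFFFFFF)
    return np.random.default_rng(words)


class ConfigError(ValueError):
    pass


@dataclass
class ScenarioConfig:
    """Everything needed to regenerate one simulated study deterministically.

    ``conditions`` maps condition name -> {gene_id: selection coefficient s};
    genes absent from the mapping are neutral (s = 0) in that condition.
    ``doublings`` gives the reference population doublings D per condition.
    ``strain_effect_sd`` adds per-strain rate jitter on top of the gene
    effect (insertion-position-specific disruption strength); ``sigma`` is
    the log2 intensity noise; ``background`` the additive array background
    floor in linear intensity units.
    """

    seed: int = 0
    n_genes: int = 200
    mean_gene_length: int = 900
    gene_length_sd: int = 100
    min_gene_length: int = 600
    max_gene_length: int = 1500
    intergenic_gap: int = 150
    n1: int = 200
    n2: int = 200
    overlap: int = 50
    intergenic_fraction: float = 0.05
    strain_effect_sd: float = 0.0
    conditions: dict = field(default_factory=dict)
    doublings: dict = field(default_factory=dict)
    sigma: float = 0.3
    scale: float = 65536.0
    background: float = 0.0
    tnle_sites: int = 10000
    tnle_reads: int = 50000
    tnle_condition: str = ""
    growth_mode: str = "strain"  # "strain": fixed per-strain doublings; "population": yield-limited
    ensure_covered: list = field(default_factory=list)
    min_strains_per_covered: int = 2
    planted_positive: list = field(default_factory=list)
    planted_sick: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.overlap > min(self.n1, self.n2):
            raise ConfigError("overlap exceeds the smaller pool size")
        if self.sigma < 0:
            raise ConfigError("sigma must be >= 0")
        if any(d < 0 for d in self.doublings.values()):
            raise ConfigError("doublings must be >= 0")
        if self.n_genes < 1:
            raise ConfigError("need at least one gene")
        if self.tnle_reads < self.tnle_sites:
            raise ConfigError("tnle_reads must be >= tnle_sites")
        if self.growth_mode not in ("strain", "population"):
            raise ConfigError("growth_mode must be 'strain' or 'population'")

    def gene_selection(self, condition: str) -> dict[str, float]:
        if condition not in self.conditions:
            raise ConfigError(f"unknown condition {condition!r}")
        return self.conditions[condition]

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "ScenarioConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class AbundanceState:
    """Relative strain abundances before and after one growth competition."""

    ids: np.ndarray
    x_start: np.ndarray
    x_end: np.ndarray

    def __post_init__(self) -> None:
        for x in (self.x_start, self.x_end):
            if abs(float(np.sum(x)) - 1.0) > 1e-12:
                raise ValueError("abundances must sum to 1")

    def true_fitness(self) -> np.ndarray:
        """log2 fold change in relative abundance — the quantity both
        pipelines estimate."""
        return np.log2(self.x_end / self.x_start)


def build_genome(config: ScenarioConfig) -> GenomeAnnotation:
    """Non-overlapping genes on one chromosome, lengths ~ N(mean, sd) clipped,
    separated by the configured gap; operons are consecutive same-strand runs
    with geometric run lengths (mean 2)."""
    rng = _rng(config.seed, "genome")
    n = config.n_genes
    lengths = np.clip(
        np.rint(rng.normal(config.mean_gene_length, config.gene_length_sd, n)),
        config.min_gene_length,
        config.max_gene_length,
    ).astype(int)

    genes: list[Gene] = []
    pos = config.intergenic_gap + 1
    i = 0
    op = 0
    while i < n:
        run = min(int(rng.geometric(0.5)), n - i)
        strand = "+" if rng.random() < 0.5 else "-"
        operon_id = f"op{op:04d}" if run >= 2 else None
        op += run >= 2
        for _ in range(run):
            genes.append(
                Gene(
                    gene_id=f"g{i:04d}",
                    chrom="chr1",
                    start=pos,
                    end=pos + lengths[i] - 1,
                    strand=strand,
                    operon_id=operon_id,
                )
            )
            pos += lengths[i] + config.intergenic_gap
            i += 1
    chrom_len = genes[-1].end + config.intergenic_gap
    return GenomeAnnotation({"chr1": chrom_len}, genes)


def build_barcoded_library(
    annotation: GenomeAnnotation,
    n1: int,
    n2: int,
    overlap: int,
    seed: int,
    intergenic_fraction: float = 0.05,
    strain_effect_sd: float = 0.0,
    ensure_covered: Sequence[str] = (),
    min_strains_per_covered: int = 2,
) -> pd.DataFrame:
    """Two overlapping barcoded pools of insertion mutants.

    ``n1 + n2 - overlap`` distinct strains; exactly ``overlap`` of them are
    members of both pools (same TagModule read through its uptag in pool 1
    and its downtag in pool 2). Insertion positions are uniform over gene
    bodies, with ``intergenic_fraction`` of strains placed in intergenic
    gaps. ``ensure_covered`` genes are guaranteed at least
    ``min_strains_per_covered`` insertions. ``true_rate`` is the strain's
    relative growth rate under no selection: 1 plus an optional
    insertion-specific jitter (different insertion points disrupt a gene to
    different degrees).
    """
    if overlap > min(n1, n2):
        raise ConfigError("overlap exceeds the smaller pool size")
    rng = _rng(seed, "library")
    n_distinct = n1 + n2 - overlap

    genes = list(annotation)
    lengths = np.array([g.length for g in genes], dtype=float)
    starts = np.array([g.start for g in genes])
    chrom_len = annotation.chrom_lengths[genes[0].chrom]

    # intergenic gap intervals (1-based inclusive) and their cumulative span
    gaps: list[tuple[int, int]] = []
    prev = 0
    for g in genes:
        if g.start > prev + 1:
            gaps.append((prev + 1, g.start - 1))
        prev = max(prev, g.end)
    if chrom_len > prev:
        gaps.append((prev + 1, chrom_len))
    gap_lens = np.array([b - a + 1 for a, b in gaps], dtype=float)

    # reserved placements first, then uniform over gene bodies / gaps
    gene_idx_of: list[Optional[int]] = []
    positions: list[int] = []
    by_id = {g.gene_id: i for i, g in enumerate(genes)}
    for gid in ensure_covered:
        gi = by_id[gid]
        for _ in range(min_strains_per_covered):
            gene_idx_of.append(gi)
            positions.append(int(rng.integers(genes[gi].start, genes[gi].end + 1)))
    n_rest = n_distinct - len(positions)
    if n_rest < 0:
        raise ConfigError("more reserved strains than library size")
    for _ in range(n_rest):
        if gaps and rng.random() < intergenic_fraction:
            gene_idx_of.append(None)
            gi = int(rng.choice(len(gaps), p=gap_lens / gap_lens.sum()))
            positions.append(int(rng.integers(gaps[gi][0], gaps[gi][1] + 1)))
        else:
            gi = int(rng.choice(len(genes), p=lengths / lengths.sum()))
            gene_idx_of.append(gi)
            positions.append(int(rng.integers(genes[gi].start, genes[gi].end + 1)))

    perm = rng.permutation(n_distinct)
    pools = np.empty(n_distinct, dtype=object)
    pools[perm[:overlap]] = "1;2"
    pools[perm[overlap : n1]] = "1"
    pools[perm[n1:]] = "2"

    jitter = (
        rng.normal(0.0, strain_effect_sd, n_distinct)
        if strain_effect_sd > 0
        else np.zeros(n_distinct)
    )
    rates = np.maximum(1.0 + jitter, 0.05)

    rows = []
    chrom = genes[0].chrom
    for k in range(n_distinct):
        gi = gene_idx_of[k]
        if gi is not None and starts[gi] <= positions[k] <= genes[gi].end:
            feature = genes[gi].gene_id
        else:
            feature = map_position(annotation, chrom, positions[k]).label
        rows.append(
            {
                "strain_id": f"s{k:05d}",
                "chrom": chrom,
                "position": positions[k],
                "feature": feature,
                "pools": pools[k],
                "uptag_id": f"u{k:05d}",
                "downtag_id": f"d{k:05d}",
                "true_rate": rates[k],
            }
        )
    return pd.DataFrame(rows, columns=STRAIN_COLUMNS)


def strain_selection(
    strains: pd.DataFrame, selection: Mapping[str, float]
) -> np.ndarray:
    """Per-strain selection coefficient: the containing gene's s, 0 for
    intergenic strains and genes without an assigned effect."""
    return strains["feature"].map(lambda f: selection.get(f, 0.0)).to_numpy(float)


def simulate_competition(
    ids: Sequence[str],
    rates: np.ndarray,
    doublings: float,
    x_start: Optional[np.ndarray] = None,
) -> AbundanceState:
    """Deterministic exponential competition: a_i = x_i(0) * 2^(rho_i * D),
    renormalized. Computed in log space so extreme jackpot selection cannot
    overflow."""
    ids = np.asarray(ids)
    rates = np.asarray(rates, dtype=float)
    if doublings < 0:
        raise ValueError("doublings must be >= 0")
    if (rates <= 0).any():
        raise ValueError("relative growth rates must be > 0")
    if x_start is None:
        x_start = np.full(len(ids), 1.0 / len(ids))
    else:
        x_start = np.asarray(x_start, dtype=float)
        if (x_start <= 0).any():
            raise ValueError("all START abundances must be > 0")
        x_start = x_start / x_start.sum()
    log_a = np.log2(x_start) + rates * doublings
    log_a -= log_a.max()
    a = np.exp2(log_a)
    return AbundanceState(ids, x_start, a / a.sum())


def _log2_total_growth(x_start: np.ndarray, rates: np.ndarray, t: float) -> float:
    log_a = np.log2(x_start) + rates * t
    m = log_a.max()
    return float(m + np.log2(np.exp2(log_a - m).sum()))


def simulate_competition_to_yield(
    ids: Sequence[str],
    rates: np.ndarray,
    population_doublings: float,
    x_start: Optional[np.ndarray] = None,
) -> AbundanceState:
    """Competition in a yield-limited culture.

    The culture grows until TOTAL biomass has doubled ``population_doublings``
    times (the observable an OD curve measures), then stops: solve
    sum_i x_i(0) * 2^(rho_i * t) = 2^D for the shared growth time t and
    renormalize. Under jackpot selection the fastest strains consume the
    yield quickly, so every other strain receives far fewer effective
    doublings than it would in an unrestricted culture — the reason most
    strains "never get the opportunity to grow" in a strongly selective
    condition.
    """
    from scipy.optimize import brentq

    ids = np.asarray(ids)
    rates = np.asarray(rates, dtype=float)
    if population_doublings < 0:
        raise ValueError("doublings must be >= 0")
    if (rates <= 0).any():
        raise ValueError("relative growth rates must be > 0")
    if x_start is None:
        x_start = np.full(len(ids), 1.0 / len(ids))
    else:
        x_start = np.asarray(x_start, dtype=float)
        if (x_start <= 0).any():
            raise ValueError("all START abundances must be > 0")
        x_start = x_start / x_start.sum()
    if population_doublings == 0:
        return AbundanceState(ids, x_start, x_start.copy())
    hi = population_doublings / float(rates.min())
    t = brentq(
        lambda tt: _log2_total_growth(x_start, rates, tt) - population_doublings,
        0.0,
        hi + 1e-9,
        xtol=1e-12,
    )
    return simulate_competition(ids, rates, t, x_start)


def simulate_microarray(
    state: AbundanceState,
    strains: pd.DataFrame,
    pool: int,
    sigma: float,
    seed: int,
    scale: float = 65536.0,
    background: float = 0.0,
    mode: str = "array",
) -> dict[str, IntensityTable]:
    """Noisy barcode-array readout of one pool's START and END samples.

    Per tag, log2 intensity = log2(scale * x + background) + eps with
    eps ~ Normal(0, sigma). In "array" mode only the uptags of pool 1 and
    the downtags of pool 2 are amplified and hybridized (one tag suffices to
    quantify a strain, and the two pools' tags do not collide on the array);
    "full" mode emits both tags. Noise is drawn from a stream keyed by
    (seed, pool, phase) only, so different conditions at the same master
    seed see identical noise — common random numbers for paired
    condition-versus-control comparisons. The ``background`` floor
    compresses the signal of strains that failed to grow, which is what
    degrades pool agreement under jackpot selection.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    sub = strains.set_index("strain_id").loc[state.ids]
    if mode == "array":
        tag_cols = ["uptag_id"] if pool == 1 else ["downtag_id"]
    elif mode == "full":
        tag_cols = ["uptag_id", "downtag_id"]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out = {}
    for phase, x in (("START", state.x_start), ("END", state.x_end)):
        rng = _rng(seed, "array", pool, phase)
        tags, vals = [], []
        signal = np.log2(scale * x + background)
        for col in tag_cols:
            eps = rng.normal(0.0, sigma, len(x)) if sigma > 0 else 0.0
            tags.extend(sub[col].tolist())
            vals.extend(np.asarray(signal + eps).tolist())
        out[phase] = IntensityTable(
            f"pool{pool}_{phase}", pd.Series(vals, index=tags, dtype=float)
        )
    return out


def simulate_pool_experiment(
    strains: pd.DataFrame,
    config: ScenarioConfig,
    condition: str,
    mode: str = "array",
) -> tuple[dict[int, AbundanceState], dict[int, dict[str, IntensityTable]]]:
    """Grow both pools under one condition and read them out on the array.

    Each pool is a separate culture: abundances are normalized within the
    pool. Returns per-pool AbundanceStates (ground truth) and per-pool
    {START, END} intensity tables.
    """
    selection = config.gene_selection(condition)
    D = config.doublings[condition]
    states: dict[int, AbundanceState] = {}
    arrays: dict[int, dict[str, IntensityTable]] = {}
    for pool in (1, 2):
        members = strains[strains["pools"].map(lambda p: str(pool) in str(p).split(";"))]
        rates = members["true_rate"].to_numpy(float) + strain_selection(members, selection)
        compete = (
            simulate_competition_to_yield
            if config.growth_mode == "population"
            else simulate_competition
        )
        states[pool] = compete(
            members["strain_id"].to_numpy(), np.maximum(rates, 0.05), D
        )
        arrays[pool] = simulate_microarray(
            states[pool],
            members,
            pool,
            config.sigma,
            config.seed,
            scale=config.scale,
            background=config.background,
            mode=mode,
        )
    return states, arrays


def true_gene_fitness(
    strains: pd.DataFrame, states: Mapping[int, AbundanceState]
) -> pd.Series:
    """Ground-truth gene fitness: mean true strain fitness over every
    (strain, pool) measurement mapping to the gene — the same aggregation
    the pipeline performs, applied to the simulator's exact abundances."""
    frames = []
    feature = strains.set_index("strain_id")["feature"]
    for state in states.values():
        frames.append(
            pd.DataFrame(
                {"feature": feature.loc[state.ids].to_numpy(), "w": state.true_fitness()}
            )
        )
    return pd.concat(frames).groupby("feature")["w"].mean()


def simulate_tnle(
    annotation: GenomeAnnotation,
    selection: Mapping[str, float],
    doublings: float,
    n_sites: int,
    total_reads: int,
    seed: int,
    min_reads: int = 1,
) -> InsertionTable:
    """Dense random-insertion library grown under selection, then sequenced.

    ``n_sites`` unique positions uniform over the genome; each site inherits
    the selection coefficient of its containing gene (intergenic sites are
    neutral); reads are multinomial over sites with probabilities
    proportional to post-competition abundance. Only sites attracting at
    least ``min_reads`` reads are detected and reported — under strong
    selection most neutral lineages fall below the detection limit, which is
    how the jackpot reshapes the observed insertion density.
    """
    if n_sites < 1:
        raise ValueError("need at least one site")
    if total_reads < n_sites:
        raise ValueError("total_reads must be >= n_sites")
    rng = _rng(seed, "tnle")
    chrom = next(iter(annotation.chrom_lengths))
    chrom_len = annotation.chrom_lengths[chrom]
    positions = rng.choice(chrom_len, size=n_sites, replace=False) + 1
    positions.sort()
    strands = np.where(rng.random(n_sites) < 0.5, "+", "-")

    starts = np.array([g.start for g in annotation])
    ends = np.array([g.end for g in annotation])
    s_genes = np.array([selection.get(g.gene_id, 0.0) for g in annotation])
    idx = np.searchsorted(starts, positions, side="right") - 1
    inside = (idx >= 0) & (positions <= ends[np.clip(idx, 0, None)])
    s_sites = np.where(inside, s_genes[np.clip(idx, 0, None)], 0.0)

    state = simulate_competition(
        positions.astype(str), np.maximum(1.0 + s_sites, 0.05), doublings
    )
    reads = rng.multinomial(total_reads, state.x_end)
    keep = reads >= min_reads
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "position": positions[keep],
            "strand": strands[keep],
            "reads": reads[keep],
        }
    )
    return InsertionTable(df)


def summarize_library(strains: pd.DataFrame) -> dict:
    """Pool-composition accounting: pool sizes, shared strains, distinct
    strains, and how many genes are represented once / twice / three or more
    times across the whole library."""
    pools = strains["pools"].map(lambda p: set(str(p).split(";")))
    n1 = int(pools.map(lambda s: "1" in s).sum())
    n2 = int(pools.map(lambda s: "2" in s).sum())
    shared = int(pools.map(lambda s: s == {"1", "2"}).sum())
    genic = strains[~strains["feature"].str.startswith("intergenic:")]
    per_gene = genic.groupby("feature").size()
    return {
        "n_pool1": n1,
        "n_pool2": n2,
        "n_shared": shared,
        "n_distinct": len(strains),
        "genes_once": int((per_gene == 1).sum()),
        "genes_twice": int((per_gene == 2).sum()),
        "genes_three_plus": int((per_gene >= 3).sum()),
        "genes_covered": int(len(per_gene)),
        "intergenic_regions": int(
            strains.loc[
                strains["feature"].str.startswith("intergenic:"), "feature"
            ].nunique()
        ),
    }


NITRATE_CONDITIONS = ("NaNO3", "KNO3", "NaCl", "KCl", "NaNO2", "none")


def nitrate_scenario(seed: int = 1, **overrides) -> ScenarioConfig:
    """Canonical nitrate-resistance study: a 2400-gene genome where a
    contiguous 9-gene cluster plus a rex-like regulator carry strong positive
    selection (s in 2..4) under both nitrate salts, are neutral under the
    osmotic controls (NaCl, KCl), nitrite and no-stress conditions, and 2% of
    genes are mildly sick auxotroph analogues (s = -1) in the defined medium
    of every condition."""
    rng = _rng(seed, "scenario")
    n_genes = int(overrides.pop("n_genes", 2400))
    cluster = [f"g{i:04d}" for i in range(597, 606)]
    regulator = "g2102"
    planted = cluster + [regulator]
    s_pos = dict(zip(cluster, rng.uniform(2.0, 4.0, len(cluster))))
    s_pos[regulator] = 4.0

    candidates = [i for i in range(n_genes) if f"g{i:04d}" not in planted]
    sick = [f"g{i:04d}" for i in sorted(rng.choice(candidates, size=max(1, n_genes // 50), replace=False))]
    s_sick = {g: -1.0 for g in sick}

    conditions = {}
    for cond in NITRATE_CONDITIONS:
        sel = dict(s_sick)
        if cond in ("NaNO3", "KNO3"):
            sel.update({g: float(s) for g, s in s_pos.items()})
        else:
            # disrupting the cluster/regulator is mildly deleterious when the
            # stress is absent (loss of a native transport/regulatory function)
            sel.update({g: -0.15 for g in planted})
        conditions[cond] = sel

    defaults = dict(
        seed=seed,
        n_genes=n_genes,
        mean_gene_length=900,
        gene_length_sd=100,
        intergenic_gap=150,
        n1=2300,
        n2=2300,
        overlap=600,
        intergenic_fraction=0.05,
        strain_effect_sd=0.5,
        growth_mode="population",
        conditions=conditions,
        doublings={c: 3.3 for c in NITRATE_CONDITIONS},
        sigma=0.3,
        scale=65536.0,
        background=0.25,
        tnle_sites=500_000,
        tnle_reads=2_500_000,
        tnle_condition="NaNO3",
        ensure_covered=planted,
        min_strains_per_covered=2,
        planted_positive=planted,
        planted_sick=sick,
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


def build_scenario_library(config: ScenarioConfig) -> tuple[GenomeAnnotation, pd.DataFrame]:
    """Genome + barcoded library for a scenario, with guaranteed coverage of
    the genes the scenario plants effects in."""
    annotation = build_genome(config)
    strains = build_barcoded_library(
        annotation,
        config.n1,
        config.n2,
        config.overlap,
        config.seed,
        intergenic_fraction=config.intergenic_fraction,
        strain_effect_sd=config.strain_effect_sd,
        ensure_covered=config.ensure_covered,
        min_strains_per_covered=config.min_strains_per_covered,
    )
    # strains in genes with planted (exactly specified) effects carry no
    # insertion-specific jitter: their ground truth is the planted s itself
    planted = set(config.planted_positive) | set(config.planted_sick)
    if planted:
        strains.loc[strains["feature"].isin(planted), "true_rate"] = 1.0
    return annotation, strains


def write_strains_tsv(strains: pd.DataFrame, path: str | os.PathLike) -> None:
    strains.to_csv(path, sep="\t", index=False)


def read_strains_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "strain_id": str,
            "chrom": str,
            "position": int,
            "feature": str,
            "pools": str,
            "uptag_id": str,
            "downtag_id": str,
            "true_rate": float,
        },
    )
    missing = set(STRAIN_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"strains table missing columns {sorted(missing)}")
    return df
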