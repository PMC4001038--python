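"""Cross-condition assembly, candidate calling and homolog comparison.

The discovery logic of the study: collect per-condition gene fitness into
one gene x condition table, call nitrate-resistance candidates as genes with
high fitness in every nitrate salt but near-neutral fitness in the osmotic
controls, nitrite and the unstressed culture, and compare candidate fitness
between the two organisms through a homolog map.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd


class ReportError(ValueError):
    pass


@dataclass
class ConditionFitnessTable:
    """Gene x condition fitness matrix with per-condition provenance.

    ``values`` is a DataFrame indexed by gene_id with one column per
    condition; missing cells are NaN (a gene not measured in a condition is
    missing, never zero). ``source`` records which pipeline produced each
    condition ('barseq' or 'tnle').
    """

    values: pd.DataFrame
    source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ReportError("duplicate gene_id in condition table")
        if self.values.columns.has_duplicates:
            raise ReportError("duplicate condition in condition table")

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class CandidateRule:
    """Fitness > t_high in every high condition AND fitness < t_low in every
    low condition; both inequalities strict. Defaults are the nitrate rule:
    high in both nitrate salts (anion consistency), low in the osmotic
    controls, nitrite and the unstressed condition."""

    high_conditions: tuple[str, ...] = ("NaNO3", "KNO3")
    t_high: float = 2.0
    low_conditions: tuple[str, ...] = ("NaCl", "KCl", "NaNO2", "none")
    t_low: float = 0.25

    def __post_init__(self) -> None:
        # infinite thresholds are allowed (degenerate select-all / select-none
        # rules); finite thresholds must be ordered
        if np.isfinite(self.t_high) and np.isfinite(self.t_low) and self.t_high <= self.t_low:
            raise ReportError("t_high must exceed t_low")
        if set(self.high_conditions) & set(self.low_conditions):
            raise ReportError("high and low condition sets must be disjoint")


DEFAULT_NITRATE_RULE = CandidateRule()


def assemble(
    tables: Mapping[str, pd.DataFrame], sources: Optional[Mapping[str, str]] = None
) -> ConditionFitnessTable:
    """Outer-join labeled per-condition gene-fitness frames (columns gene_id,
    fitness) into one gene x condition matrix."""
    cols = {}
    for cond, df in tables.items():
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ReportError(f"duplicate gene {dup!r} in condition {cond!r}")
        cols[cond] = df.set_index("gene_id")["fitness"]
    values = pd.DataFrame(cols)
    src = dict(sources) if sources else {}
    return ConditionFitnessTable(values, src)


def select_candidates(
    table: ConditionFitnessTable, rule: CandidateRule = DEFAULT_NITRATE_RULE
) -> tuple[pd.DataFrame, list[str]]:
    """Apply the candidate rule; rank by minimum high-condition fitness,
    descending (the conservative anion-consistent score), ties broken by
    gene id.

    Returns (ranked candidates frame, genes excluded for missing rule
    cells). A gene with any missing cell among the rule's conditions cannot
    be evaluated and is excluded — absence of evidence is not resistance.
    """
    needed = list(rule.high_conditions) + list(rule.low_conditions)
    for cond in needed:
        if cond not in table.values.columns:
            raise ReportError(f"rule condition {cond!r} absent from table")
    sub = table.values[needed]
    complete = sub.notna().all(axis=1)
    incomplete = sorted(sub.index[~complete])
    sub = sub.loc[complete]
    high = sub[list(rule.high_conditions)]
    low = sub[list(rule.low_conditions)]
    passing = (high.gt(rule.t_high).all(axis=1)) & (low.lt(rule.t_low).all(axis=1))
    out = table.values.loc[sub.index[passing]].copy()
    out["score"] = high.loc[passing].min(axis=1)
    out = out.iloc[np.lexsort((out.index.to_numpy(), -out["score"].to_numpy()))]
    out.index.name = "gene_id"
    return out, incomplete


def rank(table: ConditionFitnessTable, condition: str, k: int) -> pd.DataFrame:
    """Top-k genes by fitness in one condition, descending; ties broken by
    gene id (documented, deterministic); missing cells excluded."""
    if condition not in table.values.columns:
        raise ReportError(f"condition {condition!r} absent from table")
    col = table.values[condition].dropna()
    df = col.to_frame("fitness")
    df = df.iloc[np.lexsort((df.index.to_numpy(), -df["fitness"].to_numpy()))]
    df.index.name = "gene_id"
    return df.head(k)


def join_homologs(
    table_a: ConditionFitnessTable,
    table_b: ConditionFitnessTable,
    homologs: pd.DataFrame,
    condition_a: str,
    condition_b: Optional[str] = None,
) -> tuple[pd.DataFrame, dict]:
    """Side-by-side fitness of homologous gene pairs in a focal condition.

    ``homologs`` has columns gene_a, gene_b. The summary reports the
    fraction of evaluable pairs whose fitness signs agree in the focal
    condition(s); dangling ids (absent from either table) are counted but
    not evaluated. Genes of table A with no homolog are reported separately.
    """
    if condition_b is None:
        condition_b = condition_a
    if homologs.duplicated(subset=["gene_a", "gene_b"]).any():
        raise ReportError("duplicate homolog pairs")
    fa = table_a.values[condition_a] if condition_a in table_a.values else pd.Series(dtype=float)
    fb = table_b.values[condition_b] if condition_b in table_b.values else pd.Series(dtype=float)
    rows = []
    dangling = 0
    for pair in homologs.itertuples(index=False):
        a_val = fa.get(pair.gene_a, np.nan)
        b_val = fb.get(pair.gene_b, np.nan)
        if pair.gene_a not in fa.index or pair.gene_b not in fb.index:
            dangling += 1
        rows.append(
            {
                "gene_a": pair.gene_a,
                "gene_b": pair.gene_b,
                "fitness_a": a_val,
                "fitness_b": b_val,
                "sign_concordant": (
                    bool(np.sign(a_val) == np.sign(b_val))
                    if np.isfinite(a_val) and np.isfinite(b_val)
                    else None
                ),
            }
        )
    joined = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "fitness_a", "fitness_b", "sign_concordant"]
    )
    evaluable = joined["sign_concordant"].notna()
    n_eval = int(evaluable.sum())
    summary = {
        "n_pairs": len(joined),
        "n_evaluable": n_eval,
        "n_dangling": dangling,
        "concordance": (
            float(joined.loc[evaluable, "sign_concordant"].mean()) if n_eval else None
        ),
        "no_homolog": sorted(set(table_a.genes) - set(homologs["gene_a"])),
    }
    return joined, summary


def write_condition_table(table: ConditionFitnessTable, path: str | os.PathLike) -> None:
    df = table.values.copy()
    df.index.name = "gene_id"
    with open(path, "w") as fh:
        for cond in table.conditions:
            src = table.source.get(cond, "")
            if src:
                fh.write(f"#source\t{cond}\t{src}\n")
        df.to_csv(fh, sep="\t", float_format="%.17g")


def read_condition_table(path: str | os.PathLike) -> ConditionFitnessTable:
    source = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#source"):
                break
            _, cond, src = line.rstrip("\n").split("\t")
            source[cond] = src
    df = pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")
    return ConditionFitnessTable(df, source)


def read_homologs_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise ReportError("homolog TSV needs columns gene_a, gene_b")
    return df


def format_report(
    table: ConditionFitnessTable,
    candidates: pd.DataFrame,
    homolog_summary: Optional[dict] = None,
) -> str:
    """Plain-text ranked candidate report in the style of a published
    candidate-gene table."""
    lines = ["Nitrate-resistance candidate genes", "=" * 40]
    header = ["gene_id"] + table.conditions + ["score"]
    lines.append("\t".join(header))
    for gid, row in candidates.iterrows():
        vals = [
            f"{row[c]:.2f}" if c in row and pd.notna(row[c]) else "NA"
            for c in table.conditions
        ]
        lines.append("\t".join([str(gid)] + vals + [f"{row['score']:.2f}"]))
    if homolog_summary is not None:
        lines.append("")
        conc = homolog_summary.get("concordance")
        lines.append(
            f"homolog sign concordance: "
            f"{conc:.3f} over {homolog_summary['n_evaluable']} pairs"
            if conc is not None
            else "homolog sign concordance: undefined (no evaluable pairs)"
        )
    return "\n".join(lines) + "\n"
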