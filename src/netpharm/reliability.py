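"""Per-herb target reliability: hit times and rank order.

For a herb with compounds c1..cm, a gene's *hit times* is the number of
compounds whose top-``k`` putative-target profile contains the gene; its
*order* is the gene's ordinal rank among all of the herb's candidate
genes sorted by hit times (descending), with ties broken by mean
concordance score (descending) and then symbol (ascending).  The classic
rendering is ``"18(2)"`` — 18 hits, order 2.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import CompoundTargetScoreMatrix
from .symbols import normalize_symbol


def hit_times(
    target: str,
    herb: str,
    profiles: CompoundTargetScoreMatrix,
    herb_compounds: Mapping[str, Sequence[str]],
    top_k: int,
) -> int:
    """Number of the herb's compounds whose top-``k`` list contains ``target``."""
    target = normalize_symbol(target)
    if target not in profiles.ranks.columns:
        raise KeyError(f"unknown target symbol {target!r}")
    if herb not in herb_compounds:
        raise KeyError(f"unknown herb {herb!r}")
    ranks = profiles.ranks.loc[list(herb_compounds[herb]), target]
    return int((ranks <= top_k).sum())


def _herb_ordering(
    herb: str,
    profiles: CompoundTargetScoreMatrix,
    herb_compounds: Mapping[str, Sequence[str]],
    top_k: int,
) -> pd.DataFrame:
    """All candidate genes of a herb with hit times and ordinal order."""
    compounds = list(herb_compounds[herb])
    ranks = profiles.ranks.loc[compounds]
    hits = (ranks <= top_k).sum(axis=0)
    mean_score = profiles.scores.loc[compounds].mean(axis=0)
    df = pd.DataFrame(
        {"gene": hits.index, "hit_times": hits.to_numpy(), "mean_score": mean_score.reindex(hits.index).to_numpy()}
    )
    df = df.sort_values(
        ["hit_times", "mean_score", "gene"],
        ascending=[False, False, True],
        ignore_index=True,
    )
    df["order"] = np.arange(1, len(df) + 1)  # ordinal: ties get distinct orders
    return df


def order_within_herb(
    herb: str,
    targets_of_interest: Iterable[str],
    profiles: CompoundTargetScoreMatrix,
    herb_compounds: Mapping[str, Sequence[str]],
    top_k: int,
) -> dict[str, tuple[int, int]]:
    """Map each target of interest to its ``(hit_times, order)`` in the herb."""
    targets = [normalize_symbol(t) for t in targets_of_interest]
    if not targets:
        raise ValueError("targets_of_interest is empty")
    if herb not in herb_compounds:
        raise KeyError(f"unknown herb {herb!r}")
    ordering = _herb_ordering(herb, profiles, herb_compounds, top_k).set_index("gene")
    out = {}
    for t in targets:
        if t not in ordering.index:
            raise KeyError(f"unknown target symbol {t!r}")
        row = ordering.loc[t]
        out[t] = (int(row["hit_times"]), int(row["order"]))
    return out


def reliability_table(
    targets_of_interest: Iterable[str],
    profiles: CompoundTargetScoreMatrix,
    herb_compounds: Mapping[str, Sequence[str]],
    top_k: int,
) -> pd.DataFrame:
    """Long-form (target, herb, hit_times, order) table across all herbs."""
    targets = [normalize_symbol(t) for t in targets_of_interest]
    rows = []
    for herb in sorted(herb_compounds):
        per_herb = order_within_herb(herb, targets, profiles, herb_compounds, top_k)
        for t in targets:
            h, o = per_herb[t]
            rows.append({"target": t, "herb": herb, "hit_times": h, "order": o})
    return pd.DataFrame(rows, columns=["target", "herb", "hit_times", "order"])


def render_hit_order(table: pd.DataFrame) -> pd.DataFrame:
    """Wide rendering with ``"hit(order)"`` cells, targets × herbs."""
    wide = table.assign(cell=lambda d: d["hit_times"].astype(str) + "(" + d["order"].astype(str) + ")")
    return wide.pivot(index="target", columns="herb", values="cell")


def write_reliability(
    table: pd.DataFrame, tsv_path: str | Path, text_path: str | Path | None = None
) -> None:
    table.to_csv(tsv_path, sep="\t", index=False)
    if text_path is not None:
        rendered = render_hit_order(table)
        Path(text_path).write_text(rendered.to_string() + "\n")
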