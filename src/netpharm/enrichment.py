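"""Hypergeometric over-representation analysis with Bonferroni correction.

Given a query gene set (here: the major nodes of the herb-target-disease
network) and a pathway collection, each pathway is tested one-sided for
over-representation: with a universe of ``N`` genes, a pathway of size
``K``, a query of size ``n`` and an overlap of ``k``, the raw p-value is
``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.  Raw p-values are
Bonferroni-corrected by the number of pathways tested.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .symbols import normalize_symbol

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested against.

    When ``universe`` is None the background defaults to the union of all
    member genes — the standard self-contained choice for annotation-based
    backgrounds.  It can be overridden (e.g. with all PPI genes).
    """

    sets: dict[str, frozenset]
    universe: frozenset | None = None

    def __post_init__(self):
        uni = self.effective_universe
        for name, members in self.sets.items():
            if not members <= uni:
                raise ValueError(f"gene set {name!r} has members outside the universe")

    @property
    def effective_universe(self) -> frozenset:
        if self.universe is not None:
            return self.universe
        out: set = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)

    @classmethod
    def from_members(
        cls, sets: Mapping[str, Iterable[str]], universe: Iterable[str] | None = None
    ) -> "GeneSetCollection":
        norm = {
            name: frozenset(normalize_symbol(g) for g in members)
            for name, members in sets.items()
        }
        uni = None if universe is None else frozenset(normalize_symbol(g) for g in universe)
        return cls(sets=norm, universe=uni)

    @classmethod
    def from_gmt(cls, path: str | Path, universe: Iterable[str] | None = None) -> "GeneSetCollection":
        sets: dict[str, list[str]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            sets[name] = fields[2:]
        return cls.from_members(sets, universe)

    def to_gmt(self, path: str | Path, descriptions: Mapping[str, str] | None = None) -> None:
        lines = []
        for name in sorted(self.sets):
            desc = (descriptions or {}).get(name, "na")
            lines.append("\t".join([name, desc, *sorted(self.sets[name])]))
        Path(path).write_text("\n".join(lines) + "\n")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.

    ``N`` genes in the universe, ``K`` in the pathway, ``n`` in the
    query, ``k`` in the overlap.  Computed via scipy's log-space
    survival function; ``k = 0`` gives exactly 1.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of ``query`` in every pathway of ``collection``.

    The query is intersected with the universe before counting (dropped
    genes are logged); pathways with zero overlap are omitted from the
    table but still count toward the Bonferroni factor ``m``.  Rows are
    sorted by corrected p-value, then raw p-value, then name.
    """
    if not collection.sets:
        raise ValueError("gene-set collection is empty")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    universe = collection.effective_universe
    query_norm = {normalize_symbol(g) for g in query}
    dropped = query_norm - universe
    if dropped:
        logger.info(
            "dropped %d query genes outside the enrichment universe", len(dropped)
        )
    query_in = query_norm & universe
    if not query_in:
        raise ValueError("query does not intersect the enrichment universe")
    N, n, m = len(universe), len(query_in), len(collection.sets)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        k, K = len(query_in & members), len(members)
        if k == 0:
            continue
        p_raw = hypergeom_upper_tail(k, K, n, N)
        rows.append(
            {
                "pathway": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_raw": p_raw,
                "p_bonf": min(1.0, m * p_raw),
            }
        )
    table = pd.DataFrame(
        rows, columns=["pathway", "k", "K", "n", "N", "p_raw", "p_bonf"]
    )
    # alpha == 1 means "keep everything", including p-values capped at 1
    table["significant"] = (table["p_bonf"] < alpha) | (alpha >= 1.0)
    return table.sort_values(
        ["p_bonf", "p_raw", "pathway"], ignore_index=True
    )
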