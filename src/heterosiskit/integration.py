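"""Gene-set overlap analysis and over-representation testing.

Combines the upstream results -- differential-expression gene sets per
population, dominance-mode calls, and divergent-splicing genes -- into the
overlap analyses that identify candidate heterosis genes: genes that are
differentially expressed in every population, over-dominantly expressed in
the hybrid, and alternatively spliced in the hybrid.

Over-representation of a gene set in annotation categories (e.g. pathways)
uses the one-sided hypergeometric upper-tail test (the "Fisher exact"
family) with BH adjustment across categories.  Annotation content is always
user-supplied; nothing is bundled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = [
    "HeterosisIntegration",
    "OverlapReport",
    "enrich",
    "integrate_heterosis",
    "venn_partition",
]


@dataclass
class OverlapReport:
    """Exact Venn partition of the union of 2-5 named sets.

    ``regions`` maps each non-empty membership pattern -- the tuple of set
    names a gene belongs to, in input order -- to the sorted member list.
    Every gene of the union appears in exactly one region.
    """

    set_names: tuple[str, ...]
    regions: dict[tuple[str, ...], list[str]]
    union_size: int

    @property
    def region_counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}

    def intersection(self, *names: str) -> set[str]:
        """Members of the plain intersection of the given sets."""
        want = set(names if names else self.set_names)
        out: set[str] = set()
        for pattern, members in self.regions.items():
            if want <= set(pattern):
                out.update(members)
        return out

    def pairwise_counts(self) -> dict[tuple[str, str], int]:
        return {
            (a, b): len(self.intersection(a, b))
            for a, b in combinations(self.set_names, 2)
        }


def venn_partition(sets: Mapping[str, Iterable[str]]) -> OverlapReport:
    """Partition the union of 2-5 named sets into Venn regions."""
    names = tuple(sets)
    if not 2 <= len(names) <= 5:
        raise ValueError(
            f"venn_partition handles 2-5 sets, got {len(names)}; "
            "use a membership table for more"
        )
    members = {n: set(map(str, sets[n])) for n in names}
    regions: dict[tuple[str, ...], list[str]] = {}
    union = set().union(*members.values())
    for gene in union:
        pattern = tuple(n for n in names if gene in members[n])
        regions.setdefault(pattern, []).append(gene)
    for v in regions.values():
        v.sort()
    return OverlapReport(set_names=names, regions=regions, union_size=len(union))


def enrich(
    genes: Iterable[str],
    universe: Iterable[str],
    pathway_map: Mapping[str, Iterable[str]] | pd.DataFrame,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per pathway.

    Parameters
    ----------
    genes
        The query set (must be drawn from ``universe``).
    universe
        All genes eligible for membership (e.g. all detected genes).
    pathway_map
        Either a mapping ``gene -> iterable of pathway ids`` or a two-column
        DataFrame ``(gene, pathway)``.  Genes outside the universe are
        ignored with a count reported in ``DataFrame.attrs['outside_universe']``.

    Returns a DataFrame sorted by p with columns ``pathway``, ``k`` (overlap),
    ``n`` (query size), ``K`` (pathway size in universe), ``N`` (universe
    size), ``p`` and ``fdr``.
    """
    query = set(map(str, genes))
    uni = set(map(str, universe))
    if not query:
        raise ValueError("empty query set")
    if not uni:
        raise ValueError("empty universe")
    stray = query - uni
    if stray:
        raise ValueError(
            f"{len(stray)} query gene(s) not in the universe, e.g. {sorted(stray)[:3]}"
        )

    if isinstance(pathway_map, pd.DataFrame):
        gcol, pcol = pathway_map.columns[:2]
        pairs = zip(pathway_map[gcol].astype(str), pathway_map[pcol].astype(str))
    else:
        pairs = (
            (str(g), str(pw)) for g, pws in pathway_map.items() for pw in pws
        )
    by_pathway: dict[str, set[str]] = {}
    outside = 0
    for g, pw in pairs:
        if g not in uni:
            outside += 1
            continue
        by_pathway.setdefault(pw, set()).add(g)

    n, N = len(query), len(uni)
    rows = []
    for pw, pw_genes in by_pathway.items():
        K = len(pw_genes)
        k = len(pw_genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((pw, k, n, K, N, min(p, 1.0)))
    res = pd.DataFrame(rows, columns=["pathway", "k", "n", "K", "N", "p"])
    res["fdr"] = bh_adjust(res["p"].to_numpy()) if len(res) else []
    res = res.sort_values(["p", "pathway"], kind="stable").reset_index(drop=True)
    res.attrs["outside_universe"] = outside
    return res


@dataclass
class HeterosisIntegration:
    """Stepwise intersections identifying candidate heterosis genes."""

    common_degs: set[str]
    odo_genes: set[str]
    splice_genes: set[str]
    degs_and_odo: set[str]
    final: set[str]
    deg_venn: OverlapReport
    summary_venn: OverlapReport

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "common_degs": len(self.common_degs),
            "odo_genes": len(self.odo_genes),
            "splice_genes": len(self.splice_genes),
            "degs_and_odo": len(self.degs_and_odo),
            "final": len(self.final),
        }


def integrate_heterosis(
    deg_sets: Mapping[str, Iterable[str]],
    mode_calls: pd.DataFrame,
    splice_genes: Iterable[str],
) -> HeterosisIntegration:
    """Intersect per-population DEG sets, over-dominant genes and splice genes.

    ``deg_sets`` maps population names to their heat-response DEG ids (all
    populations supplied are intersected to form the common DEGs);
    ``mode_calls`` is a classification table whose ``ODO``-labelled genes
    form the over-dominant set; ``splice_genes`` carry significant splicing
    divergence in the hybrid.  Empty upstream sets yield empty reports, not
    errors.
    """
    degs = {str(k): set(map(str, v)) for k, v in deg_sets.items()}
    if not degs:
        raise ValueError("no DEG sets supplied")
    common = set.intersection(*degs.values())
    odo = set(map(str, mode_calls.index[mode_calls["label"] == "ODO"]))
    spliced = set(map(str, splice_genes))
    step = common & odo
    final = step & spliced
    return HeterosisIntegration(
        common_degs=common,
        odo_genes=odo,
        splice_genes=spliced,
        degs_and_odo=step,
        final=final,
        deg_venn=venn_partition(degs) if len(degs) >= 2 else venn_partition({**degs, "_": set()}),
        summary_venn=venn_partition(
            {"common_degs": common, "odo_genes": odo, "splice_genes": spliced}
        ),
    )
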