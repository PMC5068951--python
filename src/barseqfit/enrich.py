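"""Gene-set over-representation: fold enrichment, hypergeometric p, BH FDR.

The arithmetic behind a functional-genomics enrichment table: for a hit
list of n genes and a term annotating K of the N background genes, of which
k are in the list,

    fold enrichment = (k / n) / (K / N)
    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

with Benjamini-Hochberg adjustment across terms.  Only over-representation
(upper tail) is tested.  The background matters: published fission-yeast
screens quote both the 5135 protein-coding genes and the 2902 mutants that
actually received a score, and the choice materially changes p-values, so
every table records which was used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Collection, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "fold_enrichment",
    "hypergeom_pvalue",
    "adjust_fdr",
    "enrich_table",
    "PROTEIN_CODING_BACKGROUND",
    "ASSAYED_BACKGROUND",
]

#: Protein-coding genes of fission yeast: the default enrichment background.
PROTEIN_CODING_BACKGROUND = 5135
#: Mutants that actually received a GI score in the published screens.
ASSAYED_BACKGROUND = 2902

DEFAULT_ALPHA = 0.01


@dataclass
class GeneSetCollection:
    """Named term -> gene-id sets plus a background universe."""

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def filtered_to_universe(self) -> tuple["GeneSetCollection", int]:
        """Drop term members outside the universe; returns (collection, n_dropped)."""
        dropped = 0
        out = {}
        for name, members in self.sets.items():
            kept = members & self.universe
            dropped += len(members) - len(kept)
            out[name] = kept
        return GeneSetCollection(out, set(self.universe)), dropped

    @classmethod
    def from_gmt(cls, path: str | Path, universe: Collection[str] | None = None) -> "GeneSetCollection":
        from gseapy import read_gmt

        raw = read_gmt(str(path))
        return cls({name: set(genes) for name, genes in raw.items()}, set(universe or ()))

    def to_gmt(self, path: str | Path, description: str = "na") -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N): list frequency over background frequency."""
    _check_counts(k, n, K, N)
    if K == 0:
        raise ValueError("term absent from background (K = 0)")
    return (k / n) / (K / N)


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    _check_counts(k, n, K, N)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _check_counts(k: int, n: int, K: int, N: int) -> None:
    if n <= 0 or N <= 0 or K < 0:
        raise ValueError(f"need n > 0, N > 0, K >= 0 (got n={n}, K={K}, N={N})")
    if k < 0 or k > min(n, K):
        raise ValueError(f"k must satisfy 0 <= k <= min(n, K) (got k={k}, n={n}, K={K})")
    if n > N or K > N:
        raise ValueError(f"n and K cannot exceed N (got n={n}, K={K}, N={N})")


def adjust_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; empty input gives empty output."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_table(
    hit_list: Collection[str],
    collection: GeneSetCollection,
    background: int | Collection[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Over-representation table over every term with at least one hit.

    ``background`` may be an explicit gene list (the universe), an integer
    N (term membership is then assumed to lie within the background), or
    None to use the collection's own universe.  One row per term with
    k >= 1: fold enrichment (raw and integer-rounded, as screening tables
    print it), list/background frequencies, hypergeometric p, BH q and a
    significance flag at ``alpha``; rows sorted by p.
    """
    hits = set(hit_list)
    if isinstance(background, int):
        N = background
        universe = None
    elif background is not None:
        universe = set(background)
        N = len(universe)
    elif collection.universe:
        universe = set(collection.universe)
        N = len(universe)
    else:
        raise ValueError("no background: pass a size, a gene list, or a collection with a universe")

    if universe is not None:
        collection, _ = GeneSetCollection(collection.sets, universe).filtered_to_universe()
        hits = hits & universe
    if not hits:
        raise ValueError("hit list is disjoint from the background universe")
    n = len(hits)

    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        overlap = sorted(hits & members)
        k = len(overlap)
        if k == 0 or K == 0:
            continue
        rows.append(
            {
                "term": name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold_enrichment": fold_enrichment(k, n, K, N),
                "fold_rounded": int(round(fold_enrichment(k, n, K, N))),
                "list_frequency": k / n,
                "background_frequency": K / N,
                "p_value": hypergeom_pvalue(k, n, K, N),
                "genes": ",".join(overlap),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "term", "k", "n", "K", "N", "fold_enrichment", "fold_rounded",
            "list_frequency", "background_frequency", "p_value", "genes",
        ],
    )
    if len(table):
        table["q_value"] = adjust_fdr(table["p_value"])
        table["significant"] = table["q_value"] <= alpha
        table = table.sort_values(["p_value", "term"]).reset_index(drop=True)
    else:
        table["q_value"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    table.attrs["background_size"] = N
    return table
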