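"""Hypergeometric over-representation statistics for gene sets.

The convention throughout: of a population of N genes containing K
"successes" (e.g. disease-causing genes), a sample of n genes (e.g. the
signature) is drawn without replacement and contains k successes.  The
reported P is the inclusive upper tail P(X >= k) under the
hypergeometric distribution, computed in log-space so that values near
1e-23 at population sizes around 16,000 survive; fold-enrichment is
(k/n)/(K/N).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from octs.io import GeneSetCollection, OrthologMap

logger = logging.getLogger("octs")


@dataclass
class HypergeomResult:
    N: int
    K: int
    n: int
    k: int
    p_raw: float
    fe: float
    p_adj: float | None = None

    def as_dict(self) -> dict:
        return {
            "N": self.N, "K": self.K, "n": self.n, "k": self.k,
            "p_raw": self.p_raw, "p_adj": self.p_adj, "fe": self.fe,
        }


def hypergeom_test(N: int, K: int, n: int, k: int) -> HypergeomResult:
    """Inclusive upper-tail hypergeometric test P(X >= k).

    scipy's survival function works in log-space internally, so the
    result is accurate down to the ~1e-30 scale these enrichments reach.
    """
    if not 0 <= K <= N:
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"require 0 <= k <= min(n, K)={min(n, K)}, got k={k}")
    p_raw = float(hypergeom.sf(k - 1, N, K, n))
    fe = (k / n) / (K / N) if n > 0 and K > 0 else np.nan
    return HypergeomResult(N=N, K=K, n=n, k=k, p_raw=p_raw, fe=float(fe))


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment min(1, m*p), order-preserving."""
    p_values = list(p_values)
    if any(p < 0 or p > 1 for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p_values) if m is None else m
    return [min(1.0, m * p) for p in p_values]


def group_enrichment(
    groups: GeneSetCollection,
    signature: Iterable[str],
    universe: Iterable[str],
    min_group: int = 3,
) -> pd.DataFrame:
    """One hypergeometric test per disease group against the signature.

    N = |universe|, K = |group ∩ universe|, n = |signature ∩ universe|,
    k = |group ∩ signature ∩ universe|.  Groups with fewer than
    ``min_group`` members in the universe are not tested; groups entirely
    outside the universe are skipped with a warning.  Bonferroni m =
    number of groups actually tested.
    """
    universe_set = set(universe)
    signature_set = set(signature) & universe_set
    if not set(signature) <= universe_set:
        outside = len(set(signature) - universe_set)
        logger.warning("%d signature gene(s) outside the universe dropped", outside)
    N, n = len(universe_set), len(signature_set)

    rows = []
    for name, members in groups.items():
        in_universe = members & universe_set
        if not in_universe:
            logger.warning("group %s entirely outside universe; skipped", name)
            continue
        if len(in_universe) < min_group:
            continue
        k = len(in_universe & signature_set)
        res = hypergeom_test(N=N, K=len(in_universe), n=n, k=k)
        rows.append({"group": name, **res.as_dict()})
    if not rows:
        return pd.DataFrame(
            columns=["group", "N", "K", "n", "k", "p_raw", "p_adj", "fe"]
        ).set_index("group")
    table = pd.DataFrame(rows).set_index("group")
    table["p_adj"] = bonferroni(table["p_raw"].tolist())
    return table


def nearest_gene_enrichment(
    nearest: Sequence[str],
    members: Iterable[str],
    universe: Iterable[str],
) -> HypergeomResult:
    """Over-representation of ``members`` among nearest genes to GWAS loci.

    ``nearest`` may repeat genes (one entry per locus); genes nearest to
    multiple loci are counted once.  Everything is intersected with the
    universe: N = |universe|, K = |members ∩ universe|,
    n = |unique nearest ∩ universe|, k = |nearest ∩ members ∩ universe|.
    """
    universe_set = set(universe)
    members_set = set(members) & universe_set
    unique_nearest = set(nearest) & universe_set
    if not unique_nearest:
        raise ValueError("no nearest genes remain after intersecting with the universe")
    return hypergeom_test(
        N=len(universe_set),
        K=len(members_set),
        n=len(unique_nearest),
        k=len(unique_nearest & members_set),
    )


def map_orthologs(
    mouse_genes: Iterable[str],
    omap: OrthologMap,
    universe: Iterable[str],
) -> set[str]:
    """Human partners of the mouse genes, restricted to the human universe.

    Many-to-many relations expand to all partners; unmapped mouse genes
    contribute nothing and are counted in the log.
    """
    mouse_set = set(mouse_genes)
    universe_set = set(universe)
    partners: dict[str, set[str]] = {}
    for mouse, human in omap.pairs:
        if mouse in mouse_set:
            partners.setdefault(mouse, set()).add(human)
    unmapped = len(mouse_set) - len(partners)
    if unmapped:
        logger.info("%d of %d mouse genes had no ortholog mapping", unmapped, len(mouse_set))
    out: set[str] = set()
    for humans in partners.values():
        out |= humans & universe_set
    return out
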