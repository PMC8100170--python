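"""The three-rule filter defining the osteocyte transcriptome signature.

A gene belongs to the signature iff it is
(1) actively expressed in osteocytes in any of the configured sample
    types (union of per-group active calls),
(2) enriched in the osteocyte fraction relative to whole bone (mixture
    threshold + CI call), and
(3) not significantly higher in blood, bone marrow or skeletal muscle
    than in osteocyte-enriched bone (P < 0.05 in an external
    differential-expression table, oriented so positive LFC = higher in
    the contaminant tissue).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from octs.io import DEFAULT_CONTRAST_TISSUES

logger = logging.getLogger("octs")

DEFAULT_ALPHA = 0.05


def exclusion_set(
    dge_table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    allowed_tissues: Iterable[str] = DEFAULT_CONTRAST_TISSUES,
) -> dict[str, list[str]]:
    """Genes significantly higher in a contaminant tissue than in bone.

    A gene is excluded when, in ANY allowed contrast tissue, p_value <
    alpha (strict) and lfc > 0 under the higher-in-contaminant
    orientation.  Returns gene -> list of triggering tissues.
    """
    allowed = set(allowed_tissues)
    unknown = set(dge_table["contrast_tissue"]) - allowed
    if unknown:
        raise ValueError(f"unknown contrast tissue(s): {sorted(unknown)}")
    hits = dge_table[(dge_table["p_value"] < alpha) & (dge_table["lfc"] > 0)]
    out: dict[str, list[str]] = {}
    for gene, grp in hits.groupby("gene"):
        out[str(gene)] = sorted(grp["contrast_tissue"].unique())
    return out


@dataclass
class SignatureResult:
    """Signature membership with per-rule provenance and stage counts."""

    table: pd.DataFrame  # per gene: active_any, enriched, excluded_tissue, in_signature
    counts: dict[str, int]

    @property
    def genes(self) -> set[str]:
        return set(self.table.index[self.table["in_signature"]])


def define_signature(
    active_any: Iterable[str],
    enriched: Iterable[str],
    excluded: Iterable[str] | dict[str, list[str]],
) -> SignatureResult:
    """Apply the three-rule conjunction over a common gene universe.

    The reported universe is the union of the three input sets; the
    signature is active_any AND enriched AND NOT excluded.  Stage counts
    (enriched∩active, excluded among them, final) are logged and returned.
    """
    active_set = set(active_any)
    enriched_set = set(enriched)
    if isinstance(excluded, dict):
        excluded_tissues = {g: list(t) for g, t in excluded.items()}
    else:
        excluded_tissues = {g: [] for g in excluded}
    excluded_set = set(excluded_tissues)

    universe = sorted(active_set | enriched_set | excluded_set)
    table = pd.DataFrame(index=pd.Index(universe, name="gene_id"))
    table["active_any"] = [g in active_set for g in universe]
    table["enriched"] = [g in enriched_set for g in universe]
    table["excluded_tissue"] = [g in excluded_set for g in universe]
    table["excluding_tissues"] = [
        ",".join(excluded_tissues.get(g, [])) for g in universe
    ]
    table["in_signature"] = (
        table["active_any"] & table["enriched"] & ~table["excluded_tissue"]
    )

    candidate = active_set & enriched_set
    dropped = candidate & excluded_set
    counts = {
        "active_any": len(active_set),
        "enriched": len(enriched_set),
        "active_and_enriched": len(candidate),
        "excluded_from_candidates": len(dropped),
        "signature": len(candidate) - len(dropped),
    }
    result = SignatureResult(table=table, counts=counts)
    assert counts["signature"] == int(table["in_signature"].sum())
    logger.info(
        "signature: %(active_and_enriched)d active+enriched, "
        "%(excluded_from_candidates)d excluded, %(signature)d final", counts,
    )
    return result
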