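"""Readers and writers for the tabular formats the pipeline exchanges.

All matrices travel as TSV with a ``gene_id`` first column, tab separators,
'.' decimal and UTF-8 — no quoting, no locale surprises.  Gene identifiers
are opaque, case-sensitive strings; no symbol/ID conversion is attempted
(ortholog relationships come in as an explicit two-column map instead of a
live database lookup).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("octs")

GENE_ID_COLUMN = "gene_id"

#: Sample-table column order used by writers.
SAMPLE_COLUMNS = [
    "sample_id",
    "cohort",
    "tissue",
    "condition",
    "animal_id",
    "age_weeks",
    "sex",
    "replicate",
]

VALID_COHORTS = {"bone_comparison", "maturation", "enrichment", "tissue_panel"}
VALID_CONDITIONS = {"osteocyte_enriched", "whole_bone", "other"}


class OctsIOError(ValueError):
    """Raised when an input file violates the pipeline's format contracts."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values, flagged as FPKM or raw counts.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    unit
        ``"FPKM"`` (non-negative reals) or ``"counts"`` (non-negative
        integers).
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in ("FPKM", "counts"):
            raise OctsIOError(f"unknown unit {self.unit!r}; expected FPKM or counts")
        validate_expression_frame(self.values, self.unit)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. nosology disease groups, nearest-gene lists)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass
class OrthologMap:
    """Many-to-many mouse-to-human gene pairs."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.pairs) != len(set(self.pairs)):
            seen: set[tuple[str, str]] = set()
            for p in self.pairs:
                if p in seen:
                    raise OctsIOError(f"duplicate ortholog pair {p}")
                seen.add(p)

    def human_partners(self, mouse_gene: str) -> set[str]:
        return {h for m, h in self.pairs if m == mouse_gene}


def validate_expression_frame(frame: pd.DataFrame, unit: str) -> None:
    """Check uniqueness, non-negativity and (for counts) integrality."""
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise OctsIOError(f"duplicate gene id {dup!r}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()][0]
        raise OctsIOError(f"duplicate sample id {dup!r}")
    arr = frame.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise OctsIOError("non-numeric values in expression matrix")
    if np.isnan(arr).any():
        g, s = np.argwhere(np.isnan(arr))[0]
        raise OctsIOError(
            f"missing value at gene {frame.index[g]!r}, sample {frame.columns[s]!r}"
        )
    neg = np.argwhere(arr < 0)
    if neg.size:
        g, s = neg[0]
        raise OctsIOError(
            f"negative value {arr[g, s]} at gene {frame.index[g]!r}, "
            f"sample {frame.columns[s]!r}"
        )
    if unit == "counts":
        frac = np.argwhere(arr != np.floor(arr))
        if frac.size:
            g, s = frac[0]
            raise OctsIOError(
                f"non-integer count {arr[g, s]} at gene {frame.index[g]!r}, "
                f"sample {frame.columns[s]!r}"
            )


def read_expression_matrix(path: str | Path, unit: str) -> ExpressionMatrix:
    """Read a gene-by-sample TSV (first column ``gene_id``, header = samples)."""
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    matrix = ExpressionMatrix(values=frame, unit=unit)
    logger.info(
        "read expression matrix %s: %d genes x %d samples (%s)",
        path, *frame.shape, unit,
    )
    return matrix


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    frame = matrix.values.copy()
    frame.index.name = GENE_ID_COLUMN
    if matrix.unit == "counts":
        frame = frame.astype(np.int64)
    frame.to_csv(path, sep="\t", float_format="%.17g")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read sample metadata; validates ids, cohort/condition vocabularies
    and the paired design of the enrichment cohort (one osteocyte-enriched
    and one whole-bone sample per animal)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_COLUMNS if c not in table.columns]
    if missing:
        raise OctsIOError(f"sample table missing columns: {missing}")
    table = table[SAMPLE_COLUMNS].copy()
    table["age_weeks"] = table["age_weeks"].astype(int)
    table["replicate"] = table["replicate"].astype(int)
    validate_sample_table(table)
    return table


def validate_sample_table(table: pd.DataFrame) -> None:
    if table["sample_id"].duplicated().any():
        dup = table.loc[table["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise OctsIOError(f"duplicate sample_id {dup!r}")
    bad = set(table["cohort"]) - VALID_COHORTS
    if bad:
        raise OctsIOError(f"unknown cohort value(s): {sorted(bad)}")
    bad = set(table["condition"]) - VALID_CONDITIONS
    if bad:
        raise OctsIOError(f"unknown condition value(s): {sorted(bad)}")
    enr = table[table["cohort"] == "enrichment"]
    for animal, grp in enr.groupby("animal_id"):
        conds = sorted(grp["condition"])
        if conds != ["osteocyte_enriched", "whole_bone"]:
            raise OctsIOError(
                f"enrichment animal {animal!r} must have exactly one "
                f"osteocyte_enriched and one whole_bone sample; got {conds}"
            )


def write_sample_table(table: pd.DataFrame, path: str | Path) -> None:
    table[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read GMT: ``set_name TAB description TAB gene1 TAB gene2 ...``."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise OctsIOError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, description = fields[0].strip(), fields[1]
            if name in sets:
                raise OctsIOError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [g.strip() for g in fields[2:] if g.strip()]
            unique = frozenset(members)
            if len(unique) < len(members):
                logger.warning(
                    "set %s: %d duplicate member(s) collapsed",
                    name, len(members) - len(unique),
                )
            if not unique:
                raise OctsIOError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = unique
            descriptions[name] = description
    if not sets:
        raise OctsIOError(f"{path}: no sets found")
    logger.info("read %d gene sets from %s", len(sets), path)
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            handle.write("\t".join([name, desc, *sorted(members)]) + "\n")


EXCLUSION_COLUMNS = ["gene", "contrast_tissue", "lfc", "p_value"]
DEFAULT_CONTRAST_TISSUES = ("blood", "bone_marrow", "muscle")


def read_exclusion_table(
    path: str | Path,
    allowed_tissues: Iterable[str] = DEFAULT_CONTRAST_TISSUES,
) -> pd.DataFrame:
    """Read the differential-expression exclusion table.

    Sign convention (declared, validated): positive ``lfc`` means higher
    expression in the contaminant contrast tissue than in
    osteocyte-enriched bone.
    """
    table = pd.read_csv(path, sep="\t", dtype={"gene": str, "contrast_tissue": str})
    missing = [c for c in EXCLUSION_COLUMNS if c not in table.columns]
    if missing:
        raise OctsIOError(f"exclusion table missing columns: {missing}")
    table = table[EXCLUSION_COLUMNS].copy()
    if len(table):
        table["lfc"] = table["lfc"].astype(float)
        table["p_value"] = table["p_value"].astype(float)
        bad_p = table[(table["p_value"] < 0) | (table["p_value"] > 1)]
        if len(bad_p):
            row = bad_p.iloc[0]
            raise OctsIOError(
                f"p_value {row['p_value']} outside [0, 1] for gene {row['gene']!r}"
            )
        allowed = set(allowed_tissues)
        bad_t = set(table["contrast_tissue"]) - allowed
        if bad_t:
            raise OctsIOError(
                f"contrast tissue(s) {sorted(bad_t)} not in allow-list {sorted(allowed)}"
            )
    return table


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column TSV of (mouse_gene_id, human_gene_id) pairs."""
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise OctsIOError(f"{path}:{lineno}: expected 2 columns")
            pairs.append((fields[0].strip(), fields[1].strip()))
    return OrthologMap(pairs=pairs)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for mouse, human in omap.pairs:
            handle.write(f"{mouse}\t{human}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene per line; blank lines skipped; order preserved, de-duplication
    left to the caller (nearest-gene lists legitimately repeat genes)."""
    with open(path, encoding="utf-8") as handle:
        return [line.strip() for line in handle if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for gene in genes:
            handle.write(f"{gene}\n")


def write_run_manifest(
    path: str | Path,
    stage: str,
    inputs: Mapping[str, object],
    parameters: Mapping[str, object],
    seed: int | None = None,
) -> None:
    """Write the JSON run-manifest each CLI stage emits."""
    from octs import __version__

    manifest = {
        "stage": stage,
        "artifact_version": __version__,
        "python": sys.version.split()[0],
        "seed": seed,
        "inputs": dict(inputs),
        "parameters": dict(parameters),
    }
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
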