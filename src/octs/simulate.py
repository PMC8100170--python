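"""Seeded generators emulating the statistical structure of the study data.

Each generator is a pure function of its parameters and a seed, and
returns ground-truth labels (:class:`SimTruth`) alongside the simulated
data so recovery experiments can score the pipeline against what was
planted.

What is emulated, per stage:

* ``simulate_cohort`` — the bimodal per-sample log-FPKM distribution bulk
  RNA-seq shows: a near-zero mass of inactive genes (zeros plus an
  exponential trickle) under a log-normal mode of active genes, with
  replicate-level multiplicative noise.
* ``simulate_enrichment_experiment`` — paired osteocyte-enriched vs
  whole-bone count samples whose per-gene log fold-changes follow a
  four-component Gaussian mixture (strongly enriched / moderately
  enriched / unchanged / marrow-depleted), with negative-binomial count
  noise around animal-specific library sizes.
* ``simulate_tissue_panel`` — a multi-tissue FPKM panel with a planted
  fraction of strictly single-tissue genes over a shared background.
* ``simulate_gene_sets`` — a gene-set universe in which one group
  overlaps a member set at a planted fold-enrichment over baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from octs.io import ExpressionMatrix, GeneSetCollection


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated dataset."""

    genes: pd.DataFrame
    params: dict = field(default_factory=dict)

    def write(self, directory: str | Path, stem: str = "truth") -> None:
        directory = Path(directory)
        frame = self.genes.copy()
        frame.index.name = "gene_id"
        frame.to_csv(directory / f"{stem}.tsv", sep="\t")
        with open(directory / f"{stem}.json", "w", encoding="utf-8") as handle:
            json.dump(self.params, handle, indent=2, sort_keys=True, default=str)
            handle.write("\n")

    @classmethod
    def read(cls, directory: str | Path, stem: str = "truth") -> "SimTruth":
        directory = Path(directory)
        genes = pd.read_csv(directory / f"{stem}.tsv", sep="\t", index_col=0)
        with open(directory / f"{stem}.json", encoding="utf-8") as handle:
            params = json.load(handle)
        return cls(genes=genes, params=params)


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Bone cohort: bimodal FPKM distribution for activity calling


def simulate_cohort(
    n_genes: int = 5000,
    groups: Sequence[str] = ("tibia", "femur", "humerus"),
    replicates: int = 8,
    active_fraction: float = 0.55,
    active_mean_log2: float = 5.0,
    active_sd_log2: float = 2.0,
    replicate_noise_sd: float = 0.25,
    dropout: float = 0.7,
    inactive_scale: float = 0.05,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame, SimTruth]:
    """Simulate a multi-site bone cohort with a planted active gene set.

    Exactly ``round(n_genes * active_fraction)`` genes are active in every
    group: their log2-FPKM is gene-specific Gaussian
    (``active_mean_log2``, ``active_sd_log2``) plus per-replicate noise.
    Inactive genes yield FPKM 0 with probability ``dropout`` and an
    Exponential(``inactive_scale``) trickle otherwise.
    """
    if not 0.0 < active_fraction < 1.0:
        raise ValueError(f"active_fraction must be in (0, 1), got {active_fraction}")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    n_active = int(round(n_genes * active_fraction))
    is_active = np.zeros(n_genes, dtype=bool)
    is_active[rng.choice(n_genes, size=n_active, replace=False)] = True

    base_log2 = rng.normal(active_mean_log2, active_sd_log2, size=n_genes)

    sample_rows = []
    columns = {}
    for tissue in groups:
        for rep in range(1, replicates + 1):
            sample_id = f"{tissue}_r{rep}"
            sample_rows.append(
                {
                    "sample_id": sample_id,
                    "cohort": "bone_comparison",
                    "tissue": tissue,
                    "condition": "other",
                    "animal_id": f"{tissue}_m{rep}",
                    "age_weeks": 10,
                    "sex": "M",
                    "replicate": rep,
                }
            )
            fpkm = np.zeros(n_genes)
            noise = rng.normal(0.0, replicate_noise_sd, size=n_genes)
            fpkm[is_active] = 2.0 ** (base_log2 + noise)[is_active]
            n_inactive = int((~is_active).sum())
            keep = rng.random(n_inactive) >= dropout
            trickle = rng.exponential(inactive_scale, size=n_inactive) * keep
            fpkm[~is_active] = trickle
            columns[sample_id] = fpkm

    frame = pd.DataFrame(columns, index=genes).rename_axis("gene_id")
    matrix = ExpressionMatrix(values=frame, unit="FPKM")
    samples = pd.DataFrame(sample_rows)
    truth = SimTruth(
        genes=pd.DataFrame({"is_active": is_active}, index=frame.index),
        params={
            "n_genes": n_genes,
            "groups": list(groups),
            "replicates": replicates,
            "active_fraction": active_fraction,
            "active_mean_log2": active_mean_log2,
            "active_sd_log2": active_sd_log2,
            "replicate_noise_sd": replicate_noise_sd,
            "dropout": dropout,
            "inactive_scale": inactive_scale,
            "seed": seed,
        },
    )
    return matrix, samples, truth


# ---------------------------------------------------------------------------
# Paired enrichment experiment: 4-component LFC mixture


DEFAULT_COMPONENT_WEIGHTS = (0.05, 0.15, 0.45, 0.35)
DEFAULT_COMPONENT_MEANS = (4.5, 1.0, 0.0, -1.5)
DEFAULT_COMPONENT_SDS = (0.6, 0.3, 0.4, 0.5)


def simulate_enrichment_experiment(
    n_genes: int = 10000,
    n_animals: int = 5,
    weights: Sequence[float] = DEFAULT_COMPONENT_WEIGHTS,
    means: Sequence[float] = DEFAULT_COMPONENT_MEANS,
    sds: Sequence[float] = DEFAULT_COMPONENT_SDS,
    baseline_log2_mean: float = 7.5,
    baseline_log2_sd: float = 1.5,
    nb_size: float = 100.0,
    library_scale_sd: float = 0.1,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame, SimTruth]:
    """Simulate paired osteocyte-enriched vs whole-bone count samples.

    Each gene is assigned a mixture component and a true LFC drawn from
    it; counts are negative binomial around a log-normal per-gene
    baseline, with the fold-change split symmetrically between the
    conditions (whole bone at baseline * 2**(-LFC/2), osteocyte-enriched
    at baseline * 2**(+LFC/2)) and a per-sample library scale on top.
    The symmetric split keeps the two libraries depth-balanced, so
    library-size normalisation recovers ratios on the planted LFC scale
    instead of folding the mixture's compositional imbalance into a
    global shift.  Truth records the component, the true LFC, and the
    planted enrichment label: the gene belongs to a component whose mean
    exceeds the truth-derived threshold mean2 + 2*sd2 (second-highest
    component mean plus two of its standard deviations) and its own true
    LFC also clears that threshold, so a mixture with no component above
    the threshold plants no enriched genes.
    """
    weights = np.asarray(weights, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"component weights must sum to 1, got {weights.sum()}")
    if n_animals < 3:
        raise ValueError(f"need at least 3 animals, got {n_animals}")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)

    component = rng.choice(len(weights), size=n_genes, p=weights)
    true_lfc = rng.normal(means[component], sds[component])
    baseline = 2.0 ** rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_genes)

    rank = np.argsort(-means, kind="stable")
    second = rank[1]
    truth_threshold = float(means[second] + 2.0 * sds[second])
    enriched_components = means > truth_threshold
    is_enriched = enriched_components[component] & (true_lfc > truth_threshold)

    sample_rows = []
    columns: dict[str, np.ndarray] = {}

    def _nb(mean_counts: np.ndarray) -> np.ndarray:
        p = nb_size / (nb_size + mean_counts)
        return rng.negative_binomial(nb_size, p)

    for a in range(1, n_animals + 1):
        animal = f"m{a:02d}"
        for condition, mean_counts in (
            ("whole_bone", baseline * 2.0 ** (-0.5 * true_lfc)),
            ("osteocyte_enriched", baseline * 2.0 ** (0.5 * true_lfc)),
        ):
            scale = 2.0 ** rng.normal(0.0, library_scale_sd)
            sample_id = f"{animal}_{'enr' if condition == 'osteocyte_enriched' else 'whole'}"
            sample_rows.append(
                {
                    "sample_id": sample_id,
                    "cohort": "enrichment",
                    "tissue": "humerus",
                    "condition": condition,
                    "animal_id": animal,
                    "age_weeks": 10,
                    "sex": "M",
                    "replicate": a,
                }
            )
            columns[sample_id] = _nb(mean_counts * scale).astype(np.int64)

    frame = pd.DataFrame(columns, index=genes).rename_axis("gene_id")
    matrix = ExpressionMatrix(values=frame, unit="counts")
    samples = pd.DataFrame(sample_rows)
    truth = SimTruth(
        genes=pd.DataFrame(
            {
                "component": component + 1,
                "true_lfc": true_lfc,
                "is_enriched": is_enriched,
            },
            index=frame.index,
        ),
        params={
            "n_genes": n_genes,
            "n_animals": n_animals,
            "weights": weights.tolist(),
            "means": means.tolist(),
            "sds": sds.tolist(),
            "baseline_log2_mean": baseline_log2_mean,
            "baseline_log2_sd": baseline_log2_sd,
            "nb_size": nb_size,
            "library_scale_sd": library_scale_sd,
            "truth_threshold": truth_threshold,
            "seed": seed,
        },
    )
    return matrix, samples, truth


# ---------------------------------------------------------------------------
# Multi-tissue panel with planted tissue-specific genes


DEFAULT_PANEL_TISSUES = (
    "osteocyte", "adrenal", "aorta", "brown_fat", "brainstem", "cerebellum",
    "heart", "hypothalamus", "kidney", "liver", "lung", "muscle", "white_fat",
)


def simulate_tissue_panel(
    n_genes: int = 2000,
    tissues: Sequence[str] = DEFAULT_PANEL_TISSUES,
    specific_fraction: float = 0.05,
    replicates: int = 4,
    background_mean_log2: float = 4.0,
    background_sd_log2: float = 1.0,
    tissue_effect_sd: float = 0.2,
    replicate_noise_sd: float = 0.2,
    specific_level_log2: float = 8.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame, SimTruth]:
    """Simulate a multi-tissue FPKM panel with planted single-tissue genes.

    Background genes share a gene-level log2 baseline across tissues with
    mild tissue and replicate jitter; planted specific genes are silent
    (FPKM 0) everywhere except their target tissue.
    """
    if len(tissues) < 3:
        raise ValueError(f"need at least 3 tissues, got {len(tissues)}")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    n_specific = int(round(n_genes * specific_fraction))
    specific_idx = rng.choice(n_genes, size=n_specific, replace=False)
    target = np.full(n_genes, "", dtype=object)
    target[specific_idx] = rng.choice(list(tissues), size=n_specific)

    base_log2 = rng.normal(background_mean_log2, background_sd_log2, size=n_genes)
    tissue_effect = {
        t: rng.normal(0.0, tissue_effect_sd, size=n_genes) for t in tissues
    }

    sample_rows = []
    columns = {}
    for tissue in tissues:
        for rep in range(1, replicates + 1):
            sample_id = f"{tissue}_r{rep}"
            sample_rows.append(
                {
                    "sample_id": sample_id,
                    "cohort": "tissue_panel",
                    "tissue": tissue,
                    "condition": "other",
                    "animal_id": f"{tissue}_m{rep}",
                    "age_weeks": 10,
                    "sex": "NA",
                    "replicate": rep,
                }
            )
            log2_fpkm = (
                base_log2
                + tissue_effect[tissue]
                + rng.normal(0.0, replicate_noise_sd, size=n_genes)
            )
            fpkm = 2.0 ** log2_fpkm
            planted = target != ""
            on_target = planted & (target == tissue)
            fpkm[planted & ~on_target] = 0.0
            fpkm[on_target] = 2.0 ** (
                specific_level_log2 + rng.normal(0.0, replicate_noise_sd, int(on_target.sum()))
            )
            columns[sample_id] = fpkm

    frame = pd.DataFrame(columns, index=genes).rename_axis("gene_id")
    matrix = ExpressionMatrix(values=frame, unit="FPKM")
    samples = pd.DataFrame(sample_rows)
    truth = SimTruth(
        genes=pd.DataFrame(
            {"specific_tissue": np.where(target == "", "none", target)},
            index=frame.index,
        ),
        params={
            "n_genes": n_genes,
            "tissues": list(tissues),
            "specific_fraction": specific_fraction,
            "replicates": replicates,
            "specific_level_log2": specific_level_log2,
            "seed": seed,
        },
    )
    return matrix, samples, truth


# ---------------------------------------------------------------------------
# Gene-set universe with one planted over-represented group


def simulate_gene_sets(
    universe_size: int = 16000,
    member_fraction: float = 0.0625,
    n_groups: int = 10,
    group_size_range: tuple[int, int] = (20, 40),
    planted_fe: float = 5.0,
    seed: int = 0,
) -> tuple[GeneSetCollection, set[str], list[str], SimTruth]:
    """Simulate disease-style gene groups over a universe.

    A "member" set (e.g. a signature) of size ``member_fraction *
    universe_size`` is drawn; each group samples its genes so that the
    probability of hitting the member set is ``member_fraction`` at
    baseline and ``planted_fe * member_fraction`` for the single planted
    group (group_01).
    """
    if planted_fe < 1.0:
        raise ValueError(f"planted_fe must be >= 1, got {planted_fe}")
    hit_prob = planted_fe * member_fraction
    if hit_prob > 1.0:
        raise ValueError(
            f"planted_fe={planted_fe} infeasible: fe * member_fraction = "
            f"{hit_prob:.3f} > 1"
        )
    rng = np.random.default_rng(seed)
    universe = _gene_ids(universe_size)
    n_members = int(round(universe_size * member_fraction))
    member_idx = rng.choice(universe_size, size=n_members, replace=False)
    member_mask = np.zeros(universe_size, dtype=bool)
    member_mask[member_idx] = True
    members = {universe[i] for i in member_idx}
    member_pool = np.flatnonzero(member_mask)
    other_pool = np.flatnonzero(~member_mask)

    sets = {}
    rows = []
    for g in range(1, n_groups + 1):
        name = f"group_{g:02d}"
        planted = g == 1 and planted_fe > 1.0
        q = hit_prob if planted else member_fraction
        size = int(rng.integers(group_size_range[0], group_size_range[1] + 1))
        n_hit = int(rng.binomial(size, q))
        n_hit = min(n_hit, len(member_pool))
        chosen = np.concatenate(
            [
                rng.choice(member_pool, size=n_hit, replace=False),
                rng.choice(other_pool, size=size - n_hit, replace=False),
            ]
        )
        sets[name] = frozenset(universe[i] for i in chosen)
        rows.append(
            {"group": name, "size": size, "planted": planted, "hit_prob": q, "n_hit": n_hit}
        )

    truth = SimTruth(
        genes=pd.DataFrame(rows).set_index("group"),
        params={
            "universe_size": universe_size,
            "member_fraction": member_fraction,
            "n_groups": n_groups,
            "group_size_range": list(group_size_range),
            "planted_fe": planted_fe,
            "seed": seed,
        },
    )
    collection = GeneSetCollection(
        sets=sets, descriptions={name: "simulated" for name in sets}
    )
    return collection, members, universe, truth
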