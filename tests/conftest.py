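import numpy as np
import pandas as pd
import pytest

from octs.io import ExpressionMatrix


@pytest.fixture
def toy_fpkm():
    """4 genes x 3 samples with easily hand-checked values."""
    frame = pd.DataFrame(
        {
            "s1": [8.0, 1.0, 0.0, 2.0],
            "s2": [4.0, 2.0, 0.5, 2.0],
            "s3": [2.0, 4.0, 1.0, 2.0],
        },
        index=["gA", "gB", "gC", "gD"],
    ).rename_axis("gene_id")
    return ExpressionMatrix(values=frame, unit="FPKM")


@pytest.fixture
def enrichment_samples():
    """Paired enrichment cohort metadata for 3 animals."""
    rows = []
    for a in (1, 2, 3):
        for cond, tag in (("osteocyte_enriched", "enr"), ("whole_bone", "whole")):
            rows.append(
                {
                    "sample_id": f"m{a}_{tag}",
                    "cohort": "enrichment",
                    "tissue": "humerus",
                    "condition": cond,
                    "animal_id": f"m{a}",
                    "age_weeks": 10,
                    "sex": "M",
                    "replicate": a,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def bimodal_sample():
    """One sample drawn from the bimodal FPKM model: half zeros/near-zero,
    half log-normal active with log2 mean 5, sd 1.5."""
    rng = np.random.default_rng(42)
    n = 4000
    active = 2.0 ** rng.normal(5.0, 1.5, size=n // 2)
    inactive = np.where(rng.random(n // 2) < 0.7, 0.0, rng.exponential(0.05, n // 2))
    return np.concatenate([active, inactive])


@pytest.fixture(scope="session")
def default_cohort():
    """Default simulated bone cohort plus activity-pipeline outputs."""
    from octs import ActivityThreshold, call_activity, simulate_cohort

    matrix, samples, truth = simulate_cohort(seed=7)
    est = ActivityThreshold().fit(matrix)
    zfpkm = est.transform(matrix)
    groups = {t: list(g["sample_id"]) for t, g in samples.groupby("tissue")}
    status = call_activity(zfpkm, groups)
    return {
        "matrix": matrix,
        "samples": samples,
        "truth": truth,
        "est": est,
        "zfpkm": zfpkm,
        "groups": groups,
        "status": status,
    }


@pytest.fixture(scope="session")
def default_enrichment():
    """Default simulated paired enrichment experiment, fully fitted."""
    from octs import LfcMixture, compute_lfc, libsize_normalize, simulate_enrichment_experiment

    matrix, samples, truth = simulate_enrichment_experiment(seed=1)
    lfc = compute_lfc(libsize_normalize(matrix), samples)
    model = LfcMixture(seed=1).fit(lfc)
    calls = model.predict_table(lfc)
    return {
        "matrix": matrix,
        "samples": samples,
        "truth": truth,
        "lfc": lfc,
        "model": model,
        "calls": calls,
    }
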