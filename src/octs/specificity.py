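"""Tau tissue-specificity index over a multi-tissue expression panel.

Tau summarises how restricted a gene's expression is across tissues:

    tau = sum_i (1 - x_i / max_j x_j) / (N_t - 1)

computed on per-tissue median log2-FPKM values after quantile
normalisation, with negative values floored at zero.  Tau is 0 for a gene
expressed equally everywhere and 1 for a gene expressed in exactly one
tissue.  Genes are binned as low (tau < 0.15), moderate
(0.15 <= tau <= 0.85) or high (tau > 0.85) specificity.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from octs.io import ExpressionMatrix

logger = logging.getLogger("octs")

LOW_CUT = 0.15
HIGH_CUT = 0.85
DEFAULT_PSEUDOCOUNT = 1.0


def tissue_medians(
    matrix: ExpressionMatrix | pd.DataFrame,
    tissue_groups: Mapping[str, Iterable[str]],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Median log2(FPKM + pseudocount) per gene and tissue.

    A pooled pseudo-tissue (e.g. "osteocyte" spanning tibia, femur and
    humerus samples) is expressed simply as one entry of ``tissue_groups``
    listing all its samples.
    """
    frame = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    cols = {}
    for tissue, samples in tissue_groups.items():
        samples = list(samples)
        if not samples:
            raise ValueError(f"tissue {tissue!r} has no samples")
        missing = [s for s in samples if s not in frame.columns]
        if missing:
            raise ValueError(f"tissue {tissue!r}: sample(s) {missing} not in matrix")
        cols[tissue] = np.median(np.log2(frame[samples].to_numpy() + pseudocount), axis=1)
    logger.info("tissue medians over %d tissues", len(cols))
    return pd.DataFrame(cols, index=frame.index).rename_axis("gene_id")


def quantile_normalize(medians: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common reference distribution.

    The reference is the row-wise mean of the column-sorted matrix; ties
    within a column receive the mean of the reference values they span.
    """
    if medians.shape[1] < 2:
        logger.warning("quantile normalisation with a single column is the identity")
        return medians.copy()
    arr = medians.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        sorted_vals = col[order]
        start = 0
        while start < len(col):
            stop = start
            while stop + 1 < len(col) and sorted_vals[stop + 1] == sorted_vals[start]:
                stop += 1
            assigned[order[start : stop + 1]] = reference[start : stop + 1].mean()
            start = stop + 1
        out[:, j] = assigned
    return pd.DataFrame(out, index=medians.index, columns=medians.columns)


def tau_index(row: np.ndarray) -> float:
    """Tau for one gene over tissues; NaN if no tissue is positive."""
    x = np.maximum(np.asarray(row, dtype=float), 0.0)
    peak = x.max()
    if peak <= 0:
        return float("nan")
    xhat = x / peak
    return float(np.sum(1.0 - xhat) / (x.size - 1))


def classify_tau(tau: float) -> str:
    if np.isnan(tau):
        return "undefined"
    if tau < LOW_CUT:
        return "low"
    if tau > HIGH_CUT:
        return "high"
    return "moderate"


def compute_tau(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Tau and specificity class from a gene x tissue matrix.

    Negative post-normalisation values are floored at zero before the
    ratio; all-zero genes get tau = NaN, class "undefined".
    """
    if normalized.shape[1] < 2:
        raise ValueError("Tau needs at least 2 tissues")
    tau = normalized.apply(lambda r: tau_index(r.to_numpy()), axis=1)
    table = pd.DataFrame({"tau": tau})
    table["spec_class"] = table["tau"].map(classify_tau)
    return table.rename_axis("gene_id")


class TauSpecificity(BaseEstimator, TransformerMixin):
    """Tissue-specificity scoring as a transformer.

    ``fit`` is stateless apart from recording tissue groups; ``transform``
    maps an FPKM matrix to the per-gene Tau table via tissue medians and
    quantile normalisation.

    Parameters
    ----------
    tissue_groups
        Mapping tissue name -> sample ids; pooled pseudo-tissues allowed.
    pseudocount
        Added to FPKM inside the log2 of the medians step.
    """

    def __init__(
        self,
        tissue_groups: Mapping[str, Iterable[str]] | None = None,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ):
        self.tissue_groups = tissue_groups
        self.pseudocount = pseudocount

    def fit(self, X: ExpressionMatrix | pd.DataFrame, y=None) -> "TauSpecificity":
        if self.tissue_groups is None:
            raise ValueError("tissue_groups must be provided")
        self.n_tissues_ = len(self.tissue_groups)
        return self

    def transform(self, X: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
        medians = tissue_medians(X, self.tissue_groups, pseudocount=self.pseudocount)
        self.medians_ = medians
        self.normalized_ = quantile_normalize(medians)
        return compute_tau(self.normalized_)
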