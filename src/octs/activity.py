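"""Active-expression calling from bulk RNA-seq FPKM via the zFPKM transform.

Bulk log2-FPKM distributions are bimodal: a near-zero mass of inactive
genes and a roughly Gaussian mode of actively transcribed genes.  For each
sample we locate the active mode as the maximum of a Gaussian kernel
density estimate of log2(FPKM > 0), fit a half-normal spread above that
peak, and z-score every gene against the resulting Gaussian:

    zFPKM = (log2(FPKM) - mu) / SD

Genes with zFPKM above a conservative cutoff (default -2.6) are actively
expressed in that sample; a gene is called *active* in a replicate group
only when it clears its sample-specific threshold in every replicate,
*inactive* when it clears none, and *variable* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator, TransformerMixin

from octs.io import ExpressionMatrix

DEFAULT_Z_CUTOFF = -2.6
#: Minimum strictly-positive observations required to fit a density.
DEFAULT_MIN_POSITIVE = 50
KDE_GRID_POINTS = 4096

ACTIVE, INACTIVE, VARIABLE = "active", "inactive", "variable"


@dataclass
class ActivityModel:
    """Per-sample Gaussian of active expression.

    Attributes
    ----------
    mu
        log2-FPKM at the kernel-density maximum (the active mode).
    sd
        Half-normal spread estimated from values above ``mu``.
    z_cutoff
        Activity cutoff on the zFPKM scale.
    fpkm_threshold
        The same cutoff back on the FPKM scale, ``2 ** (mu + z_cutoff * sd)``;
        a gene's zFPKM exceeds ``z_cutoff`` iff its FPKM exceeds this.
    """

    sample_id: str
    mu: float
    sd: float
    z_cutoff: float = DEFAULT_Z_CUTOFF

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"sample {self.sample_id!r}: sd must be > 0, got {self.sd}")

    @property
    def fpkm_threshold(self) -> float:
        return float(2.0 ** (self.mu + self.z_cutoff * self.sd))

    def zfpkm(self, fpkm: np.ndarray) -> np.ndarray:
        fpkm = np.asarray(fpkm, dtype=float)
        with np.errstate(divide="ignore"):
            return np.where(
                fpkm > 0, (np.log2(np.where(fpkm > 0, fpkm, 1.0)) - self.mu) / self.sd,
                -np.inf,
            )


def fit_activity_model(
    fpkm_values: np.ndarray,
    sample_id: str = "",
    z_cutoff: float = DEFAULT_Z_CUTOFF,
    min_positive: int = DEFAULT_MIN_POSITIVE,
    grid_points: int = KDE_GRID_POINTS,
) -> ActivityModel:
    """Fit the per-sample activity Gaussian.

    Zeros are omitted; the KDE uses a Gaussian kernel with Scott's
    bandwidth (``sigma_hat * n**(-1/5)``), evaluated on a ``grid_points``
    regular grid spanning the data range extended by three bandwidths.
    The mode is the (first, on ties) grid argmax; the spread is the
    half-normal estimator ``sqrt(mean((x - mu)**2))`` over ``x > mu``.
    """
    fpkm_values = np.asarray(fpkm_values, dtype=float)
    positive = fpkm_values[fpkm_values > 0]
    if positive.size < min_positive:
        raise ValueError(
            f"sample {sample_id!r}: {positive.size} positive values, "
            f"need at least {min_positive} to fit a density"
        )
    log2_fpkm = np.log2(positive)
    sigma_hat = float(np.std(log2_fpkm, ddof=1))
    if sigma_hat == 0.0:
        raise ValueError(
            f"sample {sample_id!r}: all positive values identical "
            f"({positive[0]} FPKM); density is degenerate"
        )
    bandwidth = sigma_hat * positive.size ** (-1.0 / 5.0)
    # gaussian_kde scales a scalar bw_method by the data std internally.
    kde = gaussian_kde(log2_fpkm, bw_method=positive.size ** (-1.0 / 5.0))
    grid = np.linspace(
        log2_fpkm.min() - 3.0 * bandwidth,
        log2_fpkm.max() + 3.0 * bandwidth,
        grid_points,
    )
    density = kde(grid)
    mu = float(grid[int(np.argmax(density))])

    above = log2_fpkm[log2_fpkm > mu]
    if above.size == 0:
        raise ValueError(f"sample {sample_id!r}: no values above the density peak")
    sd = float(np.sqrt(np.mean((above - mu) ** 2)))
    return ActivityModel(sample_id=sample_id, mu=mu, sd=sd, z_cutoff=z_cutoff)


class ActivityThreshold(BaseEstimator, TransformerMixin):
    """Per-sample active-expression thresholding, sklearn style.

    ``fit`` learns one :class:`ActivityModel` per sample (column);
    ``transform`` maps FPKM to zFPKM (``-inf`` sentinel for FPKM = 0);
    ``predict`` returns the boolean above-threshold matrix.

    Parameters
    ----------
    z_cutoff
        Activity cutoff on the zFPKM scale; strict (``z > z_cutoff``).
    min_positive
        Floor on strictly positive values per sample for the density fit.

    Attributes
    ----------
    models_ : dict[str, ActivityModel]
        Fitted per-sample models.
    model_table_ : pandas.DataFrame
        (mu, sd, fpkm_threshold) per sample.
    """

    def __init__(
        self,
        z_cutoff: float = DEFAULT_Z_CUTOFF,
        min_positive: int = DEFAULT_MIN_POSITIVE,
        grid_points: int = KDE_GRID_POINTS,
    ):
        self.z_cutoff = z_cutoff
        self.min_positive = min_positive
        self.grid_points = grid_points

    def fit(self, X: ExpressionMatrix | pd.DataFrame, y=None) -> "ActivityThreshold":
        frame = _as_fpkm_frame(X)
        self.models_ = {
            sample: fit_activity_model(
                frame[sample].to_numpy(),
                sample_id=sample,
                z_cutoff=self.z_cutoff,
                min_positive=self.min_positive,
                grid_points=self.grid_points,
            )
            for sample in frame.columns
        }
        self.model_table_ = pd.DataFrame(
            {
                "mu": {s: m.mu for s, m in self.models_.items()},
                "sd": {s: m.sd for s, m in self.models_.items()},
                "fpkm_threshold": {s: m.fpkm_threshold for s, m in self.models_.items()},
            }
        ).rename_axis("sample_id")
        return self

    def transform(self, X: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
        """zFPKM matrix; raises if a sample has no fitted model."""
        frame = _as_fpkm_frame(X)
        missing = [s for s in frame.columns if s not in self.models_]
        if missing:
            raise ValueError(f"no fitted activity model for sample(s) {missing}")
        out = {s: self.models_[s].zfpkm(frame[s].to_numpy()) for s in frame.columns}
        return pd.DataFrame(out, index=frame.index, columns=frame.columns)

    def predict(self, X: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
        """Boolean above-threshold calls per gene and sample (strict >)."""
        return self.transform(X) > self.z_cutoff


def zfpkm_transform(
    matrix: ExpressionMatrix | pd.DataFrame,
    models: Mapping[str, ActivityModel],
) -> pd.DataFrame:
    """Functional form of :meth:`ActivityThreshold.transform`."""
    est = ActivityThreshold()
    est.models_ = dict(models)
    return est.transform(matrix)


def call_activity(
    zfpkm: pd.DataFrame,
    groups: Mapping[str, Iterable[str]],
    z_cutoff: float = DEFAULT_Z_CUTOFF,
) -> pd.DataFrame:
    """Replicate-level activity status per gene and sample group.

    A gene is ``active`` in a group iff its zFPKM strictly exceeds
    ``z_cutoff`` in *all* replicates, ``inactive`` iff in none, and
    ``variable`` otherwise.  Every group needs at least two replicates.
    """
    status: dict[str, pd.Series] = {}
    for group, samples in groups.items():
        samples = list(samples)
        if len(samples) == 0:
            raise ValueError(f"group {group!r} is empty")
        if len(samples) < 2:
            raise ValueError(f"group {group!r} has {len(samples)} replicate(s); need >=2")
        missing = [s for s in samples if s not in zfpkm.columns]
        if missing:
            raise ValueError(f"group {group!r}: sample(s) {missing} not in zFPKM matrix")
        above = zfpkm[samples].to_numpy() > z_cutoff
        n_above = above.sum(axis=1)
        labels = np.where(
            n_above == len(samples), ACTIVE,
            np.where(n_above == 0, INACTIVE, VARIABLE),
        )
        status[group] = pd.Series(labels, index=zfpkm.index)
    return pd.DataFrame(status).rename_axis("gene_id")


def active_union(status: pd.DataFrame, scope: Iterable[str] | None = None) -> set[str]:
    """Union of the per-group active gene sets over ``scope`` groups."""
    scope = list(status.columns) if scope is None else list(scope)
    if not scope:
        raise ValueError("scope is empty")
    unknown = [g for g in scope if g not in status.columns]
    if unknown:
        raise ValueError(f"unknown group(s) {unknown}")
    mask = (status[scope] == ACTIVE).any(axis=1)
    return set(status.index[mask])


def sample_correlation(
    matrix: ExpressionMatrix | pd.DataFrame,
    gene_subset: Iterable[str] | None = None,
    groups: Mapping[str, Iterable[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Pearson correlation between samples over a gene subset.

    Zero-variance samples yield NaN correlations (reported, not raised).
    When ``groups`` is given, also returns the mean of between-sample
    correlations for each ordered pair of groups (self-pairs exclude the
    unit diagonal).
    """
    frame = _as_fpkm_frame(matrix)
    if gene_subset is not None:
        gene_subset = list(gene_subset)
        if len(gene_subset) < 3:
            raise ValueError(f"need >=3 genes for correlation, got {len(gene_subset)}")
        frame = frame.loc[gene_subset]
    corr = frame.corr(method="pearson")

    group_means = None
    if groups is not None:
        rows = {}
        for ga, sa in groups.items():
            rows[ga] = {}
            for gb, sb in groups.items():
                block = corr.loc[list(sa), list(sb)].to_numpy().astype(float)
                if ga == gb:
                    off = ~np.eye(block.shape[0], dtype=bool)
                    rows[ga][gb] = float(np.nanmean(block[off])) if off.any() else np.nan
                else:
                    rows[ga][gb] = float(np.nanmean(block))
        group_means = pd.DataFrame(rows).T
    return corr, group_means


def _as_fpkm_frame(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(matrix, ExpressionMatrix):
        return matrix.values
    return matrix
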