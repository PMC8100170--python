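"""Osteocyte-enrichment calling from paired enriched vs whole-bone counts.

The enrichment cohort pairs, within each animal, a bone sample with the
marrow flushed and the osteocyte fraction retained ("osteocyte_enriched")
against the contralateral intact bone ("whole_bone").  Per-gene log2
fold-changes of library-size-normalised counts between the paired
conditions form a multimodal distribution: a small component of strongly
osteocyte-enriched genes, a component of moderately enriched genes, a bulk
of unchanged genes, and a component depleted by marrow removal.

A univariate Gaussian mixture with unequal variances is fitted to the
per-gene mean LFCs by expectation-maximisation, initialised from k-means
cluster statistics, with the number of components chosen by BIC.  An
*enrichment threshold* is then set two standard deviations above the mean
of the component with the second-highest mean — high enough to exclude
genes plausibly belonging to the moderately-enriched component — and a
gene is called enriched when the lower bound of the 95% confidence
interval of its mean LFC (a t-interval across animals) strictly exceeds
that threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm, t as student_t
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from octs.io import ExpressionMatrix

logger = logging.getLogger("octs")

DEFAULT_K_CANDIDATES = (1, 2, 3, 4, 5, 6)
DEFAULT_PSEUDOCOUNT = 1.0
SD_FLOOR = 1e-3
EM_TOL = 1e-8
EM_MAX_ITER = 2000
KMEANS_RESTARTS = 10
MAX_EM_RESTARTS = 3


def libsize_normalize(counts: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Scale each sample by (mean library size / its library size).

    After scaling, every column sums to the mean of the original library
    sizes, so per-gene ratios between samples are depth-comparable.
    """
    if isinstance(counts, ExpressionMatrix):
        if counts.unit != "counts":
            raise ValueError(f"expected a counts matrix, got unit {counts.unit!r}")
        frame = counts.values
    else:
        frame = counts
    totals = frame.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    factors = totals.mean() / totals
    return frame * factors


def compute_lfc(
    normalized: pd.DataFrame,
    samples: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-animal and mean log2 fold-change, osteocyte-enriched over whole bone.

    ``samples`` is a sample table restricted (or restrictable) to the
    enrichment cohort; each animal must contribute exactly one sample of
    each condition.  Returns a DataFrame with one ``lfc_<animal>`` column
    per animal plus ``mean_lfc``.
    """
    enr = samples[samples["cohort"] == "enrichment"]
    if not len(enr):
        raise ValueError("no enrichment-cohort samples in the sample table")
    pairs: dict[str, tuple[str, str]] = {}
    for animal, grp in enr.groupby("animal_id"):
        cond = grp.set_index("condition")["sample_id"]
        if sorted(cond.index) != ["osteocyte_enriched", "whole_bone"]:
            raise ValueError(
                f"animal {animal!r} is unpaired: conditions {sorted(cond.index)}"
            )
        pairs[animal] = (cond["osteocyte_enriched"], cond["whole_bone"])
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")

    out = {}
    for animal, (s_enr, s_whole) in sorted(pairs.items()):
        out[f"lfc_{animal}"] = np.log2(
            (normalized[s_enr] + pseudocount) / (normalized[s_whole] + pseudocount)
        )
    table = pd.DataFrame(out, index=normalized.index)
    table["mean_lfc"] = table.mean(axis=1)
    return table.rename_axis("gene_id")


@dataclass
class GmmFit:
    """A fitted univariate Gaussian mixture with unequal variances."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    bic: float
    n: int
    loglik_trace: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if (self.sds <= 0).any():
            raise ValueError("all component sds must be positive")
        if np.any(np.diff(self.loglik_trace) < -1e-7):
            raise ValueError("EM log-likelihood decreased")

    @property
    def rank_by_mean(self) -> np.ndarray:
        """Component indices ordered by descending mean; ties broken by
        larger weight, then lower index."""
        order = sorted(
            range(self.k),
            key=lambda i: (-self.means[i], -self.weights[i], i),
        )
        return np.asarray(order)

    def component_by_rank(self, rank: int) -> int:
        """0-based index of the rank-th most enriched component (rank 0 =
        highest mean)."""
        return int(self.rank_by_mean[rank])

    def log_density(self, x: np.ndarray) -> np.ndarray:
        return logsumexp(self._component_logpdf(x), axis=1)

    def posteriors(self, x: np.ndarray) -> np.ndarray:
        lp = self._component_logpdf(x)
        return np.exp(lp - logsumexp(lp, axis=1, keepdims=True))

    def _component_logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)[:, None]
        return np.log(self.weights)[None, :] + norm.logpdf(
            x, loc=self.means[None, :], scale=self.sds[None, :]
        )


def _em_fit(
    x: np.ndarray,
    weights: np.ndarray,
    means: np.ndarray,
    sds: np.ndarray,
    tol: float,
    max_iter: int,
    sd_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """EM for a 1-D Gaussian mixture with per-component variances.

    Returns (weights, means, sds, loglik_trace); raises on sd collapse.
    """
    n = x.size
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        # E-step
        logp = np.log(weights)[None, :] + norm.logpdf(
            x[:, None], loc=means[None, :], scale=sds[None, :]
        )
        log_total = logsumexp(logp, axis=1)
        loglik = float(log_total.sum())
        trace.append(loglik)
        resp = np.exp(logp - log_total[:, None])
        if abs(loglik - prev) < tol:
            break
        prev = loglik
        # M-step
        nk = resp.sum(axis=0)
        if (nk < 1e-10).any():
            raise _DegenerateEM("empty component")
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(var)
        if (sds < sd_floor).any():
            raise _DegenerateEM("component sd collapsed below floor")
    return weights, means, sds, np.asarray(trace)


class _DegenerateEM(RuntimeError):
    pass


def _kmeans_init(
    x: np.ndarray, k: int, seed: int, sd_floor: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Initial mixture parameters from seeded k-means cluster statistics."""
    if k == 1:
        return (
            np.array([1.0]),
            np.array([float(x.mean())]),
            np.array([max(float(x.std()), sd_floor)]),
        )
    km = KMeans(n_clusters=k, n_init=KMEANS_RESTARTS, random_state=seed)
    labels = km.fit_predict(x[:, None])
    weights = np.empty(k)
    means = np.empty(k)
    sds = np.empty(k)
    for c in range(k):
        members = x[labels == c]
        weights[c] = members.size / x.size
        means[c] = members.mean() if members.size else x.mean()
        sds[c] = max(members.std() if members.size > 1 else x.std(), sd_floor)
    return weights, means, sds


def fit_lfc_gmm(
    lfc_values: np.ndarray,
    k_candidates: tuple[int, ...] = DEFAULT_K_CANDIDATES,
    seed: int = 0,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    sd_floor: float = SD_FLOOR,
) -> GmmFit:
    """Fit the LFC mixture for each candidate k and return the BIC winner.

    For each k: seeded k-means (10 restarts, best inertia) supplies
    initial weights/means/sds; EM runs to a log-likelihood change below
    ``tol`` or ``max_iter`` sweeps; BIC = -2*loglik + (3k - 1)*ln(n)
    (lower is better).  A degenerate fit (component sd collapsing below
    ``sd_floor``) is retried up to three times with jittered initial
    means before that k is abandoned.
    """
    x = np.asarray(lfc_values, dtype=float)
    x = x[np.isfinite(x)]
    kmax = max(k_candidates)
    if x.size < 10 * kmax:
        raise ValueError(
            f"{x.size} values is too few for k up to {kmax}; need >= {10 * kmax}"
        )
    rng = np.random.default_rng(seed)
    best: GmmFit | None = None
    for k in k_candidates:
        weights, means, sds = _kmeans_init(x, k, seed, sd_floor)
        fit = None
        for attempt in range(MAX_EM_RESTARTS + 1):
            try:
                w, m, s, trace = _em_fit(x, weights, means, sds, tol, max_iter, sd_floor)
            except _DegenerateEM:
                jitter = rng.normal(scale=0.1 * max(x.std(), sd_floor), size=k)
                means = means + jitter
                sds = np.maximum(sds, 10 * sd_floor)
                continue
            loglik = float(trace[-1])
            bic = -2.0 * loglik + (3 * k - 1) * np.log(x.size)
            fit = GmmFit(
                k=k, weights=w, means=m, sds=s, loglik=loglik, bic=bic,
                n=x.size, loglik_trace=trace,
            )
            break
        if fit is None:
            logger.warning("k=%d: EM degenerate after %d restarts; skipped",
                           k, MAX_EM_RESTARTS)
            continue
        logger.info("k=%d: loglik=%.3f BIC=%.3f", k, fit.loglik, fit.bic)
        if best is None or fit.bic < best.bic:
            best = fit
    if best is None:
        raise RuntimeError("every candidate k produced a degenerate EM fit")
    return best


def enrichment_threshold(fit: GmmFit) -> float:
    """Mean + 2 SD of the component with the second-highest mean."""
    if fit.k < 2:
        raise ValueError(f"threshold needs k >= 2 components, got k={fit.k}")
    second = fit.component_by_rank(1)
    return float(fit.means[second] + 2.0 * fit.sds[second])


def call_enriched(
    lfc_table: pd.DataFrame,
    threshold: float,
    conf: float = 0.95,
    interval: str = "t",
    fit: GmmFit | None = None,
) -> pd.DataFrame:
    """CI-based enrichment calls per gene.

    The confidence interval of a gene's mean LFC is
    ``mean +/- q * sd / sqrt(n)`` over its per-animal LFCs, with ``q``
    the two-sided t quantile at ``conf`` on n-1 degrees of freedom
    (``interval="normal"`` swaps in the normal quantile).  A gene is
    enriched iff the CI's lower bound strictly exceeds the threshold; a
    zero-variance gene has a point interval and is decided by its mean.
    Mixture posteriors are appended when ``fit`` is given.
    """
    lfc_cols = [c for c in lfc_table.columns if c.startswith("lfc_")]
    if len(lfc_cols) < 2:
        raise ValueError("need per-animal LFCs from >=2 animals")
    per_animal = lfc_table[lfc_cols].to_numpy(dtype=float)
    n = per_animal.shape[1]
    mean = per_animal.mean(axis=1)
    sd = per_animal.std(axis=1, ddof=1)
    if interval == "t":
        q = float(student_t.ppf(0.5 * (1.0 + conf), df=n - 1))
    elif interval == "normal":
        q = float(norm.ppf(0.5 * (1.0 + conf)))
    else:
        raise ValueError(f"unknown interval family {interval!r}")
    half = q * sd / np.sqrt(n)
    ci_low, ci_high = mean - half, mean + half

    out = pd.DataFrame(
        {"mean_lfc": mean, "ci_low": ci_low, "ci_high": ci_high},
        index=lfc_table.index,
    ).rename_axis("gene_id")
    out["enriched"] = np.where(sd == 0, mean > threshold, ci_low > threshold)
    out["enriched"] = out["enriched"].astype(bool)
    if fit is not None:
        post = fit.posteriors(mean)
        for rank, comp in enumerate(fit.rank_by_mean, start=1):
            out[f"posterior_c{rank}"] = post[:, comp]
    return out


class LfcMixture(BaseEstimator):
    """Gaussian-mixture enrichment model over per-gene mean LFCs.

    ``fit`` selects k by BIC among ``k_candidates`` using k-means-seeded
    EM, and derives the enrichment threshold (mean + 2 SD of the
    second-most-enriched component).  ``predict`` takes a per-animal LFC
    table and returns boolean enrichment calls; ``predict_table`` returns
    the full call table with CIs and posteriors.

    Attributes
    ----------
    fit_ : GmmFit
        Winning mixture (weights_, means_, sds_ mirror its fields).
    threshold_ : float
        Enrichment threshold in LFC units.
    bic_by_k_ : dict[int, float]
        BIC of the best non-degenerate fit per candidate k.
    """

    def __init__(
        self,
        k_candidates: tuple[int, ...] = DEFAULT_K_CANDIDATES,
        seed: int = 0,
        tol: float = EM_TOL,
        max_iter: int = EM_MAX_ITER,
        conf: float = 0.95,
        interval: str = "t",
    ):
        self.k_candidates = k_candidates
        self.seed = seed
        self.tol = tol
        self.max_iter = max_iter
        self.conf = conf
        self.interval = interval

    def fit(self, X, y=None) -> "LfcMixture":
        """X: 1-D array of per-gene mean LFCs, or a compute_lfc table."""
        values = X["mean_lfc"].to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
        self.fit_ = fit_lfc_gmm(
            values,
            k_candidates=self.k_candidates,
            seed=self.seed,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        self.weights_ = self.fit_.weights
        self.means_ = self.fit_.means
        self.sds_ = self.fit_.sds
        self.k_ = self.fit_.k
        self.threshold_ = enrichment_threshold(self.fit_) if self.fit_.k >= 2 else np.nan
        return self

    def predict_table(self, lfc_table: pd.DataFrame) -> pd.DataFrame:
        return call_enriched(
            lfc_table,
            threshold=self.threshold_,
            conf=self.conf,
            interval=self.interval,
            fit=self.fit_,
        )

    def predict(self, lfc_table: pd.DataFrame) -> np.ndarray:
        return self.predict_table(lfc_table)["enriched"].to_numpy()
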