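"""Count preprocessing: low-count filter, TMM normalization, log-CPM, PCA QC.

TMM (trimmed mean of M-values) is implemented from the published definition:
for each sample against a reference, gene-wise log-ratios M weighted by their
asymptotic variances are doubly trimmed (by M and by average log abundance)
and averaged; genes with a zero in either sample are excluded and the factors
are rescaled to geometric mean 1.

Hidden-batch correction is deliberately not part of this pipeline; a log
message flags the omission whenever normalization runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedMatrix",
    "filter_low_counts",
    "tmm_factors",
    "normalize",
    "pca_qc",
]


@dataclass
class NormalizedMatrix:
    """log2 CPM-TMM expression with its normalization bookkeeping.

    ``values`` is log2(cpm + pseudocount); ``cpm`` is the linear CPM-TMM
    matrix without pseudocount.  ``norm_factors`` have geometric mean 1.
    """

    values: pd.DataFrame
    cpm: pd.DataFrame
    norm_factors: pd.Series
    lib_sizes: pd.Series
    pseudocount: float = 1.0

    def linear(self, pseudocount: float = 0.0) -> pd.DataFrame:
        return self.cpm + pseudocount


def _cpm(counts: pd.DataFrame) -> pd.DataFrame:
    lib = counts.sum(axis=0).astype(float)
    return counts / lib * 1e6


def filter_low_counts(
    counts: pd.DataFrame,
    cpm_threshold: float = 1.0,
    min_samples_fraction: float = 0.5,
) -> pd.DataFrame:
    """Keep genes with CPM >= cpm_threshold in at least a fraction of samples.

    Gene order is preserved.  Raises if nothing survives.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    cpm = _cpm(counts)
    keep = (cpm >= cpm_threshold).mean(axis=1) >= min_samples_fraction
    if not keep.any():
        raise ValueError(
            f"low-count filter (cpm >= {cpm_threshold} in >= "
            f"{min_samples_fraction:.0%} of samples) removed every gene"
        )
    return counts.loc[keep]


def _quantile_ref(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> int:
    """Reference sample: upper-quartile of scaled counts closest to the mean."""
    f = np.percentile(counts / lib[None, :], p * 100, axis=0)
    return int(np.argmin(np.abs(f - f.mean())))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    abs_trim: float,
) -> float:
    """log2 TMM factor of one sample against the reference."""
    with np.errstate(divide="ignore", invalid="ignore"):
        po, pr = obs / lib_obs, ref / lib_ref
        m = np.log2(po) - np.log2(pr)
        a = 0.5 * (np.log2(po) + np.log2(pr))
    fin = np.isfinite(m) & np.isfinite(a)
    m, a = m[fin], a[fin]
    obs_f, ref_f = obs[fin], ref[fin]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 0.0
    # inverse asymptotic variance of M (delta method, binomial sampling)
    w = (lib_obs - obs_f) / (lib_obs * obs_f) + (lib_ref - ref_f) / (lib_ref * ref_f)

    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or not np.isfinite(w[keep]).all():
        return 0.0
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scaling factors, geometric mean 1."""
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0].tolist()
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    if ref_sample is None:
        ref_idx = _quantile_ref(mat, lib)
    else:
        ref_idx = counts.columns.get_loc(ref_sample)
    log_f = np.array(
        [
            _tmm_pair(mat[:, j], mat[:, ref_idx], lib[j], lib[ref_idx],
                      logratio_trim, abs_trim)
            for j in range(mat.shape[1])
        ]
    )
    factors = 2.0**log_f
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def normalize(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> NormalizedMatrix:
    """CPM against the TMM-effective library size, then log2(x + pseudocount)."""
    if factors is None:
        factors = tmm_factors(counts)
    logger.info(
        "normalizing %d genes x %d samples (TMM-CPM); hidden-batch correction "
        "is not applied by this pipeline", *counts.shape
    )
    lib = counts.sum(axis=0).astype(float)
    eff = lib * factors.reindex(counts.columns)
    cpm = counts / eff * 1e6
    values = np.log2(cpm + pseudocount)
    return NormalizedMatrix(
        values=values,
        cpm=cpm,
        norm_factors=factors,
        lib_sizes=lib,
        pseudocount=pseudocount,
    )


def pca_qc(norm: NormalizedMatrix, n_components: int = 5) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample PC scores and explained-variance fractions of log expression."""
    from sklearn.decomposition import PCA

    if norm.values.shape[1] < 3:
        raise ValueError("PCA QC needs at least 3 samples")
    X = norm.values.to_numpy().T  # samples x genes
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    scores_df = pd.DataFrame(
        scores, index=norm.values.columns, columns=[f"PC{i+1}" for i in range(k)]
    )
    return scores_df, pca.explained_variance_ratio_
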