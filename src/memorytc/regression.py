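"""Per-gene polynomial time-course regression with hierarchical backward
stepwise refinement.

Each gene's log2 expression is modeled as a quadratic function of time whose
intercept and slopes may shift with memory, strain, and their interaction —
a 12-term model (intercept; memory; strain; memory*strain; t and t2, each
plain and crossed with memory, strain, memory*strain).  Time is in raw
minutes (no centering), memory/strain coded 0/1 with reference (WT,
no-memory), so coefficient magnitudes are per-minute (or per-minute**2)
log2-expression effects against that baseline.

Backward stepwise removes, one at a time, the least significant term with
p > alpha among terms that are *removable*: a term may not leave while a
retained higher-order term marginalizes it (t2*memory keeps t, t2, memory
and t*memory in the model).  After refinement, genes with no significant
time-family term are dropped under Benjamini-Hochberg FDR control across
genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import TERM_NAMES, design_row

__all__ = [
    "TERM_NAMES",
    "TIME_TERMS",
    "build_design",
    "fit_gene",
    "backward_stepwise",
    "fit_all_genes",
    "filter_time_significant",
    "GeneFit",
]

# (time power, memory flag, strain flag) per term, in model order
_TERM_ORDERS = [
    (0, 0, 0), (0, 1, 0), (0, 0, 1), (0, 1, 1),
    (1, 0, 0), (1, 1, 0), (1, 0, 1), (1, 1, 1),
    (2, 0, 0), (2, 1, 0), (2, 0, 1), (2, 1, 1),
]
TIME_TERMS = [t for t, o in zip(TERM_NAMES, _TERM_ORDERS) if o[0] > 0]


def _covers(a: int, b: int) -> bool:
    """True if retaining term a forces term b to stay (a marginalizes b)."""
    if a == b:
        return False
    pa, ma, sa = _TERM_ORDERS[a]
    pb, mb, sb = _TERM_ORDERS[b]
    return pa >= pb and ma >= mb and sa >= sb


_COVERS = np.array(
    [[_covers(a, b) for b in range(len(TERM_NAMES))] for a in range(len(TERM_NAMES))]
)


@dataclass
class GeneFit:
    """OLS estimates for one gene over the 12-term model.

    Arrays are aligned with ``TERM_NAMES``; removed terms carry beta 0 and
    p-value NaN.  ``retained[0]`` (intercept) is always True.
    """

    gene_id: str
    beta: np.ndarray
    se: np.ndarray
    pval: np.ndarray
    retained: np.ndarray
    r2: float
    df_resid: int
    rank_deficient: bool = False
    time_significant: bool = False

    def check_hierarchy(self) -> bool:
        ret = self.retained
        for a in np.flatnonzero(ret):
            if not ret[_COVERS[a]].all():
                return False
        return True


def build_design(
    design: pd.DataFrame,
    ref_strain: str | None = None,
    ref_memory: str | None = None,
) -> pd.DataFrame:
    """12-column model matrix from the sample sheet.

    Reference levels default to the lexicographically *later*-declared order
    being irrelevant: the first unique value of each factor is taken as
    reference unless given explicitly.
    """
    strains = list(pd.unique(design["strain"]))
    memories = list(pd.unique(design["memory"]))
    if len(strains) != 2 or len(memories) != 2:
        raise ValueError("design needs exactly two strains and two memory levels")
    if len(design["time"].unique()) < 3:
        raise ValueError("design needs at least 3 time points")
    ref_strain = strains[0] if ref_strain is None else ref_strain
    ref_memory = memories[0] if ref_memory is None else ref_memory
    rows = np.stack(
        [
            design_row(
                int(r.strain != ref_strain), int(r.memory != ref_memory), r.time
            )
            for r in design.itertuples()
        ]
    )
    X = pd.DataFrame(rows, index=design.index, columns=TERM_NAMES)
    if np.linalg.matrix_rank(rows) < len(TERM_NAMES):
        raise ValueError("model matrix is rank deficient for this design")
    return X


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool]:
    """Normal-equation OLS with per-coefficient two-sided t-tests."""
    n, k = X.shape
    XtX = X.T @ X
    rank_def = np.linalg.matrix_rank(XtX) < k
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - k
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if df > 0 and not rank_def:
        sigma2 = rss / df
        cov = sigma2 * np.linalg.inv(XtX)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        pval = 2.0 * stats.t.sf(np.abs(tstat), df)
        pval = np.where(se > 0, pval, 0.0)
    else:
        se = np.full(k, np.nan)
        pval = np.full(k, np.nan)
    return beta, se, pval, r2, df, rank_def


def fit_gene(y: np.ndarray, X: pd.DataFrame, gene_id: str = "gene") -> GeneFit:
    """Full-model OLS fit of one gene."""
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("response length does not match design rows")
    beta, se, pval, r2, df, rank_def = _ols(y, X.to_numpy())
    k = X.shape[1]
    return GeneFit(
        gene_id=gene_id,
        beta=beta,
        se=se,
        pval=pval,
        retained=np.ones(k, dtype=bool),
        r2=r2,
        df_resid=df,
        rank_deficient=rank_def,
    )


def backward_stepwise(
    y: np.ndarray, X: pd.DataFrame, alpha: float = 0.05, gene_id: str = "gene"
) -> GeneFit:
    """Hierarchy-respecting backward elimination at per-term level alpha.

    Repeatedly refits after removing the removable term with the largest
    p-value above alpha; stops when every removable retained term is
    significant.  The intercept-only model is a legal endpoint.
    """
    y = np.asarray(y, dtype=float)
    Xn = X.to_numpy()
    k = Xn.shape[1]
    retained = np.ones(k, dtype=bool)
    while True:
        idx = np.flatnonzero(retained)
        beta_s, se_s, pval_s, r2, df, rank_def = _ols(y, Xn[:, idx])
        # removable: not the intercept, and no retained term covers it
        removable = np.array(
            [
                i != 0 and not retained[_COVERS[:, i]].any()
                for i in idx
            ]
        )
        pv = np.where(removable, np.nan_to_num(pval_s, nan=1.0), -1.0)
        worst = int(np.argmax(pv))
        if pv[worst] > alpha:
            retained[idx[worst]] = False
            continue
        break

    beta = np.zeros(k)
    se = np.full(k, np.nan)
    pval = np.full(k, np.nan)
    beta[idx] = beta_s
    se[idx] = se_s
    pval[idx] = pval_s
    fit = GeneFit(
        gene_id=gene_id,
        beta=beta,
        se=se,
        pval=pval,
        retained=retained,
        r2=r2,
        df_resid=df,
        rank_deficient=rank_def,
    )
    assert fit.check_hierarchy(), "stepwise produced a hierarchy violation"
    return fit


# factor -> the time-interaction terms jointly tested by the nested-model F
FACTOR_TERMS = {
    "memory": ("t_memory", "t2_memory"),
    "strain": ("t_strain", "t2_strain"),
    "interaction": ("t_memory_strain", "t2_memory_strain"),
}


def factor_ftest(y: np.ndarray, X: pd.DataFrame, factor: str) -> float:
    """p-value of the full model against the model without a factor's
    time-interaction terms (linear and quadratic jointly).

    This full-vs-reduced comparison is calibrated — it involves no term
    selection — and retains power despite the near-collinearity of t and t2,
    which is resolved jointly even though the individual coefficients are
    noisy.
    """
    terms = FACTOR_TERMS[factor]
    Xf = X.to_numpy()
    n, k = Xf.shape
    drop = [TERM_NAMES.index(t) for t in terms]
    keep = [i for i in range(k) if i not in drop]
    bf, *_ = np.linalg.lstsq(Xf, y, rcond=None)
    rss_f = float(((y - Xf @ bf) ** 2).sum())
    br, *_ = np.linalg.lstsq(Xf[:, keep], y, rcond=None)
    rss_r = float(((y - Xf[:, keep] @ br) ** 2).sum())
    df_f = n - k
    q = len(drop)
    if df_f <= 0 or rss_f <= 0:
        return np.nan
    F = ((rss_r - rss_f) / q) / (rss_f / df_f)
    return float(stats.f.sf(F, q, df_f))


def fit_all_genes(
    values: pd.DataFrame, X: pd.DataFrame, alpha: float = 0.05, stepwise: bool = True
) -> pd.DataFrame:
    """Fit every gene (rows of ``values``); returns a tidy per-gene table.

    Columns: beta_<term>, p_<term> (refined model), pfull_<term> (full
    model), retained_<term> for the 12 terms; pF_memory / pF_strain /
    pF_interaction nested-model F p-values; plus r2, df_resid and
    rank_deficient.
    """
    if list(values.columns) != list(X.index):
        values = values[X.index]
    records = []
    for gene_id, y in values.iterrows():
        yv = y.to_numpy()
        full = fit_gene(yv, X, gene_id=str(gene_id))
        if stepwise:
            fit = backward_stepwise(yv, X, alpha=alpha, gene_id=str(gene_id))
        else:
            fit = full
        rec: dict[str, object] = {"gene_id": fit.gene_id}
        for i, term in enumerate(TERM_NAMES):
            rec[f"beta_{term}"] = fit.beta[i]
            rec[f"p_{term}"] = fit.pval[i]
            # pre-selection p-value: calibrated, unlike post-stepwise ones
            rec[f"pfull_{term}"] = full.pval[i]
            rec[f"retained_{term}"] = bool(fit.retained[i])
        for factor in FACTOR_TERMS:
            rec[f"pF_{factor}"] = factor_ftest(yv, X, factor)
        rec["p_time_family"] = time_family_ftest(yv, X)
        rec["r2"] = fit.r2
        rec["df_resid"] = fit.df_resid
        rec["rank_deficient"] = fit.rank_deficient
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("gene_id")


def time_family_ftest(y: np.ndarray, X: pd.DataFrame) -> float:
    """p-value of the full model against the time-free model (intercept,
    memory, strain, memory*strain): joint evidence for any linear or
    quadratic time association.  Calibrated — no term selection involved."""
    Xf = X.to_numpy()
    n, k = Xf.shape
    keep = [i for i, o in enumerate(_TERM_ORDERS) if o[0] == 0]
    bf, *_ = np.linalg.lstsq(Xf, y, rcond=None)
    rss_f = float(((y - Xf @ bf) ** 2).sum())
    br, *_ = np.linalg.lstsq(Xf[:, keep], y, rcond=None)
    rss_r = float(((y - Xf[:, keep] @ br) ** 2).sum())
    df_f = n - k
    q = k - len(keep)
    if df_f <= 0 or rss_f <= 0:
        return np.nan
    F = ((rss_r - rss_f) / q) / (rss_f / df_f)
    return float(stats.f.sf(F, q, df_f))


def filter_time_significant(fits: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Flag genes whose association with time survives BH FDR across genes.

    A gene's time p-value is the joint F-test of all eight time-family terms
    (linear and quadratic, plain and crossed) against the time-free model —
    a calibrated p-value, unlike the post-stepwise per-term ones — and a gene
    additionally needs at least one time-family term retained by stepwise.
    Adds p_time, q_time and time_significant columns.
    """
    from statsmodels.stats.multitest import multipletests

    r_cols = [f"retained_{t}" for t in TIME_TERMS]
    any_time = fits[r_cols].to_numpy(dtype=bool).any(axis=1)
    p_time = fits["p_time_family"].to_numpy(dtype=float)
    p_time = np.where(np.isfinite(p_time), p_time, 1.0)
    _, q_time, _, _ = multipletests(p_time, method="fdr_bh")
    out = fits.copy()
    out["p_time"] = p_time
    out["q_time"] = q_time
    out["time_significant"] = any_time & (q_time <= fdr)
    return out
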