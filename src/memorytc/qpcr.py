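"""qPCR relative quantification (2^-ddCt) and paired t-tests.

Technical replicates are averaged on the Ct scale first; dCt is target minus
reference-gene Ct within each (condition, biological replicate) cell; ddCt
subtracts the same replicate's calibrator-condition dCt; the relative
quantity is 2**-ddCt, assuming perfect doubling per cycle.  The calibrator
condition therefore has RQ = 1 in every replicate by construction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ddct", "ddct_summary", "paired_ttest"]

_REQUIRED = {"gene", "condition", "bio_rep", "tech_rep", "ct"}


def _tech_means(ct: pd.DataFrame) -> pd.DataFrame:
    missing = _REQUIRED - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    if not np.isfinite(ct["ct"]).all() or (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    return ct.groupby(["gene", "condition", "bio_rep"], sort=False)["ct"].mean()


def ddct(
    ct: pd.DataFrame,
    target: str,
    reference_gene: str,
    calibrator_condition: str,
) -> pd.DataFrame:
    """Relative quantity of ``target`` per (condition, biological replicate).

    Returns delta_ct, ddct and rq columns; raises naming the cell if the
    reference gene is missing anywhere the target was measured.
    """
    means = _tech_means(ct)
    if target not in means.index.get_level_values("gene"):
        raise ValueError(f"target gene {target!r} absent from Ct table")
    tgt = means.xs(target, level="gene")
    try:
        ref = means.xs(reference_gene, level="gene")
    except KeyError:
        raise ValueError(f"reference gene {reference_gene!r} absent from Ct table")
    for cond, rep in tgt.index:
        if (cond, rep) not in ref.index:
            raise ValueError(
                f"reference gene {reference_gene!r} missing in cell "
                f"(condition={cond!r}, bio_rep={rep!r})"
            )
    dct = (tgt - ref.reindex(tgt.index)).rename("delta_ct")
    out = dct.reset_index()
    if calibrator_condition not in set(out["condition"]):
        raise ValueError(f"calibrator condition {calibrator_condition!r} not present")
    cal = out[out["condition"] == calibrator_condition].set_index("bio_rep")["delta_ct"]
    out["ddct"] = out["delta_ct"] - out["bio_rep"].map(cal).to_numpy()
    if out["ddct"].isna().any():
        rep = out.loc[out["ddct"].isna(), "bio_rep"].iloc[0]
        raise ValueError(
            f"calibrator condition {calibrator_condition!r} missing bio_rep {rep!r}"
        )
    out["rq"] = 2.0 ** (-out["ddct"])
    out.insert(0, "gene", target)
    return out


def ddct_summary(rq_table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean RQ with SE on both the RQ and the ddCt scale."""
    def agg(sub: pd.DataFrame) -> pd.Series:
        n = len(sub)
        return pd.Series(
            {
                "n": n,
                "mean_rq": sub["rq"].mean(),
                "se_rq": sub["rq"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "mean_ddct": sub["ddct"].mean(),
                "se_ddct": sub["ddct"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            }
        )
    return rq_table.groupby("condition", sort=False).apply(agg, include_groups=False)


def paired_ttest(a, b) -> tuple[float, int, float]:
    """Two-tailed paired t-test; returns (t, df, p).

    Zero-variance nonzero differences give t = +/-inf and p = 0 with a
    warning (degenerate but well-defined limit).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired_ttest needs two equal-length vectors, n >= 2")
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        warnings.warn("zero-variance differences: t is infinite, p -> 0")
        return float(np.sign(d.mean()) * np.inf), n - 1, 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)
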