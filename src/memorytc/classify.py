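"""Classification of memory, strain and interaction effects on time trends.

For a gene with linear time slope beta_t, a factor's interaction slope b
modulates the response:

* sign(beta_t + b) opposite to sign(beta_t)  -> reversed (the trend flips);
* |beta_t + b| > |beta_t|                    -> enhanced;
* |beta_t + b| < |beta_t|                    -> dampened;
* within tolerance of |beta_t|               -> no_change.

The sign check takes precedence over the magnitude check, and exact
cancellation (beta_t + b == 0) counts as dampening — total suppression has no
sign to flip.  The memory-x-strain interaction is judged by the net slope in
the (memory, mutant) cell, beta_t + b_tm + b_ts + b_tms, against the additive
expectation beta_t + b_tm + b_ts, with the same sign anchor beta_t.

Quadratic interaction terms never enter classification (profiles are judged
on linear slopes), although the fitted model may retain them.  A factor whose
interaction coefficient was not retained, or not significant, is no_change;
genes whose only time term is quadratic get their direction from the fitted
net change over the time course and not_applicable factor labels.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "classify_effect",
    "classify_strain",
    "classify_interaction",
    "assign_direction",
    "classify_genes",
    "overlap_summary",
    "proportion_test",
    "EFFECT_LABELS",
]

EFFECT_LABELS = ("enhanced", "dampened", "reversed", "no_change", "not_applicable")
DEFAULT_TOL = 1e-9


def _compare(anchor: float, total: float, reference_mag: float, tol: float) -> str:
    """Shared reversal/enhanced/dampened comparison against a magnitude."""
    if total == 0.0:
        return "dampened"
    if math.copysign(1.0, total) != math.copysign(1.0, anchor):
        return "reversed"
    if abs(total) > reference_mag + tol:
        return "enhanced"
    if abs(total) < reference_mag - tol:
        return "dampened"
    return "no_change"


def classify_effect(
    beta_time: float,
    beta_interaction: float,
    significant: bool = True,
    tol: float = DEFAULT_TOL,
) -> str:
    """Label one factor's modulation of the linear time trend."""
    if not significant:
        return "no_change"
    if beta_time == 0.0:
        raise ValueError("classification needs a nonzero linear time slope")
    return _compare(beta_time, beta_time + beta_interaction, abs(beta_time), tol)


def classify_strain(
    beta_time: float,
    beta_time_strain: float,
    significant: bool = True,
    tol: float = DEFAULT_TOL,
) -> str:
    """Strain modulation; identical rule with the strain interaction slope."""
    return classify_effect(beta_time, beta_time_strain, significant, tol)


def classify_interaction(
    beta_time: float,
    beta_time_memory: float,
    beta_time_strain: float,
    beta_tms: float,
    significant: bool = True,
    tol: float = DEFAULT_TOL,
) -> str:
    """Memory-x-strain synergy: net slope in the doubly-exposed cell vs the
    additive expectation from the single-factor effects."""
    if not significant:
        return "no_change"
    if beta_time == 0.0:
        raise ValueError("classification needs a nonzero linear time slope")
    additive = beta_time + beta_time_memory + beta_time_strain
    net = additive + beta_tms
    return _compare(beta_time, net, abs(additive), tol)


def assign_direction(
    beta_t: float,
    beta_t2: float,
    t_linear_retained: bool,
    t_quad_retained: bool,
    t_min: float,
    t_max: float,
) -> str:
    """HS-induced vs HS-repressed from the reference-cell time profile."""
    if t_linear_retained and beta_t != 0.0:
        return "induced" if beta_t > 0 else "repressed"
    if t_quad_retained:
        net = beta_t * (t_max - t_min) + beta_t2 * (t_max**2 - t_min**2)
        if net != 0.0:
            return "induced" if net > 0 else "repressed"
    return "flat"


def classify_genes(
    fits: pd.DataFrame,
    design: pd.DataFrame | None = None,
    alpha: float = 0.05,
    tol: float = DEFAULT_TOL,
    significance_from: str = "ftest",
    t_min: float = 0.0,
    t_max: float = 20.0,
) -> pd.DataFrame:
    """Per-gene direction and memory/strain/interaction labels.

    ``fits`` is the tidy table from :func:`memorytc.regression.fit_all_genes`
    (optionally restricted to time-significant genes).  A factor counts as
    significant when its linear interaction term was retained by stepwise
    and the evidence for the factor passes at level alpha, judged by
    ``significance_from``:

    * ``"ftest"`` (default) — the nested full-vs-reduced model comparison of
      the factor's time-interaction terms; calibrated (no selection bias)
      and powerful (the near-collinear linear/quadratic pair is tested
      jointly);
    * ``"full"`` — the term's t-test in the pre-selection full model;
    * ``"final"`` — the term's t-test in the refined model (anti-conservative
      for terms that survived backward elimination);
    * ``"retained"`` — stepwise retention alone.
    """
    if significance_from not in ("ftest", "full", "final", "retained"):
        raise ValueError("significance_from must be 'ftest', 'full', 'final' or 'retained'")
    if design is not None:
        t_min = float(design["time"].min())
        t_max = float(design["time"].max())

    _FACTOR_OF = {"t_memory": "memory", "t_strain": "strain",
                  "t_memory_strain": "interaction"}

    def sig(row: pd.Series, term: str) -> bool:
        if not row[f"retained_{term}"]:
            return False
        if significance_from == "retained":
            return True
        if significance_from == "ftest":
            col = f"pF_{_FACTOR_OF[term]}"
        elif significance_from == "full":
            col = f"pfull_{term}"
        else:
            col = f"p_{term}"
        p = row.get(col, row[f"p_{term}"])
        return bool(np.isfinite(p) and p <= alpha)

    records = []
    for gene_id, row in fits.iterrows():
        bt = float(row["beta_t"])
        lin = bool(row["retained_t"]) and bt != 0.0
        quad = bool(row["retained_t2"])
        direction = assign_direction(bt, float(row["beta_t2"]), lin, quad, t_min, t_max)
        if not lin:
            mem = strain = inter = "not_applicable"
        else:
            mem = classify_effect(bt, float(row["beta_t_memory"]), sig(row, "t_memory"), tol)
            strain = classify_strain(bt, float(row["beta_t_strain"]), sig(row, "t_strain"), tol)
            inter = classify_interaction(
                bt,
                float(row["beta_t_memory"]),
                float(row["beta_t_strain"]),
                float(row["beta_t_memory_strain"]),
                sig(row, "t_memory_strain"),
                tol,
            )
        records.append(
            {
                "gene_id": gene_id,
                "direction": direction,
                "memory_effect": mem,
                "strain_effect": strain,
                "interaction_effect": inter,
                "beta_t": bt,
                "beta_t_memory": float(row["beta_t_memory"]),
                "beta_t_strain": float(row["beta_t_strain"]),
                "beta_t_memory_strain": float(row["beta_t_memory_strain"]),
            }
        )
    return pd.DataFrame.from_records(records).set_index("gene_id")


_AFFECTED = {"enhanced", "dampened", "reversed"}


def overlap_summary(classes: pd.DataFrame) -> pd.DataFrame:
    """UpSet-style disjoint intersection counts over the three factors.

    A gene belongs to a factor's group when its label is enhanced, dampened
    or reversed.  The eight disjoint combinations sum to the classified total.
    """
    mem = classes["memory_effect"].isin(_AFFECTED)
    strain = classes["strain_effect"].isin(_AFFECTED)
    inter = classes["interaction_effect"].isin(_AFFECTED)
    rows = []
    for m in (True, False):
        for s in (True, False):
            for i in (True, False):
                n = int(((mem == m) & (strain == s) & (inter == i)).sum())
                parts = [
                    name
                    for name, flag in (("memory", m), ("strain", s), ("interaction", i))
                    if flag
                ]
                rows.append(
                    {
                        "memory": m,
                        "strain": s,
                        "interaction": i,
                        "combination": "+".join(parts) if parts else "none",
                        "n_genes": n,
                    }
                )
    return pd.DataFrame(rows)


def proportion_test(
    subset_ids,
    classes: pd.DataFrame,
    factor: str = "interaction_effect",
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Two-proportion z-test of each category's share, subset vs all genes.

    For every label of ``factor``: proportion among ``subset_ids`` against
    the proportion among all classified genes, with a normal-approximation
    confidence interval on the difference and a pooled-variance z p-value.
    """
    subset_ids = pd.Index(subset_ids)
    missing = subset_ids.difference(classes.index)
    subset = classes.loc[subset_ids.intersection(classes.index)]
    if len(subset) == 0:
        raise ValueError("subset has no genes in the classification table")
    zcrit = stats.norm.ppf(0.5 + conf_level / 2)
    n1, n0 = len(subset), len(classes)
    rows = []
    for label in ("enhanced", "dampened", "reversed", "no_change"):
        k1 = int((subset[factor] == label).sum())
        k0 = int((classes[factor] == label).sum())
        p1, p0 = k1 / n1, k0 / n0
        diff = p1 - p0
        se_ci = math.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
        pooled = (k1 + k0) / (n1 + n0)
        se_z = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n0))
        z = diff / se_z if se_z > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        rows.append(
            {
                "category": label,
                "n_subset": k1,
                "n_background": k0,
                "prop_subset": p1,
                "prop_background": p0,
                "diff": diff,
                "ci_low": diff - zcrit * se_ci,
                "ci_high": diff + zcrit * se_ci,
                "z": z,
                "pvalue": p,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_unmatched_subset_ids"] = len(missing)
    return out
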