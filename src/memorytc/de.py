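"""NOISeq-style pairwise differential expression and fold-change categories.

The DE probability is nonparametric: a gene's signal pair (|M|, D) — log2
ratio and absolute difference of condition means on the linear normalized
scale — is compared against a pooled noise distribution of the same
statistics computed between replicates *within* each condition across all
genes.  prob is the fraction of noise pairs dominated by the signal.

Convention: ``cond_ref`` is the baseline (here, time 0 of the same strain and
memory condition) and ``cond_test`` the later time point; positive M /
positive signed fold change mean higher expression in the test condition.
The signed fold change is the linear ratio when >= 1, else the negated
reciprocal, so |signed_fc| >= 1 and the 1.2 / 2 bands apply symmetrically.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .preprocess import NormalizedMatrix

__all__ = [
    "noiseq_probability",
    "categorize_fc",
    "transition_table",
    "de_vs_baseline",
    "FC_LABELS",
]

FC_LABELS = ("strong_up", "up", "unchanged", "down", "strong_down")


def condition_samples(design: pd.DataFrame, cond: Mapping[str, object]) -> list[str]:
    """Sample ids matching a condition given as {column: value}."""
    mask = pd.Series(True, index=design.index)
    for col, val in cond.items():
        if col not in design.columns:
            raise ValueError(f"unknown design column {col!r}")
        mask &= design[col] == val
    ids = design.index[mask].tolist()
    if not ids:
        raise ValueError(f"no samples match condition {dict(cond)!r}")
    return ids


def _noise_pairs(expr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """|M| and D for every within-condition replicate pair, pooled over genes."""
    abs_m, d = [], []
    for i, j in combinations(range(expr.shape[1]), 2):
        x, y = expr[:, i], expr[:, j]
        abs_m.append(np.abs(np.log2(x / y)))
        d.append(np.abs(x - y))
    return np.concatenate(abs_m), np.concatenate(d)


def noiseq_probability(
    norm: NormalizedMatrix,
    design: pd.DataFrame,
    cond_ref: Mapping[str, object],
    cond_test: Mapping[str, object],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene (M, D, prob, signed_fc) for cond_test vs cond_ref.

    Deterministic given its inputs: no resampling, the noise distribution is
    the exhaustive set of within-condition replicate pairs of both conditions.
    """
    ref_ids = condition_samples(design, cond_ref)
    test_ids = condition_samples(design, cond_test)
    if len(ref_ids) < 2 or len(test_ids) < 2:
        raise ValueError("need >= 2 replicates per condition")

    expr = norm.linear(pseudocount)
    ref = expr[ref_ids].to_numpy()
    test = expr[test_ids].to_numpy()
    mean_ref = ref.mean(axis=1)
    mean_test = test.mean(axis=1)

    m = np.log2(mean_test / mean_ref)
    d = np.abs(mean_test - mean_ref)

    # noise pools replicate pairs within each condition separately
    nm_ref, nd_ref = _noise_pairs(ref)
    nm_test, nd_test = _noise_pairs(test)
    noise_m = np.concatenate([nm_ref, nm_test])
    noise_d = np.concatenate([nd_ref, nd_test])

    abs_m = np.abs(m)
    prob = np.empty(len(abs_m))
    chunk = 512
    for start in range(0, len(abs_m), chunk):
        sl = slice(start, start + chunk)
        dominated = (noise_m[None, :] <= abs_m[sl, None]) & (
            noise_d[None, :] <= d[sl, None]
        )
        prob[sl] = dominated.mean(axis=1)

    ratio = mean_test / mean_ref
    signed_fc = np.where(ratio >= 1.0, ratio, -1.0 / ratio)

    return pd.DataFrame(
        {"M": m, "D": d, "prob": prob, "signed_fc": signed_fc},
        index=norm.values.index.rename("gene_id"),
    )


def categorize_fc(
    de: pd.DataFrame,
    fc_lo: float = 1.2,
    fc_hi: float = 2.0,
    prob_threshold: float = 0.8,
) -> pd.Series:
    """Five-level fold-change category per gene.

    unchanged iff |signed_fc| <= fc_lo or prob < prob_threshold; beyond that,
    |signed_fc| > fc_hi separates strong_(up|down) from (up|down).
    """
    if not fc_hi > fc_lo > 1.0:
        raise ValueError("need fc_hi > fc_lo > 1")
    fc = de["signed_fc"].to_numpy()
    sig = (de["prob"].to_numpy() >= prob_threshold) & (np.abs(fc) > fc_lo)
    strong = np.abs(fc) > fc_hi
    up = fc > 0
    labels = np.full(len(fc), "unchanged", dtype=object)
    labels[sig & up & strong] = "strong_up"
    labels[sig & up & ~strong] = "up"
    labels[sig & ~up & strong] = "strong_down"
    labels[sig & ~up & ~strong] = "down"
    return pd.Series(
        pd.Categorical(labels, categories=list(FC_LABELS)),
        index=de.index, name="fc_category",
    )


def transition_table(cat_a: pd.Series, cat_b: pd.Series) -> pd.DataFrame:
    """5x5 category-transition counts (Sankey source); cells sum to n genes."""
    if not cat_a.index.equals(cat_b.index):
        raise ValueError("category series must cover the same genes")
    a = pd.Categorical(cat_a, categories=list(FC_LABELS))
    b = pd.Categorical(cat_b, categories=list(FC_LABELS))
    tab = pd.crosstab(a, b, dropna=False)
    tab = tab.reindex(index=list(FC_LABELS), columns=list(FC_LABELS), fill_value=0)
    tab.index.name, tab.columns.name = "from", "to"
    return tab


def de_vs_baseline(
    norm: NormalizedMatrix,
    design: pd.DataFrame,
    baseline_time: float = 0.0,
    fc_lo: float = 1.2,
    fc_hi: float = 2.0,
    prob_threshold: float = 0.8,
) -> dict[tuple[str, str, float], pd.DataFrame]:
    """DE of every later time against time 0 of the same strain and memory
    condition, the comparison scheme of the study design."""
    out: dict[tuple[str, str, float], pd.DataFrame] = {}
    times = sorted(design["time"].unique())
    if baseline_time not in times:
        raise ValueError(f"baseline time {baseline_time} absent from design")
    for strain in design["strain"].unique():
        for memory in design["memory"].unique():
            for t in times:
                if t == baseline_time:
                    continue
                de = noiseq_probability(
                    norm,
                    design,
                    {"strain": strain, "memory": memory, "time": baseline_time},
                    {"strain": strain, "memory": memory, "time": t},
                )
                de["fc_category"] = categorize_fc(de, fc_lo, fc_hi, prob_threshold)
                out[(strain, memory, t)] = de
    return out
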