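"""Gene-set over-representation: one-sided Fisher (hypergeometric tail) with
Benjamini-Hochberg correction.

The universe defaults to every gene surviving the low-count filter; gene sets
come from GMT or two-column TSV files and are validated against the universe
before testing, with unmatched identifiers reported rather than silently
dropped.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_gmt",
    "read_gene_sets_tsv",
    "validate_sets",
    "fisher_enrich",
    "bh_adjust",
]


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Parse a GMT file: set id, description, then member gene ids."""
    sets: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = {"name": fields[1], "genes": set(fields[2:]) - {""}}
    return sets


def read_gene_sets_tsv(path: str | Path) -> dict[str, dict]:
    """Two-column set_id<TAB>gene_id table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set_id", "gene_id"])
    return {
        sid: {"name": sid, "genes": set(sub["gene_id"])}
        for sid, sub in df.groupby("set_id")
    }


def validate_sets(
    sets: dict[str, dict], universe: set[str]
) -> tuple[dict[str, dict], dict[str, int]]:
    """Restrict set members to the universe; report unmatched ids per set."""
    validated, unmatched = {}, {}
    for sid, rec in sets.items():
        genes = set(rec["genes"])
        inside = genes & universe
        unmatched[sid] = len(genes - universe)
        if inside:
            validated[sid] = {"name": rec.get("name", sid), "genes": inside}
    return validated, unmatched


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def fisher_enrich(
    query_ids,
    sets: dict[str, dict],
    universe_ids,
    q_cutoff: float | None = 0.05,
    min_set_size: int = 1,
) -> pd.DataFrame:
    """Over-representation of the query in each gene set.

    One-sided hypergeometric tail P(X >= k) with k = |query ∩ set|,
    n = |query|, K = |set ∩ universe|, N = |universe|; BH q across the tested
    sets; rows with q >= q_cutoff dropped unless q_cutoff is None.
    """
    universe = set(universe_ids)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_ids) & universe
    if not query:
        raise ValueError("empty query after restriction to the universe")
    validated, unmatched = validate_sets(sets, universe)

    N, n = len(universe), len(query)
    rows = []
    for sid, rec in validated.items():
        K = len(rec["genes"])
        if K < min_set_size:
            continue
        k = len(rec["genes"] & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        a, b, c, d = k, n - k, K - k, N - K - (n - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append(
            {
                "set_id": sid,
                "name": rec["name"],
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold_enrichment": fold,
                "odds_ratio": odds,
                "pvalue": p,
                "n_unmatched_ids": unmatched[sid],
            }
        )
    result = pd.DataFrame(rows)
    if result.empty:
        result["qvalue"] = []
        return result
    result["qvalue"] = bh_adjust(result["pvalue"])
    result = result.sort_values(["qvalue", "pvalue"]).reset_index(drop=True)
    if q_cutoff is not None:
        result = result[result["qvalue"] < q_cutoff].reset_index(drop=True)
    return result
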