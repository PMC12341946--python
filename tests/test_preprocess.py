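"""Filtering, TMM and PCA, checked against brute-force and edgeR oracles."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from memorytc import filter_low_counts, normalize, pca_qc, tmm_factors


# ---------------------------------------------------------------- filtering

def test_all_zero_gene_removed(toy_counts):
    kept = filter_low_counts(toy_counts)
    assert "g0" not in kept.index


def test_filter_identity_when_everything_expressed():
    counts = pd.DataFrame(
        np.full((5, 4), 1000), index=[f"g{i}" for i in range(5)], columns=list("ABCD")
    )
    pd.testing.assert_frame_equal(filter_low_counts(counts), counts)


def test_filter_matches_hand_computed_cpm(toy_counts):
    lib = toy_counts.sum(axis=0)
    expected = []
    for g, row in toy_counts.iterrows():
        above = sum(row[s] / lib[s] * 1e6 >= 1.0 for s in toy_counts.columns)
        if above >= 2:  # half of 4 samples
            expected.append(g)
    kept = filter_low_counts(toy_counts, cpm_threshold=1.0, min_samples_fraction=0.5)
    assert list(kept.index) == expected


def test_filter_idempotent(toy_counts):
    once = filter_low_counts(toy_counts)
    twice = filter_low_counts(once)
    pd.testing.assert_frame_equal(once, twice)


def test_filter_empty_result_errors():
    counts = pd.DataFrame({"A": [1, 0], "B": [0, 1]}, index=["g1", "g2"])
    counts *= 0
    counts.iloc[0, 0] = 1
    with pytest.raises(ValueError, match="cpm >= 1000"):
        filter_low_counts(counts, cpm_threshold=1000.0, min_samples_fraction=1.0)


# --------------------------------------------------------------------- TMM

def _brute_force_tmm(counts: pd.DataFrame, ref: str, logratio_trim=0.3, abs_trim=0.05):
    """Plain-loop reimplementation of the weighted trimmed mean of M-values."""
    lib = counts.sum(axis=0).astype(float)
    factors = {}
    for s in counts.columns:
        ms, aas, ws = [], [], []
        for g in counts.index:
            o, r = counts.at[g, s], counts.at[g, ref]
            if o == 0 or r == 0:
                continue
            po, pr = o / lib[s], r / lib[ref]
            ms.append(np.log2(po / pr))
            aas.append(0.5 * np.log2(po * pr))
            ws.append((lib[s] - o) / (lib[s] * o) + (lib[ref] - r) / (lib[ref] * r))
        ms, aas, ws = map(np.asarray, (ms, aas, ws))
        if len(ms) == 0 or np.abs(ms).max() < 1e-6:
            factors[s] = 1.0
            continue
        n = len(ms)
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * abs_trim) + 1, n - np.floor(n * abs_trim)
        rm, ra = rankdata(ms), rankdata(aas)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        factors[s] = 2.0 ** (np.sum(ms[keep] / ws[keep]) / np.sum(1.0 / ws[keep]))
    f = pd.Series(factors)
    return f / np.exp(np.mean(np.log(f)))


def test_tmm_identical_samples_give_unit_factors():
    col = np.array([10, 50, 200, 1000, 30, 5])
    counts = pd.DataFrame({s: col for s in "ABC"}, index=[f"g{i}" for i in range(6)])
    f = tmm_factors(counts)
    assert np.allclose(f, 1.0)


def test_pure_depth_difference_normalizes_away():
    rng = np.random.default_rng(4)
    a = rng.integers(5, 2000, size=50)
    counts = pd.DataFrame({"A": a, "B": 2 * a, "C": a + 0}, index=[f"g{i}" for i in range(50)])
    norm = normalize(counts, tmm_factors(counts))
    assert np.allclose(norm.values["A"], norm.values["B"], atol=1e-9)


def test_tmm_matches_brute_force_oracle():
    counts = pd.DataFrame(
        {"A": [100, 200, 300, 50, 10, 700], "B": [120, 180, 900, 40, 15, 600]},
        index=[f"g{i}" for i in range(6)],
    )
    ref = "A"
    mine = tmm_factors(counts, ref_sample=ref)
    oracle = _brute_force_tmm(counts, ref)
    assert np.allclose(mine, oracle[mine.index], rtol=1e-12)


def test_tmm_matches_brute_force_on_random_matrix():
    rng = np.random.default_rng(77)
    counts = pd.DataFrame(
        rng.negative_binomial(10, 0.01, size=(80, 3)),
        index=[f"g{i}" for i in range(80)], columns=list("ABC"),
    )
    mine = tmm_factors(counts, ref_sample="B")
    oracle = _brute_force_tmm(counts, "B")
    assert np.allclose(mine, oracle[mine.index], rtol=1e-12)


def test_tmm_matches_edger(tmp_path):
    """Cross-check against Bioconductor edgeR's calcNormFactors."""
    rng = np.random.default_rng(11)
    counts = pd.DataFrame(
        rng.negative_binomial(8, 0.004, size=(120, 4)),
        index=[f"g{i}" for i in range(120)], columns=list("ABCD"),
    )
    path = tmp_path / "counts.tsv"
    counts.to_csv(path, sep="\t")
    script = textwrap.dedent(f"""
        suppressMessages(library(edgeR))
        x <- as.matrix(read.delim("{path}", row.names=1))
        cat(calcNormFactors(x, method="TMM"), sep="\\n")
    """)
    out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, check=True)
    edger = np.array([float(v) for v in out.stdout.split()])
    mine = tmm_factors(counts).to_numpy()
    assert np.allclose(mine, edger, rtol=1e-4)


def test_tmm_invariant_to_gene_relabeling():
    rng = np.random.default_rng(21)
    counts = pd.DataFrame(
        rng.integers(1, 1000, size=(40, 3)),
        index=[f"g{i}" for i in range(40)], columns=list("ABC"),
    )
    perm = rng.permutation(counts.index)
    f1 = tmm_factors(counts)
    f2 = tmm_factors(counts.loc[perm])
    assert np.allclose(f1, f2)


def test_tmm_all_zero_sample_errors():
    counts = pd.DataFrame({"A": [1, 2], "B": [0, 0]}, index=["g1", "g2"])
    with pytest.raises(ValueError, match="all-zero"):
        tmm_factors(counts)


# --------------------------------------------------------------- normalize

def test_normalize_matches_hand_arithmetic():
    counts = pd.DataFrame({"A": [90, 10], "B": [50, 50]}, index=["g1", "g2"])
    factors = pd.Series([1.0, 1.0], index=["A", "B"])
    norm = normalize(counts, factors)
    assert norm.values.at["g1", "A"] == pytest.approx(np.log2(90 / 100 * 1e6 + 1))
    assert norm.values.at["g2", "B"] == pytest.approx(np.log2(50 / 100 * 1e6 + 1))


def test_normalize_monotone_in_counts():
    counts = pd.DataFrame({"A": [10, 20, 400], "B": [5, 5, 5]}, index=list("xyz"))
    norm = normalize(counts, pd.Series([1.0, 1.0], index=["A", "B"]))
    assert norm.values["A"].is_monotonic_increasing


def test_scaling_a_sample_only_shifts_its_values_by_a_constant():
    """Scaling one sample's counts leaves its composition unchanged: the
    gene-wise M-values are identical, so normalized expression changes only
    by a tiny common constant.  (The constant is not exactly zero because
    the asymptotic-variance weights of the trimmed mean depend on depth.)"""
    rng = np.random.default_rng(3)
    a = rng.integers(10, 5000, size=30).astype(int)
    counts = pd.DataFrame({"A": a, "B": rng.integers(10, 5000, size=30)})
    scaled = counts.copy()
    scaled["A"] = counts["A"] * 4
    n1 = normalize(counts, tmm_factors(counts))
    n2 = normalize(scaled, tmm_factors(scaled))
    ratio = np.log2(n1.cpm["A"] / n2.cpm["A"]).to_numpy()
    assert np.allclose(ratio, ratio[0], atol=1e-9)  # pure shift, shape preserved
    assert abs(ratio[0]) < 0.05  # and the shift itself is tiny


# --------------------------------------------------------------------- PCA

def test_pca_variance_fractions_non_increasing(small_sim):
    _, counts, design, _ = small_sim
    norm = normalize(filter_low_counts(counts))
    _, var_frac = pca_qc(norm)
    assert var_frac.sum() <= 1.0 + 1e-9
    assert (np.diff(var_frac) <= 1e-12).all()


def test_pca_duplicated_samples_get_identical_scores():
    rng = np.random.default_rng(6)
    counts = pd.DataFrame(
        rng.integers(10, 5000, size=(60, 3)),
        index=[f"g{i}" for i in range(60)], columns=list("ABC"),
    )
    counts["D"] = counts["C"]
    norm = normalize(counts, pd.Series(1.0, index=counts.columns))
    scores, _ = pca_qc(norm)
    assert np.allclose(scores.loc["C"], scores.loc["D"], atol=1e-9)


def test_pca_first_component_tracks_time(small_sim):
    _, counts, design, _ = small_sim
    norm = normalize(filter_low_counts(counts))
    scores, _ = pca_qc(norm)
    r = np.corrcoef(scores["PC1"], design["time"])[0, 1]
    assert abs(r) > 0.8
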