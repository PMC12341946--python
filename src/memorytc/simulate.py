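"""Negative-binomial count simulator for a factorial heat-shock time course.

Emulates a bulk RNA-seq experiment in which two yeast strains (wild type and a
deletion mutant) are sampled along a heat-shock time course, each either naive
("no-memory") or pre-exposed to a first shock plus recovery ("memory").  Every
gene follows a quadratic-in-time log2 expression model whose linear time slope
can be modulated by memory, strain, or their interaction — the modulation
classes (enhanced / dampened / reversed / no_change) are the ground truth that
downstream classification is asked to recover.

Coefficients act on log2 expression with time in raw minutes.  Memory and
strain are coded 0/1 with reference levels (WT, no-memory); coefficient signs
are relative to that coding.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "simulate_counts",
    "truth_class_counts",
    "TERM_NAMES",
    "write_simulation",
]

# Eq-style design columns, in model order.  (time power, memory flag, strain flag)
TERM_NAMES = [
    "intercept",
    "memory",
    "strain",
    "memory_strain",
    "t",
    "t_memory",
    "t_strain",
    "t_memory_strain",
    "t2",
    "t2_memory",
    "t2_strain",
    "t2_memory_strain",
]

EFFECT_CLASSES = ("no_change", "dampened", "enhanced", "reversed")
PROFILE_CLASSES = ("flat",) + EFFECT_CLASSES


def _default_class_proportions() -> dict[str, float]:
    # Qualitative shape of the study: ~1/3 of genes without a time trend, and
    # dampening dominating among memory-affected responders.
    return {
        "flat": 0.35,
        "no_change": 0.30,
        "dampened": 0.25,
        "enhanced": 0.06,
        "reversed": 0.04,
    }


def _default_strain_proportions() -> dict[str, float]:
    return {"no_change": 0.70, "dampened": 0.12, "enhanced": 0.10, "reversed": 0.08}


def _default_interaction_proportions() -> dict[str, float]:
    return {"no_change": 0.85, "dampened": 0.08, "enhanced": 0.04, "reversed": 0.03}


@dataclass
class SimConfig:
    """Generating parameters for one synthetic experiment.

    Parameters
    ----------
    n_genes, n_reps
        Number of genes and biological replicates per condition.
    times
        Sampling times in minutes; needs >= 3 distinct values.
    strains, memory_levels
        Two labels each; the first is the reference level.
    dispersion
        NB dispersion phi > 0 (variance = mu + phi * mu**2).
    lib_size_mean, lib_size_cv
        Log-normal library-size distribution (expected total counts per
        sample and its coefficient of variation).
    class_proportions
        Map profile class -> fraction over {flat, no_change, dampened,
        enhanced, reversed}; governs the *memory* modulation class ("flat"
        genes have every time-family coefficient zero).
    strain_class_proportions, interaction_class_proportions
        Same idea for the strain and memory-x-strain modulation of non-flat
        genes (no "flat" key).
    effect_scale
        Typical |beta_t| in log2 units per minute; per-gene slopes are drawn
        uniformly in [0.5, 1.5] * effect_scale.
    quad_curvature
        c in beta_t2 = -c * beta_t / t_max; the default 0.5 bends every
        trajectory so its slope reaches zero at t_max (saturating profile),
        mirroring the strong linear/quadratic coupling of real responses.
        0 disables quadratic terms.
    baseline_log2_range
        Uniform range for the baseline log2 mean expression beta_0.
    seed
        Seed for the single RNG driving all draws.
    """

    n_genes: int = 6000
    n_reps: int = 3
    times: tuple[float, ...] = (0.0, 15.0, 20.0)
    strains: tuple[str, str] = ("WT", "mip6d")
    memory_levels: tuple[str, str] = ("no_memory", "memory")
    dispersion: float = 0.1
    lib_size_mean: float = 5e6
    lib_size_cv: float = 0.2
    class_proportions: dict[str, float] = field(default_factory=_default_class_proportions)
    strain_class_proportions: dict[str, float] = field(default_factory=_default_strain_proportions)
    interaction_class_proportions: dict[str, float] = field(
        default_factory=_default_interaction_proportions
    )
    effect_scale: float = 0.2
    quad_curvature: float = 0.5
    baseline_log2_range: tuple[float, float] = (3.0, 10.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_reps < 1:
            raise ValueError("n_genes and n_reps must be positive")
        if len(set(self.times)) < 3:
            raise ValueError("times needs at least 3 distinct values")
        if not self.dispersion > 0:
            raise ValueError("NB dispersion must be > 0")
        if self.lib_size_cv < 0:
            raise ValueError("lib_size_cv must be >= 0")
        for name, props, allowed in (
            ("class_proportions", self.class_proportions, PROFILE_CLASSES),
            ("strain_class_proportions", self.strain_class_proportions, EFFECT_CLASSES),
            ("interaction_class_proportions", self.interaction_class_proportions, EFFECT_CLASSES),
        ):
            unknown = set(props) - set(allowed)
            if unknown:
                raise ValueError(f"{name}: unknown classes {sorted(unknown)}")
            total = float(sum(props.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
        if len(self.strains) != 2 or len(self.memory_levels) != 2:
            raise ValueError("exactly two strains and two memory levels are required")


def build_sample_design(config: SimConfig) -> pd.DataFrame:
    """Sample sheet: one row per (strain x memory x time x replicate)."""
    rows = []
    for strain in config.strains:
        for memory in config.memory_levels:
            for t in config.times:
                for rep in range(1, config.n_reps + 1):
                    sid = f"{strain}_{memory}_t{t:g}_r{rep}"
                    rows.append((sid, strain, memory, float(t), rep))
    design = pd.DataFrame(
        rows, columns=["sample", "strain", "memory", "time", "replicate"]
    ).set_index("sample")
    return design


def _rule_label(beta_t: float, beta_inter: float) -> str:
    """Literal modulation rule applied to true coefficients (tie -> no_change,
    exact cancellation -> dampened).  Kept here so SimTruth classes are
    consistent with the classifier by construction."""
    if beta_inter == 0.0 or beta_t == 0.0:
        return "no_change"
    s = beta_t + beta_inter
    if s == 0.0:
        return "dampened"
    if np.sign(s) != np.sign(beta_t):
        return "reversed"
    if abs(s) > abs(beta_t):
        return "enhanced"
    if abs(s) < abs(beta_t):
        return "dampened"
    return "no_change"


def _interaction_rule_label(bt: float, btm: float, bts: float, btms: float) -> str:
    if btms == 0.0 or bt == 0.0:
        return "no_change"
    additive = bt + btm + bts
    net = additive + btms
    if net == 0.0:
        return "dampened"
    if np.sign(net) != np.sign(bt):
        return "reversed"
    if abs(net) > abs(additive):
        return "enhanced"
    if abs(net) < abs(additive):
        return "dampened"
    return "no_change"


def _draw_modulation(rng: np.random.Generator, beta_t: float, cls: str) -> float:
    """Interaction slope realizing a target modulation class for beta_t."""
    if cls == "no_change":
        return 0.0
    if cls == "dampened":
        return -float(rng.uniform(0.5, 0.9)) * beta_t
    if cls == "enhanced":
        return float(rng.uniform(0.5, 1.0)) * beta_t
    if cls == "reversed":
        return -float(rng.uniform(1.5, 2.5)) * beta_t
    raise ValueError(f"unknown class {cls!r}")


def _draw_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    classes = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes], dtype=float)
    mem_class = rng.choice(classes, size=n, p=probs / probs.sum())

    s_classes = list(config.strain_class_proportions)
    s_probs = np.array([config.strain_class_proportions[c] for c in s_classes], dtype=float)
    i_classes = list(config.interaction_class_proportions)
    i_probs = np.array(
        [config.interaction_class_proportions[c] for c in i_classes], dtype=float
    )

    lo, hi = config.baseline_log2_range
    t_max = max(config.times)

    beta = np.zeros((n, len(TERM_NAMES)))
    beta[:, 0] = rng.uniform(lo, hi, size=n)
    direction = np.full(n, "flat", dtype=object)
    strain_cls = np.full(n, "no_change", dtype=object)
    inter_cls = np.full(n, "no_change", dtype=object)

    for g in range(n):
        if mem_class[g] == "flat":
            continue
        # baseline (time-independent) offsets
        beta[g, 1] = rng.normal(0.0, 0.25)
        beta[g, 2] = rng.normal(0.0, 0.25)
        beta[g, 3] = rng.normal(0.0, 0.10)

        sc = str(rng.choice(s_classes, p=s_probs / s_probs.sum()))
        ic = str(rng.choice(i_classes, p=i_probs / i_probs.sum()))
        affected = (mem_class[g], sc, ic) != ("no_change", "no_change", "no_change")

        sign = 1.0 if rng.random() < 0.5 else -1.0
        if affected:
            # Condition-regulated genes are the strong responders (HSP-class
            # inductions/repressions): slopes 1-2x the typical scale.
            mag = rng.uniform(1.0, 2.0)
        else:
            # Unmodulated bulk: exponential magnitudes with a small mean —
            # most genes barely move, a few drift visibly.  Real
            # transcriptomes keep such a quiet majority, and it is the
            # anchor that scaling normalization relies on.  Capped so means
            # stay finite on the count scale.
            mag = min(rng.exponential(0.35), 3.0)
        bt = sign * config.effect_scale * mag
        direction[g] = "induced" if bt > 0 else "repressed"

        btm = _draw_modulation(rng, bt, str(mem_class[g]))
        bts = _draw_modulation(rng, bt, sc)
        additive = bt + btm + bts
        base = abs(additive) if additive != 0.0 else abs(bt)
        if ic == "no_change":
            btms = 0.0
        elif ic == "dampened":
            btms = np.sign(bt) * rng.uniform(0.3, 0.7) * base - additive
        elif ic == "enhanced":
            btms = np.sign(bt) * rng.uniform(1.3, 1.8) * base - additive
        else:  # reversed
            btms = -np.sign(bt) * rng.uniform(0.5, 1.5) * base - additive

        beta[g, 4:8] = (bt, btm, bts, btms)
        if config.quad_curvature != 0.0:
            beta[g, 8:12] = -config.quad_curvature / t_max * beta[g, 4:8]
        strain_cls[g] = sc
        inter_cls[g] = ic

    truth = pd.DataFrame(
        beta,
        columns=[f"beta_{t}" for t in TERM_NAMES],
        index=pd.Index([f"gene_{g:05d}" for g in range(n)], name="gene_id"),
    )
    truth["direction"] = direction
    # Declared classes come from the literal rules applied to the true
    # coefficients, so the internal-consistency invariant holds exactly.
    truth["memory_class"] = [
        _rule_label(b[4], b[5]) if d != "flat" else "no_change"
        for b, d in zip(beta, direction)
    ]
    truth["strain_class"] = [
        _rule_label(b[4], b[6]) if d != "flat" else "no_change"
        for b, d in zip(beta, direction)
    ]
    truth["interaction_class"] = [
        _interaction_rule_label(b[4], b[5], b[6], b[7]) if d != "flat" else "no_change"
        for b, d in zip(beta, direction)
    ]
    return truth


def design_row(strain_is_mut: int, memory_on: int, t: float) -> np.ndarray:
    """One row of the 12-column model matrix for a sample."""
    m, s = float(memory_on), float(strain_is_mut)
    return np.array(
        [1.0, m, s, m * s, t, t * m, t * s, t * m * s,
         t * t, t * t * m, t * t * s, t * t * m * s]
    )


def simulate_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw a (counts, design, truth) triple from the generative model.

    For gene g and sample j the NB mean is mu_gj = s_j * 2**(x_j . beta_g),
    where x_j is the model-matrix row of sample j and s_j scales the sample so
    its expected total equals the drawn library size.  Counts are NB with
    dispersion phi (variance mu + phi mu^2).  Identical seeds give bitwise
    identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = build_sample_design(config)
    truth = _draw_truth(config, rng)

    X = np.stack(
        [
            design_row(
                int(row.strain == config.strains[1]),
                int(row.memory == config.memory_levels[1]),
                row.time,
            )
            for row in design.itertuples()
        ]
    )  # samples x 12
    beta = truth[[f"beta_{t}" for t in TERM_NAMES]].to_numpy()
    log2_mu = beta @ X.T  # genes x samples
    if not np.all(np.isfinite(log2_mu)) or np.abs(log2_mu).max() > 50:
        g, j = np.unravel_index(np.nanargmax(np.abs(log2_mu)), log2_mu.shape)
        raise ValueError(
            "non-finite expected expression for gene class "
            f"{truth['memory_class'].iloc[g]!r} (gene {truth.index[g]}, sample "
            f"{design.index[j]}); reduce effect_scale or times"
        )
    rel = np.exp2(log2_mu)

    if config.lib_size_cv > 0:
        sigma2 = np.log1p(config.lib_size_cv**2)
        lib_sizes = rng.lognormal(
            np.log(config.lib_size_mean) - sigma2 / 2, np.sqrt(sigma2), size=len(design)
        )
    else:
        lib_sizes = np.full(len(design), config.lib_size_mean)

    scale = lib_sizes / rel.sum(axis=0)
    mu = rel * scale[None, :]

    r = 1.0 / config.dispersion  # NB shape
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)

    counts_df = pd.DataFrame(counts, index=truth.index, columns=design.index)
    return counts_df, design, truth


def truth_class_counts(truth: pd.DataFrame) -> pd.DataFrame:
    """Tabulate ground-truth classes; per factor the counts sum to n_genes."""
    out = []
    for factor in ("memory_class", "strain_class", "interaction_class"):
        vc = truth[factor].value_counts()
        for cls in EFFECT_CLASSES:
            out.append((factor.removesuffix("_class"), cls, int(vc.get(cls, 0))))
    vc = truth["direction"].value_counts()
    for cls in ("induced", "repressed", "flat"):
        out.append(("direction", cls, int(vc.get(cls, 0))))
    return pd.DataFrame(out, columns=["factor", "class", "n"])


def write_simulation(
    outdir: str | Path,
    counts: pd.DataFrame,
    design: pd.DataFrame,
    truth: pd.DataFrame,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "design": outdir / "design.tsv",
        "truth": outdir / "truth.tsv",
    }
    counts.to_csv(paths["counts"], sep="\t")
    design.to_csv(paths["design"], sep="\t")
    truth.to_csv(paths["truth"], sep="\t")
    return paths


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain (e.g. YAML) mapping."""
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
    d = dict(d)
    for key in ("times", "strains", "memory_levels", "baseline_log2_range"):
        if key in d:
            d[key] = tuple(d[key])
    return SimConfig(**d)
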