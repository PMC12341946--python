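# memorytc

Analysis toolkit for **transcriptional memory in heat-shock time-course
RNA-seq**.  When yeast cells receive a heat shock, recover, and are shocked
again, the second response is typically *dampened* — prior exposure leaves a
"memory" that attenuates re-induction and re-repression.  `memorytc`
implements the complete statistical pipeline for detecting and classifying
this behavior from a factorial experiment (2 strains × 2 memory conditions ×
a short time course with replicates), plus a negative-binomial simulator that
generates such experiments with known ground truth.

Intended users: computational biologists analyzing stress time-course RNA-seq
with a repeated-stimulus design, and method developers who need a
ground-truth simulator for memory-effect classification.

## The model

Each gene's log2 expression is modeled as a quadratic polynomial in time *t*
(minutes) whose shape can shift with memory (M ∈ {0,1}), strain (S ∈ {0,1})
and their interaction:

```
Y = β0 + βM·M + βS·S + βMS·MS
  + βT·t + βTM·tM + βTS·tS + βTMS·tMS
  + βT2·t² + βT2M·t²M + βT2S·t²S + βT2MS·t²MS + ε
```

Per gene the pipeline: (1) filters low counts (CPM ≥ 1 in a quorum of
samples), (2) normalizes by TMM (weighted trimmed mean of M-values, matching
edgeR's `calcNormFactors` to ~1e-4), (3) computes NOISeq-style pairwise DE
probabilities and five-level fold-change categories against the same-condition
time-0 baseline, (4) fits the model above by OLS and refines it by
hierarchy-respecting backward stepwise elimination, (5) drops genes with no
time association (joint F-test of the eight time terms, BH FDR), and
(6) classifies each factor's effect on the time trend:

* **reversed** — sign(βT + βTM) opposite to sign(βT);
* **enhanced** — |βT + βTM| > |βT|;
* **dampened** — |βT + βTM| < |βT|;
* **no_change** — interaction not significant (nested-model F-test).

The same rule applies to strain (βTS) and, with the net slope of the
doubly-exposed cell against the additive expectation, to the memory×strain
interaction (βTMS).  Genes are split into HS-induced (βT > 0) and
HS-repressed (βT < 0).  Downstream summaries include UpSet-style factor
overlaps, two-proportion tests of a gene subset against the background, and
Fisher/BH gene-set over-representation.  A `2^-ΔΔCt` module quantifies qPCR
validation data.

## Worked example

```python
from memorytc import RunConfig, SimConfig, run_pipeline

cfg = RunConfig(
    outdir="demo",
    simulation=SimConfig(n_genes=1000, seed=42),
    seed=42,
)
report = run_pipeline(cfg)
print(report["stages"])
```

which prints (abridged):

```
input_genes:            1000
filtered_genes:         1000
time_significant_genes: 546
memory_effect:          {"no_change": 212, "dampened": 199,
                         "reversed": 69, "enhanced": 66}
```

Of the 1,000 simulated genes, 546 show a time trend surviving FDR control;
among those, dampening is the dominant memory effect (199 vs 66 enhanced) —
the simulator's default truth mirrors the biology, and
`report["recovery"]` compares recovered labels to that truth (here: memory
0.84, strain 0.90, interaction 0.86, direction 0.99 agreement).  Every table
(counts, normalized expression, DE per comparison, per-gene fits,
classifications, overlaps) is written as TSV under `demo/` together with a
JSON run report; re-running with the same seed reproduces all of them
bitwise.

The same pipeline runs from the shell:

```bash
memorytc simulate --seed 42 --out sim/
memorytc all --config run.yaml
memorytc qpcr --ct ct.tsv --target HSP12 --reference SCR1 --calibrator "WT_t0"
```

Real data enter through `counts_path`/`design_path` (TSV count matrix plus a
sample sheet with strain, memory, time, replicate columns).

## Layout

```
src/memorytc/simulate.py    NB count simulator + ground truth
src/memorytc/preprocess.py  CPM filter, TMM, log2-CPM, PCA QC
src/memorytc/de.py          NOISeq-style DE, FC categories, transitions
src/memorytc/regression.py  per-gene OLS + hierarchical backward stepwise
src/memorytc/classify.py    enhanced/dampened/reversed classification
src/memorytc/enrichment.py  Fisher/BH over-representation (GMT input)
src/memorytc/qpcr.py        2^-ΔΔCt and paired t-tests
src/memorytc/pipeline.py    orchestration, run report
src/memorytc/cli.py         `memorytc` command-line interface
```

See `docs/methods.md` for the statistical details and the simulator's design
assumptions.
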