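# metabotype

Metabolic subtyping of plasma metabolomics cohorts: from raw,
batch-structured, semi-quantitative metabolite intensities to

- **consensus-NMF metabolic subtypes** with cophenetic / silhouette / PAC
  rank selection,
- **classifier metabolites** and lipid-subclass change summaries,
- **pathway differential-abundance scores** (DAS), and
- **metabolic programs** — weighted-correlation-network modules of
  co-varying metabolites, correlated back to the subtypes,

plus a **synthetic-cohort generator** that reproduces the measurement
design (24-sample analytical batches with 4 reference-pool replicates,
calibrant replicates of known concentration, three study phases,
lipid-dominated metabolite panels) with full ground truth, so the whole
pipeline is developed and validated without patient data.

The package is aimed at computational metabolomics researchers who want a
reproducible, scriptable implementation of this subtyping workflow — the
kind used to stratify pancreatic-cancer plasma profiles into
sphingolipid-high, sphingolipid-low and triacylglycerol-driven phenotypes.

## The core methods

**Normalization.** Each measurement is divided by the within-batch median
of the pooled-reference replicates (per metabolite), then anchored by
single-point calibration: `value / median(calibrant ratios) x known
concentration`. Metabolites missing in ≥10% of any phase's patients are
dropped; the rest are log10-transformed, phase-median imputed and
auto-scaled.

**Subtyping.** The auto-scaled matrix is folded non-negative
(`[max(X,0); max(−X,0)]`) and factorized `V ≈ WH` with Lee–Seung
multiplicative updates from many random starts. Co-assignment frequencies
across replicates form a consensus matrix per rank k ∈ 3..6; the chosen
rank maximizes the cophenetic correlation (ties: silhouette, then PAC),
and final labels cut the consensus dendrogram.

**Pathway scoring.** Per subtype-versus-rest contrast, Welch t-tests with
Benjamini–Hochberg correction feed the differential abundance score

    DAS = (n↑ − n↓) / (n↑ + n↓)

over a pathway's significantly changed members: +1 = all increased,
−1 = all decreased.

**Programs.** A signed adjacency `((1+r)/2)^β` (β = 12) smoothed by the
topological overlap measure is clustered into modules; eigen-metabolite
(PC1) profiles summarize each module, near-duplicate modules merge, and
module–subtype correlations with hypergeometric pathway enrichment
identify the programs behind each subtype.

See `docs/methods.md` for model details, defaults and limitations.

## Worked example

```python
from metabotype import CohortConfig, generate_cohort
from metabotype.preprocess import run_preprocess
from metabotype.nmf import subtype_study
from metabotype.diffabund import das, one_vs_rest
from metabotype.programs import fit_programs

cohort = generate_cohort(CohortConfig(seed=7).scaled(200))
scaled = run_preprocess(cohort.study, cohort.calibrant_concentrations)
X = scaled.patient_values()

result = subtype_study(X, n_replicates=100, seed=7)
print("chosen rank:", result.chosen_k)
print(result.diagnostics_frame().round(3))
```

```
chosen rank: 3
   cophenetic  silhouette    pac
k
3       0.999       0.990  0.004
4       0.976       0.752  0.298
5       0.951       0.679  0.316
6       0.969       0.681  0.312
```

Rank 3 wins on every diagnostic: the consensus matrix at k = 3 is almost
perfectly reproducible (cophenetic 0.999, PAC 0.004), while higher ranks
split unstably. The recovered subtypes (29/49/122 patients) mirror the
planted size-ordered fractions.

```python
diff = one_vs_rest(X, result.labels)
scores = das(diff, cohort.annotation)
print(scores[scores["pathway"] == "sphingolipid metabolism"]
      [["contrast", "n_up", "n_down", "das"]].to_string(index=False))
```

```
        contrast  n_up  n_down       das
subtype1_vs_rest    14      16 -0.066667
subtype2_vs_rest    30       0  1.000000
subtype3_vs_rest     0      30 -1.000000
```

The sphingolipid pathway scores +1 in subtype 2 (every significant member
increased — the sphingolipid-high phenotype), −1 in subtype 3 (all
decreased) and near 0 in subtype 1, whose signature is a mixed
triacylglycerol-up / ceramide-down pattern.

```python
modules, net = fit_programs(X, annotation=cohort.annotation, labels=result.labels)
print(modules.trait_cor.r.round(2))
```

```
      1     2     3
1 -0.09  0.95 -0.77
2  0.73  0.33 -0.82
3 -0.08  0.02  0.04
4 -0.12 -0.04  0.12
```

Program 1 (the sphingolipid module) tracks subtype 2 at r = 0.95 and
anti-tracks subtype 3; program 2 (triacylglycerols) tracks subtype 1.

The same pipeline runs from the shell:

```sh
metabotype run --synth-defaults --seed 7 --out results/run7
metabotype synth --seed 7 --n-patients 200 --out cohort/
metabotype preprocess --input cohort/study.tsv \
    --calibrants cohort/calibrant_concentrations.tsv --out norm.tsv
metabotype subtype --input norm.tsv --replicates 1000 --out subtypes.tsv
```

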