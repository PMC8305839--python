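"""Synthetic plasma-metabolomics cohorts with full ground truth.

The generator reproduces the measurement design the downstream analysis
assumes: three prospective study phases, analytical batches of 24 samples
(20 patients plus 4 replicates of a pooled reference), a set of calibrant
replicates of known concentration, log-normal metabolite abundances,
multiplicative per-batch instrument factors, subtype-specific shifts on
lipid subclasses, planted blocks of co-varying metabolites, and optional
detection-limit missingness.  Every latent quantity (subtype labels, block
memberships, batch factors, calibrant concentrations) is returned so
parameter-recovery tests can compare estimates against truth.

Abundance model, on the log10 scale, for patient sample *s* and
metabolite *m*::

    log10 x[s, m] = a_m + c_m + effect(subtype_s, subclass_m)
                    + block_scale * f[block_m, s] + s_m * eps
                    + b[batch_s, m]

where ``a_m`` is the instrument response, ``c_m`` the cohort-median log
concentration, ``f`` a standard-normal latent factor shared within a
planted block (complex-lipid species of one subclass co-vary severalfold
between individuals, so the shared factor carries more variance than the
metabolite-specific noise), and ``b`` the batch factor.  Reference replicates measure
the pooled profile ``a_m + c_m`` plus replicate noise; calibrant
replicates measure a known concentration through the same response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    LIPID_CLASS,
    AnnotationTable,
    StudyMatrix,
    write_annotation_tsv,
    write_series_tsv,
    write_study_tsv,
)

LIPID_SUBCLASSES = ("SM", "CER", "TAG", "PC", "LPC", "other lipid")

#: non-lipid ontology classes, in apportionment order
OTHER_CLASSES = (
    "amino acids and related",
    "carbohydrates and energy",
    "nucleotides",
    "cofactors and vitamins",
)

#: fixed pathway catalogue; names mirror common KEGG pathway labels
PATHWAY_CATALOGUE = (
    "sphingolipid metabolism",
    "sphingolipid signaling pathway",
    "regulation of lipolysis",
    "cholesterol metabolism",
    "choline metabolism in cancer",
    "glycerophospholipid metabolism",
    "glycerolipid metabolism",
    "ether lipid metabolism",
    "linoleic acid metabolism",
    "biosynthesis of unsaturated fatty acids",
    "fatty acid biosynthesis",
    "fatty acid degradation",
    "arachidonic acid metabolism",
    "steroid biosynthesis",
    "autophagy",
    "apoptosis",
    "alanine, aspartate and glutamate metabolism",
    "valine, leucine and isoleucine degradation",
    "glycolysis / gluconeogenesis",
    "purine metabolism",
)

#: deterministic core pathway memberships per lipid subclass
SUBCLASS_PATHWAYS: dict[str, tuple[str, ...]] = {
    "SM": ("sphingolipid metabolism", "sphingolipid signaling pathway"),
    "CER": ("sphingolipid metabolism", "sphingolipid signaling pathway", "apoptosis"),
    "TAG": ("glycerolipid metabolism", "regulation of lipolysis"),
    "PC": ("glycerophospholipid metabolism", "choline metabolism in cancer"),
    "LPC": ("glycerophospholipid metabolism", "ether lipid metabolism"),
    "other lipid": ("biosynthesis of unsaturated fatty acids", "fatty acid degradation"),
}

#: deterministic core pathway memberships per non-lipid class
CLASS_PATHWAYS: dict[str, tuple[str, ...]] = {
    "amino acids and related": ("alanine, aspartate and glutamate metabolism",),
    "carbohydrates and energy": ("glycolysis / gluconeogenesis",),
    "nucleotides": ("purine metabolism",),
    "cofactors and vitamins": ("steroid biosynthesis",),
}

#: qualitative subtype effect directions on lipid subclasses:
#: subtype 1 gains triacylglycerols and loses ceramides, subtype 2 gains
#: ceramides and sphingomyelins, subtype 3 loses all three; patterns for
#: ranks beyond 3 keep additional planted subtypes distinguishable.
SUBTYPE_EFFECT_PATTERNS: tuple[dict[str, float], ...] = (
    {"TAG": +1.0, "CER": -1.0},
    {"CER": +1.0, "SM": +1.0},
    {"CER": -1.0, "TAG": -1.0, "SM": -1.0},
    {"PC": +1.0, "LPC": -1.0},
    {"LPC": +1.0, "PC": -1.0, "TAG": +1.0},
    {"SM": +1.0, "PC": -1.0, "CER": -1.0},
)


class ConfigError(ValueError):
    """Raised for an inconsistent cohort configuration."""


def _as_fraction_map(mapping: Mapping[str, float], what: str) -> dict[str, float]:
    total = float(sum(mapping.values()))
    if abs(total - 1.0) > 1e-12:
        raise ConfigError(f"{what} proportions must sum to 1 (got {total!r})")
    if any(v < 0 for v in mapping.values()):
        raise ConfigError(f"{what} proportions must be non-negative")
    return dict(mapping)


def _apportion(total: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of `total` items to `fractions`."""
    raw = [total * f for f in fractions]
    counts = [int(math.floor(r)) for r in raw]
    remainder = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the measurement design of a three-phase pancreatic
    cancer plasma study: phases of 80/79/202 patients, 24-sample batches
    with 4 reference-pool replicates, 12 calibrant replicates, three
    subtypes at fractions 50/361, 88/361, 223/361, and a metabolite panel
    dominated (>76%) by complex lipids and fatty acids.
    """

    n_subtypes: int = 3
    subtype_fractions: tuple[float, ...] = (50 / 361, 88 / 361, 223 / 361)
    phase_sizes: tuple[int, ...] = (80, 79, 202)
    phase_names: tuple[str, ...] = ("ID", "VD1", "VD2")
    n_metabolites: int = 150
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            LIPID_CLASS: 0.80,
            "amino acids and related": 0.10,
            "carbohydrates and energy": 0.05,
            "nucleotides": 0.03,
            "cofactors and vitamins": 0.02,
        }
    )
    subclass_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "SM": 0.18,
            "CER": 0.16,
            "TAG": 0.20,
            "PC": 0.16,
            "LPC": 0.08,
            "other lipid": 0.22,
        }
    )
    batch_size: int = 24
    n_reference_per_batch: int = 4
    n_calibrant_replicates: int = 12
    effect_size: float = 0.8
    batch_sd: float = 0.15
    n_blocks: int = 5
    block_scale: float = 0.30
    replicate_sd: float = 0.05
    missing_rate: float = 0.05
    missing_mechanism: str = "MNAR-low"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subtypes < 1 or self.n_subtypes > len(SUBTYPE_EFFECT_PATTERNS):
            raise ConfigError(
                f"n_subtypes must be in 1..{len(SUBTYPE_EFFECT_PATTERNS)}"
            )
        if len(self.subtype_fractions) != self.n_subtypes:
            raise ConfigError("subtype_fractions length must equal n_subtypes")
        if abs(sum(self.subtype_fractions) - 1.0) > 1e-12:
            raise ConfigError("subtype_fractions must sum to 1")
        if len(self.phase_sizes) != len(self.phase_names):
            raise ConfigError("phase_sizes and phase_names must align")
        if any(n <= 0 for n in self.phase_sizes):
            raise ConfigError("phase sizes must be positive")
        if self.n_metabolites < 1:
            raise ConfigError("n_metabolites must be positive")
        if self.batch_size != 24 or self.n_reference_per_batch != 4:
            raise ConfigError(
                "the analytical design is fixed at 24-sample batches with "
                "4 reference replicates"
            )
        if not 0.0 <= self.missing_rate <= 0.3:
            raise ConfigError("missing_rate must lie in [0, 0.3]")
        if self.missing_mechanism not in ("MCAR", "MNAR-low"):
            raise ConfigError("missing_mechanism must be 'MCAR' or 'MNAR-low'")
        _as_fraction_map(self.class_mix, "class_mix")
        _as_fraction_map(self.subclass_mix, "subclass_mix")
        if self.n_blocks < 0:
            raise ConfigError("n_blocks must be non-negative")
        if self.block_scale < 0:
            raise ConfigError("block_scale must be non-negative")

    @property
    def n_patients(self) -> int:
        return int(sum(self.phase_sizes))

    @property
    def patients_per_batch(self) -> int:
        return self.batch_size - self.n_reference_per_batch

    def scaled(self, n_patients: int, **overrides) -> "CohortConfig":
        """Config with phase sizes rescaled to a total of `n_patients`."""
        fracs = [p / self.n_patients for p in self.phase_sizes]
        sizes = tuple(_apportion(n_patients, fracs))
        kwargs = {**self.__dict__, "phase_sizes": sizes, **overrides}
        return CohortConfig(**kwargs)


@dataclass
class GeneratedCohort:
    """A synthetic cohort together with its generating ground truth."""

    study: StudyMatrix
    annotation: AnnotationTable
    truth_labels: pd.Series  # patient sample -> subtype id (1-based)
    truth_modules: pd.Series  # metabolite -> planted block id (0 = none)
    truth_batch_factors: pd.DataFrame  # batch x metabolite multiplicative factor
    calibrant_concentrations: pd.Series  # metabolite -> known concentration

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_study_tsv(self.study, outdir / "study.tsv")
        write_annotation_tsv(self.annotation, outdir / "annotation.tsv")
        write_series_tsv(self.truth_labels, outdir / "truth_labels.tsv", "sample_id", "subtype")
        write_series_tsv(self.truth_modules, outdir / "truth_modules.tsv", "metabolite_id", "block")
        write_series_tsv(
            self.calibrant_concentrations,
            outdir / "calibrant_concentrations.tsv",
            "metabolite_id",
            "concentration",
        )
        bf = self.truth_batch_factors.copy()
        bf.index.name = "batch"
        bf.to_csv(outdir / "truth_batch_factors.tsv", sep="\t")


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(config: CohortConfig) -> AnnotationTable:
    """Draw a metabolite annotation table under the configured class mix.

    Class and subclass counts are apportioned deterministically (largest
    remainder), so the configured proportions are met exactly up to
    rounding; pathway memberships combine a deterministic subclass core
    with 0-2 random extras, for 1-4 memberships per metabolite.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    classes_order = [LIPID_CLASS] + [c for c in OTHER_CLASSES if c in config.class_mix]
    extra = [c for c in config.class_mix if c not in classes_order]
    classes_order += extra
    class_counts = _apportion(
        config.n_metabolites, [config.class_mix.get(c, 0.0) for c in classes_order]
    )

    rows: list[tuple[str, str, str, tuple[str, ...]]] = []
    idx = 0
    for cls, n_cls in zip(classes_order, class_counts):
        if cls == LIPID_CLASS:
            sub_order = [s for s in LIPID_SUBCLASSES if s in config.subclass_mix]
            sub_counts = _apportion(n_cls, [config.subclass_mix[s] for s in sub_order])
            sub_seq: list[str] = []
            for s, n_s in zip(sub_order, sub_counts):
                sub_seq += [s] * n_s
        else:
            sub_seq = [""] * n_cls
        for sub in sub_seq:
            met = f"met_{idx:04d}"
            core = SUBCLASS_PATHWAYS.get(sub) if sub else CLASS_PATHWAYS.get(cls)
            if core is None:
                core = ("fatty acid biosynthesis",)
            n_extra = int(rng.integers(0, 3))
            pool = [p for p in PATHWAY_CATALOGUE if p not in core]
            extras = tuple(rng.choice(pool, size=n_extra, replace=False)) if n_extra else ()
            pathways = tuple(core[: 4 - len(extras)]) + extras
            rows.append((met, cls, sub, pathways[:4]))
            idx += 1

    table = pd.DataFrame(
        {
            "class": [r[1] for r in rows],
            "subclass": [r[2] for r in rows],
            "pathways": [r[3] for r in rows],
        },
        index=pd.Index([r[0] for r in rows], name="metabolite_id"),
    )
    return AnnotationTable(table=table)


# ---------------------------------------------------------------------------
# cohort


def _plant_blocks(annotation: AnnotationTable, n_blocks: int) -> pd.Series:
    """Assign metabolites to planted correlated blocks.

    The first blocks coincide with the subtype-responsive lipid subclasses
    (SM, CER, TAG, PC, LPC), so the planted co-variation and the subtype
    effects reinforce the same structure; further blocks are carved from
    the remaining metabolites in id order.
    """
    subclass = annotation.subclass_of()
    assignment = pd.Series(0, index=annotation.table.index, dtype=int)
    groups: list[list[str]] = []
    for sub in ("SM", "CER", "TAG", "PC", "LPC"):
        ids = list(subclass.index[subclass == sub])
        if ids:
            groups.append(ids)
    leftovers = [m for m in annotation.table.index if subclass[m] in ("", "other lipid")]
    if n_blocks > len(groups) and leftovers:
        n_more = n_blocks - len(groups)
        chunks = np.array_split(np.asarray(leftovers, dtype=object), n_more)
        groups += [list(c) for c in chunks if len(c)]
    for block_id, ids in enumerate(groups[:n_blocks], start=1):
        assignment.loc[ids] = block_id
    return assignment


def _subtype_effect_matrix(config: CohortConfig, annotation: AnnotationTable) -> np.ndarray:
    """(n_subtypes x n_metabolites) additive log10 effects."""
    subclass = annotation.subclass_of().to_numpy()
    eff = np.zeros((config.n_subtypes, len(subclass)))
    for s in range(config.n_subtypes):
        pattern = SUBTYPE_EFFECT_PATTERNS[s]
        for sub, direction in pattern.items():
            eff[s, subclass == sub] = direction * config.effect_size
    return eff


def _missing_probability(log_values: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Per-cell missingness probability for patient measurements."""
    n, m = log_values.shape
    if config.missing_rate == 0:
        return np.zeros((n, m))
    if config.missing_mechanism == "MCAR":
        return np.full((n, m), config.missing_rate)
    # MNAR-low: logistic in the within-metabolite intensity rank, loading
    # missingness onto the lowest decile (detection-limit censoring).
    order = np.argsort(np.argsort(log_values, axis=0), axis=0)
    q = (order + 0.5) / n
    w = 1.0 / (1.0 + np.exp((q - 0.10) / 0.05))
    w_mean = w.mean(axis=0, keepdims=True)
    p = config.missing_rate * w / np.maximum(w_mean, 1e-12)
    return np.clip(p, 0.0, 0.95)


def generate_cohort(config: CohortConfig) -> GeneratedCohort:
    """Generate a full synthetic cohort with ground truth.

    Pure function of the configuration: the same config (including seed)
    reproduces the cohort bit-for-bit.
    """
    annotation = generate_annotation(config)
    mets = annotation.table.index.to_numpy(dtype=object)
    n_met = len(mets)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))

    # metabolite-level latent parameters
    a_m = rng.normal(2.0, 0.4, size=n_met)  # log10 instrument response
    c_m = rng.normal(0.0, 0.8, size=n_met)  # log10 cohort-median concentration
    s_m = rng.uniform(0.15, 0.30, size=n_met)  # biological log10 sd

    truth_modules = _plant_blocks(annotation, config.n_blocks)
    block = truth_modules.to_numpy()
    effects = _subtype_effect_matrix(config, annotation)

    # patients: ids, phases, batches
    patient_ids: list[str] = []
    phases: list[str] = []
    batches: list[int] = []
    batch_phase: dict[int, str] = {}
    batch_id = 0
    for phase, size in zip(config.phase_names, config.phase_sizes):
        for i in range(size):
            if i % config.patients_per_batch == 0:
                batch_id += 1
                batch_phase[batch_id] = phase
            patient_ids.append(f"{phase}_P{i + 1:03d}")
            phases.append(phase)
            batches.append(batch_id)
    n_pat = len(patient_ids)
    n_batches = batch_id

    # subtype labels: exact counts by largest remainder, randomly placed
    counts = _apportion(n_pat, config.subtype_fractions)
    label_pool = np.repeat(np.arange(1, config.n_subtypes + 1), counts)
    labels = label_pool[rng.permutation(n_pat)]

    # patient log10 intensities
    factors = rng.standard_normal((max(config.n_blocks, 1), n_pat))
    eps = rng.standard_normal((n_pat, n_met))
    log_pat = np.tile(a_m + c_m, (n_pat, 1))
    log_pat += effects[labels - 1, :]
    log_pat += s_m * eps
    in_block = block > 0
    if in_block.any() and config.n_blocks > 0:
        shared = factors[block[in_block] - 1, :].T  # n_pat x n_block_members
        log_pat[:, in_block] += config.block_scale * shared

    # batch factors (log10, metabolite-specific) applied to every sample
    log_bf = rng.normal(0.0, config.batch_sd, size=(n_batches, n_met))
    pat_batch = np.asarray(batches)
    log_pat += log_bf[pat_batch - 1, :]

    # reference-pool replicates: pooled profile + replicate noise
    ref_ids, ref_phases, ref_batches = [], [], []
    ref_rows = []
    for b in range(1, n_batches + 1):
        for r in range(config.n_reference_per_batch):
            ref_ids.append(f"B{b:02d}_REF{r + 1}")
            ref_phases.append(batch_phase[b])
            ref_batches.append(b)
            ref_rows.append(
                a_m + c_m + rng.normal(0.0, config.replicate_sd, size=n_met) + log_bf[b - 1]
            )
    log_ref = np.asarray(ref_rows)

    # calibrant replicates with known concentrations, cycled over batches
    conc = 10.0 ** (c_m + rng.normal(0.0, 0.10, size=n_met))
    cal_ids, cal_phases, cal_batches = [], [], []
    cal_rows = []
    for r in range(config.n_calibrant_replicates):
        b = (r % n_batches) + 1
        cal_ids.append(f"CAL{r + 1:02d}")
        cal_phases.append(batch_phase[b])
        cal_batches.append(b)
        cal_rows.append(
            a_m + np.log10(conc) + rng.normal(0.0, config.replicate_sd, size=n_met) + log_bf[b - 1]
        )
    log_cal = np.asarray(cal_rows) if cal_rows else np.empty((0, n_met))

    # missingness on patient measurements only
    p_miss = _missing_probability(log_pat, config)
    miss = rng.random((n_pat, n_met)) < p_miss

    values_pat = 10.0 ** log_pat
    values_pat[miss] = np.nan

    all_ids = patient_ids + ref_ids + cal_ids
    all_values = np.vstack([values_pat, 10.0 ** log_ref, 10.0 ** log_cal])
    values = pd.DataFrame(all_values, index=pd.Index(all_ids, name="sample_id"), columns=mets)
    meta = pd.DataFrame(
        {
            "role": ["patient"] * n_pat
            + ["reference"] * len(ref_ids)
            + ["calibrant"] * len(cal_ids),
            "batch": batches + ref_batches + cal_batches,
            "phase": phases + ref_phases + cal_phases,
        },
        index=values.index,
    )
    study = StudyMatrix(values=values, sample_meta=meta, stage="raw")

    return GeneratedCohort(
        study=study,
        annotation=annotation,
        truth_labels=pd.Series(labels, index=pd.Index(patient_ids, name="sample_id"), name="subtype"),
        truth_modules=truth_modules,
        truth_batch_factors=pd.DataFrame(
            10.0 ** log_bf, index=pd.RangeIndex(1, n_batches + 1, name="batch"), columns=mets
        ),
        calibrant_concentrations=pd.Series(conc, index=pd.Index(mets, name="metabolite_id"), name="concentration"),
    )
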