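"""End-to-end orchestration: synth -> preprocess -> subtype -> diff -> programs.

A pipeline run is driven by a configuration mapping (typically parsed
from YAML or JSON) holding either input paths (study, annotation and
optionally calibrant-concentration TSVs) or a ``synth`` block of cohort
parameters, plus stage parameters and a global seed.  The global seed
fans out to fixed per-stage child seeds, so any stage can be re-run in
isolation and the whole run is bit-reproducible from the manifest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .containers import (
    AnnotationTable,
    StudyMatrix,
    read_annotation_tsv,
    read_series_tsv,
    read_study_tsv,
    write_series_tsv,
    write_study_tsv,
)
from .diffabund import (
    covariate_independence,
    das,
    one_vs_rest,
    pairwise,
    pathway_network,
    select_classifiers,
    subclass_summary,
)
from .nmf import subtype_study
from .preprocess import run_preprocess
from .programs import fit_programs, hub_metabolites, significant_modules
from .synth import CohortConfig, generate_cohort

STAGE_NAMES = ("synth", "preprocess", "subtype", "diff", "programs")


def stage_seeds(seed: int) -> dict[str, int]:
    """Fixed derivation of per-stage child seeds from the global seed."""
    state = np.random.SeedSequence(int(seed)).generate_state(len(STAGE_NAMES))
    return {name: int(s & 0x7FFFFFFF) for name, s in zip(STAGE_NAMES, state)}


def validate_inputs(study: StudyMatrix, annotation: AnnotationTable) -> pd.DataFrame:
    """Report-only consistency checks between a study and its annotation.

    Checks metabolite id agreement, completeness of role/batch/phase
    metadata, and positivity of raw intensities; returns one row per
    violation (empty frame when clean).
    """
    issues: list[dict[str, str]] = []
    ann_ids = set(annotation.table.index)
    for m in study.metabolite_ids:
        if m not in ann_ids:
            issues.append(
                {"severity": "warning", "location": m, "message": "metabolite missing from annotation"}
            )
    for m in ann_ids - set(study.metabolite_ids):
        issues.append(
            {"severity": "info", "location": m, "message": "annotated metabolite not measured"}
        )
    meta = study.sample_meta
    for col in ("role", "batch", "phase"):
        bad = meta.index[meta[col].isna()]
        for s in bad:
            issues.append({"severity": "error", "location": str(s), "message": f"missing {col}"})
    if study.stage in ("raw", "pool_normalized", "calibrated"):
        v = study.values
        bad_cells = np.argwhere((v.to_numpy() <= 0) & ~np.isnan(v.to_numpy()))
        for i, j in bad_cells:
            issues.append(
                {
                    "severity": "error",
                    "location": f"{v.index[i]}/{v.columns[j]}",
                    "message": "non-positive raw intensity",
                }
            )
    return pd.DataFrame(issues, columns=["severity", "location", "message"])


def _load_inputs(config: Mapping[str, Any], seeds: dict[str, int]):
    if "synth" in config:
        synth_params = dict(config["synth"] or {})
        synth_params.setdefault("seed", seeds["synth"])
        cohort = generate_cohort(CohortConfig(**synth_params))
        return cohort.study, cohort.annotation, cohort.calibrant_concentrations, cohort
    if "inputs" not in config:
        raise ValueError("config needs either an 'inputs' or a 'synth' block")
    inputs = config["inputs"]
    study = read_study_tsv(inputs["study"])
    annotation = read_annotation_tsv(inputs["annotation"])
    conc = None
    if inputs.get("calibrant_concentrations"):
        conc = read_series_tsv(inputs["calibrant_concentrations"], "metabolite_id")
    return study, annotation, conc, None


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> Path:
    """Execute the full pipeline and write every stage's tables.

    Returns the output directory.  Artifacts: ``study_raw.tsv`` (synth
    runs), ``study_autoscaled.tsv``, ``subtypes.tsv``, ``diagnostics.tsv``,
    consensus matrices, ``differential.tsv``, ``das.tsv``,
    ``classifiers.tsv``, ``subclass_summary.tsv``, ``network_edges.tsv``,
    ``modules.tsv``, ``eigen.tsv``, ``trait_cor.tsv``, ``enrichment.tsv``
    and a ``manifest.json`` echoing version, seed and parameters.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    seeds = stage_seeds(seed)
    params = dict(config.get("params", {}))

    study, annotation, conc, cohort = _load_inputs(config, seeds)
    if cohort is not None:
        cohort.write(outdir / "synth")

    report = validate_inputs(study, annotation)
    report.to_csv(outdir / "validation.tsv", sep="\t", index=False)

    scaled = run_preprocess(study, conc, threshold=float(params.get("threshold", 0.10)))
    write_study_tsv(scaled, outdir / "study_autoscaled.tsv")
    X = scaled.patient_values()

    kmin = int(params.get("kmin", 3))
    kmax = int(params.get("kmax", 6))
    result = subtype_study(
        X,
        k_range=range(kmin, kmax + 1),
        n_replicates=int(params.get("n_replicates", 100)),
        seed=seeds["subtype"],
        max_iter=int(params.get("max_iter", 100)),
    )
    write_series_tsv(result.labels, outdir / "subtypes.tsv", "sample_id", "subtype")
    result.diagnostics_frame().to_csv(outdir / "diagnostics.tsv", sep="\t")
    for k, d in result.ranks.items():
        pd.DataFrame(d.consensus, index=X.index, columns=X.index).to_csv(
            outdir / f"consensus_k{k}.tsv", sep="\t"
        )

    labels = result.labels
    alpha = float(params.get("alpha", 0.05))
    diff = one_vs_rest(X, labels)
    diff_pw = pairwise(X, labels)
    pd.concat([diff, diff_pw], ignore_index=True).to_csv(
        outdir / "differential.tsv", sep="\t", index=False
    )
    das(pd.concat([diff, diff_pw], ignore_index=True), annotation, alpha=alpha).to_csv(
        outdir / "das.tsv", sep="\t", index=False
    )
    select_classifiers(diff, n=int(params.get("n_classifiers", 30)), alpha=alpha).to_csv(
        outdir / "classifiers.tsv", sep="\t", index=False
    )
    subclass_summary(diff, annotation, alpha=alpha).to_csv(
        outdir / "subclass_summary.tsv", sep="\t", index=False
    )
    pathway_network(diff, annotation, alpha=alpha).edge_list().to_csv(
        outdir / "network_edges.tsv", sep="\t", index=False
    )
    if cohort is not None:
        covariate_independence(
            labels, scaled.sample_meta.loc[labels.index, ["phase"]]
        ).to_csv(outdir / "covariate_independence.tsv", sep="\t", index=False)

    beta_param = params.get("beta", 12)
    modules, net = fit_programs(
        X,
        annotation=annotation,
        labels=labels,
        beta=None if beta_param in (None, "auto") else int(beta_param),
        target_r2=float(params.get("target_r2", 0.8)),
        min_size=int(params.get("min_size", 5)),
        cut_height=float(params.get("cut_height", 0.96)),
        merge_height=float(params.get("merge_height", 0.25)),
    )
    assignment = modules.assignment.to_frame()
    if modules.kme is not None:
        own = [
            modules.kme.loc[m, mod] if mod in modules.kme.columns else np.nan
            for m, mod in modules.assignment.items()
        ]
        assignment["kme_own"] = own
    assignment.index.name = "metabolite_id"
    assignment.to_csv(outdir / "modules.tsv", sep="\t")
    if modules.eigen is not None:
        eig = modules.eigen.copy()
        eig.columns = [f"MP{c}" for c in eig.columns]
        eig.index.name = "sample_id"
        eig.to_csv(outdir / "eigen.tsv", sep="\t")
        hubs = hub_metabolites(modules.kme, modules.assignment, n=3)
        pd.DataFrame(
            [{"module": m, "rank": i + 1, "metabolite": met} for m, hs in hubs.items() for i, met in enumerate(hs)]
        ).to_csv(outdir / "hubs.tsv", sep="\t", index=False)
    if modules.trait_cor is not None:
        tc = modules.trait_cor.r.copy()
        tc.columns = [f"subtype{c}_r" for c in tc.columns]
        tp = modules.trait_cor.p.copy()
        tp.columns = [f"subtype{c}_p" for c in tp.columns]
        out = tc.join(tp)
        out.index.name = "module"
        out.to_csv(outdir / "trait_cor.tsv", sep="\t")
    if modules.enrichment is not None:
        modules.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        if modules.trait_cor is not None:
            sig = significant_modules(modules.enrichment, modules.trait_cor, alpha=alpha)
            (outdir / "significant_modules.txt").write_text(
                "\n".join(str(m) for m in sig) + ("\n" if sig else ""), encoding="utf-8"
            )

    manifest = {
        "package": "metabotype",
        "version": __version__,
        "seed": seed,
        "stage_seeds": seeds,
        "params": {**params, "kmin": kmin, "kmax": kmax, "alpha": alpha},
        "synth": dict(config.get("synth", {})) if "synth" in config else None,
        "inputs": dict(config.get("inputs", {})) if "inputs" in config else None,
        "chosen_k": int(result.chosen_k),
        "soft_threshold_beta": float(net.beta),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return outdir
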