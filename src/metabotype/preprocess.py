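"""Normalization, calibration, filtering and scaling of a study matrix.

The stages follow the semi-quantitative two-reference design: every
analytical batch carries four replicates of a pooled reference, and the
whole study carries a set of calibrant replicates of known concentration.

1. :func:`pool_normalize` — divide each measurement by the within-batch
   median of the reference-pool replicates (per metabolite), removing
   inter- and intra-instrument variation.
2. :func:`calibrate` — single-point calibration: scale the pool-normalized
   ratio by the known calibrant concentration over the calibrant median.
3. :func:`filter_missing` — keep only metabolites missing in fewer than a
   threshold fraction (strictly less than 10% by default) of patient
   samples in *every* study phase.
4. :func:`log_impute_scale` — log10 transform, impute missing cells with
   the within-phase patient median, and auto-scale each metabolite to zero
   mean and unit standard deviation across patient samples.

The order log10 -> impute -> auto-scale keeps imputed cells at the phase
median z-position and prevents the imputed values from influencing the
scale estimate asymmetrically.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CalibrantPanel, StudyMatrix


class PreprocessError(ValueError):
    pass


def pool_normalize(study: StudyMatrix) -> StudyMatrix:
    """Normalize every sample against the batch-wise reference-pool median.

    ``value[s, m] <- value[s, m] / median(reference replicates of batch(s), m)``

    Metabolites with no usable (positive, non-missing) reference median in
    some batch are set missing for that batch's samples and flagged.
    Raises :class:`PreprocessError` for a batch without any reference
    replicate.
    """
    if study.stage != "raw":
        raise PreprocessError(f"pool_normalize expects stage 'raw', got {study.stage!r}")
    values = study.values.copy()
    meta = study.sample_meta
    extra_flags: dict[str, tuple[str, ...]] = {}
    for batch, batch_meta in meta.groupby("batch", sort=True):
        ref_ids = batch_meta.index[batch_meta["role"] == "reference"]
        if len(ref_ids) == 0:
            raise PreprocessError(f"batch {batch!r} contains no reference replicates")
        med = study.values.loc[ref_ids].median(axis=0, skipna=True)
        usable = med.notna() & (med > 0)
        rows = batch_meta.index
        values.loc[rows, usable[usable].index] = (
            study.values.loc[rows, usable[usable].index] / med[usable]
        )
        for m in med.index[~usable]:
            values.loc[rows, m] = np.nan
            extra_flags[m] = extra_flags.get(m, ()) + (f"no_reference_median_batch_{batch}",)
    return study.advanced(values, "pool_normalized", extra_flags=extra_flags)


def extract_calibrant_panel(study: StudyMatrix, concentrations: pd.Series) -> CalibrantPanel:
    """Build a calibrant panel from a study's calibrant rows."""
    cal_ids = study.rows_with_role("calibrant")
    if len(cal_ids) < 2:
        raise PreprocessError("study contains fewer than 2 calibrant replicates")
    return CalibrantPanel(
        replicate_values=study.values.loc[cal_ids],
        concentrations=concentrations.reindex(study.values.columns),
    )


def calibrate(study: StudyMatrix, panel: CalibrantPanel) -> StudyMatrix:
    """Single-point calibration against the calibrant replicate median.

    ``value[s, m] <- value[s, m] / median(panel[:, m]) * concentration[m]``

    Metabolites lacking a known concentration keep the pool-normalized
    ratio and are flagged ``semi_quantitative``; metabolites with a
    non-positive calibrant median are flagged and left uncalibrated.
    """
    if study.stage != "pool_normalized":
        raise PreprocessError(
            f"calibrate expects stage 'pool_normalized', got {study.stage!r}"
        )
    med = panel.replicate_values.median(axis=0, skipna=True).reindex(study.values.columns)
    conc = panel.concentrations.reindex(study.values.columns)
    values = study.values.copy()
    extra_flags: dict[str, tuple[str, ...]] = {}
    for m in study.values.columns:
        if pd.isna(conc[m]):
            extra_flags[m] = ("semi_quantitative",)
            continue
        if pd.isna(med[m]) or med[m] <= 0:
            extra_flags[m] = ("uncalibrated_nonpositive_calibrant_median",)
            continue
        values[m] = study.values[m] / med[m] * conc[m]
    return study.advanced(values, "calibrated", extra_flags=extra_flags)


def filter_missing(study: StudyMatrix, threshold: float = 0.10) -> StudyMatrix:
    """Keep metabolites missing in < `threshold` of patients in every phase.

    The comparison is strict (a metabolite missing in exactly 10% of one
    phase's patients is dropped at the default threshold), the fractions
    are computed over patient samples only, and the survivor order is
    preserved.  Idempotent, and independent of sample row order.
    """
    if study.stage not in ("raw", "pool_normalized", "calibrated"):
        raise PreprocessError("filter_missing must run before imputation")
    pat = study.patient_ids
    if len(pat) == 0:
        raise PreprocessError("study contains no patient samples")
    phases = study.sample_meta.loc[pat, "phase"]
    keep = pd.Series(True, index=study.values.columns)
    for phase, ids in phases.groupby(phases).groups.items():
        if len(ids) == 0:
            raise PreprocessError(f"phase {phase!r} has no patient samples")
        frac = study.values.loc[ids].isna().mean(axis=0)
        # strict "<", except that a fully observed metabolite always
        # survives (so threshold 0 keeps exactly the complete ones)
        keep &= (frac < threshold) | (frac == 0)
    survivors = study.values.columns[keep]
    return StudyMatrix(
        values=study.values[survivors].copy(),
        sample_meta=study.sample_meta,
        stage=study.stage,
        flags={m: f for m, f in study.flags.items() if m in set(survivors)},
    )


def log_impute_scale(study: StudyMatrix) -> StudyMatrix:
    """log10 transform, phase-median impute, auto-scale; patients only out.

    Missing cells are imputed with the per-metabolite median of the log10
    values among the *patient* samples of the cell's study phase (global
    patient median as fallback when a phase is entirely missing).  Each
    metabolite is then centred and scaled to unit standard deviation
    (ddof=1) across patient samples.  Reference and calibrant rows are
    dropped: downstream statistics and clustering operate on patients.

    Metabolites with zero variance after imputation are dropped with a
    warning.
    """
    if study.stage not in ("pool_normalized", "calibrated"):
        raise PreprocessError(
            f"log_impute_scale expects stage 'pool_normalized' or 'calibrated', got {study.stage!r}"
        )
    pat = study.patient_ids
    if len(pat) == 0:
        raise PreprocessError("study contains no patient samples")
    logv = np.log10(study.values.loc[pat])
    phases = study.sample_meta.loc[pat, "phase"]

    global_median = logv.median(axis=0, skipna=True)
    imputed = logv.copy()
    for phase, ids in phases.groupby(phases).groups.items():
        block = logv.loc[ids]
        med = block.median(axis=0, skipna=True).fillna(global_median)
        imputed.loc[ids] = block.fillna(med)

    mean = imputed.mean(axis=0)
    sd = imputed.std(axis=0, ddof=1)
    degenerate = ~(sd > 0) | sd.isna()
    if degenerate.any():
        dropped = list(imputed.columns[degenerate])
        warnings.warn(
            f"dropping {len(dropped)} zero-variance metabolite(s) after imputation: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
        imputed = imputed.loc[:, ~degenerate]
        mean, sd = mean[~degenerate], sd[~degenerate]
    scaled = (imputed - mean) / sd
    return study.advanced(scaled, "autoscaled", sample_meta=study.sample_meta.loc[pat])


def run_preprocess(
    study: StudyMatrix,
    calibrant_concentrations: pd.Series | None = None,
    threshold: float = 0.10,
) -> StudyMatrix:
    """Full preprocessing chain on a raw study matrix."""
    norm = pool_normalize(study)
    if calibrant_concentrations is not None and len(norm.rows_with_role("calibrant")) >= 2:
        panel = extract_calibrant_panel(norm, calibrant_concentrations)
        norm = calibrate(norm, panel)
    filtered = filter_missing(norm, threshold=threshold)
    return log_impute_scale(filtered)
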