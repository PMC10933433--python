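"""QC filtering, log10 + median normalization, and batch correction.

The processing order mirrors standard TMT practice: drop low-evidence,
decoy and contaminant protein groups; log-transform (base 10) and shift
each sample so its observed median matches the grand median; then remove
additive per-batch offsets estimated by per-protein least squares with the
treatment/time covariates protected, so treatment structure cannot be
absorbed into the batch estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .quant_io import ProteinQuantTable, validate_design


@dataclass
class NormalizedMatrix:
    """Log-scale proteins x samples matrix with an append-only provenance."""

    values: pd.DataFrame  # NaN = missing
    log_base: int = 10
    provenance: tuple = ()

    def with_step(self, values: pd.DataFrame, step: str,
                  log_base: Optional[int] = None) -> "NormalizedMatrix":
        return NormalizedMatrix(
            values=values,
            log_base=self.log_base if log_base is None else log_base,
            provenance=self.provenance + (step,),
        )


def qc_filter(table: ProteinQuantTable, min_razor: int = 3):
    """Remove proteins with fewer than ``min_razor`` unique+razor peptides
    and all reverse-decoy / potential-contaminant rows.

    Returns ``(filtered_table, tally)``; the tally counts removals by reason
    (a row can hit several reasons) plus the total removed.
    """
    low = table.meta["n_unique_razor_peptides"] < min_razor
    rev = table.meta["is_reverse"].astype(bool)
    con = table.meta["is_contaminant"].astype(bool)
    drop = low | rev | con
    tally = {
        "low_peptides": int(low.sum()),
        "reverse": int(rev.sum()),
        "contaminant": int(con.sum()),
        "removed": int(drop.sum()),
        "kept": int((~drop).sum()),
    }
    keep = ~drop
    filtered = ProteinQuantTable(
        meta=table.meta.loc[keep].copy(),
        intensities=table.intensities.loc[keep].copy(),
        scale_tag=table.scale_tag,
    )
    return filtered, tally


def log_median_normalize(table: ProteinQuantTable) -> NormalizedMatrix:
    """log10-transform raw intensities and equalise sample medians.

    Each sample is shifted so that its median over observed values equals
    the grand target, defined as the median of the pre-shift sample medians.
    """
    if table.scale_tag != "raw":
        raise ConfigError(f"expected raw-scale table, got '{table.scale_tag}'")
    intens = table.intensities
    bad = (intens <= 0)
    if bad.any().any():
        prot = bad.any(axis=1).idxmax()
        samp = bad.loc[prot].idxmax()
        raise DataError(
            f"non-positive intensity for protein '{prot}' in sample '{samp}'"
        )
    logged = np.log10(intens)
    medians = logged.median(axis=0, skipna=True)
    target = float(np.median(medians.to_numpy()))
    shifted = logged.add(target - medians, axis=1)
    return NormalizedMatrix(
        values=shifted, log_base=10,
        provenance=("log10", "median_normalize"),
    )


def _design_dummies(design: pd.DataFrame, column: str) -> pd.DataFrame:
    """Treatment-style dummy coding with the design's first-listed level as
    reference (DMSO / Nascent in the standard layout)."""
    levels = list(dict.fromkeys(design[column]))
    return pd.DataFrame(
        {f"{column}[{lvl}]": (design[column] == lvl).astype(float)
         for lvl in levels[1:]},
        index=design.index,
    )


def batch_correct(matrix: NormalizedMatrix, design: pd.DataFrame,
                  protect_design: bool = True):
    """Subtract additive per-batch offsets estimated protein by protein.

    For each protein the observed values are regressed on batch indicators
    together with (by default) the treatment and time-point covariates, so
    condition effects are protected from absorption into the batch term;
    the estimated batch effects are re-centred to mean zero across batches
    before subtraction, leaving the grand level untouched.  Proteins for
    which the batch effect is inestimable (a batch entirely missing, or a
    collinear per-protein design) pass through unchanged and are reported.

    Returns ``(corrected_matrix, report)``.
    """
    design = validate_design(
        design,
        treatment_ref=next(iter(design["treatment"])),
        time_ref=next(iter(design["time_point"])),
    )
    design = design.set_index("sample_id").loc[list(matrix.values.columns)].reset_index()
    batch_levels = list(dict.fromkeys(design["batch"]))
    n_batches = len(batch_levels)
    report = {"skipped": [], "n_corrected": 0, "batch_levels": batch_levels}
    if n_batches < 2:
        return matrix.with_step(matrix.values.copy(), "batch_correct[identity]"), report

    covariates = [pd.Series(1.0, index=design.index, name="Intercept")]
    if protect_design:
        covariates.append(_design_dummies(design, "treatment"))
        covariates.append(_design_dummies(design, "time_point"))
    batch_dummies = pd.DataFrame(
        {f"batch[{lvl}]": (design["batch"] == lvl).astype(float)
         for lvl in batch_levels[1:]},
        index=design.index,
    )
    X = pd.concat(covariates + [batch_dummies], axis=1)
    batch_cols = [X.columns.get_loc(c) for c in batch_dummies.columns]
    Xn = X.to_numpy()
    batch_of_sample = design["batch"].to_numpy()

    values = matrix.values.to_numpy(copy=True)
    obs_all = ~np.isnan(values)
    batch_estimates = {}
    for i, protein in enumerate(matrix.values.index):
        obs = obs_all[i]
        present = set(batch_of_sample[obs])
        if len(present) < n_batches:
            report["skipped"].append((protein, "batch with no observed value"))
            continue
        Xi = Xn[obs]
        yi = values[i, obs]
        beta, _, rank, _ = np.linalg.lstsq(Xi, yi, rcond=None)
        if rank < Xi.shape[1]:
            report["skipped"].append((protein, "collinear design"))
            continue
        effects = np.concatenate([[0.0], beta[batch_cols]])  # ref batch = 0
        offsets = effects - effects.mean()
        offset_of = dict(zip(batch_levels, offsets))
        values[i] -= np.array([offset_of[b] for b in batch_of_sample])
        batch_estimates[protein] = offset_of
        report["n_corrected"] += 1
    report["batch_estimates"] = batch_estimates
    corrected = pd.DataFrame(values, index=matrix.values.index,
                             columns=matrix.values.columns)
    step = "batch_correct" if protect_design else "batch_correct[unprotected]"
    return matrix.with_step(corrected, step), report
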