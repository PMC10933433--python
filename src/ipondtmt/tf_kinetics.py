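"""Five-way kinetic classification of transcription factors.

TFs are classified from the Nascent-vs-mature (2 h chase) contrast in the
control arm: a positive log2FC means higher abundance on nascent than on
mature chromatin (transient gain of access behind the fork).  The fold-
change gate dominates: any TF with |log2FC| below the cut is "flat"
regardless of its FDR.  Category proportions carry Wilson score confidence
intervals.  "Flat" TFs that nevertheless respond to transcription
inhibition (significant under TPL and/or DRB in the full model) are flagged
separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import ValidationError
from .quant_io import GeneSet

CATEGORIES = ("sig_gain", "nonsig_gain", "flat", "nonsig_loss", "sig_loss")


@dataclass
class TFCategoryTable:
    per_tf: pd.DataFrame      # gene, log2fc, fdr, category
    summary: pd.DataFrame     # category, count, proportion, ci_low, ci_high
    unquantified: list


def _category(log2fc: float, fdr: float, fc_cut: float, fdr_cut: float) -> str:
    if abs(log2fc) < fc_cut:
        return "flat"
    if log2fc >= fc_cut:
        return "sig_gain" if fdr <= fdr_cut else "nonsig_gain"
    return "sig_loss" if fdr <= fdr_cut else "nonsig_loss"


def proportion_ci(k: int, n: int, level: float = 0.95,
                  method: str = "wilson"):
    """Point estimate and confidence interval for a proportion k/n.

    Wilson score interval by default; Wald available for comparison.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValidationError("k must lie in [0, n]")
    if method not in ("wilson", "wald"):
        raise ValidationError(f"unknown CI method '{method}'")
    low, high = proportion_confint(k, n, alpha=1.0 - level,
                                   method="wilson" if method == "wilson" else "normal")
    point = k / n
    # guard against tiny float residue at the k=0 / k=n boundaries
    low = min(max(float(low), 0.0), point)
    high = max(min(float(high), 1.0), point)
    return point, low, high


def categorize_tfs(results: pd.DataFrame, tf_set: GeneSet,
                   fc_cut: float = 0.5, fdr_cut: float = 0.05,
                   key_of_protein: Optional[Mapping[str, str]] = None,
                   ci_level: float = 0.95) -> TFCategoryTable:
    """Classify each quantified TF from one contrast's results.

    ``results`` needs columns protein_id, log2fc, fdr (one contrast only);
    ``key_of_protein`` maps protein ids to the gene-set matching key.  TFs
    absent from the results are listed as unquantified and excluded from
    the category denominators.
    """
    if results["contrast"].nunique() > 1:
        raise ValidationError("results must be restricted to a single contrast")
    key_of_protein = key_of_protein or {}
    res = results.copy()
    res["gene"] = [key_of_protein.get(p, p) for p in res["protein_id"]]
    res = res[res["gene"].isin(tf_set.members)]
    unquantified = sorted(set(tf_set.members) - set(res["gene"]))

    per_tf = pd.DataFrame({
        "gene": res["gene"].to_numpy(),
        "log2fc": res["log2fc"].to_numpy(),
        "fdr": res["fdr"].to_numpy(),
    })
    per_tf["category"] = [
        _category(fc, q, fc_cut, fdr_cut)
        for fc, q in zip(per_tf["log2fc"], per_tf["fdr"])
    ]
    per_tf = per_tf.sort_values("gene").reset_index(drop=True)

    n = len(per_tf)
    rows = []
    for cat in CATEGORIES:
        k = int((per_tf["category"] == cat).sum())
        if n:
            point, low, high = proportion_ci(k, n, level=ci_level)
        else:
            point = low = high = np.nan
        rows.append({"category": cat, "count": k, "proportion": point,
                     "ci_low": low, "ci_high": high})
    summary = pd.DataFrame(rows)
    return TFCategoryTable(per_tf=per_tf, summary=summary,
                           unquantified=unquantified)


def flag_treatment_dependent_tfs(categories: TFCategoryTable,
                                 results_by_treatment: Mapping[str, pd.DataFrame],
                                 key_of_protein: Optional[Mapping[str, str]] = None,
                                 wce_significant: Optional[set] = None) -> pd.DataFrame:
    """Flag 'flat' TFs that respond to transcription inhibition.

    ``results_by_treatment`` maps treatment contrast labels (e.g. TPL, DRB)
    to significance-called result tables from the full model.  The output
    has one row per flat TF with flag in {TPL_only, DRB_only, both, neither}
    (generalised to the provided labels) and a boolean marking significance
    in the whole-cell extract, when supplied.
    """
    key_of_protein = key_of_protein or {}
    flat = categories.per_tf.loc[categories.per_tf["category"] == "flat", "gene"]
    sig_sets = {}
    for label, res in results_by_treatment.items():
        sig = res.loc[res["significant"], "protein_id"]
        sig_sets[label] = {key_of_protein.get(p, p) for p in sig}
    labels = list(results_by_treatment)
    rows = []
    for gene in flat:
        hits = [lab for lab in labels if gene in sig_sets[lab]]
        if not hits:
            flag = "neither"
        elif len(hits) == len(labels) and len(labels) > 1:
            flag = "both"
        else:
            flag = "_".join(hits) + "_only"
        row = {"gene": gene, "flag": flag}
        for lab in labels:
            row[f"sig_{lab}"] = gene in sig_sets[lab]
        if wce_significant is not None:
            row["wce_significant"] = gene in wce_significant
        rows.append(row)
    return pd.DataFrame(rows)
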