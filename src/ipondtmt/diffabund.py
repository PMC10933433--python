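"""Per-protein linear models with empirical-Bayes moderated t-statistics.

Each protein's log2 abundance is modelled additively as
``~ treatment + time_point`` (no interaction) on its observed samples only.
Residual variances are shrunk towards a pooled prior estimated by
moment-matching the log sample variances against a scaled-F model: if the
true variances follow a scaled inverse-chi-square prior with d0 degrees of
freedom and scale s0^2, then ``log s^2_g`` has known digamma/trigamma
moments, which yields closed-form estimates of (d0, s0^2) and the posterior
variances ``s~^2_g = (d0 s0^2 + df_g s^2_g) / (d0 + df_g)``.  The moderated
t uses ``d0 + df_g`` degrees of freedom.

Also here: BH-FDR adjustment, the fold-change/FDR significance call used for
volcano plots, per-protein mean-centred fold-change matrices for heatmaps,
and complete-linkage hierarchical clustering of those rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.special import digamma, polygamma

from .errors import ConfigError, ValidationError
from .preprocess import NormalizedMatrix, _design_dummies
from .quant_io import validate_design

LOG2_10 = np.log2(10.0)


@dataclass
class EBayesPrior:
    """Scaled inverse-chi-square variance prior: d0 may be +inf (all
    variances shrunk to the common scale s0sq)."""

    d0: float
    s0sq: float

    def __post_init__(self):
        if self.s0sq <= 0:
            raise ValidationError("s0sq must be positive")
        if not (self.d0 > 0):
            raise ValidationError("d0 must be positive (or +inf)")


@dataclass
class LinearFit:
    """Per-protein least-squares fits of the additive model."""

    terms: list
    coef: pd.DataFrame            # proteins x terms (NaN when skipped)
    cov_unit: np.ndarray          # (n_proteins, p, p) unit-variance covariance
    s2: pd.Series                 # residual variance (log2 units)
    df: pd.Series                 # residual degrees of freedom
    n_obs: pd.Series
    skipped: dict                 # protein -> reason
    treatment_levels: list
    time_levels: list


def fit_linear_models(matrix: NormalizedMatrix, design: pd.DataFrame,
                      min_obs_per_level: int = 1) -> LinearFit:
    """Fit ``~ treatment + time_point`` per protein on observed samples.

    Input log10 matrices are converted to log2 (multiplying by log2(10)),
    so coefficients are log2 fold changes against the reference levels.
    Proteins with residual df < 1, a rank-deficient per-protein design, or
    fewer than ``min_obs_per_level`` observations at some factor level are
    skipped and reported.
    """
    design = validate_design(
        design,
        treatment_ref=next(iter(design["treatment"])),
        time_ref=next(iter(design["time_point"])),
    )
    design = design.set_index("sample_id").loc[list(matrix.values.columns)].reset_index()
    values = matrix.values.to_numpy(copy=True)
    if matrix.log_base == 10:
        values = values * LOG2_10
    elif matrix.log_base != 2:
        raise ConfigError(f"unsupported log base {matrix.log_base}")

    treat_d = _design_dummies(design, "treatment")
    time_d = _design_dummies(design, "time_point")
    X = pd.concat(
        [pd.Series(1.0, index=design.index, name="Intercept"), treat_d, time_d],
        axis=1,
    )
    terms = list(X.columns)
    Xn = X.to_numpy()
    p = Xn.shape[1]
    treatment_levels = list(dict.fromkeys(design["treatment"]))
    time_levels = list(dict.fromkeys(design["time_point"]))
    level_masks = [
        (design["treatment"] == lvl).to_numpy() for lvl in treatment_levels
    ] + [(design["time_point"] == lvl).to_numpy() for lvl in time_levels]

    n_prot = values.shape[0]
    coef = np.full((n_prot, p), np.nan)
    cov_unit = np.full((n_prot, p, p), np.nan)
    s2 = np.full(n_prot, np.nan)
    df = np.full(n_prot, np.nan)
    n_obs = np.zeros(n_prot, dtype=int)
    skipped = {}

    for i, protein in enumerate(matrix.values.index):
        obs = ~np.isnan(values[i])
        n_obs[i] = int(obs.sum())
        if any(int((obs & m).sum()) < min_obs_per_level for m in level_masks):
            skipped[protein] = "too few observations at a factor level"
            continue
        Xi = Xn[obs]
        yi = values[i, obs]
        rank = np.linalg.matrix_rank(Xi)
        if rank < p:
            skipped[protein] = "rank-deficient design"
            continue
        if n_obs[i] - p < 1:
            skipped[protein] = "residual df < 1"
            continue
        XtX = Xi.T @ Xi
        XtX_inv = np.linalg.inv(XtX)
        beta = XtX_inv @ (Xi.T @ yi)
        resid = yi - Xi @ beta
        dfi = n_obs[i] - p
        coef[i] = beta
        cov_unit[i] = XtX_inv
        s2[i] = float(resid @ resid) / dfi
        df[i] = dfi

    index = matrix.values.index
    return LinearFit(
        terms=terms,
        coef=pd.DataFrame(coef, index=index, columns=terms),
        cov_unit=cov_unit,
        s2=pd.Series(s2, index=index, name="s2"),
        df=pd.Series(df, index=index, name="df"),
        n_obs=pd.Series(n_obs, index=index, name="n_obs"),
        skipped=skipped,
        treatment_levels=treatment_levels,
        time_levels=time_levels,
    )


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x by Newton iteration on 1/trigamma (monotone)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_prior(s2: Sequence[float], df: Sequence[float]) -> EBayesPrior:
    """Estimate (d0, s0sq) by matching digamma/trigamma moments of log s^2.

    With z_g = log s^2_g and e_g = z_g - digamma(df_g/2) + log(df_g/2), the
    scaled-F model implies E e_g = log s0^2 + digamma(d0/2) - log(d0/2) and
    Var e_g = trigamma(d0/2) + trigamma(df_g/2).  If the observed spread of
    e is no larger than the sampling component, the prior is a point mass
    (d0 = +inf) at the geometric-mean variance.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & np.isfinite(df) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if len(s2) < 10:
        raise ValidationError("need >=10 positive-variance proteins to fit the prior")
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0sq = np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0sq = float(np.exp(z.mean()))  # geometric mean: equals the common s2
    return EBayesPrior(d0=float(d0), s0sq=float(s0sq))


def ebayes_moderate(s2: pd.Series, df: pd.Series,
                    prior: Optional[EBayesPrior] = None):
    """Shrink residual variances towards the (estimated) prior scale.

    Returns ``(prior, s2_post)`` with
    ``s2_post = (d0*s0sq + df*s2) / (d0 + df)``; ``d0 = +inf`` collapses all
    variances onto s0sq, and ``d0 -> 0`` leaves them untouched.
    """
    if prior is None:
        prior = estimate_prior(s2.to_numpy(), df.to_numpy())
    d0, s0sq = prior.d0, prior.s0sq
    if np.isinf(d0):
        s2_post = pd.Series(np.where(np.isfinite(s2), s0sq, np.nan),
                            index=s2.index, name="s2_post")
    else:
        s2_post = (d0 * s0sq + df * s2) / (d0 + df)
        s2_post.name = "s2_post"
    return prior, s2_post


def _contrast_vector(fit: LinearFit, contrast: str) -> np.ndarray:
    """Map a label like 'TPL-vs-DMSO' or 'Nascent-vs-2h' onto the terms."""
    try:
        a, b = contrast.split("-vs-")
    except ValueError as err:
        raise ConfigError(f"contrast '{contrast}' is not of the form A-vs-B") from err
    for factor, levels in (("treatment", fit.treatment_levels),
                           ("time_point", fit.time_levels)):
        if a in levels and b in levels:
            c = np.zeros(len(fit.terms))
            for lvl, sign in ((a, 1.0), (b, -1.0)):
                term = f"{factor}[{lvl}]"
                if term in fit.terms:  # reference level contributes 0
                    c[fit.terms.index(term)] = sign
            return c
    raise ConfigError(f"contrast '{contrast}' does not match one design factor")


def moderated_contrasts(fit: LinearFit, prior: EBayesPrior, s2_post: pd.Series,
                        contrasts: Sequence[str],
                        fdr_cut: float = 0.05, fc_cut: float = 0.5) -> pd.DataFrame:
    """Moderated t-test for each protein and contrast.

    p-values are two-sided on ``d0 + df_g`` degrees of freedom and BH-
    adjusted within each contrast; ``significant`` applies the volcano rule
    (FDR <= fdr_cut and |log2fc| >= fc_cut).
    """
    frames = []
    coef = fit.coef.to_numpy()
    for contrast in contrasts:
        c = _contrast_vector(fit, contrast)
        log2fc = coef @ c
        se_unit = np.sqrt(np.einsum("i,gij,j->g", c, fit.cov_unit, c))
        se = se_unit * np.sqrt(s2_post.to_numpy())
        with np.errstate(divide="ignore", invalid="ignore"):
            t_mod = log2fc / se
        df_total = prior.d0 + fit.df.to_numpy()
        df_total = np.where(np.isfinite(df_total), df_total, 1e12)
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
        ok = np.isfinite(p)
        fdr = np.full_like(p, np.nan)
        if ok.any():
            fdr[ok] = bh_adjust(p[ok])
        frames.append(pd.DataFrame({
            "protein_id": fit.coef.index,
            "contrast": contrast,
            "log2fc": log2fc,
            "t_mod": t_mod,
            "p": p,
            "fdr": fdr,
            "n_obs": fit.n_obs.to_numpy(),
        }))
    results = pd.concat(frames, ignore_index=True)
    results = results[np.isfinite(results["p"])].reset_index(drop=True)
    return call_significant(results, fdr_cut=fdr_cut, fc_cut=fc_cut)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Literal step-up: sort, scale p_(i) by n/i, take the running minimum
    from the largest rank down, cap at 1, restore the input order.
    Ties are preserved (stable sort + running minimum)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def call_significant(results: pd.DataFrame, fdr_cut: float = 0.05,
                     fc_cut: float = 0.5) -> pd.DataFrame:
    """Volcano significance call: FDR <= fdr_cut and |log2fc| >= fc_cut."""
    out = results.copy()
    out["significant"] = (out["fdr"] <= fdr_cut) & (out["log2fc"].abs() >= fc_cut)
    return out


def significance_partition(res_a: pd.DataFrame, res_b: pd.DataFrame) -> dict:
    """Three-way partition of significant proteins for two contrasts
    (A-only / B-only / both) plus the union count."""
    sig_a = set(res_a.loc[res_a["significant"], "protein_id"])
    sig_b = set(res_b.loc[res_b["significant"], "protein_id"])
    both = sig_a & sig_b
    return {
        "a_only": len(sig_a - sig_b),
        "b_only": len(sig_b - sig_a),
        "both": len(both),
        "union": len(sig_a | sig_b),
    }


def compare_significant_sets(res_a: pd.DataFrame, res_b: pd.DataFrame,
                             direction: str = "down") -> dict:
    """Overlap of depleted (or enriched) significant proteins between two
    analyses, e.g. replicated chromatin vs whole-cell extract."""
    sign = -1.0 if direction == "down" else 1.0

    def picked(res):
        mask = res["significant"] & (sign * res["log2fc"] > 0)
        return set(res.loc[mask, "protein_id"])

    a, b = picked(res_a), picked(res_b)
    return {"n_a": len(a), "n_b": len(b), "intersection": len(a & b),
            "proteins": sorted(a & b)}


def condition_means(matrix: NormalizedMatrix, design: pd.DataFrame,
                    to_log2: bool = True) -> pd.DataFrame:
    """Mean log abundance per (treatment, time_point) cell over observed
    replicates; columns labelled ``treatment:time_point``."""
    design = validate_design(
        design,
        treatment_ref=next(iter(design["treatment"])),
        time_ref=next(iter(design["time_point"])),
    ).set_index("sample_id").loc[list(matrix.values.columns)]
    factor = np.log2(10.0) if (to_log2 and matrix.log_base == 10) else 1.0
    values = matrix.values * factor
    labels = design["treatment"] + ":" + design["time_point"]
    cells = list(dict.fromkeys(labels))
    out = pd.DataFrame(index=values.index, columns=cells, dtype=float)
    for cell in cells:
        cols = labels.index[labels == cell]
        out[cell] = values[cols].mean(axis=1, skipna=True)
    return out


def center_per_protein(means: pd.DataFrame) -> pd.DataFrame:
    """Subtract each protein's row mean: values become log fold changes with
    respect to the protein mean (the heatmap quantity)."""
    return means.sub(means.mean(axis=1), axis=0)


@dataclass
class ClusterResult:
    linkage: Optional[np.ndarray]
    order: list
    newick: str


def _tree_to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _tree_to_newick(node.get_left(), labels)
    right = _tree_to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_rows(fc: pd.DataFrame) -> ClusterResult:
    """Complete-linkage hierarchical clustering (Euclidean) of the rows of a
    mean-centred fold-change matrix; deterministic for a given row order."""
    labels = list(fc.index)
    if fc.isna().any().any():
        raise ConfigError("fold-change matrix has missing entries")
    if len(labels) < 2:
        return ClusterResult(linkage=None, order=labels,
                             newick=(labels[0] + ";") if labels else ";")
    Z = hierarchy.linkage(fc.to_numpy(), method="complete", metric="euclidean")
    tree = hierarchy.to_tree(Z)
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(linkage=Z, order=order,
                         newick=_tree_to_newick(tree, labels) + ";")
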