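"""Histone-PTM relative abundance from peptide areas.

Within one sample, the summed area of all modified forms of a histone
peptide is taken as 100% and each form's area is expressed as a percentage
of that total.  Isobaric form pairs (same precursor mass) are apportioned
beforehand from distinguishing fragment ions: the species-A share of each
ion's area is averaged over ions, and the parent area split by that ratio.
Time-course changes are tested with classical paired t-tests, pairing by
biological replicate.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ValidationError


def relative_abundance(table: pd.DataFrame):
    """Convert per-form areas into percentages per (peptide_key, sample).

    Returns ``(rel, report)``: ``rel`` is the input plus a ``percent``
    column; groups whose areas are all zero get missing percents and are
    listed in the report.
    """
    if (table["area"] < 0).any():
        raise DataError("areas must be non-negative")
    rel = table.copy()
    totals = rel.groupby(["peptide_key", "sample_id"])["area"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        rel["percent"] = 100.0 * rel["area"] / totals
    rel.loc[totals == 0, "percent"] = np.nan
    report = sorted(
        set(map(tuple, rel.loc[totals == 0, ["peptide_key", "sample_id"]]
                .itertuples(index=False, name=None)))
    )
    return rel, report


def split_isobaric(fragment_ions: pd.DataFrame):
    """Relative ratio of two isobaric forms from distinguishing fragments.

    ``fragment_ions`` needs columns ``species_a_area`` and
    ``species_b_area``, one row per distinguishing ion; per ion the species-A
    share a/(a+b) is computed and the shares are averaged over ions.
    Returns ``(ratio_a, ratio_b)`` with ratio_b = 1 - ratio_a.
    """
    a = fragment_ions["species_a_area"].to_numpy(dtype=float)
    b = fragment_ions["species_b_area"].to_numpy(dtype=float)
    total = a + b
    usable = total > 0
    if not usable.any():
        raise DataError("no distinguishing fragment ion with positive area")
    ratios = a[usable] / total[usable]
    ratio_a = float(ratios.mean())
    return ratio_a, 1.0 - ratio_a


def apportion_isobaric(table: pd.DataFrame, pairs) -> pd.DataFrame:
    """Split combined isobaric rows into their two forms before the 100%
    normalization.

    ``pairs`` is a sequence of dicts with keys ``peptide_key``,
    ``combined_form``, ``form_a``, ``form_b`` and ``fragment_ions`` (a
    DataFrame as for :func:`split_isobaric`, optionally per sample via a
    ``sample_id`` column).  Pairs without usable ions are left unsplit and
    flagged in ``result.attrs['unsplit']``; split rows conserve the parent
    area exactly.
    """
    out = table.copy()
    unsplit = []
    new_rows = []
    drop_idx = []
    for pair in pairs:
        mask = ((out["peptide_key"] == pair["peptide_key"])
                & (out["form"] == pair["combined_form"]))
        for idx, row in out[mask].iterrows():
            ions = pair["fragment_ions"]
            if "sample_id" in ions.columns:
                ions = ions[ions["sample_id"] == row["sample_id"]]
            try:
                ratio_a, ratio_b = split_isobaric(ions)
            except DataError:
                unsplit.append((pair["peptide_key"], pair["combined_form"],
                                row["sample_id"]))
                continue
            for form, ratio in ((pair["form_a"], ratio_a),
                                (pair["form_b"], ratio_b)):
                split_row = row.copy()
                split_row["form"] = form
                split_row["area"] = row["area"] * ratio
                new_rows.append(split_row)
            drop_idx.append(idx)
    if drop_idx:
        out = out.drop(index=drop_idx)
    if new_rows:
        out = pd.concat([out, pd.DataFrame(new_rows)], ignore_index=True)
    out = out.reset_index(drop=True)
    out.attrs["unsplit"] = unsplit
    return out


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def compare_timecourse(rel: pd.DataFrame, mode: str = "time_within_treatment",
                       ref: Optional[str] = None) -> pd.DataFrame:
    """Paired t-tests on relative abundances, pairing by replicate.

    ``mode="time_within_treatment"`` compares each time point against the
    reference time point (default: first in order of appearance) within
    each treatment; ``mode="treatment_within_time"`` compares each
    treatment against the reference treatment (default DMSO) at each time
    point.  Comparisons with fewer than two complete pairs, or with all
    paired differences exactly zero, are reported but not tested.
    """
    if mode == "time_within_treatment":
        group_col, compare_col = "treatment", "time_point"
    elif mode == "treatment_within_time":
        group_col, compare_col = "time_point", "treatment"
    else:
        raise ValidationError(f"unknown mode '{mode}'")
    levels = list(dict.fromkeys(rel[compare_col]))
    if ref is None:
        ref = "DMSO" if (compare_col == "treatment" and "DMSO" in levels) else levels[0]
    if ref not in levels:
        raise ValidationError(f"reference level '{ref}' absent")

    rows = []
    grouped = rel.groupby(["peptide_key", "form", group_col], sort=True)
    for (pk, form, grp), sub in grouped:
        by_level = {
            lvl: lsub.set_index("replicate")["percent"]
            for lvl, lsub in sub.groupby(compare_col)
        }
        if ref not in by_level:
            continue
        base = by_level[ref]
        for lvl in levels:
            if lvl == ref or lvl not in by_level:
                continue
            other = by_level[lvl]
            common = base.index.intersection(other.index)
            x = other.loc[common].to_numpy(dtype=float)
            y = base.loc[common].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            row = {
                "peptide_key": pk, "form": form, group_col: grp,
                "comparison": f"{lvl}-vs-{ref}", "n_pairs": len(x),
                "mean_ref": float(np.mean(y)) if len(y) else np.nan,
                "mean_other": float(np.mean(x)) if len(x) else np.nan,
                "sem_ref": float(stats.sem(y)) if len(y) > 1 else np.nan,
                "sem_other": float(stats.sem(x)) if len(x) > 1 else np.nan,
            }
            if len(x) < 2:
                row.update(t=np.nan, p=np.nan, stars="", note="fewer than 2 pairs")
            else:
                d = x - y
                if np.all(d == 0.0):
                    row.update(t=np.nan, p=np.nan, stars="",
                               note="degenerate: all paired differences zero")
                else:
                    t, p = stats.ttest_rel(x, y)
                    row.update(t=float(t), p=float(p), stars=_stars(float(p)),
                               note="")
            rows.append(row)
    return pd.DataFrame(rows)
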