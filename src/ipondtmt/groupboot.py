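"""Bootstrap gene-set depletion test.

For a gene set of size k with observed mean log2 fold change m, draw B
random sets of k distinct proteins uniformly from the full quantified
universe (set members included), compute each null mean, and report the
lower-tail empirical p: the proportion of null means strictly lower than m.
By default B = 100,000 and the strict proportion is used, so p = 0 is
representable; a (count+1)/(B+1) rule is available for reporting.  BH-FDR
is applied across the set x contrast grid of one panel (stratum).

The random subset indices depend only on (universe size, set size, seed),
never on the fold-change values; shifting a set's members down at a fixed
seed therefore can only decrease the p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .diffabund import bh_adjust
from .quant_io import GeneSet


@dataclass
class GroupTestResult:
    set_name: str
    contrast: str
    n_members_used: int
    n_members_dropped: int
    observed_mean_log2fc: float
    B: int
    p_lower: float
    p: float
    tail: str
    null_mean: float
    null_sd: float
    fdr: Optional[float] = None


def _sample_subset_indices(rng: np.random.Generator, n: int, k: int, B: int,
                           chunk: int = 20000) -> np.ndarray:
    """B uniform random k-subsets of range(n), as a (B, k) index array.

    Uses vectorised rejection (draw k iid indices, redraw rows containing a
    duplicate) when collisions are rare, else per-row partial argsort of
    random keys.  Both are exact uniform samplers over subsets.
    """
    if k > n:
        raise ValidationError(f"cannot draw {k} distinct items from {n}")
    if k * k > n:  # collisions likely: partial sort of random keys
        out = np.empty((B, k), dtype=np.int64)
        for start in range(0, B, chunk):
            stop = min(start + chunk, B)
            keys = rng.random((stop - start, n))
            out[start:stop] = np.argpartition(keys, k - 1, axis=1)[:, :k]
        return out
    idx = rng.integers(0, n, size=(B, k))
    while True:
        srt = np.sort(idx, axis=1)
        bad = (np.diff(srt, axis=1) == 0).any(axis=1)
        if not bad.any():
            return idx
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), k))


def group_depletion_test(fc: pd.Series, gene_set: GeneSet, B: int = 100000,
                         seed: Optional[int] = None,
                         rng: Optional[np.random.Generator] = None,
                         p_rule: str = "strict_lower",
                         tail: str = "lower",
                         replace: bool = False,
                         contrast: str = "") -> GroupTestResult:
    """Empirical p for the mean log2FC of one gene set against size-matched
    random sets drawn from all quantified proteins.

    ``fc`` is indexed by the gene-set matching key (gene name, protein id
    fallback); members absent from the index are dropped and counted.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    if p_rule not in ("strict_lower", "plus_one"):
        raise ValidationError(f"unknown p_rule '{p_rule}'")
    if tail not in ("lower", "upper", "two_sided"):
        raise ValidationError(f"unknown tail '{tail}'")
    universe = fc.dropna()
    n = len(universe)
    used = sorted(set(gene_set.members) & set(universe.index))
    dropped = len(gene_set.members) - len(used)
    if not used:
        raise ConfigError(f"set '{gene_set.name}': no member in the universe")
    k = len(used)
    observed = float(universe.loc[used].mean())

    values = universe.to_numpy()
    if rng is None:
        rng = np.random.default_rng(seed)
    if replace:
        idx = rng.integers(0, n, size=(B, k))
    elif k == n:
        idx = np.tile(np.arange(n), (B, 1))
    else:
        idx = _sample_subset_indices(rng, n, k, B)
    null_means = values[idx].mean(axis=1)

    n_lower = int((null_means < observed).sum())
    n_upper = int((null_means > observed).sum())
    if p_rule == "strict_lower":
        p_lower = n_lower / B
        p_upper = n_upper / B
    else:
        p_lower = (n_lower + 1) / (B + 1)
        p_upper = (n_upper + 1) / (B + 1)
    p = {"lower": p_lower, "upper": p_upper,
         "two_sided": min(1.0, 2.0 * min(p_lower, p_upper))}[tail]
    return GroupTestResult(
        set_name=gene_set.name,
        contrast=contrast,
        n_members_used=k,
        n_members_dropped=dropped,
        observed_mean_log2fc=observed,
        B=B,
        p_lower=p_lower,
        p=p,
        tail=tail,
        null_mean=float(null_means.mean()),
        null_sd=float(null_means.std(ddof=1)) if B > 1 else 0.0,
    )


def run_group_suite(fc_by_contrast: Mapping[str, pd.Series],
                    sets: Sequence[GeneSet], B: int = 100000, seed: int = 0,
                    p_rule: str = "strict_lower", tail: str = "lower",
                    fdr_cut: float = 0.05) -> pd.DataFrame:
    """Run the depletion test over a set x contrast grid (one panel) and
    BH-adjust the p-values across the whole grid.

    Per-test generators are spawned from one seed sequence in fixed
    iteration order, so the suite is deterministic and each test gets an
    independent stream.  Sets with no usable member are skipped and listed
    in the ``skipped`` attribute of the returned frame.
    """
    ss = np.random.SeedSequence(seed)
    n_tests = len(sets) * len(fc_by_contrast)
    children = ss.spawn(n_tests)
    rows, skipped = [], []
    i = 0
    for gene_set in sets:
        for contrast, fc in fc_by_contrast.items():
            child = children[i]
            i += 1
            try:
                res = group_depletion_test(
                    fc, gene_set, B=B, rng=np.random.default_rng(child),
                    p_rule=p_rule, tail=tail, contrast=contrast,
                )
            except ConfigError as err:
                skipped.append((gene_set.name, contrast, str(err)))
                continue
            rows.append(asdict(res))
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["fdr"] < fdr_cut
    table.attrs["skipped"] = skipped
    return table


def run_group_suites(strata: Mapping[str, Mapping[str, pd.Series]],
                     sets: Sequence[GeneSet], B: int = 100000, seed: int = 0,
                     pool: str = "panel", **kwargs) -> pd.DataFrame:
    """Run the suite for several strata (e.g. replicated chromatin,
    steady-state chromatin, whole-cell lysate).

    ``pool="panel"`` (default) applies BH within each stratum's grid;
    ``pool="grid"`` re-adjusts across all strata together.
    """
    if pool not in ("panel", "grid"):
        raise ValidationError(f"unknown pooling mode '{pool}'")
    frames = []
    for j, (stratum, fc_by_contrast) in enumerate(strata.items()):
        table = run_group_suite(fc_by_contrast, sets, B=B, seed=seed + j, **kwargs)
        table.insert(0, "stratum", stratum)
        frames.append(table)
    out = pd.concat(frames, ignore_index=True)
    if pool == "grid" and len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["fdr"] < kwargs.get("fdr_cut", 0.05)
    return out
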