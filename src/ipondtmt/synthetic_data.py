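"""Synthetic TMT-like data with known planted structure.

Emulates an iPOND-TMT time course: three treatments (DMSO control and the
transcription inhibitors TPL and DRB) crossed with three chase time points
(Nascent, 1 h, 2 h) across replicate batches, one TMT channel per cell.
Protein baselines are log-normal on the raw-intensity scale, per-protein
residual variances follow a scaled inverse-chi-square prior (the model the
empirical-Bayes moderation downstream assumes), batches carry additive
offsets, and missingness is logistic in true intensity (missing-not-at-
random, as low-abundance proteins drop out first).  Treatment/time effects
are planted additively in log2 space into named gene sets, and everything
planted is recorded in a truth record so downstream estimates can be checked
against ground truth.

Decoy (reverse) and contaminant rows and sub-threshold razor-peptide counts
are included so the QC filter has something to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .quant_io import GeneSet, ProteinQuantTable, validate_design

LOG2_10 = np.log2(10.0)

_DEFAULT_BATCH_OFFSETS = (0.0, 0.35, -0.25, 0.15, 0.2, -0.1)


@dataclass
class SimConfig:
    """Study-design and noise parameters for the simulator.

    Intensity baselines are on the log10 scale (typical TMT reporter sums
    sit around 1e6); residual noise, batch offsets and planted effects are
    in log2 units, the scale on which fold changes are reported.
    """

    n_proteins: int = 3000
    treatments: Sequence[str] = ("DMSO", "TPL", "DRB")
    time_points: Sequence[str] = ("Nascent", "1h", "2h")
    n_batches: int = 4
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 0.8
    d0_true: float = 4.0
    s0sq_true: float = 0.04
    batch_offsets: Optional[Sequence[float]] = None
    sample_scale_log2: Optional[Mapping[str, float]] = None
    missing_rate_at_low: float = 0.12
    missing_rate_at_high: float = 0.01
    n_decoys: int = 100
    n_contaminants: int = 40
    frac_low_peptides: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be positive")
        if self.n_batches < 1:
            raise ConfigError("n_batches must be positive")
        for name in ("treatments", "time_points"):
            labels = list(getattr(self, name))
            if len(labels) != len(set(labels)):
                raise ConfigError(f"{name} labels must be unique")
        for name in ("missing_rate_at_low", "missing_rate_at_high",
                     "frac_low_peptides"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {v}")
        if self.d0_true <= 0 or self.s0sq_true <= 0:
            raise ConfigError("variance prior parameters must be positive")
        if self.n_decoys < 0 or self.n_contaminants < 0:
            raise ConfigError("decoy/contaminant counts must be non-negative")
        if self.batch_offsets is not None and len(self.batch_offsets) != self.n_batches:
            raise ConfigError("batch_offsets length must equal n_batches")

    def resolved_batch_offsets(self) -> np.ndarray:
        if self.batch_offsets is not None:
            return np.asarray(self.batch_offsets, dtype=float)
        reps = -(-self.n_batches // len(_DEFAULT_BATCH_OFFSETS))
        return np.asarray((_DEFAULT_BATCH_OFFSETS * reps)[: self.n_batches])


@dataclass(frozen=True)
class PlantedEffect:
    """An additive log2 shift applied to members of a named gene set at one
    level of one design factor."""

    set_name: str
    factor: str  # "treatment" or "time_point"
    level: str
    delta: float

    def __post_init__(self):
        if self.factor not in ("treatment", "time_point"):
            raise ConfigError(f"unknown factor '{self.factor}'")


def _make_design(config: SimConfig) -> pd.DataFrame:
    rows = []
    for t in config.treatments:
        for tp in config.time_points:
            for b in range(1, config.n_batches + 1):
                rows.append(
                    {
                        "sample_id": f"{t}_{tp}_b{b}",
                        "treatment": t,
                        "time_point": tp,
                        "batch": f"b{b}",
                    }
                )
    return validate_design(
        pd.DataFrame(rows),
        treatment_ref=config.treatments[0],
        time_ref=config.time_points[0],
    )


def _check_effects(config: SimConfig, effects: Sequence[PlantedEffect],
                   sets: Sequence[GeneSet], genes: Sequence[str]) -> None:
    set_by_name = {s.name: s for s in sets}
    universe = set(genes)
    for eff in effects:
        if eff.set_name not in set_by_name:
            raise ConfigError(f"planted effect references unknown set '{eff.set_name}'")
        levels = config.treatments if eff.factor == "treatment" else config.time_points
        if eff.level not in levels:
            raise ConfigError(
                f"planted effect level '{eff.level}' not a {eff.factor} level"
            )
        missing = set_by_name[eff.set_name].members - universe
        if missing:
            raise ConfigError(
                f"set '{eff.set_name}' has members outside the simulated "
                f"universe: {sorted(missing)[:5]}"
            )


def _missing_prob(true_log10: np.ndarray, config: SimConfig) -> np.ndarray:
    """Logistic missingness in true log10 intensity, anchored at +/-2 sd of
    the baseline distribution."""
    lo, hi = config.missing_rate_at_low, config.missing_rate_at_high
    if lo == hi:
        return np.full_like(true_log10, lo)
    eps = 1e-12
    logit = lambda p: np.log((p + eps) / (1 - p + eps))
    x_lo = config.baseline_log_mean - 2 * config.baseline_log_sd
    x_hi = config.baseline_log_mean + 2 * config.baseline_log_sd
    slope = (logit(hi) - logit(lo)) / (x_hi - x_lo)
    z = logit(lo) + slope * (true_log10 - x_lo)
    return 1.0 / (1.0 + np.exp(-z))


def simulate_dataset(config: SimConfig,
                     effects: Sequence[PlantedEffect] = (),
                     sets: Sequence[GeneSet] = ()):
    """Simulate a quantification table, its design, and a truth record.

    Returns ``(table, design, truth)`` where ``table`` is a raw-scale
    ProteinQuantTable (decoy and contaminant rows appended), ``design`` maps
    samples to treatment/time/batch, and ``truth`` records every planted
    delta, the per-protein residual variances, and the noise-free log2
    signal matrix.  The same (config, effects, sets) and seed reproduce the
    output bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(1, config.n_proteins + 1)]
    prot_ids = [f"P{i:05d}" for i in range(1, config.n_proteins + 1)]
    _check_effects(config, effects, sets, genes)
    design = _make_design(config)
    n_s = len(design)
    set_by_name = {s.name: s for s in sets}

    base10 = rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                        config.n_proteins)
    if np.isinf(config.d0_true):
        sigma2 = np.full(config.n_proteins, config.s0sq_true)
    else:
        sigma2 = (config.d0_true * config.s0sq_true
                  / rng.chisquare(config.d0_true, config.n_proteins))

    batch_offsets = config.resolved_batch_offsets()
    batch_levels = [f"b{b}" for b in range(1, config.n_batches + 1)]
    batch_of_sample = design["batch"].map(dict(zip(batch_levels, batch_offsets)))

    # noise-free signal in log2 units
    signal2 = np.tile((base10 * LOG2_10)[:, None], (1, n_s))
    signal2 += batch_of_sample.to_numpy()[None, :]
    if config.sample_scale_log2:
        scale = design["sample_id"].map(
            lambda s: config.sample_scale_log2.get(s, 0.0)
        )
        signal2 += scale.to_numpy()[None, :]

    gene_pos = {g: i for i, g in enumerate(genes)}
    for eff in effects:
        rows = [gene_pos[g] for g in sorted(set_by_name[eff.set_name].members)]
        cols = (design[eff.factor] == eff.level).to_numpy()
        signal2[np.ix_(rows, cols)] += eff.delta

    noise = rng.normal(0.0, 1.0, signal2.shape) * np.sqrt(sigma2)[:, None]
    y2 = signal2 + noise
    raw = np.power(2.0, y2)

    p_miss = _missing_prob(signal2 / LOG2_10, config)
    miss = rng.random(signal2.shape) < p_miss
    raw = np.where(miss, np.nan, raw)

    u = rng.random(config.n_proteins)
    razor = np.where(
        u < config.frac_low_peptides,
        rng.integers(1, 3, config.n_proteins),
        3 + rng.poisson(5.0, config.n_proteins),
    )

    meta = pd.DataFrame(
        {
            "gene_name": genes,
            "n_unique_razor_peptides": razor,
            "is_reverse": False,
            "is_contaminant": False,
        },
        index=pd.Index(prot_ids, name="protein_id"),
    )
    intens = pd.DataFrame(raw, index=meta.index, columns=design["sample_id"].tolist())

    extra_meta, extra_intens = [], []
    for kind, n_extra, prefix in (
        ("is_reverse", config.n_decoys, "REV__P"),
        ("is_contaminant", config.n_contaminants, "CON__P"),
    ):
        for j in range(n_extra):
            pid = f"{prefix}{j:04d}"
            row = {
                "gene_name": "",
                "n_unique_razor_peptides": int(rng.integers(1, 12)),
                "is_reverse": kind == "is_reverse",
                "is_contaminant": kind == "is_contaminant",
            }
            vals = np.power(
                10.0, rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_s)
            )
            extra_meta.append((pid, row))
            extra_intens.append(vals)
    if extra_meta:
        em = pd.DataFrame([r for _, r in extra_meta],
                          index=pd.Index([p for p, _ in extra_meta], name="protein_id"))
        ei = pd.DataFrame(np.vstack(extra_intens), index=em.index,
                          columns=intens.columns)
        meta = pd.concat([meta, em])
        intens = pd.concat([intens, ei])

    table = ProteinQuantTable(meta=meta, intensities=intens, scale_tag="raw")
    truth = {
        "effects": [
            {"set_name": e.set_name, "factor": e.factor, "level": e.level,
             "delta": float(e.delta)}
            for e in effects
        ],
        "sigma2_log2": pd.Series(sigma2, index=pd.Index(prot_ids, name="protein_id")),
        "baseline_log10": pd.Series(base10, index=pd.Index(prot_ids, name="protein_id")),
        "signal_log2": pd.DataFrame(signal2, index=pd.Index(prot_ids, name="protein_id"),
                                    columns=design["sample_id"].tolist()),
        "batch_offsets_log2": dict(zip(batch_levels, batch_offsets.tolist())),
        "gene_of_protein": dict(zip(prot_ids, genes)),
    }
    return table, design, truth


def default_gene_sets(config: SimConfig) -> list:
    """Carve disjoint functional sets out of the simulated gene universe:
    a replisome set, four remodeller families, six DNA-repair pathways and a
    TF list (with a pioneer subset and planted gain/loss kinetic subsets)."""
    genes = [f"G{i:05d}" for i in range(1, config.n_proteins + 1)]
    if len(genes) < 500:
        raise ConfigError("default gene sets need at least 500 simulated proteins")
    cursor = 0

    def take(n):
        nonlocal cursor
        block = genes[cursor:cursor + n]
        cursor += n
        return block

    sets = [GeneSet.of("replisome", take(30), "replisome")]
    for fam in ("SWI/SNF", "CHD", "ISWI", "INO80"):
        sets.append(GeneSet.of(fam, take(15), "remodeller_family"))
    for pw in ("HR", "NER", "MMR", "BER", "FA", "FQC"):
        sets.append(GeneSet.of(pw, take(20), "repair_pathway"))
    tf_genes = take(200)
    sets.append(GeneSet.of("TF_all", tf_genes, "TF"))
    sets.append(GeneSet.of("pioneer_TF", tf_genes[:34], "pioneer_TF"))
    sets.append(GeneSet.of("TF_gain", tf_genes[34:104], "TF"))
    sets.append(GeneSet.of("TF_loss", tf_genes[104:130], "TF"))
    return sets


def default_effects() -> list:
    """The planted scenario: replisome enriched on nascent chromatin (falls
    away during the chase), remodeller families and repair pathways depleted
    under transcription inhibition, and TF subsets with gain/loss kinetics."""
    effects = [
        PlantedEffect("replisome", "time_point", "1h", -0.7),
        PlantedEffect("replisome", "time_point", "2h", -1.1),
    ]
    for fam in ("SWI/SNF", "CHD", "ISWI", "INO80"):
        effects.append(PlantedEffect(fam, "treatment", "TPL", -0.5))
    effects.append(PlantedEffect("SWI/SNF", "treatment", "DRB", -0.35))
    for pw in ("HR", "NER", "MMR", "BER", "FA", "FQC"):
        effects.append(PlantedEffect(pw, "treatment", "TPL", -0.4))
    for pw in ("HR", "MMR", "FA", "FQC"):
        effects.append(PlantedEffect(pw, "treatment", "DRB", -0.3))
    # TF kinetics: gain = enriched on nascent relative to 2 h mature
    effects.append(PlantedEffect("TF_gain", "time_point", "2h", -0.8))
    effects.append(PlantedEffect("TF_loss", "time_point", "2h", 0.8))
    return effects


def simulate_ptm_table(proportions: Mapping[str, Mapping[str, float]],
                       n_replicates: int = 3,
                       noise_cv: float = 0.1,
                       seed: int = 0,
                       conditions: Sequence[tuple] = (("DMSO", "Nascent"),),
                       overrides: Optional[Mapping[tuple, Mapping[str, float]]] = None,
                       total_area: float = 1e8):
    """Simulate a histone-PTM area table with known form proportions.

    ``proportions`` maps peptide_key -> {form: proportion summing to 1};
    ``overrides`` optionally replaces the form proportions for a specific
    (peptide_key, treatment, time_point).  Areas are
    ``total_area * proportion * multiplicative log-normal noise`` whose
    coefficient of variation is ``noise_cv`` (mean 1, so noise_cv 0 recovers
    the planted proportions exactly).  Returns ``(table, truth)``.
    """
    rng = np.random.default_rng(seed)
    overrides = overrides or {}
    for pk, forms in proportions.items():
        total = sum(forms.values())
        if abs(total - 1.0) > 1e-8:
            raise ConfigError(f"proportions for '{pk}' sum to {total}, not 1")
    for key, forms in overrides.items():
        total = sum(forms.values())
        if abs(total - 1.0) > 1e-8:
            raise ConfigError(f"override proportions for {key} sum to {total}, not 1")

    sigma = np.sqrt(np.log1p(noise_cv ** 2)) if noise_cv > 0 else 0.0
    rows = []
    truth = {}
    for treatment, time_point in conditions:
        for rep in range(1, n_replicates + 1):
            sample_id = f"{treatment}_{time_point}_r{rep}"
            for pk in proportions:
                forms = overrides.get((pk, treatment, time_point), proportions[pk])
                truth[(pk, treatment, time_point)] = dict(forms)
                for form, prop in forms.items():
                    mult = (np.exp(rng.normal(-sigma ** 2 / 2.0, sigma))
                            if sigma > 0 else 1.0)
                    rows.append(
                        {
                            "histone": pk.split()[0],
                            "peptide_key": pk,
                            "form": form,
                            "area": total_area * prop * mult,
                            "sample_id": sample_id,
                            "replicate": f"r{rep}",
                            "treatment": treatment,
                            "time_point": time_point,
                        }
                    )
    return pd.DataFrame(rows), truth
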