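"""End-to-end orchestration: simulate (or load) -> preprocess -> differential
abundance -> gene-set bootstrap -> TF classification -> PTM analysis.

A run is described by a single config (YAML on disk or a dict): exactly one
of a simulation block or a set of input paths, plus thresholds and seeds.
Every stage writes its tables under the output directory and the run ends
with a machine-readable manifest (seeds, thresholds, per-stage row counts,
file list).  Re-running the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, PipelineError
from . import diffabund, groupboot, histone_ptm, preprocess, quant_io, synthetic_data
from . import tf_kinetics

DEFAULT_CONTRASTS = ("TPL-vs-DMSO", "DRB-vs-DMSO", "Nascent-vs-2h")


@dataclass
class RunConfig:
    out_dir: str
    simulate: Optional[dict] = None
    inputs: Optional[dict] = None  # protein_groups, design, gmt, ptm_areas
    min_razor: int = 3
    fdr_cut: float = 0.05
    fc_cut: float = 0.5
    B: int = 100000
    seed: int = 0
    contrasts: tuple = DEFAULT_CONTRASTS

    def __post_init__(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError(
                "config must contain exactly one of a 'simulate' block or 'inputs' paths"
            )
        if not (0 < self.fdr_cut <= 1):
            raise ConfigError("fdr_cut must be in (0, 1]")
        if self.B < 1 or self.min_razor < 0 or self.fc_cut < 0:
            raise ConfigError("invalid threshold configuration")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "contrasts" in raw:
            raw = dict(raw, contrasts=tuple(raw["contrasts"]))
        return cls(**raw)


def _stage(manifest: dict, name: str):
    class _Ctx:
        def __enter__(self):
            manifest["stages"].append({"name": name, "rows": {}, "files": []})
            return manifest["stages"][-1]

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_all(config: RunConfig) -> dict:
    """Run every stage and return (and write) the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "min_razor": config.min_razor,
            "fdr_cut": config.fdr_cut,
            "fc_cut": config.fc_cut,
            "B": config.B,
        },
        "contrasts": list(config.contrasts),
        "stages": [],
    }

    with _stage(manifest, "simulate") as st:
        if config.simulate is not None:
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed)
            sim_cfg = synthetic_data.SimConfig(**sim_kwargs)
            sets = synthetic_data.default_gene_sets(sim_cfg)
            effects = synthetic_data.default_effects()
            table, design, truth = synthetic_data.simulate_dataset(
                sim_cfg, effects, sets
            )
            pg_path = out_dir / "proteinGroups.txt"
            quant_io.write_protein_groups(table, pg_path)
            quant_io.write_design(design, out_dir / "design.csv")
            quant_io.write_gmt(sets, out_dir / "gene_sets.gmt")
            truth_out = {
                "effects": truth["effects"],
                "batch_offsets_log2": truth["batch_offsets_log2"],
            }
            with open(out_dir / "truth.yaml", "w") as fh:
                yaml.safe_dump(truth_out, fh, sort_keys=True)
            ptm_table, ptm_truth = synthetic_data.simulate_ptm_table(
                proportions={
                    "H3 27-40": {"K36un": 0.55, "K36me1": 0.2, "K36me2": 0.15,
                                 "K36me3": 0.1},
                    "H4 4-17": {"un": 0.6, "K16ac": 0.25, "K5acK12ac": 0.15},
                },
                n_replicates=3,
                noise_cv=0.08,
                seed=config.seed + 1,
                conditions=[(t, tp) for t in ("DMSO", "TPL", "DRB")
                            for tp in ("Nascent", "1h", "2h")],
            )
            ptm_table.to_csv(out_dir / "ptm_areas.csv", index=False,
                             float_format=quant_io.FLOAT_FORMAT)
            st["rows"]["proteins"] = len(table)
            st["files"] = ["proteinGroups.txt", "design.csv", "gene_sets.gmt",
                           "truth.yaml", "ptm_areas.csv"]
        else:
            paths = config.inputs
            design = quant_io.read_design(paths["design"])
            table = quant_io.read_protein_groups(paths["protein_groups"], design)
            sets = quant_io.read_gmt(paths["gmt"]) if paths.get("gmt") else []
            ptm_table = (quant_io.read_ptm_areas(paths["ptm_areas"])
                         if paths.get("ptm_areas") else None)
            st["rows"]["proteins"] = len(table)

    with _stage(manifest, "preprocess") as st:
        filtered, tally = preprocess.qc_filter(table, min_razor=config.min_razor)
        matrix = preprocess.log_median_normalize(filtered)
        matrix, batch_report = preprocess.batch_correct(matrix, design)
        st["rows"].update(tally)
        st["rows"]["batch_corrected"] = batch_report["n_corrected"]
        st["rows"]["batch_skipped"] = len(batch_report["skipped"])
        mat_out = matrix.values.reset_index()
        quant_io.write_results({"normalized_matrix": mat_out}, out_dir)
        st["files"] = ["normalized_matrix.tsv"]

    with _stage(manifest, "diffabund") as st:
        fit = diffabund.fit_linear_models(matrix, design)
        prior, s2_post = diffabund.ebayes_moderate(fit.s2, fit.df)
        results = diffabund.moderated_contrasts(
            fit, prior, s2_post, config.contrasts,
            fdr_cut=config.fdr_cut, fc_cut=config.fc_cut,
        )
        means = diffabund.condition_means(matrix, design)
        fc_matrix = diffabund.center_per_protein(means.dropna())
        clus = diffabund.cluster_rows(fc_matrix)
        quant_io.write_results(
            {"contrast_results": results,
             "foldchange_matrix": fc_matrix.reset_index()},
            out_dir,
        )
        (out_dir / "dendrogram.nwk").write_text(clus.newick + "\n")
        st["rows"]["tests"] = len(results)
        st["rows"]["significant"] = int(results["significant"].sum())
        st["rows"]["fitted"] = int(fit.df.notna().sum())
        st["ebayes_prior"] = {"d0": prior.d0 if prior.d0 != float("inf") else "inf",
                              "s0sq": prior.s0sq}
        st["files"] = ["contrast_results.tsv", "foldchange_matrix.tsv",
                       "dendrogram.nwk"]

    with _stage(manifest, "groupboot") as st:
        key_of_protein = dict(
            zip(filtered.meta.index, filtered.match_key())
        )
        boot_sets = [s for s in sets
                     if s.category in ("repair_pathway", "remodeller_family")]
        if boot_sets:
            fc_by_contrast = {}
            for contrast in config.contrasts:
                sub = results[results["contrast"] == contrast]
                fc = pd.Series(sub["log2fc"].to_numpy(),
                               index=[key_of_protein.get(p, p)
                                      for p in sub["protein_id"]])
                fc_by_contrast[contrast] = fc[~fc.index.duplicated()]
            boot = groupboot.run_group_suite(
                fc_by_contrast, boot_sets, B=config.B, seed=config.seed,
                fdr_cut=config.fdr_cut,
            )
            quant_io.write_results({"group_tests": boot}, out_dir)
            st["rows"]["tests"] = len(boot)
            st["rows"]["significant"] = int(boot["significant"].sum())
            st["files"] = ["group_tests.tsv"]
        else:
            st["rows"]["tests"] = 0

    with _stage(manifest, "tfcat") as st:
        tf_sets = [s for s in sets if s.category == "TF" and s.name == "TF_all"]
        if not tf_sets:
            tf_sets = [s for s in sets if s.category == "TF"]
        nascent_contrast = next(
            (c for c in config.contrasts if "Nascent" in c), None)
        if tf_sets and nascent_contrast is not None:
            tf_res = results[results["contrast"] == nascent_contrast]
            cats = tf_kinetics.categorize_tfs(
                tf_res, tf_sets[0], fc_cut=config.fc_cut,
                fdr_cut=config.fdr_cut, key_of_protein=key_of_protein,
            )
            treatment_results = {
                c.split("-vs-")[0]: results[results["contrast"] == c]
                for c in config.contrasts if "Nascent" not in c
            }
            flags = tf_kinetics.flag_treatment_dependent_tfs(
                cats, treatment_results, key_of_protein=key_of_protein)
            quant_io.write_results(
                {"tf_categories": cats.per_tf, "tf_category_summary": cats.summary,
                 "tf_flat_treatment_flags": flags},
                out_dir,
            )
            st["rows"]["classified"] = len(cats.per_tf)
            st["rows"]["unquantified"] = len(cats.unquantified)
            st["files"] = ["tf_categories.tsv", "tf_category_summary.tsv",
                           "tf_flat_treatment_flags.tsv"]
        else:
            st["rows"]["classified"] = 0

    with _stage(manifest, "ptm") as st:
        if ptm_table is not None:
            rel, zero_report = histone_ptm.relative_abundance(ptm_table)
            tests = histone_ptm.compare_timecourse(rel)
            quant_io.write_results(
                {"ptm_relative_abundance": rel, "ptm_paired_tests": tests},
                out_dir,
            )
            st["rows"]["forms"] = len(rel)
            st["rows"]["tests"] = len(tests)
            st["rows"]["all_zero_groups"] = len(zero_report)
            st["files"] = ["ptm_relative_abundance.tsv", "ptm_paired_tests.tsv"]
        else:
            st["rows"]["forms"] = 0

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
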