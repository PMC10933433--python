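"""Readers and writers for the tables the pipeline touches.

Protein quantification tables use the MaxQuant ``proteinGroups.txt``
tab-separated dialect: one row per protein group, ``+`` flags for reverse
(decoy) and potential-contaminant rows, a razor+unique peptide count, and one
reporter-intensity column per TMT channel.  A reporter intensity of 0 means
"not quantified" and is converted to a missing value on read.

Gene sets are plain GMT (name, description, members...).  Sample designs and
histone-PTM area tables are CSV.  Result tables are written as TSV with a
fixed float format so repeated runs are byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignMismatchError, FormatError

ID_COL = "Majority protein IDs"
GENE_COL = "Gene names"
DEFAULT_PEPTIDE_COL = "Razor + unique peptides"
REVERSE_COL = "Reverse"
CONTAMINANT_COL = "Potential contaminant"
REPORTER_PREFIX = "Reporter intensity corrected "

FLOAT_FORMAT = "%.6g"

GENESET_CATEGORIES = (
    "repair_pathway",
    "remodeller_family",
    "TF",
    "pioneer_TF",
    "replisome",
    "RNAPII",
    "other",
)

DESIGN_COLUMNS = ("sample_id", "treatment", "time_point", "batch")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers with a coarse functional category."""

    name: str
    members: frozenset
    category: str = "other"

    def __post_init__(self):
        if not self.members:
            raise FormatError(f"gene set '{self.name}' has no members")
        if self.category not in GENESET_CATEGORIES:
            raise FormatError(
                f"gene set '{self.name}': unknown category '{self.category}'"
            )

    @classmethod
    def of(cls, name: str, members: Iterable[str], category: str = "other") -> "GeneSet":
        return cls(name=name, members=frozenset(members), category=category)


@dataclass
class ProteinQuantTable:
    """Protein rows x sample columns of reporter intensities plus QC metadata.

    ``meta`` is indexed by protein_id with columns ``gene_name``,
    ``n_unique_razor_peptides``, ``is_reverse``, ``is_contaminant``;
    ``intensities`` shares the index, one column per design sample, NaN for
    missing.  ``scale_tag`` records the current scale (raw / log10 / log2)
    and only changes through declared transforms.
    """

    meta: pd.DataFrame
    intensities: pd.DataFrame
    scale_tag: str = "raw"

    def __post_init__(self):
        if self.meta.index.has_duplicates:
            dups = self.meta.index[self.meta.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate protein_id entries: {dups[:5]}")
        if not self.meta.index.equals(self.intensities.index):
            raise FormatError("meta and intensities indexes differ")

    @property
    def samples(self) -> list:
        return list(self.intensities.columns)

    def __len__(self) -> int:
        return len(self.meta)

    def copy(self) -> "ProteinQuantTable":
        return ProteinQuantTable(
            self.meta.copy(), self.intensities.copy(), self.scale_tag
        )

    def match_key(self) -> pd.Series:
        """Identifier used for gene-set matching: gene_name, falling back to
        protein_id where the gene name is blank."""
        gene = self.meta["gene_name"].astype(str)
        blank = gene.isin(["", "nan", "None"])
        key = gene.where(~blank, pd.Series(self.meta.index, index=self.meta.index))
        return key


def validate_design(design: pd.DataFrame, treatment_ref: str = "DMSO",
                    time_ref: str = "Nascent") -> pd.DataFrame:
    """Check a sample-design table and normalise its dtypes.

    Requires columns sample_id/treatment/time_point/batch, unique
    (treatment, time_point, batch) combinations, and the reference levels
    present.
    """
    for col in DESIGN_COLUMNS:
        if col not in design.columns:
            raise FormatError(f"design table is missing required column '{col}'")
    design = design.loc[:, list(DESIGN_COLUMNS)].copy()
    for col in DESIGN_COLUMNS:
        design[col] = design[col].astype(str)
    if design["sample_id"].duplicated().any():
        raise FormatError("design table has duplicate sample_id values")
    combos = design[["treatment", "time_point", "batch"]]
    if combos.duplicated().any():
        raise FormatError("duplicate (treatment, time_point, batch) combinations")
    if treatment_ref not in set(design["treatment"]):
        raise FormatError(f"reference treatment '{treatment_ref}' absent from design")
    if time_ref not in set(design["time_point"]):
        raise FormatError(f"reference time point '{time_ref}' absent from design")
    return design.reset_index(drop=True)


def read_design(path) -> pd.DataFrame:
    return validate_design(pd.read_csv(path, dtype=str))


def write_design(design: pd.DataFrame, path) -> None:
    design.loc[:, list(DESIGN_COLUMNS)].to_csv(path, index=False)


def _resolve_intensity_column(columns, sample_id: str):
    for candidate in (REPORTER_PREFIX + sample_id, "Reporter intensity " + sample_id,
                      sample_id):
        if candidate in columns:
            return candidate
    return None


def read_protein_groups(path, design: pd.DataFrame,
                        peptide_col: str = DEFAULT_PEPTIDE_COL) -> ProteinQuantTable:
    """Parse a MaxQuant-dialect proteinGroups.txt against a sample design.

    ``+`` in the Reverse / Potential contaminant columns sets the respective
    flag; intensity 0 becomes missing (MaxQuant writes 0 for unquantified);
    the returned table is on the raw scale.
    """
    df = pd.read_csv(path, sep="\t", dtype={REVERSE_COL: str, CONTAMINANT_COL: str})
    for col in (ID_COL, GENE_COL, peptide_col, REVERSE_COL, CONTAMINANT_COL):
        if col not in df.columns:
            raise FormatError(f"protein groups file lacks required column '{col}'")
    design = validate_design(design)

    colmap = {}
    for sid in design["sample_id"]:
        col = _resolve_intensity_column(df.columns, sid)
        if col is None:
            raise DesignMismatchError(
                f"sample '{sid}' from the design has no intensity column in the file"
            )
        colmap[sid] = col

    meta = pd.DataFrame(
        {
            "gene_name": df[GENE_COL].fillna("").astype(str),
            "n_unique_razor_peptides": df[peptide_col].astype(int),
            "is_reverse": df[REVERSE_COL].fillna("") == "+",
            "is_contaminant": df[CONTAMINANT_COL].fillna("") == "+",
        }
    )
    meta.index = pd.Index(df[ID_COL].astype(str), name="protein_id")

    intens = pd.DataFrame(
        {sid: pd.to_numeric(df[col], errors="coerce") for sid, col in colmap.items()}
    )
    intens.index = meta.index
    intens = intens.mask(intens == 0)  # zero means unquantified
    if (intens.to_numpy() < 0).any():
        raise FormatError("negative reporter intensities found")
    return ProteinQuantTable(meta=meta, intensities=intens, scale_tag="raw")


def write_protein_groups(table: ProteinQuantTable, path,
                         peptide_col: str = DEFAULT_PEPTIDE_COL) -> None:
    """Write a quantification table back out in the MaxQuant dialect."""
    out = pd.DataFrame(
        {
            ID_COL: table.meta.index,
            GENE_COL: table.meta["gene_name"].to_numpy(),
            peptide_col: table.meta["n_unique_razor_peptides"].to_numpy(),
            REVERSE_COL: np.where(table.meta["is_reverse"], "+", ""),
            CONTAMINANT_COL: np.where(table.meta["is_contaminant"], "+", ""),
        }
    )
    for sid in table.samples:
        out[REPORTER_PREFIX + sid] = table.intensities[sid].fillna(0.0).to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_gmt(path) -> list:
    """Read gene sets from a GMT file (name, description, members...).

    A ``category=<name>`` token in the description field restores the set
    category; duplicate members within a line are deduplicated.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT lines need >=3 tab-separated fields"
                )
            name, desc = fields[0], fields[1]
            category = "other"
            for token in desc.split(";"):
                if token.startswith("category="):
                    category = token.split("=", 1)[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise FormatError(f"{path}: line {lineno}: gene set '{name}' empty")
            sets.append(GeneSet(name=name, members=members, category=category))
    return sets


def write_gmt(sets: Sequence[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            members = "\t".join(sorted(s.members))
            fh.write(f"{s.name}\tcategory={s.category}\t{members}\n")


def read_ptm_areas(path) -> pd.DataFrame:
    """Read a histone-PTM area table (CSV, long format)."""
    df = pd.read_csv(path)
    required = ("histone", "peptide_key", "form", "area", "sample_id",
                "replicate", "treatment", "time_point")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"PTM area table lacks required column '{col}'")
    if (df["area"] < 0).any():
        raise FormatError("negative PTM areas found")
    if df.duplicated(subset=["peptide_key", "form", "sample_id"]).any():
        raise FormatError("duplicate (peptide_key, form, sample_id) rows")
    return df


def write_results(tables: Mapping[str, pd.DataFrame], out_dir) -> list:
    """Write result DataFrames as TSVs with stable column order and fixed
    float precision; returns the manifest of files written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        manifest.append(str(path))
    return manifest
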