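"""Delimited-text I/O for dosage matrices, phenotype tables and pedigrees.

All formats are plain TSV: a dosage matrix has a header row of marker ids
and sample ids in the first column, missing calls written as ``NA``; a
phenotype table is long-format with one plot record per row; a pedigree
has three columns (id, parent1, parent2).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .qc import DosageMatrix

NA = "NA"


def write_dosage(dm: DosageMatrix, path, meta_path=None) -> None:
    out = dm.dosages.copy()
    if not dm.has_missing():
        out = out.astype(np.int64)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep=NA)
    if meta_path is not None and dm.sample_meta is not None:
        meta = dm.sample_meta.copy()
        meta.index.name = "sample_id"
        meta.to_csv(meta_path, sep="\t", na_rep=NA)


def read_dosage(path, meta_path=None) -> DosageMatrix:
    dosages = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, na_values=[NA])
        if "is_check" in meta.columns:
            meta["is_check"] = meta["is_check"].astype(bool)
        if "family" in meta.columns:
            meta["family"] = meta["family"].fillna("")
    return DosageMatrix(dosages, meta)


def nucleotide_to_dosage(geno: pd.DataFrame, ref_alleles: pd.Series) -> pd.DataFrame:
    """Convert a 4-letter nucleotide genotype table (e.g. ``AATG``) to
    dosage counts of the non-reference allele per marker."""
    out = {}
    for marker in geno.columns:
        ref = ref_alleles[marker]
        col = geno[marker]
        out[marker] = col.map(
            lambda s: np.nan if pd.isna(s) else sum(1 for ch in str(s) if ch != ref)
        )
    return pd.DataFrame(out, index=geno.index)


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA])


def write_pedigree(ped: pd.DataFrame, path) -> None:
    ped.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_pedigree(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
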