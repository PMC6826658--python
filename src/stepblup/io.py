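"""Readers and writers for the package's plain-text file dialects.

Pedigree and phenotype tables travel as CSV; genotypes as PLINK
``.raw``-style additive tables (whitespace separated, ``NA`` missing)
or a plain TSV dialect; relationship matrices as TSV with id headers or
coordinate triplets; reports as JSON/TSV; configuration as YAML.  Every
writer round-trips with its paired reader.  The unknown-parent sentinel
in all file dialects is ``0``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .genomic import MISSING, GenotypeMatrix, QCReport
from .mme import TraitDataset
from .pedigree import Pedigree, RelationshipMatrix, read_and_validate_pedigree

__all__ = [
    "read_pedigree_csv",
    "write_pedigree_csv",
    "read_phenotypes_csv",
    "write_phenotypes_csv",
    "read_plink_raw",
    "write_plink_raw",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_matrix_triplets",
    "write_qc_report",
    "load_config",
    "dump_config",
]


def read_pedigree_csv(path) -> Pedigree:
    df = pd.read_csv(path)
    return read_and_validate_pedigree(df)


def write_pedigree_csv(pedigree: Pedigree, path) -> None:
    df = pedigree.frame.copy()
    df["sire"] = df["sire"].fillna(0)
    df["dam"] = df["dam"].fillna(0)
    df.to_csv(path, index=False)


def read_phenotypes_csv(path, traits: list[str] | None = None) -> TraitDataset:
    df = pd.read_csv(path)
    if traits is None:
        known = {"id", "record", "year_season", "age_months", "interval_days"}
        traits = [c for c in df.columns if c not in known]
    return TraitDataset(records=df, traits=list(traits))


def write_phenotypes_csv(dataset: TraitDataset, path) -> None:
    dataset.records.to_csv(path, index=False)


def write_plink_raw(genotypes: GenotypeMatrix, path) -> None:
    """PLINK --recode A style table: FID IID PAT MAT SEX PHENOTYPE SNPs..."""
    codes = genotypes.codes.astype(object)
    codes[genotypes.codes == MISSING] = "NA"
    df = pd.DataFrame(codes, columns=[f"{s}_A" for s in genotypes.snp_ids])
    meta = pd.DataFrame(
        {
            "FID": genotypes.ids,
            "IID": genotypes.ids,
            "PAT": 0,
            "MAT": 0,
            "SEX": 0,
            "PHENOTYPE": -9,
        }
    )
    pd.concat([meta.reset_index(drop=True), df], axis=1).to_csv(
        path, sep=" ", index=False
    )


def read_plink_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+")
    meta_cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    snp_cols = [c for c in df.columns if c not in meta_cols]
    codes = df[snp_cols].to_numpy(dtype=object)
    out = np.full(codes.shape, MISSING, dtype=np.int8)
    mask = pd.notna(pd.DataFrame(codes)) & (pd.DataFrame(codes) != "NA")
    vals = pd.DataFrame(codes).where(mask)
    out_f = vals.apply(pd.to_numeric, errors="coerce").to_numpy()
    good = ~np.isnan(out_f)
    out[good] = out_f[good].astype(np.int8)
    snp_ids = [c[:-2] if c.endswith("_A") else c for c in snp_cols]
    return GenotypeMatrix(out, pd.Index(df["IID"]), pd.Index(snp_ids))


def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    """Plain TSV: rows = individuals, missing written as NA."""
    codes = genotypes.codes.astype(object)
    codes[genotypes.codes == MISSING] = "NA"
    pd.DataFrame(codes, index=genotypes.ids, columns=genotypes.snp_ids).to_csv(
        path, sep="\t", index_label="id"
    )


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="id")
    vals = df.apply(pd.to_numeric, errors="coerce").to_numpy()
    out = np.full(vals.shape, MISSING, dtype=np.int8)
    good = ~np.isnan(vals)
    out[good] = vals[good].astype(np.int8)
    return GenotypeMatrix(out, pd.Index(df.index), pd.Index(df.columns))


def write_matrix_tsv(matrix: RelationshipMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="id")


def read_matrix_tsv(path, role: str = "A") -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col="id")
    return RelationshipMatrix(df.to_numpy(), pd.Index(df.index), role=role)


def write_matrix_triplets(matrix: RelationshipMatrix, path) -> None:
    """Coordinate-format sparse triplets (row id, col id, value)."""
    m = sp.coo_matrix(matrix.values)
    df = pd.DataFrame(
        {
            "row": matrix.ids[m.row],
            "col": matrix.ids[m.col],
            "value": m.data,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_qc_report(report: QCReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, pd.Index):
        return list(obj)
    return obj


def dump_config(config, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
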