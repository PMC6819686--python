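"""Plain-text readers and writers: PLINK .raw genotypes, TSV genotypes, phenotypes."""

from __future__ import annotations

import numpy as np
import pandas as pd

PHENOTYPE_COLUMNS = ["animal", "adg", "batch", "sex", "pen", "litter", "age_days"]


def _coerce_ids(values: pd.Index | pd.Series):
    """Animal ids as int where possible (matches pedigree CSV round-trips)."""
    try:
        return values.astype(np.int64)
    except (TypeError, ValueError):
        return values


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype CSV with columns animal, adg, batch, sex, pen, litter, age_days[, period]."""
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file {path} lacks columns {missing}")
    if "period" not in df.columns:
        df["period"] = df["batch"]
    df["animal"] = _coerce_ids(df["animal"])
    return df


def read_genotypes_raw(path) -> pd.DataFrame:
    """PLINK .raw dosage text: header FID IID PAT MAT SEX PHENOTYPE + one column
    per marker; dosages 0/1/2, missing NA.  Returns animals x markers with the
    IID column as index."""
    df = pd.read_csv(path, sep=r"\s+")
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is not PLINK .raw (missing {missing})")
    out = df.drop(columns=meta[:1] + meta[2:]).set_index("IID")
    out.index = _coerce_ids(out.index)
    out.index.name = "animal"
    return out.astype(float)


def write_genotypes_raw(genotypes: pd.DataFrame, path) -> None:
    df = genotypes.copy()
    cols = [c if str(c).endswith(("_A", "_B")) else f"{c}_A" for c in df.columns]
    df.columns = cols
    df.insert(0, "PHENOTYPE", -9)
    df.insert(0, "SEX", 0)
    df.insert(0, "MAT", 0)
    df.insert(0, "PAT", 0)
    df.insert(0, "IID", genotypes.index)
    df.insert(0, "FID", genotypes.index)
    df.to_csv(path, sep=" ", index=False, na_rep="NA")


def read_genotypes_tsv(path) -> pd.DataFrame:
    """Simple dialect: first column animal id, remaining columns marker dosages."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index = _coerce_ids(df.index)
    df.index.name = "animal"
    return df.astype(float)


def write_genotypes_tsv(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t", index=True, na_rep="NA")


def read_marker_metadata(path) -> pd.DataFrame:
    """Optional marker metadata (marker, chromosome) used by the nonautosomal QC rule."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "marker" not in df.columns or "chromosome" not in df.columns:
        raise ValueError(f"{path} needs 'marker' and 'chromosome' columns")
    return df
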