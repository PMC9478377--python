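"""Readers and writers for the package's plain-text tabular artifacts.

Everything is delimited text (TSV by default).  Formats:

* particle table — one row per detected particle; columns ``sample_id``
  and the four attribute columns, optionally ``region`` and ``depth_layer``.
* sample metadata — ``sample_id, region, depth_layer, replicate,
  soil_mass_g``.
* distance matrix — square table, first column holds row labels, header
  holds column labels; must be symmetric with a zero diagonal.
* OTU table — rows = samples, columns = taxa, nonnegative integer counts.
* covariate table — rows keyed by ``sample_id``, numeric columns.
"""

from __future__ import annotations

from typing import IO, Union

import numpy as np
import pandas as pd

from .community import DistanceMatrix
from .errors import DataError
from .vocab import FAMILIES, canonicalize

PathOrBuffer = Union[str, "IO[str]"]

PARTICLE_ATTRIBUTES = ("size_class", "shape", "color", "polymer")
_REQUIRED_PARTICLE_COLUMNS = ("sample_id",) + PARTICLE_ATTRIBUTES
_META_COLUMNS = ("sample_id", "region", "depth_layer", "replicate", "soil_mass_g")


def canonicalize_particles(df: pd.DataFrame, policy: str = "strict") -> pd.DataFrame:
    """Canonicalize every categorical column of a particle table in place.

    Returns a copy with ``df.attrs["coercions"]`` set to the number of
    values that had to be coerced under the permissive policy.
    """
    out = df.copy()
    coercions = 0
    for column in out.columns:
        family = column if column in FAMILIES else None
        if family is None:
            continue
        canon = []
        for i, raw in enumerate(out[column].astype(str)):
            try:
                value = canonicalize(raw, family, policy="strict")
            except DataError:
                if policy == "strict":
                    raise DataError(
                        f"row {i}: value {raw!r} is not in the closed "
                        f"{family} vocabulary"
                    ) from None
                value = canonicalize(raw, family, policy="permissive")
                coercions += 1
            canon.append(value)
        out[column] = canon
    out.attrs["coercions"] = coercions
    return out


def read_particle_table(
    source: PathOrBuffer, policy: str = "strict", sep: str = "\t"
) -> pd.DataFrame:
    """Read and canonicalize a per-particle table.

    Unknown categorical values are rejected under ``policy="strict"``
    (naming the row and value) or coerced to ``"other"`` and counted in
    ``result.attrs["coercions"]`` under ``policy="permissive"``.
    Row count is preserved in both cases.
    """
    df = pd.read_csv(source, sep=sep, dtype=str)
    missing = [c for c in _REQUIRED_PARTICLE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"particle table is missing columns {missing}")
    return canonicalize_particles(df, policy=policy)


def write_particle_table(df: pd.DataFrame, target: PathOrBuffer) -> None:
    df.to_csv(target, sep="\t", index=False)


def read_sample_meta(source: PathOrBuffer, sep: str = "\t") -> pd.DataFrame:
    meta = pd.read_csv(source, sep=sep)
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise DataError(f"sample metadata is missing columns {missing}")
    meta["region"] = [canonicalize(v, "region") for v in meta["region"].astype(str)]
    meta["depth_layer"] = [
        canonicalize(v, "depth_layer") for v in meta["depth_layer"].astype(str)
    ]
    if (meta["soil_mass_g"] <= 0).any():
        bad = meta.loc[meta["soil_mass_g"] <= 0, "sample_id"].tolist()
        raise DataError(f"soil_mass_g must be positive; offending samples: {bad}")
    key = meta[["region", "depth_layer", "replicate"]].apply(tuple, axis=1)
    if key.duplicated().any():
        raise DataError("(region, depth_layer, replicate) must be unique")
    if meta["sample_id"].duplicated().any():
        raise DataError("sample_id must be unique in sample metadata")
    return meta


def write_sample_meta(meta: pd.DataFrame, target: PathOrBuffer) -> None:
    meta.to_csv(target, sep="\t", index=False)


def write_distance_matrix(dm: DistanceMatrix, target: PathOrBuffer) -> None:
    dm.to_dataframe().to_csv(target, sep="\t", index_label="sample_id",
                             float_format="%.12g")


def read_distance_matrix(source: PathOrBuffer, sep: str = "\t") -> DistanceMatrix:
    """Read a square symmetric distance matrix; rejects asymmetry beyond
    1e-9, negative entries and a nonzero diagonal."""
    df = pd.read_csv(source, sep=sep, index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise DataError("distance matrix row and column labels differ")
    values = df.to_numpy(dtype=float)
    return DistanceMatrix(labels=list(df.index.astype(str)), values=values)


def read_otu_table(source: PathOrBuffer, sep: str = "\t") -> pd.DataFrame:
    """Read an OTU/ASV count table (rows = samples, columns = taxa)."""
    df = pd.read_csv(source, sep=sep, index_col=0)
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise DataError("OTU table contains negative counts")
    if not np.allclose(values, np.round(values)):
        raise DataError("OTU table contains non-integer counts")
    return df.astype(np.int64)


def write_otu_table(df: pd.DataFrame, target: PathOrBuffer) -> None:
    df.to_csv(target, sep="\t", index_label="sample_id")


def read_covariates(source: PathOrBuffer, sep: str = "\t") -> pd.DataFrame:
    """Read a covariate table keyed by sample_id; all columns numeric,
    missing cells allowed (handled pairwise-complete downstream)."""
    df = pd.read_csv(source, sep=sep, index_col=0)
    for column in df.columns:
        df[column] = pd.to_numeric(df[column], errors="raise")
    return df


def write_covariates(df: pd.DataFrame, target: PathOrBuffer) -> None:
    df.to_csv(target, sep="\t", index_label="sample_id", float_format="%.12g")
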