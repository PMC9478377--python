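"""Community-matrix construction and per-sample summaries.

The "MP community" treats the microplastic particles of a sample like a
species community: every particle carries a shape, a colour and a polymer
type, and the sample's community vector counts attribute levels.  Two
encodings are supported:

* ``attribute-union`` (default) — one feature per attribute *level*
  (fiber, black, PE, ...).  Each particle contributes one count to each
  of its three attribute features, so row totals are 3x the particle
  count.  This is the encoding under which single attribute levels can be
  reported as discriminant features.
* ``attribute-triple`` — one feature per observed (shape, colour,
  polymer) combination; each particle contributes exactly one count.

Size class is not part of the community by default but can be included.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .vocab import COLORS, POLYMERS, SHAPES, SIZE_CLASSES

FEATURE_MODES = ("attribute-union", "attribute-triple")

_UNION_FAMILIES = (("shape", SHAPES), ("color", COLORS), ("polymer", POLYMERS))


def build_community_matrix(
    particles: pd.DataFrame,
    feature_mode: str = "attribute-union",
    include_size: bool = False,
) -> pd.DataFrame:
    """Aggregate a particle table into a samples x features count matrix.

    Features are named ``family:level`` in union mode and
    ``shape|color|polymer`` in triple mode.  Only observed samples appear
    as rows; only observed features appear as columns in triple mode,
    while union mode keeps every vocabulary level (drop all-zero columns
    downstream if needed).
    """
    if len(particles) == 0:
        raise DataError("cannot build a community matrix from an empty particle table")
    if feature_mode not in FEATURE_MODES:
        raise ConfigError(
            f"unknown feature_mode {feature_mode!r}; expected one of {FEATURE_MODES}"
        )
    samples = pd.unique(particles["sample_id"])
    if feature_mode == "attribute-union":
        families = list(_UNION_FAMILIES)
        if include_size:
            families.append(("size_class", SIZE_CLASSES))
        blocks = []
        for family, levels in families:
            counts = (
                particles.groupby(["sample_id", family], observed=True)
                .size()
                .unstack(fill_value=0)
                .reindex(index=samples, columns=list(levels), fill_value=0)
            )
            counts.columns = [f"{family}:{level}" for level in counts.columns]
            blocks.append(counts)
        out = pd.concat(blocks, axis=1)
    else:
        keys = ["shape", "color", "polymer"] + (["size_class"] if include_size else [])
        labels = particles[keys].agg("|".join, axis=1)
        out = (
            pd.DataFrame({"sample_id": particles["sample_id"], "feature": labels})
            .groupby(["sample_id", "feature"], observed=True)
            .size()
            .unstack(fill_value=0)
            .reindex(index=samples, fill_value=0)
        )
    out.index.name = "sample_id"
    return out.astype(np.int64)


def relative_abundance(matrix: pd.DataFrame, scale: float = 1.0) -> pd.DataFrame:
    """Row-normalise a community (or OTU) matrix to sum to ``scale``."""
    totals = matrix.sum(axis=1)
    if (totals == 0).any():
        empty = list(matrix.index[totals == 0])
        raise DataError(f"all-zero rows cannot be normalised: {empty}")
    return matrix.div(totals, axis=0) * scale


def summarize_samples(particles: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample abundance (items per kg dry soil) and attribute proportions.

    Every sample in ``meta`` gets a row, including samples without
    particles: those get abundance 0, ``has_particles=False`` and missing
    proportions (so they can be excluded explicitly downstream instead of
    propagating NaN silently).
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    counts = particles.groupby("sample_id").size().reindex(meta.index, fill_value=0)
    mass_kg = meta["soil_mass_g"].astype(float) / 1000.0
    out = pd.DataFrame(
        {
            "n_particles": counts.astype(np.int64),
            "abundance": counts / mass_kg,
            "has_particles": counts > 0,
        },
        index=meta.index,
    )
    for family, levels in (
        ("size_class", SIZE_CLASSES),
        ("shape", SHAPES),
        ("color", COLORS),
        ("polymer", POLYMERS),
    ):
        tab = (
            particles.groupby(["sample_id", family], observed=True)
            .size()
            .unstack(fill_value=0)
            .reindex(index=meta.index, columns=list(levels), fill_value=0)
        )
        props = tab.div(counts.where(counts > 0), axis=0)  # NaN for empty samples
        props.columns = [f"prop_{family}:{level}" for level in props.columns]
        out = pd.concat([out, props], axis=1)
    out.index.name = "sample_id"
    return out


def metric_table(particles: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample MP metrics on the items-per-kg scale, for association
    screens: total abundance plus the abundance of every shape and size
    level (the quantities correlated against soil and climate covariates).
    """
    summary = summarize_samples(particles, meta)
    out = pd.DataFrame({"abundance": summary["abundance"]})
    for family in ("shape", "size_class"):
        for column in summary.columns:
            if column.startswith(f"prop_{family}:"):
                level = column.split(":", 1)[1]
                out[f"{family}:{level}"] = (
                    summary[column].fillna(0.0) * summary["abundance"]
                )
    out.index.name = "sample_id"
    return out
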