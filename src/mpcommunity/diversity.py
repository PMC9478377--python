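"""Diversity statistics: Gini-Simpson, the MDII composite, and Chao1.

The MP community diversity index (MDII) is the geometric mean of the
Gini-Simpson diversities of the three attribute families,

    MDII = (Simpson_shape * Simpson_color * Simpson_polymer)^(1/3),

with Simpson taken as the Gini-Simpson index 1 - sum(p_i^2), which is
bounded in [0, 1) so the composite stays in [0, 1).  A higher MDII means
the sample's particles are spread over more shapes, colours and polymer
types at once — read in the field as a wider mix of pollution sources.

Chao1 is the classic nonparametric richness estimator for the companion
microbial (16S OTU) tables, built from singleton and doubleton counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StatisticalError


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    simpson_shape: float
    simpson_color: float
    simpson_polymer: float
    mdii: float


@dataclass(frozen=True)
class Chao1Result:
    s_obs: int
    f1: int
    f2: int
    chao1: float


def gini_simpson(counts, variant: str = "gini") -> float:
    """Simpson-type diversity of a count vector.

    ``variant="gini"`` returns 1 - sum(p_i^2), the probability that two
    randomly drawn particles differ in category, bounded in [0, 1).
    ``variant="inverse"`` returns 1 / sum(p_i^2) for sensitivity analysis.
    All-zero counts are an error: diversity of nothing is undefined.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise StatisticalError("counts must be a 1-D vector")
    if (c < 0).any():
        raise StatisticalError("counts must be nonnegative")
    total = c.sum()
    if total == 0:
        raise StatisticalError("diversity of an all-zero count vector is undefined")
    p = c / total
    d2 = float(np.sum(p * p))
    if variant == "gini":
        return 1.0 - d2
    if variant == "inverse":
        return 1.0 / d2
    raise StatisticalError(f"unknown Simpson variant {variant!r}")


def mdii(shape_counts, color_counts, polymer_counts) -> float:
    """Composite diversity: cube root of the product of the three
    Gini-Simpson values.  Zero iff any attribute is monomorphic."""
    parts = {}
    for name, counts in (
        ("shape", shape_counts),
        ("color", color_counts),
        ("polymer", polymer_counts),
    ):
        try:
            parts[name] = gini_simpson(counts)
        except StatisticalError as exc:
            raise StatisticalError(f"{name}: {exc}") from None
    return float(
        (parts["shape"] * parts["color"] * parts["polymer"]) ** (1.0 / 3.0)
    )


def diversity_table(particles: pd.DataFrame, level: str = "sample") -> pd.DataFrame:
    """Per-sample (default) or per-region pooled Simpson triple + MDII.

    ``level="region"`` pools all particles of a region before computing
    the indices; the aggregation level the composite is reported at is a
    reporting choice, so both are exposed.
    """
    if level == "sample":
        key = "sample_id"
    elif level == "region":
        key = "region"
    else:
        raise StatisticalError(f"unknown aggregation level {level!r}")
    rows = []
    for unit, group in particles.groupby(key, sort=False):
        values = {}
        for family in ("shape", "color", "polymer"):
            counts = group[family].value_counts().to_numpy()
            values[family] = gini_simpson(counts)
        rows.append(
            DiversityResult(
                sample_id=str(unit),
                simpson_shape=values["shape"],
                simpson_color=values["color"],
                simpson_polymer=values["polymer"],
                mdii=float(
                    (values["shape"] * values["color"] * values["polymer"])
                    ** (1.0 / 3.0)
                ),
            )
        )
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("sample_id")
    out.index.name = key
    return out


def chao1(taxon_counts) -> Chao1Result:
    """Chao1 richness estimate for one sample's taxon count vector.

    Uses the classic estimator S_obs + f1^2 / (2 f2) when doubletons are
    present and the bias-corrected form S_obs + f1 (f1 - 1) / (2 (f2 + 1))
    when f2 = 0, so the estimate is always finite and >= S_obs.
    """
    c = np.asarray(taxon_counts)
    if not np.issubdtype(c.dtype, np.number):
        raise StatisticalError("taxon counts must be numeric")
    cf = c.astype(float)
    if (cf < 0).any():
        raise StatisticalError("taxon counts must be nonnegative")
    if not np.allclose(cf, np.round(cf)):
        raise StatisticalError("Chao1 is defined on integer counts")
    ci = np.round(cf).astype(np.int64)
    s_obs = int((ci > 0).sum())
    f1 = int((ci == 1).sum())
    f2 = int((ci == 2).sum())
    if f2 > 0:
        estimate = s_obs + f1 * f1 / (2.0 * f2)
    else:
        estimate = s_obs + f1 * (f1 - 1) / 2.0
    return Chao1Result(s_obs=s_obs, f1=f1, f2=f2, chao1=float(estimate))


def chao1_table(otu: pd.DataFrame) -> pd.DataFrame:
    """Chao1 per sample for an OTU table (rows = samples)."""
    rows = {sid: chao1(otu.loc[sid].to_numpy()).__dict__ for sid in otu.index}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out
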