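"""Null-calibration harness for the downstream tests.

Simulates surveys with every planted effect zero and all regions
exchangeable, runs each inferential procedure on quantities that are
independent under that null, and reports rejection rates at a nominal
level.  A well-calibrated stack rejects close to the nominal level; this
is the operational check that the permutation machinery, rank handling
and approximations are sound, and it is also a property of the generator
(its null really is a null).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from . import associations as assoc
from . import community as comm
from . import matrix as mx
from . import synthetic as syn

TESTS = ("anosim", "mantel", "spearman", "t_test", "anova")

_SOIL_COLUMNS = ["pH", "SOC", "POXC", "POC", "DOC", "MBC", "C/N", "C/P", "N/P"]


def _child_seed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + 7919 * k + 1) % (2**31 - 1))


def null_pvalues_once(seed: int, n_permutations: int = 199) -> dict[str, float]:
    """One null survey, one p-value per test."""
    bundle = syn.simulate_survey(syn.null_config(), seed=seed)
    meta_ix = bundle.meta.set_index("sample_id")
    matrix = mx.build_community_matrix(bundle.particles)
    groups = meta_ix["region"].loc[matrix.index]
    dist = comm.bray_curtis(matrix)

    out: dict[str, float] = {}
    out["anosim"] = comm.anosim(
        dist, groups, n_permutations=n_permutations, seed=seed
    ).p_value

    soil = bundle.covariates.loc[matrix.index, _SOIL_COLUMNS]
    z = (soil - soil.mean()) / soil.std(ddof=0).replace(0.0, 1.0)
    env = comm.DistanceMatrix(
        labels=list(matrix.index.astype(str)),
        values=squareform(pdist(z.to_numpy())),
        method="euclidean",
    )
    out["mantel"] = comm.mantel(
        dist, env, n_permutations=n_permutations, seed=seed
    ).p_value

    summary = mx.summarize_samples(bundle.particles, bundle.meta)
    abundance = summary["abundance"]
    rho = assoc.spearman_rho(abundance.to_numpy(), soil["pH"].to_numpy())
    out["spearman"] = assoc._spearman_p(
        abundance.to_numpy(), soil["pH"].to_numpy(), rho, exact_max_n=0
    )

    top = abundance[meta_ix["depth_layer"] == "0-20 cm"]
    sub = abundance[meta_ix["depth_layer"] == "20-40 cm"]
    out["t_test"] = assoc.independent_t_test(top, sub)[1]

    out["anova"] = assoc.one_way_anova(
        abundance.to_numpy(), meta_ix["region"].to_numpy()
    )[1]
    return out


def null_rejection_rates(
    n_sims: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    n_permutations: int = 199,
) -> pd.DataFrame:
    """Rejection rate of each test at ``alpha`` over ``n_sims`` null
    surveys, with the binomial Monte-Carlo standard error."""
    hits = {t: 0 for t in TESTS}
    for k in range(n_sims):
        ps = null_pvalues_once(_child_seed(seed, k), n_permutations=n_permutations)
        for t in TESTS:
            hits[t] += ps[t] <= alpha
    rows = []
    for t in TESTS:
        rate = hits[t] / n_sims
        rows.append(
            {
                "test": t,
                "rejection_rate": rate,
                "alpha": alpha,
                "n_sims": n_sims,
                "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_sims)),
            }
        )
    return pd.DataFrame(rows).set_index("test")
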