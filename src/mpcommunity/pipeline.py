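"""End-to-end survey analysis pipeline.

Runs, in dependency order: data acquisition (simulation or ingestion of
particle/metadata/OTU/covariate tables), community-matrix construction,
per-sample summaries and diversity indices, Bray-Curtis + ANOSIM + LDA +
LEfSe + pairwise-region Mantel, Chao1 (when an OTU table is present),
and the association screens (Spearman matrix, abundance~population
regression, ANOVA with Duncan letters per depth, depth t-tests per
region).  Stages whose inputs are absent are skipped with an explicit
notice.  Every stage writes a typed TSV/JSON artifact; the human-readable
summary only restates numbers present in those artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import associations as assoc
from . import community as comm
from . import diversity as div
from . import io as mio
from . import matrix as mx
from . import synthetic as syn
from .errors import ConfigError, DataError
from .lefse import lefse as run_lefse_stage
from .lefse import lefse_table


@dataclass
class PipelineConfig:
    outdir: str = "mpcommunity_run"
    seed: int = 0
    simulate: bool = True
    # input paths (used when simulate=False; otu/covariates also accepted
    # alongside simulation to override the synthetic ones)
    particles_path: str | None = None
    meta_path: str | None = None
    otu_path: str | None = None
    covariates_path: str | None = None
    feature_mode: str = "attribute-union"
    include_size: bool = False
    relative_abundance: bool = True
    alpha: float = 0.05
    n_permutations: int = 999
    n_boot: int = 30
    lda_threshold: float = 2.0
    run_lefse: bool = True
    run_mantel: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown pipeline config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass
class ReportBundle:
    outdir: Path
    results: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    notices: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(outdir=outdir)
    results, paths, notices = bundle.results, bundle.paths, bundle.notices

    # --- stage: data -------------------------------------------------
    otu = covariates = None
    if config.simulate:
        survey = syn.simulate_survey(syn.default_config(), seed=config.seed)
        particles, meta = survey.particles, survey.meta
        otu, covariates = survey.otu, survey.covariates
        written = syn.write_bundle(survey, outdir / "data")
        paths.update({f"data/{k}": v for k, v in written.items()})
    else:
        if not config.particles_path or not config.meta_path:
            raise ConfigError("particles_path and meta_path are required when simulate=False")
        for name, p in (("particles", config.particles_path), ("meta", config.meta_path)):
            if not Path(p).exists():
                raise DataError(f"{name} file not found: {p}")
        particles = mio.read_particle_table(config.particles_path)
        meta = mio.read_sample_meta(config.meta_path)
        if config.otu_path:
            otu = mio.read_otu_table(config.otu_path)
        if config.covariates_path:
            covariates = mio.read_covariates(config.covariates_path)

    regions = meta.set_index("sample_id")["region"]

    # --- stage: summaries & community matrix -------------------------
    summary = mx.summarize_samples(particles, meta)
    summary.to_csv(outdir / "sample_summary.tsv", sep="\t", float_format="%.10g")
    paths["summary"] = outdir / "sample_summary.tsv"
    results["summary"] = summary

    matrix = mx.build_community_matrix(
        particles, feature_mode=config.feature_mode, include_size=config.include_size
    )
    matrix.to_csv(outdir / "community_matrix.tsv", sep="\t")
    paths["community_matrix"] = outdir / "community_matrix.tsv"
    results["community_matrix"] = matrix

    # --- stage: diversity --------------------------------------------
    diversity = div.diversity_table(particles, level="sample")
    diversity.to_csv(outdir / "diversity.tsv", sep="\t", float_format="%.10g")
    paths["diversity"] = outdir / "diversity.tsv"
    results["diversity"] = diversity
    results["diversity_region"] = div.diversity_table(particles, level="region")

    if otu is not None:
        chao = div.chao1_table(otu)
        chao.to_csv(outdir / "chao1.tsv", sep="\t", float_format="%.10g")
        paths["chao1"] = outdir / "chao1.tsv"
        results["chao1"] = chao
    else:
        notices.append("no OTU table provided: Chao1 stage skipped")

    # --- stage: community inference ----------------------------------
    sample_order = [s for s in matrix.index]
    dist = comm.bray_curtis(matrix, relative=config.relative_abundance)
    mio.write_distance_matrix(dist, outdir / "bray_curtis.tsv")
    paths["distance"] = outdir / "bray_curtis.tsv"
    results["distance"] = dist

    group_vector = regions.loc[sample_order]
    anosim_res = comm.anosim(
        dist, group_vector, n_permutations=config.n_permutations, seed=config.seed
    )
    results["anosim"] = anosim_res
    (outdir / "anosim.json").write_text(
        json.dumps(dataclasses.asdict(anosim_res), indent=2) + "\n"
    )
    paths["anosim"] = outdir / "anosim.json"

    lda = comm.lda_ordination(matrix, group_vector, relative=config.relative_abundance)
    results["lda"] = lda
    lda.scores.to_csv(outdir / "lda_scores.tsv", sep="\t", float_format="%.10g")
    paths["lda"] = outdir / "lda_scores.tsv"

    if config.run_lefse:
        feats = run_lefse_stage(
            matrix,
            group_vector,
            alpha=config.alpha,
            lda_threshold=config.lda_threshold,
            n_boot=config.n_boot,
            seed=config.seed,
        )
        lefse_df = lefse_table(feats)
        lefse_df.to_csv(outdir / "lefse.tsv", sep="\t", index=False,
                        float_format="%.10g")
        paths["lefse"] = outdir / "lefse.tsv"
        results["lefse"] = lefse_df
    else:
        notices.append("LEfSe stage disabled in config")

    if config.run_mantel:
        mantel_df = comm.mantel_between_regions(
            matrix, group_vector, meta,
            n_permutations=config.n_permutations, seed=config.seed,
        )
        mantel_df.to_csv(outdir / "mantel_regions.tsv", sep="\t", index=False,
                         float_format="%.10g")
        paths["mantel"] = outdir / "mantel_regions.tsv"
        results["mantel"] = mantel_df
    else:
        notices.append("Mantel stage disabled in config")

    # --- stage: association screens ----------------------------------
    if covariates is not None:
        metrics = mx.metric_table(particles, meta)
        cov_all = covariates.copy()
        if otu is not None:
            cov_all["chao1"] = results["chao1"]["chao1"]
        screen = assoc.spearman_screen(metrics, cov_all)
        for name, table in (("rho", screen.rho), ("p", screen.p),
                            ("q", screen.q), ("n", screen.n)):
            table.to_csv(outdir / f"spearman_{name}.tsv", sep="\t",
                         float_format="%.10g")
            paths[f"spearman_{name}"] = outdir / f"spearman_{name}.tsv"
        results["spearman"] = screen

        if "population" in cov_all.columns:
            ab = summary["abundance"].loc[cov_all.index]
            reg = assoc.simple_regression(cov_all["population"], ab)
            results["regression"] = reg
            (outdir / "regression.json").write_text(
                json.dumps(dataclasses.asdict(reg), indent=2) + "\n"
            )
            paths["regression"] = outdir / "regression.json"
    else:
        notices.append("no covariate table provided: association screens skipped")

    # ANOVA + Duncan letters among regions, per depth layer; t-tests
    # between depths, per region
    meta_ix = meta.set_index("sample_id")
    letter_rows, ttest_rows = [], []
    for depth, ids in meta_ix.groupby("depth_layer").groups.items():
        ab = summary.loc[list(ids), "abundance"].to_numpy()
        grp = meta_ix.loc[list(ids), "region"].to_numpy()
        f, p = assoc.one_way_anova(ab, grp)
        letters = assoc.duncan_letters(ab, grp, alpha=config.alpha)
        for region in letters.letters:
            letter_rows.append(
                {"depth_layer": depth, "region": region,
                 "mean_abundance": letters.means[region],
                 "letter": letters.letters[region], "anova_F": f, "anova_p": p}
            )
    for region, ids in meta_ix.groupby("region").groups.items():
        sub = meta_ix.loc[list(ids)]
        top = summary.loc[sub.index[sub["depth_layer"] == "0-20 cm"], "abundance"]
        deep = summary.loc[sub.index[sub["depth_layer"] == "20-40 cm"], "abundance"]
        if len(top) >= 2 and len(deep) >= 2:
            t, p = assoc.independent_t_test(top, deep)
            ttest_rows.append({"region": region, "t": t, "p_value": p})
    letters_df = pd.DataFrame(letter_rows)
    letters_df.to_csv(outdir / "duncan_letters.tsv", sep="\t", index=False,
                      float_format="%.10g")
    paths["letters"] = outdir / "duncan_letters.tsv"
    results["letters"] = letters_df
    ttests_df = pd.DataFrame(ttest_rows)
    ttests_df.to_csv(outdir / "depth_ttests.tsv", sep="\t", index=False,
                     float_format="%.10g")
    paths["ttests"] = outdir / "depth_ttests.tsv"
    results["ttests"] = ttests_df

    # --- manifest & summary ------------------------------------------
    bundle.manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "notices": notices,
        "warnings": list(getattr(results.get("anosim"), "warnings", ())),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2) + "\n"
    )
    summary_text = render_report(bundle)
    (outdir / "summary.txt").write_text(summary_text)
    paths["report"] = outdir / "summary.txt"
    return bundle


def render_report(bundle: ReportBundle) -> str:
    """Human-readable summary; every number restates a stage artifact."""
    lines = ["mpcommunity pipeline summary", "=" * 30]
    r = bundle.results
    if "summary" in r:
        ab = r["summary"]["abundance"]
        lines.append(
            f"MP abundance: mean {ab.mean():,.0f} +/- {ab.std(ddof=1):,.0f} "
            f"items/kg (range {ab.min():,.0f}-{ab.max():,.0f}, n={len(ab)})"
        )
    if "letters" in r and len(r["letters"]):
        lines.append("\nAbundance by region with Duncan letters:")
        for _, row in r["letters"].iterrows():
            lines.append(
                f"  {row['depth_layer']:>9} {row['region']:>3}: "
                f"{row['mean_abundance']:>9,.0f} items/kg  {row['letter']}"
            )
    if "diversity_region" in r:
        lines.append("\nMDII by region (pooled particles):")
        for region, row in r["diversity_region"].iterrows():
            lines.append(f"  {region}: MDII={row['mdii']:.3f}")
    if "anosim" in r:
        a = r["anosim"]
        lines.append(
            f"\nANOSIM (region groups): R={a.r:.3f}, p={a.p_value:.4g} "
            f"({a.method}, {a.n_permutations} permutations, seed={a.seed})"
        )
    if "lda" in r:
        expl = ", ".join(
            f"LD{i + 1} {100 * e:.2f}%" for i, e in enumerate(r["lda"].explained[:2])
        )
        lines.append(f"LDA ordination explained variance: {expl}")
    if "lefse" in r:
        hits = r["lefse"][r["lefse"]["passed"]]
        lines.append(f"LEfSe discriminant features ({len(hits)}):")
        for _, row in hits.iterrows():
            lines.append(
                f"  {row['feature']:>22} -> {row['enriched_group']} "
                f"(LDA {row['lda_score']:.2f}, KW p={row['kw_p']:.3g})"
            )
    if "mantel" in r and len(r["mantel"]):
        rmin, rmax = r["mantel"]["r"].min(), r["mantel"]["r"].max()
        lines.append(
            f"Pairwise-region Mantel r range: {rmin:.2f} to {rmax:.2f}"
        )
    if "regression" in r:
        reg = r["regression"]
        lines.append(
            f"Abundance ~ population: R={reg.r:.3f}, p={reg.p_value:.3g}, "
            f"slope={reg.slope:.2f} items/kg per 1e4 persons (n={reg.n})"
        )
    if "chao1" in r:
        lines.append(f"Chao1 mean richness: {r['chao1']['chao1'].mean():.1f}")
    for notice in bundle.notices:
        lines.append(f"note: {notice}")
    return "\n".join(lines) + "\n"
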