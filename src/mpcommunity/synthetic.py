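"""Synthetic paddy-soil microplastic survey generator.

Emulates a five-region, two-depth, three-replicate field design: each
sample is 10 g of lyophilised soil whose particle count is Poisson with a
region- and depth-specific mean abundance (items per kg dry soil), and
each particle's size class, shape, colour and polymer are drawn from
region-specific multinomials.  Regional community differences are
planted as a deterministic exponential tilt of the shared base
composition along fixed per-region signature directions, scaled by a
single shift magnitude delta; delta = 0 makes all regions identical.

The bundle also carries a soil-property table (means/SDs per region and
depth), regional climate and population covariates, and a companion OTU
count table whose per-sample richness co-varies with MP abundance by a
configurable amount, so that every downstream statistic of the package
can be exercised against known planted effects.

All randomness flows from one integer seed through named substreams
(particles, covariates, OTU), so identical (config, seed) pairs produce
bit-identical bundles.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .vocab import COLORS, DEPTH_LAYERS, POLYMERS, REGIONS, SHAPES, SIZE_CLASSES

_FAMILY_LEVELS = {
    "size_class": SIZE_CLASSES,
    "shape": SHAPES,
    "color": COLORS,
    "polymer": POLYMERS,
}

#: planted-effect registry: effect name -> PlantedEffects field
EFFECT_REGISTRY = {
    "community_shift": "community_shift",
    "population_slope": "population_slope",
    "chao1_association": "chao1_association",
    "soil_ratio_correlation": "soil_ratio_correlation",
}


@dataclass
class PlantedEffects:
    community_shift: float = 1.0  # delta: tilt magnitude between regions
    population_slope: float = 0.0  # beta: items/kg per unit population
    chao1_association: float = 0.25  # fractional richness change per SD abundance
    soil_ratio_correlation: float = 0.5  # corr of C/P and N/P within-region noise


@dataclass
class OtuParams:
    n_taxa_pool: int = 400
    base_richness: int = 220
    reads: int = 5000
    lognormal_sigma: float = 1.5


@dataclass
class RegionParams:
    # mean abundance (items per kg dry soil) by depth layer
    abundance: dict[str, float]
    # attribute family -> level -> log-tilt applied at delta = 1
    signature: dict[str, dict[str, float]]
    population: float  # 1e4 persons in the sampled prefecture
    meteorology: dict[str, float]
    # soil property -> depth layer -> (mean, sd)
    soil: dict[str, dict[str, tuple[float, float]]]


@dataclass
class SurveyConfig:
    regions: dict[str, RegionParams]
    base_composition: dict[str, dict[str, float]]
    replicates: int = 3
    soil_mass_g: float = 10.0
    # composition tilt applied to the subsoil layer in every region
    # (subsoil more fiber-pure and finer-grained than topsoil); shared
    # across regions, it gives regional communities a common depth block
    # structure
    depth_shift: float = 1.0
    planted: PlantedEffects = field(default_factory=PlantedEffects)
    otu: OtuParams = field(default_factory=OtuParams)
    negbin_dispersion: float | None = None  # None -> Poisson counts
    seed: int = 0


@dataclass
class SurveyBundle:
    particles: pd.DataFrame
    meta: pd.DataFrame
    covariates: pd.DataFrame
    otu: pd.DataFrame
    ground_truth: dict
    config: SurveyConfig
    seed: int


# Soil properties by region and depth: (mean, sd) in the units of the
# survey's soil table (pH unitless; SOC/POXC/POC g per kg; DOC/MBC mg per
# kg; ratios unitless).  DOC and MBC means are plausible paddy-soil
# values; the rest follow the survey's soil-property table.
_SOIL = {
    "SD": {
        "pH": (7.92, 0.10, 8.44, 0.03),
        "SOC": (9.40, 2.61, 7.03, 0.47),
        "POXC": (3.45, 0.05, 2.59, 0.37),
        "POC": (3.97, 0.01, 4.35, 0.66),
        "DOC": (62.0, 6.0, 48.0, 5.0),
        "MBC": (310.0, 30.0, 220.0, 25.0),
        "C/N": (13.49, 1.06, 14.52, 0.56),
        "C/P": (13.52, 1.50, 11.97, 0.82),
        "N/P": (1.04, 0.02, 0.82, 0.02),
    },
    "HE": {
        "pH": (7.83, 0.03, 7.88, 0.02),
        "SOC": (9.82, 1.05, 8.50, 0.22),
        "POXC": (2.76, 0.14, 3.99, 0.46),
        "POC": (1.68, 0.20, 1.95, 0.29),
        "DOC": (58.0, 6.0, 50.0, 5.0),
        "MBC": (290.0, 28.0, 240.0, 24.0),
        "C/N": (10.32, 0.99, 10.54, 0.11),
        "C/P": (15.18, 1.47, 13.17, 0.48),
        "N/P": (1.47, 0.02, 1.25, 0.04),
    },
    "TJ": {
        "pH": (8.12, 0.02, 8.37, 0.03),
        "SOC": (8.50, 0.52, 10.46, 0.24),
        "POXC": (3.23, 0.19, 4.61, 0.18),
        "POC": (3.21, 0.33, 3.41, 0.26),
        "DOC": (54.0, 5.0, 52.0, 5.0),
        "MBC": (270.0, 27.0, 230.0, 23.0),
        "C/N": (9.31, 0.35, 9.70, 0.14),
        "C/P": (16.87, 0.83, 16.76, 0.18),
        "N/P": (1.81, 0.03, 1.73, 0.04),
    },
    "HN": {
        "pH": (6.91, 0.10, 6.55, 0.06),
        "SOC": (16.51, 0.55, 15.54, 0.47),
        "POXC": (6.24, 0.05, 6.13, 0.32),
        "POC": (10.28, 0.40, 11.52, 1.00),
        "DOC": (88.0, 8.0, 80.0, 8.0),
        "MBC": (420.0, 40.0, 380.0, 38.0),
        "C/N": (11.99, 0.19, 11.90, 0.28),
        "C/P": (58.23, 1.70, 51.51, 2.36),
        "N/P": (4.86, 0.09, 4.33, 0.11),
    },
    "DB": {
        "pH": (5.49, 0.06, 5.46, 0.02),
        "SOC": (18.81, 0.84, 19.20, 0.65),
        "POXC": (4.58, 0.61, 7.61, 0.15),
        "POC": (15.41, 0.01, 7.01, 0.40),
        "DOC": (95.0, 9.0, 90.0, 9.0),
        "MBC": (450.0, 45.0, 430.0, 43.0),
        "C/N": (9.82, 0.25, 9.33, 0.28),
        "C/P": (34.09, 1.34, 33.95, 1.20),
        "N/P": (3.47, 0.05, 3.64, 0.03),
    },
}

# Regional annual climate (avg/min temperature degC, precipitation mm,
# solar radiation kWh m-2 day-1, wind speed m s-1) and population (1e4
# persons), plausible for the five rice regions.
_MET = {
    "SD": {"avg_temperature": 13.5, "min_temperature": 9.0, "precipitation": 650.0,
           "solar_radiation": 4.6, "wind_speed": 3.2},
    "HE": {"avg_temperature": 14.5, "min_temperature": 10.0, "precipitation": 700.0,
           "solar_radiation": 4.4, "wind_speed": 2.8},
    "TJ": {"avg_temperature": 12.5, "min_temperature": 8.0, "precipitation": 550.0,
           "solar_radiation": 4.8, "wind_speed": 3.5},
    "HN": {"avg_temperature": 17.5, "min_temperature": 14.0, "precipitation": 1400.0,
           "solar_radiation": 3.6, "wind_speed": 2.2},
    "DB": {"avg_temperature": 3.5, "min_temperature": -3.0, "precipitation": 550.0,
           "solar_radiation": 4.2, "wind_speed": 3.0},
}

_POPULATION = {"SD": 800.0, "HE": 1150.0, "TJ": 900.0, "HN": 1300.0, "DB": 700.0}

# Mean abundance (items per kg) by region and depth, inside the survey's
# printed 4,000-10,300 range with an overall mean near 6,400: highest in
# Hunan topsoil, lowest in Shandong topsoil, subsoil above topsoil in SD
# and HE and below it in TJ, HN and DB.
_ABUNDANCE = {
    "SD": {"0-20 cm": 4300.0, "20-40 cm": 5600.0},
    "HE": {"0-20 cm": 6300.0, "20-40 cm": 7200.0},
    "TJ": {"0-20 cm": 5400.0, "20-40 cm": 4800.0},
    "HN": {"0-20 cm": 10100.0, "20-40 cm": 7800.0},
    "DB": {"0-20 cm": 6600.0, "20-40 cm": 5200.0},
}

# Fixed per-region community signatures (log-tilts at delta = 1),
# mirroring the discriminant types the survey design plants: black MPs in
# HE, rayon/blue/other in HN, transparent in TJ, PE in DB, none in SD.
_SIGNATURES = {
    "SD": {},
    "HE": {"color": {"black": 0.8}},
    "TJ": {"color": {"transparent": 0.6}},
    "HN": {"polymer": {"Rayon": 0.5}, "color": {"blue": 0.8, "other": 0.8}},
    "DB": {"polymer": {"PE": 1.2}},
}

_BASE_COMPOSITION = {
    "size_class": {"<0.5 mm": 0.55, "0.5-1 mm": 0.25, "1-2 mm": 0.12, "2-5 mm": 0.08},
    "shape": {"fiber": 0.95, "pellet": 0.02, "fragment": 0.02, "foam": 0.005,
              "film": 0.005},
    "color": {"white": 0.12, "black": 0.30, "transparent": 0.35, "blue": 0.13,
              "other": 0.10},
    "polymer": {"Rayon": 0.45, "PE": 0.10, "PP": 0.07, "PP+PE": 0.04, "PET": 0.06,
                "Polyester": 0.20, "Acrylic": 0.03, "PS": 0.03, "PA": 0.02},
}


def default_config() -> SurveyConfig:
    """The study conditions: 5 regions x 2 depths x 3 replicates of 10 g
    soil, region mean abundances spanning the 4,000-10,300 items/kg band,
    fiber-dominated shapes (~95%), rayon-dominant polymers, <0.5 mm modal
    size, and the default planted regional community shift."""
    regions = {}
    for name in REGIONS:
        soil = {
            prop: {
                DEPTH_LAYERS[0]: (top_m, top_s),
                DEPTH_LAYERS[1]: (sub_m, sub_s),
            }
            for prop, (top_m, top_s, sub_m, sub_s) in _SOIL[name].items()
        }
        regions[name] = RegionParams(
            abundance=dict(_ABUNDANCE[name]),
            signature=copy.deepcopy(_SIGNATURES[name]),
            population=_POPULATION[name],
            meteorology=dict(_MET[name]),
            soil=soil,
        )
    return SurveyConfig(
        regions=regions,
        base_composition=copy.deepcopy(_BASE_COMPOSITION),
    )


def null_config() -> SurveyConfig:
    """All planted effects zero and all regions exchangeable in abundance
    and composition (covariates keep their regional values, so they can
    serve as independent x-variables in calibration runs)."""
    config = default_config()
    mean_abundance = float(
        np.mean([a for r in config.regions.values() for a in r.abundance.values()])
    )
    for region in config.regions.values():
        region.abundance = {d: mean_abundance for d in DEPTH_LAYERS}
    config.depth_shift = 0.0
    config.planted = PlantedEffects(
        community_shift=0.0,
        population_slope=0.0,
        chao1_association=0.0,
        soil_ratio_correlation=0.0,
    )
    return config


def perturb_config(config: SurveyConfig, effect_name: str, magnitude: float) -> SurveyConfig:
    """Copy of ``config`` differing only in the named planted effect."""
    if effect_name not in EFFECT_REGISTRY:
        raise ConfigError(
            f"unknown planted effect {effect_name!r}; known effects: "
            f"{sorted(EFFECT_REGISTRY)}"
        )
    out = copy.deepcopy(config)
    setattr(out.planted, EFFECT_REGISTRY[effect_name], float(magnitude))
    return out


# subsoil tilt at depth_shift = 1: more fiber-pure and finer-grained,
# darker (black up, transparent down), slightly more rayon
_DEPTH_SIGNATURE = {
    "shape": {"fiber": 1.0},
    "size_class": {"<0.5 mm": 0.3},
    "color": {"black": 0.6, "transparent": -0.4},
    "polymer": {"Rayon": 0.3},
}


def region_composition(
    config: SurveyConfig, region: str, depth: str | None = None
) -> dict[str, np.ndarray]:
    """Attribute probabilities for one region (and optionally one depth
    layer): base composition tilted by exp(delta * region signature),
    plus the shared subsoil tilt, then renormalised."""
    params = config.regions[region]
    delta = config.planted.community_shift
    subsoil = depth == DEPTH_LAYERS[1]
    out = {}
    for family, levels in _FAMILY_LEVELS.items():
        base = np.array([config.base_composition[family][lv] for lv in levels])
        tilt = np.array(
            [params.signature.get(family, {}).get(lv, 0.0) for lv in levels]
        )
        log_p = delta * tilt
        if subsoil:
            log_p = log_p + config.depth_shift * np.array(
                [_DEPTH_SIGNATURE.get(family, {}).get(lv, 0.0) for lv in levels]
            )
        p = base * np.exp(log_p)
        out[family] = p / p.sum()
    return out


def _validate(config: SurveyConfig) -> None:
    if config.replicates < 1:
        raise ConfigError("replicates must be >= 1")
    if config.soil_mass_g <= 0:
        raise ConfigError("soil_mass_g must be positive")
    if config.planted.community_shift < 0:
        raise ConfigError("community_shift (delta) must be >= 0")
    if config.negbin_dispersion is not None and config.negbin_dispersion <= 0:
        raise ConfigError("negbin_dispersion must be positive")
    for name, region in config.regions.items():
        for depth, lam in region.abundance.items():
            if lam <= 0:
                raise ConfigError(f"abundance for {name}/{depth} must be positive")
    for family, probs in config.base_composition.items():
        if any(p <= 0 for p in probs.values()):
            raise ConfigError(f"base composition for {family} must be positive")


def _sample_id(region: str, depth: str, replicate: int) -> str:
    layer = "T" if depth == DEPTH_LAYERS[0] else "S"
    return f"{region}-{layer}{replicate}"


def simulate_survey(config: SurveyConfig | None = None, seed: int | None = None) -> SurveyBundle:
    """Draw a complete survey bundle from the configured design.

    Per sample: particle count ~ Poisson(lambda_region,depth adjusted by
    the population slope, times soil mass in kg), optionally
    negative-binomial with the configured dispersion; particle attributes
    from the region's tilted multinomials; soil covariates from the
    region/depth normals (C/P and N/P noise correlated per the planted
    value); OTU richness tied to abundance by the planted association.
    """
    config = default_config() if config is None else config
    _validate(config)
    if seed is None:
        seed = config.seed
    root = np.random.SeedSequence(seed)
    rng_particles, rng_cov, rng_otu = (
        np.random.default_rng(s) for s in root.spawn(3)
    )

    mass_kg = config.soil_mass_g / 1000.0
    beta = config.planted.population_slope
    populations = {n: r.population for n, r in config.regions.items()}
    pop_center = float(np.mean(list(populations.values())))

    meta_rows, particle_frames = [], []
    expected_lambda = {}
    for region_name, region in config.regions.items():
        for depth in DEPTH_LAYERS:
            comp = region_composition(config, region_name, depth)
            lam = region.abundance[depth] + beta * (
                populations[region_name] - pop_center
            )
            lam = max(lam, 1.0)
            for rep in range(1, config.replicates + 1):
                sid = _sample_id(region_name, depth, rep)
                expected_lambda[sid] = lam
                mean_count = lam * mass_kg
                if config.negbin_dispersion is None:
                    count = int(rng_particles.poisson(mean_count))
                else:
                    k = config.negbin_dispersion
                    rate = rng_particles.gamma(shape=k, scale=mean_count / k)
                    count = int(rng_particles.poisson(rate))
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "region": region_name,
                        "depth_layer": depth,
                        "replicate": rep,
                        "soil_mass_g": config.soil_mass_g,
                    }
                )
                if count == 0:
                    continue
                draws = {"sample_id": np.repeat(sid, count),
                         "region": np.repeat(region_name, count),
                         "depth_layer": np.repeat(depth, count)}
                for family, levels in _FAMILY_LEVELS.items():
                    idx = rng_particles.choice(
                        len(levels), size=count, p=comp[family]
                    )
                    draws[family] = np.asarray(levels, dtype=object)[idx]
                particle_frames.append(pd.DataFrame(draws))
    meta = pd.DataFrame(meta_rows)
    particles = (
        pd.concat(particle_frames, ignore_index=True)
        if particle_frames
        else pd.DataFrame(
            columns=["sample_id", "region", "depth_layer", *_FAMILY_LEVELS]
        )
    )

    covariates = _draw_covariates(config, meta, rng_cov)
    abundance = (
        particles.groupby("sample_id").size().reindex(meta["sample_id"], fill_value=0)
        / mass_kg
    )
    otu = _draw_otu(config, meta, abundance.to_numpy(dtype=float), rng_otu)

    ground_truth = {
        "seed": int(seed),
        "expected_lambda": expected_lambda,
        "region_composition": {
            name: {
                depth: {
                    family: dict(zip(_FAMILY_LEVELS[family], probs.round(12).tolist()))
                    for family, probs in region_composition(config, name, depth).items()
                }
                for depth in DEPTH_LAYERS
            }
            for name in config.regions
        },
        "planted": dataclasses.asdict(config.planted),
        "population": populations,
        "soil_mass_g": config.soil_mass_g,
        "replicates": config.replicates,
    }
    return SurveyBundle(
        particles=particles,
        meta=meta,
        covariates=covariates,
        otu=otu,
        ground_truth=ground_truth,
        config=config,
        seed=int(seed),
    )


def _draw_covariates(config: SurveyConfig, meta: pd.DataFrame, rng) -> pd.DataFrame:
    rho = config.planted.soil_ratio_correlation
    rows = []
    for _, m in meta.iterrows():
        region = config.regions[m["region"]]
        row: dict[str, float] = {}
        z_cp, z_np_raw = rng.standard_normal(2)
        z_np = rho * z_cp + np.sqrt(max(1.0 - rho * rho, 0.0)) * z_np_raw
        for prop, by_depth in region.soil.items():
            mean, sd = by_depth[m["depth_layer"]]
            if prop == "C/P":
                row[prop] = mean + sd * z_cp
            elif prop == "N/P":
                row[prop] = mean + sd * z_np
            else:
                row[prop] = mean + sd * rng.standard_normal()
        row.update(region.meteorology)
        row["population"] = region.population
        rows.append(row)
    out = pd.DataFrame(rows, index=pd.Index(meta["sample_id"], name="sample_id"))
    return out


def _draw_otu(config: SurveyConfig, meta: pd.DataFrame, abundance: np.ndarray, rng) -> pd.DataFrame:
    p = config.otu
    # one shared lognormal species-abundance pool per bundle
    pool = rng.lognormal(mean=0.0, sigma=p.lognormal_sigma, size=p.n_taxa_pool)
    sd = abundance.std()
    z = (abundance - abundance.mean()) / sd if sd > 0 else np.zeros_like(abundance)
    gamma = config.planted.chao1_association
    counts = np.zeros((len(meta), p.n_taxa_pool), dtype=np.int64)
    for i in range(len(meta)):
        richness = int(np.clip(round(p.base_richness * (1.0 + gamma * z[i] / 2.0)),
                               20, p.n_taxa_pool))
        taxa = rng.choice(p.n_taxa_pool, size=richness, replace=False)
        weights = pool[taxa]
        counts[i, taxa] = rng.multinomial(p.reads, weights / weights.sum())
    return pd.DataFrame(
        counts,
        index=pd.Index(meta["sample_id"], name="sample_id"),
        columns=[f"OTU{j + 1}" for j in range(p.n_taxa_pool)],
    )


def write_bundle(bundle: SurveyBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as the package's TSV formats plus a ground-truth
    sidecar and the resolved config (both JSON)."""
    from . import io as mio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "particles": outdir / "particles.tsv",
        "meta": outdir / "sample_meta.tsv",
        "covariates": outdir / "covariates.tsv",
        "otu": outdir / "otu_table.tsv",
        "ground_truth": outdir / "ground_truth.json",
        "config": outdir / "config.json",
    }
    mio.write_particle_table(bundle.particles, paths["particles"])
    mio.write_sample_meta(bundle.meta, paths["meta"])
    mio.write_covariates(bundle.covariates, paths["covariates"])
    mio.write_otu_table(bundle.otu, paths["otu"])
    paths["ground_truth"].write_text(
        json.dumps(bundle.ground_truth, indent=2, sort_keys=True) + "\n"
    )
    paths["config"].write_text(
        json.dumps(config_to_dict(bundle.config), indent=2, sort_keys=True) + "\n"
    )
    return paths


def config_to_dict(config: SurveyConfig) -> dict:
    return dataclasses.asdict(config)
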