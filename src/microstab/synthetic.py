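"""Synthetic factorial pulse-perturbation mesocosm studies with latent ground truth.

The generator emulates the statistical structure the stability analysis
assumes: niche-specific feature pools with a shared core, replicate-level
compositional heterogeneity (Dirichlet), log-normal sequencing depth with
multinomial counting noise, a multiplicative pulse effect on a subset of
responsive features directly after stress, and partial-to-full reversal of
that effect after the recovery period.  Every study carries its noise-free
latent compositions, and the ground-truth resistance/resilience table is by
definition the stability module run on those latents.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import derive_seed, map_features_to_functions
from .tables import (FeatureTable, NICHES, SampleMetadata, TaxonomyMap,
                     TIMEPOINTS, TREATMENTS, ValidationError)

__all__ = ["SimulationConfig", "SimulatedStudy", "simulate_study",
           "latent_truth", "calibrate_effect_size"]

_EXCLUDED_LINEAGES = (
    ("Bacteria", "Cyanobacteria", "Cyanobacteriia", "Chloroplast", "", ""),
    ("Bacteria", "Cyanobacteria", "Cyanobacteriia", "Synechococcales", "Cyanobiaceae", "Synechococcus"),
    ("Eukaryota", "", "", "", "", "Mitochondria"),
)
_PHYLA = ("Proteobacteria", "Bacteroidota", "Actinobacteriota",
          "Firmicutes", "Verrucomicrobiota", "Planctomycetota")


@dataclass
class SimulationConfig:
    """Parameters of the simulated pulse-perturbation design.

    Defaults emulate a mesocosm amplicon study: three algal-associated
    niches, four treatment arms (control plus three perturbations) sampled
    before stress, directly after the 3-day pulse and after recovery, three
    replicates per condition, ~28k reads per sample with a heavy right tail.
    """

    n_features_per_niche: int = 500
    core_fraction: float = 0.3
    niches: tuple[str, ...] = ("endo", "epi", "rhizo")
    treatments: tuple[str, ...] = TREATMENTS
    n_replicates: int = 3
    n_experiments: int = 1
    #: Dirichlet concentration; lower = more replicate heterogeneity.  The
    #: default puts mean within-condition Bray–Curtis near 0.4, typical of
    #: controlled mesocosm replicates.
    base_concentration: float = 300.0
    depth_mean: float = 28000.0
    #: log-scale sigma of the log-normal depth distribution.
    depth_dispersion: float = 0.5
    #: per-treatment log-fold shift of responsive features at T1.
    effect_size: float = 2.0
    responsive_fraction: float = 0.1
    #: fraction of the T1 shift reversed at T2 (1 = full recovery).
    recovery: float = 0.5
    #: log-scale temporal jitter applied to every condition, controls included.
    drift: float = 0.05
    n_functions: int = 200
    function_map_density: float = 0.05
    #: share of features given cyanobacterial/organellar lineages.
    excluded_lineage_fraction: float = 0.05
    #: spread of log base abundances (rank-abundance steepness).
    base_log_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("core_fraction", "responsive_fraction", "recovery",
                     "function_map_density", "excluded_lineage_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if self.depth_mean <= 0:
            raise ValidationError("depth_mean must be positive")
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        if self.base_concentration <= 0:
            raise ValidationError("base_concentration must be positive")
        unknown = [n for n in self.niches if n not in NICHES]
        if unknown:
            raise ValidationError(f"unknown niches {unknown}")
        unknown = [t for t in self.treatments if t not in TREATMENTS]
        if unknown:
            raise ValidationError(f"unknown treatments {unknown}")
        if "control" not in self.treatments:
            raise ValidationError("treatments must include 'control'")


@dataclass
class SimulatedStudy:
    """A generated study: observed tables, metadata, and latent ground truth."""

    config: SimulationConfig
    counts_table: FeatureTable
    function_table: FeatureTable
    metadata: SampleMetadata
    taxonomy: TaxonomyMap
    #: noise-free per-sample relative abundances (features × samples).
    latent_compositions: FeatureTable
    function_map: pd.DataFrame
    #: (niche, treatment) → feature ids truly shifted by the pulse.
    responsive_features: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    #: stability profile computed on the latent compositions.
    truth: pd.DataFrame = field(repr=False, default=None)


def _softmax(log_abund: np.ndarray) -> np.ndarray:
    z = np.exp(log_abund - log_abund.max())
    return z / z.sum()


def _feature_pools(cfg: SimulationConfig) -> tuple[list[str], dict[str, np.ndarray]]:
    """Global feature list and per-niche index arrays (core shared by all)."""
    n_core = int(round(cfg.core_fraction * cfg.n_features_per_niche))
    n_private = cfg.n_features_per_niche - n_core
    features = [f"OTU_{i + 1:05d}" for i in range(n_core)]
    pools = {}
    offset = n_core
    for niche in cfg.niches:
        private = [f"OTU_{offset + i + 1:05d}" for i in range(n_private)]
        features.extend(private)
        pools[niche] = np.concatenate([
            np.arange(n_core),
            np.arange(offset, offset + n_private),
        ]).astype(int)
        offset += n_private
    return features, pools


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a complete study; bit-identical for identical configs."""
    cfg = config
    features, pools = _feature_pools(cfg)
    n_total = len(features)
    rng = np.random.default_rng(derive_seed(cfg.seed, "simulate"))

    # per-niche base log-abundances over the niche pool
    base_log = {niche: rng.normal(0.0, cfg.base_log_sigma, size=len(pools[niche]))
                for niche in cfg.niches}

    # per (niche, treatment) responsive features and shift signs
    shift_sign: dict[tuple[str, str], np.ndarray] = {}
    for niche in cfg.niches:
        pool_size = len(pools[niche])
        n_resp = int(round(cfg.responsive_fraction * pool_size))
        for treat in cfg.treatments:
            signs = np.zeros(pool_size)
            if treat != "control" and n_resp:
                idx = rng.choice(pool_size, size=n_resp, replace=False)
                half = n_resp // 2
                signs[idx[:half]] = -1.0
                signs[idx[half:]] = 1.0
            shift_sign[(niche, treat)] = signs

    # temporal drift shared by every condition of a niche at a timepoint
    drift_vec = {
        (niche, tp): (np.zeros(len(pools[niche])) if tp == "T0"
                      else rng.normal(0.0, cfg.drift, size=len(pools[niche])))
        for niche in cfg.niches for tp in TIMEPOINTS
    }
    effect_scale = {"T0": 0.0, "T1": 1.0, "T2": 1.0 - cfg.recovery}

    sample_ids, meta_rows = [], []
    latent = np.zeros((n_total, 0))
    latent_cols = []
    counts_cols = []
    for niche in cfg.niches:
        pool = pools[niche]
        for treat in cfg.treatments:
            for tp in TIMEPOINTS:
                log_mean = (base_log[niche]
                            + drift_vec[(niche, tp)]
                            + shift_sign[(niche, treat)]
                            * cfg.effect_size * effect_scale[tp])
                mean_comp = _softmax(log_mean)
                alpha = cfg.base_concentration * mean_comp
                for exp in range(1, cfg.n_experiments + 1):
                    for rep in range(1, cfg.n_replicates + 1):
                        sid = f"{niche}.{treat}.{tp}.e{exp}.r{rep}"
                        srng = np.random.default_rng(
                            derive_seed(cfg.seed, "sample", sid))
                        comp = srng.dirichlet(alpha)
                        full = np.zeros(n_total)
                        full[pool] = comp
                        if cfg.depth_dispersion > 0:
                            depth = int(max(1, round(srng.lognormal(
                                np.log(cfg.depth_mean) - cfg.depth_dispersion**2 / 2,
                                cfg.depth_dispersion))))
                        else:
                            depth = int(round(cfg.depth_mean))
                        counts = np.zeros(n_total)
                        counts[pool] = srng.multinomial(depth, comp)
                        sample_ids.append(sid)
                        latent_cols.append(full)
                        counts_cols.append(counts)
                        meta_rows.append({
                            "sample_id": sid, "niche": niche, "treatment": treat,
                            "timepoint": tp, "experiment": f"e{exp}",
                            "replicate": f"r{rep}", "run": "run1",
                        })

    counts_df = pd.DataFrame(np.column_stack(counts_cols), index=features,
                             columns=sample_ids)
    latent_df = pd.DataFrame(np.column_stack(latent_cols), index=features,
                             columns=sample_ids)
    counts_table = FeatureTable(counts_df, scale="counts", axis_kind="taxonomic")
    latent_table = FeatureTable(latent_df, scale="relative", axis_kind="taxonomic")
    metadata = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))

    taxonomy = _synthetic_taxonomy(features, cfg,
                                   np.random.default_rng(derive_seed(cfg.seed, "taxonomy")))
    function_map = _synthetic_function_map(
        features, cfg, np.random.default_rng(derive_seed(cfg.seed, "functions")))
    function_table = map_features_to_functions(counts_table, function_map)

    responsive = {
        (niche, treat): [features[pools[niche][i]]
                         for i in np.flatnonzero(signs)]
        for (niche, treat), signs in shift_sign.items() if treat != "control"
    }
    study = SimulatedStudy(
        config=cfg, counts_table=counts_table, function_table=function_table,
        metadata=metadata, taxonomy=taxonomy, latent_compositions=latent_table,
        function_map=function_map, responsive_features=responsive, truth=None,
    )
    study.truth = latent_truth(study)
    return study


def _synthetic_taxonomy(features: list[str], cfg: SimulationConfig,
                        rng: np.random.Generator) -> TaxonomyMap:
    n_excluded = int(round(cfg.excluded_lineage_fraction * len(features)))
    excluded_idx = set(rng.choice(len(features), size=n_excluded, replace=False).tolist())
    lineages, confidence = {}, {}
    for i, fid in enumerate(features):
        if i in excluded_idx:
            lineage = _EXCLUDED_LINEAGES[int(rng.integers(len(_EXCLUDED_LINEAGES)))]
        else:
            phylum = _PHYLA[int(rng.integers(len(_PHYLA)))]
            lineage = ("Bacteria", phylum, f"{phylum}_class",
                       f"Order_{int(rng.integers(40)) + 1}",
                       f"Family_{int(rng.integers(120)) + 1}",
                       f"Genus_{int(rng.integers(400)) + 1}")
        lineages[fid] = lineage
        confidence[fid] = tuple(
            round(float(c), 3) for c in np.clip(rng.uniform(0.9, 1.0, len(lineage)), 0, 1)
        )
    return TaxonomyMap(lineages=lineages, confidence=confidence)


def _synthetic_function_map(features: list[str], cfg: SimulationConfig,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Sparse non-negative function × feature weights; every feature mapped."""
    n_fun = cfg.n_functions
    m = np.zeros((n_fun, len(features)))
    for j in range(len(features)):
        n_hits = max(1, rng.binomial(n_fun, cfg.function_map_density))
        hits = rng.choice(n_fun, size=n_hits, replace=False)
        m[hits, j] = rng.lognormal(0.0, 0.5, size=n_hits)
    return pd.DataFrame(m, index=[f"K{i + 1:05d}" for i in range(n_fun)],
                        columns=features)


def latent_truth(study: SimulatedStudy) -> pd.DataFrame:
    """Ground-truth stability profile: the stability module run on the latent
    (noise-free) compositions.  Invariant to sequencing depth by construction."""
    from .stability import stability_profile

    return stability_profile(study.latent_compositions, study.metadata)


def calibrate_effect_size(target_rs: float, config: SimulationConfig,
                          deltas: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0, 1.25,
                                                       1.5, 2.0, 2.5, 3.0, 4.0),
                          n_seeds: int = 3) -> float:
    """Effect size whose mean latent-truth resistance is closest to a target.

    Evaluates a fixed grid of log-fold shifts, averaging latent-truth RS over
    treatments, niches and a few seeds, and returns the best grid point.
    """
    best_delta, best_err = deltas[0], np.inf
    for delta in deltas:
        vals = []
        for s in range(n_seeds):
            cfg = replace(config, effect_size=delta,
                          seed=derive_seed(config.seed, "calibrate", str(delta), str(s)))
            truth = simulate_study(cfg).truth
            vals.extend(truth.loc[truth["RS_defined"], "RS"].tolist())
        err = abs(float(np.mean(vals)) - target_rs)
        if err < best_err:
            best_delta, best_err = delta, err
    return best_delta
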