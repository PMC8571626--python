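"""End-to-end orchestration: simulate/load → preprocess → distances →
stability → PERMANOVA/indicators, with a machine-readable run log.

The pipeline is configured by a plain mapping (usually parsed from YAML):

.. code-block:: yaml

    seed: 1
    simulate:            # either a simulation block ...
      n_features_per_niche: 200
    # inputs:            # ... or paths to user data
    #   table: counts.tsv
    #   metadata: meta.tsv
    #   taxonomy: tax.tsv
    #   function_table: ko.tsv
    preprocess:
      depth: 2821
    permanova:
      terms: [niche, timepoint, treatment]
      n_perm: 999
    indval:
      group: treatment_timepoint
      n_perm: 199
      max_order: 1
    pcoa:
      k: 2

One global seed drives every stage; stage seeds are derived by stable
hashing of (seed, stage name), so reruns of an identical config produce
byte-identical TSV outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import bray_curtis, pcoa, write_distance_matrix
from .perm_stats import indval, permanova
from .preprocess import (DEFAULT_EXCLUSION_TERMS, derive_seed, filter_taxa,
                         rarefy, to_relative)
from .stability import stability_profile
from .synthetic import SimulationConfig, simulate_study
from .tables import (FeatureTable, SampleMetadata, read_feature_table,
                     read_metadata, read_taxonomy, write_feature_table,
                     write_metadata, write_taxonomy)

__all__ = ["run_all", "load_config", "PipelineError"]

logger = logging.getLogger(__name__)

_DEFAULT_TERMS = ["niche", "run", "experiment", "timepoint", "treatment", "replicate"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError(f"config {path}: expected a mapping at top level")
    return cfg


def _validate_config(config: dict) -> None:
    if ("simulate" in config) == ("inputs" in config):
        raise PipelineError(
            "config must contain exactly one of 'simulate' or 'inputs'")
    if "inputs" in config:
        inputs = config["inputs"]
        for key in ("table", "metadata"):
            if key not in inputs:
                raise PipelineError(f"config inputs: missing required path {key!r}")
        for key, p in inputs.items():
            if not Path(p).exists():
                raise PipelineError(f"config inputs: {key} path not found: {p}")


def _compose_factor(metadata: SampleMetadata, name: str) -> pd.Series:
    """A metadata column, or an underscore-composed interaction of columns."""
    frame = metadata.frame
    if name in frame.columns:
        return frame[name]
    parts = name.split("_")
    if all(p in frame.columns for p in parts) and len(parts) > 1:
        return frame[parts].astype(str).agg("_".join, axis=1).rename(name)
    raise PipelineError(f"unknown grouping factor {name!r}")


def run_all(config: dict, out_dir: str | Path) -> dict:
    """Run the full analysis; returns the run log (also written as JSON).

    Output layout: input tables (for simulated studies), the filtered and
    rarefied table(s), one distance matrix and PCoA coordinate file per
    niche × axis, the stability profile, PERMANOVA and indicator tables, and
    ``run_log.json`` recording seeds, versions and dropped samples.
    """
    _validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    log: dict = {"microstab_version": __version__, "seed": seed, "stages": {}}

    # ------------------------------------------------------------------ inputs
    taxonomy = None
    function_table = None
    if "simulate" in config:
        stage_seed = derive_seed(seed, "simulate")
        sim_cfg = SimulationConfig(**{**config["simulate"], "seed": stage_seed})
        try:
            study = simulate_study(sim_cfg)
        except Exception as exc:
            raise PipelineError(f"stage simulate: {exc}") from exc
        table, metadata, taxonomy = study.counts_table, study.metadata, study.taxonomy
        function_table = study.function_table
        write_feature_table(table, out / "counts.tsv")
        write_feature_table(function_table, out / "functions.tsv")
        write_metadata(metadata, out / "metadata.tsv")
        write_taxonomy(taxonomy, out / "taxonomy.tsv")
        study.truth.to_csv(out / "latent_truth.tsv", sep="\t", index=False,
                           lineterminator="\n")
        log["stages"]["simulate"] = {"seed": stage_seed,
                                     "n_samples": table.n_samples,
                                     "n_features": table.n_features}
    else:
        inputs = config["inputs"]
        try:
            table = read_feature_table(inputs["table"])
            metadata = read_metadata(inputs["metadata"])
            if "taxonomy" in inputs:
                taxonomy = read_taxonomy(inputs["taxonomy"])
            if "function_table" in inputs:
                function_table = read_feature_table(inputs["function_table"],
                                                    axis_kind="functional")
        except Exception as exc:
            raise PipelineError(f"stage load-inputs: {exc}") from exc

    # -------------------------------------------------------------- preprocess
    pp = config.get("preprocess", {})
    stage_seed = derive_seed(seed, "preprocess")
    try:
        removed = 0
        if taxonomy is not None:
            fres = filter_taxa(table, taxonomy,
                               tuple(pp.get("exclude", DEFAULT_EXCLUSION_TERMS)))
            table = fres.table
            removed = fres.n_removed
        depth = int(pp.get("depth", 2821))
        rres = rarefy(table, depth, stage_seed)
        table = rres.table
        write_feature_table(table, out / "table.filtered_rarefied.tsv")
        rel = to_relative(table)
        write_feature_table(rel, out / "table.relative.tsv")
        if function_table is not None:
            fvals = function_table.values
            if np.allclose(fvals, np.rint(fvals)):
                fdepth = int(pp.get("function_depth",
                                    int(function_table.sample_sums().min())))
                function_table = rarefy(function_table, fdepth, stage_seed).table
            write_feature_table(function_table, out / "functions.preprocessed.tsv")
    except Exception as exc:
        raise PipelineError(f"stage preprocess: {exc}") from exc
    log["stages"]["preprocess"] = {
        "seed": stage_seed, "depth": depth, "removed_taxa": removed,
        "dropped_samples": rres.dropped_samples,
        "pruned_features": len(rres.pruned_features),
    }

    metadata = metadata.subset([s for s in metadata.sample_ids
                                if s in set(table.sample_ids)])

    # ------------------------------------------------- distances & ordination
    k = int(config.get("pcoa", {}).get("k", 2))
    tables_by_axis = {"taxonomic": rel}
    if function_table is not None:
        tables_by_axis["functional"] = to_relative(function_table)
    try:
        for axis, axis_table in tables_by_axis.items():
            for niche in pd.unique(metadata.frame["niche"]):
                ids = [s for s in metadata.samples_where(niche=niche)
                       if s in set(axis_table.sample_ids)]
                if len(ids) < 3:
                    continue
                dm = bray_curtis(axis_table.select_samples(ids))
                write_distance_matrix(dm, out / f"dm.{axis}.{niche}.tsv")
                res = pcoa(dm, k=min(k, len(ids) - 1))
                res.coordinates.to_csv(out / f"pcoa.{axis}.{niche}.tsv",
                                       sep="\t", lineterminator="\n")
    except Exception as exc:
        raise PipelineError(f"stage distances: {exc}") from exc

    # --------------------------------------------------------------- stability
    try:
        profile = stability_profile(rel, metadata,
                                    function_table=tables_by_axis.get("functional"))
        profile.to_csv(out / "stability_profile.tsv", sep="\t", index=False,
                       lineterminator="\n")
    except Exception as exc:
        raise PipelineError(f"stage stability: {exc}") from exc
    log["stages"]["stability"] = {"n_rows": int(len(profile))}

    # --------------------------------------------------------------- permanova
    pv = config.get("permanova", {})
    stage_seed = derive_seed(seed, "permanova")
    terms = pv.get("terms")
    if terms is None:
        terms = [t for t in _DEFAULT_TERMS
                 if t in metadata.frame.columns
                 and metadata.frame[t].nunique(dropna=True) >= 2]
    try:
        dm_all = bray_curtis(rel)
        pres = permanova(dm_all, metadata, terms=list(terms),
                         n_perm=int(pv.get("n_perm", 999)), seed=stage_seed)
        pres.table.to_csv(out / "permanova.tsv", sep="\t", lineterminator="\n")
    except Exception as exc:
        raise PipelineError(f"stage permanova: {exc}") from exc
    log["stages"]["permanova"] = {"seed": stage_seed, "terms": list(terms),
                                  "n_perm": pres.n_permutations}

    # ------------------------------------------------------------------ indval
    iv = config.get("indval", {})
    stage_seed = derive_seed(seed, "indval")
    group = iv.get("group", "treatment_timepoint")
    try:
        factor = _compose_factor(metadata, group)
        ordered = rel.select_samples(list(factor.index))
        ires = indval(ordered, factor.to_numpy(),
                      max_order=int(iv.get("max_order", 1)),
                      n_perm=int(iv.get("n_perm", 199)), seed=stage_seed)
        ires.to_csv(out / "indval.tsv", sep="\t", index=False, lineterminator="\n")
    except Exception as exc:
        raise PipelineError(f"stage indval: {exc}") from exc
    log["stages"]["indval"] = {"seed": stage_seed, "group": group,
                               "n_perm": ires.attrs["n_permutations"]}

    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return log
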