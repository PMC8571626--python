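"""Filtering, rarefaction, compositional normalisation and table summaries.

The preprocessing chain mirrors standard 16S amplicon practice: remove
lineages that are not free-living prokaryotes (cyanobacteria, chloroplast and
mitochondrial reads), rarefy every sample to a common depth by subsampling
reads without replacement, then convert to relative abundances before any
dissimilarity-based analysis.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import FeatureTable, SampleMetadata, TaxonomyMap

__all__ = [
    "DEFAULT_EXCLUSION_TERMS",
    "TaxonFilterResult",
    "RarefactionResult",
    "SharedFeatureResult",
    "filter_taxa",
    "rarefy",
    "to_relative",
    "richness",
    "shared_feature_counts",
    "map_features_to_functions",
    "derive_seed",
]

logger = logging.getLogger(__name__)

#: Lineage substrings removed by default: photosynthetic/organellar reads.
DEFAULT_EXCLUSION_TERMS = ("Cyanobacteria", "Chloroplast", "Mitochondria", "Mitochondrion")


@dataclass
class TaxonFilterResult:
    """Outcome of a lineage-based feature filter."""

    table: FeatureTable
    removed_features: list[str]
    removed_reads: float

    @property
    def n_removed(self) -> int:
        return len(self.removed_features)


def filter_taxa(table: FeatureTable, taxonomy: TaxonomyMap,
                exclusion_terms: tuple[str, ...] | list[str] = DEFAULT_EXCLUSION_TERMS,
                ) -> TaxonFilterResult:
    """Remove features whose lineage contains any exclusion term.

    Matching is case-insensitive and substring-based across all ranks, because
    lineage strings from different classifiers label ranks inconsistently.
    Features without a taxonomy entry are retained.  Idempotent.
    """
    terms = [t.lower() for t in exclusion_terms]
    removed = []
    for fid in table.feature_ids:
        if fid in taxonomy:
            lineage = taxonomy.lineage_string(fid).lower()
            if any(term in lineage for term in terms):
                removed.append(fid)
    keep = [fid for fid in table.feature_ids if fid not in set(removed)]
    removed_reads = float(table.data.loc[removed].to_numpy().sum()) if removed else 0.0
    out = FeatureTable(table.data.loc[keep].copy(), scale=table.scale,
                       axis_kind=table.axis_kind)
    if out.n_features == 0:
        warnings.warn("filter_taxa removed every feature", stacklevel=2)
    logger.info("filter_taxa: removed %d features (%.0f reads)",
                len(removed), removed_reads)
    return TaxonFilterResult(table=out, removed_features=removed,
                             removed_reads=removed_reads)


@dataclass
class RarefactionResult:
    """Outcome of rarefaction: the subsampled table plus bookkeeping."""

    table: FeatureTable
    depth: int
    dropped_samples: list[str]
    pruned_features: list[str] = field(default_factory=list)


def derive_seed(seed: int, *tokens: str) -> int:
    """Derive a sub-stream seed from a global seed and string tokens.

    Stable across runs and platforms (SHA-256 based), independent of sample
    order, and below 2**31.
    """
    digest = hashlib.sha256(("\x1f".join([str(seed), *tokens])).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rarefy(table: FeatureTable, depth: int, seed: int,
           prune_empty_features: bool = True) -> RarefactionResult:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each retained column is a multivariate-hypergeometric draw from its count
    vector; samples with fewer than ``depth`` total reads are dropped (and
    logged), never padded.  Per-sample RNG streams are derived by stable
    hashing of (seed, sample_id), so the result does not depend on sample
    order.  Features left with zero total count are pruned by default.
    """
    if table.scale != "counts":
        raise ValueError("rarefy requires a counts-scale table")
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    counts = np.rint(table.values).astype(np.int64)
    if not np.allclose(counts, table.values, atol=1e-6):
        raise ValueError("rarefy requires integer counts")
    totals = counts.sum(axis=0)
    kept_cols, dropped = [], []
    out = {}
    for j, sid in enumerate(table.sample_ids):
        if totals[j] < depth:
            dropped.append(sid)
            continue
        if totals[j] == depth:
            out[sid] = counts[:, j]
        else:
            rng = np.random.default_rng(derive_seed(seed, "rarefy", sid))
            out[sid] = rng.multivariate_hypergeometric(counts[:, j], depth)
        kept_cols.append(sid)
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    df = pd.DataFrame(
        {sid: out[sid] for sid in kept_cols},
        index=table.data.index,
        dtype=float,
    )
    if not kept_cols:
        df = pd.DataFrame(index=table.data.index, dtype=float)
    pruned: list[str] = []
    if prune_empty_features and df.shape[1]:
        empty = df.sum(axis=1) == 0
        pruned = [str(i) for i in df.index[empty]]
        if pruned:
            logger.info("rarefy: pruned %d features with zero total after rarefaction",
                        len(pruned))
        df = df.loc[~empty]
    result_table = FeatureTable(df, scale="counts", axis_kind=table.axis_kind)
    return RarefactionResult(table=result_table, depth=depth,
                             dropped_samples=dropped, pruned_features=pruned)


def to_relative(table: FeatureTable) -> FeatureTable:
    """Compositional transform: divide each sample column by its total."""
    sums = table.values.sum(axis=0)
    zero = [sid for sid, s in zip(table.sample_ids, sums) if s == 0]
    if zero:
        raise ValueError(f"cannot normalise all-zero samples: {zero[:5]}")
    df = table.data.div(table.data.sum(axis=0), axis=1)
    return FeatureTable(df, scale="relative", axis_kind=table.axis_kind)


def richness(table: FeatureTable) -> pd.Series:
    """Number of features with non-zero abundance, per sample."""
    return (table.data > 0).sum(axis=0).astype(int)


@dataclass
class SharedFeatureResult:
    """Per-group presence counts and exact Venn-cell counts.

    ``venn`` maps a sorted tuple of group levels to the number of features
    present in exactly that set of groups (and no other).
    """

    per_group: pd.Series
    venn: dict[tuple[str, ...], int]

    def shared_by_all(self) -> int:
        """Features present in every group (the innermost Venn cell)."""
        full = tuple(sorted(self.per_group.index))
        return self.venn.get(full, 0)


def shared_feature_counts(table: FeatureTable, metadata: SampleMetadata,
                          group_var: str) -> SharedFeatureResult:
    """Presence-based feature sharing between levels of a metadata factor.

    A feature is present in a group if it is > 0 in any sample of that group.
    """
    if group_var not in metadata.frame.columns:
        raise KeyError(f"unknown metadata factor {group_var!r}")
    meta = metadata.frame.loc[[s for s in table.sample_ids if s in metadata.frame.index]]
    groups = sorted(meta[group_var].dropna().unique())
    presence = {}
    for g in groups:
        samples = [str(i) for i in meta.index[meta[group_var] == g]]
        presence[g] = (table.data[samples] > 0).any(axis=1)
    per_group = pd.Series({g: int(p.sum()) for g, p in presence.items()})
    membership = pd.DataFrame(presence)  # features × groups booleans
    venn: dict[tuple[str, ...], int] = {}
    present_any = membership.any(axis=1)
    for _, row in membership.loc[present_any].iterrows():
        cell = tuple(sorted(g for g in groups if row[g]))
        venn[cell] = venn.get(cell, 0) + 1
    return SharedFeatureResult(per_group=per_group, venn=venn)


def map_features_to_functions(table: FeatureTable, mapping: pd.DataFrame,
                              ) -> FeatureTable:
    """Project a taxonomic table onto functions via a linear weight matrix.

    ``mapping`` is function × feature with non-negative weights; its columns
    must cover every feature of the table.  Returns a functional table with
    the same samples: ``functions = M · features``.
    """
    missing = [f for f in table.feature_ids if f not in mapping.columns]
    if missing:
        raise ValueError(f"mapping does not cover features: {missing[:5]}")
    m = mapping.loc[:, table.feature_ids].to_numpy(dtype=float)
    if m.size and m.min() < 0:
        raise ValueError("mapping weights must be non-negative")
    values = m @ table.values
    df = pd.DataFrame(values, index=[str(i) for i in mapping.index],
                      columns=table.sample_ids)
    # weighted sums are abundance-like even for relative input, never simplex-closed
    return FeatureTable(df, scale="counts", axis_kind="functional")
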