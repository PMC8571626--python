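"""Community resistance and resilience from distance-to-control contrasts.

The response variable is Bray–Curtis dissimilarity to the control community,
evaluated at two timepoints of a pulse-perturbation design: directly after
the stress (T1) and after the recovery period (T2).  Within a stratum
(a morphological niche, on either the taxonomic or the functional axis) and
for each treatment:

* ``C_t`` — mean pairwise dissimilarity among control replicates at
  timepoint *t*: the control level of the distance response.
* ``D_t`` — mean dissimilarity over all treatment-replicate × control-replicate
  pairs at timepoint *t*.

The Orwin–Wardle indices are then

* resistance   RS = 1 − 2·|C1 − D1| / (C1 + |C1 − D1|)
* resilience   RL = 2·|C1 − D1| / (|C1 − D1| + |C2 − D2|) − 1

RS = 1 means the perturbed community is indistinguishable from controls
immediately after stress; RL = 1 means the initial displacement has fully
closed by the recovery timepoint, RL < 0 means it keeps growing.  Both lie
in [−1, 1] when defined.  Undefined cases (no displacement at either
timepoint for RL; C1 = D1 = 0 for RS) are flagged, never coerced.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .preprocess import to_relative
from .tables import FeatureTable, SampleMetadata, TREATMENTS

__all__ = [
    "ControlContrast",
    "StabilityIndices",
    "resistance_index",
    "resilience_index",
    "stability_indices",
    "control_contrasts",
    "stability_profile",
]


@dataclass
class ControlContrast:
    """The (C1, D1, C2, D2) quadruple for one stratum × treatment."""

    niche: str
    treatment: str
    axis_kind: str
    C1: float
    D1: float
    C2: float
    D2: float
    valid: bool
    replicate_distances: dict[str, list[float]] = field(default_factory=dict)
    reason: str | None = None


@dataclass
class StabilityIndices:
    RS: float
    RL: float
    RS_defined: bool
    RL_defined: bool


def resistance_index(C1: float, D1: float) -> float:
    """RS = 1 − 2|C1−D1| / (C1 + |C1−D1|); NaN when C1 = D1 = 0.

    Equals 1 when the treatment sits at the control baseline (D1 = C1), 0 when
    the displacement equals the baseline itself, and approaches −1 as the
    displacement grows without bound.  Values below 0 are reported as-is,
    never clamped.
    """
    if C1 < 0 or D1 < 0:
        raise ValueError("C1 and D1 must be non-negative")
    delta = abs(C1 - D1)
    denom = C1 + delta
    if denom == 0.0:
        return math.nan
    return 1.0 - 2.0 * delta / denom


def resilience_index(C1: float, D1: float, C2: float, D2: float) -> float:
    """RL = 2|C1−D1| / (|C1−D1| + |C2−D2|) − 1; NaN for a fully resistant community.

    Positive values mean the displacement shrank over the recovery period,
    negative values mean the community is still diverging from controls.
    """
    if min(C1, D1, C2, D2) < 0:
        raise ValueError("contrast values must be non-negative")
    d1 = abs(C1 - D1)
    d2 = abs(C2 - D2)
    if d1 == 0.0 and d2 == 0.0:
        return math.nan
    return 2.0 * d1 / (d1 + d2) - 1.0


def stability_indices(C1: float, D1: float, C2: float, D2: float) -> StabilityIndices:
    """Both indices with explicit defined-ness flags."""
    rs = resistance_index(C1, D1)
    rl = resilience_index(C1, D1, C2, D2)
    return StabilityIndices(RS=rs, RL=rl,
                            RS_defined=not math.isnan(rs),
                            RL_defined=not math.isnan(rl))


def _mean_pairwise(dm: DistanceMatrix, ids: list[str]) -> float:
    vals = [dm[a, b] for a, b in combinations(sorted(ids), 2)]
    return float(np.mean(vals)) if vals else math.nan


def _mean_between(dm: DistanceMatrix, group_a: list[str], group_b: list[str]) -> float:
    vals = [dm[a, b] for a in sorted(group_a) for b in sorted(group_b)]
    return float(np.mean(vals)) if vals else math.nan


def control_contrasts(dm: DistanceMatrix, metadata: SampleMetadata, niche: str,
                      axis_kind: str = "taxonomic",
                      timepoints: tuple[str, str] = ("T1", "T2"),
                      experiment: str | None = None,
                      ) -> list[ControlContrast]:
    """One (C1, D1, C2, D2) contrast per non-control treatment in a niche.

    Controls and treatment replicates are pooled across experimental patches
    by default; pass ``experiment`` to stratify.  A contrast is flagged
    invalid when a timepoint has fewer than two control replicates (C_t
    undefined) or no treatment replicate.
    """
    ids = set(dm.ids)

    def _samples(**factors) -> list[str]:
        if experiment is not None:
            factors["experiment"] = experiment
        return [s for s in metadata.samples_where(niche=niche, **factors) if s in ids]

    t1, t2 = timepoints
    controls = {t: _samples(treatment="control", timepoint=t) for t in (t1, t2)}
    contrasts = []
    treatments_present = [
        t for t in TREATMENTS
        if t != "control" and _samples(treatment=t)
    ]
    for treat in treatments_present:
        values: dict[str, float] = {}
        rep_dists: dict[str, list[float]] = {}
        reasons = []
        for label, t in (("1", t1), ("2", t2)):
            ctrl = controls[t]
            trt = _samples(treatment=treat, timepoint=t)
            if len(ctrl) < 2:
                reasons.append(f"<2 control samples at {t}")
                values[f"C{label}"] = math.nan
            else:
                values[f"C{label}"] = _mean_pairwise(dm, ctrl)
                rep_dists[f"C{label}"] = [
                    dm[a, b] for a, b in combinations(sorted(ctrl), 2)
                ]
            if not trt or len(ctrl) < 1:
                reasons.append(f"no {treat} samples at {t}" if not trt
                               else f"no controls at {t}")
                values[f"D{label}"] = math.nan
            else:
                values[f"D{label}"] = _mean_between(dm, trt, ctrl)
                rep_dists[f"D{label}"] = [
                    dm[a, b] for a in sorted(trt) for b in sorted(ctrl)
                ]
        valid = not any(math.isnan(v) for v in values.values())
        contrasts.append(ControlContrast(
            niche=niche, treatment=treat, axis_kind=axis_kind,
            C1=values["C1"], D1=values["D1"], C2=values["C2"], D2=values["D2"],
            valid=valid, replicate_distances=rep_dists,
            reason="; ".join(reasons) if reasons else None,
        ))
    return contrasts


_PROFILE_COLUMNS = ["niche", "treatment", "axis", "C1", "D1", "C2", "D2",
                    "RS", "RL", "RS_defined", "RL_defined", "valid"]


def _profile_one_axis(table: FeatureTable, metadata: SampleMetadata,
                      axis_kind: str, dissimilarity) -> list[dict]:
    rows = []
    meta_niches = [n for n in metadata.frame["niche"].unique()]
    table_samples = set(table.sample_ids)
    for niche in meta_niches:
        niche_samples = [s for s in metadata.samples_where(niche=niche)
                         if s in table_samples]
        if len(niche_samples) < 3:
            warnings.warn(f"niche {niche!r}: not enough samples in table, skipped",
                          stacklevel=3)
            continue
        sub = table.select_samples(niche_samples)
        if sub.scale == "counts":
            sub = to_relative(sub)
        dm = dissimilarity(sub)
        for contrast in control_contrasts(dm, metadata, niche, axis_kind=axis_kind):
            if contrast.valid:
                idx = stability_indices(contrast.C1, contrast.D1,
                                        contrast.C2, contrast.D2)
            else:
                idx = StabilityIndices(math.nan, math.nan, False, False)
            rows.append({
                "niche": niche, "treatment": contrast.treatment, "axis": axis_kind,
                "C1": contrast.C1, "D1": contrast.D1,
                "C2": contrast.C2, "D2": contrast.D2,
                "RS": idx.RS, "RL": idx.RL,
                "RS_defined": idx.RS_defined, "RL_defined": idx.RL_defined,
                "valid": contrast.valid,
            })
    return rows


def stability_profile(table: FeatureTable, metadata: SampleMetadata,
                      function_table: FeatureTable | None = None,
                      ) -> pd.DataFrame:
    """Resistance/resilience profile per niche × treatment (× axis).

    Counts-scale tables are compositionally transformed before the
    Bray–Curtis computation; the dissimilarity is computed within each niche
    subset.  If a functional table is supplied the identical computation is
    repeated on it and both axes appear in the output.
    """
    from .diversity import bray_curtis

    rows = _profile_one_axis(table, metadata, table.axis_kind, bray_curtis)
    if function_table is not None:
        rows += _profile_one_axis(function_table, metadata,
                                  function_table.axis_kind, bray_curtis)
    return pd.DataFrame(rows, columns=_PROFILE_COLUMNS)
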