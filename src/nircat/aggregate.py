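"""Collapse replicate-level detections and fits into per-slice release metrics.

Each field of view is stimulated three times (occasionally twice, when the
electrode loses slice contact); the three release metrics — active-site
density (%), mean peak dF/F0 over active sites, and mean non-excluded
tau_off over active sites — are computed per replicate and then averaged
across replicates.  A replicate with no active ROIs contributes 0 to the
density average and is skipped for the peak/tau_off means; a slice where
every replicate is empty carries missing values forward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import KineticsFit
from .roi import ActiveCall, RoiGrid, site_density
from .stack_io import SampleRecord

__all__ = ["ReplicateMetrics", "SliceMetrics", "replicate_metrics", "aggregate_slice", "build_metrics_table"]

METRIC_COLUMNS = ("density_pct", "peak_dff_active", "tau_off_s")


@dataclass(frozen=True)
class ReplicateMetrics:
    """The three release metrics for one stimulation replicate."""

    animal_id: str
    treatment: str
    region: str
    slice_id: str
    replicate_index: int
    density_pct: float
    peak_dff_active: float | None  # None when no active ROIs
    tau_off_s: float | None  # None when no active ROI survives exclusion
    n_active: int
    n_excluded: int


@dataclass(frozen=True)
class SliceMetrics:
    """Replicate-averaged release metrics for one slice/field of view."""

    animal_id: str
    treatment: str
    region: str
    slice_id: str
    n_replicates: int
    density_pct: float
    peak_dff_active: float | None
    tau_off_s: float | None


def replicate_metrics(
    record: SampleRecord,
    calls: Sequence[ActiveCall],
    fits: Mapping[int, KineticsFit],
    grid: RoiGrid,
) -> ReplicateMetrics:
    """Compute one replicate's metrics from its calls and active-ROI fits.

    ``fits`` maps roi_index -> KineticsFit for (at least) the active ROIs.
    Excluded fits (tau_off > 10 s) and non-converged/degenerate fits
    contribute no tau_off.
    """
    density = site_density(calls, grid)
    active = [c for c in calls if c.is_active]
    peaks = [c.peak_dff for c in active]
    taus = []
    n_excluded = 0
    for c in active:
        fit = fits.get(c.roi_index)
        if fit is None or fit.degenerate or not fit.converged:
            continue
        if fit.excluded:
            n_excluded += 1
            continue
        taus.append(fit.tau_off_s)
    return ReplicateMetrics(
        animal_id=record.animal_id,
        treatment=record.treatment,
        region=record.region,
        slice_id=record.slice_id,
        replicate_index=record.replicate_index,
        density_pct=density,
        peak_dff_active=float(np.mean(peaks)) if peaks else None,
        tau_off_s=float(np.mean(taus)) if taus else None,
        n_active=len(active),
        n_excluded=n_excluded,
    )


def aggregate_slice(replicates: Sequence[ReplicateMetrics]) -> SliceMetrics:
    """Average per-replicate metrics into one SliceMetrics.

    Requires 2 or 3 replicates of a single (animal, region, slice); order
    is irrelevant.  Density averages over all replicates (zeros included);
    peak and tau_off average over the replicates where they are defined.
    """
    if len(replicates) not in (2, 3):
        raise ValueError(
            f"need 2 or 3 replicates per slice, got {len(replicates)}"
        )
    keys = {(r.animal_id, r.treatment, r.region, r.slice_id) for r in replicates}
    if len(keys) != 1:
        raise ValueError(f"replicates mix slice keys: {sorted(keys)}")
    reps = {r.replicate_index for r in replicates}
    if len(reps) != len(replicates):
        raise ValueError("duplicate replicate indices within one slice")
    animal_id, treatment, region, slice_id = next(iter(keys))

    density = float(np.mean([r.density_pct for r in replicates]))
    peaks = [r.peak_dff_active for r in replicates if r.peak_dff_active is not None]
    taus = [r.tau_off_s for r in replicates if r.tau_off_s is not None]
    return SliceMetrics(
        animal_id=animal_id,
        treatment=treatment,
        region=region,
        slice_id=slice_id,
        n_replicates=len(replicates),
        density_pct=density,
        peak_dff_active=float(np.mean(peaks)) if peaks else None,
        tau_off_s=float(np.mean(taus)) if taus else None,
    )


def build_metrics_table(
    records: Sequence[SampleRecord],
    slice_metrics: Sequence[SliceMetrics],
) -> pd.DataFrame:
    """Assemble the per-slice analysis table with design labels.

    Every result must correspond to a manifest slice (orphans are an error);
    manifest slices with no result are reported in the table's attrs under
    ``missing_slices``.  Duplicate slice rows are rejected.
    """
    manifest_keys = {r.slice_key for r in records}
    seen: set[tuple] = set()
    rows = []
    for sm in slice_metrics:
        key = (sm.animal_id, sm.region, sm.slice_id)
        if key not in manifest_keys:
            raise ValueError(f"result for slice {key} has no manifest entry")
        if key in seen:
            raise ValueError(f"duplicate slice metrics for {key}")
        seen.add(key)
        rows.append(
            {
                "animal_id": sm.animal_id,
                "treatment": sm.treatment,
                "region": sm.region,
                "slice_id": sm.slice_id,
                "n_replicates": sm.n_replicates,
                "density_pct": sm.density_pct,
                "peak_dff_active": math.nan if sm.peak_dff_active is None else sm.peak_dff_active,
                "tau_off_s": math.nan if sm.tau_off_s is None else sm.tau_off_s,
            }
        )
    columns = ["animal_id", "treatment", "region", "slice_id", "n_replicates", *METRIC_COLUMNS]
    table = pd.DataFrame(rows, columns=columns)
    table.attrs["missing_slices"] = sorted(manifest_keys - seen)
    return table
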