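"""Panel summaries and core-panel selection.

Markers are assigned to QTL windows, adjacent-marker spacing is summarized
in kb and centimorgans (using the rice heuristic of ~244 kb per cM),
background-utility cardinalities are histogrammed, and a configurable
criteria set nominates a core introgression panel with a full audit trail.
The published 12-assay panel ships as a pinned id list
(:func:`kaspanel.io.load_core_panel`) because the published selection prints
no numeric thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import QTLRegion, ValidationError

log = logging.getLogger(__name__)

KB_PER_CM_DEFAULT = 244.0

_TIER_ORDER = {"ns": 0, "*": 1, "**": 2, "***": 3}


@dataclass(frozen=True)
class PanelSelectionCriteria:
    max_fpr: float = 1.0
    max_fnr: float = 1.0
    min_utility: int = 0
    require_significance: str = "ns"  # minimum tier
    per_region_quota: dict | None = None

    def __post_init__(self):
        if not (0 <= self.max_fpr <= 1 and 0 <= self.max_fnr <= 1):
            raise ValidationError("FPR/FNR thresholds must lie in [0,1]")
        if self.require_significance not in _TIER_ORDER:
            raise ValidationError(f"unknown significance tier {self.require_significance!r}")


def assign_regions(markers: pd.DataFrame, registry: list[QTLRegion]) -> dict:
    """Map each marker to its QTL window.

    ``markers`` needs marker_id / chromosome / position_bp columns. Returns
    a dict with the marker->region map, per-region and per-chromosome counts
    (assigned markers), the unassigned list, and the plain per-chromosome
    histogram of all input markers.
    """
    mapping: dict[str, str] = {}
    unassigned: list[str] = []
    for row in markers.itertuples(index=False):
        region = next(
            (r.id for r in registry if r.contains(str(row.chromosome), int(row.position_bp))),
            None,
        )
        if region is None:
            unassigned.append(row.marker_id)
        else:
            mapping[row.marker_id] = region
    per_region = pd.Series(mapping).value_counts().to_dict()
    assigned = markers[markers["marker_id"].isin(mapping)]
    per_chromosome = assigned["chromosome"].astype(str).value_counts().to_dict()
    chromosome_histogram = markers["chromosome"].astype(str).value_counts().to_dict()
    if unassigned:
        log.info("assign_regions: %d markers outside all windows: %s", len(unassigned), unassigned)
    return dict(
        mapping=mapping,
        per_region=per_region,
        per_chromosome=per_chromosome,
        chromosome_histogram=chromosome_histogram,
        unassigned=unassigned,
    )


def cm_from_kb(distance_kb: float, kb_per_cm: float = KB_PER_CM_DEFAULT) -> float:
    """Genetic distance implied by a physical distance."""
    if kb_per_cm <= 0:
        raise ValidationError("kb_per_cm must be positive")
    return distance_kb / kb_per_cm


@dataclass
class SpacingSummary:
    region_id: str
    n_markers: int
    mean_adjacent_kb: float
    mean_adjacent_cm: float
    kb_per_cm: float = KB_PER_CM_DEFAULT


def spacing_summary(
    positions_bp, region_id: str = "", kb_per_cm: float = KB_PER_CM_DEFAULT
) -> SpacingSummary:
    """Mean adjacent-marker distance (sorted positions) in kb and cM."""
    pos = np.sort(np.asarray(list(positions_bp), dtype=float))
    if len(pos) < 2:
        log.warning("spacing_summary(%s): <2 markers, undefined", region_id)
        return SpacingSummary(region_id, len(pos), float("nan"), float("nan"), kb_per_cm)
    mean_kb = float(np.diff(pos).mean() / 1000.0)
    return SpacingSummary(region_id, len(pos), mean_kb, cm_from_kb(mean_kb, kb_per_cm), kb_per_cm)


def utility_histogram(utility_sets) -> dict[int, int]:
    """Counts of markers by background-utility cardinality (zeros excluded)."""
    counts: dict[int, int] = {}
    for u in utility_sets:
        size = len(u.split(";")) if isinstance(u, str) and u else (len(u) if not isinstance(u, str) else 0)
        if size == 0:
            continue
        counts[size] = counts.get(size, 0) + 1
    return dict(sorted(counts.items(), reverse=True))


def select_core_panel(
    qc: pd.DataFrame, criteria: PanelSelectionCriteria, registry: list[QTLRegion] | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Nominate a core panel from per-marker QC rows.

    ``qc`` needs columns marker_id, fpr, fnr, utility (semicolon-joined or
    int), significance, kw_p; optionally chromosome/position_bp for region
    quotas. Markers passing every threshold are ranked by utility (desc),
    FPR (asc), FNR (asc), Kruskal-Wallis p (asc). Returns the ordered panel
    and a per-marker audit trail of pass/fail per criterion.
    """
    df = qc.copy()
    if df["utility"].dtype == object:
        df["utility_n"] = df["utility"].map(lambda u: len(u.split(";")) if u else 0)
    else:
        df["utility_n"] = df["utility"].astype(int)
    df["sig_rank"] = df["significance"].map(_TIER_ORDER).fillna(0)
    audit = pd.DataFrame(
        {
            "marker_id": df["marker_id"],
            "pass_fpr": df["fpr"].fillna(np.inf) <= criteria.max_fpr,
            "pass_fnr": df["fnr"].fillna(np.inf) <= criteria.max_fnr,
            "pass_utility": df["utility_n"] >= criteria.min_utility,
            "pass_significance": df["sig_rank"] >= _TIER_ORDER[criteria.require_significance],
        }
    )
    audit["pass_all"] = audit[
        ["pass_fpr", "pass_fnr", "pass_utility", "pass_significance"]
    ].all(axis=1)
    passing = df[audit["pass_all"].to_numpy()]
    order = passing.sort_values(
        by=["utility_n", "fpr", "fnr", "kw_p", "marker_id"],
        ascending=[False, True, True, True, True],
        kind="mergesort",
    )
    selected = list(order["marker_id"])
    if criteria.per_region_quota and registry is not None:
        assignment = assign_regions(
            df.rename(columns=str)[["marker_id", "chromosome", "position_bp"]], registry
        )["mapping"]
        kept, used = [], {}
        for m in selected:
            region = assignment.get(m)
            quota = criteria.per_region_quota.get(region)
            if quota is None or used.get(region, 0) < quota:
                kept.append(m)
                used[region] = used.get(region, 0) + 1
        selected = kept
    if not selected:
        log.warning("select_core_panel: no marker passes all criteria")
    return selected, audit


def favorable_allele_matrix(
    calls: pd.DataFrame, populations: pd.Series
) -> pd.DataFrame:
    """Population x marker donor-allele carrier frequencies.

    Entries are the fraction of non-missing calls carrying the donor allele
    (het or donor-hom); markers with no calls in a population are NaN.
    """
    from .datamodel import HET, HOM_ALT, MISSING

    rows = {}
    for pop, idx in calls.groupby(populations).groups.items():
        sub = calls.loc[idx]
        carrier = ((sub == HET) | (sub == HOM_ALT)).sum(axis=0)
        called = (sub != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rows[pop] = np.where(called > 0, carrier / called, np.nan)
    return pd.DataFrame(rows, index=calls.columns).T
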