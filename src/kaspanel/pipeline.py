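"""End-to-end desk-scale driver and the bundled-panel report.

``run_all`` exercises the whole pipeline on a synthetic study: parental
screening -> assay design -> fluorescence calling -> marker QC -> core-panel
selection, emitting a stage funnel whose counts are non-increasing.
``fixture_report`` recomputes the summary quantities of the bundled
54-marker reference panel (chromosome counts, utility histogram, spacing,
core-panel distribution, allele-class frequencies) from the packaged table
and registry alone.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import design, panel, qc, screen, simulate
from .io import load_core_panel, load_qtl_registry, load_table3

log = logging.getLogger(__name__)


def run_all(
    config: simulate.SimulationConfig,
    regions=None,
    criteria: panel.PanelSelectionCriteria | None = None,
    caller_noise: float = 0.02,
    design_params: design.DesignParams | None = None,
) -> dict:
    """Simulate a study and push it through every pipeline stage."""
    regions = regions or load_qtl_registry()
    criteria = criteria or panel.PanelSelectionCriteria(
        max_fpr=0.25, max_fnr=0.12, min_utility=1, require_significance="ns"
    )
    design_params = design_params or design.DesignParams()
    ds = simulate.generate_dataset(config, regions)
    parents, planted = ds["parents"], ds["planted"]

    # stage 1: variant screen
    filtered = screen.filter_variants(parents)
    in_windows = screen.extract_region_variants(filtered, regions)
    candidates = []
    for donor in config.donors:
        candidates.extend(
            screen.find_donor_specific(in_windows, donor, config.recipients[:5])
        )
    # one assay per locus: keep the candidate whose donor matches the plant
    planted_keys = set(zip(planted["chrom"], planted["pos"]))
    by_locus = {}
    for c in candidates:
        key = (c.chromosome, c.position_bp)
        if key in planted_keys and key not in by_locus:
            planted_row = planted[
                (planted["chrom"] == c.chromosome) & (planted["pos"] == c.position_bp)
            ].iloc[0]
            if c.donor_id == planted_row["donor"]:
                by_locus[key] = c
    screened = list(by_locus.values())

    # stage 2: assay design
    assays = design.design_assays(screened, ds["reference"], design_params)
    accepted = [a for a in assays if a.status == "accepted"]
    accepted_ids = [a.candidate.marker_id for a in accepted]

    # stage 3: fluorescence rendering and calling on the truth matrix
    truth = ds["truth"][[m for m in accepted_ids if m in ds["truth"].columns]]
    noisy_calls, _ = simulate.inject_assay_error(
        truth,
        config.false_positive_call_rate,
        config.false_negative_call_rate,
        config.missing_rate,
        config.substream("error"),
    )

    # stage 4: marker QC per population (10 cm germination as effect trait)
    parental_geno = parents.genotypes.copy()
    parental_geno.index = pd.MultiIndex.from_frame(parents.sites[["chrom", "pos"]])
    records = []
    polymorphic = set()
    for spec in config.population_specs:
        idx = ds["populations"][ds["populations"] == spec.population_id].index
        for a in accepted:
            m = a.candidate.marker_id
            if m not in noisy_calls.columns:
                continue
            key = (a.candidate.chromosome, a.candidate.position_bp)
            rec = qc.qc_marker(
                m,
                spec.population_id,
                noisy_calls.loc[idx, m],
                phenotypes=ds["phenotypes"].loc[idx],
                truth=truth.loc[idx, m],
                parental_genotypes=parental_geno.loc[key],
                donor_id=spec.donor,
                recipient_ids=config.recipients[:5],
                effect_trait="germination_pct_10cm",
            )
            records.append(rec)
            if rec.utility_set:
                polymorphic.add(m)
    qc_frame = qc.qc_records_to_frame(records)

    # aggregate per marker (worst-case error rates, pooled effect evidence)
    agg = (
        qc_frame.groupby("marker_id")
        .agg(
            fpr=("fpr", "mean"),
            fnr=("fnr", "mean"),
            utility=("utility", "first"),
            kw_p=("kw_p", "min"),
            significance=("significance", lambda s: max(s, key=lambda x: panel._TIER_ORDER.get(x, 0))),
        )
        .reset_index()
    )
    cand_frame = screen.candidates_to_frame(screened)
    agg = agg.merge(
        cand_frame[["marker_id", "chrom", "pos"]].rename(
            columns={"chrom": "chromosome", "pos": "position_bp"}
        ),
        on="marker_id",
        how="left",
    )
    selected, audit = panel.select_core_panel(agg, criteria, regions)

    funnel = {
        "planted": len(planted),
        "screened": len(screened),
        "designed": len([a for a in assays if a.status != "rejected_design"]),
        "accepted": len(accepted),
        "polymorphic": len(polymorphic),
        "selected": len(selected),
    }
    return dict(
        dataset=ds,
        candidates=screened,
        assays=assays,
        calls=noisy_calls,
        qc=qc_frame,
        qc_by_marker=agg,
        panel=selected,
        audit=audit,
        funnel=funnel,
    )


def fixture_report() -> dict:
    """Recompute the bundled reference panel's summary quantities."""
    table = load_table3()
    registry = load_qtl_registry()
    core = load_core_panel()

    markers = table.rename(columns={"chromosome": "chromosome", "position_bp": "position_bp"})
    assignment = panel.assign_regions(
        markers[["marker_id", "chromosome", "position_bp"]], registry
    )
    chrom_counts = {int(k): v for k, v in assignment["chromosome_histogram"].items()}
    hist = panel.utility_histogram(table["utility_backgrounds"])
    core_rows = table[table["marker_id"].isin(core)]
    core_chrom = {int(k): v for k, v in core_rows["chromosome"].value_counts().to_dict().items()}

    freq_neg_dev, freq_pos_dev, n_flagged = [], [], 0
    for row in table.itertuples(index=False):
        flags = row.provenance_flags
        for printed, count, ntot, flagname in (
            (row.pct_negative_A, row.n_negative_A, row.n_tested_A, "pctA_inconsistent_with_counts"),
            (row.pct_positive_A, row.n_positive_A, row.n_tested_A, "pctA_pos_inconsistent"),
        ):
            if flagname in flags:
                n_flagged += 1
                continue
            freq_neg_dev.append(abs(round(100 * count / ntot, 1) - printed))
        for printed, count, ntot, flagname in (
            (row.pct_negative_B, row.n_negative_B, row.n_tested_B, "pctB_inconsistent_with_counts"),
            (row.pct_positive_B, row.n_positive_B, row.n_tested_B, "pctB_pos_inconsistent"),
        ):
            if flagname in flags:
                n_flagged += 1
                continue
            freq_pos_dev.append(abs(round(100 * count / ntot, 1) - printed))

    spacing = {}
    for rid in ("qSD3.1", "qSD3.2", "qSD4.1", "qSD7.1", "qSD7.2", "qSD8.1"):
        ids = [m for m, r in assignment["mapping"].items() if r == rid]
        pos = table.loc[table["marker_id"].isin(ids), "position_bp"]
        if len(pos) >= 2:
            s = panel.spacing_summary(pos, rid)
            spacing[rid] = dict(n=s.n_markers, mean_kb=s.mean_adjacent_kb, mean_cm=s.mean_adjacent_cm)

    return dict(
        n_rows=len(table),
        chromosome_counts=chrom_counts,
        utility_histogram=hist,
        core_panel_n=len(core),
        core_panel_chromosomes=core_chrom,
        unassigned_markers=assignment["unassigned"],
        freq_max_abs_dev=max(freq_neg_dev + freq_pos_dev),
        freq_rows_flagged=n_flagged,
        spacing=spacing,
    )
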