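"""End-to-end analysis: simulated study -> per-subject results -> statistics.

Mirrors the study workflow: quantify T/S and TREC/KREC from the qPCR
plates, classify and score the spectratype repertoire against a 12-HC
reference, then run the three-group comparisons and correlation panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohort_stats, qpcr, spectratype
from .synthetic import CohortConfig, SimulatedStudy, simulate_study


@dataclass
class StudyResult:
    """Everything the pipeline computes on one (simulated) study."""

    study: SimulatedStudy
    results: pd.DataFrame  # per subject: group, ts, trec, krec, global D, ...
    reference: spectratype.ReferenceRepertoire
    classifications: dict[str, dict[str, spectratype.ProfileClass]]
    perturbations: dict[str, spectratype.PerturbationResult]
    category_summary: spectratype.CategorySummary
    comparisons: dict[str, cohort_stats.GroupComparison] = field(default_factory=dict)
    proportion_test: cohort_stats.GroupComparison | None = None
    correlations: list[cohort_stats.CorrelationResult] = field(default_factory=list)


def analyze_study(study: SimulatedStudy, n_ref: int = 12, ref_seed: int | None = None) -> StudyResult:
    """Run the full analysis on a simulated (or equivalently formatted) study."""
    groups = {s.subject_id: s.group for s in study.subjects}

    # qPCR quantification
    ts = {
        sid: qpcr.compute_ts_ratio(study.telomere, sid).ts_ratio
        for sid in study.telomere.sample_ids()
    }
    excision = {
        sid: qpcr.quantify_excision_circles(study.excision, sid, study.blood_norm)
        for sid in study.excision.sample_ids()
    }

    # spectratype
    records = spectratype.parse_peak_table(study.peak_table)
    profiles = spectratype.profiles_from_peaks(records)
    hc_profiles = {sid: prof for sid, prof in profiles.items() if groups[sid] == "HC"}
    seed = study.config.seed if ref_seed is None else ref_seed
    reference = spectratype.build_reference(hc_profiles, n_ref=n_ref, seed=seed)
    classifications = {
        sid: {
            trbv: spectratype.classify_profile(dist)
            for trbv, dist in prof.items()
            if dist.detected
        }
        for sid, prof in profiles.items()
    }
    perturbations = {
        sid: spectratype.score_subject(sid, prof, reference) for sid, prof in profiles.items()
    }
    summary = spectratype.summarize_categories(classifications, perturbations, groups)

    rows = []
    for s in study.subjects:
        exc = excision[s.subject_id]
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "gender": s.gender,
                "cd4_abs": s.cd4_abs,
                "cd4_pct": s.cd4_pct,
                "cd8_abs": s.cd8_abs,
                "cd8_pct": s.cd8_pct,
                "cd4_cd8_ratio": s.cd4_cd8_ratio,
                "ts_ratio": ts.get(s.subject_id, np.nan),
                "trec_copies_per_ml": exc.trec_copies_per_ml,
                "krec_copies_per_ml": exc.krec_copies_per_ml,
                "global_perturbation": perturbations[s.subject_id].global_perturbation,
                "n_overperturbed": perturbations[s.subject_id].n_overperturbed,
                "fraction_nonnormal": summary.per_subject_fraction_nonnormal.get(
                    s.subject_id, np.nan
                ),
            }
        )
    results = pd.DataFrame(rows)

    comparisons = {}
    for var in ("ts_ratio", "trec_copies_per_ml", "krec_copies_per_ml", "global_perturbation"):
        by_group = {
            g: sub[var].dropna().to_numpy(float) for g, sub in results.groupby("group", sort=False)
        }
        comparisons[var] = cohort_stats.compare_groups(by_group, variable=var)

    proportion_test = cohort_stats.category_proportion_test(
        summary.per_subject_fraction_nonnormal, groups
    )

    correlations = []
    ph = results[results["group"] == "pHIVy"]
    if len(ph) >= 3:
        correlations += cohort_stats.correlate(
            ph["trec_copies_per_ml"], ph["cd4_abs"], variable_pair=("trec", "cd4_abs"),
            strata=["pHIVy"] * len(ph),
        )
        correlations += cohort_stats.correlate(
            ph["ts_ratio"], ph["cd4_abs"], variable_pair=("ts", "cd4_abs"),
            strata=["pHIVy"] * len(ph),
        )
        correlations += cohort_stats.correlate(
            ph["global_perturbation"], ph["cd4_cd8_ratio"],
            variable_pair=("global_perturbation", "cd4_cd8_ratio"), strata=["pHIVy"] * len(ph),
        )

    return StudyResult(
        study=study,
        results=results,
        reference=reference,
        classifications=classifications,
        perturbations=perturbations,
        category_summary=summary,
        comparisons=comparisons,
        proportion_test=proportion_test,
        correlations=correlations,
    )


def run_study(config: CohortConfig | None = None) -> StudyResult:
    """Simulate a study with ``config`` and analyze it end to end."""
    return analyze_study(simulate_study(config or CohortConfig()))
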