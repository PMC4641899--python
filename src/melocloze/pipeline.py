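"""End-to-end orchestration: raw tables -> full norming-study analysis.

Glue over the analysis modules; each step is available individually.
The order mirrors the study workflow: process raw responses, screen
participants, aggregate distributions, compute constraint and condition
comparisons, validate key projection, and compare behavior with the I-R
model on high-constraint stems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cloze_stats import (
    ConditionSummary,
    ConstraintResult,
    DegreeProfile,
    ResponseDistribution,
    build_distributions,
    compare_conditions,
    constraint,
    scale_degree_profile,
    training_tonic_correlation,
)
from .io_formats import ParticipantRecord, ResponseTableRow
from .ir_model import ExpectancyTable, ModelConfig, expectancy_table
from .key_finding import GroupValidation, validate_stimulus_groups
from .melody_core import MelodicStem, StemPair
from .model_comparison import ComparisonResult, evaluate, select_high_constraint
from .response_processing import (
    ExclusionReport,
    SungResponse,
    process_table,
    screen_participant,
)

__all__ = ["StudyResults", "analyze"]


@dataclass
class StudyResults:
    """Everything the analysis computes, in one bundle."""

    responses: list[SungResponse]
    exclusions: list[ExclusionReport]
    retained_participants: list[str]
    distributions: dict[str, ResponseDistribution]
    constraints: dict[str, ConstraintResult]
    constraint_summary: ConditionSummary
    rt_summary: ConditionSummary | None
    confidence_summary: ConditionSummary | None
    degree_profile: DegreeProfile
    key_validation: GroupValidation
    expectancies: dict[str, ExpectancyTable]
    high_constraint_threshold: float
    model_comparison: ComparisonResult
    training_correlation_deg7: tuple[float, float] | None = None


def _participant_condition_means(
    responses: Sequence[SungResponse], attr: str
) -> tuple[list[float], list[float]]:
    """Per-participant AC and NC means of an attribute, aligned."""
    acc: dict[str, dict[str, list[float]]] = {}
    for r in responses:
        if not r.valid or getattr(r, attr) is None:
            continue
        acc.setdefault(r.participant_id, {"AC": [], "NC": []})
        if r.condition in ("AC", "NC"):
            acc[r.participant_id][r.condition].append(float(getattr(r, attr)))
    ac, nc = [], []
    for pid in sorted(acc):
        if acc[pid]["AC"] and acc[pid]["NC"]:
            ac.append(float(np.mean(acc[pid]["AC"])))
            nc.append(float(np.mean(acc[pid]["NC"])))
    return ac, nc


def analyze(
    pairs: Sequence[StemPair],
    rows: Sequence[ResponseTableRow],
    participants: Sequence[ParticipantRecord],
    model_config: ModelConfig = ModelConfig(),
    octave_equivalent_matching: bool = True,
) -> StudyResults:
    """Run the full analysis on one corpus + response set."""
    stems: dict[str, MelodicStem] = {}
    for p in pairs:
        stems[p.ac.stem_id] = p.ac
        stems[p.nc.stem_id] = p.nc

    processed = process_table(rows, stems)
    exclusions = [
        screen_participant(rec, processed, octave_equivalent_matching)
        for rec in participants
    ]
    excluded_ids = {e.participant_id for e in exclusions if e.excluded}
    retained = [r for r in processed if r.participant_id not in excluded_ids]
    retained_ids = sorted(
        {p.participant_id for p in participants} - excluded_ids
    )

    dists = build_distributions(retained)
    constraints = {
        sid: constraint(d, stems[sid].key) for sid, d in dists.items()
    }

    ac_vals, nc_vals = [], []
    for p in pairs:
        if p.ac.stem_id in constraints and p.nc.stem_id in constraints:
            ac_vals.append(constraints[p.ac.stem_id].constraint)
            nc_vals.append(constraints[p.nc.stem_id].constraint)
    constraint_summary = compare_conditions(ac_vals, nc_vals, "constraint")

    rt_summary = conf_summary = None
    ac_rt, nc_rt = _participant_condition_means(retained, "onset_latency_ms")
    if len(ac_rt) >= 2:
        rt_summary = compare_conditions(ac_rt, nc_rt, "rt_ms")
    ac_cf, nc_cf = _participant_condition_means(retained, "confidence")
    if len(ac_cf) >= 2:
        conf_summary = compare_conditions(ac_cf, nc_cf, "confidence")

    profile = scale_degree_profile(dists, stems)
    key_validation = validate_stimulus_groups(
        [p.ac for p in pairs], [p.nc for p in pairs]
    )

    expectancies = {
        sid: expectancy_table(stem, model_config) for sid, stem in stems.items()
    }
    ac_mean = constraint_summary.ac_mean
    selected = select_high_constraint(list(constraints.values()), ac_mean)
    comparison = evaluate(expectancies, selected, dists)

    training = {
        p.participant_id: p.years_formal_training
        for p in participants
        if p.participant_id not in excluded_ids
    }
    corr = None
    try:
        r, pval, _ = training_tonic_correlation(
            training, retained, stems, final_degree=7
        )
        corr = (r, pval)
    except ValueError:
        pass

    return StudyResults(
        responses=retained,
        exclusions=exclusions,
        retained_participants=retained_ids,
        distributions=dists,
        constraints=constraints,
        constraint_summary=constraint_summary,
        rt_summary=rt_summary,
        confidence_summary=conf_summary,
        degree_profile=profile,
        key_validation=key_validation,
        expectancies=expectancies,
        high_constraint_threshold=ac_mean,
        model_comparison=comparison,
        training_correlation_deg7=corr,
    )
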