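"""Cloze probabilities, constraint, scale-degree profiles and comparisons.

The cloze probability of a note after a melodic stem is the proportion
of respondents who sang it (octave-generalized to pitch classes); the
*constraint* of a stem is the proportion singing the most common note —
the stem's predictive strength.  This module aggregates processed sung
responses into per-stem distributions and computes the behavioral
statistics of a norming study: AC vs NC condition comparisons (paired t
tests), averaged scale-degree profiles with per-degree tests, and the
musical-training x tonic-response correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _sps

from .melody_core import DegreeLabel, KeyContext, MelodicStem, scale_degree
from .response_processing import SungResponse

__all__ = [
    "ResponseDistribution",
    "ConstraintResult",
    "ConditionSummary",
    "DegreeProfile",
    "build_distribution",
    "build_distributions",
    "cloze_probability",
    "constraint",
    "scale_degree_profile",
    "compare_conditions",
    "paired_t",
    "training_tonic_correlation",
    "fisher_z",
    "fisher_z_inverse",
]

NON_DIATONIC = "non-diatonic"
DEGREE_BINS: tuple[str, ...] = ("1", "2", "3", "4", "5", "6", "7", NON_DIATONIC)


@dataclass(frozen=True)
class ResponseDistribution:
    """Per-stem distribution of sung pitch classes over valid respondents."""

    stem_id: str
    counts: dict[int, int]
    n_valid: int

    def __post_init__(self) -> None:
        if self.n_valid <= 0:
            raise ValueError(f"stem {self.stem_id!r}: no valid responses")
        if sum(self.counts.values()) != self.n_valid:
            raise ValueError(f"stem {self.stem_id!r}: counts do not sum to n_valid")

    def proportions(self) -> dict[int, float]:
        return {pc: c / self.n_valid for pc, c in self.counts.items()}


@dataclass(frozen=True)
class ConstraintResult:
    """Constraint of a stem: the maximum cloze probability.

    ``modal_pitch_classes`` lists every argmax class (ties possible);
    downstream consumers needing a single modal note must declare their
    own tie policy.
    """

    stem_id: str
    modal_pitch_classes: tuple[int, ...]
    constraint: float
    modal_degrees: tuple[DegreeLabel, ...] = ()
    n_valid: int = 0

    @property
    def ranked_classes(self) -> tuple[int, ...]:
        return self.modal_pitch_classes


@dataclass(frozen=True)
class ConditionSummary:
    """Per-condition means/SDs with the paired test statistics."""

    measure: str
    ac_mean: float
    ac_sd: float
    nc_mean: float
    nc_sd: float
    t_statistic: float
    df: int
    p_value: float


def build_distribution(
    responses: Iterable[SungResponse], stem_id: str
) -> ResponseDistribution:
    """Count valid sung responses to one stem, collapsed across octaves."""
    counts: dict[int, int] = {}
    for r in responses:
        if r.stem_id != stem_id or not r.valid:
            continue
        counts[r.pitch_class] = counts.get(r.pitch_class, 0) + 1
    n = sum(counts.values())
    if n == 0:
        raise ValueError(f"stem {stem_id!r}: no valid responses to aggregate")
    return ResponseDistribution(stem_id=stem_id, counts=counts, n_valid=n)


def build_distributions(
    responses: Iterable[SungResponse],
) -> dict[str, ResponseDistribution]:
    """Group responses by stem and build each stem's distribution."""
    by_stem: dict[str, list[SungResponse]] = {}
    for r in responses:
        by_stem.setdefault(r.stem_id, []).append(r)
    return {
        sid: build_distribution(rs, sid)
        for sid, rs in by_stem.items()
        if any(r.valid for r in rs)
    }


def cloze_probability(dist: ResponseDistribution, pitch_class: int) -> float:
    """Proportion of respondents who sang ``pitch_class`` (0 if unsung)."""
    return dist.counts.get(pitch_class % 12, 0) / dist.n_valid


def constraint(
    dist: ResponseDistribution, key: KeyContext | None = None
) -> ConstraintResult:
    """Maximum cloze probability and the modal pitch class(es)."""
    max_count = max(dist.counts.values())
    modal = tuple(sorted(pc for pc, c in dist.counts.items() if c == max_count))
    degrees = (
        tuple(scale_degree(pc, key) for pc in modal) if key is not None else ()
    )
    return ConstraintResult(
        stem_id=dist.stem_id,
        modal_pitch_classes=modal,
        constraint=max_count / dist.n_valid,
        modal_degrees=degrees,
        n_valid=dist.n_valid,
    )


# -- scale-degree profiles ---------------------------------------------------


def _degree_vector(dist: ResponseDistribution, key: KeyContext) -> np.ndarray:
    """Pitch-class proportions -> 8-bin degree vector (7 diatonic + pooled)."""
    vec = np.zeros(len(DEGREE_BINS))
    for pc, p in dist.proportions().items():
        deg = scale_degree(pc, key)
        if isinstance(deg, int):
            vec[deg - 1] += p
        else:
            vec[-1] += p
    return vec


@dataclass(frozen=True)
class DegreeProfile:
    """Averaged scale-degree response profile per condition.

    Profiles are the unweighted mean of per-stem proportion vectors
    (stems have unequal respondent counts; each stem contributes
    equally).  ``p_values`` are Bonferroni-corrected per-degree AC vs NC
    t tests over the 7 diatonic degrees.
    """

    bins: tuple[str, ...]
    ac_profile: np.ndarray
    nc_profile: np.ndarray
    t_statistics: np.ndarray
    p_values_corrected: np.ndarray
    paired: bool = False


def scale_degree_profile(
    dists: Mapping[str, ResponseDistribution],
    stems: Mapping[str, MelodicStem],
    paired: bool = False,
    bonferroni_m: int = 7,
) -> DegreeProfile:
    """Average degree distributions for AC and NC stems and test per degree.

    ``paired=True`` pairs AC/NC stems sharing a ``pair_id`` and uses a
    paired t per degree; the default treats stems as independent items
    (two-sample Welch t).
    """
    ac_rows: dict[str, np.ndarray] = {}
    nc_rows: dict[str, np.ndarray] = {}
    for sid, dist in dists.items():
        stem = stems[sid]
        row = _degree_vector(dist, stem.key)
        if stem.condition == "AC":
            ac_rows[stem.pair_id or sid] = row
        elif stem.condition == "NC":
            nc_rows[stem.pair_id or sid] = row
    if not ac_rows or not nc_rows:
        raise ValueError("need response distributions in both conditions")
    ac = np.vstack(list(ac_rows.values()))
    nc = np.vstack(list(nc_rows.values()))
    tvals = np.full(bonferroni_m, np.nan)
    pvals = np.full(bonferroni_m, np.nan)
    for d in range(bonferroni_m):
        if paired:
            shared = sorted(set(ac_rows) & set(nc_rows))
            x = np.array([ac_rows[k][d] for k in shared])
            y = np.array([nc_rows[k][d] for k in shared])
            t, df, p = paired_t(x, y)
        else:
            t, p = _sps.ttest_ind(ac[:, d], nc[:, d], equal_var=False)
        tvals[d] = t
        pvals[d] = min(1.0, float(p) * bonferroni_m)
    return DegreeProfile(
        bins=DEGREE_BINS,
        ac_profile=ac.mean(axis=0),
        nc_profile=nc.mean(axis=0),
        t_statistics=tvals,
        p_values_corrected=pvals,
        paired=paired,
    )


# -- paired comparisons ------------------------------------------------------


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Paired two-sided t test by the textbook formula.

    t = mean(d) / (sd(d)/sqrt(n)) with d = x - y and df = n - 1.
    Returns (t, df, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t requires at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else math.inf * math.copysign(1, d.mean())
    else:
        t = float(d.mean() / (sd / math.sqrt(n)))
    df = n - 1
    p = float(2.0 * _sps.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    return t, df, p


def compare_conditions(
    ac_values: Sequence[float],
    nc_values: Sequence[float],
    measure: str = "constraint",
) -> ConditionSummary:
    """Paired AC vs NC comparison of aligned per-pair (or per-participant)
    values: means, SDs, and the paired t statistic."""
    ac = np.asarray(ac_values, dtype=float)
    nc = np.asarray(nc_values, dtype=float)
    t, df, p = paired_t(ac, nc)
    return ConditionSummary(
        measure=measure,
        ac_mean=float(ac.mean()),
        ac_sd=float(ac.std(ddof=1)),
        nc_mean=float(nc.mean()),
        nc_sd=float(nc.std(ddof=1)),
        t_statistic=t,
        df=df,
        p_value=p,
    )


# -- musical experience ------------------------------------------------------


def training_tonic_correlation(
    years_training: Mapping[str, float],
    responses: Iterable[SungResponse],
    stems: Mapping[str, MelodicStem],
    final_degree: int | None = None,
    condition: str = "AC",
) -> tuple[float, float, dict[str, float]]:
    """Correlate years of formal training with tonic-response frequency.

    For each participant, the tonic-response frequency is the fraction
    of their valid responses (to stems of ``condition``, optionally
    restricted to stems whose final note is on ``final_degree``) that
    were the tonic pitch class.  Returns (Pearson r, two-sided p,
    per-participant frequencies).
    """
    eligible = {
        sid
        for sid, s in stems.items()
        if s.condition == condition
        and (final_degree is None or s.final_degree == final_degree)
    }
    hits: dict[str, int] = {}
    totals: dict[str, int] = {}
    for r in responses:
        if not r.valid or r.stem_id not in eligible:
            continue
        totals[r.participant_id] = totals.get(r.participant_id, 0) + 1
        if r.degree == 1:
            hits[r.participant_id] = hits.get(r.participant_id, 0) + 1
    freqs = {
        pid: hits.get(pid, 0) / n
        for pid, n in totals.items()
        if pid in years_training
    }
    if len(freqs) < 3:
        raise ValueError("need at least 3 participants with eligible responses")
    pids = sorted(freqs)
    x = np.array([years_training[p] for p in pids])
    y = np.array([freqs[p] for p in pids])
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = _sps.pearsonr(x, y)
    return float(r), float(p), freqs


# -- Fisher transform --------------------------------------------------------


def fisher_z(r: float) -> float:
    """Fisher z-transform atanh(r); defined for |r| < 1."""
    if abs(r) >= 1:
        raise ValueError("Fisher z requires |r| < 1")
    return math.atanh(r)


def fisher_z_inverse(z: float) -> float:
    return math.tanh(z)
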