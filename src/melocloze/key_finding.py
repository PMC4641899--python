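"""Krumhansl-Schmuckler key-finding for stimulus validation.

A melody's duration-weighted pitch-class distribution is correlated
against the 24 rotated Krumhansl-Kessler probe-tone profiles (12 major,
12 minor); the best-correlating key is the inferred key.  For matched
AC/NC stimulus groups, the correlation with each stem's labeled correct
key is averaged on the Fisher-z scale and compared with a paired t test:
well-matched groups project their keys equally strongly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .melody_core import MelodicStem, StemPair

__all__ = [
    "KK_MAJOR_PROFILE",
    "KK_MINOR_PROFILE",
    "PitchClassProfile",
    "KeyCorrelationResult",
    "GroupValidation",
    "key_profile",
    "duration_weighted_distribution",
    "key_correlations",
    "validate_stimulus_groups",
]

# Krumhansl-Kessler probe-tone ratings: perceived stability of each of the
# 12 chromatic pitch classes relative to the tonic (index 0).  Rotating the
# vector by k semitones gives the profile of the key k semitones up.
KK_MAJOR_PROFILE = np.array(
    [6.35, 2.23, 3.48, 2.33, 4.38, 4.09, 2.52, 5.19, 2.39, 3.66, 2.29, 2.88]
)
KK_MINOR_PROFILE = np.array(
    [6.33, 2.68, 3.52, 5.38, 2.60, 3.53, 2.54, 4.75, 3.98, 2.69, 3.34, 3.17]
)


@dataclass(frozen=True)
class PitchClassProfile:
    """12 nonnegative weights indexed by pitch class relative to C."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (12,):
            raise ValueError("profile must have exactly 12 values")
        if (v < 0).any():
            raise ValueError("profile weights must be nonnegative")
        object.__setattr__(self, "values", v)

    def rotate(self, k: int) -> "PitchClassProfile":
        """Profile of the same content transposed up by ``k`` semitones."""
        return PitchClassProfile(np.roll(self.values, k))


def key_profile(tonic_pitch_class: int, mode: str) -> PitchClassProfile:
    """Krumhansl-Kessler profile of the key with the given tonic and mode."""
    base = KK_MAJOR_PROFILE if mode == "major" else KK_MINOR_PROFILE
    return PitchClassProfile(np.roll(base, tonic_pitch_class))


@dataclass(frozen=True)
class KeyCorrelationResult:
    """Correlations of a melody's pitch distribution with all 24 keys."""

    correlations: dict[tuple[int, str], float]
    best_key: tuple[int, str]
    correlation_with_correct_key: float | None = None

    @property
    def best_correlation(self) -> float:
        return self.correlations[self.best_key]


def duration_weighted_distribution(stem: MelodicStem) -> PitchClassProfile:
    """Total sounded beats per pitch class (unnormalized).

    Correlation with key profiles is invariant to overall scale, so no
    normalization is applied.
    """
    if not stem.notes:
        raise ValueError("empty stem has no pitch distribution")
    values = np.zeros(12)
    for n in stem.notes:
        values[n.pitch.pitch_class] += n.duration_beats
    return PitchClassProfile(values)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def key_correlations(
    dist: PitchClassProfile,
    correct_key: tuple[int, str] | None = None,
) -> KeyCorrelationResult:
    """Pearson correlation of a distribution with all 24 key profiles."""
    if np.allclose(dist.values, dist.values[0]):
        raise ValueError(
            "pitch-class distribution has zero variance; key correlation undefined"
        )
    corrs: dict[tuple[int, str], float] = {}
    for mode in ("major", "minor"):
        for tonic in range(12):
            corrs[(tonic, mode)] = _pearson(
                dist.values, key_profile(tonic, mode).values
            )
    best = max(corrs, key=lambda k: corrs[k])
    with_correct = corrs[correct_key] if correct_key is not None else None
    return KeyCorrelationResult(
        correlations=corrs, best_key=best, correlation_with_correct_key=with_correct
    )


@dataclass(frozen=True)
class GroupValidation:
    """Key-projection comparison between AC and NC stem groups.

    Group means are computed on the Fisher-z scale and reported
    back-transformed to correlations.
    """

    ac_mean_r: float
    nc_mean_r: float
    t_statistic: float
    df: int
    p_value: float
    ac_correlations: tuple[float, ...] = field(default=())
    nc_correlations: tuple[float, ...] = field(default=())


def _correct_key_correlation(stem: MelodicStem) -> float:
    if stem.key is None:  # pragma: no cover - dataclass forbids None anyway
        raise ValueError(f"stem {stem.stem_id!r} has no key label")
    res = key_correlations(
        duration_weighted_distribution(stem),
        correct_key=(stem.key.tonic_pitch_class, stem.key.mode),
    )
    assert res.correlation_with_correct_key is not None
    return res.correlation_with_correct_key


def validate_stimulus_groups(
    ac_stems: list[MelodicStem], nc_stems: list[MelodicStem]
) -> GroupValidation:
    """Compare how strongly paired AC and NC stems project their key.

    ``ac_stems[i]`` and ``nc_stems[i]`` must be the two members of pair
    ``i``.  The per-stem correlations with the labeled correct key are
    Fisher-z transformed, averaged per group (back-transformed for
    reporting), and compared across pairs with a paired t test.
    """
    from .cloze_stats import fisher_z, fisher_z_inverse, paired_t

    if len(ac_stems) != len(nc_stems):
        raise ValueError("AC and NC groups must be paired (equal length)")
    if len(ac_stems) < 2:
        raise ValueError("need at least 2 pairs")
    ac_r = np.array([_correct_key_correlation(s) for s in ac_stems])
    nc_r = np.array([_correct_key_correlation(s) for s in nc_stems])
    ac_z = np.array([fisher_z(r) for r in ac_r])
    nc_z = np.array([fisher_z(r) for r in nc_r])
    t, df, p = paired_t(ac_z, nc_z)
    return GroupValidation(
        ac_mean_r=fisher_z_inverse(float(ac_z.mean())),
        nc_mean_r=fisher_z_inverse(float(nc_z.mean())),
        t_statistic=t,
        df=df,
        p_value=p,
        ac_correlations=tuple(ac_r),
        nc_correlations=tuple(nc_r),
    )
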