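"""Data preparation turning raw longitudinal measures into model-ready series.

Two steps make heterogeneous measures comparable on the dimensionless scale
the spring–damper model assumes:

1. fold-change normalization — divide each series by a reference mean of the
   corresponding measure, so the unit of measurement drops out;
2. minimum subtraction — shift each normalized series so its minimum is
   exactly 0, anchoring the rest state of the model (x = 0) to the least
   disturbed observation.

A third helper rescales raw clock time onto the 0–100 analysis scale with the
challenge window mapped to [20, 60].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .model import DEFAULT_TAU1, DEFAULT_TAU2

__all__ = [
    "ObservationSeries",
    "normalize_fold_change",
    "shift_min_zero",
    "preprocess_series",
    "preprocess_cohort",
    "grand_means",
    "rescale_time",
]


@dataclass(frozen=True)
class ObservationSeries:
    """One individual × measure time series with grouping metadata.

    The statistical individual is the unit each (K, C) pair is fitted on —
    an aquarium of fish in the confinement study this package emulates.
    ``is_preprocessed`` marks a series that has been fold-change normalized
    and minimum-shifted (so min(values) == 0).
    """

    individual_id: str
    measure: str
    times: NDArray[np.float64]
    values: NDArray[np.float64]
    line: str | None = None
    replicate: str | None = None
    is_preprocessed: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("times must be a non-empty 1-D sequence")
        if t.size != v.size:
            raise ValueError("times and values must have equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if self.is_preprocessed:
            if v.min() != 0.0 or (v < 0).any():
                raise ValueError(
                    "a preprocessed series must be non-negative with minimum 0"
                )

    @property
    def n(self) -> int:
        return len(self.times)


def normalize_fold_change(
    series: ObservationSeries, reference_mean: float
) -> ObservationSeries:
    """Divide a raw series by ``reference_mean``, giving a fold change.

    The reference is conventionally the grand mean of that measure over every
    individual and time point in the cohort (see :func:`grand_means`); it is
    an explicit argument so callers can substitute e.g. a known baseline.
    """
    if series.is_preprocessed:
        raise ValueError("series is already preprocessed")
    if not reference_mean > 0:
        raise ValueError(f"reference_mean must be > 0, got {reference_mean}")
    return replace(series, values=series.values / reference_mean)


def shift_min_zero(
    series: ObservationSeries,
    challenge_window: tuple[float, float] = (DEFAULT_TAU1, DEFAULT_TAU2),
) -> ObservationSeries:
    """Subtract the series minimum so the least disturbed point sits at x = 0.

    Emits a warning when the minimum falls strictly inside the challenge
    window: the anchoring hypothesis (the individual is near its rest state
    at some observed time) is then doubtful, since the system is maximally
    pulled during the challenge.
    """
    if series.n == 0:
        raise ValueError("empty series")
    i_min = int(np.argmin(series.values))
    t_min = series.times[i_min]
    lo, hi = challenge_window
    if lo < t_min < hi:
        warnings.warn(
            f"series {series.individual_id}/{series.measure}: minimum at "
            f"t={t_min:g}, strictly inside the challenge window ({lo}, {hi}); "
            "the rest-state anchoring assumption may not hold",
            stacklevel=2,
        )
    shifted = series.values - series.values[i_min]
    shifted[i_min] = 0.0  # exact zero despite rounding
    return replace(series, values=shifted, is_preprocessed=True)


def preprocess_series(
    series: ObservationSeries,
    reference_mean: float,
    challenge_window: tuple[float, float] = (DEFAULT_TAU1, DEFAULT_TAU2),
) -> ObservationSeries:
    """Fold-change normalization followed by minimum subtraction."""
    return shift_min_zero(
        normalize_fold_change(series, reference_mean), challenge_window
    )


def grand_means(series_list: list[ObservationSeries]) -> dict[str, float]:
    """Grand mean of each measure over all individuals and all time points."""
    pooled: dict[str, list[NDArray[np.float64]]] = {}
    for s in series_list:
        pooled.setdefault(s.measure, []).append(s.values)
    return {m: float(np.concatenate(v).mean()) for m, v in pooled.items()}


def preprocess_cohort(
    series_list: list[ObservationSeries],
    reference_means: dict[str, float] | None = None,
    challenge_window: tuple[float, float] = (DEFAULT_TAU1, DEFAULT_TAU2),
) -> list[ObservationSeries]:
    """Preprocess every series of a cohort.

    ``reference_means`` maps measure -> reference; when omitted, the grand
    mean of each measure over the whole cohort is used (the default
    normalization convention for real data, where no baseline is known).
    """
    if reference_means is None:
        reference_means = grand_means(series_list)
    out = []
    for s in series_list:
        if s.measure not in reference_means:
            raise KeyError(f"no reference mean for measure {s.measure!r}")
        out.append(preprocess_series(s, reference_means[s.measure], challenge_window))
    return out


def rescale_time(
    times_raw: ArrayLike,
    challenge_onset: float,
    challenge_duration: float,
    window_hours: float = 10.0,
    challenge_start_scaled: float = 20.0,
    challenge_end_scaled: float = 60.0,
) -> NDArray[np.float64]:
    """Affinely map raw clock time (hours) onto the 0–100 analysis scale.

    The map sends the challenge onset to ``challenge_start_scaled`` and its
    end to ``challenge_end_scaled``.  Consistency is required between the
    scaled challenge span and the observation window: duration / window must
    equal (end - start) / 100, otherwise the same affine map cannot send the
    window onto [0, 100].

    For the reference design (onset at hour 0, 4-h challenge, window from
    hour -2 to +8) this is ``scaled_t = (t_hours + 2) * 10``.
    """
    if not challenge_duration > 0:
        raise ValueError("challenge_duration must be > 0")
    span = challenge_end_scaled - challenge_start_scaled
    if not span > 0:
        raise ValueError("scaled challenge bounds must be increasing")
    if abs(challenge_duration / window_hours - span / 100.0) > 1e-9:
        raise ValueError(
            "inconsistent window/challenge proportions: "
            f"duration/window = {challenge_duration / window_hours:g} but "
            f"scaled span/100 = {span / 100.0:g}"
        )
    t = np.asarray(times_raw, dtype=float)
    return challenge_start_scaled + (t - challenge_onset) * (span / challenge_duration)
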