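"""Synthetic cohorts with known ground-truth (K, C).

Emulates the statistical structure of the reference confinement experiment:
2 isogenic lines x 2 replicates x 4 aquaria (the statistical individuals),
four measures — two physiological (cortisol release rate, oxygen consumption)
sampled sparsely through the whole window including the challenge, and two
behavioral (group activity, group dispersion) that cannot be observed while
the fish are confined, hence have no in-challenge time points.  Observation
times live on the 0–100 analysis scale with the challenge between 20 and 60.

Each individual x measure draws its (K, C) lognormally around a per-line
median, simulates the closed-form response with F_pert = 0.1 and perc = 1,
and converts to a raw measurement scale as ``baseline * (1 + x)`` — so raw
series are unit-contaminated and require fold-change normalization — before
multiplicative observation noise is applied.  Because x has rest value 0 and
the designs always sample the rest state, dividing by the baseline and
subtracting the minimum reconstructs x up to noise, making preprocessing a
genuine inverse of generation.

The default per-line medians follow the fitted per-line parameter pattern of
the reference study (line R stiffer than line A for the physiological
measures, the reverse for group dispersion), so cohort-level contrasts have
a known expected direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import ModelParams, simulate_closed_form
from .preprocess import ObservationSeries

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "plant_outliers",
    "TROUT_MEASURES",
    "PHYSIO_SAMPLING",
    "BEHAVIOR_SAMPLING",
    "DEFAULT_LINE_MEDIANS",
    "DEFAULT_BASELINES",
]

TROUT_MEASURES = (
    "cortisol_release",
    "oxygen_consumption",
    "group_activity",
    "group_dispersion",
)

#: Sparse sampling for physiological measures: water samplings / oxygen
#: readings every hour-equivalent, including during the challenge.
PHYSIO_SAMPLING = np.array([0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 100.0])

#: Behavioral measures (short film records) are dense before and after the
#: challenge but absent during it — confinement makes them unobservable.
BEHAVIOR_SAMPLING = np.array(
    [0.0, 5.0, 10.0, 15.0, 62.0, 65.0, 70.0, 75.0, 80.0, 85.0, 90.0, 95.0, 100.0]
)

DEFAULT_SAMPLING = {
    "cortisol_release": PHYSIO_SAMPLING,
    "oxygen_consumption": PHYSIO_SAMPLING,
    "group_activity": BEHAVIOR_SAMPLING,
    "group_dispersion": BEHAVIOR_SAMPLING,
}

#: Per-line median (K, C), mirroring the per-line fitted values of the
#: reference confinement study.
DEFAULT_LINE_MEDIANS = {
    "A": {
        "cortisol_release": (0.018, 0.302),
        "oxygen_consumption": (0.080, 1.074),
        "group_activity": (0.120, 0.740),
        "group_dispersion": (0.453, 3.871),
    },
    "R": {
        "cortisol_release": (0.039, 0.537),
        "oxygen_consumption": (0.179, 1.449),
        "group_activity": (0.126, 2.428),
        "group_dispersion": (0.245, 5.791),
    },
}

#: Raw-scale baselines spanning a 100-fold range across measures, so the raw
#: series genuinely need fold-change normalization.
DEFAULT_BASELINES = {
    "cortisol_release": 200.0,
    "oxygen_consumption": 20.0,
    "group_activity": 2.0,
    "group_dispersion": 5.0,
}


@dataclass(frozen=True)
class CohortSpec:
    """Design of one synthetic cohort.

    ``dispersion`` is the between-individual lognormal scale (SD of log K and
    log C around the line median).  ``measure_corr`` adds an equicorrelation
    across measures of an individual's log-parameters, for studying
    between-measure parameter correlations; 0 means independent draws.
    ``noise_sigma`` is the multiplicative observation-noise fraction.
    """

    n_replicates: int = 2
    n_individuals_per_cell: int = 4
    measures: tuple[str, ...] = TROUT_MEASURES
    line_medians: dict = field(default_factory=lambda: DEFAULT_LINE_MEDIANS)
    dispersion: float = 0.3
    baseline_scale: dict = field(default_factory=lambda: DEFAULT_BASELINES)
    noise_sigma: float = 0.05
    sampling_times: dict = field(default_factory=lambda: DEFAULT_SAMPLING)
    measure_corr: float = 0.0
    F_pert: float = 0.1
    perc: float = 1.0
    tau1: float = 20.0
    tau2: float = 60.0
    seed: int = 0

    @property
    def lines(self) -> tuple[str, ...]:
        return tuple(self.line_medians)

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.n_individuals_per_cell < 1:
            raise ValueError("counts must be >= 1")
        if not self.line_medians:
            raise ValueError("line_medians must define at least one line")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not (0.0 <= self.measure_corr < 1.0):
            raise ValueError("measure_corr must be in [0, 1)")
        for line, med in self.line_medians.items():
            for m in self.measures:
                if m not in med:
                    raise ValueError(f"line {line!r} lacks medians for {m!r}")
                K, C = med[m]
                if K <= 0 or C <= 0:
                    raise ValueError(f"medians must be positive ({line}/{m})")
        for m in self.measures:
            if m not in self.baseline_scale:
                raise ValueError(f"no baseline for measure {m!r}")
            if m not in self.sampling_times:
                raise ValueError(f"no sampling times for measure {m!r}")


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated raw series plus the ground-truth parameter table.

    ``truth`` has one row per individual x measure with columns
    individual_id, measure, line, replicate, K, C, baseline, planted_outlier.
    """

    series: tuple[ObservationSeries, ...]
    truth: pd.DataFrame
    spec: CohortSpec


def _equicorr_chol(n: int, rho: float) -> np.ndarray:
    R = np.full((n, n), rho)
    np.fill_diagonal(R, 1.0)
    return np.linalg.cholesky(R)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full cohort from ``spec``; bitwise reproducible given the seed."""
    rng = np.random.default_rng(spec.seed)
    nm = len(spec.measures)
    L = _equicorr_chol(nm, spec.measure_corr) if spec.measure_corr > 0 else np.eye(nm)
    series: list[ObservationSeries] = []
    truth_rows = []
    for line in spec.lines:
        for rep in range(1, spec.n_replicates + 1):
            for i in range(1, spec.n_individuals_per_cell + 1):
                ind = f"aq_{line}_r{rep}_{i}"
                zK = L @ rng.standard_normal(nm)
                zC = L @ rng.standard_normal(nm)
                for j, meas in enumerate(spec.measures):
                    mK, mC = spec.line_medians[line][meas]
                    K = mK * float(np.exp(spec.dispersion * zK[j]))
                    C = mC * float(np.exp(spec.dispersion * zC[j]))
                    params = ModelParams(
                        K=K, C=C, F_pert=spec.F_pert, perc=spec.perc,
                        tau1=spec.tau1, tau2=spec.tau2,
                    )
                    times = np.asarray(spec.sampling_times[meas], dtype=float)
                    x = simulate_closed_form(params, times, x0=0.0).x
                    baseline = spec.baseline_scale[meas]
                    raw = baseline * (1.0 + x)
                    if spec.noise_sigma > 0:
                        raw = raw * (
                            1.0 + spec.noise_sigma * rng.standard_normal(times.size)
                        )
                    series.append(ObservationSeries(
                        individual_id=ind, measure=meas,
                        times=times, values=raw,
                        line=line, replicate=f"rep{rep}",
                    ))
                    truth_rows.append({
                        "individual_id": ind, "measure": meas,
                        "line": line, "replicate": f"rep{rep}",
                        "K": K, "C": C, "baseline": baseline,
                        "planted_outlier": False,
                    })
    return SyntheticCohort(tuple(series), pd.DataFrame(truth_rows), spec)


def plant_outliers(
    cohort: SyntheticCohort,
    k_outliers: int,
    magnitude: float,
    measure: str = "cortisol_release",
    seed: int = 0,
) -> tuple[SyntheticCohort, list[str]]:
    """Inflate the responses of ``k_outliers`` individuals in one measure.

    The deviation from baseline of each chosen series is multiplied by
    ``magnitude``, which drives the fitted K and C down by roughly the same
    factor — far outside the Tukey fences of the rest of the cohort for large
    magnitudes.  ``magnitude = 1`` leaves the cohort unchanged.  Returns the
    modified cohort and the chosen individual ids.
    """
    individuals = sorted({s.individual_id for s in cohort.series})
    if k_outliers > len(individuals):
        raise ValueError("k_outliers exceeds cohort size")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(individuals, size=k_outliers, replace=False).tolist())
    baseline = cohort.spec.baseline_scale[measure]
    new_series = []
    for s in cohort.series:
        if magnitude != 1.0 and s.individual_id in chosen and s.measure == measure:
            dev = s.values / baseline - 1.0
            new_series.append(replace(s, values=baseline * (1.0 + magnitude * dev)))
        else:
            new_series.append(s)
    truth = cohort.truth.copy()
    planted = truth["individual_id"].isin(chosen) & (truth["measure"] == measure)
    if magnitude != 1.0:
        truth.loc[planted, "planted_outlier"] = True
    return SyntheticCohort(tuple(new_series), truth, cohort.spec), chosen
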