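"""Overwintering statistics, habitat grading and source-sink classification.

The overwintering success rate of a pond is the ratio of the early-spring to
the late-autumn quantitative capture counts. Ponds enter rate-based analyses
only when their autumn count strictly exceeds the basin median (the survey's
realized median is 10, so a pond with exactly 10 autumn captures is
excluded).

Habitat quality is summarised on a five-grade radar profile: each factor is
rank-binned into five grades with the cohort median at grade 3; factors
where smaller is better (concrete revetment, shore gradient, inflow count)
have their grades reversed so that grade 5 always means favourable.

Source-sink labels combine the radar grades with overwintering evidence:
a pond with high density and high haplotype diversity that overwinters
successfully is a source; an occupied pond whose population collapses over
winter is a sink; ponds with zero autumn density are unoccupied; everything
else is intermediate. The grade and rate thresholds are configuration
defaults chosen to reproduce the survey's named examples; they are not
field-measured constants and remain configurable.

A small IRLS engine fits the binomial/Poisson generalized linear models used
to relate overwintering success (and capture counts) to habitat covariates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import StatisticError, ValidationError
from .io_survey import PondEnvironment

__all__ = [
    "OverwinteringRecord",
    "RadarProfile",
    "SourceSinkCall",
    "SourceSinkThresholds",
    "GlmFit",
    "overwintering_rate",
    "median_inclusion_threshold",
    "grade_factor",
    "radar_profile",
    "radar_profiles",
    "classify_source_sink",
    "glm_fit",
]

DEFAULT_INCLUSION_THRESHOLD = 10

#: axis -> direction for the six radar factors; grade 5 is always favourable.
RADAR_AXES = {
    "surface_area": "higher_better",
    "concrete_revetment_rate": "lower_better",
    "shore_gradient_mean": "lower_better",
    "inflow_count": "lower_better",
    "density": "higher_better",
    "hd": "higher_better",
}


@dataclass(frozen=True)
class OverwinteringRecord:
    """Autumn/spring capture counts with the derived success rate.

    ``rate`` is undefined (None) when nothing was caught in autumn. A rate
    above 1 (more captures in spring than autumn) is reported as-is with
    ``rate_exceeds_one`` set, never clamped.
    """

    site_id: str
    autumn_count: int
    spring_count: int
    rate: float | None
    included: bool

    @property
    def rate_exceeds_one(self) -> bool:
        return self.rate is not None and self.rate > 1.0


def overwintering_rate(
    autumn: int,
    spring: int,
    inclusion_threshold: int = DEFAULT_INCLUSION_THRESHOLD,
    site_id: str = "",
) -> OverwinteringRecord:
    """Overwintering success rate with the strict median inclusion rule.

    ``included`` is True only when the autumn count strictly exceeds the
    threshold, so a pond at exactly the threshold stays out.
    """
    if autumn < 0 or spring < 0:
        raise ValidationError("capture counts must be non-negative")
    rate = spring / autumn if autumn > 0 else None
    return OverwinteringRecord(
        site_id=str(site_id),
        autumn_count=int(autumn),
        spring_count=int(spring),
        rate=rate,
        included=autumn > inclusion_threshold,
    )


def median_inclusion_threshold(autumn_counts) -> int:
    """Sample median of autumn counts, floored to an integer when fractional."""
    counts = np.asarray(autumn_counts, dtype=float).ravel()
    if counts.size == 0:
        raise ValidationError("no autumn counts supplied")
    return int(math.floor(float(np.median(counts))))


# ---------------------------------------------------------------------------
# five-grade radar evaluation
# ---------------------------------------------------------------------------

def grade_factor(
    values: Mapping[str, float], direction: str = "higher_better"
) -> dict[str, int]:
    """Rank-based five-grade evaluation of one factor across a cohort.

    Ranks are binned at the 20/40/60/80 percentiles of the rank scale, which
    places the cohort median in grade 3 by construction and makes the grades
    invariant under any monotone transformation of the raw values. Tied
    values share their (average) rank and therefore their grade. With
    ``lower_better`` the grades are reversed (6 - g).
    """
    if direction not in ("higher_better", "lower_better"):
        raise ValidationError("direction must be 'higher_better' or 'lower_better'")
    sites = list(values)
    data = np.asarray([float(values[s]) for s in sites])
    if data.size == 0:
        raise ValidationError("no values to grade")
    if np.all(data == data[0]):
        warnings.warn("all values identical; every site graded 3", stacklevel=2)
        return {s: 3 for s in sites}
    from scipy.stats import rankdata

    ranks = rankdata(data, method="average")
    # relative rank in (0, 1); median rank -> 0.5 -> bin 3
    relative = (ranks - 0.5) / data.size
    grades = np.minimum(np.floor(relative * 5).astype(int) + 1, 5)
    if direction == "lower_better":
        grades = 6 - grades
    return {s: int(g) for s, g in zip(sites, grades)}


@dataclass(frozen=True)
class RadarProfile:
    """Five-grade profile of one pond over the six assessment axes."""

    site_id: str
    grades: dict[str, int]

    @property
    def area_score(self) -> int:
        """Sum of grades; a balance diagnostic for 'large and well-balanced' charts."""
        return sum(self.grades.values())


def radar_profiles(
    ponds: Sequence[PondEnvironment],
    densities: Mapping[str, float],
    hds: Mapping[str, float],
) -> dict[str, RadarProfile]:
    """Radar profiles for every pond in the cohort.

    ``densities`` are autumn capture densities (count per unit effort or raw
    counts, grading is rank-based so either works) and ``hds`` per-pond
    haplotype diversities; both must cover every pond.
    """
    missing = [p.site_id for p in ponds if p.site_id not in densities]
    if missing:
        raise ValidationError(f"densities missing for ponds: {missing}")
    missing = [p.site_id for p in ponds if p.site_id not in hds]
    if missing:
        raise ValidationError(f"hd values missing for ponds: {missing}")
    axis_values: dict[str, dict[str, float]] = {
        "surface_area": {p.site_id: p.surface_area for p in ponds},
        "concrete_revetment_rate": {
            p.site_id: p.concrete_revetment_rate for p in ponds
        },
        "shore_gradient_mean": {p.site_id: p.shore_gradient_mean for p in ponds},
        "inflow_count": {p.site_id: float(p.inflow_count) for p in ponds},
        "density": {p.site_id: float(densities[p.site_id]) for p in ponds},
        "hd": {p.site_id: float(hds[p.site_id]) for p in ponds},
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        axis_grades = {
            axis: grade_factor(values, RADAR_AXES[axis])
            for axis, values in axis_values.items()
        }
    return {
        p.site_id: RadarProfile(
            site_id=p.site_id,
            grades={axis: axis_grades[axis][p.site_id] for axis in RADAR_AXES},
        )
        for p in ponds
    }


def radar_profile(
    pond: PondEnvironment,
    density: float,
    hd: float,
    cohort: Sequence[tuple[PondEnvironment, float, float]],
) -> RadarProfile:
    """Radar profile of one pond graded against its cohort.

    ``cohort`` lists (pond, density, hd) for every pond in the comparison
    set and must contain the pond itself.
    """
    ids = [p.site_id for p, _, _ in cohort]
    if pond.site_id not in ids:
        raise ValidationError(f"pond {pond.site_id} not in cohort")
    index = ids.index(pond.site_id)
    member, member_density, member_hd = cohort[index]
    if member_density != density or member_hd != hd:
        raise ValidationError(
            f"pond {pond.site_id}: density/hd disagree with the cohort entry"
        )
    profiles = radar_profiles(
        [p for p, _, _ in cohort],
        {p.site_id: dens for p, dens, _ in cohort},
        {p.site_id: h for p, _, h in cohort},
    )
    return profiles[pond.site_id]


# ---------------------------------------------------------------------------
# source-sink classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SourceSinkThresholds:
    """Configurable decision thresholds for the source-sink rules."""

    source_density_grade: int = 4
    source_hd_grade: int = 4
    source_min_rate: float = 0.25
    sink_max_rate: float = 0.10
    sink_density_grade: int = 2
    collapse_fraction: float = 0.25  # spring < autumn * fraction counts as collapse


@dataclass(frozen=True)
class SourceSinkCall:
    """Per-pond metapopulation role with the evidence that produced it."""

    site_id: str
    label: str  # source | sink | intermediate | unoccupied
    density_grade: int
    hd_grade: int
    rate: float | None
    included: bool
    flags: tuple[str, ...] = ()


def classify_source_sink(
    profile: RadarProfile,
    overwinter: OverwinteringRecord,
    thresholds: SourceSinkThresholds | None = None,
) -> SourceSinkCall:
    """Deterministic source/sink/intermediate/unoccupied label for one pond.

    Rules, in order:
      * unoccupied - nothing caught in autumn;
      * source - density and haplotype-diversity grades both high, and
        overwintering not observed to fail (rate above the source floor, or
        no usable rate because the pond fell below the inclusion rule);
      * sink - an included pond whose success rate is below the sink
        ceiling, or a low-density pond whose spring count collapsed;
      * intermediate - everything else.
    """
    if profile.site_id != overwinter.site_id:
        raise ValidationError(
            f"profile is for {profile.site_id} but record is for {overwinter.site_id}"
        )
    t = thresholds or SourceSinkThresholds()
    density_grade = profile.grades["density"]
    hd_grade = profile.grades["hd"]
    rate = overwinter.rate
    flags: list[str] = []
    if overwinter.rate_exceeds_one:
        flags.append("rate_exceeds_one")
    if overwinter.autumn_count == 0:
        label = "unoccupied"
    else:
        collapse = overwinter.spring_count < overwinter.autumn_count * t.collapse_fraction
        overwinter_ok = (rate is not None and rate >= t.source_min_rate) or (
            rate is None and not overwinter.included
        )
        if (
            density_grade >= t.source_density_grade
            and hd_grade >= t.source_hd_grade
            and overwinter_ok
        ):
            label = "source"
        elif overwinter.included and rate is not None and rate < t.sink_max_rate:
            label = "sink"
            flags.append("overwinter_failure")
        elif density_grade <= t.sink_density_grade and collapse:
            label = "sink"
            flags.append("spring_collapse")
        else:
            label = "intermediate"
    return SourceSinkCall(
        site_id=profile.site_id,
        label=label,
        density_grade=density_grade,
        hd_grade=hd_grade,
        rate=rate,
        included=overwinter.included,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# GLM via IRLS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlmFit:
    """IRLS fit of a canonical-link binomial or Poisson GLM."""

    family: str
    coefficients: np.ndarray
    standard_errors: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    deviance: float
    converged: bool
    iterations: int


def _prepare_design(covariates, n_rows: int) -> np.ndarray:
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != n_rows:
        raise ValidationError("covariate rows do not match the response length")
    return np.column_stack([np.ones(n_rows), x])


def glm_fit(
    response,
    covariates,
    family: str = "binomial",
    max_iter: int = 100,
    tol: float = 1e-9,
) -> GlmFit:
    """Fit a GLM by iteratively reweighted least squares.

    ``response`` is either a 1-d vector (Poisson counts or Bernoulli 0/1) or
    a (successes, trials) pair for grouped binomial data. An intercept column
    is always prepended to ``covariates``. Canonical links (logit, log) are
    used; Wald z statistics and two-sided p-values are reported per
    coefficient. Non-convergence (e.g. perfect separation) is flagged, the
    last coefficients are still reported with a warning.
    """
    if family not in ("binomial", "poisson"):
        raise ValidationError("family must be 'binomial' or 'poisson'")
    if family == "binomial" and isinstance(response, tuple):
        successes = np.asarray(response[0], dtype=float).ravel()
        trials = np.asarray(response[1], dtype=float).ravel()
        if successes.size != trials.size:
            raise ValidationError("successes and trials differ in length")
        if np.any(trials <= 0):
            raise ValidationError("trials must be positive")
        if np.any(successes > trials):
            raise ValidationError("successes cannot exceed trials")
        y = successes / trials
        weights_prior = trials
    else:
        y = np.asarray(response, dtype=float).ravel()
        if family == "binomial" and np.any((y < 0) | (y > 1)):
            raise ValidationError("bernoulli responses must lie in [0, 1]")
        if family == "poisson" and np.any(y < 0):
            raise ValidationError("poisson counts must be non-negative")
        weights_prior = np.ones_like(y)
    x = _prepare_design(covariates, y.size)
    n, p = x.shape
    if n < p:
        raise ValidationError(f"need at least {p} rows for {p} coefficients")
    if np.linalg.matrix_rank(x) < p:
        raise np.linalg.LinAlgError("singular design matrix")
    beta = np.zeros(p)
    if family == "binomial":
        mu = np.clip((weights_prior * y + 0.5) / (weights_prior + 1.0), 1e-10, 1 - 1e-10)
        eta = np.log(mu / (1 - mu))
    else:
        mu = np.clip(y, 0.1, None)
        eta = np.log(mu)
    deviance = _deviance(y, mu, weights_prior, family)
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        if family == "binomial":
            variance = mu * (1 - mu)
        else:
            variance = mu
        w = weights_prior * variance  # canonical link: W = m * V(mu)
        z = eta + (y - mu) / np.clip(variance, 1e-12, None)
        wx = x * w[:, None]
        try:
            beta = np.linalg.solve(x.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError:
            warnings.warn("IRLS normal equations singular; stopping", stacklevel=2)
            break
        eta = x @ beta
        if family == "binomial":
            mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
        else:
            mu = np.clip(np.exp(np.clip(eta, -30, 30)), 1e-12, None)
        new_deviance = _deviance(y, mu, weights_prior, family)
        if abs(new_deviance - deviance) < tol * (abs(deviance) + 0.1):
            deviance = new_deviance
            converged = True
            break
        deviance = new_deviance
    if family == "binomial" and converged and np.max(np.abs(eta)) > 15.0:
        # fitted probabilities numerically 0 or 1: perfect separation
        converged = False
    if not converged:
        warnings.warn(
            "IRLS did not converge (possible separation); "
            "coefficients reported as-is",
            stacklevel=2,
        )
    if family == "binomial":
        variance = mu * (1 - mu)
    else:
        variance = mu
    w = weights_prior * variance
    information = x.T @ (x * w[:, None])
    covariance = np.linalg.pinv(information)
    se = np.sqrt(np.clip(np.diag(covariance), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z_values = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    from scipy.stats import norm

    p_values = 2.0 * norm.sf(np.abs(z_values))
    return GlmFit(
        family=family,
        coefficients=beta,
        standard_errors=se,
        z_values=z_values,
        p_values=p_values,
        deviance=float(deviance),
        converged=converged,
        iterations=iteration,
    )


def _deviance(y, mu, m, family: str) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        if family == "binomial":
            term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
            term2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
            return float(2.0 * np.sum(m * (term1 + term2)))
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2.0 * np.sum(m * (term - (y - mu))))
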