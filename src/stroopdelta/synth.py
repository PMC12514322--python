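"""Synthetic multi-study spatial-Stroop cohort generator.

The generator produces trial-level reaction times (RTs) whose congruency
effect has a *known closed form at every percentile of the RT
distribution*, so the downstream quantile/delta machinery can be validated
exactly.

Model
-----
For one participant and one target type, congruent RTs are drawn from an
ex-Gaussian law ``X ~ exGauss(mu, sigma, tau)`` (the canonical right-skewed
RT distribution).  Incongruent RTs are a monotone warp of the same law::

    RT_inc = g(X) = X + delta(F(X)),

where ``F`` is the congruent CDF and ``delta(p) = a + b*p + c*p**2`` is a
percentile-indexed congruency shift.  Because ``g`` is strictly increasing,
the population ``q``-quantile of the incongruent distribution is exactly
``Q_cong(q) + delta(q)`` — the ground-truth contract every recovery test
relies on.  Additive study/participant offsets shift both conditions
equally and therefore cancel in the quantile difference.

A positive, flat-ish profile mimics the standard congruency effect (SCE)
seen with arrow targets; a negative profile that is null at the fastest
percentiles and grows with p mimics the reversed congruency effect (RCE)
reported for face/eye targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExGaussian",
    "DeltaProfile",
    "SimConfig",
    "MonotonicityError",
    "make_delta_profile",
    "theoretical_delta",
    "theoretical_quantiles",
    "simulate_participant",
    "simulate_cohort",
    "DEFAULT_BASELINES",
    "DEFAULT_PROFILES",
    "TARGET_TYPES",
    "CONGRUENCIES",
    "TRIAL_COLUMNS",
]

TARGET_TYPES = ("face", "eyes", "arrows")
CONGRUENCIES = ("congruent", "incongruent")
TRIAL_COLUMNS = [
    "study_id",
    "participant_id",
    "target_type",
    "congruency",
    "rt_ms",
    "accuracy",
    "responded",
]


class MonotonicityError(ValueError):
    """Raised when a delta profile breaks the monotone-warp requirement."""


@dataclass(frozen=True)
class ExGaussian:
    """Ex-Gaussian RT baseline: Normal(mu, sigma) + Exponential(tau), in ms."""

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.tau <= 0:
            raise ValueError("sigma and tau must be positive")

    @property
    def mean(self) -> float:
        return self.mu + self.tau

    def _dist(self) -> stats.rv_continuous:
        return stats.exponnorm(K=self.tau / self.sigma, loc=self.mu, scale=self.sigma)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        return self._dist().cdf(x)

    def ppf(self, p: np.ndarray) -> np.ndarray:
        return self._dist().ppf(p)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.mu, self.sigma, size) + rng.exponential(self.tau, size)


@dataclass(frozen=True)
class DeltaProfile:
    """Percentile-indexed congruency shift ``delta(p) = a + b*p + c*p**2`` (ms).

    ``a`` is the shift at p -> 0 (ms); ``b`` is ms per unit percentile;
    ``c`` is ms per squared percentile.  A profile is only usable with a
    baseline for which the induced incongruent warp stays strictly
    increasing; :func:`make_delta_profile` enforces this.
    """

    a: float
    b: float
    c: float = 0.0

    def __call__(self, p: np.ndarray | float) -> np.ndarray | float:
        p = np.asarray(p, dtype=float)
        out = self.a + self.b * p + self.c * p * p
        return float(out) if out.ndim == 0 else out


_GRID_SIZE = 10_000
_GRID_EPS = 1e-4


def make_delta_profile(
    a: float, b: float, c: float = 0.0, *, baseline: ExGaussian
) -> DeltaProfile:
    """Build a :class:`DeltaProfile`, verifying the monotone-warp condition.

    The warp ``g(x) = x + delta(F(x))`` is evaluated on a 10^4-point grid
    spanning baseline quantiles 1e-4 .. 1-1e-4 and must be strictly
    increasing; otherwise incongruent quantiles would no longer equal
    ``Q_cong(q) + delta(q)`` and a :class:`MonotonicityError` is raised
    naming the first offending grid point.
    """
    profile = DeltaProfile(float(a), float(b), float(c))
    lo, hi = baseline.ppf(np.array([_GRID_EPS, 1.0 - _GRID_EPS]))
    x = np.linspace(lo, hi, _GRID_SIZE)
    grid_p = baseline.cdf(x)
    g = x + profile(grid_p)
    diffs = np.diff(g)
    bad = np.nonzero(diffs <= 0)[0]
    if bad.size:
        i = int(bad[0])
        raise MonotonicityError(
            f"delta profile (a={a}, b={b}, c={c}) makes the incongruent warp "
            f"non-increasing at x={x[i]:.2f} ms (p={grid_p[i]:.4f}): "
            f"g({x[i]:.2f})={g[i]:.2f} >= g({x[i + 1]:.2f})={g[i + 1]:.2f}"
        )
    return profile


def theoretical_delta(profile: DeltaProfile, probs) -> np.ndarray:
    """Closed-form delta(p) at the given percentiles — the recovery oracle."""
    probs = np.asarray(probs, dtype=float)
    if np.any((probs <= 0) | (probs >= 1)):
        raise ValueError("probs must lie strictly inside (0, 1)")
    return np.asarray(profile(probs), dtype=float)


def theoretical_quantiles(
    baseline: ExGaussian, profile: DeltaProfile, probs
) -> pd.DataFrame:
    """Population quantiles per congruency plus delta/meanRT at ``probs``.

    Returns columns prob, q_congruent, q_incongruent, delta, mean_rt; the
    incongruent quantile is exactly ``Q_cong(p) + delta(p)``.
    """
    probs = np.asarray(probs, dtype=float)
    qc = baseline.ppf(probs)
    d = theoretical_delta(profile, probs)
    return pd.DataFrame(
        {
            "prob": probs,
            "q_congruent": qc,
            "q_incongruent": qc + d,
            "delta": d,
            "mean_rt": qc + d / 2.0,
        }
    )


# Defaults emulate the multi-study spatial-Stroop cohort the package is
# aimed at: a flat-ish positive profile for arrows (SCE across the whole
# distribution) and negative profiles for face/eyes that are null at the
# fastest percentile and grow (saturating) with p (RCE from the second
# quantile on).  Quantile-averaged magnitudes sit near +31 / -30 / -22 ms.
DEFAULT_BASELINES: dict[str, ExGaussian] = {
    "arrows": ExGaussian(380.0, 40.0, 110.0),
    "face": ExGaussian(460.0, 45.0, 140.0),
    "eyes": ExGaussian(460.0, 45.0, 140.0),
}

DEFAULT_PROFILES: dict[str, DeltaProfile] = {
    "arrows": DeltaProfile(28.0, 5.0, 1.0),
    "face": DeltaProfile(11.6, -122.2, 60.0),
    "eyes": DeltaProfile(8.65, -91.0, 45.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic multi-study cohort.

    ``study_sd`` / ``participant_sd`` are SDs (ms) of additive normal
    offsets drawn once per study / participant; they shift both congruency
    conditions equally.  ``contamination`` is ``(rate, low_ms, high_ms)``:
    with probability ``rate`` a trial's RT is replaced by a uniform draw
    from the part of [low_ms, high_ms] lying outside the canonical
    200-1300 ms analysis window (anticipations / lapses).
    """

    n_studies: int = 11
    participants_per_study: int = 64
    trials_per_cell: int = 48
    target_types: tuple[str, ...] = TARGET_TYPES
    baselines: dict[str, ExGaussian] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    profiles: dict[str, DeltaProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    study_sd: float = 25.0
    participant_sd: float = 40.0
    error_rate: float = 0.06
    nonresponse_rate: float = 0.02
    contamination: tuple[float, float, float] = (0.01, 100.0, 2000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_studies, self.participants_per_study, self.trials_per_cell) < 1:
            raise ValueError("counts must be >= 1")
        if self.study_sd < 0 or self.participant_sd < 0:
            raise ValueError("offset SDs must be >= 0")
        for r in (self.error_rate, self.nonresponse_rate, self.contamination[0]):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        unknown = set(self.target_types) - set(TARGET_TYPES)
        if unknown:
            raise ValueError(f"unknown target types: {sorted(unknown)}")
        for t in self.target_types:
            if t not in self.baselines or t not in self.profiles:
                raise ValueError(f"missing baseline or profile for target {t!r}")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def simulate_participant(
    baseline: ExGaussian,
    profile: DeltaProfile,
    trials_per_cell: int,
    offset: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Draw one participant's congruent and incongruent RTs for one target.

    Congruent RTs are ``X + offset`` with ``X ~ exGauss(baseline)``;
    incongruent RTs are ``g(X') + offset`` with ``g(x) = x + delta(F(x))``
    applied to an independent draw ``X'``.  Returns clean RTs; error /
    non-response / contamination flags are applied at cohort level.
    """
    x_c = baseline.rvs(trials_per_cell, rng)
    x_i = baseline.rvs(trials_per_cell, rng)
    rt_inc = x_i + np.asarray(profile(baseline.cdf(x_i)), dtype=float)
    return {"congruent": x_c + offset, "incongruent": rt_inc + offset}


def _contaminate(
    rt: np.ndarray, rate: float, low: float, high: float, rng: np.random.Generator
) -> np.ndarray:
    """Replace a ``rate`` fraction of RTs with uniform draws from the part
    of [low, high] outside the 200-1300 ms window (both tails if spanned)."""
    if rate <= 0:
        return rt
    segs = []
    if low < 200.0:
        segs.append((low, min(high, 200.0)))
    if high > 1300.0:
        segs.append((max(low, 1300.0), high))
    if not segs:
        segs = [(low, high)]
    lengths = np.array([b - a for a, b in segs], dtype=float)
    hit = rng.random(rt.size) < rate
    n_hit = int(hit.sum())
    if n_hit == 0:
        return rt
    seg_idx = rng.choice(len(segs), size=n_hit, p=lengths / lengths.sum())
    draws = np.array(
        [rng.uniform(segs[j][0], segs[j][1]) for j in seg_idx], dtype=float
    )
    out = rt.copy()
    out[hit] = draws
    return out


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate a full trial table (one row per trial) for the configured cohort.

    Offsets are drawn once per study and once per participant; incorrect
    trials, non-responses (missing RT) and contaminated RTs occur at the
    configured rates.  Identical config + seed yields an identical table.
    """
    rng = np.random.default_rng(config.seed)
    rate, lo, hi = config.contamination
    rows: list[pd.DataFrame] = []
    for s in range(config.n_studies):
        study_id = f"study{s + 1:02d}"
        study_off = rng.normal(0.0, config.study_sd) if config.study_sd else 0.0
        for j in range(config.participants_per_study):
            pid = f"p{j + 1:03d}"
            part_off = (
                rng.normal(0.0, config.participant_sd) if config.participant_sd else 0.0
            )
            offset = study_off + part_off
            for target in config.target_types:
                draws = simulate_participant(
                    config.baselines[target],
                    config.profiles[target],
                    config.trials_per_cell,
                    offset,
                    rng,
                )
                for cong in CONGRUENCIES:
                    rt = _contaminate(draws[cong], rate, lo, hi, rng)
                    n = rt.size
                    accuracy = rng.random(n) >= config.error_rate
                    responded = rng.random(n) >= config.nonresponse_rate
                    rt = np.where(responded, rt, np.nan)
                    accuracy = accuracy & responded
                    rows.append(
                        pd.DataFrame(
                            {
                                "study_id": study_id,
                                "participant_id": pid,
                                "target_type": target,
                                "congruency": cong,
                                "rt_ms": rt,
                                "accuracy": accuracy,
                                "responded": responded,
                            }
                        )
                    )
    out = pd.concat(rows, ignore_index=True)
    return out[TRIAL_COLUMNS]


def write_trials_csv(table: pd.DataFrame, path) -> None:
    """Write a trial table as CSV; missing RTs become empty fields."""
    table.to_csv(path, index=False, float_format="%.6f")
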