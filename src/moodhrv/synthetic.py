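"""Synthetic cohorts and wearable streams with known ground truth.

The generator emulates the structure of the study cohort the analysis was
designed for: 23 subjects (14 recruited in mania, 9 in depression), each
assessed 3–4 times over an acute episode with strictly decreasing YMRS/HDRS
totals ending at or below the euthymia threshold of 7. Night lnRMSSD values
are drawn from the same hierarchical generative process the models assume:

    lnRMSSD[i,t] ~ N(beta0[i] + beta1[i] * I[i,t] + beta2 * M[i,t], sigma[i])
    beta0[i]     ~ N(alpha0 + alpha1*A[i] + alpha2*S[i] + alpha3*B[i], 0.5)
    beta1[i]     ~ N(gamma[polarity[i]], 0.1)
    sigma[i]     ~ InvGamma(3, 0.5)

Setting ``gamma_mania == gamma_depression`` reproduces the polarity-free
generative process. All latent draws are recorded in a :class:`GroundTruth`
for recovery tests. Raw wearable streams (RR intervals + 4 Hz EDA) with a
controllable true RMSSD, artifact rate and off-body segments are produced
by :func:`generate_night_recording` so the extraction stage can be
round-tripped against a known answer.

Seeding: one base seed per config; per-subject, per-session and
per-replicate child seeds are derived with ``numpy.random.SeedSequence``
spawning, so any subset regenerates identically on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MEDICATION_CLASSES, Assessment, Polarity, Subject, standardize_age
from .errors import ConfigError, DomainError, IntervalError
from .hrv import RawRecording

__all__ = [
    "TrueParams",
    "CohortConfig",
    "GroundTruth",
    "generate_score_trajectory",
    "generate_cohort",
    "generate_night_recording",
    "simulate_hdi_exclusion_rate",
    "write_cohort_csv",
    "write_session_csv",
]

EUTHYMIA_MAX = 7  # remission threshold on either scale


@dataclass(frozen=True)
class TrueParams:
    """Ground-truth hyperparameters of the generative process.

    Defaults put typical night lnRMSSD near 3.6 (RMSSD ~ 37 ms), covariate
    effects at the prior centre used by the models, and a positive slope of
    0.2 for both polarities (the size of effect the analysis is built to
    detect).
    """

    alpha0: float = 3.6
    alpha1: float = -0.1
    alpha2: float = -0.1
    alpha3: float = -0.1
    beta2: float = -0.05
    gamma_mania: float = 0.2
    gamma_depression: float = 0.2
    sigma_shape: float = 3.0
    sigma_scale: float = 0.5
    sd_beta0: float = 0.5
    sd_beta1: float = 0.1
    #: when set, subject noise scales are fixed at this value instead of
    #: being drawn from the inverse gamma (degenerate-noise testing hook)
    sigma_fixed: float | None = None

    def __post_init__(self) -> None:
        for name in ("gamma_mania", "gamma_depression"):
            g = getattr(self, name)
            if not -1.0 <= g <= 1.0:
                raise ConfigError(f"{name}={g} outside the uniform(-1, 1) support")
        for name in ("sigma_shape", "sigma_scale"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("sd_beta0", "sd_beta1"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")

    def gamma(self, polarity: Polarity) -> float:
        return self.gamma_mania if polarity is Polarity.MANIA else self.gamma_depression


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generator settings; defaults reproduce the study sample."""

    n_mania: int = 14
    n_depression: int = 9
    #: map {3: count, 4: count} over all subjects
    n_assessments_distribution: Mapping[int, int] = field(
        default_factory=lambda: {3: 17, 4: 6}
    )
    baseline_score_mean: Mapping[str, float] = field(
        default_factory=lambda: {"mania": 25.64, "depression": 19.11}
    )
    baseline_score_sd: Mapping[str, float] = field(
        default_factory=lambda: {"mania": 5.09, "depression": 3.21}
    )
    age_mean: Mapping[str, float] = field(
        default_factory=lambda: {"mania": 42.14, "depression": 44.56}
    )
    age_sd: Mapping[str, float] = field(
        default_factory=lambda: {"mania": 12.81, "depression": 13.03}
    )
    female_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"mania": 5 / 14, "depression": 6 / 9}
    )
    medication_count_mean: Mapping[str, float] = field(
        default_factory=lambda: {"mania": 2.86, "depression": 3.78}
    )
    medication_count_sd: Mapping[str, float] = field(
        default_factory=lambda: {"mania": 1.30, "depression": 0.63}
    )
    true_params: TrueParams = field(default_factory=TrueParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mania < 0 or self.n_depression < 0:
            raise ConfigError("n_mania and n_depression must be nonnegative")
        if any(k not in (3, 4) for k in self.n_assessments_distribution):
            raise ConfigError("n_assessments_distribution keys must be 3 or 4")
        if any(v < 0 for v in self.n_assessments_distribution.values()):
            raise ConfigError("n_assessments_distribution counts must be nonnegative")
        total = sum(self.n_assessments_distribution.values())
        if total != self.n_mania + self.n_depression:
            raise ConfigError(
                "n_assessments_distribution must sum to n_mania + n_depression "
                f"({self.n_mania + self.n_depression}), got {total}"
            )
        for fname in ("female_fraction",):
            for pol, v in getattr(self, fname).items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"{fname}[{pol}]={v} outside [0, 1]")


@dataclass
class GroundTruth:
    """Latent draws behind a generated cohort, for recovery tests."""

    true_params: TrueParams
    subject_ids: list[str]
    beta0: np.ndarray
    beta1: np.ndarray
    sigma: np.ndarray
    #: noiseless linear predictor per (subject_id, t)
    noiseless_mean: dict[tuple[str, int], float]


def generate_score_trajectory(
    polarity: Polarity,
    baseline: int,
    n_assessments: int,
    rng: np.random.Generator,
) -> list[int]:
    """Strictly decreasing integer scale totals from baseline to euthymia.

    The final total is drawn uniformly from the feasible euthymic range
    (<= 7) and the intermediate totals uniformly without replacement from
    the integers strictly between, so the trajectory shape is unconstrained
    beyond monotonicity.
    """
    if n_assessments not in (3, 4):
        raise DomainError("n_assessments must be 3 or 4")
    baseline = int(baseline)
    if not 0 <= baseline <= polarity.scale_max:
        raise DomainError(
            f"baseline {baseline} outside [0, {polarity.scale_max}] for {polarity.scale}"
        )
    n_after = n_assessments - 1
    # need final <= 7 and n_after strictly decreasing values below baseline
    max_final = min(EUTHYMIA_MAX, baseline - n_after)
    if max_final < 0:
        raise DomainError(
            f"baseline {baseline} admits no strictly decreasing euthymic "
            f"trajectory of {n_assessments} assessments"
        )
    final = int(rng.integers(0, max_final + 1))
    between = np.arange(final + 1, baseline)
    middle = np.sort(rng.choice(between, size=n_assessments - 2, replace=False))[::-1]
    return [baseline, *(int(m) for m in middle), final]


def _draw_medication_flags(count: int, rng: np.random.Generator) -> dict[str, bool]:
    chosen = rng.choice(len(MEDICATION_CLASSES), size=count, replace=False)
    return {c: (i in set(chosen)) for i, c in enumerate(MEDICATION_CLASSES)}


def generate_cohort(cfg: CohortConfig) -> tuple[list[Subject], GroundTruth]:
    """Draw a full cohort from the hierarchical generative process.

    Returns the subjects (each assessment carries its drawn lnRMSSD) and the
    ground-truth latents. Deterministic given ``cfg`` (including its seed).
    """
    tp = cfg.true_params
    root = np.random.SeedSequence(cfg.seed)
    n_total = cfg.n_mania + cfg.n_depression
    ss_assign, *ss_subjects = root.spawn(1 + n_total)
    rng_assign = np.random.default_rng(ss_assign)

    # assessment-count assignment: shuffle the multiset {3,4} over subjects
    counts = [k for k, v in sorted(cfg.n_assessments_distribution.items()) for _ in range(v)]
    counts = list(rng_assign.permutation(counts))

    polarities = [Polarity.MANIA] * cfg.n_mania + [Polarity.DEPRESSION] * cfg.n_depression
    subjects: list[Subject] = []
    raw: list[dict] = []
    for i, (pol, n_a, ss) in enumerate(zip(polarities, counts, ss_subjects)):
        rng = np.random.default_rng(ss)
        key = pol.value
        age = float(np.clip(rng.normal(cfg.age_mean[key], cfg.age_sd[key]), 18.0, 85.0))
        sex = int(rng.random() < cfg.female_fraction[key])
        baseline = int(
            np.clip(
                round(rng.normal(cfg.baseline_score_mean[key], cfg.baseline_score_sd[key])),
                EUTHYMIA_MAX + 1,
                pol.scale_max,
            )
        )
        med_count = int(
            np.clip(
                round(rng.normal(cfg.medication_count_mean[key], cfg.medication_count_sd[key])),
                0,
                len(MEDICATION_CLASSES),
            )
        )
        flags = _draw_medication_flags(med_count, rng)
        scores = generate_score_trajectory(pol, baseline, int(n_a), rng)
        raw.append(
            dict(i=i, pol=pol, age=age, sex=sex, scores=scores, flags=flags, rng=rng)
        )

    # standardize age across the cohort, as the model table will
    a_std = standardize_age([r["age"] for r in raw])

    beta0 = np.empty(n_total)
    beta1 = np.empty(n_total)
    sigma = np.empty(n_total)
    noiseless: dict[tuple[str, int], float] = {}
    base_dt = datetime(2024, 1, 8, 11, 0, tzinfo=timezone.utc)
    for r in raw:
        i, pol, rng = r["i"], r["pol"], r["rng"]
        sid = f"S{i:03d}"
        b_i = r["scores"][0] / pol.scale_max
        mu_beta0 = tp.alpha0 + tp.alpha1 * a_std[i] + tp.alpha2 * r["sex"] + tp.alpha3 * b_i
        beta0[i] = rng.normal(mu_beta0, tp.sd_beta0)
        beta1[i] = rng.normal(tp.gamma(pol), tp.sd_beta1)
        if tp.sigma_fixed is not None:
            sigma[i] = tp.sigma_fixed
        else:
            sigma[i] = stats.invgamma.rvs(
                tp.sigma_shape, scale=tp.sigma_scale, random_state=rng
            )
        m_i = sum(r["flags"].values())
        assessments = []
        for t, score in enumerate(r["scores"]):
            improvement = (r["scores"][0] - score) / r["scores"][0]
            mu = beta0[i] + beta1[i] * improvement + tp.beta2 * m_i
            y = float(rng.normal(mu, sigma[i]))
            noiseless[(sid, t)] = float(mu)
            assessments.append(
                Assessment(
                    subject_id=sid,
                    t=t,
                    score=score,
                    datetime=base_dt + timedelta(days=14 * t),
                    medication_flags=dict(r["flags"]),
                    ln_rmssd=y,
                )
            )
        subjects.append(
            Subject(
                subject_id=sid,
                polarity=pol,
                age=r["age"],
                sex=r["sex"],
                assessments=assessments,
            )
        )

    truth = GroundTruth(
        true_params=tp,
        subject_ids=[s.subject_id for s in subjects],
        beta0=beta0,
        beta1=beta1,
        sigma=sigma,
        noiseless_mean=noiseless,
    )
    return subjects, truth


def generate_night_recording(
    true_rmssd: float,
    session_start: datetime | None = None,
    duration_s: float = 18 * 3600.0,
    artifact_fraction: float = 0.0,
    offbody_segments: Sequence[tuple[float, float]] = (),
    mean_rr_ms: float = 850.0,
    seed: int | np.random.Generator = 0,
) -> RawRecording:
    """Simulate one session's RR + EDA streams with a known night RMSSD.

    The heart period follows a mean-reverting AR(1) around ``mean_rr_ms``
    whose Gaussian successive differences are calibrated so the expected
    squared successive difference equals ``true_rmssd**2``; periods are
    clipped to the physiological range [300, 1500] ms. Artifacts are
    injected at ``artifact_fraction`` of beats, half as spikes (RR doubled)
    and half as dropouts (two beats merged). EDA runs at 4 Hz around ~1 μS
    on-body and below 0.05 μS inside ``offbody_segments`` (seconds since
    session start).
    """
    if true_rmssd < 0:
        raise DomainError("true_rmssd must be nonnegative")
    if not 0.0 <= artifact_fraction < 1.0:
        raise DomainError("artifact_fraction must be in [0, 1)")
    segs = sorted((float(a), float(b)) for a, b in offbody_segments)
    for a, b in segs:
        if a >= b or a < 0 or b > duration_s:
            raise IntervalError(f"off-body segment ({a}, {b}) out of range")
    for (_, b), (c, _) in zip(segs, segs[1:]):
        if b > c:
            raise IntervalError("off-body segments overlap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if session_start is None:
        session_start = datetime(2024, 1, 8, 14, 0, tzinfo=timezone.utc)

    # AR(1): rr' = mu + phi (rr - mu) + e;  E[(drr)^2] = 2 se^2/(1+phi) = rmssd^2
    phi = 0.9
    se = true_rmssd * math.sqrt((1.0 + phi) / 2.0)
    n_max = int(duration_s / (mean_rr_ms / 1000.0) * 1.6) + 10
    innov = rng.normal(0.0, 1.0, size=n_max) if se > 0 else np.zeros(n_max)
    rr_vals = np.empty(n_max)
    x = mean_rr_ms
    onsets = np.empty(n_max)
    t = 0.0
    n = 0
    while t < duration_s and n < n_max:
        onsets[n] = t
        rr_vals[n] = x
        n += 1
        t += x / 1000.0
        x = float(np.clip(mean_rr_ms + phi * (x - mean_rr_ms) + se * innov[n - 1], 300.0, 1500.0))
    onsets, rr_vals = onsets[:n], rr_vals[:n]

    if artifact_fraction > 0 and n > 4:
        n_art = int(round(artifact_fraction * n))
        idx = rng.choice(np.arange(1, n - 1), size=min(n_art, n - 2), replace=False)
        half = len(idx) // 2
        spike, drop = idx[:half], idx[half:]
        rr_vals = rr_vals.copy()
        rr_vals[spike] *= 2.0  # spike: doubled interval
        keep = np.ones(n, dtype=bool)
        for j in drop:  # dropout: merge beat j into j-1
            if keep[j] and keep[j - 1]:
                rr_vals[j - 1] += rr_vals[j]
                keep[j] = False
        onsets, rr_vals = onsets[keep], rr_vals[keep]

    # EDA at 4 Hz: slow on-body drift around 1 uS, off-body pinned < 0.05 uS
    t_eda = np.arange(0.0, duration_s, 0.25)
    eda_vals = 1.0 + 0.3 * np.sin(2 * np.pi * t_eda / 5400.0) + rng.normal(0, 0.02, t_eda.size)
    eda_vals = np.clip(eda_vals, 0.06, None)
    for a, b in segs:
        m = (t_eda >= a) & (t_eda < b)
        eda_vals[m] = rng.uniform(0.0, 0.04, m.sum())

    return RawRecording(
        rr=np.column_stack([onsets, rr_vals]),
        eda=np.column_stack([t_eda, eda_vals]),
        session_start=session_start,
    )


def simulate_hdi_exclusion_rate(
    n_subjects: int,
    n_obs_per_subject: int,
    truth: TrueParams,
    n_reps: int,
    base_seed: int = 0,
    rope: tuple[float, float] = (-0.05, 0.05),
    sampler_cfg=None,
) -> float:
    """Fraction of replicate fits whose pooled-slope HDI-95 excludes the ROPE.

    Each replicate generates a fresh cohort of ``n_subjects`` (split as
    evenly as possible between polarities) with ``n_obs_per_subject``
    assessments each, fits the polarity-free model, pools the per-subject
    slope draws, and checks whether the 95% highest-density interval lies
    entirely outside ``rope``. Replicate seeds are spawned deterministically
    from ``base_seed``.
    """
    from .cohort import apply_inclusion_filters, build_table
    from .inference import SamplerConfig, fit
    from .models import build_model
    from .report import hdi, pool_beta1

    if n_reps < 1:
        raise DomainError("n_reps must be >= 1")
    if n_obs_per_subject not in (3, 4):
        raise DomainError("n_obs_per_subject must be 3 or 4")
    cfg0 = sampler_cfg or SamplerConfig(
        n_chains=2, n_tune=300, n_draws=300, target_accept=0.9, dense_metric=False
    )
    n_mania = n_subjects - n_subjects // 2
    seeds = np.random.SeedSequence(base_seed).generate_state(2 * n_reps) % (2**31)
    hits = 0
    for r in range(n_reps):
        cohort_cfg = CohortConfig(
            n_mania=n_mania,
            n_depression=n_subjects // 2,
            n_assessments_distribution={n_obs_per_subject: n_subjects},
            true_params=truth,
            seed=int(seeds[2 * r]),
        )
        subjects, _ = generate_cohort(cohort_cfg)
        included, _ = apply_inclusion_filters(subjects)
        table = build_table(included)
        spec = build_model(table, "one_disease")
        post = fit(spec, table, replace(cfg0, seed=int(seeds[2 * r + 1])))
        interval = hdi(pool_beta1(post), 0.95)
        if interval.upper < rope[0] or interval.lower > rope[1]:
            hits += 1
    return hits / n_reps


def write_cohort_csv(subjects: Sequence[Subject], path) -> None:
    """Write the assessments table (one row per assessment)."""
    rows = []
    for s in subjects:
        for a in s.assessments:
            row = {
                "subject_id": s.subject_id,
                "polarity": s.polarity.value,
                "t": a.t,
                "datetime": a.datetime.isoformat() if a.datetime else "",
                "score": a.score,
                "age": s.age,
                "sex": s.sex,
            }
            row.update({c: int(bool(a.medication_flags.get(c))) for c in MEDICATION_CLASSES})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_session_csv(recording: RawRecording, session_dir) -> None:
    """Write one session as the ``rr.csv`` / ``eda.csv`` pair."""
    session_dir = Path(session_dir)
    session_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(recording.rr, columns=["onset_time_s", "rr_ms"]).to_csv(
        session_dir / "rr.csv", index=False
    )
    pd.DataFrame(recording.eda, columns=["time_s", "eda_uS"]).to_csv(
        session_dir / "eda.csv", index=False
    )
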