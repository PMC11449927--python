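"""Posterior summaries, decision rules, WAIC model comparison, and reporting.

The headline quantity of the analysis is the pooled improvement slope: the
per-subject posterior draws of ``beta1`` concatenated across subjects,
summarized by its median, probability of direction (PD), and 95% highest
density interval (HDI-95), then judged against a region of practical
equivalence (ROPE, default [-0.05, 0.05] on the lnRMSSD scale — a
multiplicative RMSSD change between e^-0.05 = 0.951 and e^0.05 = 1.051).
Models are compared by WAIC on the deviance scale (lower is better).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np
from scipy.special import logsumexp

from .errors import ComparabilityError, DomainError, EmptyInputError, InsufficientDataError
from .inference import PosteriorDraws, bfmi, ess, rhat

__all__ = [
    "Interval",
    "SummaryStats",
    "ModelComparison",
    "DEFAULT_ROPE",
    "pool_beta1",
    "probability_of_direction",
    "hdi",
    "rope_decision",
    "rope_to_multiplicative",
    "waic",
    "compare_models",
    "summarize_pooled_slope",
    "report",
    "render_markdown",
]

DEFAULT_ROPE = (-0.05, 0.05)


@dataclass(frozen=True)
class Interval:
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise DomainError(f"interval lower {self.lower} exceeds upper {self.upper}")


@dataclass
class SummaryStats:
    median: float
    pd: float  # percent in [50, 100]
    hdi95: Interval
    rope: Interval
    decision: str  # reject_rope | accept_equivalence | withhold


@dataclass
class ModelComparison:
    waic: dict[str, float]
    pwaic: dict[str, float]
    lppd: dict[str, float]
    preferred: str | None  # None on an exact tie

    @property
    def delta_waic(self) -> float:
        a, b = self.waic.values()
        return abs(a - b)


def pool_beta1(posterior: PosteriorDraws) -> np.ndarray:
    """Concatenate all chains, draws and subjects of beta1 into one sample."""
    if "beta1" not in posterior.posterior:
        raise KeyError("posterior carries no per-subject beta1 draws")
    return np.asarray(posterior.posterior["beta1"]).ravel()


def probability_of_direction(sample: np.ndarray) -> float:
    """Percent of draws sharing the median's sign.

    Draws exactly at zero count toward neither sign; a zero median reports
    50% by convention. Invariant under positive scaling of the sample.
    """
    arr = np.asarray(sample, dtype=float).ravel()
    if arr.size == 0:
        raise EmptyInputError("empty sample")
    med = np.median(arr)
    if med == 0:
        return 50.0
    share = np.mean(arr > 0) if med > 0 else np.mean(arr < 0)
    return 100.0 * float(share)


def hdi(sample: np.ndarray, mass: float = 0.95) -> Interval:
    """Narrowest interval containing ``mass`` of the sample.

    Among contiguous sorted-sample windows of ceil(mass * n) draws, the one
    of minimal width; ties resolve to the lowest lower bound.
    """
    arr = np.sort(np.asarray(sample, dtype=float).ravel())
    if arr.size < 20:
        raise InsufficientDataError("HDI needs at least 20 draws")
    if not 0.0 < mass < 1.0:
        raise DomainError("mass must lie in (0, 1)")
    k = math.ceil(mass * arr.size)
    widths = arr[k - 1 :] - arr[: arr.size - k + 1]
    j = int(np.argmin(widths))  # argmin takes the first minimum: lowest lower bound
    return Interval(float(arr[j]), float(arr[j + k - 1]))


def rope_decision(hdi95: Interval, rope: Interval) -> str:
    """HDI-vs-ROPE rule: reject, accept equivalence, or withhold decision."""
    if hdi95.upper < rope.lower or hdi95.lower > rope.upper:
        return "reject_rope"
    if rope.lower <= hdi95.lower and hdi95.upper <= rope.upper:
        return "accept_equivalence"
    return "withhold"


def rope_to_multiplicative(c: float) -> float:
    """A lnRMSSD change of c maps to a multiplicative RMSSD factor e^c."""
    if not np.isfinite(c):
        raise DomainError("c must be finite")
    return math.exp(c)


def waic(log_likelihood: np.ndarray) -> tuple[float, float, float]:
    """Widely applicable information criterion on the deviance scale.

    ``log_likelihood`` is (chain, draw, obs) or (draws, obs). Returns
    (waic, p_waic, lppd) with ``lppd = sum_obs log mean_draws exp(ll)``,
    ``p_waic = sum_obs var_draws(ll)`` (population variance) and
    ``waic = -2 (lppd - p_waic)``; lower values indicate better estimated
    out-of-sample fit.
    """
    ll = np.asarray(log_likelihood, dtype=float)
    if ll.ndim == 3:
        ll = ll.reshape(-1, ll.shape[-1])
    if ll.ndim != 2 or ll.shape[0] < 1 or ll.shape[1] < 1:
        raise InsufficientDataError("need draws x observations log likelihood")
    if not np.all(np.isfinite(ll)):
        raise DomainError("log likelihood contains non-finite values")
    s = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - math.log(s)))
    p_waic = float(np.sum(np.var(ll, axis=0)))
    return -2.0 * (lppd - p_waic), p_waic, lppd


def compare_models(posteriors: Mapping[str, PosteriorDraws]) -> ModelComparison:
    """WAIC comparison across model fits on the same observation set."""
    if len(posteriors) < 2:
        raise ComparabilityError("need at least two fitted models to compare")
    n_obs = {k: p.log_likelihood.shape[-1] for k, p in posteriors.items()}
    if len(set(n_obs.values())) != 1:
        raise ComparabilityError(f"models fitted to different observation sets: {n_obs}")
    waics, pwaics, lppds = {}, {}, {}
    for name, post in posteriors.items():
        w, p, l = waic(post.log_likelihood)
        waics[name], pwaics[name], lppds[name] = w, p, l
    values = list(waics.values())
    preferred = None
    if len(set(values)) > 1:
        preferred = min(waics, key=waics.get)
    return ModelComparison(waic=waics, pwaic=pwaics, lppd=lppds, preferred=preferred)


def summarize_pooled_slope(
    posterior: PosteriorDraws, rope: tuple[float, float] = DEFAULT_ROPE
) -> SummaryStats:
    """Median / PD / HDI-95 / ROPE decision for the pooled improvement slope."""
    pooled = pool_beta1(posterior)
    interval = hdi(pooled, 0.95)
    rope_iv = Interval(*rope)
    return SummaryStats(
        median=float(np.median(pooled)),
        pd=probability_of_direction(pooled),
        hdi95=interval,
        rope=rope_iv,
        decision=rope_decision(interval, rope_iv),
    )


def report(
    cohort_counts: Mapping[str, int] | None = None,
    qc_summary: Mapping[str, float] | None = None,
    prior_quantiles: Mapping[str, list[float]] | None = None,
    prior_kl: float | None = None,
    diagnostics: Mapping[str, Mapping[str, float]] | None = None,
    comparison: ModelComparison | None = None,
    pooled_summary: SummaryStats | None = None,
) -> dict:
    """Assemble the machine-readable analysis report.

    Missing stages are listed under ``"absent"`` rather than raising, so a
    partial pipeline still reports what it has.
    """
    sections = {
        "cohort": cohort_counts,
        "quality_control": qc_summary,
        "prior_predictive_quantiles": prior_quantiles,
        "prior_predictive_kl": prior_kl,
        "diagnostics": diagnostics,
        "model_comparison": None if comparison is None else {
            "waic": comparison.waic,
            "p_waic": comparison.pwaic,
            "lppd": comparison.lppd,
            "preferred": comparison.preferred,
        },
        "pooled_slope": None if pooled_summary is None else {
            "median": pooled_summary.median,
            "pd_percent": pooled_summary.pd,
            "hdi95": [pooled_summary.hdi95.lower, pooled_summary.hdi95.upper],
            "rope": [pooled_summary.rope.lower, pooled_summary.rope.upper],
            "rope_multiplicative": [
                rope_to_multiplicative(pooled_summary.rope.lower),
                rope_to_multiplicative(pooled_summary.rope.upper),
            ],
            "decision": pooled_summary.decision,
        },
    }
    absent = [k for k, v in sections.items() if v is None]
    doc = {k: v for k, v in sections.items() if v is not None}
    doc["absent"] = absent
    return doc


def diagnostics_table(posterior: PosteriorDraws) -> dict[str, dict[str, float]]:
    """Min-ESS / max-R-hat per parameter and min BFMI for one fit."""
    out: dict[str, dict[str, float]] = {}
    for name, arr in posterior.posterior.items():
        e = ess(arr)
        r = rhat(arr)
        out[name] = {
            "min_ess": float(np.nanmin(np.atleast_1d(e))),
            "max_rhat": float(np.nanmax(np.atleast_1d(r))),
        }
    out["__energy__"] = {"min_bfmi": float(np.nanmin(bfmi(posterior.energy)))}
    return out


def plot_subject_posterior_lines(
    posterior: PosteriorDraws,
    table,
    subject_index: int,
    out_path=None,
    n_lines: int = 100,
    rng_seed: int = 0,
):
    """Expected-lnRMSSD lines over improvement for one subject's posterior draws.

    Each line is one draw of ``beta0[i] + beta1[i] * I`` (medication term at
    the subject's own values); observed points are overlaid. Returns the
    matplotlib figure (saved to ``out_path`` when given).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = table[table["subject_index"] == subject_index].sort_values("t")
    if rows.empty:
        raise DomainError(f"no rows for subject_index {subject_index}")
    b0 = posterior.stacked("beta0")[:, subject_index]
    b1 = posterior.stacked("beta1")[:, subject_index]
    b2 = posterior.stacked("beta2").ravel()
    m = float(rows["M"].iloc[0])
    rng = np.random.default_rng(rng_seed)
    pick = rng.choice(b0.size, size=min(n_lines, b0.size), replace=False)
    grid = np.linspace(0.0, 1.0, 50)
    fig, ax = plt.subplots(figsize=(5, 4))
    lines = b0[pick, None] + b1[pick, None] * grid + b2[pick, None] * m
    ax.plot(grid, lines.T, color="k", alpha=0.08, lw=0.8)
    ax.plot(grid, lines.mean(axis=0), color="g", ls="--", lw=2, label="posterior mean")
    ax.plot(rows["I"], rows["ln_rmssd"], "rx", ms=9, mew=2, label="observed")
    ax.set_xlabel("symptom improvement I")
    ax.set_ylabel("lnRMSSD")
    ax.legend(frameon=False)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=110)
        plt.close(fig)
    return fig


def render_markdown(doc: dict) -> str:
    """Plain-text rendering of the report dictionary."""
    lines = ["# HRV trajectory analysis report", ""]
    for key, value in doc.items():
        if key == "absent":
            continue
        lines.append(f"## {key.replace('_', ' ')}")
        lines.append("```json")
        lines.append(json.dumps(value, indent=2, default=float))
        lines.append("```")
        lines.append("")
    if doc.get("absent"):
        lines.append(f"_Sections not available: {', '.join(doc['absent'])}_")
    return "\n".join(lines)
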