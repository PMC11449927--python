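"""The two hierarchical models of night lnRMSSD over an acute episode.

Both models share the observation level

    lnRMSSD[i,t] ~ N(beta0[i] + beta1[i] * I[i,t] + beta2 * M[i,t], sigma[i])

with subject intercepts partially pooled through subject covariates

    beta0[i] ~ N(alpha0 + alpha1*A[i] + alpha2*S[i] + alpha3*B[i], 0.5)
    sigma[i] ~ InvGamma(3, 0.5)                       (on the sd itself)
    alpha0   ~ N(mean(lnRMSSD), 0.1)                  (empirical centring)
    alpha1, alpha2, alpha3, beta2 ~ N(-0.1, 0.1)

and differ only in the prior on the per-subject improvement slope:

* ``two_polarities``: beta1[i] ~ N(gamma[polarity[i]], 0.1) with
  gamma_mania, gamma_depression ~ U(-1, 1) — the slope's centre may differ
  between manic and depressive episodes;
* ``one_disease``: beta1[i] ~ U(-1, 1) — no polarity structure.

All Normal second arguments are standard deviations. ``log_joint`` is an
explicit, sampler-independent evaluation of the full joint density;
:func:`unconstrained_posterior` supplies the transformed log density and
analytic gradient the NUTS engine consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .errors import EmptyInputError, ModelStructureError

__all__ = [
    "VARIANTS",
    "ModelSpec",
    "ModelParameters",
    "build_model",
    "log_joint",
    "sample_prior",
    "prior_predictive",
    "unconstrained_posterior",
]

VARIANTS = ("two_polarities", "one_disease")

_LOG_2PI = math.log(2.0 * math.pi)


def _norm_logpdf(x, mu, sd):
    z = (np.asarray(x) - mu) / sd
    return -0.5 * _LOG_2PI - np.log(sd) - 0.5 * z * z


def _invgamma_logpdf(x, shape, scale):
    x = np.asarray(x, dtype=float)
    return shape * np.log(scale) - gammaln(shape) - (shape + 1) * np.log(x) - scale / x


@dataclass
class ModelSpec:
    """Model variant, hyperparameter constants, and the design arrays.

    Built from a cohort table by :func:`build_model`; carries everything
    needed to evaluate the joint density except the outcome vector.
    """

    variant: str
    alpha0_prior_mean: float
    n_subjects: int
    # row-level design
    subj_idx: np.ndarray = field(repr=False, default=None)
    improvement: np.ndarray = field(repr=False, default=None)
    medications: np.ndarray = field(repr=False, default=None)
    # subject-level covariates
    age_std: np.ndarray = field(repr=False, default=None)
    sex: np.ndarray = field(repr=False, default=None)
    baseline_sev: np.ndarray = field(repr=False, default=None)
    polarity_idx: np.ndarray = field(repr=False, default=None)
    # hyperparameter constants
    sd_beta0: float = 0.5
    sd_beta1: float = 0.1
    sigma_shape: float = 3.0
    sigma_scale: float = 0.5
    alpha0_prior_sd: float = 0.1
    coef_prior_mean: float = -0.1
    coef_prior_sd: float = 0.1
    gamma_bounds: tuple[float, float] = (-1.0, 1.0)
    beta1_bounds: tuple[float, float] = (-1.0, 1.0)
    n_polarities: int = 2

    @property
    def n_obs(self) -> int:
        return len(self.subj_idx)

    def param_names(self) -> list[str]:
        names = ["alpha0", "alpha1", "alpha2", "alpha3", "beta2", "beta0", "beta1", "sigma"]
        if self.variant == "two_polarities":
            names.append("gamma")
        return names


@dataclass
class ModelParameters:
    """One full parameter setting (scalars, per-subject arrays, per-polarity gamma)."""

    alpha0: float
    alpha1: float
    alpha2: float
    alpha3: float
    beta2: float
    beta0: np.ndarray
    beta1: np.ndarray
    sigma: np.ndarray
    gamma: np.ndarray | None = None  # (2,) for two_polarities, else None


def spec_to_yaml(spec: ModelSpec, path) -> None:
    """Serialize a model spec (constants plus design arrays) to YAML."""
    import yaml

    doc = {
        "variant": spec.variant,
        "alpha0_prior_mean": spec.alpha0_prior_mean,
        "n_subjects": spec.n_subjects,
        "hyperconstants": {
            "sd_beta0": spec.sd_beta0,
            "sd_beta1": spec.sd_beta1,
            "sigma_shape": spec.sigma_shape,
            "sigma_scale": spec.sigma_scale,
            "alpha0_prior_sd": spec.alpha0_prior_sd,
            "coef_prior_mean": spec.coef_prior_mean,
            "coef_prior_sd": spec.coef_prior_sd,
            "gamma_bounds": list(spec.gamma_bounds),
            "beta1_bounds": list(spec.beta1_bounds),
        },
        "design": {
            "subj_idx": spec.subj_idx.tolist(),
            "improvement": spec.improvement.tolist(),
            "medications": spec.medications.tolist(),
            "age_std": spec.age_std.tolist(),
            "sex": spec.sex.tolist(),
            "baseline_sev": spec.baseline_sev.tolist(),
            "polarity_idx": spec.polarity_idx.tolist(),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def spec_from_yaml(path) -> ModelSpec:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    hc = doc["hyperconstants"]
    d = doc["design"]
    return ModelSpec(
        variant=doc["variant"],
        alpha0_prior_mean=float(doc["alpha0_prior_mean"]),
        n_subjects=int(doc["n_subjects"]),
        subj_idx=np.asarray(d["subj_idx"], dtype=int),
        improvement=np.asarray(d["improvement"], dtype=float),
        medications=np.asarray(d["medications"], dtype=float),
        age_std=np.asarray(d["age_std"], dtype=float),
        sex=np.asarray(d["sex"], dtype=float),
        baseline_sev=np.asarray(d["baseline_sev"], dtype=float),
        polarity_idx=np.asarray(d["polarity_idx"], dtype=int),
        sd_beta0=hc["sd_beta0"],
        sd_beta1=hc["sd_beta1"],
        sigma_shape=hc["sigma_shape"],
        sigma_scale=hc["sigma_scale"],
        alpha0_prior_sd=hc["alpha0_prior_sd"],
        coef_prior_mean=hc["coef_prior_mean"],
        coef_prior_sd=hc["coef_prior_sd"],
        gamma_bounds=tuple(hc["gamma_bounds"]),
        beta1_bounds=tuple(hc["beta1_bounds"]),
    )


def build_model(table: pd.DataFrame, variant: str) -> ModelSpec:
    """Assemble a model spec from the long-format cohort table."""
    if variant not in VARIANTS:
        raise ModelStructureError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if table is None or len(table) == 0:
        raise EmptyInputError("cohort table is empty")
    subj = table["subject_index"].to_numpy()
    n_subjects = int(subj.max()) + 1
    if n_subjects < 2 or len(np.unique(subj)) != n_subjects:
        raise ModelStructureError("table must contain at least two contiguously indexed subjects")
    for col in ("ln_rmssd", "I", "M", "A_std", "B"):
        if not np.all(np.isfinite(table[col].to_numpy(dtype=float))):
            raise ModelStructureError(f"non-finite values in column {col!r}")
    first = table.sort_values("t").groupby("subject_index").first()
    pol_idx = first["polarity_index"].to_numpy()
    if variant == "two_polarities" and len(np.unique(pol_idx)) < 2:
        raise ModelStructureError(
            "two_polarities model requires both polarities in the table"
        )
    return ModelSpec(
        variant=variant,
        alpha0_prior_mean=float(table["ln_rmssd"].mean()),
        n_subjects=n_subjects,
        subj_idx=subj.astype(int),
        improvement=table["I"].to_numpy(dtype=float),
        medications=table["M"].to_numpy(dtype=float),
        age_std=first["A_std"].to_numpy(dtype=float),
        sex=first["S"].to_numpy(dtype=float),
        baseline_sev=first["B"].to_numpy(dtype=float),
        polarity_idx=pol_idx.astype(int),
    )


def _check_params(spec: ModelSpec, params: ModelParameters) -> None:
    n = spec.n_subjects
    for name in ("beta0", "beta1", "sigma"):
        arr = np.asarray(getattr(params, name))
        if arr.shape != (n,):
            raise ModelStructureError(f"{name} must have shape ({n},), got {arr.shape}")
    if spec.variant == "two_polarities":
        if params.gamma is None or np.asarray(params.gamma).shape != (spec.n_polarities,):
            raise ModelStructureError("two_polarities model requires gamma of shape (2,)")
    elif params.gamma is not None:
        raise ModelStructureError("one_disease model takes no gamma parameter")


def pointwise_loglik(spec: ModelSpec, params: ModelParameters, y: np.ndarray) -> np.ndarray:
    """Observation-level Gaussian log likelihood (one value per table row)."""
    mu = (
        np.asarray(params.beta0)[spec.subj_idx]
        + np.asarray(params.beta1)[spec.subj_idx] * spec.improvement
        + params.beta2 * spec.medications
    )
    sd = np.asarray(params.sigma)[spec.subj_idx]
    return _norm_logpdf(y, mu, sd)


def log_joint(spec: ModelSpec, params: ModelParameters, table: pd.DataFrame) -> float:
    """Sum of all prior log densities and observation log likelihoods.

    Returns ``-inf`` when any bounded parameter is outside its support
    (sigma <= 0, gamma or one-disease slopes outside (-1, 1)).
    """
    _check_params(spec, params)
    sigma = np.asarray(params.sigma, dtype=float)
    beta1 = np.asarray(params.beta1, dtype=float)
    if np.any(sigma <= 0):
        return -np.inf
    lo, hi = spec.beta1_bounds
    if spec.variant == "one_disease" and (np.any(beta1 <= lo) or np.any(beta1 >= hi)):
        return -np.inf
    if spec.variant == "two_polarities":
        glo, ghi = spec.gamma_bounds
        gamma = np.asarray(params.gamma, dtype=float)
        if np.any(gamma <= glo) or np.any(gamma >= ghi):
            return -np.inf

    y = table["ln_rmssd"].to_numpy(dtype=float)
    total = float(np.sum(pointwise_loglik(spec, params, y)))

    mu0 = (
        params.alpha0
        + params.alpha1 * spec.age_std
        + params.alpha2 * spec.sex
        + params.alpha3 * spec.baseline_sev
    )
    total += float(np.sum(_norm_logpdf(params.beta0, mu0, spec.sd_beta0)))
    if spec.variant == "two_polarities":
        centres = gamma[spec.polarity_idx]
        total += float(np.sum(_norm_logpdf(beta1, centres, spec.sd_beta1)))
        total += -spec.n_polarities * math.log(ghi - glo)  # uniform gamma prior
    else:
        total += -spec.n_subjects * math.log(hi - lo)  # uniform beta1 prior
    total += float(np.sum(_invgamma_logpdf(sigma, spec.sigma_shape, spec.sigma_scale)))
    total += float(_norm_logpdf(params.alpha0, spec.alpha0_prior_mean, spec.alpha0_prior_sd))
    for coef in (params.alpha1, params.alpha2, params.alpha3, params.beta2):
        total += float(_norm_logpdf(coef, spec.coef_prior_mean, spec.coef_prior_sd))
    return total


def sample_prior(spec: ModelSpec, n_draws: int, seed: int = 0) -> dict[str, np.ndarray]:
    """Ancestral draws of the full parameter set from the prior.

    Returns arrays keyed by parameter name; per-subject arrays have shape
    ``(n_draws, n_subjects)``. beta0 is drawn given each draw's alphas and
    the subject covariates.
    """
    if n_draws < 1:
        raise EmptyInputError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    out: dict[str, np.ndarray] = {}
    out["alpha0"] = rng.normal(spec.alpha0_prior_mean, spec.alpha0_prior_sd, n_draws)
    for name in ("alpha1", "alpha2", "alpha3", "beta2"):
        out[name] = rng.normal(spec.coef_prior_mean, spec.coef_prior_sd, n_draws)
    mu0 = (
        out["alpha0"][:, None]
        + out["alpha1"][:, None] * spec.age_std
        + out["alpha2"][:, None] * spec.sex
        + out["alpha3"][:, None] * spec.baseline_sev
    )
    out["beta0"] = rng.normal(mu0, spec.sd_beta0)
    if spec.variant == "two_polarities":
        glo, ghi = spec.gamma_bounds
        out["gamma"] = rng.uniform(glo, ghi, size=(n_draws, spec.n_polarities))
        centres = out["gamma"][:, spec.polarity_idx]
        out["beta1"] = rng.normal(centres, spec.sd_beta1)
    else:
        lo, hi = spec.beta1_bounds
        out["beta1"] = rng.uniform(lo, hi, size=(n_draws, n))
    # inverse gamma via reciprocal of gamma draws (shape-scale convention)
    out["sigma"] = spec.sigma_scale / rng.gamma(spec.sigma_shape, 1.0, size=(n_draws, n))
    return out


def prior_predictive(spec: ModelSpec, n_draws: int, seed: int = 0) -> np.ndarray:
    """Synthetic lnRMSSD per table row for each prior draw, shape (n_draws, n_obs)."""
    draws = sample_prior(spec, n_draws, seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    mu = (
        draws["beta0"][:, spec.subj_idx]
        + draws["beta1"][:, spec.subj_idx] * spec.improvement
        + draws["beta2"][:, None] * spec.medications
    )
    return rng.normal(mu, draws["sigma"][:, spec.subj_idx])


# ---------------------------------------------------------------------------
# Unconstrained parameterization for the HMC engine
# ---------------------------------------------------------------------------

def _spawn_layout(spec: ModelSpec) -> dict[str, slice]:
    n = spec.n_subjects
    layout = {
        "head": slice(0, 5),  # alpha0..alpha3, beta2
        "beta0": slice(5, 5 + n),
        "beta1": slice(5 + n, 5 + 2 * n),
        "sigma": slice(5 + 2 * n, 5 + 3 * n),
    }
    if spec.variant == "two_polarities":
        layout["gamma"] = slice(5 + 3 * n, 5 + 3 * n + spec.n_polarities)
    return layout


def unconstrained_posterior(
    spec: ModelSpec, table: pd.DataFrame
) -> tuple[Callable, Callable, Callable]:
    """Posterior density on an unconstrained vector, with analytic gradient.

    Transforms: ``sigma = exp(z)``; interval-bounded parameters (gamma, and
    the one-disease slopes) map through a scaled logistic. The returned
    ``logp_grad(x)`` includes the log-Jacobian so the induced density over
    ``x`` matches the constrained joint. Also returns ``initial(rng)``
    (prior means with uniform jitter) and ``constrain(x) -> dict``.
    """
    n = spec.n_subjects
    y = table["ln_rmssd"].to_numpy(dtype=float)
    subj = spec.subj_idx
    I, M = spec.improvement, spec.medications
    A, S, B = spec.age_std, spec.sex, spec.baseline_sev
    pol = spec.polarity_idx
    two_pol = spec.variant == "two_polarities"
    lo, hi = spec.beta1_bounds
    glo, ghi = spec.gamma_bounds
    sd0, sd1 = spec.sd_beta0, spec.sd_beta1
    a_sh, a_sc = spec.sigma_shape, spec.sigma_scale
    ybar, s_a0 = spec.alpha0_prior_mean, spec.alpha0_prior_sd
    cm, cs = spec.coef_prior_mean, spec.coef_prior_sd
    layout = _spawn_layout(spec)
    dim = 5 + 3 * n + (spec.n_polarities if two_pol else 0)
    n_obs_i = np.bincount(subj, minlength=n).astype(float)
    n_obs = len(y)

    # rows sorted by subject allow cheap segment sums in the gradient
    if np.any(np.diff(subj) < 0):
        order = np.argsort(subj, kind="stable")
        y, subj = y[order], subj[order]
        I, M = I[order], M[order]
    seg_starts = np.flatnonzero(np.r_[1, np.diff(subj)])
    assert len(seg_starts) == n

    def _seg_sum(values: np.ndarray) -> np.ndarray:
        return np.add.reduceat(values, seg_starts)

    # constant pieces of the log density
    ig_const = n * (a_sh * math.log(a_sc) - math.lgamma(a_sh))
    beta0_const = n * (-0.5 * _LOG_2PI - math.log(sd0))
    lik_const = -0.5 * _LOG_2PI * n_obs
    if two_pol:
        slope_const = n * (-0.5 * _LOG_2PI - math.log(sd1)) - spec.n_polarities * math.log(
            ghi - glo
        )
    else:
        slope_const = -n * math.log(hi - lo)

    def constrain(x: np.ndarray) -> dict[str, np.ndarray]:
        out = {
            "alpha0": x[0],
            "alpha1": x[1],
            "alpha2": x[2],
            "alpha3": x[3],
            "beta2": x[4],
            "beta0": x[layout["beta0"]],
            "sigma": np.exp(x[layout["sigma"]]),
        }
        zb = x[layout["beta1"]]
        out["beta1"] = lo + (hi - lo) * expit(zb) if not two_pol else zb
        if two_pol:
            out["gamma"] = glo + (ghi - glo) * expit(x[layout["gamma"]])
        return out

    def logp_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            lp, grad = _logp_grad_impl(x)
        if not np.isfinite(lp) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros_like(x)
        return lp, grad

    def _logp_grad_impl(x: np.ndarray) -> tuple[float, np.ndarray]:
        alpha0, alpha1, alpha2, alpha3, beta2 = x[:5]
        beta0 = x[layout["beta0"]]
        z_sig = x[layout["sigma"]]
        sigma = np.exp(z_sig)
        if two_pol:
            zb = None
            beta1 = x[layout["beta1"]]
            zg = x[layout["gamma"]]
            sg = expit(zg)
            gamma = glo + (ghi - glo) * sg
        else:
            zb = x[layout["beta1"]]
            sb = expit(zb)
            beta1 = lo + (hi - lo) * sb

        grad = np.empty_like(x)
        inv_var = 1.0 / (sigma * sigma)

        # likelihood (rows segment-summed per subject)
        mu = beta0[subj] + beta1[subj] * I + beta2 * M
        e = y - mu
        w = e * inv_var[subj]
        ew = e * w
        logp = lik_const - (n_obs_i * z_sig).sum() - 0.5 * ew.sum()
        g_beta0 = _seg_sum(w)
        g_beta1 = _seg_sum(I * w)
        grad[4] = M @ w - (beta2 - cm) / (cs * cs)
        g_sigma = (-n_obs_i + _seg_sum(ew)) / sigma  # ew already has 1/sigma^2

        # beta0 prior
        mu0 = alpha0 + alpha1 * A + alpha2 * S + alpha3 * B
        d0 = beta0 - mu0
        r0 = d0 / (sd0 * sd0)
        logp += beta0_const - 0.5 * (d0 * r0).sum()
        g_beta0 -= r0
        grad[0] = r0.sum() - (alpha0 - ybar) / (s_a0 * s_a0)
        grad[1] = A @ r0 - (alpha1 - cm) / (cs * cs)
        grad[2] = S @ r0 - (alpha2 - cm) / (cs * cs)
        grad[3] = B @ r0 - (alpha3 - cm) / (cs * cs)

        # slope prior
        if two_pol:
            d1 = beta1 - gamma[pol]
            r1 = d1 / (sd1 * sd1)
            logp += slope_const - 0.5 * (d1 * r1).sum()
            g_beta1 -= r1
            g_gamma = np.bincount(pol, weights=r1, minlength=spec.n_polarities)
        else:
            logp += slope_const

        # sigma prior (inverse gamma, shape-scale, on the sd)
        logp += ig_const - (a_sh + 1.0) * z_sig.sum() - a_sc * (1.0 / sigma).sum()
        g_sigma += -(a_sh + 1.0) / sigma + a_sc * inv_var

        # top-level priors
        logp += (
            -0.5 * _LOG_2PI - math.log(s_a0) - 0.5 * ((alpha0 - ybar) / s_a0) ** 2
            + 4 * (-0.5 * _LOG_2PI - math.log(cs))
            - 0.5
            * (
                (alpha1 - cm) ** 2
                + (alpha2 - cm) ** 2
                + (alpha3 - cm) ** 2
                + (beta2 - cm) ** 2
            )
            / (cs * cs)
        )

        # change of variables
        logp += z_sig.sum()  # d sigma / d z = sigma
        grad[layout["sigma"]] = g_sigma * sigma + 1.0
        grad[layout["beta0"]] = g_beta0
        # log|J| of the scaled logistic, written via logaddexp for stability
        if two_pol:
            logp += (
                math.log(ghi - glo) * spec.n_polarities
                - (np.logaddexp(0.0, zg) + np.logaddexp(0.0, -zg)).sum()
            )
            grad[layout["beta1"]] = g_beta1
            grad[layout["gamma"]] = g_gamma * (ghi - glo) * sg * (1.0 - sg) + (1.0 - 2.0 * sg)
        else:
            logp += (
                math.log(hi - lo) * n
                - (np.logaddexp(0.0, zb) + np.logaddexp(0.0, -zb)).sum()
            )
            grad[layout["beta1"]] = g_beta1 * (hi - lo) * sb * (1.0 - sb) + (1.0 - 2.0 * sb)
        return float(logp), grad

    def initial(rng: np.random.Generator) -> np.ndarray:
        x = np.zeros(dim)
        x[0] = ybar
        x[1:5] = cm
        mu0 = x[0] + x[1] * A + x[2] * S + x[3] * B
        x[layout["beta0"]] = mu0
        x[layout["beta1"]] = 0.0  # slope prior centre in either parameterization
        x[layout["sigma"]] = math.log(a_sc / (a_sh - 1.0)) if a_sh > 1 else math.log(a_sc)
        return x + rng.uniform(-0.05, 0.05, size=dim)

    return logp_grad, initial, constrain
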