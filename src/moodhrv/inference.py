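"""Model fitting and MCMC / prior-predictive diagnostics.

``fit`` runs the NUTS engine on either model variant under the study's
sampler settings (four chains of 2000 tuning steps and 2000 draws with a
0.99 target acceptance probability by default) and packages the draws,
observation-level log likelihood, and sampler energy for diagnostics and
model comparison. ESS and R-hat use the rank-normalized split-chain
formulations via ArviZ; BFMI is the per-chain mean squared energy
difference over the energy variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import arviz as az
import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyInputError, InsufficientDataError
from .models import ModelParameters, ModelSpec, pointwise_loglik, unconstrained_posterior
from .sampling import sample_nuts_chain

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "fit",
    "ess",
    "rhat",
    "bfmi",
    "prior_predictive_quantiles",
    "kl_divergence",
]


@dataclass(frozen=True)
class SamplerConfig:
    n_chains: int = 4
    n_tune: int = 2000
    n_draws: int = 2000
    target_accept: float = 0.99
    seed: int = 0
    max_treedepth: int = 10
    dense_metric: bool = True

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_tune + 1, self.n_draws) < 1:
            raise ConfigError("chain, tune and draw counts must be >= 1")
        if not 0.0 < self.target_accept < 1.0:
            raise ConfigError("target_accept must lie in (0, 1)")


@dataclass
class PosteriorDraws:
    """Posterior draws plus everything diagnostics need.

    ``posterior`` maps parameter names to arrays indexed (chain, draw, ...);
    ``log_likelihood`` is (chain, draw, observation); ``energy`` (chain, draw).
    """

    posterior: Mapping[str, np.ndarray]
    log_likelihood: np.ndarray
    energy: np.ndarray
    divergent: np.ndarray
    spec: ModelSpec | None
    config: SamplerConfig
    warnings: list[str] = field(default_factory=list)
    variant_name: str = ""

    @property
    def n_chains(self) -> int:
        return self.energy.shape[0]

    @property
    def n_draws(self) -> int:
        return self.energy.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Flatten chains and draws for one parameter, keeping trailing dims."""
        arr = self.posterior[name]
        return arr.reshape(-1, *arr.shape[2:])

    def to_inference_data(self) -> az.InferenceData:
        post = {k: np.asarray(v) for k, v in self.posterior.items()}
        return az.from_dict(
            posterior=post,
            sample_stats={"energy": self.energy, "diverging": self.divergent},
            log_likelihood={"ln_rmssd": self.log_likelihood},
        )

    def save(self, path) -> None:
        """Persist draws as a columnar archive: one array per parameter,
        sampler config and variant stored as attributes."""
        import json

        from dataclasses import asdict

        arrays = {f"posterior/{k}": np.asarray(v) for k, v in self.posterior.items()}
        arrays["log_likelihood"] = self.log_likelihood
        arrays["energy"] = self.energy
        arrays["divergent"] = self.divergent
        attrs = {
            "config": asdict(self.config),
            "variant": self.spec.variant,
            "warnings": self.warnings,
        }
        arrays["attrs_json"] = np.frombuffer(
            json.dumps(attrs).encode(), dtype=np.uint8
        )
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path, spec: ModelSpec | None = None) -> "PosteriorDraws":
        import json

        with np.load(path) as data:
            attrs = json.loads(bytes(data["attrs_json"].tobytes()).decode())
            posterior = {
                k.split("/", 1)[1]: data[k] for k in data.files if k.startswith("posterior/")
            }
            return cls(
                posterior=posterior,
                log_likelihood=data["log_likelihood"],
                energy=data["energy"],
                divergent=data["divergent"],
                spec=spec,
                config=SamplerConfig(**attrs["config"]),
                warnings=list(attrs.get("warnings", [])),
                variant_name=attrs.get("variant", ""),
            )


def fit(spec: ModelSpec, table: pd.DataFrame, config: SamplerConfig | None = None) -> PosteriorDraws:
    """Sample the posterior of the given model by NUTS.

    Chains run sequentially with independent seeds spawned from
    ``config.seed``; the result is reproducible for a fixed config. A
    warning is surfaced in ``result.warnings`` when more than 1% of draws
    diverge.
    """
    config = config or SamplerConfig()
    logp_grad, initial, constrain = unconstrained_posterior(spec, table)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        x0 = initial(rng)
        lp0, _ = logp_grad(x0)
        if not np.isfinite(lp0):
            raise FloatingPointError("non-finite log density at initialization")
        chains.append(
            sample_nuts_chain(
                logp_grad,
                x0,
                n_tune=config.n_tune,
                n_draws=config.n_draws,
                target_accept=config.target_accept,
                rng=rng,
                max_treedepth=config.max_treedepth,
                dense_metric=config.dense_metric,
            )
        )

    n, n_obs = spec.n_subjects, spec.n_obs
    names = ["alpha0", "alpha1", "alpha2", "alpha3", "beta2", "beta0", "beta1", "sigma"]
    if spec.variant == "two_polarities":
        names.append("gamma")
    posterior: dict[str, np.ndarray] = {}
    first = constrain(chains[0].draws[0])
    for name in names:
        shape = np.shape(first[name])
        posterior[name] = np.empty((config.n_chains, config.n_draws, *shape))
    log_lik = np.empty((config.n_chains, config.n_draws, n_obs))
    y = table["ln_rmssd"].to_numpy(dtype=float)
    for c, ch in enumerate(chains):
        for d in range(config.n_draws):
            values = constrain(ch.draws[d])
            for name in names:
                posterior[name][c, d] = values[name]
            params = ModelParameters(
                alpha0=float(values["alpha0"]),
                alpha1=float(values["alpha1"]),
                alpha2=float(values["alpha2"]),
                alpha3=float(values["alpha3"]),
                beta2=float(values["beta2"]),
                beta0=values["beta0"],
                beta1=values["beta1"],
                sigma=values["sigma"],
                gamma=values.get("gamma"),
            )
            log_lik[c, d] = pointwise_loglik(spec, params, y)

    energy = np.stack([ch.energy for ch in chains])
    divergent = np.stack([ch.divergent for ch in chains])
    notes = []
    div_frac = float(divergent.mean())
    if div_frac > 0.01:
        notes.append(f"{100 * div_frac:.2f}% of post-warmup draws diverged")
    return PosteriorDraws(
        posterior=posterior,
        log_likelihood=log_lik,
        energy=energy,
        divergent=divergent,
        spec=spec,
        config=config,
        warnings=notes,
        variant_name=spec.variant,
    )


def _as_chain_array(draws: np.ndarray) -> np.ndarray:
    arr = np.asarray(draws, dtype=float)
    if arr.ndim < 2:
        raise InsufficientDataError("draws must be indexed (chain, draw, ...)")
    return arr


def ess(draws: np.ndarray) -> np.ndarray | float:
    """Rank-normalized bulk effective sample size.

    ``draws`` is (chain, draw) or (chain, draw, k); a constant chain yields
    NaN (flagged, not raised). Returns a scalar for 2-d input, else an
    array over the trailing dimensions.
    """
    arr = _as_chain_array(draws)
    if arr.shape[0] < 2 or arr.shape[1] < 4:
        raise InsufficientDataError("ESS needs >= 2 chains and >= 4 draws")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = az.ess(az.convert_to_dataset(arr), method="bulk")["x"].to_numpy()
    # a perfectly autocorrelated (constant) series has no defined ESS
    constant = (arr == arr[0, 0]).all(axis=(0, 1))
    out = np.where(constant, np.nan, out)
    return float(out) if out.ndim == 0 else out


def rhat(draws: np.ndarray) -> np.ndarray | float:
    """Rank-normalized split R-hat (Gelman-Rubin potential scale reduction)."""
    arr = _as_chain_array(draws)
    if arr.shape[0] < 2:
        raise InsufficientDataError("R-hat requires at least two chains")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = az.rhat(az.convert_to_dataset(arr))["x"].to_numpy()
    return float(out) if out.ndim == 0 else out


def bfmi(energy: np.ndarray) -> np.ndarray:
    """Bayesian fraction of missing information, one value per chain.

    Mean squared first difference of the energy over its variance; NaN
    (flagged, not raised) for a chain with zero energy variance.
    """
    arr = _as_chain_array(energy)
    if arr.shape[1] < 2:
        raise InsufficientDataError("BFMI needs at least two draws per chain")
    num = np.mean(np.diff(arr, axis=1) ** 2, axis=1)
    den = np.var(arr, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def prior_predictive_quantiles(
    draws: np.ndarray, probs: tuple[float, ...] = (0.05, 0.50, 0.95)
) -> np.ndarray:
    """Empirical quantiles (linear interpolation) of pooled prior-predictive draws."""
    arr = np.asarray(draws, dtype=float).ravel()
    if arr.size == 0:
        raise EmptyInputError("no prior predictive draws supplied")
    return np.quantile(arr, probs)


def kl_divergence(
    samples_p: np.ndarray,
    samples_q: np.ndarray,
    n_bins: int = 100,
    regularization: float = 1e-10,
) -> float:
    """Histogram estimate of KL(p || q) from two samples.

    Both samples are binned on a shared support spanning their union;
    ``regularization`` mass is added to every bin before normalization so
    empty q-bins never produce infinities. The estimate is clipped at zero.
    """
    p = np.asarray(samples_p, dtype=float).ravel()
    q = np.asarray(samples_q, dtype=float).ravel()
    if p.size < 1000 or q.size < 1000:
        raise InsufficientDataError("KL estimate needs >= 1000 draws per sample")
    lo = min(p.min(), q.min())
    hi = max(p.max(), q.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    ph, _ = np.histogram(p, bins=edges)
    qh, _ = np.histogram(q, bins=edges)
    pw = ph / ph.sum() + regularization
    qw = qh / qh.sum() + regularization
    pw /= pw.sum()
    qw /= qw.sum()
    kl = float(np.sum(pw * np.log(pw / qw)))
    return max(kl, 0.0)
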