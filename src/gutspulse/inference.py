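"""Bayesian estimation machinery: priors, multi-start engines, diagnostics.

All free parameters carry log-normal priors (normal on the log scale) with a
default log-sd of 2 — weakly informative, anchored at biologically plausible
medians (e.g. the RNA decay rate at a ~20 min half-life, protein turnover at
a ~23 h half-life).  Multi-start initialization draws u ~ U(-1, 1) per
parameter and maps it to ``median * exp(u * log_sd)``; this is a bounded
initializer covering the prior's central mass, *not* a prior draw.

Two posterior engines share one interface:

``variational``
    multi-start MAP optimization (L-BFGS-B on the log scale) followed by a
    Gaussian approximation at the best mode (inverse-Hessian covariance),
    sampled to produce draws — an optimization-based posterior in the
    variational family.
``mcmc``
    affine-invariant ensemble MCMC (emcee) initialized in a tight ball
    around the best multi-start mode.

Per-start losses (the engine-native objective: negative log-posterior at
the start's optimized endpoint) are retained; the multi-start endpoint cloud
is the input of the posterior-cluster identifiability diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .params import ScalingContext, free_parameter_labels, get_variant

__all__ = [
    "DEFAULT_ANCHORS",
    "PriorSpec",
    "init_from_unit_interval",
    "PosteriorResult",
    "multistart_fit",
    "posterior_trajectory_bci",
    "detect_posterior_clusters",
    "compare_models",
    "fit_posterior_from_logdensity",
]

#: plausibility anchors (natural scale) for prior log-medians; keys may be
#: (variant, name) for variant-specific overrides, else bare names apply
DEFAULT_ANCHORS: Dict[object, float] = {
    "k_i": 0.5,          # 1/h, uptake
    "k_m": 0.3,          # 1/h, scaled metabolization
    "z_ci": 0.3,         # scaled C_i threshold
    "v_rt": 10.0,        # activation slope
    "r_rt": 5.0,         # fc/h, expression rate after activation
    "k_rd": 2.0,         # 1/h, RNA decay ~ ln2 / 20 min
    "k_p": 0.03,         # 1/h, protein turnover ~ ln2 / 23 h
    "z": 2.0,            # fc, hazard threshold
    "k_k": 0.05,         # 1/(fc h), killing rate
    "h_b": 5e-4,         # 1/h, background hazard
    "sigma_cint": 0.2,
    "sigma_nrf2": 0.2,
    "k_e": 0.05,         # 1/h, passive elimination (comparison variants)
    "k_d": 0.1,          # 1/h, damage rate constant
    "k_a": 0.02,         # damage gain per internal concentration
    "k_r": 1.0,          # 1/h, damage recovery
    ("guts_reduced", "z"): 5.0,       # damage is on the C_e scale here
    ("guts_reduced", "k_k"): 0.005,
    ("guts_scaled_damage", "z"): 50.0,
    ("guts_scaled_damage", "k_k"): 0.001,
}

DEFAULT_LOG_SD = 2.0


def _anchor(variant: str, name: str) -> float:
    base = name.split("[")[0]
    if (variant, base) in DEFAULT_ANCHORS:
        return DEFAULT_ANCHORS[(variant, base)]
    return DEFAULT_ANCHORS[base]


@dataclass
class PriorSpec:
    """Per-parameter log-normal priors: label -> (log_median, log_sd)."""

    entries: Dict[str, tuple]

    def __post_init__(self):
        for label, (_, log_sd) in self.entries.items():
            if not log_sd > 0:
                raise ValueError(f"log-sd for {label!r} must be > 0")

    @classmethod
    def defaults(
        cls,
        variant: str,
        substances: Sequence[str],
        sharing: Mapping[str, str],
        include_error: bool = True,
        log_sd: float = DEFAULT_LOG_SD,
        overrides: Mapping[str, tuple] | None = None,
    ) -> "PriorSpec":
        labels = free_parameter_labels(variant, substances, sharing, include_error)
        entries = {
            lab: (math.log(_anchor(variant, lab)), log_sd) for lab in labels
        }
        if overrides:
            entries.update({k: tuple(v) for k, v in overrides.items()})
        return cls(entries=entries)

    @property
    def labels(self) -> List[str]:
        return list(self.entries)

    def log_medians(self) -> np.ndarray:
        return np.array([v[0] for v in self.entries.values()])

    def log_sds(self) -> np.ndarray:
        return np.array([v[1] for v in self.entries.values()])

    def logpdf(self, x_log: np.ndarray) -> float:
        """Normal log-density of log-scale parameters under the prior."""
        mu, sd = self.log_medians(), self.log_sds()
        z = (np.asarray(x_log) - mu) / sd
        return float(np.sum(-np.log(sd) - 0.5 * math.log(2 * math.pi) - 0.5 * z ** 2))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.normal(self.log_medians(), self.log_sds(), size=(n, len(self.entries)))


def init_from_unit_interval(u, priors: PriorSpec) -> Dict[str, float]:
    """Map a vector in [-1, 1]^k to natural-scale start values.

    ``u = 0`` returns the prior medians; the endpoints map to
    ``median * exp(+-log_sd)``.  This is a bounded initializer spanning the
    prior's central mass, not a draw from the prior.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (len(priors.entries),):
        raise ValueError(
            f"u must have length {len(priors.entries)}, got shape {u.shape}"
        )
    if np.any(np.abs(u) > 1.0):
        raise ValueError("all components of u must lie in [-1, 1]")
    values = np.exp(priors.log_medians() + u * priors.log_sds())
    return dict(zip(priors.labels, values))


@dataclass
class PosteriorResult:
    """Posterior draws, multi-start bookkeeping and model-comparison scores."""

    variant: str
    substances: List[str]
    sharing: Dict[str, str]
    labels: List[str]
    draws: pd.DataFrame = field(repr=False)
    start_points: np.ndarray = field(repr=False)  # (n_starts, k) log scale
    start_losses: np.ndarray = field(repr=False)
    best_start: int = 0
    map_log: np.ndarray = field(default=None, repr=False)
    loglik_hat: float = float("nan")
    k_params: int = 0
    n_obs: int = 0
    bic: float = float("nan")
    engine: str = "variational"
    seed: int | None = None
    scaling: ScalingContext | None = None
    diagnostics: Dict[str, object] = field(default_factory=dict)
    data_fingerprint: str = ""

    def __post_init__(self):
        counts = {c: len(self.draws[c]) for c in self.draws.columns}
        if len(set(counts.values())) > 1:  # pragma: no cover - DataFrame invariant
            raise ValueError("draw counts differ across parameters")

    @property
    def provenance(self) -> Dict[str, object]:
        return {
            "seed": self.seed,
            "engine": self.engine,
            "best_start": int(self.best_start),
            "n_starts": int(len(self.start_losses)),
        }

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        lo = (1 - level) / 2
        qs = self.draws.quantile([lo, 0.5, 1 - lo]).T
        qs.columns = ["lower", "median", "upper"]
        assert (qs["lower"] <= qs["median"]).all() and (qs["median"] <= qs["upper"]).all()
        return qs

    def params_at(self, which: str = "median") -> tuple:
        """Natural-scale parameter blocks at the posterior median or MAP."""
        if which == "median":
            point = self.draws.median()
        elif which == "map":
            point = pd.Series(np.exp(self.map_log), index=self.labels)
        else:
            raise ValueError("which must be 'median' or 'map'")
        spec = get_variant(self.variant)
        params = {sub: {} for sub in self.substances}
        errors = {}
        for lab, val in point.items():
            if "[" in lab:
                name, sub = lab[:-1].split("[")
                params[sub][name] = float(val)
            elif lab in spec.error_parameters:
                errors[lab] = float(val)
            else:
                for sub in self.substances:
                    params[sub][lab] = float(val)
        return params, errors

    def save(self, out_dir) -> None:
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.draws.to_csv(out / "draws.csv", index=False, float_format="%.10g")
        pd.DataFrame({
            "start": np.arange(len(self.start_losses)),
            "loss": self.start_losses,
        }).to_csv(out / "start_losses.csv", index=False, float_format="%.10g")
        summary = {
            "variant": self.variant,
            "substances": self.substances,
            "sharing": self.sharing,
            "labels": self.labels,
            "loglik_hat": self.loglik_hat,
            "k_params": self.k_params,
            "n_obs": self.n_obs,
            "bic": self.bic,
            "provenance": self.provenance,
            "scaling": None if self.scaling is None else self.scaling.model_dump(),
            "diagnostics": {
                k: v for k, v in self.diagnostics.items()
                if isinstance(v, (int, float, str, bool, type(None)))
            },
            "data_fingerprint": self.data_fingerprint,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# engine primitives (generic over a log-density; reused by the estimator and
# by closed-form sanity checks)
# ---------------------------------------------------------------------------

def _map_multistart(neg_log_post, starts_log, maxiter=300):
    """L-BFGS-B from each start; returns endpoints, losses, best index."""
    endpoints = np.empty_like(starts_log)
    losses = np.empty(len(starts_log))
    messages = []
    for i, x0 in enumerate(starts_log):
        res = minimize(
            neg_log_post, x0, method="L-BFGS-B",
            options={"maxiter": maxiter, "maxfun": 40 * maxiter},
        )
        endpoints[i] = res.x
        losses[i] = res.fun if np.isfinite(res.fun) else np.inf
        messages.append(str(res.message))
    if not np.any(np.isfinite(losses)):
        raise RuntimeError(
            "all multistart optimizations diverged; per-start reasons: "
            + "; ".join(messages)
        )
    return endpoints, losses, int(np.argmin(losses))


def _hessian_fd(f, x, step=1e-4):
    """Central-difference Hessian with relative steps."""
    k = len(x)
    h = step * (1.0 + np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            H[i, j] = H[j, i] = (
                f(xpp) - f(xpm) - f(xmp) + f(xmm)
            ) / (4 * h[i] * h[j])
    return H, f0


def _gaussian_from_mode(neg_log_post, x_map, min_eig=1e-8):
    """Covariance from the inverse Hessian, eigenvalue-floored to be PD."""
    H, _ = _hessian_fd(neg_log_post, np.asarray(x_map, dtype=float))
    H = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(H)
    w = np.maximum(w, min_eig)
    cov = (V / w) @ V.T
    return cov, {"hessian_min_eig": float(w.min()), "hessian_max_eig": float(w.max())}


def fit_posterior_from_logdensity(
    log_post,
    ndim: int,
    starts_log: np.ndarray,
    engine: str,
    n_draws: int,
    rng: np.random.Generator,
    maxiter: int = 300,
    mcmc_burn: int = 300,
):
    """Generic multi-start posterior fit on an arbitrary log-density.

    Returns ``(draws_log, endpoints, losses, best, x_map, diagnostics)``.
    """
    if engine not in ("mcmc", "variational"):
        raise ValueError(f"engine must be 'mcmc' or 'variational', got {engine!r}")

    def neg(x):
        v = log_post(np.asarray(x, dtype=float))
        if not np.isfinite(v):
            return 1e12
        return -v

    endpoints, losses, best = _map_multistart(neg, starts_log, maxiter=maxiter)
    x_map = endpoints[best]
    diagnostics: Dict[str, object] = {"loss_spread": float(np.ptp(losses[np.isfinite(losses)]))}

    if engine == "variational":
        cov, hdiag = _gaussian_from_mode(neg, x_map)
        diagnostics.update(hdiag)
        draws_log = rng.multivariate_normal(x_map, cov, size=n_draws,
                                            method="eigh")
    else:
        import emcee

        n_walkers = max(2 * ndim + 2, 8)
        # overdisperse the initial ensemble with the mode's Gaussian
        # approximation so flat posterior directions are covered from the start
        cov, hdiag = _gaussian_from_mode(neg, x_map)
        diagnostics.update(hdiag)
        p0 = rng.multivariate_normal(x_map, cov, size=n_walkers, method="eigh")
        sampler = emcee.EnsembleSampler(n_walkers, ndim, lambda x: -neg(x))
        sampler._random = np.random.RandomState(
            int(rng.integers(0, 2**31 - 1))
        )
        n_steps = mcmc_burn + max(1, int(np.ceil(n_draws / n_walkers)))
        sampler.run_mcmc(p0, n_steps, progress=False)
        chain = sampler.get_chain(discard=mcmc_burn, flat=True)
        draws_log = chain[-n_draws:]
        diagnostics["mcmc_acceptance_fraction"] = float(
            np.mean(sampler.acceptance_fraction)
        )
    return draws_log, endpoints, losses, best, x_map, diagnostics


def multistart_fit(
    variant: str,
    observations,
    priors: PriorSpec | None = None,
    sharing="independent",
    scaling: ScalingContext | None = None,
    n_starts: int = 100,
    seed: int | None = None,
    engine: str = "variational",
    draws: int = 1000,
    **opts,
) -> PosteriorResult:
    """Fit ``variant`` to an observation table; thin wrapper over GutsModel."""
    from .estimators import GutsModel

    est = GutsModel(
        variant=variant, sharing=sharing, engine=engine, n_starts=n_starts,
        seed=seed, draws=draws, priors=priors, scaling=scaling, **opts,
    )
    est.fit(observations)
    return est.result_


def posterior_trajectory_bci(
    posterior: PosteriorResult,
    scenario,
    level: float = 0.95,
    t_grid: Sequence[float] | None = None,
    max_draws: int = 200,
    solver_step: float = 0.05,
) -> pd.DataFrame:
    """Pointwise credible envelopes of the deterministic trajectories.

    Quantiles are taken over posterior parameter draws only; the residual
    (predictive) observation error is explicitly excluded, so the envelopes
    reflect parametric uncertainty in the expected trajectories.
    """
    from ._fast import fast_solve

    if len(posterior.draws) < 1:
        raise ValueError("posterior must contain at least one draw")
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    spec = get_variant(posterior.variant)
    if t_grid is None:
        t_grid = np.arange(scenario.t_start, scenario.t_end + 1e-9, 2.0)
    t_grid = np.asarray(t_grid, dtype=float)

    draws = posterior.draws
    if len(draws) > max_draws:
        idx = np.linspace(0, len(draws) - 1, max_draws).astype(int)
        draws = draws.iloc[idx]

    ce = scenario.c_at(scenario.t_start)
    curves = {ep: [] for ep in spec.endpoints}
    for _, row in draws.iterrows():
        params = {}
        for lab, val in row.items():
            name = lab.split("[")[0]
            if "[" in lab:
                sub = lab[:-1].split("[")[1]
                if sub != scenario.substance:
                    continue
            if name in spec.parameters:
                params[name] = float(val)
        sol = fast_solve(
            posterior.variant, params, np.array([ce]), t_grid,
            posterior.scaling, h=solver_step,
        )[0]
        for ep in spec.endpoints:
            si = spec.endpoint_state[ep]
            y = sol[si]
            if ep == "survival":
                y = np.exp(-np.maximum(y, 0.0))
            curves[ep].append(y)

    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    frames = []
    for ep, ys in curves.items():
        arr = np.asarray(ys)
        frames.append(pd.DataFrame({
            "endpoint": ep,
            "t": t_grid,
            "lower": np.quantile(arr, lo_q, axis=0),
            "median": np.quantile(arr, 0.5, axis=0),
            "upper": np.quantile(arr, hi_q, axis=0),
        }))
    return pd.concat(frames, ignore_index=True)


def detect_posterior_clusters(
    points,
    params: Sequence[str] | None = None,
    losses: Sequence[float] | None = None,
    eps: float = 0.5,
    min_samples: int = 2,
):
    """Density-based grouping of multi-start endpoints in log-parameter space.

    The paper-style identifiability diagnostic: multiple clusters with
    similar loss indicate non-identifiable parameter combinations.  Accepts a
    :class:`PosteriorResult` (optionally restricted to a parameter pair) or a
    raw (n, k) array.  Returns ``(labels, summary)`` where labels are
    0..n_clusters-1 ordered by best loss; isolated points become singleton
    clusters (a single cluster is a perfectly valid outcome).
    """
    from sklearn.cluster import DBSCAN

    if isinstance(points, PosteriorResult):
        result = points
        cols = list(result.labels)
        pts = np.asarray(result.start_points, dtype=float)
        if params is not None:
            idx = [cols.index(p) for p in params]
            pts = pts[:, idx]
        if losses is None:
            losses = result.start_losses
    else:
        pts = np.asarray(points, dtype=float)
    finite = np.all(np.isfinite(pts), axis=1)
    if losses is not None:
        losses = np.asarray(losses, dtype=float)
        finite &= np.isfinite(losses)
    pts_f = pts[finite]
    if len(pts_f) < 10:
        raise ValueError("need at least 10 retained starts/draws")

    # dimensions with negligible spread (< 1e-3 log units) are effectively
    # constant; leave them unscaled instead of magnifying numerical noise
    std = pts_f.std(axis=0)
    std = np.where(std > 1e-3, std, 1.0)
    zs = (pts_f - pts_f.mean(axis=0)) / std
    raw = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(zs)
    labels = raw.copy()
    next_label = labels.max() + 1 if labels.max() >= 0 else 0
    for i in np.where(raw == -1)[0]:
        labels[i] = next_label
        next_label += 1

    have_loss = losses is not None
    loss_f = losses[finite] if have_loss else np.zeros(len(pts_f))
    rows = []
    for lab in np.unique(labels):
        sel = labels == lab
        rows.append({
            "cluster": int(lab),
            "size": int(sel.sum()),
            "best_loss": float(np.min(loss_f[sel])) if have_loss else np.nan,
            "loss_spread": float(np.ptp(loss_f[sel])) if have_loss else np.nan,
        })
    summary = pd.DataFrame(rows).sort_values("best_loss", kind="stable").reset_index(drop=True)
    # relabel clusters in order of best loss for deterministic output
    remap = {int(r.cluster): i for i, r in enumerate(summary.itertuples())}
    labels = np.array([remap[int(l)] for l in labels])
    summary["cluster"] = np.arange(len(summary))

    full_labels = np.full(len(pts), -1, dtype=int)
    full_labels[finite] = labels
    return full_labels, summary


def compare_models(results: Iterable[PosteriorResult]) -> pd.DataFrame:
    """BIC comparison table, sorted ascending with Δ-BIC to the best model."""
    results = list(results)
    if not results:
        raise ValueError("no results to compare")
    fps = {r.data_fingerprint for r in results}
    if len(fps) > 1:
        raise ValueError(
            "results were fitted to different observation tables "
            f"(fingerprints {sorted(fps)})"
        )
    rows = []
    for r in results:
        rows.append({
            "variant": r.variant,
            "sharing": "specific"
            if all(v == "specific" for v in r.sharing.values()) else "independent",
            "engine": r.engine,
            "k_params": r.k_params,
            "n_obs": r.n_obs,
            "loglik_hat": r.loglik_hat,
            "bic": r.bic,
        })
    table = pd.DataFrame(rows).sort_values("bic", kind="stable").reset_index(drop=True)
    table["delta_bic"] = table["bic"] - table["bic"].iloc[0]
    return table
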