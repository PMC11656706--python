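"""Scikit-learn-style estimator for calibrating GUTS variants.

``GutsModel`` follows the sklearn estimator protocol: all configuration in
``__init__`` (stored verbatim, validated in ``fit``), fitted state in
trailing-underscore attributes, ``get_params``/``set_params``/``clone``
compatibility.  ``fit`` takes the long-format observation table,
``predict`` returns deterministic trajectories at the posterior point
estimate, ``predict_interval`` the credible envelopes over posterior draws,
and ``score`` the joint log-likelihood of a table under the fitted point
estimate.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .inference import (
    PosteriorResult,
    PriorSpec,
    fit_posterior_from_logdensity,
    init_from_unit_interval,
    posterior_trajectory_bci,
)
from .likelihood import ObservationTable, PreparedLikelihood, bic
from .params import (
    ScalingContext,
    free_parameter_labels,
    get_variant,
    make_sharing_map,
    validate_sharing_map,
)
from .simulate import ExposureScenario, batch_simulate, compute_scaling


class GutsModel(BaseEstimator):
    """Bayesian multi-start calibration of one GUTS variant.

    Parameters
    ----------
    variant : one of the registered variant ids.
    sharing : "specific", "independent", or an explicit parameter->flag map.
    engine : "variational" (optimization-based Gaussian posterior) or "mcmc".
    n_starts : number of multi-start initializations (u ~ U(-1, 1)
        transformed to the prior scales).
    draws : posterior draws to retain.
    seed : master seed; fans out to per-start substreams and the engine.
    priors : PriorSpec or None for the anchored defaults (log-sd 2).
    scaling : ScalingContext or None to derive C_i_max from the data.
    restrict_endpoints : subset the table to the endpoints the variant
        produces before fitting (e.g. survival only for guts_reduced).
    solver_step : RK4 base step (h) of the likelihood solver.
    maxiter : per-start L-BFGS-B iteration cap.
    """

    def __init__(
        self,
        variant: str = "guts_rna_pulse",
        sharing="independent",
        engine: str = "variational",
        n_starts: int = 100,
        draws: int = 1000,
        seed: int | None = None,
        priors: PriorSpec | None = None,
        scaling: ScalingContext | None = None,
        restrict_endpoints: bool = True,
        solver_step: float = 0.1,
        maxiter: int = 300,
        mcmc_burn: int = 300,
    ):
        self.variant = variant
        self.sharing = sharing
        self.engine = engine
        self.n_starts = n_starts
        self.draws = draws
        self.seed = seed
        self.priors = priors
        self.scaling = scaling
        self.restrict_endpoints = restrict_endpoints
        self.solver_step = solver_step
        self.maxiter = maxiter
        self.mcmc_burn = mcmc_burn

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None):
        """Calibrate the model on an observation table (DataFrame or
        ObservationTable); returns self."""
        spec = get_variant(self.variant)
        obs = X if isinstance(X, ObservationTable) else ObservationTable.from_dataframe(X)
        if self.restrict_endpoints:
            obs = obs.subset_endpoints(spec.endpoints)
        if len(obs) == 0:
            raise ValueError("no usable observations for this variant")

        sharing = (
            dict(self.sharing)
            if isinstance(self.sharing, Mapping)
            else make_sharing_map(self.variant, self.sharing)
        )
        validate_sharing_map(self.variant, sharing)
        substances = sorted(obs.df["substance"].unique())

        scaling = self.scaling
        if scaling is None and self.variant == "guts_rna_pulse":
            scaling = compute_scaling(obs)

        priors = self.priors
        if priors is None:
            priors = PriorSpec.defaults(self.variant, substances, sharing)
        labels = free_parameter_labels(self.variant, substances, sharing)
        if list(priors.labels) != labels:
            raise ValueError(
                "priors do not cover the free-parameter layout; expected "
                f"{labels}, got {list(priors.labels)}"
            )

        prepared = PreparedLikelihood(
            self.variant, obs, scaling, solver_step=self.solver_step
        )

        # unpacking: label order is [specific x substances, shared, errors]
        err_names = set(spec.error_parameters)

        def unpack(x_log):
            vals = np.exp(np.clip(x_log, -300.0, 300.0))
            params = {sub: {} for sub in substances}
            errors = {}
            for lab, v in zip(labels, vals):
                if "[" in lab:
                    name, sub = lab[:-1].split("[")
                    params[sub][name] = v
                elif lab in err_names:
                    errors[lab] = v
                else:
                    for sub in substances:
                        params[sub][lab] = v
            return params, errors

        def log_post(x_log):
            params, errors = unpack(x_log)
            ll = prepared.loglik(params, errors)
            if not np.isfinite(ll):
                return -np.inf
            return ll + priors.logpdf(x_log)

        ndim = len(labels)
        ss = np.random.SeedSequence(self.seed)
        rng_starts, rng_engine = (np.random.default_rng(s) for s in ss.spawn(2))
        u = rng_starts.uniform(-1.0, 1.0, size=(self.n_starts, ndim))
        starts_log = np.array([
            np.log(np.array(list(init_from_unit_interval(ui, priors).values())))
            for ui in u
        ])

        draws_log, endpoints, losses, best, x_map, diag = (
            fit_posterior_from_logdensity(
                log_post, ndim, starts_log, self.engine, self.draws,
                rng_engine, maxiter=self.maxiter, mcmc_burn=self.mcmc_burn,
            )
        )

        params_map, errors_map = unpack(x_map)
        loglik_hat = prepared.loglik(params_map, errors_map)
        n_obs = len(obs)
        k = ndim

        self.labels_ = labels
        self.substances_ = substances
        self.scaling_ = scaling
        self.priors_ = priors
        self.n_obs_ = n_obs
        self.loglik_ = float(loglik_hat)
        self.bic_ = bic(loglik_hat, k, n_obs)
        self.result_ = PosteriorResult(
            variant=self.variant,
            substances=substances,
            sharing=sharing,
            labels=labels,
            draws=pd.DataFrame(np.exp(np.clip(draws_log, -300.0, 300.0)),
                               columns=labels),
            start_points=endpoints,
            start_losses=losses,
            best_start=best,
            map_log=x_map,
            loglik_hat=float(loglik_hat),
            k_params=k,
            n_obs=n_obs,
            bic=self.bic_,
            engine=self.engine,
            seed=self.seed,
            scaling=scaling,
            diagnostics=diag,
            data_fingerprint=obs.fingerprint(),
        )
        return self

    # -- prediction ---------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise AttributeError("this GutsModel instance is not fitted yet")

    def predict(
        self,
        scenarios: ExposureScenario | Sequence[ExposureScenario],
        t_grid=None,
        point: str = "median",
    ):
        """Deterministic trajectories at the posterior point estimate."""
        self._check_fitted()
        single = isinstance(scenarios, ExposureScenario)
        if single:
            scenarios = [scenarios]
        params, _ = self.result_.params_at(point)
        out = batch_simulate(self.variant, params, scenarios, self.scaling_, t_grid)
        return out[0] if single else out

    def predict_interval(self, scenario: ExposureScenario, level: float = 0.95,
                         t_grid=None):
        """Credible envelopes of the deterministic trajectories."""
        self._check_fitted()
        return posterior_trajectory_bci(self.result_, scenario, level, t_grid)

    def score(self, X, y=None) -> float:
        """Joint log-likelihood of ``X`` at the posterior median estimate."""
        self._check_fitted()
        obs = X if isinstance(X, ObservationTable) else ObservationTable.from_dataframe(X)
        if self.restrict_endpoints:
            obs = obs.subset_endpoints(get_variant(self.variant).endpoints)
        params, errors = self.result_.params_at("median")
        prepared = PreparedLikelihood(self.variant, obs, self.scaling_,
                                      solver_step=self.solver_step)
        return prepared.loglik(params, errors)
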