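"""Reproducible benchmark experiments built from the package's own pieces.

These drivers are what the validation suite and the acceptance script run:
closed-form solver oracles, the survival-likelihood equivalence check,
simulation-based parameter recovery on the toy design, and the BIC ordering
of substance-specific vs parameter-sharing fits on data whose truth is
substance-specific.  Problem sizes are deliberately small (toy designs,
few multistarts, reduced draw counts) so a full run completes in minutes on
one CPU; docs/methods.md discusses what the reduced scale does and does not
demonstrate.
"""

from __future__ import annotations

from itertools import product
from typing import Dict

import numpy as np
from scipy.stats import multinomial

from .estimators import GutsModel
from .inference import compare_models
from .likelihood import conditional_binomial_loglik, count_free_parameters
from .params import ScalingContext, make_sharing_map
from .simulate import ExposureScenario, simulate
from .synthetic import make_benchmark

__all__ = [
    "parameter_registry_counts",
    "design_bookkeeping",
    "closed_form_benchmarks",
    "survival_likelihood_equivalence",
    "recovery_experiment",
    "bic_sharing_experiment",
]


def parameter_registry_counts() -> Dict[str, int]:
    """Free-parameter counts of the model family (error params excluded)."""
    shared = make_sharing_map("guts_rna_pulse", "independent")
    specific = make_sharing_map("guts_rna_pulse", "specific")
    return {
        "guts_rna_single_substance": count_free_parameters(
            "guts_rna", 1, make_sharing_map("guts_rna", "specific")
        ),
        "guts_rna_pulse_single_substance": count_free_parameters(
            "guts_rna_pulse", 1, specific
        ),
        "guts_rna_pulse_shared_3_substances": count_free_parameters(
            "guts_rna_pulse", 3, shared
        ),
        "guts_rna_pulse_specific_3_substances": count_free_parameters(
            "guts_rna_pulse", 3, specific
        ),
    }


def design_bookkeeping(seed: int = 0) -> Dict[str, int]:
    """Grid arithmetic of the paper-scale synthetic design."""
    bundle = make_benchmark("paper_scale", seed=seed)
    grid = bundle.grid
    counts = bundle.observations.df["endpoint"].value_counts()
    return {
        "n_treatments": int(grid["treatment_id"].nunique()),
        "n_distinct_times": int(grid["time"].nunique()),
        "n_endpoints": int(grid["endpoint"].nunique()),
        "n_grid_cells": int(len(grid)),
        "n_observations": int(grid["realized"].sum()),
        "n_missing": int((~grid["realized"]).sum()),
        "n_cint": int(counts.get("cint", 0)),
        "n_nrf2": int(counts.get("nrf2", 0)),
        "n_survival": int(counts.get("survival", 0)),
    }


def closed_form_benchmarks() -> Dict[str, float]:
    """Max relative errors of the adaptive solver against analytic solutions.

    Covers linear uptake with metabolization off, the saturating RNA response
    under full activation, one-compartment damage in the reduced variant, and
    exponential survival under constant (background-only) hazard.
    """
    scaling = ScalingContext(C_i_max=1.0)
    t = np.linspace(1.0, 96.0, 40)

    def relerr(a, b):
        return float(np.max(np.abs(a - b) / np.maximum(np.abs(b), 1e-300)))

    out = {}

    # metabolization off -> pure linear uptake C_i = k_i * C_e * t
    sc = ExposureScenario(substance="s", c_external=5.0, treatment_id="lin")
    params = {"k_i": 0.5, "k_m": 0.0, "z_ci": 0.3, "v_rt": 10.0, "r_rt": 5.0,
              "k_rd": 2.0, "k_p": 0.03, "z": 1e6, "k_k": 0.05, "h_b": 0.0}
    traj = simulate("guts_rna_pulse", params, ScalingContext(C_i_max=240.0), sc, t)
    out["linear_uptake"] = relerr(traj.states["C_i"], 0.5 * 5.0 * t)

    # activation == 1 -> R(t) = R0 + (r_rt/k_rd)(1 - exp(-k_rd t))
    params = {"k_i": 1.0, "k_m": 0.0, "z_ci": 0.0, "v_rt": 1e9, "r_rt": 5.0,
              "k_rd": 2.0, "k_p": 0.03, "z": 1e6, "k_k": 0.05, "h_b": 0.0}
    sc = ExposureScenario(substance="s", c_external=10.0, treatment_id="sat")
    traj = simulate("guts_rna_pulse", params, scaling, sc, t)
    closed = 1.0 + (5.0 / 2.0) * (1.0 - np.exp(-2.0 * t))
    out["saturating_rna"] = relerr(traj.states["R"], closed)

    # reduced variant: D(t) = C_e (1 - exp(-k_d t))
    params = {"k_d": 0.08, "z": 1e6, "k_k": 0.0, "h_b": 0.0}
    sc = ExposureScenario(substance="s", c_external=3.0, treatment_id="red")
    traj = simulate("guts_reduced", params, None, sc, t)
    out["reduced_damage"] = relerr(traj.states["D"], 3.0 * (1 - np.exp(-0.08 * t)))

    # damage below threshold -> S(t) = exp(-h_b t) exactly
    params = {"k_i": 0.5, "k_m": 0.3, "z_ci": 0.3, "v_rt": 10.0, "r_rt": 5.0,
              "k_rd": 2.0, "k_p": 0.03, "z": 1e6, "k_k": 0.05, "h_b": 0.004}
    sc = ExposureScenario(substance="s", c_external=5.0, treatment_id="surv")
    traj = simulate("guts_rna_pulse", params, ScalingContext(C_i_max=240.0), sc, t)
    out["constant_hazard_survival"] = relerr(traj.S, np.exp(-0.004 * t))

    out["max_relative_error"] = max(out.values())
    return out


def survival_likelihood_equivalence(max_n: int = 4) -> Dict[str, float]:
    """Exhaustive conditional-binomial vs multinomial check.

    For every initial group size up to ``max_n`` and three observation times,
    enumerate all non-increasing survivor sequences, compare the
    conditional-binomial probability with the multinomial death-interval
    probability, and verify the outcome probabilities sum to one.
    """
    rng = np.random.default_rng(7)
    max_pmf_diff = 0.0
    max_total_prob_err = 0.0
    for n0 in range(1, max_n + 1):
        for _ in range(5):
            s = np.sort(rng.uniform(0.05, 1.0, size=3))[::-1]
            total = 0.0
            for seq in product(range(n0 + 1), repeat=3):
                if not (n0 >= seq[0] >= seq[1] >= seq[2]):
                    continue
                ll = conditional_binomial_loglik(list(seq), s, n0)
                p_chain = np.exp(ll)
                deaths = np.diff([n0, *seq]) * -1
                probs = [1 - s[0], s[0] - s[1], s[1] - s[2], s[2]]
                p_multi = multinomial.pmf(
                    [*deaths, seq[2]], n=n0, p=probs
                )
                max_pmf_diff = max(max_pmf_diff, abs(p_chain - p_multi))
                total += p_chain
            max_total_prob_err = max(max_total_prob_err, abs(total - 1.0))
    return {
        "max_pmf_abs_diff": float(max_pmf_diff),
        "max_total_probability_error": float(max_total_prob_err),
    }


def recovery_experiment(
    n_replicates: int = 20,
    seed: int = 1,
    n_starts: int = 4,
    draws: int = 600,
    engine: str = "mcmc",
    level: float = 0.95,
) -> Dict[str, object]:
    """Simulation-based parameter recovery on the toy design.

    Each replicate regenerates the toy bundle with fresh noise from the same
    ground truth, refits the generating variant, and checks which free
    parameters' true values fall inside their credible intervals.  Returns
    the overall coverage fraction (target for a calibrated fit: the nominal
    level) and the per-parameter breakdown.
    """
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_replicates)]
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2

    per_param: Dict[str, list] = {}
    n_inside = 0
    n_total = 0
    for rep_seed in rep_seeds:
        bundle = make_benchmark("toy", seed=rep_seed)
        truth = bundle.truth
        est = GutsModel(
            variant=truth.variant,
            sharing="specific",
            engine=engine,
            n_starts=n_starts,
            draws=draws,
            seed=rep_seed,
            scaling=truth.scaling,
            maxiter=250,
        )
        est.fit(bundle.observations)
        sub = bundle.config.substances[0]
        truth_values = {}
        for lab in est.labels_:
            name = lab.split("[")[0]
            if name in truth.params_by_substance[sub]:
                truth_values[lab] = truth.params_by_substance[sub][name]
            else:
                truth_values[lab] = truth.error_params.to_dict()[name]
        q = est.result_.draws.quantile([lo_q, hi_q])
        for lab, tv in truth_values.items():
            inside = bool(q[lab].iloc[0] <= tv <= q[lab].iloc[1])
            per_param.setdefault(lab, []).append(inside)
            n_inside += inside
            n_total += 1
    return {
        "coverage": n_inside / n_total,
        "n_checks": n_total,
        "n_replicates": n_replicates,
        "level": level,
        "per_parameter": {k: float(np.mean(v)) for k, v in per_param.items()},
    }


def bic_sharing_experiment(
    seed: int = 1,
    n_starts: int = 3,
    draws: int = 200,
) -> Dict[str, float]:
    """Substance-specific vs parameter-sharing fit on specific-truth data.

    Generates the three-substance toy bundle whose RNA/death parameters
    differ across substances, fits the GUTS-RNA-pulse model once with all
    parameters substance-specific and once with the default sharing set, and
    compares BIC.  When the truth is substance-specific, the specific fit
    should win despite its 14 extra parameters.
    """
    bundle = make_benchmark("toy_multisubstance", seed=seed)
    fits = {}
    for mode in ("specific", "independent"):
        est = GutsModel(
            variant="guts_rna_pulse",
            sharing=mode,
            engine="variational",
            n_starts=n_starts,
            draws=draws,
            seed=seed,
            scaling=bundle.truth.scaling,
            maxiter=250,
        )
        est.fit(bundle.observations)
        fits[mode] = est
    table = compare_models([fits["specific"].result_, fits["independent"].result_])
    return {
        "bic_specific": fits["specific"].bic_,
        "bic_shared": fits["independent"].bic_,
        "delta_bic_shared_minus_specific": fits["independent"].bic_ - fits["specific"].bic_,
        "loglik_specific": fits["specific"].loglik_,
        "loglik_shared": fits["independent"].loglik_,
        "k_specific": fits["specific"].result_.k_params,
        "k_shared": fits["independent"].result_.k_params,
        "n_obs": fits["specific"].result_.n_obs,
        "specific_wins": bool(table.iloc[0]["sharing"] == "specific"),
    }
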