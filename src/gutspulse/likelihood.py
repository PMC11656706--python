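"""Error models and the joint likelihood over fragmented multi-endpoint data.

Internal concentrations and *nrf2* fold-changes carry log-normal errors
centered (in the median sense) on the deterministic predictions.  Survivor
counts follow a conditional-binomial chain: survivors at each observation
time are binomial given the survivors at the previous time with probability
S(t)/S(t_prev), which is algebraically identical to the multinomial
death-interval likelihood.  Records are independent given the trajectory, so
the joint log-likelihood is a plain sum and explicitly missing grid cells
contribute nothing.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from ._fast import fast_solve
from .params import ErrorParams, ScalingContext, get_variant, validate_sharing_map

__all__ = [
    "ObservationTable",
    "lognormal_loglik",
    "conditional_binomial_loglik",
    "joint_loglik",
    "PreparedLikelihood",
    "count_free_parameters",
    "bic",
    "SURVIVAL_RATIO_FLOOR",
]

OBS_COLUMNS = (
    "treatment_id", "substance", "endpoint", "time", "value", "n_at_risk",
    "c_external",
)

#: numerical floor on conditional survival ratios before the binomial pmf;
#: adaptive solvers can return S marginally above the previous value
SURVIVAL_RATIO_FLOOR = 1e-12


class _ClipCounter:
    """Counts survival-ratio clips during likelihood evaluation."""

    def __init__(self):
        self.count = 0

    def reset(self):
        self.count = 0


clip_counter = _ClipCounter()


@dataclass
class ObservationTable:
    """Long-format multi-endpoint observations with explicit missingness.

    One row per realized (treatment, endpoint, time) cell; absent grid cells
    are simply absent.  ``n_at_risk`` holds, for survival rows, the survivor
    count entering the interval (the previous observed count, or the initial
    count for the first row of a treatment).
    """

    df: pd.DataFrame = field(repr=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, validate: bool = True):
        missing = set(OBS_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"observation table missing columns: {sorted(missing)}")
        obj = cls(df=df.reset_index(drop=True).copy())
        if validate:
            obj.validate(raise_on_error=True)
        return obj

    @classmethod
    def from_csv(cls, path, validate: bool = True):
        df = pd.read_csv(path, comment="#")
        return cls.from_dataframe(df, validate=validate)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# gutspulse observation table, schema v1\n")
            self.df.to_csv(fh, index=False, float_format="%.10g")

    def __len__(self) -> int:
        return len(self.df)

    def subset_endpoints(self, endpoints: Iterable[str]) -> "ObservationTable":
        keep = self.df["endpoint"].isin(list(endpoints))
        return ObservationTable(df=self.df[keep].reset_index(drop=True))

    def fingerprint(self) -> str:
        canon = self.df.sort_values(
            ["treatment_id", "endpoint", "time"]
        ).reset_index(drop=True)
        payload = canon.to_csv(index=False, float_format="%.10g").encode()
        return hashlib.sha256(payload).hexdigest()

    def validate(self, raise_on_error: bool = False) -> List[str]:
        """Check the table invariants; returns per-record violation messages."""
        df = self.df
        problems: List[str] = []

        def rec(i):
            r = df.loc[i]
            return (f"row {i} (treatment={r['treatment_id']}, "
                    f"endpoint={r['endpoint']}, t={r['time']})")

        for i in df.index[~df["endpoint"].isin(["cint", "nrf2", "survival"])]:
            problems.append(f"{rec(i)}: unknown endpoint")
        for i in df.index[df["time"] < 0]:
            problems.append(f"{rec(i)}: negative time")
        for i in df.index[df["c_external"] < 0]:
            problems.append(f"{rec(i)}: negative external concentration")

        pos = df["endpoint"].isin(["cint", "nrf2"])
        for i in df.index[pos & ~(df["value"] > 0)]:
            problems.append(f"{rec(i)}: non-positive value (log-normal support)")

        surv = df[df["endpoint"] == "survival"]
        for i in surv.index:
            v, n = surv.loc[i, "value"], surv.loc[i, "n_at_risk"]
            if pd.isna(n):
                problems.append(f"{rec(i)}: survival row without n_at_risk")
                continue
            if not float(v).is_integer() or not float(n).is_integer():
                problems.append(f"{rec(i)}: survival counts must be integers")
            elif not (0 <= v <= n):
                problems.append(f"{rec(i)}: value outside [0, n_at_risk]")
        for tid, grp in surv.groupby("treatment_id"):
            grp = grp.sort_values("time")
            prev = None
            for i in grp.index:
                v, n = grp.loc[i, "value"], grp.loc[i, "n_at_risk"]
                if prev is not None and not pd.isna(n) and n != prev:
                    problems.append(
                        f"{rec(i)}: n_at_risk {n} != previous survivor count {prev}"
                    )
                if prev is not None and v > prev:
                    problems.append(f"{rec(i)}: survivor count increased")
                prev = v

        dup = df.duplicated(subset=["treatment_id", "endpoint", "time"])
        for i in df.index[dup]:
            problems.append(f"{rec(i)}: duplicate (treatment, endpoint, time)")

        ce_per_treat = df.groupby("treatment_id")["c_external"].nunique()
        for tid in ce_per_treat.index[ce_per_treat > 1]:
            problems.append(
                f"treatment {tid}: c_external not constant across records"
            )

        if problems and raise_on_error:
            raise ValueError(
                "observation table invalid:\n" + "\n".join(problems[:20])
            )
        return problems


def lognormal_loglik(obs, pred, sigma) -> float:
    """Log-density of a log-normal with log-median ``log(pred)`` at ``obs``.

    Includes the 1/obs Jacobian; the prediction is the distribution's median.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    sigma = float(sigma)
    if np.any(~np.isfinite(obs)) or np.any(obs <= 0):
        raise ValueError("observations must be finite and > 0 (data-cleaning failure?)")
    if np.any(~np.isfinite(pred)) or np.any(pred <= 0):
        raise ValueError("predictions must be finite and > 0")
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    z = (np.log(obs) - np.log(pred)) / sigma
    ll = -np.log(obs) - math.log(sigma) - 0.5 * math.log(2 * math.pi) - 0.5 * z ** 2
    return float(np.sum(ll))


def conditional_binomial_loglik(
    survivor_counts: Sequence[int],
    S_model: Sequence[float],
    n_initial: int,
    ratio_floor: float = SURVIVAL_RATIO_FLOOR,
) -> float:
    """Conditional-binomial survival log-likelihood for one treatment.

    ``survivor_counts[j]`` observed at the j-th observation time with model
    survival ``S_model[j]``; conditioning uses the previous *observed* count
    (``n_initial`` before the first observation, where S = 1).
    """
    counts = np.asarray(survivor_counts)
    S = np.asarray(S_model, dtype=float)
    if counts.shape != S.shape:
        raise ValueError("survivor_counts and S_model must align")
    if np.any(np.diff(counts) > 0):
        raise ValueError("survivor counts must be non-increasing over time")
    if counts.size and counts[0] > n_initial:
        raise ValueError("first survivor count exceeds n_initial")
    total = 0.0
    n_prev = int(n_initial)
    s_prev = 1.0
    for n_t, s_t in zip(counts, S):
        ratio = s_t / s_prev if s_prev > 0 else 0.0
        if ratio > 1.0 or ratio < ratio_floor:
            clip_counter.count += 1
            ratio = min(max(ratio, ratio_floor), 1.0)
        total += float(binom.logpmf(int(n_t), n_prev, ratio))
        n_prev = int(n_t)
        s_prev = max(s_t, ratio_floor)
    return total


class PreparedLikelihood:
    """Index-compiled joint likelihood for repeated evaluation at new params.

    Builds, once, the per-substance treatment lists, output-time unions and
    gather indices for every record; each :meth:`loglik` call is then one
    batched ODE solve per substance plus vectorized density sums.
    """

    def __init__(
        self,
        variant: str,
        observations: "ObservationTable | pd.DataFrame",
        scaling: ScalingContext | None = None,
        solver_step: float = 0.05,
    ):
        spec = get_variant(variant)
        df = observations.df if isinstance(observations, ObservationTable) else observations
        self.variant = variant
        self.spec = spec
        self.solver_step = solver_step
        self.n_obs = len(df)
        bad = set(df["endpoint"].unique()) - set(spec.endpoints)
        if bad:
            raise ValueError(
                f"endpoint(s) {sorted(bad)} present in data but not produced "
                f"by variant {variant!r}"
            )
        if variant == "guts_rna_pulse" and scaling is None and len(df):
            from .simulate import compute_scaling

            scaling = compute_scaling(df)
        self.scaling = scaling

        self._blocks = []
        for sub, sdf in df.groupby("substance", sort=True):
            treats = sdf[["treatment_id", "c_external"]].drop_duplicates("treatment_id")
            tids = treats["treatment_id"].to_numpy()
            ces = treats["c_external"].to_numpy(dtype=float)
            t_union = np.unique(sdf["time"].to_numpy(dtype=float))
            t_index = {t: i for i, t in enumerate(t_union)}
            tid_index = {tid: i for i, tid in enumerate(tids)}

            block = {"substance": sub, "ces": ces, "t_union": t_union}
            for ep in ("cint", "nrf2"):
                edf = sdf[sdf["endpoint"] == ep]
                block[ep] = (
                    np.array([tid_index[t] for t in edf["treatment_id"]], dtype=int),
                    np.array([t_index[float(t)] for t in edf["time"]], dtype=int),
                    edf["value"].to_numpy(dtype=float),
                )
            surv = sdf[sdf["endpoint"] == "survival"].sort_values(
                ["treatment_id", "time"]
            )
            ti = np.array([tid_index[t] for t in surv["treatment_id"]], dtype=int)
            xi = np.array([t_index[float(t)] for t in surv["time"]], dtype=int)
            # previous observed cell of the same treatment, -1 at chain start
            prev = np.full(len(surv), -1, dtype=int)
            for r in range(1, len(surv)):
                if ti[r] == ti[r - 1]:
                    prev[r] = r - 1
            block["survival"] = (
                ti, xi, prev,
                surv["value"].to_numpy(dtype=int),
                surv["n_at_risk"].to_numpy(dtype=int) if len(surv) else
                np.array([], dtype=int),
            )
            self._blocks.append(block)

    def loglik(self, params_by_substance, error_params=None) -> float:
        if self.n_obs == 0:
            return 0.0
        if hasattr(error_params, "to_dict"):
            error_params = error_params.to_dict()
        error_params = error_params or {}
        for name in self.spec.error_parameters:
            if name not in error_params:
                raise ValueError(
                    f"variant {self.variant!r} requires error parameter {name!r}"
                )
        si = self.spec.endpoint_state
        total = 0.0
        for block in self._blocks:
            sub = block["substance"]
            if sub not in params_by_substance:
                raise KeyError(f"no parameter block for substance {sub!r}")
            sol = fast_solve(
                self.variant, params_by_substance[sub], block["ces"],
                block["t_union"], self.scaling, h=self.solver_step,
            )
            if np.any(np.isnan(sol)):
                return -np.inf
            for ep, sigma_name in (("cint", "sigma_cint"), ("nrf2", "sigma_nrf2")):
                ti, xi, obs = block[ep]
                if len(obs) == 0:
                    continue
                pred = sol[ti, si[ep], xi]
                if np.any(pred <= 0):
                    return -np.inf
                total += lognormal_loglik(obs, pred, error_params[sigma_name])
            ti, xi, prev, n_t, n_risk = block["survival"]
            if len(n_t):
                H = np.maximum(sol[ti, si["survival"], xi], 0.0)
                S = np.exp(-H)
                S_prev = np.where(prev >= 0, S[np.maximum(prev, 0)], 1.0)
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = np.where(S_prev > 0, S / S_prev, 0.0)
                n_clip = int(np.sum((ratio > 1.0) | (ratio < SURVIVAL_RATIO_FLOOR)))
                if n_clip:
                    clip_counter.count += n_clip
                ratio = np.clip(ratio, SURVIVAL_RATIO_FLOOR, 1.0)
                total += float(np.sum(binom.logpmf(n_t, n_risk, ratio)))
        return float(total)


def joint_loglik(
    variant: str,
    params_by_substance: Mapping[str, Mapping[str, float]],
    error_params: ErrorParams | Mapping[str, float] | None,
    observations: ObservationTable | pd.DataFrame,
    scaling: ScalingContext | None = None,
    solver_step: float = 0.05,
) -> float:
    """Joint log-likelihood of all observations under one variant.

    Endpoints are produced by the variant's states (survival from H via
    S = exp(-H)); residuals are independent, so the result is the sum of the
    per-record log-densities and explicitly missing entries contribute 0.
    An endpoint present in the data but not produced by the variant is an
    error.
    """
    prepared = PreparedLikelihood(variant, observations, scaling, solver_step)
    return prepared.loglik(params_by_substance, error_params)


def count_free_parameters(
    variant: str,
    n_substances: int,
    sharing: Mapping[str, str],
    include_error: bool = False,
) -> int:
    """Free-parameter count: shared + n_substances x specific (+ errors)."""
    validate_sharing_map(variant, sharing)
    spec = get_variant(variant)
    n_shared = sum(1 for p in spec.parameters if sharing[p] == "shared")
    n_specific = sum(1 for p in spec.parameters if sharing[p] == "specific")
    k = n_shared + n_substances * n_specific
    if include_error:
        k += len(spec.error_parameters)
    return k


def bic(loglik_max: float, k_params: int, n_obs: int) -> float:
    """Bayesian information criterion, ``k ln(n) - 2 ln L``."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    if k_params < 1:
        raise ValueError("k_params must be >= 1")
    return k_params * math.log(n_obs) - 2.0 * float(loglik_max)
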