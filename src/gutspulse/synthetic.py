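"""Synthetic study-design fixtures and noisy observation generation.

The generator emulates the structure of the zebrafish-embryo exposure
study the models are built for: three substances in serial-dilution
concentration series over a 96 h exposure window (24-120 hpf), endpoint
grids with internal concentrations sampled densely (1.5-96 hpe), survival
at 24/48/72/96 hpe and *nrf2* fold-change on its own grid, strongly
unbalanced endpoint coverage, and — the structurally hard property — no
treatment ever carries more than one endpoint, so the joint likelihood must
stitch fragmented data together.  Concentration-type endpoints receive
log-normal noise, survival follows a conditional-binomial death chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from ._fast import fast_solve
from .likelihood import ObservationTable
from .params import ErrorParams, ScalingContext
from .simulate import ExposureScenario, calibrate_scaling

__all__ = [
    "DesignConfig",
    "GroundTruth",
    "Bundle",
    "generate_design",
    "simulate_observations",
    "make_benchmark",
    "default_truth",
    "PRESETS",
]

CINT_TIMES = [1.5, 3, 6, 8, 10, 12, 24, 36, 48, 60, 72, 84, 96]
SURVIVAL_TIMES = [24, 48, 72, 96]
NRF2_TIMES = [3, 6, 12, 24, 48, 72]


class DesignConfig(BaseModel):
    """Structure of a synthetic exposure study."""

    model_config = ConfigDict(extra="forbid")

    substances: List[str]
    top_concentration: float = 20.0
    dilution_factor: float = 3.0
    n_concentrations: int = 4
    t_start: float = 0.0
    t_end: float = 96.0
    times_cint: List[float] = CINT_TIMES
    times_survival: List[float] = SURVIVAL_TIMES
    times_nrf2: List[float] = NRF2_TIMES
    replicates_per_treatment: int = 3
    organisms_per_replicate: int = 3
    control_replicates: int = 6
    #: total treatments per endpoint (distributed round-robin over substances)
    treatments_per_endpoint: Dict[str, int] = {"cint": 4, "nrf2": 5, "survival": 5}
    #: realized observations per endpoint; None keeps the full grid
    target_observations: Optional[Dict[str, int]] = None

    @model_validator(mode="after")
    def _check(self) -> "DesignConfig":
        if not self.substances:
            raise ValueError("need at least one substance")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must be > t_start")
        for ep, times in (
            ("cint", self.times_cint), ("survival", self.times_survival),
            ("nrf2", self.times_nrf2),
        ):
            arr = np.asarray(times, float)
            if arr.size and (arr.min() < self.t_start or arr.max() > self.t_end):
                raise ValueError(f"{ep} sampling times outside the exposure window")
        if self.target_observations:
            for ep, target in self.target_observations.items():
                cells = self.treatments_per_endpoint.get(ep, 0) * len(
                    getattr(self, f"times_{ep}")
                )
                if target > cells:
                    raise ValueError(
                        f"target of {target} {ep} observations exceeds the "
                        f"{cells} available grid cells"
                    )
        return self

    def times_for(self, endpoint: str) -> List[float]:
        return list(getattr(self, f"times_{endpoint}"))

    def all_times(self) -> np.ndarray:
        return np.unique(
            np.concatenate([
                np.asarray(self.times_cint, float),
                np.asarray(self.times_survival, float),
                np.asarray(self.times_nrf2, float),
            ])
        )


class GroundTruth(BaseModel):
    """Generating parameters, error model, sharing mode and scaling."""

    model_config = ConfigDict(extra="forbid")

    variant: str = "guts_rna_pulse"
    params_by_substance: Dict[str, Dict[str, float]]
    error_params: ErrorParams
    sharing_mode: str = "independent"
    scaling: ScalingContext
    seed: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(self.model_dump(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "GroundTruth":
        try:
            with open(source) as fh:
                doc = json.load(fh)
        except (OSError, TypeError):
            doc = json.loads(source)
        return cls(**doc)


#: baseline GUTS-RNA-pulse truth (natural scale); see docs/methods.md for
#: the biological rationale of each value
BASE_TRUTH = {
    "k_i": 0.5, "k_m": 0.3, "z_ci": 0.3, "v_rt": 10.0, "r_rt": 5.0,
    "k_rd": 2.0, "k_p": 0.03, "z": 2.0, "k_k": 0.05, "h_b": 5e-4,
}
#: substance-to-substance variation of the uptake/activation block
TK_FACTORS = [1.0, 0.6, 1.6]
TK_SPECIFIC = ("k_i", "k_m", "z_ci")
#: RNA/death-block variation for substance-specific truths; the factors move
#: identifiable quantities (the pulse equilibrium R0 + r_rt a / k_rd and the
#: hazard response), not just transient speeds
TD_VARIATION = [
    {},
    {"r_rt": 0.6, "k_rd": 1.3, "z": 0.7, "k_k": 2.0},
    {"r_rt": 1.6, "k_rd": 0.75, "z": 1.35, "k_k": 0.5},
]


def default_truth(
    substances: Sequence[str],
    mode: str = "shared",
    sigma: float = 0.1,
    seed: int = 0,
) -> GroundTruth:
    """Build a ground truth; ``mode='specific'`` also varies the RNA-protein
    and death parameters across substances (a truth the parameter-sharing
    model cannot represent)."""
    params = {}
    for i, sub in enumerate(substances):
        block = dict(BASE_TRUTH)
        f = TK_FACTORS[i % len(TK_FACTORS)]
        for name in TK_SPECIFIC:
            block[name] = block[name] * f
        if mode == "specific":
            for name, g in TD_VARIATION[i % len(TD_VARIATION)].items():
                block[name] = block[name] * g
        params[sub] = block
    return GroundTruth(
        params_by_substance=params,
        error_params=ErrorParams(sigma_cint=sigma, sigma_nrf2=sigma),
        sharing_mode="independent" if mode == "shared" else "specific",
        scaling=ScalingContext(C_i_max=1.0),  # placeholder until calibrated
        seed=seed,
    )


def generate_design(config: DesignConfig, seed: int = 0):
    """Enumerate treatments and the realized-observation mask.

    Returns ``(scenarios, grid)`` where ``grid`` is the full treatment x
    distinct-time x endpoint table with a boolean ``realized`` column.
    Deterministic given the seed; a different seed reshuffles which grid
    cells are realized but keeps the per-endpoint totals.
    """
    rng = np.random.default_rng(seed)
    series = [
        config.top_concentration / config.dilution_factor ** k
        for k in range(config.n_concentrations)
    ]
    scenarios: List[ExposureScenario] = []
    counter = 0
    for ep in ("survival", "cint", "nrf2"):
        n_total = config.treatments_per_endpoint.get(ep, 0)
        # distribute treatments round-robin over substances
        for j in range(n_total):
            sub = config.substances[j % len(config.substances)]
            slot = j // len(config.substances)
            if ep in ("survival", "nrf2") and slot % (config.n_concentrations + 1) == 0:
                c_e = 0.0  # negative control
                reps = config.control_replicates
            else:
                offset = 1 if ep in ("survival", "nrf2") else 0
                c_e = series[(slot - offset) % config.n_concentrations]
                reps = config.replicates_per_treatment
            counter += 1
            scenarios.append(ExposureScenario(
                treatment_id=f"T{counter:04d}",
                substance=sub,
                c_external=c_e,
                t_start=config.t_start,
                t_end=config.t_end,
                replicate_count=reps,
                organisms_per_replicate=config.organisms_per_replicate,
                observation_times={ep: config.times_for(ep)},
            ))

    # realized mask per endpoint: stratified round-robin subsampling so every
    # treatment keeps observations and the per-endpoint totals hit the target
    realized = set()
    for ep in ("survival", "cint", "nrf2"):
        eps_scen = [s for s in scenarios if ep in s.observation_times]
        times = config.times_for(ep)
        cells_by_treatment = {}
        for s in eps_scen:
            order = list(times)
            rng.shuffle(order)
            cells_by_treatment[s.treatment_id] = order
        n_cells = sum(len(v) for v in cells_by_treatment.values())
        target = n_cells
        if config.target_observations and ep in config.target_observations:
            target = config.target_observations[ep]
        picked = 0
        round_i = 0
        while picked < target:
            progressed = False
            for s in eps_scen:
                if picked >= target:
                    break
                order = cells_by_treatment[s.treatment_id]
                if round_i < len(order):
                    realized.add((s.treatment_id, ep, float(order[round_i])))
                    picked += 1
                    progressed = True
            round_i += 1
            if not progressed:  # pragma: no cover - guarded by config validator
                raise ValueError(f"infeasible target for endpoint {ep!r}")

    all_times = config.all_times()
    rows = []
    for s in scenarios:
        for t in all_times:
            for ep in ("cint", "nrf2", "survival"):
                rows.append((
                    s.treatment_id, s.substance, ep, float(t),
                    (s.treatment_id, ep, float(t)) in realized,
                ))
    grid = pd.DataFrame(
        rows, columns=["treatment_id", "substance", "endpoint", "time", "realized"]
    )

    # survival chains must be chronological: keep realized times sorted per
    # treatment (the mask construction already guarantees membership only)
    return scenarios, grid


def simulate_observations(
    scenarios: Sequence[ExposureScenario],
    truth: GroundTruth,
    variant: str | None = None,
    seed: int = 0,
    grid: pd.DataFrame | None = None,
    solver_step: float = 0.02,
) -> ObservationTable:
    """Draw noisy observations at the realized design cells.

    Concentration-type endpoints get log-normal noise around the
    deterministic trajectory (the prediction is the median); survivor counts
    follow the conditional-binomial chain with probabilities S(t)/S(t_prev).
    """
    variant = variant or truth.variant
    rng = np.random.default_rng(seed)
    if grid is not None:
        realized = {
            (r.treatment_id, r.endpoint, float(r.time))
            for r in grid[grid["realized"]].itertuples()
        }
    else:
        realized = None

    scen_by_sub: Dict[str, List[ExposureScenario]] = {}
    for s in scenarios:
        scen_by_sub.setdefault(s.substance, []).append(s)

    sig = truth.error_params
    rows = []
    for sub, subs in scen_by_sub.items():
        params = truth.params_by_substance[sub]
        times_needed = sorted({
            float(t) for s in subs for ts in s.observation_times.values() for t in ts
        })
        t_union = np.asarray(times_needed, float)
        ces = np.array([s.c_at(s.t_start) for s in subs])
        sol = fast_solve(variant, params, ces, t_union, truth.scaling,
                         h=solver_step)
        if np.any(np.isnan(sol)):
            raise RuntimeError(f"ground-truth simulation unstable for {sub!r}")
        t_index = {t: i for i, t in enumerate(t_union)}
        from .params import get_variant

        spec = get_variant(variant)
        for i, s in enumerate(subs):
            for ep, times in s.observation_times.items():
                times = sorted(float(t) for t in times)
                if realized is not None:
                    times = [t for t in times if (s.treatment_id, ep, t) in realized]
                si = spec.endpoint_state[ep]
                if ep in ("cint", "nrf2"):
                    sigma = sig.sigma_cint if ep == "cint" else sig.sigma_nrf2
                    for t in times:
                        pred = sol[i, si, t_index[t]]
                        value = pred * np.exp(sigma * rng.standard_normal())
                        rows.append((
                            s.treatment_id, sub, ep, t, value, np.nan,
                            s.c_at(s.t_start),
                        ))
                else:
                    n_prev = s.n_initial
                    s_prev = 1.0
                    for t in times:
                        S_t = float(np.exp(-max(sol[i, si, t_index[t]], 0.0)))
                        p = min(max(S_t / s_prev, 0.0), 1.0) if s_prev > 0 else 0.0
                        n_t = int(rng.binomial(n_prev, p))
                        rows.append((
                            s.treatment_id, sub, ep, t, n_t, n_prev,
                            s.c_at(s.t_start),
                        ))
                        n_prev = n_t
                        s_prev = max(S_t, 1e-300)
    df = pd.DataFrame(rows, columns=[
        "treatment_id", "substance", "endpoint", "time", "value", "n_at_risk",
        "c_external",
    ]).sort_values(["treatment_id", "endpoint", "time"]).reset_index(drop=True)
    return ObservationTable.from_dataframe(df)


@dataclass
class Bundle:
    """A generated benchmark: design, observations, truth and provenance."""

    preset: str
    config: DesignConfig
    scenarios: List[ExposureScenario]
    grid: pd.DataFrame
    observations: ObservationTable
    truth: GroundTruth
    manifest: Dict[str, object] = field(default_factory=dict)

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        design = pd.DataFrame([
            {
                "treatment_id": s.treatment_id,
                "substance": s.substance,
                "c_external": s.c_at(s.t_start),
                "t_start": s.t_start,
                "t_end": s.t_end,
                "replicate_count": s.replicate_count,
                "organisms_per_replicate": s.organisms_per_replicate,
                "endpoint": next(iter(s.observation_times)),
            }
            for s in self.scenarios
        ])
        design.to_csv(out / "design.csv", index=False, float_format="%.10g")
        self.observations.to_csv(out / "observations.csv")
        self.truth.to_json(out / "truth.json")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


PRESETS = ("toy", "toy_multisubstance", "paper_scale")


def _preset_config(preset: str) -> tuple:
    if preset == "toy":
        cfg = DesignConfig(
            substances=["substance_1"],
            n_concentrations=4,
            dilution_factor=3.0,
            treatments_per_endpoint={"cint": 4, "nrf2": 5, "survival": 5},
        )
        return cfg, "shared", 0.1
    if preset == "toy_multisubstance":
        cfg = DesignConfig(
            substances=["substance_1", "substance_2", "substance_3"],
            n_concentrations=3,
            dilution_factor=3.0,
            treatments_per_endpoint={"cint": 9, "nrf2": 12, "survival": 36},
        )
        return cfg, "specific", 0.15
    if preset == "paper_scale":
        cfg = DesignConfig(
            substances=["substance_1", "substance_2", "substance_3"],
            n_concentrations=5,
            dilution_factor=2.0,
            times_nrf2=[2, 4, 5, 7, 9, 14, 16, 18, 20, 30],
            treatments_per_endpoint={"survival": 62, "cint": 100, "nrf2": 40},
            target_observations={"cint": 539, "nrf2": 169, "survival": 233},
        )
        return cfg, "shared", 0.25
    raise ValueError(f"unknown preset {preset!r}; expected one of {PRESETS}")


def make_benchmark(preset: str, seed: int = 0, out_dir=None) -> Bundle:
    """Generate a complete data bundle for one preset.

    ``toy`` is a single-substance design that fits in seconds;
    ``toy_multisubstance`` adds substance-specific RNA/death truth for
    sharing comparisons; ``paper_scale`` mirrors the 202-treatment,
    941-observation, 23-time-point study layout.
    """
    config, truth_mode, sigma = _preset_config(preset)
    ss = np.random.SeedSequence(seed)
    s_design, s_obs = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))
    truth = default_truth(config.substances, mode=truth_mode, sigma=sigma, seed=seed)
    scenarios, grid = generate_design(config, seed=s_design)
    scaling = calibrate_scaling(
        truth.variant, truth.params_by_substance, scenarios
    )
    truth = truth.model_copy(update={"scaling": scaling})
    observations = simulate_observations(
        scenarios, truth, seed=s_obs, grid=grid
    )
    counts = observations.df["endpoint"].value_counts().to_dict()
    manifest = {
        "preset": preset,
        "seed": seed,
        "schema_version": 1,
        "n_treatments": len(scenarios),
        "n_observations": len(observations),
        "observations_per_endpoint": {k: int(v) for k, v in counts.items()},
        "n_distinct_times": int(len(config.all_times())),
        "observations_sha256": observations.fingerprint(),
    }
    bundle = Bundle(
        preset=preset, config=config, scenarios=scenarios, grid=grid,
        observations=observations, truth=truth, manifest=manifest,
    )
    if out_dir is not None:
        bundle.save(out_dir)
    return bundle
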