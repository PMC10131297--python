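"""Stochastic yearly projection of the age-structured populations.

Each projected year applies, in this fixed order: (1) resample the survival
vector from a beta distribution (5% SD by default) and the fertility vector
from a truncated Gaussian; (2) apply the density-feedback survival modifier at
the current total abundance (with a year-specific half-saturation parameter
when carrying capacity fluctuates); (3) apply a catastrophe with yearly
probability p_C / G, scaling the year's transition by a beta-resampled
severity centred on 0.5; (4) advance the abundance vector through the Leslie
matrix; (5) apply harvest offtake or the scheduled mortality pulse; (6) record
the census.  The first generation of every projection is discarded as
burn-in.

Replicates are simulated as lanes of a single vectorized batch, so a scenario
run is reproducible from one root seed.  Abundances are continuous expected
values; an integerized mode (Poisson rounding of the census) exists behind a
flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .density_feedback import FeedbackParams, SplitFeedback
from .life_history import LifeHistory, build_leslie, initial_population

__all__ = [
    "CatastropheParams",
    "PulseSpec",
    "ScenarioSpec",
    "SCENARIOS",
    "get_scenario",
    "AbundanceSeries",
    "BatchResult",
    "resample_survival",
    "resample_fertility",
    "catastrophe_event",
    "pulse_mortality",
    "harvest_offtake",
    "k_schedule",
    "project_batch",
    "project_series",
    "run_scenario",
    "calibrate_harvest",
    "calibrate_null_catastrophes",
    "PreparedSpecies",
]

EXTINCTION_THRESHOLD = 1.0  # quasi-extinction: less than one individual


@dataclass(frozen=True)
class CatastropheParams:
    """Catastrophic density-independent mortality regime.

    A catastrophe occurs with yearly probability p_per_generation / G and
    multiplies the year's survival vector by a beta-resampled severity with
    the given mean and SD (mean 0.5 = survival halved).  ``hits_recruitment``
    optionally extends the severity to the recruitment row, turning the event
    into a whole-population die-off instead of a survival-only one.
    """

    p_per_generation: float = 0.14
    severity_mean: float = 0.5
    severity_sd: float = 0.05
    hits_recruitment: bool = False

    def yearly_probability(self, G: float, multiplier: float = 1.0) -> float:
        if G <= 0:
            raise ValueError("generation length must be positive")
        C = multiplier * self.p_per_generation / G
        if not (0.0 <= C <= 1.0):
            raise ValueError(f"yearly catastrophe probability {C:.3f} outside [0, 1]")
        return C


@dataclass(frozen=True)
class PulseSpec:
    time_generations: float = 20.0
    mortality: float = 0.90


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the nine demographic scenarios (presets in SCENARIOS)."""

    id: str
    catastrophes_on: bool = True
    pulse: Optional[PulseSpec] = None
    harvest_target_r: Optional[float] = None
    k_fluctuation: str = "none"  # none | constant_var | increasing_var | declining
    component_feedback_on: bool = True
    k_sd: float = 0.05
    k_sd_final: float = 0.10
    k_decline_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.k_fluctuation not in (
            "none", "constant_var", "increasing_var", "declining"
        ):
            raise ValueError(f"unknown k_fluctuation {self.k_fluctuation!r}")
        if self.id == "ix" and self.component_feedback_on:
            raise ValueError("the null scenario has no component feedback")


SCENARIOS: dict[str, ScenarioSpec] = {
    "i": ScenarioSpec(id="i", catastrophes_on=False),
    "ii": ScenarioSpec(id="ii"),
    "iii": ScenarioSpec(id="iii", pulse=PulseSpec()),
    "iv": ScenarioSpec(id="iv", harvest_target_r=-0.001),
    "v": ScenarioSpec(id="v", harvest_target_r=-0.01),
    "vi": ScenarioSpec(id="vi", k_fluctuation="constant_var"),
    "vii": ScenarioSpec(id="vii", k_fluctuation="increasing_var"),
    "viii": ScenarioSpec(id="viii", k_fluctuation="declining"),
    "ix": ScenarioSpec(id="ix", component_feedback_on=False),
}


def get_scenario(scenario_id: str) -> ScenarioSpec:
    try:
        return SCENARIOS[scenario_id]
    except KeyError:
        raise KeyError(
            f"unknown scenario {scenario_id!r}; valid ids: {sorted(SCENARIOS)}"
        ) from None


@dataclass
class AbundanceSeries:
    """One projected yearly census (post burn-in)."""

    abbr: str
    scenario_id: str
    replicate: int
    seed: int
    N: np.ndarray          # yearly totals
    s_red_t: np.ndarray    # modifier used at each transition (len = len(N)-1)
    extinct_at: Optional[int] = None

    @property
    def r(self) -> np.ndarray:
        """Realized yearly growth rates; NaN where an endpoint is <= 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.log(self.N[1:] / self.N[:-1])
        out[(self.N[1:] <= 0) | (self.N[:-1] <= 0)] = np.nan
        return out


# ---------------------------------------------------------------------------
# Stochastic resampling primitives
# ---------------------------------------------------------------------------

def _beta_moments(p: np.ndarray, sd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments beta shape parameters for mean p and SD sd."""
    var = sd**2
    nu = p * (1.0 - p) / var - 1.0
    return p * nu, (1.0 - p) * nu


def resample_survival(
    S: np.ndarray,
    sd_fraction: float = 0.05,
    juvenile_sd_multiplier: float = 1.0,
    rng: np.random.Generator | None = None,
    size: int | None = None,
    juvenile_classes: int = 0,
) -> np.ndarray:
    """Beta-resampled survival vector(s) with SD = sd_fraction * S_x.

    With ``size`` the draw is vectorized to shape (size, len(S)).  SDs that
    violate the beta feasibility bound sd^2 < p(1-p) are clamped.  Boundary
    survivals (0 or 1) are returned unchanged.
    """
    S = np.asarray(S, dtype=float)
    shape = S.shape if size is None else (size, len(S))
    if sd_fraction == 0:
        return np.broadcast_to(S, shape).copy()
    rng = rng or np.random.default_rng()
    sd = sd_fraction * S
    if juvenile_sd_multiplier != 1.0 and juvenile_classes > 0:
        sd = sd.copy()
        sd[:juvenile_classes] *= juvenile_sd_multiplier
    interior = (S > 0) & (S < 1)
    # clamp infeasible SDs just inside the beta moment bound
    cap = 0.95 * np.sqrt(np.where(interior, S * (1 - S), 1.0))
    sd = np.minimum(sd, cap)
    a, b = _beta_moments(np.where(interior, S, 0.5), np.where(interior, sd, 0.1))
    draws = rng.beta(np.broadcast_to(a, shape), np.broadcast_to(b, shape))
    return np.where(interior, draws, np.broadcast_to(S, shape))


def resample_fertility(
    m: np.ndarray,
    sd_fraction: float = 0.05,
    rng: np.random.Generator | None = None,
    size: int | None = None,
) -> np.ndarray:
    """Gaussian-resampled fertility vector(s), truncated at zero."""
    m = np.asarray(m, dtype=float)
    shape = m.shape if size is None else (size, len(m))
    if sd_fraction == 0:
        return np.broadcast_to(m, shape).copy()
    rng = rng or np.random.default_rng()
    draws = rng.normal(np.broadcast_to(m, shape), np.broadcast_to(sd_fraction * m, shape))
    return np.maximum(draws, 0.0)


def _severity_shapes(cp: CatastropheParams) -> tuple[float, float]:
    nu = cp.severity_mean * (1 - cp.severity_mean) / cp.severity_sd**2 - 1.0
    return cp.severity_mean * nu, (1 - cp.severity_mean) * nu


def catastrophe_event(
    S_year: np.ndarray,
    cp: CatastropheParams,
    G: float,
    rng: np.random.Generator | None = None,
    force: bool = False,
    severity: float | None = None,
) -> tuple[np.ndarray, bool, float]:
    """Apply a catastrophe to one year's survival vector with probability p_C/G.

    Returns (modified survival vector, occurred flag, severity used).  A
    deterministic severity can be forced for testing.
    """
    C = cp.yearly_probability(G)
    rng = rng or np.random.default_rng()
    occurred = force or (rng.random() < C)
    if not occurred:
        return np.asarray(S_year, dtype=float).copy(), False, 1.0
    if severity is None:
        a, b = _severity_shapes(cp)
        severity = float(rng.beta(a, b))
    return np.asarray(S_year, dtype=float) * severity, True, severity


def pulse_mortality(n: np.ndarray, mortality: float = 0.90) -> np.ndarray:
    """Scale every age class by (1 - mortality)."""
    if not (0.0 <= mortality <= 1.0):
        raise ValueError("mortality must lie in [0, 1]")
    return np.asarray(n, dtype=float) * (1.0 - mortality)


def harvest_offtake(n: np.ndarray, h: float) -> np.ndarray:
    """Remove a proportion h of every age class (post-transition)."""
    if not (0.0 <= h <= 1.0):
        raise ValueError("harvest proportion must lie in [0, 1]")
    return np.asarray(n, dtype=float) * (1.0 - h)


def k_schedule(
    t: int,
    base_b: float,
    mode: str,
    rng: np.random.Generator | None = None,
    horizon: int = 1,
    sd: float = 0.05,
    sd_final: float = 0.10,
    decline_rate: float = 0.001,
    size: int | None = None,
):
    """Year-specific half-saturation parameter b under fluctuating K.

    constant_var: Gaussian around base_b with SD = sd * base_b.
    increasing_var: the SD fraction ramps linearly from sd to sd_final.
    declining: the mean decays as base_b * exp(-decline_rate * t), SD = sd.
    Non-positive draws are redrawn (they would make the feedback undefined).
    """
    if mode == "none":
        return base_b if size is None else np.full(size, base_b)
    rng = rng or np.random.default_rng()
    if mode == "constant_var":
        mean, frac = base_b, sd
    elif mode == "increasing_var":
        ramp = t / max(horizon - 1, 1)
        mean, frac = base_b, sd + (sd_final - sd) * ramp
    elif mode == "declining":
        mean, frac = base_b * math.exp(-decline_rate * t), sd
    else:
        raise ValueError(f"unknown K-fluctuation mode {mode!r}")
    shape = () if size is None else (size,)
    draws = rng.normal(mean, frac * mean, size=shape)
    for _ in range(10):
        bad = draws <= 0
        if not np.any(bad):
            break
        draws = np.where(bad, rng.normal(mean, frac * mean, size=shape), draws)
    draws = np.maximum(draws, 1e-9 * base_b)
    return float(draws) if size is None else draws


# ---------------------------------------------------------------------------
# Batch projection
# ---------------------------------------------------------------------------

@dataclass
class BatchResult:
    """Replicate-stacked projection output (post burn-in)."""

    abbr: str
    scenario_id: str
    seed: int
    G: float
    burn_in: int
    N: np.ndarray          # (n_reps, T)
    s_red: np.ndarray      # (n_reps, T - 1)
    extinct_at: np.ndarray  # (n_reps,), -1 if never extinct

    @property
    def r(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.log(self.N[:, 1:] / self.N[:, :-1])
        out[(self.N[:, 1:] <= 0) | (self.N[:, :-1] <= 0)] = np.nan
        return out

    def to_series(self) -> list[AbundanceSeries]:
        out = []
        for i in range(self.N.shape[0]):
            ext = int(self.extinct_at[i])
            out.append(
                AbundanceSeries(
                    abbr=self.abbr,
                    scenario_id=self.scenario_id,
                    replicate=i,
                    seed=self.seed,
                    N=self.N[i],
                    s_red_t=self.s_red[i],
                    extinct_at=None if ext < 0 else ext,
                )
            )
        return out


def project_batch(
    lh: LifeHistory,
    fp: FeedbackParams | None,
    scenario: ScenarioSpec,
    n_reps: int,
    rng: np.random.Generator,
    cp: CatastropheParams | None = None,
    n_years: int | None = None,
    harvest_rate: float = 0.0,
    catastrophe_multiplier: float = 1.0,
    catastrophe_ramp: bool = False,
    sd_survival: float = 0.05,
    sd_fertility: float = 0.05,
    juvenile_sd_multiplier: float = 1.0,
    n0_convention: str = "simplified",
    burn_in: bool = True,
    split: SplitFeedback | None = None,
    integerize: bool = False,
    seed_label: int = 0,
) -> BatchResult:
    """Project ``n_reps`` replicate populations of one species under a scenario.

    The density feedback is active when both the scenario and ``fp`` allow it;
    harvest rates and the null-scenario catastrophe multiplier must be
    calibrated beforehand (see calibrate_harvest / calibrate_null_catastrophes).
    """
    cp = cp or CatastropheParams()
    L = build_leslie(lh)
    G = L.G
    q = n_years if n_years is not None else lh.species.q
    burn = int(round(G)) if burn_in else 0
    if q <= burn + 2:
        raise ValueError("projection shorter than burn-in")
    n_cls = lh.omega + 1
    feedback_on = (
        scenario.component_feedback_on
        and fp is not None
        and fp.applies_to != "none"
    )
    cat_on = scenario.catastrophes_on or scenario.id == "ix"
    if not cat_on:
        C = 0.0
    elif catastrophe_ramp:
        # C is the mean yearly probability; the instantaneous ramp value
        # 2*C*t/(q-2) is truncated at 1 inside the loop
        C = catastrophe_multiplier * cp.p_per_generation / G
        if C < 0:
            raise ValueError("negative catastrophe probability")
    else:
        C = cp.yearly_probability(G, catastrophe_multiplier)
    sev_a, sev_b = _severity_shapes(cp)
    pulse_year = (
        int(round(scenario.pulse.time_generations * G)) if scenario.pulse else -1
    )
    juvenile_classes = int(np.argmax(lh.m > 0))

    n = np.tile(initial_population(lh, L, n0_convention), (n_reps, 1))
    N_rec = np.empty((n_reps, q))
    sr_rec = np.ones((n_reps, q - 1))
    N_rec[:, 0] = n.sum(axis=1)
    extinct_at = np.full(n_reps, -1, dtype=int)
    alive = np.ones(n_reps, dtype=bool)

    for t in range(q - 1):
        S_draw = resample_survival(
            lh.S, sd_survival, juvenile_sd_multiplier, rng,
            size=n_reps, juvenile_classes=juvenile_classes,
        )
        m_draw = resample_fertility(lh.m, sd_fertility, rng, size=n_reps)

        tot = n.sum(axis=1)
        if feedback_on:
            b_t = k_schedule(
                t, fp.b, scenario.k_fluctuation, rng, horizon=q,
                sd=scenario.k_sd, sd_final=scenario.k_sd_final,
                decline_rate=scenario.k_decline_rate, size=n_reps,
            )
            base_sr = fp.a / (1.0 + (tot / b_t) ** fp.c)
            if split is None:
                sr = base_sr
                S_eff = S_draw * sr[:, None]
                m_eff = m_draw
            else:
                sr = base_sr ** (1.0 - split.split_fraction)
                fert_mod = base_sr ** (
                    split.split_fraction * split.fertility_exponent
                )
                S_eff = S_draw * sr[:, None]
                m_eff = m_draw * fert_mod[:, None]
                sr = base_sr  # record the underlying modifier
        else:
            sr = np.ones(n_reps)
            S_eff = S_draw
            m_eff = m_draw

        if C > 0:
            C_t = C * 2.0 * t / max(q - 2, 1) if catastrophe_ramp else C
            event = rng.random(n_reps) < min(C_t, 1.0)
            severity = rng.beta(sev_a, sev_b, size=n_reps)
            factor = np.where(event, severity, 1.0)
            S_eff = S_eff * factor[:, None]
            if cp.hits_recruitment:
                m_eff = m_eff * factor[:, None]

        S_eff = np.clip(S_eff, 0.0, 1.0)

        new = np.empty_like(n)
        new[:, 0] = (m_eff * n).sum(axis=1)
        new[:, 1:] = S_eff[:, :-1] * n[:, :-1]
        new[:, -1] += S_eff[:, -1] * n[:, -1]

        if harvest_rate > 0:
            new *= 1.0 - harvest_rate
        if t + 1 == pulse_year and scenario.pulse is not None:
            new *= 1.0 - scenario.pulse.mortality
        if integerize:
            new = rng.poisson(new).astype(float)

        tot_new = new.sum(axis=1)
        dying = alive & (tot_new < EXTINCTION_THRESHOLD)
        if np.any(dying):
            extinct_at[dying] = t + 1
            new[dying] = 0.0
            alive &= ~dying
        n = new
        N_rec[:, t + 1] = n.sum(axis=1)
        sr_rec[:, t] = sr

    ext_adj = np.where(extinct_at >= 0, np.maximum(extinct_at - burn, 0), -1)
    return BatchResult(
        abbr=lh.species.abbr,
        scenario_id=scenario.id,
        seed=seed_label,
        G=G,
        burn_in=burn,
        N=N_rec[:, burn:],
        s_red=sr_rec[:, burn:],
        extinct_at=ext_adj,
    )


def project_series(
    lh: LifeHistory,
    fp: FeedbackParams | None,
    scenario: ScenarioSpec,
    cp: CatastropheParams | None = None,
    n_years: int | None = None,
    rng_seed: int = 0,
    **kwargs,
) -> AbundanceSeries:
    """Project a single abundance series (a batch of one replicate)."""
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    batch = project_batch(
        lh, fp, scenario, n_reps=1, rng=rng, cp=cp, n_years=n_years,
        seed_label=rng_seed, **kwargs,
    )
    return batch.to_series()[0]


@dataclass
class PreparedSpecies:
    """A species with everything calibrated that a scenario run needs."""

    lh: LifeHistory
    fp: FeedbackParams
    cp: CatastropheParams = field(default_factory=CatastropheParams)
    harvest_rates: dict[float, float] = field(default_factory=dict)
    null_catastrophe_multiplier: float = 1.0

    @property
    def abbr(self) -> str:
        return self.lh.species.abbr


def _scenario_code(scenario_id: str) -> int:
    return list(SCENARIOS).index(scenario_id) + 1


def run_scenario(
    scenario: ScenarioSpec | str,
    species: list[PreparedSpecies],
    n_reps: int,
    base_seed: int = 0,
    **kwargs,
) -> list[BatchResult]:
    """Run one scenario for a set of prepared species.

    Per-species batch seeds are derived deterministically from
    (base_seed, species index, scenario), so the full collection is
    reproducible from the root seed alone.
    """
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    out: list[BatchResult] = []
    code = _scenario_code(scenario.id)
    for i, sp in enumerate(species):
        rng = np.random.default_rng(np.random.SeedSequence([base_seed, i, code]))
        harvest = 0.0
        if scenario.harvest_target_r is not None:
            try:
                harvest = sp.harvest_rates[scenario.harvest_target_r]
            except KeyError:
                raise RuntimeError(
                    f"{sp.abbr}: harvest rate for target r="
                    f"{scenario.harvest_target_r} not calibrated"
                ) from None
        multiplier = (
            sp.null_catastrophe_multiplier if scenario.id == "ix" else 1.0
        )
        out.append(
            project_batch(
                sp.lh,
                sp.fp if scenario.component_feedback_on else None,
                scenario,
                n_reps=n_reps,
                rng=rng,
                cp=sp.cp,
                harvest_rate=harvest,
                catastrophe_multiplier=multiplier,
                seed_label=base_seed,
                **kwargs,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Scenario calibrations (harvest offtake, null-scenario catastrophes)
# ---------------------------------------------------------------------------

def _mean_r_of_batch(batch: BatchResult) -> float:
    r = batch.r
    if np.all(np.isnan(r)):
        return -np.inf
    return float(np.nanmean(r))


def calibrate_harvest(
    lh: LifeHistory,
    fp: FeedbackParams,
    target_mean_r: float,
    tol: float = 0.003,
    n_reps: int = 40,
    rng_seed: int = 0,
    cp: CatastropheParams | None = None,
    validate: bool = False,
) -> float:
    """Proportional yearly offtake h making the population decline on average
    at the target rate.

    The offtake removes the population's maximum compensatory growth plus the
    target decline, h = 1 - exp(r_target) / lambda_max, where lambda_max is
    the growth rate with the survival reduction at its ceiling (S_red = a).
    Once abundance has fallen enough that the feedback is saturated, the
    population then declines at exactly the target rate in expectation; a
    smaller offtake would merely re-equilibrate the population at a lower
    abundance, whose long-run mean r returns to ~0 instead of declining.
    Catastrophes in the harvest scenarios add further drag on top of the
    nominal target.

    With ``validate`` a catastrophe-free simulation checks that the mean
    yearly r over the second half of the projection (past the saturation
    transient) is within ``tol`` of the target.  A non-negative target
    returns h = 0 for a feedback-calibrated population (it is already
    stationary).
    """
    if target_mean_r >= 0.0:
        return 0.0
    n = lh.omega + 1
    M = np.zeros((n, n))
    M[0, :] = lh.m
    M[np.arange(1, n), np.arange(0, n - 1)] = lh.S[:-1] * fp.a
    M[n - 1, n - 1] = lh.S[-1] * fp.a
    lam_max = float(np.max(np.linalg.eigvals(M).real))
    h = 1.0 - math.exp(target_mean_r) / lam_max
    if h <= 0.0:
        return 0.0
    if validate:
        cp = cp or CatastropheParams()
        scen = replace(get_scenario("i"), id="iv", harvest_target_r=target_mean_r)
        rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 0xA11]))
        # doubled horizon so the second half is past the saturation transient
        batch = project_batch(
            lh, fp, scen, n_reps=n_reps, rng=rng, cp=cp, harvest_rate=h,
            n_years=2 * lh.species.q,
        )
        r = batch.r[:, batch.r.shape[1] // 2:]
        achieved = float(np.nanmean(r)) if not np.all(np.isnan(r)) else -np.inf
        if abs(achieved - target_mean_r) > tol:
            raise RuntimeError(
                f"{lh.species.abbr}: harvest offtake {h:.4f} achieved long-run "
                f"mean r {achieved:.4f}, target {target_mean_r}"
            )
    return float(h)


def calibrate_null_catastrophes(
    lh: LifeHistory,
    tol: float = 0.005,
    n_reps: int = 60,
    rng_seed: int = 0,
    cp: CatastropheParams | None = None,
) -> float:
    """Catastrophe-intensity multiplier holding a feedback-free population stable.

    With the survival reduction forced to 1 the population grows at its
    intrinsic rate; the yearly catastrophe probability is scaled up by the
    returned multiplier until the long-run mean growth rate is ~0.  Errors if
    stability would require a yearly probability above 1.
    """
    from scipy.optimize import brentq

    cp = cp or CatastropheParams()
    scen = get_scenario("ix")
    G = build_leslie(lh).G

    def mean_r(mult: float) -> float:
        rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 0xCA7]))
        batch = project_batch(
            lh, None, scen, n_reps=n_reps, rng=rng, cp=cp,
            catastrophe_multiplier=mult,
        )
        return _mean_r_of_batch(batch)

    mult_max = G / cp.p_per_generation  # yearly probability reaches 1 here
    if mean_r(mult_max) > 0:
        raise RuntimeError(
            f"{lh.species.abbr}: stability unreachable; required catastrophe "
            "probability exceeds 1"
        )
    if mean_r(0.0) <= 0:
        return 0.0
    mult = brentq(mean_r, 0.0, mult_max, xtol=1e-4)
    achieved = mean_r(mult)
    if abs(achieved) > tol:
        raise RuntimeError(
            f"{lh.species.abbr}: null-catastrophe calibration achieved mean r "
            f"{achieved:.4f} (tol {tol})"
        )
    return float(mult)
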