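"""Synthetic life histories and Leslie-matrix construction.

The simulated populations are female-only, age-structured, and censused just
before breeding, so age class ``x`` holds individuals of true age ``x + 1``
and the first-row "fertility" entries are effective recruitment rates
(daughters recruited to the first census age per female per year).  Each test
species is described only by a body mass, a target generation length (GL) and
a projection horizon; the full survival/fertility schedule is synthesized
from those targets with simple allometric rules and then calibrated so that
the realized generation length of the matrix matches GL and the dominant
eigenvalue matches a maximum-growth target (leaving room for a compensatory
density feedback to hold the population at carrying capacity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "SpeciesTarget",
    "LifeHistory",
    "LeslieMatrix",
    "LifeHistoryConfig",
    "STUDY_AREA_KM2",
    "TERMINAL_ZEROED_SPECIES",
    "load_species_table",
    "synthesize_life_history",
    "build_leslie",
    "generation_length",
    "initial_population",
    "write_life_histories",
    "read_life_histories",
]

#: Surface area of the (closed) study region, km^2.
STUDY_AREA_KM2 = 250_000.0

#: Species whose terminal self-loop survival is forced to zero to avoid an
#: unrealistic accumulation of very old individuals (wombat, thylacine, devil).
TERMINAL_ZEROED_SPECIES = frozenset({"VU", "TH", "SH"})


@dataclass(frozen=True)
class SpeciesTarget:
    """Life-history targets for one test species."""

    abbr: str
    group: str
    mass: float          # mean adult body mass, kg
    gl_target: float     # generation length, years
    q: int               # projection length, years (= round(40 * GL))

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"{self.abbr}: body mass must be positive")
        if not (2.0 <= self.gl_target <= 25.0):
            raise ValueError(f"{self.abbr}: GL {self.gl_target} outside [2, 25]")
        if abs(self.q - round(40 * self.gl_target)) > 1:
            raise ValueError(
                f"{self.abbr}: q={self.q} inconsistent with 40*GL="
                f"{40 * self.gl_target:.0f}"
            )


@dataclass
class LifeHistoryConfig:
    """Allometric rules and calibration settings for life-history synthesis.

    maturity_frac, longevity_frac
        Age at first reproduction = max(1, round(maturity_frac * GL));
        maximum age = round(longevity_frac * GL) (years).
    rmax_per_generation
        Maximum intrinsic growth target: ln(lambda1) = rmax_per_generation / GL.
    juvenile_survival_ratio
        First-year-class survival as a fraction of adult survival; the
        schedule ramps linearly up to adult survival at maturity.
    density_coeff, density_exponent
        Equilibrium density D = density_coeff * mass**density_exponent
        (individuals / km^2); density_coeff is set once so that the smallest
        carrying capacity across the species set stays above k_floor.
    gl_tolerance
        Acceptable relative error of the realized generation length.
    """

    maturity_frac: float = 0.35
    longevity_frac: float = 2.5
    rmax_per_generation: float = 0.5
    juvenile_survival_ratio: float = 0.6
    density_coeff: float = 10.0
    density_exponent: float = -0.78
    area_km2: float = STUDY_AREA_KM2
    k_floor: float = 5_000.0
    gl_tolerance: float = 0.10
    adult_survival_bounds: tuple[float, float] = (0.20, 0.99)
    max_fertility: float = 50.0


@dataclass
class LifeHistory:
    """Age-indexed survival/fertility schedules plus the density scaling."""

    species: SpeciesTarget
    omega: int                      # maximum age-class index (classes 0..omega)
    S: np.ndarray                   # survival probabilities, class x -> x+1
    m: np.ndarray                   # recruitment (daughters/female/year)
    terminal_survival_zeroed: bool
    D: float                        # equilibrium density, km^-2
    A: float                        # area, km^2
    K: float = field(init=False)    # carrying capacity, individuals

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        if len(self.S) != self.omega + 1 or len(self.m) != self.omega + 1:
            raise ValueError("S and m must have length omega + 1")
        if np.any((self.S < 0) | (self.S > 1)):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(self.m < 0):
            raise ValueError("fertilities must be non-negative")
        if self.terminal_survival_zeroed and self.S[self.omega] != 0.0:
            raise ValueError("terminal_survival_zeroed requires S[omega] = 0")
        self.K = self.D * self.A


@dataclass
class LeslieMatrix:
    """A prebreeding Leslie matrix and its eigenstructure."""

    M: np.ndarray
    lambda1: float
    w: np.ndarray   # stable age distribution, sums to 1
    v: np.ndarray   # reproductive values
    G: float        # generation length, years


def _table_path() -> Path:
    return Path(str(resources.files("densityfeedback").joinpath("data/species_table.csv")))


def load_species_table(path: str | Path | None = None) -> list[SpeciesTarget]:
    """Load the 21-species target table packaged with the library."""
    p = Path(path) if path is not None else _table_path()
    try:
        df = pd.read_csv(p)
    except (OSError, pd.errors.ParserError) as exc:
        raise RuntimeError(f"cannot load species table from {p}: {exc}") from exc
    expected = {"abbr", "group", "mass_kg", "GL_yr", "q_yr"}
    if set(df.columns) != expected:
        raise RuntimeError(f"species table {p} has columns {list(df.columns)}")
    return [
        SpeciesTarget(
            abbr=row.abbr,
            group=row.group,
            mass=float(row.mass_kg),
            gl_target=float(row.GL_yr),
            q=int(row.q_yr),
        )
        for row in df.itertuples()
    ]


def write_species_table(targets: list[SpeciesTarget], path: str | Path) -> None:
    pd.DataFrame(
        {
            "abbr": [t.abbr for t in targets],
            "group": [t.group for t in targets],
            "mass_kg": [t.mass for t in targets],
            "GL_yr": [t.gl_target for t in targets],
            "q_yr": [t.q for t in targets],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Leslie matrix, eigenstructure, generation length
# ---------------------------------------------------------------------------

def build_leslie(lh: LifeHistory) -> LeslieMatrix:
    """Assemble the prebreeding Leslie matrix of ``lh`` and decompose it.

    Row one holds the recruitment vector, the subdiagonal holds survival,
    and the bottom-right cell holds the terminal self-loop survival S[omega]
    (zero for the terminal-zeroed species).
    """
    n = lh.omega + 1
    if not np.any(lh.m > 0):
        raise ValueError("matrix has no reproduction anywhere")
    M = np.zeros((n, n))
    M[0, :] = lh.m
    if n > 1:
        M[np.arange(1, n), np.arange(0, n - 1)] = lh.S[:-1]
        M[n - 1, n - 1] = lh.S[-1]
    else:
        M[0, 0] += lh.S[0]
    return _decompose(M)


def _decompose(M: np.ndarray) -> LeslieMatrix:
    vals, vecs = np.linalg.eig(M)
    i = int(np.argmax(vals.real))
    lam = float(vals[i].real)
    if lam <= 0:
        raise ValueError("dominant eigenvalue is not positive")
    w = np.abs(vecs[:, i].real)
    w = w / w.sum()
    lvals, lvecs = np.linalg.eig(M.T)
    j = int(np.argmax(lvals.real))
    v = np.abs(lvecs[:, j].real)
    v = v / v[0]
    L = LeslieMatrix(M=M, lambda1=lam, w=w, v=v, G=float("nan"))
    L.G = generation_length(L)
    return L


def net_reproductive_rate(M: np.ndarray) -> float:
    """R0 = dominant eigenvalue of the reproductive matrix F (I - T)^-1."""
    n = M.shape[0]
    F = np.zeros_like(M)
    F[0, :] = M[0, :]
    T = M - F
    fundamental = np.linalg.solve(np.eye(n) - T.T, F.T).T  # F @ inv(I - T)
    vals = np.linalg.eigvals(fundamental)
    return float(np.max(vals.real))


def _cohort_generation_time(M: np.ndarray, tol: float = 1e-12) -> float:
    """Mean age of mothers at offspring recruitment, Σ a·l_a·m_a / Σ l_a·m_a.

    Class index x corresponds to true age x + 1 under the prebreeding census;
    the terminal self-loop is followed until its survivorship tail vanishes.
    """
    m = M[0, :].copy()
    n = M.shape[0]
    S = np.zeros(n)
    if n > 1:
        S[:-1] = np.diag(M, -1)
        S[-1] = M[-1, -1]
    num = 0.0
    den = 0.0
    l = 1.0
    x = 0
    while l > tol and x < 100_000:
        mx = m[min(x, n - 1)]
        age = x + 1
        num += age * l * mx
        den += l * mx
        l *= S[min(x, n - 1)]
        x += 1
    if den <= 0:
        raise ValueError("net reproduction is zero; generation length undefined")
    return num / den


def generation_length(L: LeslieMatrix, lambda_tol: float = 1e-8) -> float:
    """Generation length G = ln R0 / ln lambda1 (years).

    When lambda1 is numerically 1 the log-ratio is indeterminate and the
    cohort mean age of mothers is used instead.
    """
    if abs(L.lambda1 - 1.0) < lambda_tol:
        return _cohort_generation_time(L.M)
    r0 = net_reproductive_rate(L.M)
    if r0 <= 0:
        raise ValueError("net reproductive rate R0 <= 0")
    G = math.log(r0) / math.log(L.lambda1)
    if G <= 0:
        raise ValueError("generation length came out non-positive")
    return G


def initial_population(
    lh: LifeHistory, L: LeslieMatrix, convention: str = "simplified"
) -> np.ndarray:
    """Initial abundance vector at the stable age distribution.

    ``simplified``: n0 = K * w (total abundance exactly K).
    ``literal``:    n0 = K * M w = K * lambda1 * w (one projection step
    applied to the stable distribution, so total = K * lambda1).
    """
    if convention == "simplified":
        return lh.K * L.w
    if convention == "literal":
        return lh.K * (L.M @ L.w)
    raise ValueError(f"unknown n0 convention {convention!r}")


# ---------------------------------------------------------------------------
# Life-history synthesis
# ---------------------------------------------------------------------------

def _schedules(
    target: SpeciesTarget, cfg: LifeHistoryConfig, s_adult: float, fert: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Survival/fertility schedules for a candidate (adult survival, fertility)."""
    maturity_age = max(1, round(cfg.maturity_frac * target.gl_target))
    omega_age = max(maturity_age + 2, round(cfg.longevity_frac * target.gl_target))
    n = omega_age  # classes 0..omega_age-1 hold true ages 1..omega_age
    S = np.full(n, s_adult)
    mat_idx = maturity_age - 1  # class index of first reproduction
    if mat_idx > 0:
        ramp = np.linspace(cfg.juvenile_survival_ratio * s_adult, s_adult, mat_idx + 1)
        S[: mat_idx + 1] = ramp
    else:
        S[0] = s_adult
    m = np.zeros(n)
    m[mat_idx:] = fert
    if target.abbr in TERMINAL_ZEROED_SPECIES:
        S[-1] = 0.0
    return S, m, n - 1


def _lambda_of(S: np.ndarray, m: np.ndarray) -> float:
    n = len(S)
    M = np.zeros((n, n))
    M[0, :] = m
    M[np.arange(1, n), np.arange(0, n - 1)] = S[:-1]
    M[n - 1, n - 1] = S[-1]
    return float(np.max(np.linalg.eigvals(M).real))


def synthesize_life_history(
    target: SpeciesTarget,
    config: LifeHistoryConfig | None = None,
    rng_seed: int | None = None,
) -> LifeHistory:
    """Build a survival/fertility schedule matching the species targets.

    Adult survival and adult fertility are solved (nested root-finding) so
    that the matrix's generation length equals the target GL and its dominant
    eigenvalue equals exp(rmax_per_generation / GL).  The construction is
    deterministic; ``rng_seed`` is accepted for interface stability and
    ignored.
    """
    cfg = config or LifeHistoryConfig()
    lam_target = math.exp(cfg.rmax_per_generation / target.gl_target)

    def solve_fert(s_adult: float) -> tuple[np.ndarray, np.ndarray]:
        S, m_shape, _ = _schedules(target, cfg, s_adult, 1.0)

        def g(f: float) -> float:
            return _lambda_of(S, m_shape * f) - lam_target

        lo, hi = 1e-9, cfg.max_fertility
        if g(hi) < 0:
            raise RuntimeError(
                f"{target.abbr}: cannot reach lambda target {lam_target:.3f}"
            )
        f = brentq(g, lo, hi, xtol=1e-12, rtol=1e-12)
        return S, m_shape * f

    def gl_error(s_adult: float) -> float:
        S, m = solve_fert(s_adult)
        lh = _assemble(target, cfg, S, m)
        return build_leslie(lh).G - target.gl_target

    # The growth target may be unreachable at low adult survival (survivorship
    # to maturity too small), so bracket the GL root on the feasible portion
    # of the adult-survival range before refining.
    s_lo, s_hi = cfg.adult_survival_bounds
    grid = np.linspace(s_lo, s_hi, 25)
    feasible: list[tuple[float, float]] = []
    for s in grid:
        try:
            feasible.append((float(s), gl_error(float(s))))
        except RuntimeError:
            continue
    if not feasible:
        raise RuntimeError(
            f"{target.abbr}: lambda target {lam_target:.3f} unreachable for any "
            f"adult survival in [{s_lo}, {s_hi}]"
        )
    bracket = None
    for (sa, ea), (sb, eb) in zip(feasible[:-1], feasible[1:]):
        if ea == 0.0:
            bracket = (sa, sa)
            break
        if ea * eb < 0:
            bracket = (sa, sb)
            break
    if bracket is None:
        errs = [e for _, e in feasible]
        raise RuntimeError(
            f"{target.abbr}: generation-length target {target.gl_target} not "
            f"bracketed (GL errors span [{min(errs):.3f}, {max(errs):.3f}])"
        )
    s_adult = bracket[0] if bracket[0] == bracket[1] else brentq(
        gl_error, bracket[0], bracket[1], xtol=1e-10
    )
    S, m = solve_fert(s_adult)
    lh = _assemble(target, cfg, S, m)
    G = build_leslie(lh).G
    if abs(G - target.gl_target) / target.gl_target > cfg.gl_tolerance:
        raise RuntimeError(
            f"{target.abbr}: calibrated G={G:.3f} misses target "
            f"{target.gl_target} beyond tolerance"
        )
    return lh


def _assemble(
    target: SpeciesTarget, cfg: LifeHistoryConfig, S: np.ndarray, m: np.ndarray
) -> LifeHistory:
    D = cfg.density_coeff * target.mass ** cfg.density_exponent
    return LifeHistory(
        species=target,
        omega=len(S) - 1,
        S=S,
        m=m,
        terminal_survival_zeroed=target.abbr in TERMINAL_ZEROED_SPECIES,
        D=D,
        A=cfg.area_km2,
    )


# ---------------------------------------------------------------------------
# Plain-text persistence of synthesized life histories
# ---------------------------------------------------------------------------

def write_life_histories(lhs: list[LifeHistory], path: str | Path) -> None:
    """One species per block: abbr, D, A, then the S and m vectors."""
    with open(path, "w") as fh:
        for lh in lhs:
            fh.write(f"# species {lh.species.abbr}\n")
            fh.write(
                f"abbr={lh.species.abbr} group={lh.species.group} "
                f"mass={lh.species.mass!r} GL={lh.species.gl_target!r} "
                f"q={lh.species.q} D={lh.D!r} A={lh.A!r} "
                f"zeroed={int(lh.terminal_survival_zeroed)}\n"
            )
            fh.write("S=" + ",".join(repr(float(x)) for x in lh.S) + "\n")
            fh.write("m=" + ",".join(repr(float(x)) for x in lh.m) + "\n")


def read_life_histories(path: str | Path) -> list[LifeHistory]:
    out: list[LifeHistory] = []
    meta: dict[str, str] = {}
    S = m = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("abbr="):
                meta = dict(kv.split("=", 1) for kv in line.split())
            elif line.startswith("S="):
                S = np.array([float(x) for x in line[2:].split(",")])
            elif line.startswith("m="):
                m = np.array([float(x) for x in line[2:].split(",")])
                target = SpeciesTarget(
                    abbr=meta["abbr"],
                    group=meta["group"],
                    mass=float(meta["mass"]),
                    gl_target=float(meta["GL"]),
                    q=int(meta["q"]),
                )
                out.append(
                    LifeHistory(
                        species=target,
                        omega=len(S) - 1,
                        S=S,
                        m=m,
                        terminal_survival_zeroed=bool(int(meta["zeroed"])),
                        D=float(meta["D"]),
                        A=float(meta["A"]),
                    )
                )
    return out
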