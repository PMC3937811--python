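"""Constrained global fitting of scattering curves.

A real-coded genetic algorithm minimises the pooled reduced chi-squared of
one or several SAXS/SANS datasets that share a single bilayer structure,
subject to the physical constraint system: hard proximity walls between the
choline methyls and the phosphate group and between the chain interface and
the glycerol backbone (2 A each), box bounds on every gene (fragment
volumes within a tolerance of their reference values, sigma_HC within its
accepted window), a soft quadratic penalty steering the summed headgroup
volume to its target, and an infeasibility penalty whenever the methylene
or water probability turns negative anywhere.

Per-dataset intensity scale and constant background are free parameters
that are profiled analytically (weighted linear least squares) at every
objective evaluation instead of being carried as genes; the genetic search
therefore runs in the purely structural + lattice parameter space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger("sdpgap")

from .lattice import (
    InstrumentModel,
    LatticeParams,
    caille_structure_factor,
    index_lamellar,
    intensity_mlv,
    intensity_ulv,
)
from .sdp import (
    BilayerSDP,
    Contrast,
    ParsingScheme,
    form_factor,
    volume_profiles,
    water_profile,
)
from .structure import StructuralParams, derive_structure

__all__ = [
    "Dataset",
    "FitConfig",
    "PenaltyWeights",
    "ParamSpec",
    "FitProblem",
    "FitResult",
    "GAResult",
    "reduced_chi_squared",
    "penalty",
    "objective",
    "ga_optimize",
    "fit",
    "estimate_uncertainty",
]

#: Maximum admitted |z_CholCH3 - z_PCN| and |D_C - z_CG| (A).
PROXIMITY_LIMIT = 2.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """One measured or synthetic scattering curve with its contrast context."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    geometry: str = "mlv"
    contrast: Contrast = field(default_factory=Contrast)
    name: str = "dataset"
    beam_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.q.size == self.I.size == self.sigma.size):
            raise ValueError("q, I, sigma must have equal length")
        if self.q.size < 20:
            raise ValueError("dataset needs at least 20 points")
        if np.any(np.diff(self.q) <= 0) or self.q[0] <= 0:
            raise ValueError("q must be strictly increasing and positive")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        if self.geometry not in ("mlv", "ulv"):
            raise ValueError("geometry must be 'mlv' or 'ulv'")


@dataclass
class PenaltyWeights:
    """Weights of the soft penalty terms added to the fitness."""

    headgroup_volume: float = 1.0e-2  # per A^6 on (sum V_head - target)^2
    negativity: float = 1.0e4  # on the squared worst negative excursion
    negativity_floor: float = 1.0  # flat offset once infeasible


@dataclass
class FitConfig:
    """Genetic-algorithm settings.

    Defaults follow common practice for real-coded GAs at the population
    scale used for this class of problem (~2000 individuals, convergence
    declared after 100 stagnant generations, a few hundred generations
    total); ``quick`` presets in the CLI shrink them for smoke tests.
    """

    population_size: int = 2000
    max_generations: int = 500
    stagnation_generations: int = 100
    seed: int = 0
    tournament_k: int = 3
    crossover_prob: float = 0.9
    blend_alpha: float = 0.3
    mutation_prob: float = 0.1
    mutation_scale: float = 0.05  # Gaussian step as a fraction of the bound range
    mutation_scale_final: float = 0.002  # annealed to this by max_generations
    elite: int = 1
    islands: int = 4
    migrate_every: int = 20
    merge_fraction: float = 0.35  # islands merge after this fraction of the run
    polish_fraction: float = 0.35  # final fraction run as covariance polish
    polish_top_fraction: float = 0.2  # elite share fitted by the polish model
    polish_sigma: float = 0.02  # initial polish cloud, fraction of bound range
    polish_inflation: float = 1.3  # covariance multiplier (counters collapse)
    polish_ams_fraction: float = 0.3  # offspring share shifted along the mean drift
    polish_ams_mult: float = 2.0  # anticipated-mean-shift step multiplier
    n_starts: int = 1  # independent GA runs; lowest chi^2 wins
    stagnation_rtol: float = 1.0e-6
    ensemble_fraction: float = 0.05
    weights: PenaltyWeights = field(default_factory=PenaltyWeights)

    def __post_init__(self) -> None:
        if self.population_size < 10:
            raise ValueError("population_size must be >= 10")
        if self.islands < 1:
            raise ValueError("islands must be >= 1")


@dataclass
class ParamSpec:
    """One model parameter: free within [low, high], or fixed at ``value``."""

    name: str
    low: float = 0.0
    high: float = 0.0
    value: float | None = None

    @property
    def fixed(self) -> bool:
        return self.value is not None

    def __post_init__(self) -> None:
        if not self.fixed:
            if not (math.isfinite(self.low) and math.isfinite(self.high)):
                raise ValueError(f"{self.name}: bounds must be finite")
            if self.low >= self.high:
                raise ValueError(f"{self.name}: low must be < high")


@dataclass
class GAResult:
    """Raw optimizer output: best vector and the final evaluated population."""

    x: np.ndarray
    fun: float
    population: np.ndarray
    fitness: np.ndarray
    generations: int
    history: list[float]


@dataclass
class FitResult:
    """Best-fit parameters, goodness of fit, derived structure and the
    near-optimal solution ensemble used for spread estimates."""

    params: dict[str, float]
    chi2_red: float
    chi2_red_per_dataset: list[float]
    sdp: BilayerSDP
    structure: StructuralParams | None
    ensemble: list[dict[str, float]]
    spread: dict[str, float]
    generations: int
    seed: int


# ---------------------------------------------------------------------------
# Objective building blocks
# ---------------------------------------------------------------------------


def reduced_chi_squared(I_obs, I_model, sigma, n_free: int) -> float:
    """Sum of squared, sigma-weighted residuals over the degrees of freedom."""
    I_obs = np.asarray(I_obs, dtype=float)
    I_model = np.asarray(I_model, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    n = I_obs.size
    if n <= n_free:
        raise ValueError(f"{n} points cannot constrain {n_free} free parameters")
    r = (I_obs - I_model) / sigma
    return float(r @ r) / (n - n_free)


def penalty(
    sdp: BilayerSDP,
    scheme: ParsingScheme,
    weights: PenaltyWeights | None = None,
    dz: float = 0.1,
) -> float:
    """Constraint score added to the fitness; zero for a feasible state.

    Hard walls (infinite score, candidate rejected): the choline-methyl /
    phosphate distance and the chain-interface / glycerol distance may not
    exceed 2 A.  Soft terms: quadratic pull of the summed headgroup volume
    towards the scheme target, and a steep penalty on negative methylene or
    water probability (spatial-conservation violation).
    """
    w = weights or PenaltyWeights()
    if abs(sdp.z_CholCH3 - sdp.z_PCN) > PROXIMITY_LIMIT:
        return float("inf")
    if abs(sdp.D_C - sdp.z_CG) > PROXIMITY_LIMIT:
        return float("inf")

    score = 0.0
    v_head = sum(sdp.volumes[name] for name in scheme.headgroup_names)
    score += w.headgroup_volume * (v_head - scheme.headgroup_volume_target) ** 2

    span = max(sdp.z_CholCH3, sdp.z_PCN, sdp.D_C) + 10.0
    z = np.arange(0.0, span, dz)  # symmetric model: half profile suffices
    profiles = volume_profiles(sdp, scheme, z)
    pw = water_profile(profiles)
    worst = min(float(profiles[scheme.ch2.name].min()), float(pw.min()))
    if worst < 0.0:
        score += w.negativity_floor + w.negativity * worst**2
    return score


def _profile_scale_background(q, I, sigma, M, fit_background: bool = True):
    """Optimal (scale, background) for I ~ s*M + b by weighted linear LS."""
    w = 1.0 / sigma**2
    sw = w.sum()
    if fit_background:
        swM = (w * M).sum()
        swMM = (w * M * M).sum()
        swI = (w * I).sum()
        swMI = (w * M * I).sum()
        det = swMM * sw - swM * swM
        if det <= 0:
            return 0.0, float(swI / sw)
        s = (swMI * sw - swM * swI) / det
        b = (swMM * swI - swM * swMI) / det
    else:
        s = float((w * M * I).sum() / (w * M * M).sum())
        b = 0.0
    if s <= 0:  # unphysical; evaluate at a vanishing amplitude
        s = 1.0e-30
        b = float((w * I).sum() / sw) if fit_background else 0.0
    return float(s), float(b)


# ---------------------------------------------------------------------------
# Fit problem: parameter table, decoding, objective
# ---------------------------------------------------------------------------

# The choline-methyl and glycerol positions are encoded relative to the
# phosphate position and the chain interface: the 2 A proximity constraints
# then become plain box bounds on the offset genes (no rejection sampling),
# and the strongly correlated (z_CholCH3, z_PCN) and (z_CG, D_C) directions
# align with gene axes, which real-coded crossover handles far better.
_SHARED_DEFAULTS: list[tuple[str, float, float]] = [
    ("dz_CholCH3", -PROXIMITY_LIMIT, PROXIMITY_LIMIT),
    ("z_PCN", 13.0, 25.0),
    ("dz_CG", -PROXIMITY_LIMIT, PROXIMITY_LIMIT),
    ("sigma_PCN", 1.5, 4.0),
    ("sigma_CG", 1.5, 4.0),
    ("sigma_CH3", 2.0, 4.5),
    ("sigma_HC", 2.0, 2.6),
    ("D_C", 11.0, 18.0),
]

_LATTICE_DEFAULTS: list[tuple[str, float, float]] = [
    ("d", 50.0, 75.0),
    ("N", 10.0, 30.0),
    ("eta", 0.0, 0.3),
    ("N_diff", 0.0, 10.0),
]


class FitProblem:
    """Joint model of one bilayer against one or more datasets.

    Builds the parameter table (shared structural genes, per-component
    volume genes bounded by the scheme tolerances, per-MLV-dataset lattice
    genes), decodes gene vectors into model states, and exposes the fitness
    ``objective`` = pooled reduced chi-squared + penalty.
    """

    def __init__(
        self,
        scheme: ParsingScheme,
        datasets: list[Dataset],
        V_L: float,
        bounds: dict[str, tuple[float, float]] | None = None,
        fixed: dict[str, float] | None = None,
        weights: PenaltyWeights | None = None,
        fit_background: bool = True,
    ) -> None:
        if not datasets:
            raise ValueError("need at least one dataset")
        self.scheme = scheme.normalized()
        self.datasets = datasets
        self.V_L = float(V_L)
        self.weights = weights or PenaltyWeights()
        self.fit_background = fit_background
        bounds = dict(bounds or {})
        fixed = dict(fixed or {})

        specs: list[ParamSpec] = []
        for name, lo, hi in _SHARED_DEFAULTS:
            specs.append(self._make_spec(name, lo, hi, bounds, fixed))
        for c in self.scheme.components:
            name = f"V_{c.name}"
            lo = c.volume_ref * (1.0 - c.volume_tolerance)
            hi = c.volume_ref * (1.0 + c.volume_tolerance)
            specs.append(self._make_spec(name, lo, hi, bounds, fixed))
        for ds in self.datasets:
            if ds.geometry == "mlv":
                for name, lo, hi in _LATTICE_DEFAULTS:
                    key = f"{name}@{ds.name}"
                    if name == "d" and key not in bounds and key not in fixed:
                        # seed the repeat-distance search from Bragg indexing;
                        # +-10% comfortably brackets the peak-position estimate
                        d0 = index_lamellar(ds.q, ds.I)
                        lo, hi = 0.9 * d0, 1.1 * d0
                    specs.append(self._make_spec(key, lo, hi, bounds, fixed))
        self.specs = specs
        self.free = [s for s in specs if not s.fixed]
        self.lower = np.array([s.low for s in self.free])
        self.upper = np.array([s.high for s in self.free])
        # scale + background per dataset are profiled but still count as free
        self.n_free = len(self.free) + (2 if fit_background else 1) * len(datasets)
        self.n_points = sum(ds.q.size for ds in datasets)
        if self.n_points <= self.n_free:
            raise ValueError("more free parameters than data points")

    @staticmethod
    def _make_spec(name, lo, hi, bounds, fixed) -> ParamSpec:
        if name in fixed:
            return ParamSpec(name, value=float(fixed[name]))
        if name in bounds:
            lo, hi = bounds[name]
        return ParamSpec(name, float(lo), float(hi))

    # -- decoding ----------------------------------------------------------

    def _values(self, x: np.ndarray) -> dict[str, float]:
        vals: dict[str, float] = {}
        it = iter(x)
        for s in self.specs:
            vals[s.name] = s.value if s.fixed else float(next(it))
        return vals

    def decode(self, x: np.ndarray) -> tuple[BilayerSDP, list[LatticeParams | None]]:
        vals = self._values(np.asarray(x, dtype=float))
        volumes = {c.name: vals[f"V_{c.name}"] for c in self.scheme.components}
        sdp = BilayerSDP(
            z_CholCH3=vals["z_PCN"] + vals["dz_CholCH3"],
            z_PCN=vals["z_PCN"],
            z_CG=vals["D_C"] + vals["dz_CG"],
            sigma_PCN=vals["sigma_PCN"],
            sigma_CG=vals["sigma_CG"],
            sigma_CH3=vals["sigma_CH3"],
            D_C=vals["D_C"],
            sigma_HC=vals["sigma_HC"],
            volumes=volumes,
            V_L=self.V_L,
        )
        lattices: list[LatticeParams | None] = []
        for ds in self.datasets:
            if ds.geometry == "mlv":
                lattices.append(
                    LatticeParams(
                        d=vals[f"d@{ds.name}"],
                        N=int(round(vals[f"N@{ds.name}"])),
                        eta=vals[f"eta@{ds.name}"],
                        N_diff=vals[f"N_diff@{ds.name}"],
                    )
                )
            else:
                lattices.append(None)
        return sdp, lattices

    # -- model + objective -------------------------------------------------

    def model_curves(self, x: np.ndarray) -> list[np.ndarray]:
        """Best-scaled model intensity per dataset at gene vector ``x``."""
        sdp, lattices = self.decode(x)
        out = []
        for ds, lat in zip(self.datasets, lattices):
            M = self._shape(ds, sdp, lat)
            s, b = _profile_scale_background(
                ds.q, ds.I, ds.sigma, M, self.fit_background
            )
            out.append(s * M + b)
        return out

    def scales(self, x: np.ndarray) -> list[tuple[float, float]]:
        sdp, lattices = self.decode(x)
        return [
            _profile_scale_background(
                ds.q, ds.I, ds.sigma, self._shape(ds, sdp, lat), self.fit_background
            )
            for ds, lat in zip(self.datasets, lattices)
        ]

    def _shape(self, ds: Dataset, sdp: BilayerSDP, lat: LatticeParams | None):
        """Unit-scale, zero-background model intensity."""
        F = form_factor(ds.q, sdp, self.scheme, ds.contrast)
        inst = InstrumentModel(beam_sigma=ds.beam_sigma, background=0.0, scale=1.0)
        if ds.geometry == "mlv":
            S = caille_structure_factor(ds.q, lat)
            return intensity_mlv(ds.q, F, S, lat, inst)
        return intensity_ulv(ds.q, F, inst)

    def objective(self, x: np.ndarray) -> float:
        """Pooled reduced chi-squared plus penalty; +inf for rejected states."""
        try:
            sdp, lattices = self.decode(x)
        except (ValueError, KeyError):
            return float("inf")
        pen = penalty(sdp, self.scheme, self.weights)
        if not math.isfinite(pen):
            return pen
        ss = 0.0
        try:
            for ds, lat in zip(self.datasets, lattices):
                M = self._shape(ds, sdp, lat)
                if not np.all(np.isfinite(M)):
                    return float("inf")
                s, b = _profile_scale_background(
                    ds.q, ds.I, ds.sigma, M, self.fit_background
                )
                r = (ds.I - s * M - b) / ds.sigma
                ss += float(r @ r)
        except (ValueError, FloatingPointError):
            return float("inf")
        return ss / (self.n_points - self.n_free) + pen


def objective(
    x,
    datasets: list[Dataset],
    scheme: ParsingScheme,
    V_L: float,
    weights: PenaltyWeights | None = None,
) -> float:
    """Functional wrapper over :class:`FitProblem` for one-off evaluations."""
    prob = FitProblem(scheme, datasets, V_L, weights=weights)
    return prob.objective(np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------


def _evolve_once(pop, fit_vals, lower, upper, span, mut_scale, cfg, rng):
    """One generational step: elitism, tournament selection, mixed crossover,
    bounded Gaussian mutation."""
    P, ndim = pop.shape
    new_pop = np.empty_like(pop)
    n_elite = min(cfg.elite, P)
    order = np.argsort(fit_vals)
    new_pop[:n_elite] = pop[order[:n_elite]]
    i = n_elite
    while i < P:
        i1 = _tournament(pop, fit_vals, cfg.tournament_k, rng)
        i2 = _tournament(pop, fit_vals, cfg.tournament_k, rng)
        p1, p2 = pop[i1], pop[i2]
        if rng.random() < cfg.crossover_prob:
            c1, c2 = _blend(p1, p2, fit_vals[i1], fit_vals[i2], cfg.blend_alpha, rng)
        else:
            c1, c2 = p1.copy(), p2.copy()
        for child in (c1, c2):
            if i >= P:
                break
            mask = rng.random(ndim) < cfg.mutation_prob
            if mask.any():
                child = child + mask * rng.normal(0.0, mut_scale * span, ndim)
            new_pop[i] = np.clip(child, lower, upper)
            i += 1
    return new_pop


def _polish_step(pop, fit_vals, best_x, lower, upper, top, cfg, mu_prev, rng):
    """Covariance-informed exploitation: fit a Gaussian to the elite
    fraction of the population and resample around it, keeping the best
    individual.  The empirical covariance aligns the offspring cloud with
    the strongly correlated valleys of the chi^2 landscape, which isotropic
    per-gene mutation cannot follow.  Two standard safeguards against the
    premature variance collapse this scheme is prone to: the covariance is
    inflated by a constant factor, and a fraction of the offspring is
    shifted along the elite mean's drift direction (anticipated mean
    shift), which accelerates travel along connected valleys."""
    ndim = pop.shape[1]
    order = np.argsort(fit_vals)[:top]
    sel = pop[order]
    mu = sel.mean(axis=0)
    C = cfg.polish_inflation * np.cov(sel.T) + 1e-12 * np.eye(ndim)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(C + 1e-9 * np.diag(np.diag(C)) + 1e-15 * np.eye(ndim))
    n = pop.shape[0] - 1
    new = mu + rng.normal(size=(n, ndim)) @ L.T
    if mu_prev is not None and cfg.polish_ams_fraction > 0:
        k = int(cfg.polish_ams_fraction * n)
        new[:k] = new[:k] + cfg.polish_ams_mult * (mu - mu_prev)
    return np.vstack([best_x, np.clip(new, lower, upper)]), mu


def ga_optimize(objective_fn, lower, upper, cfg: FitConfig) -> GAResult:
    """Island-model real-coded GA with a covariance polish phase.

    Three phases over ``max_generations``: (1) ``islands`` subpopulations
    evolve independently (tournament selection, mixed BLX-alpha /
    fitness-directed line crossover, bounded Gaussian mutation with a
    geometrically annealed step, single-elite survival), exchanging their
    best individual around a ring every ``migrate_every`` generations;
    (2) after ``merge_fraction`` of the run the islands merge into one
    panmictic population; (3) the final ``polish_fraction`` restarts the
    population as a tight cloud around the incumbent best and evolves it by
    elite-covariance resampling, which tracks curved chi^2 valleys down to
    the basin floor.  Isolation keeps independent basins alive long enough
    to compete; the polish makes runs converge deep enough that their final
    fitness values can be compared across restarts.

    Terminates when the best fitness has not improved by a relative
    ``stagnation_rtol`` for ``stagnation_generations`` generations, or at
    ``max_generations``.  Fully deterministic for a fixed seed.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    ndim = lower.size
    rng = np.random.default_rng(cfg.seed)
    P = cfg.population_size
    n_isl = min(cfg.islands, max(1, P // 10))
    sizes = [P // n_isl] * n_isl
    sizes[0] += P - sum(sizes)
    span = upper - lower
    merge_gen = int(cfg.merge_fraction * cfg.max_generations)
    polish_gen = int((1.0 - cfg.polish_fraction) * cfg.max_generations)

    pops = [lower + rng.random((sz, ndim)) * span for sz in sizes]
    fvs = [np.array([objective_fn(x) for x in p]) for p in pops]
    if not any(np.any(np.isfinite(f)) for f in fvs):
        raise RuntimeError(
            "all initial candidates infeasible; check bounds against the "
            "hard constraint walls"
        )
    best_x, best_f = None, float("inf")
    for p, f in zip(pops, fvs):
        i = int(np.argmin(f))
        if f[i] < best_f:
            best_x, best_f = p[i].copy(), float(f[i])
    history = [best_f]
    stagnant = 0
    gen = 0
    polish_mu = None

    for gen in range(1, cfg.max_generations + 1):
        # non-uniform mutation: step size annealed geometrically so late
        # generations refine rather than re-explore
        frac = gen / cfg.max_generations
        mut_scale = cfg.mutation_scale * (
            (cfg.mutation_scale_final / cfg.mutation_scale) ** frac
        )
        if gen == merge_gen and len(pops) > 1:
            pops = [np.vstack(pops)]
            fvs = [np.concatenate(fvs)]
        in_polish = cfg.polish_fraction > 0 and gen > polish_gen
        if in_polish and gen == polish_gen + 1:
            # restart as a compact cloud around the incumbent best
            cloud = np.clip(
                best_x + rng.normal(0.0, cfg.polish_sigma, (P, ndim)) * span,
                lower,
                upper,
            )
            cloud[0] = best_x
            pops = [cloud]
            fvs = [np.array([objective_fn(x) for x in cloud])]
        for k in range(len(pops)):
            if in_polish:
                top = max(2, int(cfg.polish_top_fraction * pops[k].shape[0]))
                pops[k], polish_mu = _polish_step(
                    pops[k], fvs[k], best_x, lower, upper, top, cfg, polish_mu, rng
                )
            else:
                pops[k] = _evolve_once(
                    pops[k], fvs[k], lower, upper, span, mut_scale, cfg, rng
                )
            fvs[k] = np.array([objective_fn(x) for x in pops[k]])
        if len(pops) > 1 and gen % cfg.migrate_every == 0:
            for k in range(len(pops)):
                j = (k + 1) % len(pops)
                ib = int(np.argmin(fvs[k]))
                iw = int(np.argmax(fvs[j]))
                pops[j][iw] = pops[k][ib].copy()
                fvs[j][iw] = fvs[k][ib]
        gen_best_f = min(float(f.min()) for f in fvs)
        improved = gen_best_f < best_f * (1.0 - cfg.stagnation_rtol) or (
            best_f == float("inf") and math.isfinite(gen_best_f)
        )
        if gen_best_f < best_f:
            for p, f in zip(pops, fvs):
                i = int(np.argmin(f))
                if f[i] <= gen_best_f:
                    best_x, best_f = p[i].copy(), float(f[i])
        stagnant = 0 if improved else stagnant + 1
        history.append(best_f)
        if gen % 20 == 0 or stagnant == cfg.stagnation_generations:
            log.info("generation %d: best fitness %.6g", gen, best_f)
        if stagnant >= cfg.stagnation_generations:
            break

    population = np.vstack(pops)
    fitness = np.concatenate(fvs)
    return GAResult(best_x, best_f, population, fitness, gen, history)


def _tournament(pop, fit_vals, k, rng):
    idx = rng.integers(0, pop.shape[0], size=k)
    return int(idx[np.argmin(fit_vals[idx])])


def _blend(p1, p2, f1, f2, alpha, rng):
    """Mixed crossover: per-gene BLX-alpha (explores the parents' box) 40% of
    the time, whole-vector heuristic line crossover the other 60%.  The line
    operator orders the parents by fitness and samples children along the
    difference direction, extrapolating past the better parent -- that is
    what lets offspring track the strongly correlated valleys of the chi^2
    landscape instead of scattering across them."""
    if rng.random() < 0.4:
        lo = np.minimum(p1, p2)
        hi = np.maximum(p1, p2)
        width = hi - lo
        u1 = rng.random(p1.size)
        u2 = rng.random(p1.size)
        c1 = lo - alpha * width + u1 * (1.0 + 2.0 * alpha) * width
        c2 = lo - alpha * width + u2 * (1.0 + 2.0 * alpha) * width
    else:
        pb, pw = (p1, p2) if f1 <= f2 else (p2, p1)
        diff = pb - pw
        c1 = pb + rng.uniform(0.0, 0.8) * diff
        c2 = pw + rng.uniform(0.0, 1.8) * diff
    return c1, c2


# ---------------------------------------------------------------------------
# High-level fit driver
# ---------------------------------------------------------------------------


def fit(problem: FitProblem, cfg: FitConfig) -> FitResult:
    """Run the GA on a fit problem and assemble the full result.

    With ``cfg.n_starts > 1`` the GA is restarted from independent seeds
    derived from ``cfg.seed`` and the lowest-fitness solution wins -- the
    standard protocol for this optimizer class, where single runs can settle
    in secondary basins that a fresh start avoids.
    """
    ga = None
    for k in range(max(1, cfg.n_starts)):
        cfg_k = replace(cfg, seed=(cfg.seed + 9973 * k) % (2**31 - 1), n_starts=1)
        ga_k = ga_optimize(problem.objective, problem.lower, problem.upper, cfg_k)
        log.info("start %d/%d: best fitness %.6g", k + 1, cfg.n_starts, ga_k.fun)
        if ga is None or ga_k.fun < ga.fun:
            ga = ga_k
    sdp, lattices = problem.decode(ga.x)

    params = problem._values(ga.x)
    params["z_CholCH3"] = sdp.z_CholCH3
    params["z_CG"] = sdp.z_CG
    per_ds: list[float] = []
    for ds, lat, (s, b), M in zip(
        problem.datasets, lattices, problem.scales(ga.x), problem.model_curves(ga.x)
    ):
        params[f"scale@{ds.name}"] = s
        params[f"background@{ds.name}"] = b
        per_ds.append(reduced_chi_squared(ds.I, M, ds.sigma, n_free=0))
    chi2 = ga.fun - penalty(sdp, problem.scheme, problem.weights)

    d = eta = None
    for lat in lattices:
        if lat is not None:
            d, eta = lat.d, lat.eta
            break
    try:
        struct = derive_structure(sdp, problem.scheme, d=d, eta=eta)
    except ValueError as exc:
        log.warning("structure extraction failed: %s", exc)
        struct = None

    order = np.argsort(ga.fitness)
    n_keep = max(2, int(round(cfg.ensemble_fraction * ga.population.shape[0])))
    ensemble = [
        problem._values(ga.population[i])
        for i in order[:n_keep]
        if np.isfinite(ga.fitness[i])
    ]
    names = [s.name for s in problem.free]
    spread = {
        n: float(np.std([e[n] for e in ensemble])) if ensemble else float("nan")
        for n in names
    }
    return FitResult(
        params=params,
        chi2_red=float(chi2),
        chi2_red_per_dataset=per_ds,
        sdp=sdp,
        structure=struct,
        ensemble=ensemble,
        spread=spread,
        generations=ga.generations,
        seed=cfg.seed,
    )


def estimate_uncertainty(results: list[FitResult]) -> dict[str, dict[str, float]]:
    """Per-parameter spread over the best solutions of independent GA runs
    (different seeds): min, max, standard deviation and relative % spread."""
    if len(results) < 2:
        raise ValueError("need at least 2 independent runs for a spread estimate")
    names = sorted(set.intersection(*(set(r.params) for r in results)))
    out: dict[str, dict[str, float]] = {}
    for n in names:
        vals = np.array([r.params[n] for r in results], dtype=float)
        mean = float(vals.mean())
        out[n] = {
            "min": float(vals.min()),
            "max": float(vals.max()),
            "std": float(vals.std()),
            "rel_pct": float(100.0 * vals.std() / abs(mean)) if mean != 0 else float("nan"),
        }
    return out
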