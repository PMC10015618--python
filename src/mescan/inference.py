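"""Model fitting, likelihood grids and the parametric bootstrap.

Genome-wide fits maximize the composite log-likelihood of a bSFS tally
by bounded multi-start derivative-free search over (Ne_A, Ne_B, Ne_anc,
split time[, me]).  Window scans instead evaluate a precomputed grid of
probability tables (Cartesian product over per-parameter value lists
with the split time fixed) and record per-window argmax points.

The parametric bootstrap calibrates the DIV-vs-IM likelihood-ratio-like
statistic: replicates are simulated under the fitted strict-divergence
history, both models are refit, and the null distribution of
``dlnCL = lnCL(IM) - lnCL(DIV)`` is compared with the observed value.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import logging
from pathlib import Path

import numpy as np
import scipy.optimize

from .bsfs import BsfsTally, tally_shape
from .demography import BlockConfig, DemographyParams, Direction
from .likelihood import ModelSpec, bsfs_probabilities, composite_lnCL

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "OptimizationResult",
    "BootstrapResult",
    "optimize_model",
    "make_grid",
    "nearest_grid_value",
    "evaluate_grid",
    "parametric_bootstrap",
    "scan_grid_spec",
]

_FREE_PARAMS = {
    "DIV": ("ne_a", "ne_b", "ne_anc", "split_time"),
    "IM_into_A": ("ne_a", "ne_b", "ne_anc", "split_time", "me"),
    "IM_into_B": ("ne_a", "ne_b", "ne_anc", "split_time", "me"),
}


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Per-parameter value lists for a likelihood grid; split time fixed."""

    ne_a_values: tuple[float, ...]
    ne_b_values: tuple[float, ...]
    ne_anc_values: tuple[float, ...]
    me_values: tuple[float, ...]
    split_time: float

    def __post_init__(self) -> None:
        for name in ("ne_a_values", "ne_b_values", "ne_anc_values", "me_values"):
            vals = tuple(float(v) for v in getattr(self, name))
            if not vals:
                raise ValueError(f"{name} must be non-empty")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, vals)
        if self.split_time <= 0:
            raise ValueError("split_time must be positive")

    @property
    def n_points(self) -> int:
        return (
            len(self.ne_a_values)
            * len(self.ne_b_values)
            * len(self.ne_anc_values)
            * len(self.me_values)
        )


def scan_grid_spec(split_time: float) -> GridSpec:
    """The window-scan grid used by the analysis: 15 x 15 x 15 x 20 points.

    Linear spacing within the ranges Ne_A 20,000-720,000, Ne_B
    50,000-2,850,000, Ne_anc 50,000-2,010,000 and me 0-6.65e-7
    (inclusive endpoints), with the split time fixed to the genome-wide
    estimate.
    """
    return GridSpec(
        ne_a_values=tuple(np.linspace(20_000, 720_000, 15)),
        ne_b_values=tuple(np.linspace(50_000, 2_850_000, 15)),
        ne_anc_values=tuple(np.linspace(50_000, 2_010_000, 15)),
        me_values=tuple(np.linspace(0.0, 6.65e-7, 20)),
        split_time=split_time,
    )


def make_grid(spec: GridSpec) -> list[tuple[float, float, float, float]]:
    """Cartesian product of the value lists, lexicographic order.

    Points are ``(ne_a, ne_b, ne_anc, me)`` with ``ne_a`` varying
    slowest and ``me`` fastest; length is the product of list lengths.
    """
    return list(
        itertools.product(
            spec.ne_a_values, spec.ne_b_values, spec.ne_anc_values, spec.me_values
        )
    )


def nearest_grid_value(values, x: float) -> float:
    """Grid value minimizing |v - x|; exact ties resolve to the smaller."""
    values = list(values)
    if not values:
        raise ValueError("empty grid value list")
    return min(values, key=lambda v: (abs(v - x), v))


@dataclasses.dataclass
class OptimizationResult:
    model: str
    params: dict[str, float]
    lncl: float
    trace: list[dict]
    converged: bool

    def to_model_spec(self, mu: float = 2.9e-9, block_span: int = 64) -> ModelSpec:
        return ModelSpec(model=self.model, mu=mu, block_span=block_span, **self.params)


def _spec_from_vector(model, x, names, mu, block_span):
    kwargs = dict(zip(names, x))
    if model == "DIV":
        kwargs["me"] = 0.0
    return ModelSpec(model=model, mu=mu, block_span=block_span, **kwargs)


def optimize_model(
    tally: BsfsTally,
    model: str,
    bounds: dict[str, tuple[float, float]],
    n_starts: int = 5,
    seed: int = 1,
    mu: float = 2.9e-9,
    fixed: dict[str, float] | None = None,
    tol: float = 1e-3,
    init: dict[str, float] | None = None,
) -> OptimizationResult:
    """Multi-start bounded maximization of the composite likelihood.

    ``bounds`` maps each free parameter of ``model`` to (low, high);
    parameters in ``fixed`` are held constant (e.g. the split time during
    window-level fits).  Search runs in a unit hypercube with population
    sizes and times on a log scale (me stays linear so 0 is reachable);
    the parametrization is internal and does not affect the optimum.
    """
    if model not in _FREE_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    fixed = dict(fixed or {})
    names = [p for p in _FREE_PARAMS[model] if p not in fixed]
    for p in names:
        if p not in bounds:
            raise ValueError(f"missing bounds for parameter {p!r}")
    lo = np.array([bounds[p][0] for p in names])
    hi = np.array([bounds[p][1] for p in names])
    log_scale = np.array([p != "me" for p in names])
    if np.any(lo[log_scale] <= 0):
        raise ValueError("size/time bounds must be positive")

    def to_unit(x):
        u = np.empty_like(x, dtype=float)
        u[log_scale] = np.log(x[log_scale] / lo[log_scale]) / np.log(
            hi[log_scale] / lo[log_scale]
        )
        u[~log_scale] = (x[~log_scale] - lo[~log_scale]) / (
            hi[~log_scale] - lo[~log_scale]
        )
        return u

    def from_unit(u):
        u = np.clip(u, 0.0, 1.0)
        x = np.empty_like(u)
        x[log_scale] = lo[log_scale] * np.exp(
            u[log_scale] * np.log(hi[log_scale] / lo[log_scale])
        )
        x[~log_scale] = lo[~log_scale] + u[~log_scale] * (
            hi[~log_scale] - lo[~log_scale]
        )
        return x

    def objective(u):
        x = from_unit(u)
        kwargs = dict(zip(names, x))
        kwargs.update(fixed)
        if model == "DIV":
            kwargs["me"] = 0.0
        try:
            spec = ModelSpec(
                model=model, mu=mu, block_span=tally.block_span, **kwargs
            )
            table = bsfs_probabilities(spec, kmax=tally.kmax)
        except (ArithmeticError, ValueError) as err:
            logger.warning("kernel failure at %s: %s", kwargs, err)
            return 1e12
        lncl = composite_lnCL(tally, table)
        return -lncl if np.isfinite(lncl) else 1e12

    rng = np.random.default_rng(seed)
    starts = []
    if init is not None:
        # warm start (e.g. the DIV optimum when fitting the nested IM model)
        x0 = np.array([max(bounds[p][0], min(bounds[p][1], init[p])) for p in names])
        starts.append(np.clip(to_unit(x0), 0.0, 1.0))
    starts.append(np.full(len(names), 0.5))
    starts += [rng.random(len(names)) for _ in range(n_starts - 1)]
    trace = []
    best = None
    for s, u0 in enumerate(starts):
        res = scipy.optimize.minimize(
            objective,
            u0,
            method="Nelder-Mead",
            bounds=[(0.0, 1.0)] * len(names),
            options={"fatol": tol, "xatol": 1e-4, "maxfev": 4000},
        )
        entry = {
            "start": s,
            "x0": from_unit(u0).tolist(),
            "lncl": -float(res.fun),
            "n_eval": int(res.nfev),
            "converged": bool(res.success),
        }
        trace.append(entry)
        if res.fun < 1e11 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"all {n_starts} optimizer starts failed: {trace}")
    x = from_unit(best.x)
    params = dict(zip(names, x))
    params.update(fixed)
    if model != "DIV":
        params.setdefault("me", 0.0)
    return OptimizationResult(
        model=model,
        params={k: float(v) for k, v in params.items()},
        lncl=-float(best.fun),
        trace=trace,
        converged=any(t["converged"] for t in trace),
    )


# ---------------------------------------------------------------------------
# grid evaluation
# ---------------------------------------------------------------------------


def _grid_key(spec: GridSpec, kmax, mu, block_span) -> str:
    payload = repr((spec, tuple(kmax), mu, block_span)).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def evaluate_grid(
    spec: GridSpec,
    kmax=(2, 2, 2, 2),
    mu: float = 2.9e-9,
    block_span: int = 64,
    model: str = "IM_into_A",
    cache_dir: str | Path | None = None,
) -> tuple[list, np.ndarray]:
    """Probability tables for every grid point.

    Returns ``(points, probs)`` where ``points`` is the ordered list
    from :func:`make_grid` and ``probs`` has shape
    ``(n_points, *tally_shape(kmax))``.  With ``cache_dir`` set, tables
    are cached to disk keyed by the grid definition and reruns are
    resumable (already-computed points are loaded, not recomputed).
    Per-point kernel failures are isolated: the point's table is NaN and
    the failure logged; evaluation continues.
    """
    points = make_grid(spec)
    kmax = tuple(kmax)
    shape = tally_shape(kmax)
    n = len(points)
    probs = np.full((n,) + shape, np.nan)
    done = np.zeros(n, dtype=bool)
    cache_path = None
    if cache_dir is not None:
        cache_path = Path(cache_dir) / f"grid_{_grid_key(spec, kmax, mu, block_span)}_{model}.npz"
        if cache_path.exists():
            with np.load(cache_path) as npz:
                probs, done = npz["probs"], npz["done"]
    for i, (ne_a, ne_b, ne_anc, me) in enumerate(points):
        if done[i]:
            continue
        point_model = model if me > 0 else ("DIV" if model == "DIV" else model)
        try:
            mspec = ModelSpec(
                model=point_model,
                ne_a=ne_a,
                ne_b=ne_b,
                ne_anc=ne_anc,
                split_time=spec.split_time,
                me=me,
                mu=mu,
                block_span=block_span,
            )
            probs[i] = bsfs_probabilities(mspec, kmax=kmax).probs
            done[i] = True
        except (ArithmeticError, ValueError) as err:
            logger.error("grid point %d %s failed: %s", i, points[i], err)
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(cache_path, probs=probs, done=done)
    return points, probs


# ---------------------------------------------------------------------------
# parametric bootstrap
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class BootstrapResult:
    replicate: int
    d_lncl: float  # lnCL(IM) - lnCL(DIV) at the replicate's optima
    lncl_div: float
    lncl_im: float
    seed: int


def parametric_bootstrap(
    div_mcl: OptimizationResult,
    n_reps: int,
    config: BlockConfig,
    seed: int = 1,
    n_blocks: int = 10_000,
    im_model: str = "IM_into_A",
    bounds: dict | None = None,
    n_starts: int = 2,
    linked: bool = True,
    mu: float = 2.9e-9,
) -> list[BootstrapResult]:
    """Null distribution of dlnCL under the fitted DIV history.

    Each replicate simulates a bSFS under the DIV MCL parameters (with
    inter-block recombination at ``config.recomb_rate`` when ``linked``)
    and refits both the DIV and IM models.  Replicate failures are
    logged and excluded.
    """
    from .simulate import simulate_block_tallies

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    p = div_mcl.params
    truth = DemographyParams(
        ne_a=p["ne_a"],
        ne_b=p["ne_b"],
        ne_anc=p["ne_anc"],
        split_time=p["split_time"],
        me=0.0,
        direction=Direction.none,
        mu=mu,
    )
    if bounds is None:
        bounds = {
            "ne_a": (p["ne_a"] / 10, p["ne_a"] * 10),
            "ne_b": (p["ne_b"] / 10, p["ne_b"] * 10),
            "ne_anc": (p["ne_anc"] / 10, p["ne_anc"] * 10),
            "split_time": (p["split_time"] / 10, p["split_time"] * 10),
            "me": (0.0, 1e-5),
        }
    rng = np.random.default_rng(seed)
    results = []
    for rep in range(n_reps):
        rep_seed = int(rng.integers(1, 2**31 - 1))
        try:
            tally = simulate_block_tallies(
                truth, config, n_blocks=n_blocks, seed=rep_seed, linked=linked
            )
            fit_div = optimize_model(
                tally, "DIV", bounds, n_starts=n_starts, seed=rep_seed
            )
            fit_im = optimize_model(
                tally,
                im_model,
                bounds,
                n_starts=n_starts,
                seed=rep_seed + 1,
                init={**fit_div.params, "me": 0.0},
            )
        except (RuntimeError, ArithmeticError) as err:
            logger.error("bootstrap replicate %d failed: %s", rep, err)
            continue
        results.append(
            BootstrapResult(
                replicate=rep,
                d_lncl=fit_im.lncl - fit_div.lncl,
                lncl_div=fit_div.lncl,
                lncl_im=fit_im.lncl,
                seed=rep_seed,
            )
        )
    return results
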