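"""Age-structured model of a synchronized *Caulobacter crescentus* population.

*C. crescentus* divides asymmetrically: each division produces a motile
swarmer daughter that starts its cycle at internal age 0 and a sessile
stalked daughter that skips the G1/swarmer phase and starts at internal age
``t_S`` (by default a quarter of the mean cycle length ``t_C``).  A culture
synchronized by density-gradient centrifugation starts as swarmer cells
whose internal ages are spread uniformly over the harvest window, and the
cycle length of each cell is an independent normal draw around ``t_C``.
Both effects blur the mapping between elapsed experiment time and cell-cycle
stage, which is the whole reason population-average measurements need to be
deconvolved.

This module simulates that population forward in time and summarizes it as
an age-composition matrix ``F`` with entries ``f[m, i]``: the fraction of
cells at measurement time ``m`` whose internal age falls in the ``i``-th
age interval.  Rows of ``F`` are probability vectors.  The module also
provides the Euler–Lotka relation for the two-daughter division rule, which
links the exponential (Malthusian) growth rate of the culture to the cycle
length and is used to infer ``t_C`` from optical-density growth curves.

Division events inside a time step are resolved at their exact division
instant, with the residual step time applied to both daughters (recursively
if a daughter divides again within the same step), so the simulation is
step-size independent and equivalent to an event-driven one.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import ParameterError

__all__ = [
    "PopulationModelParams",
    "CellPopulation",
    "AgeCompositionMatrix",
    "draw_cycle_length",
    "init_synchronized_population",
    "advance",
    "snapshot_age_fractions",
    "build_composition_matrix",
    "malthusian_rate",
    "infer_cycle_length_from_growth",
]

#: Maximum number of rejection rounds when truncating the cycle-length
#: distribution.  With valid parameters (offset fraction < 1) acceptance per
#: round is at least 50%, so reaching the cap signals a pathological setup.
_MAX_REJECTION_ROUNDS = 100

_DEFAULT_MEASUREMENT_TIMES = tuple(float(t) for t in range(0, 181, 20))


@dataclasses.dataclass(frozen=True)
class PopulationModelParams:
    """Constants of the synchronized-population model.

    Parameters
    ----------
    mean_cycle_length
        Mean cell-cycle length ``t_C`` in minutes (default 137, from
        optical-density growth curves of the measured cultures).
    stalked_offset_fraction
        Internal age of a newborn stalked daughter as a fraction of the
        cycle length; ``t_S = stalked_offset_fraction * mean_cycle_length``
        (default 0.25, i.e. G1 is a quarter of the cycle).
    cycle_length_cv
        Coefficient of variation of the per-cell cycle length (default
        0.35; cycle lengths are normal, truncated below at ``t_S``).
    harvest_age_max
        Upper edge (minutes) of the uniform internal-age window of harvested
        swarmer cells.  ``None`` (default) means the full swarmer phase
        ``[0, t_S]``.
    interval_width
        Width of one age interval in minutes (default 20).
    n_intervals
        Number of age intervals; together with ``interval_width`` they must
        cover the mean cycle length (default 7, covering 0–140 min).
    measurement_times
        Strictly increasing measurement schedule in minutes after synchrony
        release (default 0–180 by 20).
    n_cells
        Number of simulated cells at synchrony release.
    seed
        Seed of the simulation's random stream; a fixed seed makes the
        composition matrix bit-reproducible.
    stalked_offset_mode
        ``"absolute"`` (default): every stalked daughter is born at the
        population-level ``t_S`` in minutes.  ``"proportional"``: a stalked
        daughter is born at ``stalked_offset_fraction`` of its *own* drawn
        cycle length.
    """

    mean_cycle_length: float = 137.0
    stalked_offset_fraction: float = 0.25
    cycle_length_cv: float = 0.35
    harvest_age_max: float | None = None
    interval_width: float = 20.0
    n_intervals: int = 7
    measurement_times: tuple[float, ...] = _DEFAULT_MEASUREMENT_TIMES
    n_cells: int = 100_000
    seed: int = 0
    stalked_offset_mode: str = "absolute"

    def __post_init__(self) -> None:
        if self.mean_cycle_length <= 0:
            raise ParameterError("mean_cycle_length must be positive")
        if not 0.0 <= self.stalked_offset_fraction < 1.0:
            raise ParameterError("stalked_offset_fraction must be in [0, 1)")
        if self.cycle_length_cv < 0:
            raise ParameterError("cycle_length_cv must be non-negative")
        if self.interval_width <= 0:
            raise ParameterError("interval_width must be positive")
        if self.n_intervals < 1:
            raise ParameterError("n_intervals must be at least 1")
        if self.n_intervals * self.interval_width < self.mean_cycle_length:
            raise ParameterError(
                "age intervals must cover the mean cycle length: "
                f"{self.n_intervals} x {self.interval_width} min < "
                f"{self.mean_cycle_length} min"
            )
        times = tuple(float(t) for t in self.measurement_times)
        if len(times) == 0:
            raise ParameterError("measurement_times must not be empty")
        if times[0] < 0 or any(b <= a for a, b in zip(times, times[1:])):
            raise ParameterError(
                "measurement_times must be non-negative and strictly increasing"
            )
        object.__setattr__(self, "measurement_times", times)
        if self.harvest_age_max is None:
            object.__setattr__(self, "harvest_age_max", self.stalked_offset)
        if self.harvest_age_max < 0:
            raise ParameterError("harvest_age_max must be non-negative")
        if self.harvest_age_max >= self.mean_cycle_length:
            raise ParameterError(
                "harvest_age_max must be smaller than the mean cycle length"
            )
        if self.n_cells < 1:
            raise ParameterError("n_cells must be at least 1")
        if self.stalked_offset_mode not in ("absolute", "proportional"):
            raise ParameterError(
                "stalked_offset_mode must be 'absolute' or 'proportional'"
            )

    @property
    def stalked_offset(self) -> float:
        """Internal age ``t_S`` (minutes) of a newborn stalked daughter."""
        return self.stalked_offset_fraction * self.mean_cycle_length

    @property
    def interval_edges(self) -> np.ndarray:
        """Age-interval edges ``[0, w, 2w, ..., n*w]`` in minutes."""
        return np.arange(self.n_intervals + 1, dtype=float) * self.interval_width

    def rng(self) -> np.random.Generator:
        """A fresh generator seeded with :attr:`seed`."""
        return np.random.default_rng(self.seed)


@dataclasses.dataclass
class CellPopulation:
    """A simulated population: per-cell internal age and division threshold.

    ``internal_ages[k] < division_thresholds[k]`` for every cell; a cell
    divides the instant its internal age reaches its threshold (that cell's
    own drawn total cycle length).
    """

    internal_ages: np.ndarray
    division_thresholds: np.ndarray
    elapsed_real_time: float = 0.0

    def __post_init__(self) -> None:
        self.internal_ages = np.asarray(self.internal_ages, dtype=float)
        self.division_thresholds = np.asarray(self.division_thresholds, dtype=float)
        if self.internal_ages.shape != self.division_thresholds.shape:
            raise ParameterError("ages and thresholds must have equal length")
        if np.any(self.internal_ages < 0):
            raise ParameterError("internal ages must be non-negative")
        if np.any(self.internal_ages >= self.division_thresholds):
            raise ParameterError("every internal age must be below its threshold")

    def __len__(self) -> int:
        return int(self.internal_ages.size)


def _draw_cycle_lengths(
    params: PopulationModelParams, rng: np.random.Generator, n: int
) -> np.ndarray:
    """``n`` cycle lengths from Normal(t_C, cv*t_C) truncated below at t_S.

    Truncation is by rejection; it removes <2% of the mass at the default
    cv of 0.35 and guarantees that a newborn stalked daughter (age t_S)
    never divides instantaneously.
    """
    t_c = params.mean_cycle_length
    sd = params.cycle_length_cv * t_c
    t_s = params.stalked_offset
    if sd == 0.0:
        return np.full(n, t_c, dtype=float)
    out = np.empty(n, dtype=float)
    filled = 0
    for _ in range(_MAX_REJECTION_ROUNDS):
        if filled == n:
            return out
        draws = rng.normal(t_c, sd, size=n - filled)
        accepted = draws[draws > t_s]
        out[filled : filled + accepted.size] = accepted
        filled += accepted.size
    raise ParameterError(
        "cycle-length rejection sampling failed to converge "
        f"in {_MAX_REJECTION_ROUNDS} rounds (pathological cv?)"
    )


def draw_cycle_length(
    params: PopulationModelParams, rng: np.random.Generator
) -> float:
    """One cycle length (minutes), normal around t_C, truncated above t_S."""
    return float(_draw_cycle_lengths(params, rng, 1)[0])


def init_synchronized_population(
    params: PopulationModelParams, rng: np.random.Generator | None = None
) -> CellPopulation:
    """Population at synchrony release: swarmer cells of uniform random age.

    Internal ages are uniform on ``[0, harvest_age_max]`` — the residual
    heterogeneity of density-gradient harvesting — and each cell gets its
    own drawn division threshold.
    """
    if rng is None:
        rng = params.rng()
    n = params.n_cells
    if params.harvest_age_max == 0.0:
        ages = np.zeros(n, dtype=float)
    else:
        ages = rng.uniform(0.0, params.harvest_age_max, size=n)
    thresholds = _draw_cycle_lengths(params, rng, n)
    return CellPopulation(ages, thresholds, elapsed_real_time=0.0)


def advance(
    population: CellPopulation,
    dt: float,
    params: PopulationModelParams,
    rng: np.random.Generator,
) -> CellPopulation:
    """Advance the population by ``dt`` minutes, dividing cells as needed.

    A cell whose age reaches its threshold within the step is replaced at
    its exact division instant by a swarmer daughter (age 0) and a stalked
    daughter (age ``t_S``), each with a freshly drawn threshold; the
    remaining step time is then applied to the daughters, recursively, so
    the result does not depend on the step size.  Population size never
    decreases.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    ages = population.internal_ages
    thresholds = population.division_thresholds
    remaining = np.full(ages.shape, float(dt))

    done_ages: list[np.ndarray] = []
    done_thresholds: list[np.ndarray] = []
    t_s = params.stalked_offset
    while ages.size:
        survives = ages + remaining < thresholds
        done_ages.append(ages[survives] + remaining[survives])
        done_thresholds.append(thresholds[survives])

        dividing = ~survives
        residual = remaining[dividing] - (thresholds[dividing] - ages[dividing])
        k = residual.size
        if k == 0:
            break
        new_thresholds = _draw_cycle_lengths(params, rng, 2 * k)
        if params.stalked_offset_mode == "proportional":
            stalked_ages = params.stalked_offset_fraction * new_thresholds[k:]
        else:
            stalked_ages = np.full(k, t_s)
        ages = np.concatenate([np.zeros(k), stalked_ages])
        thresholds = new_thresholds
        remaining = np.concatenate([residual, residual])

    return CellPopulation(
        np.concatenate(done_ages),
        np.concatenate(done_thresholds),
        elapsed_real_time=population.elapsed_real_time + dt,
    )


def snapshot_age_fractions(
    population: CellPopulation, interval_edges: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Per-interval fractions of cells by internal age.

    Intervals are half-open ``[edge_k, edge_k+1)``; ages at or beyond the
    last edge are clamped into the last interval so the fractions always
    partition the population (slow cells stay accounted for).
    """
    edges = np.asarray(interval_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2:
        raise ParameterError("interval_edges must be a 1-d array of >=2 edges")
    if edges[0] != 0.0 or np.any(np.diff(edges) <= 0):
        raise ParameterError("interval_edges must start at 0 and strictly increase")
    if len(population) == 0:
        raise ParameterError("cannot take age fractions of an empty population")
    idx = np.searchsorted(edges, population.internal_ages, side="right") - 1
    idx = np.clip(idx, 0, edges.size - 2)
    counts = np.bincount(idx, minlength=edges.size - 1)
    return counts / len(population)


@dataclasses.dataclass
class AgeCompositionMatrix:
    """The matrix ``f[m, i]``: age-interval fractions per measurement time.

    Rows correspond to measurement times (minutes after synchrony release),
    columns to age intervals; every row is a probability vector.
    """

    values: np.ndarray
    row_times: np.ndarray
    interval_edges: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_times = np.asarray(self.row_times, dtype=float)
        self.interval_edges = np.asarray(self.interval_edges, dtype=float)
        m, n = self.values.shape
        if self.row_times.size != m:
            raise ParameterError("row_times length must match the row count")
        if self.interval_edges.size != n + 1:
            raise ParameterError("interval_edges must have n_intervals + 1 entries")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ParameterError("composition entries must lie in [0, 1]")
        if np.any(np.abs(self.values.sum(axis=1) - 1.0) > 1e-9):
            raise ParameterError("every composition row must sum to 1")

    @property
    def n_intervals(self) -> int:
        return int(self.values.shape[1])

    def interval_labels(self) -> list[str]:
        e = self.interval_edges
        return [f"age_{e[i]:g}_{e[i + 1]:g}" for i in range(self.n_intervals)]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.interval_labels())
        df.insert(0, "time_min", self.row_times)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AgeCompositionMatrix":
        df = pd.read_csv(path)
        if "time_min" not in df.columns:
            raise ParameterError(f"{path}: missing 'time_min' column")
        edges: list[float] = []
        for col in df.columns[1:]:
            lo, hi = col.removeprefix("age_").split("_")
            if not edges:
                edges.append(float(lo))
            edges.append(float(hi))
        return cls(
            values=df.iloc[:, 1:].to_numpy(float),
            row_times=df["time_min"].to_numpy(float),
            interval_edges=np.asarray(edges),
        )


def build_composition_matrix(
    params: PopulationModelParams, rng: np.random.Generator | None = None
) -> AgeCompositionMatrix:
    """Simulate one synchronized population and record its age composition.

    The population is initialized at synchrony release and advanced to each
    measurement time in turn; at each one the age-interval fractions are
    recorded as one matrix row.  Deterministic given ``params.seed`` (or an
    explicitly passed generator).
    """
    if rng is None:
        rng = params.rng()
    edges = params.interval_edges
    population = init_synchronized_population(params, rng)
    rows = []
    now = 0.0
    for t in params.measurement_times:
        if t > now:
            population = advance(population, t - now, params, rng)
            now = t
        rows.append(snapshot_age_fractions(population, edges))
    return AgeCompositionMatrix(
        values=np.vstack(rows),
        row_times=np.asarray(params.measurement_times, dtype=float),
        interval_edges=edges,
    )


def malthusian_rate(t_c: float, t_s: float) -> float:
    """Exponential growth rate λ of the asymmetric-division population.

    For a deterministic cycle in which each division yields one daughter
    restarting at age 0 and one at age ``t_s``, λ solves the Euler–Lotka
    characteristic equation

        1 = exp(-λ t_c) + exp(-λ (t_c - t_s)).

    ``t_s = 0`` reduces to symmetric division, λ = ln 2 / t_c.
    """
    if not 0.0 <= t_s < t_c:
        raise ParameterError("need 0 <= t_s < t_c")
    if t_s == 0.0:
        return math.log(2.0) / t_c

    def characteristic(lam: float) -> float:
        return math.exp(-lam * t_c) + math.exp(-lam * (t_c - t_s)) - 1.0

    # characteristic(0+) = 1 > 0 and is strictly decreasing; at
    # lam = ln2/(t_c - t_s) it equals exp(-ln2 * t_c/(t_c - t_s)) - 1/2 < 0.
    upper = math.log(2.0) / (t_c - t_s)
    return float(brentq(characteristic, 1e-15, upper, xtol=1e-14, rtol=8.9e-16))


def infer_cycle_length_from_growth(rate: float, offset_fraction: float) -> float:
    """Cycle length t_C whose Euler–Lotka growth rate equals ``rate``.

    With the stalked offset a fixed fraction f of the cycle, the product
    λ·t_C depends only on f (substitute x = λ·t_C in the characteristic
    equation), so the inverse is exact: t_C = x(f) / rate.
    """
    if rate <= 0:
        raise ParameterError("growth rate must be positive")
    if not 0.0 <= offset_fraction < 1.0:
        raise ParameterError("offset_fraction must be in [0, 1)")
    x = malthusian_rate(1.0, offset_fraction)
    return x / rate
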