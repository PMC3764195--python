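"""Deconvolution of population-average c-di-GMP into stage concentrations.

The measured quantity at each timepoint ``m`` of a synchronized culture is a
population average: each cell contributes the concentration of its current
cell-cycle stage, weighted by the fraction of the population in that stage,

    p_m = sum_i f[m, i] * c_i,

where ``f`` is the age-composition matrix from
:mod:`cdgcycle.population_model` and ``c_i`` is the average intracellular
c-di-GMP concentration (nM) of cells in age interval ``i``.  With more
timepoints than intervals this is an overdetermined linear system; solving
it recovers the stage profile ``c`` from the blurred population series.
Concentrations are physical quantities, so the default solver is
non-negative least squares; plain least squares is available behind a flag.

The recovered profile, read as a function of internal age, is the modeled
single-cell trajectory: a swarmer daughter traverses it from age 0, a
stalked daughter enters the same curve at age ``t_S`` (stage concentrations
are assumed independent of a cell's origin).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .exceptions import AlignmentError, ConditioningError, ParameterError, ParseError
from .population_model import AgeCompositionMatrix

__all__ = [
    "PopulationMeasurementSeries",
    "StageConcentrationProfile",
    "DeconvolutionResult",
    "SingleCellTrace",
    "RecoveryReport",
    "forward_average",
    "solve_stage_concentrations",
    "bootstrap_stage_concentrations",
    "single_cell_trace",
    "recovery_report",
]


@dataclasses.dataclass
class PopulationMeasurementSeries:
    """Population-average c-di-GMP (nM) per timepoint, optionally replicated.

    ``values`` has shape ``(n_replicates, n_timepoints)``; a plain
    1-d series is promoted to a single replicate.
    """

    timepoints: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.timepoints.size:
            raise ParameterError("values must have one column per timepoint")
        if np.any(self.values < 0):
            raise ParameterError("concentrations must be non-negative")

    @property
    def replicate_count(self) -> int:
        return int(self.values.shape[0])

    def mean_values(self) -> np.ndarray:
        """Per-timepoint mean over replicates (nM)."""
        return self.values.mean(axis=0)

    def to_csv(self, path) -> None:
        rows = {
            "time_min": np.tile(self.timepoints, self.replicate_count),
            "replicate": np.repeat(
                np.arange(1, self.replicate_count + 1), self.timepoints.size
            ),
            "cdiGMP_nM": self.values.ravel(),
        }
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PopulationMeasurementSeries":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # malformed file
            raise ParseError(f"{path}: cannot parse measurement CSV: {exc}") from exc
        required = ("time_min", "replicate", "cdiGMP_nM")
        for col in required:
            if col not in df.columns:
                raise ParseError(f"{path}: missing required column '{col}'")
        for col in required:
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            if bad.any():
                row = int(df.index[bad][0]) + 2  # 1-based, after header
                raise ParseError(
                    f"{path}: non-numeric value in column '{col}', row {row}"
                )
        timepoints = np.sort(df["time_min"].unique().astype(float))
        replicates = np.sort(df["replicate"].unique())
        values = np.empty((replicates.size, timepoints.size), dtype=float)
        pivot = df.pivot_table(
            index="replicate", columns="time_min", values="cdiGMP_nM"
        )
        if pivot.isna().any().any():
            raise ParseError(f"{path}: incomplete replicate/timepoint grid")
        values[:] = pivot.loc[replicates, timepoints].to_numpy(float)
        return cls(timepoints=timepoints, values=values)


@dataclasses.dataclass
class StageConcentrationProfile:
    """c-di-GMP concentration (nM) per age interval."""

    concentrations: np.ndarray
    interval_edges: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.interval_edges = np.asarray(self.interval_edges, dtype=float)
        if self.concentrations.size != self.interval_edges.size - 1:
            raise ParameterError(
                "profile length must equal the number of age intervals"
            )

    @property
    def n_intervals(self) -> int:
        return int(self.concentrations.size)

    @property
    def peak_interval(self) -> int:
        """0-based index of the interval with the highest concentration."""
        return int(np.argmax(self.concentrations))

    def to_json(self, path) -> None:
        payload = {
            "interval_edges_min": self.interval_edges.tolist(),
            "concentrations_nM": self.concentrations.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "StageConcentrationProfile":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            concentrations=np.asarray(payload["concentrations_nM"], dtype=float),
            interval_edges=np.asarray(payload["interval_edges_min"], dtype=float),
        )


@dataclasses.dataclass
class DeconvolutionResult:
    """Stage profile plus fit diagnostics."""

    profile: StageConcentrationProfile
    residual_norm: float
    fitted_values: np.ndarray
    condition_number: float
    nonnegative: bool


def forward_average(
    matrix: AgeCompositionMatrix,
    profile: StageConcentrationProfile | np.ndarray,
) -> PopulationMeasurementSeries:
    """Population averages ``p_m = sum_i f[m,i] c_i`` implied by a profile."""
    c = (
        profile.concentrations
        if isinstance(profile, StageConcentrationProfile)
        else np.asarray(profile, dtype=float)
    )
    if c.size != matrix.n_intervals:
        raise ParameterError(
            f"profile has {c.size} entries but matrix has "
            f"{matrix.n_intervals} intervals"
        )
    return PopulationMeasurementSeries(
        timepoints=matrix.row_times, values=matrix.values @ c
    )


def _check_alignment(
    matrix: AgeCompositionMatrix, series: PopulationMeasurementSeries
) -> None:
    if series.timepoints.size != matrix.row_times.size or not np.allclose(
        series.timepoints, matrix.row_times
    ):
        raise AlignmentError(
            "measurement timepoints "
            f"{series.timepoints.tolist()} do not match composition rows "
            f"{matrix.row_times.tolist()}"
        )


def solve_stage_concentrations(
    matrix: AgeCompositionMatrix,
    series: PopulationMeasurementSeries,
    nonnegative: bool = True,
    allow_rank_deficient: bool = False,
) -> DeconvolutionResult:
    """Least-squares stage concentrations from a population series.

    Replicates are averaged per timepoint before solving (the measured
    quantity is a population average).  With ``nonnegative`` (the default)
    the minimizer of ``||F c - p||`` subject to ``c >= 0`` is returned;
    otherwise ordinary least squares.  Deterministic.

    Raises :class:`ConditioningError` for a rank-deficient system under
    ordinary least squares unless ``allow_rank_deficient`` is set; the
    singular-value ratio of ``F`` is always reported.
    """
    _check_alignment(matrix, series)
    A = matrix.values
    m, n = A.shape
    if m < n:
        raise ParameterError(
            f"underdetermined system: {m} timepoints < {n} intervals"
        )
    b = series.mean_values()

    singular = np.linalg.svd(A, compute_uv=False)
    tol = singular[0] * max(A.shape) * np.finfo(float).eps
    rank_deficient = singular[-1] <= tol
    condition = float("inf") if rank_deficient else float(singular[0] / singular[-1])
    if rank_deficient and not nonnegative and not allow_rank_deficient:
        raise ConditioningError(
            "composition matrix is rank deficient; pass "
            "allow_rank_deficient=True to solve anyway"
        )

    if nonnegative:
        c, _ = nnls(A, b)
    else:
        c, *_ = np.linalg.lstsq(A, b, rcond=None)
    fitted = A @ c
    return DeconvolutionResult(
        profile=StageConcentrationProfile(c, matrix.interval_edges),
        residual_norm=float(np.linalg.norm(fitted - b)),
        fitted_values=fitted,
        condition_number=condition,
        nonnegative=nonnegative,
    )


def bootstrap_stage_concentrations(
    matrix: AgeCompositionMatrix,
    series: PopulationMeasurementSeries,
    n_boot: int = 200,
    nonnegative: bool = True,
    seed: int | None = None,
) -> np.ndarray:
    """Bootstrap-over-replicates profiles, shape ``(n_boot, n_intervals)``.

    Resamples replicate series with replacement and re-solves; an
    uncertainty add-on with no counterpart in the plain population-average
    fit.  Requires at least two replicates.
    """
    if series.replicate_count < 2:
        raise ParameterError("bootstrap requires at least 2 replicates")
    if n_boot < 1:
        raise ParameterError("n_boot must be at least 1")
    rng = np.random.default_rng(seed)
    r = series.replicate_count
    out = np.empty((n_boot, matrix.n_intervals), dtype=float)
    for k in range(n_boot):
        pick = rng.integers(0, r, size=r)
        resampled = PopulationMeasurementSeries(
            timepoints=series.timepoints, values=series.values[pick]
        )
        out[k] = solve_stage_concentrations(
            matrix, resampled, nonnegative=nonnegative
        ).profile.concentrations
    return out


@dataclasses.dataclass
class SingleCellTrace:
    """Piecewise-constant c-di-GMP trajectory of one cell over its cycle.

    Maps internal age ``a`` in ``[0, cycle_length]`` to the concentration of
    the age interval containing ``a``.  This is the swarmer-progeny
    trajectory; a stalked daughter enters the same curve at
    ``stalked_birth_age``.
    """

    concentrations: np.ndarray
    interval_edges: np.ndarray
    cycle_length: float
    stalked_birth_age: float | None = None

    def __call__(self, age):
        a = np.clip(np.asarray(age, dtype=float), 0.0, self.cycle_length)
        idx = np.searchsorted(self.interval_edges, a, side="right") - 1
        idx = np.clip(idx, 0, self.concentrations.size - 1)
        out = self.concentrations[idx]
        return float(out) if np.isscalar(age) else out

    def time_average(self) -> float:
        """Mean of the trace over ``[0, cycle_length]`` (nM).

        The interval-width-weighted mean of the stage profile, with the
        last interval truncated at the cycle length.
        """
        upper = np.minimum(self.interval_edges[1:], self.cycle_length)
        lower = np.minimum(self.interval_edges[:-1], self.cycle_length)
        widths = upper - lower
        return float(np.sum(widths * self.concentrations) / self.cycle_length)

    def to_csv(self, path) -> None:
        """Breakpoint table (age_min, cdiGMP_nM) suitable for step plots."""
        ages, values = [], []
        for i, c in enumerate(self.concentrations):
            lo = self.interval_edges[i]
            hi = min(self.interval_edges[i + 1], self.cycle_length)
            if lo >= self.cycle_length:
                break
            ages.extend([lo, hi])
            values.extend([c, c])
        pd.DataFrame({"age_min": ages, "cdiGMP_nM": values}).to_csv(
            path, index=False
        )


def single_cell_trace(
    result: DeconvolutionResult | StageConcentrationProfile,
    t_c: float,
    t_s: float | None = None,
) -> SingleCellTrace:
    """The single-cell trajectory implied by a stage profile."""
    profile = result.profile if isinstance(result, DeconvolutionResult) else result
    if t_c <= 0:
        raise ParameterError("cycle length must be positive")
    if t_c > profile.interval_edges[-1]:
        raise ParameterError(
            "cycle length extends beyond the last age-interval edge"
        )
    return SingleCellTrace(
        concentrations=profile.concentrations,
        interval_edges=profile.interval_edges,
        cycle_length=float(t_c),
        stalked_birth_age=None if t_s is None else float(t_s),
    )


@dataclasses.dataclass
class RecoveryReport:
    """Error metrics of an estimated profile against a known truth."""

    rmse: float
    max_relative_error: float
    peak_interval_match: bool
    truth_peak_interval: int
    estimate_peak_interval: int


def recovery_report(
    truth: StageConcentrationProfile, estimate: StageConcentrationProfile
) -> RecoveryReport:
    """RMSE (nM), max relative error and peak-interval agreement.

    The relative error is taken over intervals with nonzero truth.
    """
    t = truth.concentrations
    e = estimate.concentrations
    if t.size != e.size:
        raise ParameterError("truth and estimate must have equal length")
    rmse = float(np.sqrt(np.mean((e - t) ** 2)))
    nonzero = t != 0
    max_rel = (
        float(np.max(np.abs(e[nonzero] - t[nonzero]) / t[nonzero]))
        if nonzero.any()
        else float("nan")
    )
    return RecoveryReport(
        rmse=rmse,
        max_relative_error=max_rel,
        peak_interval_match=truth.peak_interval == estimate.peak_interval,
        truth_peak_interval=truth.peak_interval,
        estimate_peak_interval=estimate.peak_interval,
    )
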