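"""Model objects for cell-cycle-coupled bursty gene expression.

A cell progresses through ``n`` sequential stages with exponential
sojourns (rates ``lambda_i``); protein is made in instantaneous bursts
arriving at a stage-dependent Poisson rate ``k_i``; at division the copy
number is randomly partitioned with conditional mean ``x/2`` and
conditional variance ``alpha * x / 4``.

All rates are per hour; stage indices are 1-based in documentation and
error messages (matching the conventional ``C_1..C_n`` labelling) but
stored as 0-based arrays.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import UnsupportedModelError, ValidationError

__all__ = [
    "CellCycleSpec",
    "RegulationProfile",
    "BurstModel",
    "PartitionModel",
    "ModelSpec",
    "make_cell_cycle",
    "make_strategy",
    "calibrate_rate",
    "STRATEGY_NAMES",
]

STRATEGY_NAMES = (
    "constant",
    "duplication_midpoint",
    "start_only",
    "end_only",
    "midpoint_only",
    "step",
)


def _as_float_tuple(values: Sequence[float], name: str) -> tuple[float, ...]:
    try:
        out = tuple(float(v) for v in values)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{name}: expected a sequence of numbers") from exc
    if not all(math.isfinite(v) for v in out):
        raise ValidationError(f"{name}: all entries must be finite")
    return out


@dataclass(frozen=True)
class CellCycleSpec:
    """An ``n``-stage cell cycle with per-stage exit rates.

    Total cycle duration is a sum of independent exponentials; for equal
    rates it is Erlang with squared CV ``1/n``.
    """

    n: int
    lambdas: tuple[float, ...]

    def __post_init__(self) -> None:
        if not isinstance(self.n, (int, np.integer)) or self.n < 1:
            raise ValidationError(f"n: must be a positive integer, got {self.n!r}")
        object.__setattr__(self, "n", int(self.n))
        lambdas = _as_float_tuple(self.lambdas, "lambdas")
        if len(lambdas) != self.n:
            raise ValidationError(
                f"lambdas: expected {self.n} rates, got {len(lambdas)}"
            )
        if any(lam <= 0 for lam in lambdas):
            raise ValidationError("lambdas: all stage exit rates must be > 0")
        object.__setattr__(self, "lambdas", lambdas)

    @property
    def mean_cycle_time(self) -> float:
        """Mean cycle duration, sum of per-stage mean sojourns."""
        return float(sum(1.0 / lam for lam in self.lambdas))

    @property
    def cycle_time_cv2(self) -> float:
        """Squared coefficient of variation of the cycle duration."""
        var = sum(1.0 / lam**2 for lam in self.lambdas)
        return float(var / self.mean_cycle_time**2)

    def lambdas_array(self) -> np.ndarray:
        return np.asarray(self.lambdas, dtype=float)


@dataclass(frozen=True)
class RegulationProfile:
    """Per-stage burst arrival rates ``k_i`` (bursts per hour)."""

    ks: tuple[float, ...]

    def __post_init__(self) -> None:
        ks = _as_float_tuple(self.ks, "ks")
        if any(k < 0 for k in ks):
            raise ValidationError("ks: burst arrival rates must be >= 0")
        object.__setattr__(self, "ks", ks)

    @property
    def n(self) -> int:
        return len(self.ks)

    @property
    def is_zero(self) -> bool:
        return all(k == 0.0 for k in self.ks)

    def ks_array(self) -> np.ndarray:
        return np.asarray(self.ks, dtype=float)

    def scaled(self, factor: float) -> "RegulationProfile":
        return RegulationProfile(tuple(k * factor for k in self.ks))


@dataclass(frozen=True)
class BurstModel:
    """Burst-size distribution ``B`` with exact first two moments.

    Kinds
    -----
    deterministic
        ``B == mean_b`` with probability one (``mean_b`` a positive integer).
    geometric0
        Geometric on support ``{0, 1, 2, ...}`` with mean ``m``;
        ``<B^2> = m (2m + 1)``.
    geometric1
        Geometric on support ``{1, 2, ...}`` with mean ``m``;
        ``<B^2> = m (2m - 1)``.
    custom
        Explicit pmf over ``{0, 1, ..., len(pmf) - 1}``.
    """

    kind: str
    mean_b: float
    second_moment_b: float
    pmf: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("deterministic", "geometric0", "geometric1", "custom"):
            raise ValidationError(f"burst.kind: unknown kind {self.kind!r}")
        if not (self.mean_b > 0 and math.isfinite(self.mean_b)):
            raise ValidationError("burst.mean_b: mean burst size must be > 0")
        if self.second_moment_b < self.mean_b**2 - 1e-12:
            raise ValidationError(
                "burst.second_moment_b: must be >= mean_b**2 (variance >= 0)"
            )
        if self.kind == "custom":
            if self.pmf is None:
                raise ValidationError("burst.pmf: required for kind='custom'")
            pmf = _as_float_tuple(self.pmf, "burst.pmf")
            if any(p < 0 for p in pmf) or abs(sum(pmf) - 1.0) > 1e-9:
                raise ValidationError("burst.pmf: must be non-negative and sum to 1")
            object.__setattr__(self, "pmf", pmf)
        elif self.pmf is not None:
            raise ValidationError("burst.pmf: only allowed for kind='custom'")

    # -- constructors -------------------------------------------------

    @staticmethod
    def deterministic(size: int = 1) -> "BurstModel":
        if size != int(size) or size < 1:
            raise ValidationError("burst.mean_b: deterministic size must be a positive integer")
        size = int(size)
        return BurstModel("deterministic", float(size), float(size) ** 2)

    @staticmethod
    def geometric0(mean: float) -> "BurstModel":
        m = float(mean)
        if m <= 0:
            raise ValidationError("burst.mean_b: must be > 0")
        return BurstModel("geometric0", m, m * (2 * m + 1))

    @staticmethod
    def geometric1(mean: float) -> "BurstModel":
        m = float(mean)
        if m < 1:
            raise ValidationError("burst.mean_b: geometric1 mean must be >= 1")
        return BurstModel("geometric1", m, m * (2 * m - 1))

    @staticmethod
    def custom(pmf: Sequence[float]) -> "BurstModel":
        pmf_t = _as_float_tuple(pmf, "burst.pmf")
        j = np.arange(len(pmf_t))
        p = np.asarray(pmf_t)
        mean = float(j @ p)
        second = float((j**2) @ p)
        return BurstModel("custom", mean, second, pmf_t)

    # -- sampling -----------------------------------------------------

    def sample(self, rng: np.random.Generator) -> int:
        """Draw one burst size."""
        if self.kind == "deterministic":
            return int(round(self.mean_b))
        if self.kind == "geometric1":
            return int(rng.geometric(1.0 / self.mean_b))
        if self.kind == "geometric0":
            return int(rng.geometric(1.0 / (self.mean_b + 1.0))) - 1
        return int(rng.choice(len(self.pmf), p=self.pmf))


@dataclass(frozen=True)
class PartitionModel:
    """Division partitioning with conditional mean ``x/2``, variance ``alpha*x/4``.

    ``alpha = 0`` is deterministic halving, ``alpha = 1`` binomial,
    ``0 < alpha < 1`` a binomial/deterministic mixture (sub-binomial),
    ``alpha > 1`` a clustered sampler (super-binomial; exact for integer
    ``alpha`` when clusters divide ``x``, approximate otherwise).

    On odd ``x`` the deterministic-half route uses randomized rounding
    (floor/ceil each with probability 1/2), which preserves the
    conditional mean exactly and adds variance 1/4.
    """

    alpha: float
    sampler_kind: str = ""

    def __post_init__(self) -> None:
        if self.alpha < 0 or not math.isfinite(self.alpha):
            raise ValidationError("alpha: partition-error magnitude must be >= 0")
        kind = self.sampler_kind or self._default_kind(self.alpha)
        allowed = (
            "deterministic-half",
            "binomial",
            "mixture-subbinomial",
            "clustered-superbinomial",
        )
        if kind not in allowed:
            raise ValidationError(f"partition.sampler_kind: unknown kind {kind!r}")
        object.__setattr__(self, "sampler_kind", kind)

    @staticmethod
    def _default_kind(alpha: float) -> str:
        if alpha == 0:
            return "deterministic-half"
        if alpha == 1:
            return "binomial"
        if alpha < 1:
            return "mixture-subbinomial"
        return "clustered-superbinomial"

    @staticmethod
    def from_alpha(alpha: float) -> "PartitionModel":
        return PartitionModel(float(alpha))

    def sample(self, x: int, rng: np.random.Generator) -> int:
        """Number of molecules inherited by the followed daughter."""
        if x < 0:
            raise ValidationError("x: copy number must be >= 0")
        x = int(x)
        if x == 0:
            return 0
        kind = self.sampler_kind
        if kind == "deterministic-half":
            return _half_randomized(x, rng)
        if kind == "binomial":
            return int(rng.binomial(x, 0.5))
        if kind == "mixture-subbinomial":
            if rng.random() < self.alpha:
                return int(rng.binomial(x, 0.5))
            return _half_randomized(x, rng)
        # clustered-superbinomial: partition clusters of size m binomially
        m = max(2, int(round(self.alpha)))
        q, r = divmod(x, m)
        kept = m * int(rng.binomial(q, 0.5)) if q else 0
        if r:
            kept += int(rng.binomial(r, 0.5))
        return kept


def _half_randomized(x: int, rng: np.random.Generator) -> int:
    half, odd = divmod(x, 2)
    if odd and rng.random() < 0.5:
        return half + 1
    return half


@dataclass(frozen=True)
class ModelSpec:
    """Full model: cycle + regulation + burst + partitioning (+ optional decay)."""

    cycle: CellCycleSpec
    regulation: RegulationProfile
    burst: BurstModel
    partition: PartitionModel
    degradation_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.regulation.n != self.cycle.n:
            raise ValidationError(
                f"ks: profile length {self.regulation.n} != number of stages {self.cycle.n}"
            )
        if self.degradation_rate < 0 or not math.isfinite(self.degradation_rate):
            raise ValidationError("degradation_rate: must be >= 0")

    def require_analytic(self) -> None:
        """Raise unless the closed-form/moment machinery applies."""
        if self.degradation_rate > 0:
            raise UnsupportedModelError(
                "degradation_rate > 0 is simulator-only; closed-form analytics "
                "assume a stable protein"
            )

    def with_regulation(self, regulation: RegulationProfile) -> "ModelSpec":
        return replace(self, regulation=regulation)


# ---------------------------------------------------------------------------
# constructors


def make_cell_cycle(
    n: int,
    mean_T: float | None = None,
    lambdas: Sequence[float] | None = None,
) -> CellCycleSpec:
    """Build a cell cycle, either from equal rates ``n / mean_T`` or
    from explicit per-stage rates."""
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValidationError(f"n: must be a positive integer, got {n!r}")
    if lambdas is not None:
        return CellCycleSpec(int(n), tuple(float(v) for v in lambdas))
    if mean_T is None:
        raise ValidationError("mean_T: required when lambdas are not given")
    if not (mean_T > 0 and math.isfinite(mean_T)):
        raise ValidationError(f"mean_T: must be > 0, got {mean_T!r}")
    lam = n / float(mean_T)
    return CellCycleSpec(int(n), (lam,) * int(n))


def make_strategy(
    name: str,
    k: float,
    cycle: CellCycleSpec,
    *,
    t1_fraction: float | None = None,
    fold: float | None = None,
) -> RegulationProfile:
    """Canonical regulation profiles.

    ``constant``: k everywhere; ``duplication_midpoint``: k then 2k (even n);
    ``start_only``/``end_only``/``midpoint_only``: a single non-zero stage;
    ``step``: k before the stage boundary nearest ``t1_fraction``, ``fold * k``
    after.
    """
    if name not in STRATEGY_NAMES:
        raise ValidationError(f"strategy.name: unknown strategy {name!r}")
    if not (k >= 0 and math.isfinite(k)):
        raise ValidationError("strategy.k: base rate must be >= 0")
    n = cycle.n
    if name == "constant":
        return RegulationProfile((k,) * n)
    if name == "start_only":
        return RegulationProfile((k,) + (0.0,) * (n - 1))
    if name == "end_only":
        return RegulationProfile((0.0,) * (n - 1) + (k,))
    if name in ("duplication_midpoint", "midpoint_only"):
        if n % 2:
            raise ValidationError(
                f"strategy.name: {name!r} requires an even number of stages, got n={n}"
            )
        half = n // 2
        if name == "duplication_midpoint":
            return RegulationProfile((k,) * half + (2 * k,) * half)
        ks = [0.0] * n
        ks[half - 1] = k
        return RegulationProfile(tuple(ks))
    # step
    if t1_fraction is None or fold is None:
        raise ValidationError("strategy.params: step requires t1_fraction and fold")
    if not (0.0 <= t1_fraction <= 1.0):
        raise ValidationError(f"strategy.t1_fraction: must be in [0, 1], got {t1_fraction}")
    if not (fold > 0 and math.isfinite(fold)):
        raise ValidationError(f"strategy.fold: must be > 0, got {fold}")
    boundary = round(n * t1_fraction)
    if abs(n * t1_fraction - boundary) > 1e-9:
        warnings.warn(
            f"t1_fraction={t1_fraction} is off a stage boundary for n={n}; "
            f"rounding the switch to after stage {boundary}",
            stacklevel=2,
        )
    ks = [k] * boundary + [fold * k] * (n - boundary)
    return RegulationProfile(tuple(ks))


def calibrate_rate(model: ModelSpec, target_mean: float) -> ModelSpec:
    """Rescale the whole regulation profile so the closed-form steady-state
    mean equals ``target_mean`` (the mean is linear in the profile)."""
    from .analytics import mean_protein  # local import avoids a cycle

    model.require_analytic()
    if model.regulation.is_zero:
        raise ValidationError("ks: cannot calibrate an all-zero regulation profile")
    if not (target_mean > 0 and math.isfinite(target_mean)):
        raise ValidationError(f"target_mean: must be > 0, got {target_mean!r}")
    current = mean_protein(model)
    return model.with_regulation(model.regulation.scaled(target_mean / current))
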