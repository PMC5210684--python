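"""Closed-form steady-state mean and noise for cell-cycle-coupled bursts.

All formulas are exact for the stable-protein model (no degradation).
Double sums over stage pairs are evaluated with prefix sums, which is
algebraically identical to the direct double summation but O(n), so the
same code serves both small cycles and the large-n deterministic-cycle
limit.

Noise here is the squared-CV-like quantity eta = var(z)/mean(x)^2 of the
cell-cycle-corrected process z = x - y; no square-root CV is ever
returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_model import CellCycleSpec, ModelSpec
from .errors import ValidationError

__all__ = [
    "NoiseSummary",
    "stage_occupancy",
    "mean_protein",
    "mean_protein_limit",
    "conditional_mean",
    "beta",
    "beta_profiles",
    "beta_bounds",
    "noise_coefficients",
    "noise_decomposition",
    "molecules_per_cycle",
]


@dataclass(frozen=True)
class NoiseSummary:
    """Steady-state mean and decomposed noise for one model.

    ``eta_burst`` is the bursty-synthesis term, ``eta_partition`` the
    partitioning-error term; their sum is the intrinsic noise
    ``eta_total``.
    """

    mean_x: float
    beta: float
    eta_burst: float
    eta_partition: float
    eta_total: float
    per_stage_mean: tuple[float, ...]

    def as_dict(self) -> dict:
        return {
            "mean_x": self.mean_x,
            "beta": self.beta,
            "eta_burst": self.eta_burst,
            "eta_partition": self.eta_partition,
            "eta_total": self.eta_total,
            "per_stage_mean": list(self.per_stage_mean),
        }


def stage_occupancy(cycle: CellCycleSpec) -> np.ndarray:
    """Steady-state probability of finding an asynchronous cell in each
    stage: the fraction of cycle time spent there, (1/lambda_i) / sum_j (1/lambda_j)."""
    inv = 1.0 / cycle.lambdas_array()
    return inv / inv.sum()


def _sums(model: ModelSpec) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Shared building blocks: L = sum 1/lambda_j, S = sum k_j/lambda_j,
    prefix sums S_i = sum_{j<=i} k_j/lambda_j, and 1/lambda."""
    lam = model.cycle.lambdas_array()
    ks = model.regulation.ks_array()
    inv = 1.0 / lam
    ratios = ks * inv
    return float(inv.sum()), float(ratios.sum()), np.cumsum(ratios), inv


def mean_protein(model: ModelSpec) -> float:
    """Exact steady-state mean copy number (double-sum form)."""
    model.require_analytic()
    if model.regulation.is_zero:
        return 0.0
    L, S, prefix, inv = _sums(model)
    return model.burst.mean_b / L * (L * S + float(inv @ prefix))


def mean_protein_limit(mean_b: float, mean_T: float, k: float) -> float:
    """Deterministic-cycle (n -> infinity) mean for a constant rate k:
    (3/2) <B> T k."""
    return 1.5 * mean_b * mean_T * k


def conditional_mean(model: ModelSpec) -> np.ndarray:
    """Mean copy number conditioned on the cell-cycle stage (a within-stage
    average over an asynchronous population, not a fixed-phase value):
    <B> (sum_j k_j/lambda_j + sum_{j<=i} k_j/lambda_j). Non-decreasing in i."""
    model.require_analytic()
    _, S, prefix, _ = _sums(model)
    return model.burst.mean_b * (S + prefix)


def beta(model: ModelSpec) -> float:
    """Dimensionless regulation parameter summarizing how the synthesis
    profile shapes noise; invariant under uniform scaling of the profile."""
    if model.regulation.is_zero:
        raise ValidationError("ks: beta is undefined for an all-zero profile")
    L, S, prefix, inv = _sums(model)
    return L * S / float(inv @ prefix)


def beta_profiles(cycle: CellCycleSpec, ks_matrix: np.ndarray) -> np.ndarray:
    """Vectorized beta over many profiles (rows of ``ks_matrix``)."""
    ks_matrix = np.atleast_2d(np.asarray(ks_matrix, dtype=float))
    if ks_matrix.shape[1] != cycle.n:
        raise ValidationError(
            f"ks: profiles must have {cycle.n} columns, got {ks_matrix.shape[1]}"
        )
    if np.any(ks_matrix < 0):
        raise ValidationError("ks: burst arrival rates must be >= 0")
    totals = ks_matrix.sum(axis=1)
    if np.any(totals == 0):
        raise ValidationError("ks: beta is undefined for an all-zero profile")
    inv = 1.0 / cycle.lambdas_array()
    ratios = ks_matrix * inv
    prefix = np.cumsum(ratios, axis=1)
    L = inv.sum()
    return L * ratios.sum(axis=1) / (prefix @ inv)


def beta_bounds(cycle: CellCycleSpec) -> tuple[float, float]:
    """(1, sum_j(1/lambda_j) / (1/lambda_n)): the attainable range of beta.

    The lower bound is reached by expression confined to the first stage,
    the upper by expression confined to the last."""
    inv = 1.0 / cycle.lambdas_array()
    return 1.0, float(inv.sum() * cycle.lambdas[-1])


def noise_coefficients(
    beta_value: float, second_moment_ratio: float, alpha: float
) -> tuple[float, float]:
    """Coefficients (eta_burst * <x>, eta_partition * <x>) as functions of
    beta alone. ``beta_value`` may be ``math.inf`` (deterministic-cycle,
    end-of-cycle limit)."""
    if math.isinf(beta_value):
        frac = 1.0
    else:
        if beta_value < 1.0 - 1e-12:
            raise ValidationError(f"beta: must be >= 1, got {beta_value}")
        frac = beta_value / (1.0 + beta_value)
    c_burst = (1.0 / 3.0 + (2.0 / 3.0) * (1.0 - frac)) * second_moment_ratio
    c_partition = (2.0 * alpha / 3.0) * frac
    return c_burst, c_partition


def noise_decomposition(model: ModelSpec) -> NoiseSummary:
    """Intrinsic noise split into bursty-synthesis and partitioning-error
    terms, both inversely proportional to the mean."""
    model.require_analytic()
    b = beta(model)  # rejects all-zero profiles
    mean_x = mean_protein(model)
    ratio = model.burst.second_moment_b / model.burst.mean_b
    c_burst, c_partition = noise_coefficients(b, ratio, model.partition.alpha)
    return NoiseSummary(
        mean_x=mean_x,
        beta=b,
        eta_burst=c_burst / mean_x,
        eta_partition=c_partition / mean_x,
        eta_total=(c_burst + c_partition) / mean_x,
        per_stage_mean=tuple(conditional_mean(model)),
    )


def molecules_per_cycle(model: ModelSpec) -> tuple[float, float]:
    """(expected bursts per cycle, expected molecules synthesized per cycle).

    Bursts per cycle = sum_i k_i / lambda_i; molecules multiply by <B>.
    In the deterministic-cycle limit this equals 2<x>/3 for a constant
    rate, <x>/2 for start-only and <x> for end-only expression."""
    model.require_analytic()
    bursts = float(model.regulation.ks_array() @ (1.0 / model.cycle.lambdas_array()))
    return bursts, model.burst.mean_b * bursts
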