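"""Linear moment ODEs for the stage/copy-number process, solved exactly.

The state collects, for stages i = 1..n, the moments <c_i>, <x c_i> and
<z^2 c_i>, where c_i is the stage indicator, x the copy number, and
z = x - y the deviation from the deterministic counterpart. Products of
distinct stage indicators vanish, which closes the system exactly: the
only would-be higher moments, <x c_1 c_n> and <z^2 c_1 c_n>, are
identically zero for n >= 2. The same assembly specialises correctly to
n = 1 (where c_1 is identically one), reproducing the scalar equations
for <x> and <z^2>; this is cross-checked against the closed forms and
simulation in the tests.

This module is deliberately independent of :mod:`cyclenoise.analytics`:
it serves as a second route to the same steady-state quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .core_model import ModelSpec
from .errors import CycleNoiseError

__all__ = ["MomentSystem", "MomentState", "build_system", "steady_state", "transient"]


@dataclass(frozen=True)
class MomentSystem:
    """dv/dt = A v for the ordered state (c_1..c_n, xc_1..xc_n, z2c_1..z2c_n)."""

    n: int
    A: np.ndarray
    state_labels: tuple[str, ...]
    normalization_row: int = 0  # redundant c-row replaced by sum(c) = 1

    @property
    def size(self) -> int:
        return 3 * self.n


@dataclass(frozen=True)
class MomentState:
    """One snapshot (or the steady state) of all 3n moments."""

    c: np.ndarray
    xc: np.ndarray
    z2c: np.ndarray

    @property
    def mean_x(self) -> float:
        return float(self.xc.sum())

    @property
    def var_z(self) -> float:
        return float(self.z2c.sum())

    @property
    def eta(self) -> float:
        m = self.mean_x
        if m == 0.0:
            return float("nan")
        return self.var_z / m**2

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.c, self.xc, self.z2c])

    @staticmethod
    def from_vector(v: np.ndarray, n: int) -> "MomentState":
        v = np.asarray(v, dtype=float)
        return MomentState(v[:n].copy(), v[n : 2 * n].copy(), v[2 * n :].copy())

    @staticmethod
    def zero(n: int) -> "MomentState":
        c = np.zeros(n)
        c[0] = 1.0  # a newborn cell sits in stage 1
        return MomentState(c, np.zeros(n), np.zeros(n))

    def as_dict(self) -> dict:
        return {
            "c": self.c.tolist(),
            "xc": self.xc.tolist(),
            "z2c": self.z2c.tolist(),
            "mean_x": self.mean_x,
            "var_z": self.var_z,
            "eta": self.eta,
        }


def build_system(model: ModelSpec) -> MomentSystem:
    """Assemble the closed 3n x 3n coefficient matrix.

    Per stage, with lam = stage exit rates, k = burst rates, mB/mB2 the
    burst moments and alpha the partitioning parameter:

    - d<c_1>     = lam_n <c_n> - lam_1 <c_1>, and cyclic shifts below;
    - d<xc_1>    = k_1 mB <c_1> + (lam_n/2) <xc_n> - lam_1 <xc_1>
      (the factor 1/2 is the halving of the mean at division);
    - d<z2c_1>   = k_1 mB2 <c_1> + (alpha lam_n/4) <xc_n>
                   + (lam_n/4) <z2c_n> - lam_1 <z2c_1>
      (the alpha term injects partitioning noise, the 1/4 the quartering
      of z^2 under exact halving);
    - interior stages i >= 2 only relay from stage i-1 and add their own
      burst source.
    """
    model.require_analytic()
    n = model.cycle.n
    lam = model.cycle.lambdas_array()
    ks = model.regulation.ks_array()
    mB = model.burst.mean_b
    mB2 = model.burst.second_moment_b
    alpha = model.partition.alpha

    size = 3 * n
    A = np.zeros((size, size))
    c, xc, z2c = 0, n, 2 * n  # block offsets

    for i in range(n):
        prev = i - 1 if i > 0 else n - 1
        # <c_i>
        A[c + i, c + i] -= lam[i]
        A[c + i, c + prev] += lam[prev] if i > 0 else lam[n - 1]
        # <x c_i>
        A[xc + i, c + i] += ks[i] * mB
        A[xc + i, xc + i] -= lam[i]
        if i > 0:
            A[xc + i, xc + prev] += lam[prev]
        else:
            A[xc + i, xc + (n - 1)] += lam[n - 1] / 2.0
        # <z^2 c_i>
        A[z2c + i, c + i] += ks[i] * mB2
        A[z2c + i, z2c + i] -= lam[i]
        if i > 0:
            A[z2c + i, z2c + prev] += lam[prev]
        else:
            A[z2c + i, xc + (n - 1)] += alpha * lam[n - 1] / 4.0
            A[z2c + i, z2c + (n - 1)] += lam[n - 1] / 4.0

    labels = (
        tuple(f"c_{i + 1}" for i in range(n))
        + tuple(f"xc_{i + 1}" for i in range(n))
        + tuple(f"z2c_{i + 1}" for i in range(n))
    )
    return MomentSystem(n=n, A=A, state_labels=labels)


def steady_state(system: MomentSystem) -> MomentState:
    """Solve A v = 0 with the probability normalization sum(c) = 1
    replacing the redundant c-row (a direct, deterministic linear solve)."""
    n = system.n
    M = system.A.copy()
    rhs = np.zeros(3 * n)
    M[system.normalization_row, :] = 0.0
    M[system.normalization_row, :n] = 1.0
    rhs[system.normalization_row] = 1.0
    try:
        v = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise CycleNoiseError(
            f"singular moment system (n={n}); condition estimate "
            f"{np.linalg.cond(M):.3g}"
        ) from exc
    residual = float(np.max(np.abs(M @ v - rhs)))
    if not np.isfinite(residual) or residual > 1e-6 * max(1.0, float(np.abs(v).max())):
        raise CycleNoiseError(f"steady-state solve residual too large: {residual:.3g}")
    return MomentState.from_vector(v, n)


def transient(
    system: MomentSystem, initial: MomentState, times: np.ndarray
) -> list[MomentState]:
    """Propagate the linear ODEs exactly via the matrix exponential,
    returning one state per requested time (times need not be sorted,
    but must be non-negative)."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0) or not np.all(np.isfinite(times)):
        raise CycleNoiseError("times: must be finite and non-negative")
    v0 = initial.as_vector()
    out: list[MomentState] = []
    for t in times:
        v = expm(system.A * t) @ v0
        if not np.all(np.isfinite(v)):
            raise CycleNoiseError(f"non-finite moments at t={t}")
        out.append(MomentState.from_vector(v, system.n))
    return out
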