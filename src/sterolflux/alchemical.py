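"""Alchemical free-energy estimation from reduced-potential samples.

The primary estimator is the multistate Bennett acceptance ratio (MBAR):
given u[k, n], the reduced (dimensionless, u = U/kT) potential of every
sample n evaluated at every λ state k, the state free energies f_k solve

    f_k = −ln Σ_n exp(−u_kn) / Σ_j N_j exp(f_j − u_jn),

anchored at f_0 = 0.  The solver runs a few self-consistent sweeps and then
minimises the equivalent convex objective with a quasi-Newton step;
asymptotic errors come from the standard MBAR covariance (SVD form).
Pairwise BAR and exponential averaging (Zwanzig) are provided as
cross-check estimators.

Cycle types assemble leg estimates into absolute-binding and relative-
perturbation results: an ABFE total is site leg − reference leg − restraint
bookkeeping terms; a perturbation ΔΔG is bound leg − free leg.  Errors
always combine in quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import logsumexp

from .constants import kt_kj
from .cycles import FreeEnergyValue, quadrature_error

__all__ = [
    "LambdaSchedule",
    "ReducedPotentialMatrix",
    "MBAR",
    "MBARResult",
    "AlchemicalLegResult",
    "PerturbationCycle",
    "AbsoluteBindingCycle",
    "InversePerturbationReport",
    "estimate_mbar",
    "estimate_bar",
    "estimate_exp",
    "estimate_leg",
    "combine_abfe",
    "replicate_statistics",
    "check_inverse_perturbation",
    "statistical_inefficiency",
    "cholesterol_decoupling_schedule",
    "cation_exchange_schedule",
]

#: Adjacent-state overlap below which a warning is attached to diagnostics.
OVERLAP_WARN_THRESHOLD = 0.03


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered λ points with optional phase labels.

    λ is nondecreasing overall; within each phase the coupling parameter
    runs from 0 to 1 (phases are sequential legs of one transformation,
    e.g. a mass leg followed by a van-der-Waals leg).
    """

    values: tuple[float, ...]
    phases: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size < 2:
            raise ValueError("a schedule needs at least two λ points")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("λ values must lie in [0, 1]")
        if self.phases is not None:
            if len(self.phases) != v.size:
                raise ValueError("phases must label every λ point")
            # Phases are sequential legs of one transformation.  The first
            # phase starts at λ=0; each phase ends at λ=1; at a phase
            # boundary the new phase's λ=0 point coincides with the previous
            # phase's λ=1 window and is stored once, so a later phase may
            # begin above 0.
            for idx, phase in enumerate(dict.fromkeys(self.phases)):
                pv = v[[p == phase for p in self.phases]]
                if np.any(np.diff(pv) < 0):
                    raise ValueError(f"λ must be nondecreasing within phase {phase!r}")
                if idx == 0 and pv[0] != 0.0:
                    raise ValueError("the first phase must start at λ=0")
                if pv[-1] != 1.0:
                    raise ValueError(f"phase {phase!r} must end at λ=1")
        elif np.any(np.diff(v) < 0):
            raise ValueError("λ values must be nondecreasing")

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_breakpoints(cls, breaks: Sequence[float], steps: Sequence[float]) -> "LambdaSchedule":
        """Build a piecewise-uniform schedule, e.g. from_breakpoints([0, .6, 1], [.05, .025])."""
        if len(steps) != len(breaks) - 1:
            raise ValueError("need one step size per interval")
        pts: list[float] = [float(breaks[0])]
        for lo, hi, step in zip(breaks[:-1], breaks[1:], steps):
            n = round((hi - lo) / step)
            pts.extend(np.round(np.linspace(lo, hi, n + 1)[1:], 10).tolist())
        return cls(values=tuple(pts))


def cholesterol_decoupling_schedule() -> LambdaSchedule:
    """The 29-window Lennard-Jones decoupling schedule for cholesterol ABFE.

    λ steps of 0.05 from 0 to 0.6 (13 points) and 0.025 from 0.6 to 1
    (16 more), giving 29 windows in total.
    """
    return LambdaSchedule.from_breakpoints([0.0, 0.6, 1.0], [0.05, 0.025])


def cation_exchange_schedule() -> LambdaSchedule:
    """The 31-window Na⁺→K⁺ exchange schedule: mass then van-der-Waals phase.

    The mass of the ion is transformed over 11 windows (λ step 0.1) and the
    van-der-Waals radii over the following windows (λ step 0.05); the shared
    boundary window is counted once, giving 31 windows.
    """
    mass = np.round(np.linspace(0, 1, 11), 10)
    vdw = np.round(np.linspace(0, 1, 21), 10)
    values = tuple(mass) + tuple(vdw[1:])
    phases = ("mass",) * 11 + ("vdw",) * 20
    return LambdaSchedule(values=values, phases=phases)


@dataclass
class ReducedPotentialMatrix:
    """Samples from K thermodynamic states, evaluated at all K states.

    ``u[k, n]`` is the reduced potential of pooled sample n at state k;
    ``n_k[k]`` counts the samples drawn from state k (the pooled sample
    axis is ordered state-by-state).
    """

    u: np.ndarray
    n_k: np.ndarray
    temperature: float = 298.15
    schedule: LambdaSchedule | None = None

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.n_k = np.asarray(self.n_k, dtype=int)
        if self.u.ndim != 2:
            raise ValueError("u must be a 2D (states × samples) array")
        k, n = self.u.shape
        if k < 2:
            raise ValueError("at least two states are required")
        if self.n_k.shape != (k,):
            raise ValueError("n_k must have one entry per state")
        if int(self.n_k.sum()) != n:
            raise ValueError("n_k must sum to the total number of samples")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("reduced potentials must be finite")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_states(self) -> int:
        return self.u.shape[0]

    @property
    def kt(self) -> float:
        return kt_kj(self.temperature)

    def state_slice(self, k: int) -> slice:
        start = int(self.n_k[:k].sum())
        return slice(start, start + int(self.n_k[k]))

    def pair(self, i: int, j: int) -> "ReducedPotentialMatrix":
        """Restriction to two states (their samples and their two rows)."""
        si, sj = self.state_slice(i), self.state_slice(j)
        cols = np.r_[si, sj]
        return ReducedPotentialMatrix(
            u=self.u[[i, j]][:, cols],
            n_k=np.array([self.n_k[i], self.n_k[j]]),
            temperature=self.temperature,
        )

    def discard_equilibration(self, fraction: float = 0.04) -> "ReducedPotentialMatrix":
        """Drop the leading ``fraction`` of each state's samples (equilibration)."""
        if not 0 <= fraction < 1:
            raise ValueError("fraction must be in [0, 1)")
        keep_cols = []
        new_nk = []
        for k in range(self.n_states):
            s = self.state_slice(k)
            drop = int(np.floor(self.n_k[k] * fraction))
            keep_cols.extend(range(s.start + drop, s.stop))
            new_nk.append(self.n_k[k] - drop)
        return ReducedPotentialMatrix(
            u=self.u[:, keep_cols], n_k=np.array(new_nk), temperature=self.temperature,
            schedule=self.schedule,
        )

    def subsample(self, stride_per_state: Sequence[int] | None = None) -> "ReducedPotentialMatrix":
        """Decorrelate by striding each state's samples.

        Default strides are ceil(statistical inefficiency) of each state's
        own-energy series u[k, samples of k].
        """
        keep_cols = []
        new_nk = []
        for k in range(self.n_states):
            s = self.state_slice(k)
            if stride_per_state is None:
                g = statistical_inefficiency(self.u[k, s])
                stride = max(1, int(np.ceil(g)))
            else:
                stride = max(1, int(stride_per_state[k]))
            cols = list(range(s.start, s.stop, stride))
            keep_cols.extend(cols)
            new_nk.append(len(cols))
        return ReducedPotentialMatrix(
            u=self.u[:, keep_cols], n_k=np.array(new_nk), temperature=self.temperature,
            schedule=self.schedule,
        )


def statistical_inefficiency(series: np.ndarray) -> float:
    """g = 1 + 2 τ of a time series from its normalised autocorrelation.

    Integrates the autocorrelation function until it first drops below zero
    (the usual truncation rule).  g = 1 for white noise; subsampling every
    ceil(g)-th point yields approximately independent samples.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 3:
        return 1.0
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return 1.0
    g = 1.0
    for t in range(1, n):
        c = np.dot(x[:-t], x[t:]) / ((n - t) * var)
        if c <= 0:
            break
        g += 2.0 * c * (1.0 - t / n)
    return max(1.0, g)


class MBARConvergenceError(RuntimeError):
    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class MBAR:
    """Multistate Bennett acceptance ratio model over a reduced-potential matrix."""

    def __init__(self, matrix: ReducedPotentialMatrix):
        self.matrix = matrix

    def fit(self, tolerance: float = 1e-8, max_iterations: int = 10_000) -> "MBARResult":
        """Solve the MBAR equations; returns free energies anchored at state 0.

        ``tolerance`` bounds the self-consistency residual (dimensionless
        free energies).  Non-convergence raises :class:`MBARConvergenceError`.
        """
        u = self.matrix.u
        n_k = self.matrix.n_k.astype(float)
        k_states, n_tot = u.shape
        active = n_k > 0
        log_n = np.where(active, np.log(np.maximum(n_k, 1)), -np.inf)

        def self_consistent(f: np.ndarray) -> np.ndarray:
            # log denominator per sample: logsumexp_j [log N_j + f_j - u_jn]
            log_denom = logsumexp((log_n + f)[:, None] - u, axis=0)
            f_new = -logsumexp(-u - log_denom[None, :], axis=1)
            return f_new - f_new[0]

        f = np.zeros(k_states)
        for _ in range(20):
            f = self_consistent(f)

        # convex objective: sum_n log sum_j N_j e^{f_j - u_jn} - sum_j N_j f_j
        def objective(theta: np.ndarray):
            f_full = np.concatenate([[0.0], theta])
            a = (log_n + f_full)[:, None] - u
            log_denom = logsumexp(a, axis=0)
            obj = log_denom.sum() - float(np.dot(n_k, f_full))
            w = np.exp(a - log_denom[None, :])  # N_j-weighted sample weights
            grad = w.sum(axis=1) - n_k
            return obj, grad[1:]

        opt = minimize(objective, f[1:], jac=True, method="L-BFGS-B",
                       options={"maxiter": max_iterations, "ftol": 1e-14, "gtol": 1e-10})
        f = np.concatenate([[0.0], opt.x])
        residual = float(np.max(np.abs(self_consistent(f) - f)))
        # polish with self-consistent sweeps if the optimizer stalled short
        it = 0
        while residual >= tolerance and it < max_iterations:
            f = self_consistent(f)
            residual = float(np.max(np.abs(self_consistent(f) - f)))
            it += 1
        if residual >= tolerance:
            raise MBARConvergenceError(
                f"MBAR did not reach tolerance {tolerance:g} (residual {residual:.3e})",
                residual,
            )

        # sample weight matrix W_nk = exp(f_k - u_kn) / sum_j N_j exp(f_j - u_jn)
        log_denom = logsumexp((log_n + f)[:, None] - u, axis=0)
        log_w = f[:, None] - u - log_denom[None, :]
        w = np.exp(log_w).T  # (n_tot, k_states)

        theta = self._covariance(w, n_k)
        d2 = theta[0, 0] + np.diag(theta) - 2.0 * theta[0, :]
        errors = np.sqrt(np.maximum(d2, 0.0))

        overlap = (w.T @ w) * n_k[None, :]  # O_ij = N_j sum_n W_ni W_nj
        adj = np.diagonal(overlap, offset=1)
        diagnostics: dict = {"min_adjacent_overlap": float(adj.min()) if adj.size else 1.0}
        if adj.size and adj.min() < OVERLAP_WARN_THRESHOLD:
            pair = int(np.argmin(adj))
            diagnostics["warning"] = (
                f"low overlap {adj.min():.4f} between adjacent states {pair} and {pair + 1}"
            )
            warnings.warn(diagnostics["warning"], RuntimeWarning, stacklevel=2)

        return MBARResult(
            matrix=self.matrix,
            f=f,
            f_errors=errors,
            theta=theta,
            overlap_matrix=overlap,
            residual=residual,
            diagnostics=diagnostics,
        )

    @staticmethod
    def _covariance(w: np.ndarray, n_k: np.ndarray) -> np.ndarray:
        """Asymptotic covariance of the reduced free energies (SVD form)."""
        u_svd, s, vt = np.linalg.svd(w, full_matrices=False)
        v = vt.T
        inner = np.eye(len(s)) - np.diag(s) @ v.T @ (n_k[:, None] * v) @ np.diag(s)
        theta = v @ np.diag(s) @ np.linalg.pinv(inner, rcond=1e-10) @ np.diag(s) @ v.T
        return theta


@dataclass
class MBARResult:
    """Fitted MBAR free energies with asymptotic errors and diagnostics."""

    matrix: ReducedPotentialMatrix
    f: np.ndarray                 # reduced free energies, f[0] = 0
    f_errors: np.ndarray          # reduced standard errors of f_k - f_0
    theta: np.ndarray             # covariance of reduced free energies
    overlap_matrix: np.ndarray
    residual: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def free_energies(self) -> np.ndarray:
        """Per-state free energies relative to state 0, kJ·mol⁻¹."""
        return self.f * self.matrix.kt

    @property
    def errors(self) -> np.ndarray:
        """Standard errors of the per-state free energies, kJ·mol⁻¹."""
        return self.f_errors * self.matrix.kt

    def delta_f(self, i: int, j: int) -> tuple[float, float]:
        """(Δf, σ) between states i and j in reduced units."""
        d = float(self.f[j] - self.f[i])
        var = self.theta[i, i] + self.theta[j, j] - 2.0 * self.theta[i, j]
        return d, float(np.sqrt(max(var, 0.0)))

    def leg_result(self, label: str = "") -> "AlchemicalLegResult":
        """Package the end-to-end ΔG of this leg with per-interval contributions."""
        kt = self.matrix.kt
        k = self.matrix.n_states
        contribs = np.diff(self.f) * kt
        dg, err = self.delta_f(0, k - 1)
        return AlchemicalLegResult(
            delta_g=dg * kt,
            error=err * kt,
            per_interval=contribs,
            overlap_min=self.diagnostics.get("min_adjacent_overlap", np.nan),
            label=label,
        )

    def summary(self) -> str:
        kt = self.matrix.kt
        lines = [
            "MBAR fit",
            f"  states: {self.matrix.n_states}  samples: {int(self.matrix.n_k.sum())}"
            f"  T = {self.matrix.temperature:g} K",
            f"  residual: {self.residual:.2e}",
            f"  min adjacent overlap: {self.diagnostics.get('min_adjacent_overlap', float('nan')):.4f}",
            "  state        f (kT)   dG (kJ/mol)   ±err",
        ]
        for k in range(self.matrix.n_states):
            lines.append(
                f"  {k:5d}  {self.f[k]:12.4f}  {self.f[k] * kt:12.3f}  {self.f_errors[k] * kt:7.3f}"
            )
        return "\n".join(lines)


@dataclass
class AlchemicalLegResult:
    """End-to-end ΔG of one alchemical leg (kJ·mol⁻¹) with diagnostics."""

    delta_g: float
    error: float
    per_interval: np.ndarray = field(default_factory=lambda: np.array([]))
    overlap_min: float = np.nan
    label: str = ""

    def __post_init__(self) -> None:
        if self.error < 0:
            raise ValueError("error must be nonnegative")
        self.per_interval = np.asarray(self.per_interval, dtype=float)
        if self.per_interval.size and not np.isclose(
            self.per_interval.sum(), self.delta_g, atol=1e-8, rtol=1e-8
        ):
            raise ValueError("per-interval contributions must sum to delta_g")

    def as_value(self) -> FreeEnergyValue:
        return FreeEnergyValue(self.delta_g, self.error, label=self.label)


# ---------------------------------------------------------------------------
# estimators as functions


def estimate_mbar(
    matrix: ReducedPotentialMatrix,
    tolerance: float = 1e-8,
    max_iterations: int = 10_000,
) -> MBARResult:
    """Solve MBAR on the matrix (see :class:`MBAR`)."""
    return MBAR(matrix).fit(tolerance=tolerance, max_iterations=max_iterations)


class ZeroOverlapError(RuntimeError):
    """BAR cannot converge: forward/reverse work distributions do not overlap."""


def estimate_bar(
    matrix: ReducedPotentialMatrix,
    tolerance: float = 1e-10,
    label: str = "",
) -> AlchemicalLegResult:
    """Bennett acceptance ratio on a two-state matrix.

    Solves the implicit Bennett equation with Fermi weighting for the
    reduced free-energy difference Δf (state 0 → state 1); antisymmetric
    under state swap.  Returns ΔG in kJ·mol⁻¹ with the standard asymptotic
    BAR variance.
    """
    if matrix.n_states != 2:
        raise ValueError("BAR requires exactly two states; use matrix.pair(i, j)")
    s0, s1 = matrix.state_slice(0), matrix.state_slice(1)
    w_f = matrix.u[1, s0] - matrix.u[0, s0]  # forward work, samples from 0
    w_r = matrix.u[0, s1] - matrix.u[1, s1]  # reverse work, samples from 1
    n_f, n_r = w_f.size, w_r.size
    if n_f == 0 or n_r == 0:
        raise ValueError("both states must contribute samples")
    m = np.log(n_f / n_r)

    def fermi(x: np.ndarray) -> np.ndarray:
        # numerically safe logistic 1/(1+e^x)
        out = np.empty_like(x, dtype=float)
        pos = x >= 0
        out[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
        out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
        return out

    def residual(df: float) -> float:
        return float(fermi(m + w_f - df).sum() - fermi(-m + w_r + df).sum())

    lo = min(float(-w_r.max()), float(w_f.min())) - 50.0
    hi = max(float(w_f.max()), float(-w_r.min())) + 50.0
    df = brentq(residual, lo, hi, xtol=tolerance)

    ff = fermi(m + w_f - df)
    fr = fermi(-m + w_r + df)
    # at the self-consistent point both Fermi-weight means must be resolvably
    # nonzero; underflow here means the work distributions do not overlap
    if np.mean(ff) < 1e-12 or np.mean(fr) < 1e-12:
        raise ZeroOverlapError(
            "forward and reverse work distributions do not overlap; BAR diverges"
        )
    var = (np.mean(ff**2) / np.mean(ff) ** 2 - 1.0) / n_f + (
        np.mean(fr**2) / np.mean(fr) ** 2 - 1.0
    ) / n_r
    kt = matrix.kt
    return AlchemicalLegResult(
        delta_g=df * kt,
        error=float(np.sqrt(max(var, 0.0))) * kt,
        per_interval=np.array([df * kt]),
        label=label,
    )


def estimate_exp(matrix: ReducedPotentialMatrix, direction: str = "forward") -> AlchemicalLegResult:
    """Exponential averaging (Zwanzig) on a two-state matrix, as a cross-check.

    forward: Δf = −ln⟨e^{−w_F}⟩₀; reverse: Δf = +ln⟨e^{−w_R}⟩₁.
    """
    if matrix.n_states != 2:
        raise ValueError("exponential averaging requires exactly two states")
    s0, s1 = matrix.state_slice(0), matrix.state_slice(1)
    if direction == "forward":
        w = matrix.u[1, s0] - matrix.u[0, s0]
        df = -(logsumexp(-w) - np.log(w.size))
    elif direction == "reverse":
        w = matrix.u[0, s1] - matrix.u[1, s1]
        df = logsumexp(-w) - np.log(w.size)
    else:
        raise ValueError("direction must be 'forward' or 'reverse'")
    # delta-method variance of -ln mean(e^{-w})
    ew = np.exp(-(w - w.min()))
    var = np.var(ew, ddof=1) / (w.size * np.mean(ew) ** 2)
    kt = matrix.kt
    return AlchemicalLegResult(
        delta_g=float(df) * kt,
        error=float(np.sqrt(var)) * kt,
        per_interval=np.array([float(df) * kt]),
        label=f"exp-{direction}",
    )


def estimate_leg(
    matrix: ReducedPotentialMatrix,
    method: str = "mbar",
    tolerance: float = 1e-8,
    label: str = "",
) -> AlchemicalLegResult:
    """Estimate a full leg ΔG by MBAR (default) or by summed pairwise BAR."""
    if method == "mbar":
        return estimate_mbar(matrix, tolerance=tolerance).leg_result(label=label)
    if method == "bar":
        contribs = []
        var = 0.0
        min_overlap = np.inf
        for i in range(matrix.n_states - 1):
            r = estimate_bar(matrix.pair(i, i + 1), label=f"{label}[{i}->{i + 1}]")
            contribs.append(r.delta_g)
            var += r.error**2
        contribs = np.array(contribs)
        return AlchemicalLegResult(
            delta_g=float(contribs.sum()),
            error=float(np.sqrt(var)),
            per_interval=contribs,
            overlap_min=min_overlap if np.isfinite(min_overlap) else np.nan,
            label=label,
        )
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# cycles over leg results


@dataclass(frozen=True)
class PerturbationCycle:
    """Relative perturbation: the same transformation bound vs in solution.

    ΔΔG = bound leg − free leg, error in quadrature.  Negative ΔΔG means the
    transformation is more favorable at the binding site than in solution.
    """

    bound_leg: AlchemicalLegResult
    free_leg: AlchemicalLegResult
    label: str = ""

    @property
    def ddg(self) -> FreeEnergyValue:
        return FreeEnergyValue(
            value=self.bound_leg.delta_g - self.free_leg.delta_g,
            error=quadrature_error([self.bound_leg.error, self.free_leg.error]),
            label=self.label or "ddG(bound - free)",
        )


class IncompleteCycleError(ValueError):
    """A required leg of a thermodynamic cycle is missing."""


@dataclass(frozen=True)
class AbsoluteBindingCycle:
    """Absolute binding free energy from a decoupling cycle.

    total = site decoupling leg − reference leg − Σ restraint bookkeeping
    terms.  The reference leg is the gas-phase/restraint-exchange coordinate
    that completes the cycle; restraint terms are supplied values, never
    computed analytically here.
    """

    site_leg: AlchemicalLegResult
    reference_leg: AlchemicalLegResult
    restraint_terms: tuple[FreeEnergyValue, ...] = ()
    label: str = ""

    @property
    def total(self) -> FreeEnergyValue:
        value = (
            self.site_leg.delta_g
            - self.reference_leg.delta_g
            - sum(t.value for t in self.restraint_terms)
        )
        error = quadrature_error(
            [self.site_leg.error, self.reference_leg.error]
            + [t.error for t in self.restraint_terms]
        )
        return FreeEnergyValue(value=value, error=error, label=self.label or "ABFE total")


def combine_abfe(
    site_leg: AlchemicalLegResult | None,
    reference_leg: AlchemicalLegResult | None,
    restraint_terms: Sequence[FreeEnergyValue] = (),
    label: str = "",
) -> AbsoluteBindingCycle:
    """Assemble an absolute-binding cycle; missing legs raise IncompleteCycleError."""
    if site_leg is None or reference_leg is None:
        missing = "site" if site_leg is None else "reference"
        raise IncompleteCycleError(f"cycle is missing its {missing} leg")
    return AbsoluteBindingCycle(
        site_leg=site_leg,
        reference_leg=reference_leg,
        restraint_terms=tuple(restraint_terms),
        label=label,
    )


def replicate_statistics(results: Sequence[AlchemicalLegResult | FreeEnergyValue]) -> FreeEnergyValue:
    """Mean ± sample SD over replicate estimates (the replicate-reporting rule)."""
    if len(results) < 2:
        raise ValueError("replicate statistics require at least two replicates")
    values = np.array(
        [r.delta_g if isinstance(r, AlchemicalLegResult) else r.value for r in results]
    )
    return FreeEnergyValue(
        value=float(values.mean()),
        error=float(values.std(ddof=1)),
        label="replicate mean",
    )


@dataclass(frozen=True)
class InversePerturbationReport:
    """Forward/reverse perturbation consistency: ΔΔG_fwd + ΔΔG_rev ≈ 0."""

    forward: FreeEnergyValue
    reverse: FreeEnergyValue
    discrepancy: float
    combined_error: float
    consistent: bool

    def summary(self) -> str:
        return (
            f"inverse perturbation check: forward {self.forward.value:+.3f} ± "
            f"{self.forward.error:.3f}, reverse {self.reverse.value:+.3f} ± "
            f"{self.reverse.error:.3f} kJ/mol\n"
            f"  |forward + reverse| = {self.discrepancy:.3f} "
            f"(combined error {self.combined_error:.3f}) -> "
            + ("consistent" if self.consistent else "FLAGGED")
        )


def check_inverse_perturbation(
    forward: PerturbationCycle | FreeEnergyValue,
    reverse: PerturbationCycle | FreeEnergyValue,
) -> InversePerturbationReport:
    """Check that inverse perturbations have equal magnitude and opposite sign."""
    f = forward.ddg if isinstance(forward, PerturbationCycle) else forward
    r = reverse.ddg if isinstance(reverse, PerturbationCycle) else reverse
    disc = abs(f.value + r.value)
    err = quadrature_error([f.error, r.error])
    return InversePerturbationReport(
        forward=f, reverse=r, discrepancy=float(disc), combined_error=float(err),
        consistent=bool(disc <= err),
    )
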