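"""Potential-of-mean-force reconstruction from umbrella-sampling windows.

The estimator is the weighted histogram analysis method (WHAM): biased
reaction-coordinate samples from harmonically restrained windows are pooled
into a histogram and the unbiased probability per bin together with the
per-window free-energy constants are iterated to self-consistency,

    p_b  ∝  C_b / Σ_i N_i exp(β f_i) exp(−β w_i(x_b)),
    f_i  =  −kT ln Σ_b p_b exp(−β w_i(x_b)),

with w_i(x) = ½ k_i (x − c_i)² the window bias.  The PMF is −kT ln p_b,
anchored so its minimum over a reference interval (by default the last 10 %
of the sampled range, taken as the unbound plateau) is zero.  Errors come
from a Bayesian bootstrap: Dirichlet(1,…,1) weights over complete windows
re-weight the histograms, the profile is re-solved per round, and per-bin
standard deviations over rounds are reported.

`WHAM` is the model object; `WHAM.fit()` returns a :class:`WHAMResult`
carrying the profile, diagnostics and error machinery.  The module-level
functions (`solve_wham`, `bootstrap_pmf`, `binding_free_energy`,
`convergence_series`) are thin wrappers over that pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import kt_kj
from .cycles import FreeEnergyValue, quadrature_error

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "WHAM",
    "WHAMResult",
    "WHAMConvergenceError",
    "solve_wham",
    "bootstrap_pmf",
    "binding_free_energy",
    "convergence_series",
    "profile_deviation",
]


class WHAMConvergenceError(RuntimeError):
    """Raised when the self-consistent iteration does not reach tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class UmbrellaWindow:
    """One umbrella window: a harmonic bias and its reaction-coordinate samples.

    Parameters
    ----------
    center : float
        Bias center on the reaction coordinate (nm).
    force_constant : float
        Harmonic bias stiffness (kJ·mol⁻¹·nm⁻²); zero means unbiased sampling.
    temperature : float
        Simulation temperature (K).  Required per window — coarse-grained and
        atomistic datasets in this problem run at different temperatures.
    samples : array
        Reaction-coordinate time series (nm).
    times : array, optional
        Sample times (ns); defaults to the sample index.
    equilibration_cutoff : float
        Samples with time < cutoff are discarded before analysis (the
        equilibration discard; 0 by default for synthetic data).
    """

    center: float
    force_constant: float
    temperature: float
    samples: np.ndarray
    times: np.ndarray | None = None
    equilibration_cutoff: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.force_constant < 0:
            raise ValueError("force_constant must be nonnegative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.times is None:
            self.times = np.arange(self.samples.size, dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != self.samples.shape:
                raise ValueError("times and samples must have equal length")
        if self.production_samples.size < 1:
            raise ValueError("no samples remain after the equilibration discard")

    @property
    def production_samples(self) -> np.ndarray:
        """Samples surviving the equilibration discard."""
        return self.samples[self.times >= self.equilibration_cutoff]

    def bias(self, x: np.ndarray) -> np.ndarray:
        """Harmonic bias energy ½k(x − c)² (kJ·mol⁻¹) at positions x."""
        return 0.5 * self.force_constant * (np.asarray(x) - self.center) ** 2


@dataclass
class PMFProfile:
    """A reconstructed free-energy profile with per-bin errors.

    Bins never visited by any window carry NaN free energy (flagged, not
    interpolated); downstream operations skip them.
    """

    bin_centers: np.ndarray
    free_energy: np.ndarray
    error: np.ndarray
    anchor_region: tuple[float, float]
    sample_counts: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.bin_centers)
        for name in ("free_energy", "error", "sample_counts"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must match bin_centers in length")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin_centers must be strictly increasing")
        if np.any(np.asarray(self.error)[np.isfinite(self.error)] < 0):
            raise ValueError("errors must be nonnegative")

    @property
    def defined(self) -> np.ndarray:
        """Mask of bins with a defined (non-flagged) free energy."""
        return np.isfinite(self.free_energy)

    def region_mask(self, interval: tuple[float, float]) -> np.ndarray:
        lo, hi = min(interval), max(interval)
        return (self.bin_centers >= lo) & (self.bin_centers <= hi) & self.defined

    def value_at(self, x: float) -> float:
        """Free energy of the nearest defined bin to coordinate x."""
        idx = np.where(self.defined)[0]
        if idx.size == 0:
            raise ValueError("profile has no defined bins")
        j = idx[np.argmin(np.abs(self.bin_centers[idx] - x))]
        return float(self.free_energy[j])

    def local_value(self, x: float, half_width: float = 0.05) -> float:
        """Free energy at x from a local quadratic fit over ±half_width.

        Reading a stationary point (a well bottom or barrier top) off the
        raw binned profile with min/max is biased by bin noise by
        construction; a small quadratic fit around the point is unbiased to
        leading order.  Falls back to the nearest defined bin when fewer
        than three defined bins fall in the fit interval.
        """
        mask = self.region_mask((x - half_width, x + half_width))
        if mask.sum() < 3:
            return self.value_at(x)
        coeffs = np.polyfit(self.bin_centers[mask] - x, self.free_energy[mask], 2)
        return float(coeffs[2])

    def barrier_height(self, region: tuple[float, float] | None = None) -> float:
        """max − min of the profile over ``region`` (default: all defined bins)."""
        mask = self.defined if region is None else self.region_mask(region)
        if not mask.any():
            raise ValueError("no defined bins in the requested region")
        g = self.free_energy[mask]
        return float(np.max(g) - np.min(g))

    def anchored(self, region: tuple[float, float] | None = None) -> "PMFProfile":
        """Copy shifted so the minimum over the anchor region is zero."""
        region = region or self.anchor_region
        mask = self.region_mask(region)
        if not mask.any():
            raise ValueError(f"anchor region {region} contains no defined bins")
        shift = float(np.min(self.free_energy[mask]))
        return PMFProfile(
            bin_centers=self.bin_centers.copy(),
            free_energy=self.free_energy - shift,
            error=self.error.copy(),
            anchor_region=region,
            sample_counts=self.sample_counts.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "free_energy": self.free_energy,
                "error": self.error,
                "count": self.sample_counts,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def plot(self, ax=None, label: str | None = None):
        """Profile with a shaded ±1σ band.  Returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.defined
        ax.plot(self.bin_centers[m], self.free_energy[m], label=label)
        ax.fill_between(
            self.bin_centers[m],
            self.free_energy[m] - self.error[m],
            self.free_energy[m] + self.error[m],
            alpha=0.3,
        )
        ax.set_xlabel("reaction coordinate (nm)")
        ax.set_ylabel("PMF (kJ/mol)")
        if label:
            ax.legend()
        return ax


class WHAM:
    """Weighted-histogram model over a set of umbrella windows.

    Parameters
    ----------
    windows : sequence of UmbrellaWindow
        All windows must share a temperature.
    n_bins : int
        Histogram bins over the pooled sampled range (default 200).
    bin_range : (float, float), optional
        Explicit histogram range; default is the pooled sample min/max.
    anchor_region : (float, float), optional
        Interval over which the profile minimum is set to zero; default is
        the last 10 % of the coordinate range.
    """

    def __init__(
        self,
        windows: Sequence[UmbrellaWindow],
        n_bins: int = 200,
        bin_range: tuple[float, float] | None = None,
        anchor_region: tuple[float, float] | None = None,
    ):
        if len(windows) < 1:
            raise ValueError("at least one umbrella window is required")
        temps = {w.temperature for w in windows}
        if len(temps) > 1:
            raise ValueError(f"windows must share a temperature, got {sorted(temps)}")
        self.windows = list(windows)
        self.temperature = windows[0].temperature
        self.kt = kt_kj(self.temperature)
        self.n_bins = int(n_bins)

        pooled = np.concatenate([w.production_samples for w in self.windows])
        if bin_range is None:
            lo, hi = float(pooled.min()), float(pooled.max())
            if lo == hi:
                raise ValueError("pooled samples span a single point; cannot bin")
        else:
            lo, hi = map(float, bin_range)
        self.edges = np.linspace(lo, hi, self.n_bins + 1)
        self.bin_centers = 0.5 * (self.edges[:-1] + self.edges[1:])
        if anchor_region is None:
            anchor_region = (hi - 0.1 * (hi - lo), hi)
        self.anchor_region = anchor_region

        # per-window histogram counts over the common bins
        self.counts = np.stack(
            [np.histogram(w.production_samples, bins=self.edges)[0] for w in self.windows]
        ).astype(float)
        self.n_samples = self.counts.sum(axis=1)  # samples landing inside the range
        # bias Boltzmann factor per window per bin, exp(-beta * w_i(x_b))
        bias = np.stack([w.bias(self.bin_centers) for w in self.windows])
        with np.errstate(under="ignore"):
            self._bias_boltz = np.exp(-bias / self.kt)

        if np.count_nonzero(self.counts.sum(axis=0)) < 2:
            raise ValueError("pooled samples must span more than one bin")

        self.overlap = self._adjacent_overlap()
        if len(self.windows) > 1 and np.any(self.overlap == 0):
            warnings.warn(
                "zero histogram overlap between adjacent windows; the profile "
                "may be disconnected",
                RuntimeWarning,
                stacklevel=2,
            )

    def _adjacent_overlap(self) -> np.ndarray:
        """Histogram overlap fraction for windows adjacent in center order."""
        order = np.argsort([w.center for w in self.windows])
        h = self.counts[order]
        norms = h.sum(axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        p = h / norms
        return np.minimum(p[:-1], p[1:]).sum(axis=1)

    def fit(
        self,
        tolerance: float = 1e-6,
        max_iterations: int = 100_000,
        initial_constants: np.ndarray | None = None,
        counts: np.ndarray | None = None,
        weights: np.ndarray | None = None,
    ) -> "WHAMResult":
        """Iterate the WHAM equations to self-consistency.

        ``tolerance`` is the maximum change in the window free-energy
        constants (kJ·mol⁻¹) accepted as converged.  ``counts``/``weights``
        override the stored histograms (used by the bootstrap).  Raises
        :class:`WHAMConvergenceError` when max_iterations is exhausted.
        """
        c = self.counts if counts is None else counts
        if weights is not None:
            c = c * np.asarray(weights, dtype=float)[:, None]
        n_i = c.sum(axis=1)
        pooled = c.sum(axis=0)
        occupied = pooled > 0

        f = (
            np.zeros(len(self.windows))
            if initial_constants is None
            else np.array(initial_constants, dtype=float)
        )
        kt = self.kt
        B = self._bias_boltz  # (n_windows, n_bins)
        residual = np.inf
        with np.errstate(divide="ignore", invalid="ignore", under="ignore"):
            for iteration in range(1, max_iterations + 1):
                denom = (n_i[:, None] * np.exp(f / kt)[:, None] * B).sum(axis=0)
                p = np.where(occupied, pooled / denom, 0.0)
                z = (B * p[None, :]).sum(axis=1)
                f_new = -kt * np.log(z)
                f_new -= f_new[0]
                residual = float(np.max(np.abs(f_new - f)))
                f = f_new
                if residual < tolerance:
                    break
            else:
                raise WHAMConvergenceError(
                    f"WHAM did not converge within {max_iterations} iterations "
                    f"(last residual {residual:.3e} kJ/mol)",
                    residual,
                )
            pmf = np.where(occupied, -kt * np.log(p), np.nan)

        # flag interior empty bins explicitly (exterior ones are out of range)
        interior_empty = ~occupied
        if interior_empty.any():
            first, last = np.where(occupied)[0][[0, -1]]
            interior_empty &= (np.arange(self.n_bins) > first) & (np.arange(self.n_bins) < last)

        profile = PMFProfile(
            bin_centers=self.bin_centers.copy(),
            free_energy=pmf,
            error=np.zeros(self.n_bins),
            anchor_region=self.anchor_region,
            sample_counts=pooled,
        ).anchored()
        return WHAMResult(
            model=self,
            profile=profile,
            window_constants=f,
            n_iterations=iteration,
            residual=residual,
            flagged_bins=np.where(interior_empty)[0],
        )


@dataclass
class WHAMResult:
    """Fitted WHAM solution: profile, window constants, diagnostics."""

    model: WHAM
    profile: PMFProfile
    window_constants: np.ndarray
    n_iterations: int
    residual: float
    flagged_bins: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def bootstrap_error(
        self,
        n_rounds: int = 2000,
        seed: int | None = None,
        scheme: str = "window",
        tolerance: float = 1e-6,
        max_iterations: int = 100_000,
    ) -> np.ndarray:
        """Bayesian-bootstrap per-bin error of the profile.

        ``scheme='window'`` (default) draws Dirichlet(1,…,1) weights over
        complete windows and re-weights whole histograms, matching the
        complete-histogram bootstrap of gmx wham; ``scheme='sample'``
        multinomially resamples data points within each window.  Each round
        is re-solved (warm-started from the full-data constants) and
        anchored identically before the per-bin standard deviation is taken.
        The result is stored on ``profile.error`` and returned.
        """
        if n_rounds < 2:
            raise ValueError("n_rounds must be at least 2")
        if scheme not in ("window", "sample"):
            raise ValueError(f"unknown bootstrap scheme {scheme!r}")
        rng = np.random.default_rng(seed)
        m = self.model
        k = len(m.windows)
        rounds = np.empty((n_rounds, m.n_bins))
        for r in range(n_rounds):
            if scheme == "window":
                weights = rng.dirichlet(np.ones(k)) * k
                res = m.fit(
                    tolerance=tolerance,
                    max_iterations=max_iterations,
                    initial_constants=self.window_constants,
                    weights=weights,
                )
            else:
                counts = np.stack(
                    [
                        rng.multinomial(int(n), c / n) if (n := c.sum()) > 0 else c
                        for c in m.counts
                    ]
                ).astype(float)
                res = m.fit(
                    tolerance=tolerance,
                    max_iterations=max_iterations,
                    initial_constants=self.window_constants,
                    counts=counts,
                )
            rounds[r] = res.profile.free_energy
        err = np.full(m.n_bins, np.nan)
        defined = self.profile.defined
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            err[defined] = np.nanstd(rounds[:, defined], axis=0, ddof=1)
        self.profile.error = err
        return err

    def summary(self) -> str:
        p = self.profile
        m = p.defined
        lines = [
            "WHAM fit",
            f"  windows: {len(self.model.windows)}  bins: {self.model.n_bins}"
            f"  T = {self.model.temperature:g} K",
            f"  iterations: {self.n_iterations}  residual: {self.residual:.2e} kJ/mol",
            f"  coordinate range: [{p.bin_centers[0]:.3f}, {p.bin_centers[-1]:.3f}] nm",
            f"  anchor region: [{p.anchor_region[0]:.3f}, {p.anchor_region[1]:.3f}] nm",
            f"  PMF range (defined bins): {np.nanmin(p.free_energy):.2f} .. "
            f"{np.nanmax(p.free_energy):.2f} kJ/mol",
            f"  flagged interior empty bins: {len(self.flagged_bins)}",
        ]
        if len(self.model.windows) > 1:
            lines.append(
                f"  adjacent-window overlap: min {self.model.overlap.min():.3f}, "
                f"median {np.median(self.model.overlap):.3f}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers


def solve_wham(
    windows: Sequence[UmbrellaWindow],
    n_bins: int = 200,
    tolerance: float = 1e-6,
    max_iterations: int = 100_000,
    anchor_region: tuple[float, float] | None = None,
    bin_range: tuple[float, float] | None = None,
) -> PMFProfile:
    """Solve WHAM over the windows and return the anchored profile."""
    model = WHAM(windows, n_bins=n_bins, bin_range=bin_range, anchor_region=anchor_region)
    return model.fit(tolerance=tolerance, max_iterations=max_iterations).profile


def bootstrap_pmf(
    windows: Sequence[UmbrellaWindow],
    n_rounds: int = 2000,
    seed: int | None = None,
    n_bins: int = 200,
    tolerance: float = 1e-6,
    scheme: str = "window",
    anchor_region: tuple[float, float] | None = None,
) -> np.ndarray:
    """Per-bin Bayesian-bootstrap error of the WHAM profile."""
    model = WHAM(windows, n_bins=n_bins, anchor_region=anchor_region)
    result = model.fit(tolerance=tolerance)
    return result.bootstrap_error(n_rounds=n_rounds, seed=seed, scheme=scheme, tolerance=tolerance)


def binding_free_energy(
    profile: PMFProfile,
    bound_region: tuple[float, float],
    reference_region: tuple[float, float],
) -> FreeEnergyValue:
    """Well depth of a binding region relative to a reference plateau.

    value = min PMF over ``bound_region`` − mean PMF over
    ``reference_region`` (direction reference → bound); the error combines
    the bin error at the minimum with the quadrature-of-the-mean error of
    the reference bins.
    """
    bmask = profile.region_mask(bound_region)
    rmask = profile.region_mask(reference_region)
    if not bmask.any() or not rmask.any():
        raise ValueError("region does not intersect any defined profile bin")
    bidx = np.where(bmask)[0][np.argmin(profile.free_energy[bmask])]
    ref_vals = profile.free_energy[rmask]
    ref_errs = profile.error[rmask]
    value = float(profile.free_energy[bidx] - ref_vals.mean())
    ref_err = quadrature_error(ref_errs[np.isfinite(ref_errs)]) / max(rmask.sum(), 1)
    bin_err = profile.error[bidx] if np.isfinite(profile.error[bidx]) else 0.0
    return FreeEnergyValue(
        value=value,
        error=quadrature_error([bin_err, ref_err]),
        label="binding",
        direction=("reference", "bound"),
    )


def profile_deviation(
    a: PMFProfile,
    b: PMFProfile,
    min_count_fraction: float = 0.25,
) -> float:
    """Max |ΔPMF| between two profiles over well-sampled shared bins.

    Profiles are defined up to an additive constant, so the mean offset over
    the compared bins is removed first.  Bins count as well-sampled when both
    profiles hold at least ``min_count_fraction`` of their median positive
    bin count; sparse edge bins would otherwise dominate the metric with
    pure shot noise.
    """
    both = a.defined & b.defined
    for p in (a, b):
        counts = p.sample_counts[p.sample_counts > 0]
        both &= p.sample_counts >= min_count_fraction * np.median(counts)
    if not both.any():
        raise ValueError("profiles share no well-sampled bins")
    d = a.free_energy[both] - b.free_energy[both]
    return float(np.max(np.abs(d - d.mean())))


def convergence_series(
    windows: Sequence[UmbrellaWindow],
    time_blocks: int,
    n_bins: int = 200,
    tolerance: float = 1e-6,
) -> tuple[list[PMFProfile], float]:
    """Profiles on cumulative time prefixes, plus a convergence metric.

    The windows are cut into ``time_blocks`` equal-duration prefixes; WHAM is
    solved on each cumulative prefix over a common bin range.  The metric is
    :func:`profile_deviation` between the last two prefixes (offset-aligned
    max |ΔPMF| over well-sampled shared bins).
    """
    if time_blocks < 2:
        raise ValueError("time_blocks must be at least 2")
    for w in windows:
        if w.production_samples.size < time_blocks:
            raise ValueError("every window needs at least `time_blocks` samples")

    pooled = np.concatenate([w.production_samples for w in windows])
    bin_range = (float(pooled.min()), float(pooled.max()))
    profiles: list[PMFProfile] = []
    for block in range(1, time_blocks + 1):
        cut_windows = []
        for w in windows:
            t = w.times[w.times >= w.equilibration_cutoff]
            s = w.production_samples
            t0, t1 = t.min(), t.max()
            t_cut = t0 + (t1 - t0) * block / time_blocks
            keep = t <= t_cut
            cut_windows.append(
                UmbrellaWindow(
                    center=w.center,
                    force_constant=w.force_constant,
                    temperature=w.temperature,
                    samples=s[keep],
                    times=t[keep],
                )
            )
        profiles.append(
            solve_wham(cut_windows, n_bins=n_bins, tolerance=tolerance, bin_range=bin_range)
        )
    metric = profile_deviation(profiles[-2], profiles[-1])
    return profiles, metric
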