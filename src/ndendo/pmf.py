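"""Umbrella-sampling free energies: WHAM, PMF depth, unit adhesion strength.

A ladder of harmonic umbrella windows ``U_w(z) = k/2 (z - z0_w)^2`` biases
sampling along the slab-membrane distance ``z``.  The weighted histogram
analysis method (WHAM) combines the biased window histograms into one
unbiased potential of mean force F(z).  The unit adhesion strength is the
PMF depth divided by the slab contact area:

    k_ad = depth / (L_x * L_y)     [kcal/mol/nm^2]

which the continuum wrapping model consumes with a negative sign for
favorable adhesion (see :mod:`ndendo.wrapping`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import kbt_kcal


class WhamError(RuntimeError):
    pass


class WindowOverlapError(WhamError):
    """Adjacent umbrella windows share no populated histogram bin."""


class WhamConvergenceError(WhamError):
    pass


@dataclass
class UmbrellaWindowSet:
    """Harmonic umbrella windows along a 1-D reaction coordinate.

    Either ``samples`` (per-window arrays of sampled z values, nm) or a
    pre-binned histogram (``bin_edges`` plus per-window ``counts``) must
    be provided.
    """

    centers: np.ndarray                     # (W,) bias centers z0, nm
    force_constant: float                   # kcal/mol/nm^2
    temperature: float                      # K
    samples: list | None = None             # W arrays of z values
    bin_edges: np.ndarray | None = None     # (B+1,) shared histogram edges
    counts: np.ndarray | None = None        # (W, B) per-window counts

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("bias centers must be strictly increasing")
        if self.force_constant <= 0:
            raise ValueError("force_constant must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.samples is None and (self.bin_edges is None or self.counts is None):
            raise ValueError("provide samples or (bin_edges, counts)")
        if self.samples is not None:
            self.samples = [np.asarray(s, dtype=float) for s in self.samples]
            if len(self.samples) != len(self.centers):
                raise ValueError("one sample array per window required")
            if any(len(s) == 0 for s in self.samples):
                raise ValueError("every window needs at least one sample")
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=float)
            if self.counts.shape[0] != len(self.centers):
                raise ValueError("one count row per window required")
            if np.any(self.counts.sum(axis=1) == 0):
                raise ValueError("every window needs at least one count")

    @property
    def n_windows(self) -> int:
        return len(self.centers)


@dataclass
class PMFProfile:
    """Potential of mean force on a reaction-coordinate grid.

    ``free_energy`` is min-referenced (its minimum over populated bins is
    zero) unless stated otherwise by ``reference_convention``.  Bins with
    no sampling support hold ``nan``.
    """

    z_grid: np.ndarray                      # (B,) bin centers, nm
    free_energy: np.ndarray                 # (B,) kcal/mol
    error: np.ndarray | None = None
    reference_convention: str = "min-referenced"
    converged: bool = True
    n_iterations: int = 0
    window_free_energies: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if np.any(np.diff(self.z_grid) <= 0):
            raise ValueError("z_grid must be strictly ascending")


@dataclass(frozen=True)
class SlabSpec:
    """Rectangular slab whose bottom face is the membrane contact area."""

    length_x: float  # nm
    length_y: float  # nm

    def __post_init__(self) -> None:
        if self.length_x <= 0 or self.length_y <= 0:
            raise ValueError("slab edge lengths must be positive")

    @property
    def area(self) -> float:
        return self.length_x * self.length_y


@dataclass(frozen=True)
class AdhesionEstimate:
    depth: float    # kcal/mol
    k_ad: float     # kcal/mol/nm^2 (magnitude)
    slab: SlabSpec


def _default_edges(windows: UmbrellaWindowSet, n_bins: int) -> np.ndarray:
    kbt = kbt_kcal(windows.temperature)
    sigma = np.sqrt(kbt / windows.force_constant)
    lo = windows.centers.min() - 3 * sigma
    hi = windows.centers.max() + 3 * sigma
    return np.linspace(lo, hi, n_bins + 1)


def wham_solve(
    windows: UmbrellaWindowSet,
    n_bins: int = 200,
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> PMFProfile:
    """Self-consistent WHAM solution for the unbiased PMF.

    Iterates the two coupled equations on a shared histogram grid

        p_b  proportional to  (sum_w n_wb) / (sum_w N_w exp(-beta (U_w(z_b) - f_w)))
        f_w  =  -kBT ln sum_b p_b exp(-beta U_w(z_b))

    (evaluated in log space) until the largest change in any window free
    energy ``f_w`` drops below ``tol`` (kcal/mol).  The returned profile
    is ``F(z_b) = -kBT ln p_b``, shifted so its minimum is zero.

    Raises
    ------
    WindowOverlapError
        If a pair of adjacent windows shares no populated bin.
    WhamConvergenceError
        If ``max_iter`` iterations do not reach ``tol``.
    """
    if n_bins < windows.n_windows:
        raise ValueError("n_bins must be at least the number of windows")
    kbt = kbt_kcal(windows.temperature)
    beta = 1.0 / kbt

    if windows.samples is not None:
        edges = _default_edges(windows, n_bins)
        counts = np.stack(
            [np.histogram(s, bins=edges)[0].astype(float) for s in windows.samples]
        )
    else:
        edges = np.asarray(windows.bin_edges, dtype=float)
        counts = windows.counts

    z = 0.5 * (edges[:-1] + edges[1:])
    # adjacent-window overlap check on populated bins
    populated = counts > 0
    for w in range(windows.n_windows - 1):
        if not np.any(populated[w] & populated[w + 1]):
            raise WindowOverlapError(
                "no shared populated bin between windows at "
                f"z0={windows.centers[w]:.4g} and z0={windows.centers[w + 1]:.4g} nm"
            )

    n_w = counts.sum(axis=1)                     # (W,) samples per window
    n_b = counts.sum(axis=0)                     # (B,) total counts per bin
    bias = 0.5 * windows.force_constant * (z[None, :] - windows.centers[:, None]) ** 2
    log_nw = np.log(n_w)
    support = n_b > 0
    log_nb = np.where(support, np.log(np.where(support, n_b, 1.0)), -np.inf)

    f = np.zeros(windows.n_windows)              # window free energies, kcal/mol
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # log denominator per bin: logsumexp_w [ ln N_w + beta f_w - beta U_wb ]
        log_den = logsumexp(log_nw[:, None] + beta * (f[:, None] - bias), axis=0)
        log_p = log_nb - log_den                 # unnormalized
        f_new = -kbt * logsumexp(log_p[None, :] - beta * bias, axis=1)
        f_new -= f_new[0]                        # fix the gauge
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise WhamConvergenceError(
            f"WHAM did not converge below {tol} kcal/mol in {max_iter} iterations"
        )

    free = np.full_like(log_p, np.nan)
    free[support] = -kbt * log_p[support]
    free -= np.nanmin(free)
    return PMFProfile(
        z_grid=z, free_energy=free,
        converged=converged, n_iterations=it, window_free_energies=f,
    )


def pmf_depth(profile: PMFProfile, bulk_fraction: float = 0.1) -> float:
    """Well depth: bulk plateau mean minus the profile minimum (kcal/mol).

    The bulk reference is the mean free energy over the populated bins in
    the top ``bulk_fraction`` of the z range (the large-z plateau, far
    from the membrane).
    """
    if not (0 < bulk_fraction <= 1):
        raise ValueError("bulk_fraction must be in (0, 1]")
    finite = np.isfinite(profile.free_energy)
    if not np.any(finite):
        raise ValueError("profile has no populated bins")
    z = profile.z_grid
    z_cut = z.max() - bulk_fraction * (z.max() - z.min())
    bulk = finite & (z >= z_cut)
    if not np.any(bulk):
        raise ValueError("no populated bins in the bulk region")
    depth = float(np.mean(profile.free_energy[bulk]) - np.nanmin(profile.free_energy))
    return max(depth, 0.0)


def k_ad_from_depth(depth: float, slab: SlabSpec) -> AdhesionEstimate:
    """Unit adhesion strength: free-energy depth per slab contact area."""
    if depth < 0:
        raise ValueError("depth must be non-negative")
    return AdhesionEstimate(depth=depth, k_ad=depth / slab.area, slab=slab)


def average_k_ad(values) -> float:
    """Arithmetic mean of unit adhesion strengths (kcal/mol/nm^2)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one k_ad value")
    return float(values.mean())


def bootstrap_depth(
    windows: UmbrellaWindowSet,
    n_boot: int = 200,
    seed: int = 0,
    bulk_fraction: float = 0.1,
    **wham_kwargs,
) -> tuple[float, float]:
    """Depth estimate with a bootstrap standard error.

    Each replicate resamples every window's z values with replacement,
    re-runs WHAM and re-measures the depth.  Returns ``(depth, se)``
    where ``depth`` is from the full data set.
    """
    if windows.samples is None:
        raise ValueError("bootstrap requires raw per-window samples")
    depth0 = pmf_depth(wham_solve(windows, **wham_kwargs), bulk_fraction)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        resampled = [s[rng.integers(0, len(s), size=len(s))] for s in windows.samples]
        wset = UmbrellaWindowSet(
            centers=windows.centers, force_constant=windows.force_constant,
            temperature=windows.temperature, samples=resampled,
        )
        reps[b] = pmf_depth(wham_solve(wset, **wham_kwargs), bulk_fraction)
    return depth0, float(reps.std(ddof=1))
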