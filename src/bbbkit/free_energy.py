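"""1D umbrella-sampling free-energy profiles (WHAM) with bootstrap errors.

Umbrella sampling restrains a reaction coordinate xi (here: the position of
a solute along the normal of a lipid bilayer) in a series of harmonically
biased windows.  The weighted histogram analysis method (WHAM) combines the
biased window histograms into one unbiased probability profile p(xi) by
solving the self-consistent equations

    p_j = sum_i n_ij / sum_i N_i exp((f_i - w_i(xi_j)) / kT)
    f_i = -kT ln sum_j p_j exp(-w_i(xi_j) / kT)

where n_ij are window histogram counts, N_i window sample counts and
w_i(xi) = kappa_i / 2 (xi - c_i)^2 the bias.  The free-energy profile is
G = -kT ln p, shifted so its minimum is zero (min-zero convention) or so a
designated bulk region averages zero (bulk-zero).

Statistical errors follow the Bayesian bootstrap of complete histograms:
whole windows are reweighted with flat-Dirichlet weights and WHAM re-solved
per replica; per-bin standard deviations are reported after aligning every
replica to the chosen reference convention.
"""

from __future__ import annotations

import glob as _glob
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

#: kT at 310 K in kJ/mol (k_B = 0.0083144626 kJ/mol/K).
KT_310K = 2.5775

#: Fraction of each window's samples discarded as equilibration
#: (first 1/8, mirroring discarding 5 of 40 ns of sampling).
DEFAULT_EQUILIBRATION_FRACTION = 0.125


@dataclass
class UmbrellaWindow:
    """One biased window: harmonic bias centre/force constant plus samples.

    ``force_constant`` is in kJ mol^-1 nm^-2, samples and centre in nm.
    """

    center: float
    force_constant: float
    samples: np.ndarray

    def __init__(self, center: float, force_constant: float, samples):
        if force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        samples = np.asarray(samples, dtype=float)
        if samples.size == 0:
            raise ValueError("window has no samples")
        self.center = float(center)
        self.force_constant = float(force_constant)
        self.samples = samples

    def bias(self, xi) -> np.ndarray:
        return 0.5 * self.force_constant * (np.asarray(xi) - self.center) ** 2


@dataclass
class FreeEnergyProfile:
    bin_centers: np.ndarray
    g: np.ndarray                 # kJ/mol
    g_error: np.ndarray | None    # kJ/mol, bootstrap SD (None until estimated)
    kT: float
    reference: str = "min-zero"
    converged: bool = True
    n_iterations: int = 0

    def with_errors(self, errors: np.ndarray) -> "FreeEnergyProfile":
        return FreeEnergyProfile(self.bin_centers, self.g, np.asarray(errors),
                                 self.kT, self.reference, self.converged,
                                 self.n_iterations)

    def to_tsv(self) -> str:
        lines = ["xi_nm\tG_kJ_per_mol\terr_kJ_per_mol"]
        err = (np.full_like(self.g, np.nan) if self.g_error is None
               else self.g_error)
        for x, g, e in zip(self.bin_centers, self.g, err):
            lines.append(f"{x:.6g}\t{g:.6g}\t{e:.6g}")
        return "\n".join(lines) + "\n"


def _histogram_windows(windows: Sequence[UmbrellaWindow], n_bins: int,
                       equilibration: float,
                       bin_range: tuple[float, float] | None = None):
    if not windows:
        raise ValueError("need at least one window")
    trimmed = []
    for w in windows:
        start = int(len(w.samples) * equilibration)
        samples = w.samples[start:]
        if samples.size == 0:
            raise ValueError("window empty after equilibration discard")
        trimmed.append(samples)
    if bin_range is None:
        lo = min(s.min() for s in trimmed)
        hi = max(s.max() for s in trimmed)
    else:
        lo, hi = bin_range
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.array([np.histogram(s, bins=edges)[0] for s in trimmed],
                      dtype=float)
    return centers, counts


def _check_overlap(windows: Sequence[UmbrellaWindow], counts: np.ndarray) -> None:
    if len(windows) < 2:
        return
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((counts[a] > 0) & (counts[b] > 0)):
            raise ValueError(
                "insufficient window overlap between centres "
                f"{windows[a].center} and {windows[b].center}")


def _wham_core(counts: np.ndarray, bias: np.ndarray, weights: np.ndarray,
               kT: float, tol: float, max_iter: int):
    """Self-consistent WHAM iteration on precomputed histograms.

    counts: (n_windows, n_bins); bias: (n_windows, n_bins) in kJ/mol;
    weights: per-window multipliers (Bayesian bootstrap); tol in units of kT
    on the window free energies f_i.
    """
    wcounts = counts * weights[:, None]
    n_i = wcounts.sum(axis=1)               # weighted samples per window
    numer = wcounts.sum(axis=0)             # weighted counts per bin
    boltz = np.exp(-bias / kT)              # (windows, bins)
    f = np.zeros(len(n_i))                  # window free energies, kJ/mol
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        denom = (n_i * np.exp(f / kT)) @ boltz
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, numer / denom, 0.0)
        norm = p.sum()
        if norm <= 0:
            raise ValueError("empty histograms: cannot run WHAM")
        p /= norm
        f_new = -kT * np.log(np.maximum(boltz @ p, 1e-300))
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol * kT:
            converged = True
            break
    return p, f, converged, iteration


def wham_1d(windows: Sequence[UmbrellaWindow], n_bins: int = 200,
            kT: float = KT_310K, tol: float = 1e-6, max_iter: int = 100_000,
            equilibration: float = DEFAULT_EQUILIBRATION_FRACTION,
            reference: str = "min-zero",
            bulk_region: tuple[float, float] | None = None,
            ) -> FreeEnergyProfile:
    """Unbiased 1D free-energy profile from umbrella windows.

    Bins are uniform over the union of the sampled ranges.  The first
    ``equilibration`` fraction of each window's samples is discarded.
    Convergence requires max |delta f_i| < ``tol`` * kT; hitting
    ``max_iter`` flags the profile unconverged rather than raising.

    reference: "min-zero" shifts the profile minimum to zero; "bulk-zero"
    zeroes the mean over ``bulk_region``.
    """
    if kT <= 0:
        raise ValueError("kT must be positive")
    centers, counts = _histogram_windows(windows, n_bins, equilibration)
    _check_overlap(windows, counts)
    bias = np.array([w.bias(centers) for w in windows])
    p, _f, converged, iters = _wham_core(
        counts, bias, np.ones(len(windows)), kT, tol, max_iter)
    with np.errstate(divide="ignore"):
        g = -kT * np.log(p)
    g = _apply_reference(centers, g, reference, bulk_region)
    return FreeEnergyProfile(bin_centers=centers, g=g, g_error=None, kT=kT,
                             reference=reference, converged=converged,
                             n_iterations=iters)


def _apply_reference(centers, g, reference, bulk_region):
    finite = np.isfinite(g)
    if not np.any(finite):
        raise ValueError("profile has no finite bins")
    if reference == "min-zero":
        return g - np.min(g[finite])
    if reference == "bulk-zero":
        if bulk_region is None:
            raise ValueError("bulk-zero reference requires bulk_region")
        mask = finite & (centers >= bulk_region[0]) & (centers <= bulk_region[1])
        if not np.any(mask):
            raise ValueError("no finite bins inside bulk_region")
        return g - np.mean(g[mask])
    raise ValueError(f"unknown reference convention {reference!r}")


def bayesian_bootstrap(windows: Sequence[UmbrellaWindow], n_boot: int = 50,
                       seed: int = 0, n_bins: int = 200, kT: float = KT_310K,
                       tol: float = 1e-6, max_iter: int = 100_000,
                       equilibration: float = DEFAULT_EQUILIBRATION_FRACTION,
                       reference: str = "min-zero",
                       bulk_region: tuple[float, float] | None = None,
                       replica_seeds: Sequence[int] | None = None,
                       ) -> np.ndarray:
    """Per-bin bootstrap SD (kJ/mol) via Bayesian bootstrap of histograms.

    Each replica draws per-window weights from a flat Dirichlet (complete
    histograms reweighted, never individual samples), re-solves WHAM, and
    aligns the replica profile to the reference convention; the SD over
    replicas is returned.

    ``replica_seeds`` overrides the single ``seed`` with one seed per
    replica (length must equal ``n_boot``); identical entries give
    identical replicas, hence zero SD.
    """
    if len(windows) < 2:
        raise ValueError("need >= 2 windows to bootstrap")
    if n_boot < 2:
        raise ValueError("need n_boot >= 2")
    if replica_seeds is not None and len(replica_seeds) != n_boot:
        raise ValueError("replica_seeds must have length n_boot")
    rng = np.random.default_rng(seed)
    centers, counts = _histogram_windows(windows, n_bins, equilibration)
    _check_overlap(windows, counts)
    bias = np.array([w.bias(centers) for w in windows])
    profiles = []
    for b in range(n_boot):
        draw_rng = (rng if replica_seeds is None
                    else np.random.default_rng(replica_seeds[b]))
        weights = draw_rng.dirichlet(np.ones(len(windows))) * len(windows)
        p, _f, _conv, _ = _wham_core(counts, bias, weights, kT, tol, max_iter)
        with np.errstate(divide="ignore"):
            g = -kT * np.log(p)
        profiles.append(_apply_reference(centers, g, reference, bulk_region))
    stacked = np.array(profiles)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(np.where(np.isfinite(stacked), stacked, np.nan), axis=0)
    return sd


# ---------------------------------------------------------------------------
# Profile summaries

@dataclass(frozen=True)
class PMFSummary:
    """Scalar summaries of a membrane-permeation profile (all >= 0, kJ/mol).

    immersion_dg: bulk level minus the global well minimum (free-energy
    release on entering the bilayer); central_barrier: hump in the bilayer
    centre above the well; entry_barrier: highest point between the bulk
    edge and the well, relative to bulk (0 for monotone descent).
    """

    entry_barrier: float
    central_barrier: float
    immersion_dg: float


def profile_summary(profile: FreeEnergyProfile,
                    bulk_region: tuple[float, float],
                    center_region: tuple[float, float]) -> PMFSummary:
    """Barrier heights and immersion free energy from a 1D profile.

    ``bulk_region`` selects bins representing the aqueous phase,
    ``center_region`` bins around the bilayer midplane.  All summaries are
    invariant to adding a constant to the profile.
    """
    x, g = profile.bin_centers, profile.g
    finite = np.isfinite(g)

    def region_mask(region):
        lo, hi = region
        mask = finite & (x >= lo) & (x <= hi)
        if not np.any(mask):
            raise ValueError(f"empty region {region}")
        return mask

    bulk = region_mask(bulk_region)
    center = region_mask(center_region)
    bulk_level = float(np.mean(g[bulk]))
    g_min = float(np.min(g[finite]))
    i_min = int(np.flatnonzero(finite)[np.argmin(g[finite])])
    immersion = max(0.0, bulk_level - g_min)
    central = max(0.0, float(np.max(g[center])) - g_min)
    # entry barrier: highest point between the bulk edge nearest the well
    # and the well itself, measured above the bulk level
    bulk_idx = np.flatnonzero(bulk)
    nearest_edge = bulk_idx[np.argmin(np.abs(bulk_idx - i_min))]
    lo, hi = sorted((nearest_edge, i_min))
    segment = g[lo:hi + 1]
    segment = segment[np.isfinite(segment)]
    entry = max(0.0, float(np.max(segment)) - bulk_level) if segment.size else 0.0
    return PMFSummary(entry_barrier=entry, central_barrier=central,
                      immersion_dg=immersion)


# ---------------------------------------------------------------------------
# File interfaces (xvg-like window files + metadata file)

def read_window_file(path) -> np.ndarray:
    """Two-column whitespace text (time, xi); '#'/'@' comment lines skipped."""
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "@")):
                continue
            parts = line.split()
            values.append(float(parts[1] if len(parts) > 1 else parts[0]))
    if not values:
        raise ValueError(f"no samples in window file {path}")
    return np.asarray(values)


def read_metadata_file(meta_path) -> list[UmbrellaWindow]:
    """Conventional WHAM metadata: lines of 'filename center force_constant'.

    Window-file paths are resolved relative to the metadata file.
    """
    import os

    windows = []
    base = os.path.dirname(os.fspath(meta_path))
    with open(meta_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fname, center, kappa = line.split()[:3]
            matches = sorted(_glob.glob(os.path.join(base, fname))) or [
                os.path.join(base, fname)]
            for m in matches:
                windows.append(UmbrellaWindow(center=float(center),
                                              force_constant=float(kappa),
                                              samples=read_window_file(m)))
    if not windows:
        raise ValueError(f"no windows listed in {meta_path}")
    return windows
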