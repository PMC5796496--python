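"""Chain diagnostics: autocorrelation times, mode switching, residual fits.

All diagnostics are pure functions of saved traces, so they can be
re-run offline from trace files.
"""

from __future__ import annotations

import warnings

import numpy as np


def autocorrelation(series: np.ndarray) -> np.ndarray:
    """Normalized autocorrelation function via FFT (biased estimator)."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    x = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    if acov[0] <= 0:
        return np.ones(n)
    return acov / acov[0]


def iat(series: np.ndarray) -> float:
    """Integrated autocorrelation time, >= 1.

    IAT = 1 + 2 sum_t rho_t, truncated by Geyer's initial positive
    sequence rule: successive pairs Gamma_t = rho_{2t} + rho_{2t+1} are
    summed while they stay positive.  A constant series has no
    information; its IAT is defined as the series length (ESS = 1) with
    a warning.  Values below 1 (antithetic chains) are clipped to 1.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 points to estimate IAT")
    if np.ptp(x) == 0:
        warnings.warn("constant series: IAT set to the series length", stacklevel=2)
        return float(n)
    rho = autocorrelation(x)
    total = 0.0
    t = 1
    while t + 1 < n:
        gamma = rho[t] + rho[t + 1]
        if gamma <= 0:
            break
        total += gamma
        t += 2
    return max(1.0, 1.0 + 2.0 * total)


def ess(series: np.ndarray) -> float:
    """Effective sample size, length / IAT (always <= length)."""
    return len(series) / iat(series)


def mode_switches(labels: np.ndarray) -> int:
    """Count transitions between distinct mode occupancies.

    ``labels`` assigns each iteration a mode label, with 0 (or any
    falsy/NaN value) meaning "in no mode"; those iterations are ignored,
    so A, none, B counts as one switch.
    """
    lab = np.asarray(labels, dtype=float)
    lab = lab[np.isfinite(lab)]
    lab = lab[lab != 0]
    if len(lab) < 2:
        return 0
    return int(np.count_nonzero(np.diff(lab) != 0))


def overall_efficiency(switch_count: int, wall_time: float) -> float:
    """Mode switches per unit wall time; a relative ranking only.

    Hardware-dependent: useful for comparing schemes run on the same
    machine, never as an absolute quantity.
    """
    if wall_time <= 0:
        raise ValueError("wall time must be positive")
    return switch_count / wall_time


def residual_matrix(r: np.ndarray, d: np.ndarray, phi_mean: np.ndarray) -> np.ndarray:
    """Observed VAF minus posterior mean VAF, per (variant, sample).

    Cells with zero depth are undefined and flagged NaN.
    """
    r = np.asarray(r, dtype=float)
    d = np.asarray(d, dtype=float)
    phi_mean = np.asarray(phi_mean, dtype=float)
    if r.shape != phi_mean.shape:
        if r.size != phi_mean.size:
            raise ValueError(
                f"shape mismatch: counts {r.shape} vs phi {phi_mean.shape}"
            )
        r = r.reshape(phi_mean.shape)
        d = d.reshape(phi_mean.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        obs = np.where(d > 0, r / np.where(d > 0, d, 1.0), np.nan)
    return obs - phi_mean


def find_modes(
    series: np.ndarray,
    grid: int = 512,
    rel_height: float = 0.05,
    min_mass: float = 0.02,
) -> list[dict]:
    """Locate separated modes of a scalar trace by kernel density peaks.

    A Gaussian KDE is evaluated on a regular grid; local maxima above
    ``rel_height`` of the global peak seed the modes, samples are
    assigned to the nearest peak (split at density valleys), and modes
    with less than ``min_mass`` of the samples are dropped.  Returns a
    list of dicts with keys ``location`` (mean of assigned samples),
    ``peak`` (grid position of the density peak) and ``mass``, sorted by
    location.
    """
    from scipy.stats import gaussian_kde

    x = np.asarray(series, dtype=float)
    if np.ptp(x) == 0:
        return [{"location": float(x[0]), "peak": float(x[0]), "mass": 1.0}]
    kde = gaussian_kde(x)
    lo, hi = x.min(), x.max()
    pad = 0.05 * (hi - lo)
    g = np.linspace(lo - pad, hi + pad, grid)
    dens = kde(g)
    peaks = [
        i
        for i in range(1, grid - 1)
        if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1] and dens[i] >= rel_height * dens.max()
    ]
    if not peaks:
        peaks = [int(np.argmax(dens))]
    # valleys between consecutive peaks define assignment boundaries
    bounds = [-np.inf]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(g[a + int(np.argmin(dens[a:b]))])
    bounds.append(np.inf)
    modes = []
    for t, pk in enumerate(peaks):
        sel = (x > bounds[t]) & (x <= bounds[t + 1])
        mass = sel.mean()
        if mass >= min_mass:
            modes.append(
                {"location": float(x[sel].mean()), "peak": float(g[pk]), "mass": float(mass)}
            )
    return sorted(modes, key=lambda m: m["location"])
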