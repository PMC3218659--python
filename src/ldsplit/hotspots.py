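"""Hotspot calling from a piecewise-constant recombination-rate map.

Hotspots are narrow intervals where the inferred population rate peaks:
local maxima of the map are located, a normal density (plus baseline) is
fitted to the surrounding 50-kb region, boundaries are extended to cover
the contiguous above-window-mean segments inside the smaller of the fitted
spans, overlapping calls are separated at the valley between their peaks,
and calls wider than 20 kb or with an average rate of at most 1 cM/Mb are
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .rates import RateProfile, rho_to_cm_per_mb

__all__ = [
    "PeakFit",
    "Hotspot",
    "DegenerateFitError",
    "find_peaks",
    "fit_peak",
    "delimit_hotspot",
    "resolve_overlaps",
    "call_hotspots",
    "write_hotspots_bed",
    "FWHM_FACTOR",
]

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))
FIT_WINDOW_BP = 50_000.0
MAX_WIDTH_BP = 20_000.0
MIN_AVG_RATE_CM_MB = 1.0


class DegenerateFitError(ValueError):
    """Raised when the peak-shape fit collapses (flat window, absurd sigma)."""


@dataclass(frozen=True)
class PeakFit:
    """Normal-density fit to a rate-map peak."""

    center: float  # bp, fitted mean
    sigma: float  # bp
    fit_window: tuple[float, float]

    @property
    def fwhm(self) -> float:
        return FWHM_FACTOR * self.sigma


@dataclass(frozen=True)
class Hotspot:
    """A called hotspot with fixed boundaries.

    ``strength`` is the ρ·kb sum over the spanned segments and
    ``avg_rate_cm_mb`` the width-averaged rate after ρ → cM/Mb conversion.
    """

    peak_center: float
    start: float
    end: float
    strength: float
    avg_rate_cm_mb: float

    @property
    def width(self) -> float:
        return self.end - self.start

    @property
    def interval(self) -> tuple[float, float]:
        return (self.start, self.end)

    def __post_init__(self) -> None:
        if not (self.start <= self.peak_center < self.end):
            raise ValueError("peak center must lie inside the hotspot")


def find_peaks(profile: RateProfile) -> list[float]:
    """Candidate peak centers: segments strictly above both neighbours.

    On a piecewise-constant map the derivative criterion becomes: a run of
    equal-rate segments flanked on both sides by lower rates.  A plateau
    contributes its midpoint; terminal runs are not peaks.  Centers are
    returned in coordinate order.
    """
    if profile.n_segments < 3:
        raise ValueError("need at least 3 segments to find peaks")
    rho = profile.rho_per_kb
    # run-length encode equal-rate plateaus
    change = np.flatnonzero(np.diff(rho) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(rho)]))
    centers = []
    for i in range(1, len(starts) - 1):
        left = rho[starts[i - 1]]
        right = rho[starts[i + 1]]
        val = rho[starts[i]]
        if val > left and val > right:
            lo = profile.segment_starts[starts[i]]
            hi = profile.segment_ends[ends[i] - 1]
            centers.append(0.5 * (lo + hi))
    return centers


def _window_values(profile: RateProfile, lo: float, hi: float, n: int = 256):
    x = np.linspace(lo, hi, n)
    idx = np.clip(
        np.searchsorted(profile.segment_ends, x, side="right"),
        0,
        profile.n_segments - 1,
    )
    return x, profile.rho_per_kb[idx]


def fit_peak(profile: RateProfile, center: float) -> PeakFit:
    """Least-squares normal-density + baseline fit on center ± 25 kb.

    Raises :class:`DegenerateFitError` when the window is flat or the
    fitted scale collapses to zero / exceeds the window.
    """
    lo, hi = profile.span
    if not (lo <= center < hi):
        raise ValueError(f"peak center {center} outside profile span")
    wlo = max(lo, center - FIT_WINDOW_BP / 2)
    whi = min(hi, center + FIT_WINDOW_BP / 2)
    x, y = _window_values(profile, wlo, whi)
    base0 = float(np.median(y))
    amp0 = float(y.max() - base0)
    if amp0 <= 1e-12 * max(base0, 1.0):
        raise DegenerateFitError(f"flat rate map around {center:.0f} bp")

    def model(x, amp, mu, sigma, base):
        return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + base

    try:
        popt, _ = curve_fit(
            model,
            x,
            y,
            p0=[amp0, center, 2000.0, base0],
            bounds=(
                [0.0, wlo, 1.0, 0.0],
                [np.inf, whi, FIT_WINDOW_BP, np.inf],
            ),
            maxfev=5000,
        )
    except RuntimeError as e:
        raise DegenerateFitError(f"peak fit failed near {center:.0f} bp: {e}") from e
    amp, mu, sigma, _ = popt
    if amp <= 1e-9 * max(base0, 1.0) or sigma <= 10.0 or sigma >= FIT_WINDOW_BP / 2:
        raise DegenerateFitError(
            f"degenerate peak fit near {center:.0f} bp (amp={amp:.3g}, "
            f"sigma={sigma:.3g})"
        )
    return PeakFit(center=float(mu), sigma=float(sigma), fit_window=(wlo, whi))


def delimit_hotspot(
    profile: RateProfile, fit: PeakFit, width_rule: str = "2sigma"
) -> tuple[float, float] | None:
    """Boundary rule: above-window-mean run around the peak.

    The span L is the smallest of 2·σ, the FWHM and 50 kb (with the
    alternative ``width_rule="2fwhm"`` reading, 2·FWHM replaces 2·σ).
    Within the length-L window centered at the fitted peak, the maximal
    contiguous run of segments containing the peak whose rate exceeds the
    length-weighted mean rate of the 50-kb fit region delimits the
    hotspot; boundaries snap to segment (SNP) coordinates.  Two
    refinements keep the rule meaningful on piecewise-flat maps: the
    reference mean is taken over the 50-kb fit region (a plateau filling
    its own span would otherwise be compared against itself alone), and
    a run that reaches the window edge keeps following the above-mean
    plateau beyond it (within the fit region), so that an over-wide
    plateau is measured at its real width and rejected by the width
    filter rather than truncated.  Returns None when no segment beats
    the mean (flat fit region).
    """
    if width_rule == "2sigma":
        L = min(2.0 * fit.sigma, fit.fwhm, FIT_WINDOW_BP)
    elif width_rule == "2fwhm":
        L = min(2.0 * fit.fwhm, fit.fwhm, FIT_WINDOW_BP)
    else:
        raise ValueError("width_rule must be '2sigma' or '2fwhm'")
    lo, hi = profile.span
    wlo = max(lo, fit.center - L / 2)
    whi = min(hi, fit.center + L / 2)
    # reference mean over the 50-kb fit region
    flo, fhi = fit.fit_window
    fov = np.minimum(profile.segment_ends, fhi) - np.maximum(
        profile.segment_starts, flo
    )
    fin = fov > 0
    if not fin.any():
        return None
    mean_rho = float(np.sum(profile.rho_per_kb[fin] * fov[fin]) / np.sum(fov[fin]))
    ov = np.minimum(profile.segment_ends, whi) - np.maximum(
        profile.segment_starts, wlo
    )
    inside = ov > 0
    if not inside.any():
        return None
    peak_seg = int(
        np.clip(
            np.searchsorted(profile.segment_ends, fit.center, side="right"),
            0,
            profile.n_segments - 1,
        )
    )
    above_all = (profile.rho_per_kb > mean_rho) & fin
    above = above_all & inside
    if not above[peak_seg]:
        return None
    i = peak_seg
    while i > 0 and above[i - 1]:
        i -= 1
    j = peak_seg
    while j < profile.n_segments - 1 and above[j + 1]:
        j += 1
    # plateau extension past the window edge
    if profile.segment_starts[i] <= wlo:
        while i > 0 and above_all[i - 1]:
            i -= 1
    if profile.segment_ends[j] >= whi:
        while j < profile.n_segments - 1 and above_all[j + 1]:
            j += 1
    return float(profile.segment_starts[i]), float(profile.segment_ends[j])


def resolve_overlaps(
    candidates: list[tuple[float, float, float]], profile: RateProfile
) -> list[tuple[float, float, float]]:
    """Separate overlapping calls at the valley between their peaks.

    ``candidates`` are coordinate-sorted (center, start, end) triples; for
    each overlapping adjacent pair, both boundaries move to the midpoint
    of the minimum-rate segment between the two peak centers.
    """
    out = [list(c) for c in candidates]
    for a, b in zip(out, out[1:]):
        if b[1] < a[2]:  # overlap
            sel = (profile.midpoints() > a[0]) & (profile.midpoints() < b[0])
            idx = np.flatnonzero(sel)
            if len(idx) == 0:
                valley = 0.5 * (a[0] + b[0])
            else:
                k = idx[np.argmin(profile.rho_per_kb[idx])]
                valley = 0.5 * (
                    profile.segment_starts[k] + profile.segment_ends[k]
                )
            a[2] = min(a[2], valley)
            b[1] = max(b[1], valley)
    return [tuple(c) for c in out if c[1] < c[2] and c[1] <= c[0] < c[2]]


def call_hotspots(
    profile: RateProfile,
    Ne: int,
    width_rule: str = "2sigma",
    max_width: float = MAX_WIDTH_BP,
    min_avg_rate: float = MIN_AVG_RATE_CM_MB,
) -> list[Hotspot]:
    """Full calling pipeline with the width and average-rate filters."""
    from .rates import hotspot_strength

    candidates = []
    for center in find_peaks(profile):
        try:
            fit = fit_peak(profile, center)
        except DegenerateFitError:
            continue
        if not (profile.span[0] <= fit.center < profile.span[1]):
            continue
        bounds = delimit_hotspot(profile, fit, width_rule=width_rule)
        if bounds is None:
            continue
        start, end = bounds
        if not (start <= fit.center < end):
            continue
        candidates.append((fit.center, start, end))
    candidates.sort(key=lambda c: c[0])
    resolved = resolve_overlaps(candidates, profile)

    hotspots = []
    for center, start, end in resolved:
        width = end - start
        if width <= 0 or width > max_width:
            continue
        strength = hotspot_strength(profile, (start, end))
        avg_rho = strength / (width / 1000.0)
        avg_rate = rho_to_cm_per_mb(avg_rho, Ne)
        if avg_rate <= min_avg_rate:
            continue
        hotspots.append(
            Hotspot(
                peak_center=center,
                start=start,
                end=end,
                strength=strength,
                avg_rate_cm_mb=avg_rate,
            )
        )
    return hotspots


def write_hotspots_bed(hotspots, path, chrom: str = "chr1") -> None:
    """0-based half-open BED with strength and average-rate columns."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tstrength\tavg_rate_cm_mb\n")
        for i, h in enumerate(hotspots):
            fh.write(
                f"{chrom}\t{int(h.start) - 1}\t{int(h.end) - 1}\thotspot{i}\t"
                f"{h.strength:.6g}\t{h.avg_rate_cm_mb:.6g}\n"
            )
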