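"""Ensemble conductance histograms and peak statistics.

The 1D histogram compiles all recorded conductance samples of all traces
(100 bins over the analysis window by default); the 2D histogram bins
log-conductance against displacement (30 × 30 by default). Peak statistics
report the most probable conductance (mode bin refined by a local Gaussian
fit) and the full width at half maximum, both from the fit (fwhm =
2·sqrt(2·ln2)·σ) and from interpolated half-maximum crossings of the raw
profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .trace_processing import AlignmentSpec

__all__ = ["Hist1D", "Hist2D", "PeakStats", "hist1d", "hist2d", "peak_stats"]

GAUSS_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass
class Hist1D:
    edges: np.ndarray  # n_bins + 1 ascending edges in log10(G/G0)
    counts: np.ndarray
    n_traces: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


@dataclass
class Hist2D:
    x_edges: np.ndarray  # displacement (nm)
    y_edges: np.ndarray  # log10(G/G0)
    counts: np.ndarray   # shape (n_x_bins, n_y_bins)
    n_traces: int


@dataclass
class PeakStats:
    mode_log_g: float
    fwhm_decades: float
    fwhm_raw_decades: Optional[float]
    fit: Optional[tuple[float, float, float]]  # (mean, sd, amplitude)
    resolved: bool


def _samples_in_window(traces, spec: AlignmentSpec):
    lo_g, hi_g = spec.clip_log_g
    lo_d, hi_d = spec.clip_displacement_nm
    ds, gs = [], []
    for tr in traces:
        m = (
            (tr.log_g >= lo_g) & (tr.log_g <= hi_g)
            & (tr.displacement_nm >= lo_d) & (tr.displacement_nm <= hi_d)
        )
        ds.append(tr.displacement_nm[m])
        gs.append(tr.log_g[m])
    return np.concatenate(ds), np.concatenate(gs)


def hist1d(traces, spec: AlignmentSpec | None = None, bins: int = 100) -> Hist1D:
    """100-bin (default) histogram of all conductance samples of all traces
    within the analysis windows. Bins are half-open [edge_i, edge_{i+1}),
    the last bin closed."""
    if not traces:
        raise ValueError("empty ensemble")
    spec = spec or AlignmentSpec()
    _, gs = _samples_in_window(traces, spec)
    counts, edges = np.histogram(gs, bins=bins, range=spec.clip_log_g)
    return Hist1D(edges=edges, counts=counts, n_traces=len(traces))


def hist2d(traces, spec: AlignmentSpec | None = None,
           bins: tuple[int, int] = (30, 30)) -> Hist2D:
    """30 × 30 (default) joint histogram of displacement (x) against
    log-conductance (y) over all samples of all traces."""
    if not traces:
        raise ValueError("empty ensemble")
    spec = spec or AlignmentSpec()
    ds, gs = _samples_in_window(traces, spec)
    counts, xe, ye = np.histogram2d(
        ds, gs, bins=bins,
        range=[spec.clip_displacement_nm, spec.clip_log_g],
    )
    return Hist2D(x_edges=xe, y_edges=ye, counts=counts, n_traces=len(traces))


def _gauss(x, mu, sigma, amp):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _gauss_bg(x, mu, sigma, amp, base, step):
    # peak on a constant background plus a step that turns on below the
    # peak: tunneling samples are roughly uniform in log-conductance, and
    # the post-plateau decay of each molecular trace only adds counts below
    # its own plateau level, i.e. a population-CDF-shaped step
    from scipy.special import ndtr

    return (amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)
            + base + step * ndtr((mu - x) / sigma))


def _fwhm_crossings(centers: np.ndarray, counts: np.ndarray) -> Optional[float]:
    """Width between the outermost half-maximum crossings, linearly
    interpolated on the raw profile."""
    peak = counts.max()
    half = peak / 2.0
    above = counts >= half
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        return None
    left = idx[0]
    right = idx[-1]
    if left == 0 or right == len(counts) - 1:
        return None  # peak truncated by the window
    # interpolate on each shoulder
    xl = np.interp(half, [counts[left - 1], counts[left]],
                   [centers[left - 1], centers[left]])
    xr = np.interp(half, [counts[right + 1], counts[right]],
                   [centers[right + 1], centers[right]])
    return float(xr - xl)


def peak_stats(h: Hist1D, fit_halfwidth_bins: int = 20) -> PeakStats:
    """Most probable conductance and peak width of a 1D histogram.

    The mode bin is refined by a single-Gaussian least-squares fit over a
    window of ``fit_halfwidth_bins`` bins on each side; the reported fwhm is
    2.3548·σ of the fit when it converges, otherwise the raw interpolated
    half-maximum width. A peak confined to one bin is flagged unresolved.
    """
    counts = h.counts.astype(float)
    if counts.sum() == 0:
        raise ValueError("histogram is empty")
    if np.all(counts == counts[0]):
        raise ValueError("flat histogram: no peak")
    centers = h.centers
    imax = int(np.argmax(counts))
    mode = float(centers[imax])

    nonzero = np.flatnonzero(counts)
    if len(nonzero) == 1:
        return PeakStats(mode_log_g=mode, fwhm_decades=h.bin_width,
                         fwhm_raw_decades=None, fit=None, resolved=False)

    lo = max(0, imax - fit_halfwidth_bins)
    hi = min(len(counts), imax + fit_halfwidth_bins + 1)
    base0 = float(np.median(counts))
    fit = None
    try:
        popt, _ = curve_fit(
            _gauss_bg, centers[lo:hi], counts[lo:hi],
            p0=(mode, 2.0 * h.bin_width, max(counts[imax] - base0, 1.0), base0, 0.0),
            bounds=([h.edges[0], h.bin_width / 10.0, 0.0, 0.0, 0.0],
                    [h.edges[-1], h.edges[-1] - h.edges[0], np.inf, np.inf, np.inf]),
            maxfev=5000,
        )
        mu, sigma, amp = float(popt[0]), abs(float(popt[1])), float(popt[2])
        if amp > 0:
            fit = (mu, sigma, amp)
    except RuntimeError:
        fit = None

    raw = _fwhm_crossings(centers, counts)
    if fit is not None:
        mode = fit[0]
        fwhm = GAUSS_FWHM_FACTOR * fit[1]
    elif raw is not None:
        fwhm = raw
    else:
        fwhm = h.bin_width
    resolved = fwhm > h.bin_width
    return PeakStats(mode_log_g=mode, fwhm_decades=float(fwhm),
                     fwhm_raw_decades=raw, fit=fit, resolved=resolved)
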