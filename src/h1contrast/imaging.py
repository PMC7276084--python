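"""Chromomere (punctate chromatin domain) sizing from confocal/STED images.

Confocal domains are user-seeded and fit with a 2D Gaussian; STED domains
are segmented brightest-first and fit with a 2D Lorentzian.  Both models
are parameterized directly in FWHM:

    gaussian:   offset + A * exp(-4 ln2 * ((x-x0)^2/wx^2 + (y-y0)^2/wy^2))
    lorentzian: offset + A / (1 + 4 * ((x-x0)^2/wx^2 + (y-y0)^2/wy^2))

so the rejection rule on the fractional width uncertainty applies to a
fitted parameter without error propagation.  A fit is rejected for a
negative amplitude, a center outside the local ROI, or a fractional width
uncertainty above ``max_frac_uncertainty``; STED segmentation terminates
when half of the 20 most recent attempted fits were rejected.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.optimize import OptimizeWarning, curve_fit


@dataclass
class MicroscopyImage:
    pixels: np.ndarray       # 2D, non-negative
    pixel_size: float        # nm per pixel
    modality: str = "STED"   # confocal | STED

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("image must be 2D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not np.isfinite(self.pixels).all():
            raise ValueError("image contains non-finite values")


@dataclass(frozen=True)
class FitParams:
    roi_half_width: int = 7                 # ROI is (2h+1)^2 px
    max_frac_uncertainty: float = 0.60
    termination_window: int = 20
    termination_reject_fraction: float = 0.50
    fit_background: bool = True

    def __post_init__(self) -> None:
        if self.roi_half_width < 3:
            raise ValueError("roi_half_width must be >= 3")
        if not 0 < self.max_frac_uncertainty <= 1:
            raise ValueError("max_frac_uncertainty must be in (0, 1]")
        if not 0 < self.termination_reject_fraction <= 1:
            raise ValueError("termination_reject_fraction must be in (0, 1]")


@dataclass
class DomainFit:
    model: str                       # gaussian2d | lorentzian2d
    center_px: tuple[float, float]   # (x, y) in image pixels
    center_nm: tuple[float, float]
    fwhm_x: float                    # nm
    fwhm_y: float                    # nm
    amplitude: float
    offset: float
    frac_uncertainty_width: float
    status: str                      # accepted | rejected
    reject_reason: str = "none"      # negative_amplitude | center_outside_roi
    #                                # | uncertainty_exceeded | fit_failed | none
    seed_px: Optional[tuple[int, int]] = None

    @property
    def fwhm_mean(self) -> float:
        return 0.5 * (self.fwhm_x + self.fwhm_y)

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def _gaussian2d(xy, amp, x0, y0, wx, wy, offset):
    x, y = xy
    return offset + amp * np.exp(
        -4.0 * np.log(2.0) * ((x - x0) ** 2 / wx ** 2 + (y - y0) ** 2 / wy ** 2))


def _lorentzian2d(xy, amp, x0, y0, wx, wy, offset):
    x, y = xy
    return offset + amp / (
        1.0 + 4.0 * ((x - x0) ** 2 / wx ** 2 + (y - y0) ** 2 / wy ** 2))


_MODELS = {"gaussian2d": _gaussian2d, "lorentzian2d": _lorentzian2d}


def _param_errors(func, xy, z, popt) -> np.ndarray:
    """Parameter standard errors from the residual-variance-scaled inverse
    normal-equations matrix, with a central-difference Jacobian.

    Zero-residual (noiseless) fits correctly yield zero errors; a singular
    normal matrix yields infinite errors.
    """
    popt = np.asarray(popt, dtype=float)
    resid = func(xy, *popt) - z
    dof = max(len(z) - len(popt), 1)
    s2 = float(resid @ resid) / dof
    jac = np.empty((len(z), len(popt)))
    for j, p in enumerate(popt):
        step = 1e-6 * max(abs(p), 1.0)
        hi, lo = popt.copy(), popt.copy()
        hi[j] += step
        lo[j] -= step
        jac[:, j] = (func(xy, *hi) - func(xy, *lo)) / (2.0 * step)
    jtj = jac.T @ jac
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        return np.full(len(popt), np.inf)
    d = np.diag(cov)
    if not np.all(np.isfinite(d)):
        return np.full(len(popt), np.inf)
    return np.sqrt(np.abs(d))


def _fit_domain(image: MicroscopyImage, seed_point: tuple[int, int],
                params: FitParams, model: str) -> DomainFit:
    sx, sy = int(seed_point[0]), int(seed_point[1])
    h = params.roi_half_width
    ny, nx = image.pixels.shape
    if not (h <= sx < nx - h and h <= sy < ny - h):
        raise ValueError("seed point too close to the image border for the ROI")
    roi = image.pixels[sy - h:sy + h + 1, sx - h:sx + h + 1]
    yy, xx = np.mgrid[-h:h + 1, -h:h + 1]
    xy = (xx.ravel().astype(float), yy.ravel().astype(float))
    z = roi.ravel().astype(float)

    zmin, zmax = float(z.min()), float(z.max())
    p0 = [zmax - zmin, 0.0, 0.0, max(2.0, h / 2.0), max(2.0, h / 2.0),
          zmin if params.fit_background else 0.0]
    func = _MODELS[model]
    if not params.fit_background:
        def func_nobg(xy_, amp, x0, y0, wx, wy):
            return func(xy_, amp, x0, y0, wx, wy, 0.0)
        fit_func, p_init = func_nobg, p0[:5]
    else:
        fit_func, p_init = func, p0

    def rejected(reason: str, popt=None, frac=np.inf) -> DomainFit:
        if popt is None:
            popt = p_init + ([] if params.fit_background else [0.0])
        amp, x0, y0, wx, wy = popt[:5]
        off = popt[5] if len(popt) > 5 else 0.0
        return _result(image, sx, sy, model, amp, x0, y0, wx, wy, off, frac,
                       "rejected", reason)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(fit_func, xy, z, p0=p_init, maxfev=5000)
    except (RuntimeError, ValueError):
        return rejected("fit_failed")
    if not np.all(np.isfinite(popt)):
        return rejected("fit_failed")

    amp, x0, y0, wx, wy = popt[:5]
    off = popt[5] if params.fit_background else 0.0
    # width signs are a gauge freedom of the model (w enters squared)
    wx, wy = abs(wx), abs(wy)
    perr = _param_errors(fit_func, xy, z, popt)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = float(np.nanmax([perr[3] / wx if wx > 0 else np.inf,
                                perr[4] / wy if wy > 0 else np.inf]))
    if not np.isfinite(frac):
        frac = np.inf

    if amp <= 0:
        return rejected("negative_amplitude", list(popt), frac)
    if abs(x0) > h or abs(y0) > h:
        return rejected("center_outside_roi", list(popt), frac)
    if frac > params.max_frac_uncertainty:
        return rejected("uncertainty_exceeded", list(popt), frac)
    return _result(image, sx, sy, model, amp, x0, y0, wx, wy, off, frac,
                   "accepted", "none")


def _result(image, sx, sy, model, amp, x0, y0, wx, wy, off, frac,
            status, reason) -> DomainFit:
    px = image.pixel_size
    cx, cy = sx + x0, sy + y0
    return DomainFit(model, (cx, cy), (cx * px, cy * px),
                     abs(wx) * px, abs(wy) * px, float(amp), float(off),
                     float(frac), status, reason, (sx, sy))


def fit_gaussian2d(image: MicroscopyImage, seed_point: tuple[int, int],
                   params: FitParams = FitParams()) -> DomainFit:
    """Fit one confocal domain at a user-supplied seed with a 2D Gaussian."""
    return _fit_domain(image, seed_point, params, "gaussian2d")


def fit_lorentzian2d(image: MicroscopyImage, seed_point: tuple[int, int],
                     params: FitParams = FitParams()) -> DomainFit:
    """Fit one STED domain with a 2D Lorentzian, with rejection rules."""
    return _fit_domain(image, seed_point, params, "lorentzian2d")


def segment_domains_sted(image: MicroscopyImage,
                         params: FitParams = FitParams(),
                         max_attempts: int = 10000) -> list[DomainFit]:
    """Brightest-first automated STED segmentation.

    Iterates: box-filter the unclaimed pixels at ROI size, seed at the
    maximum local summed intensity, fit a Lorentzian, claim the ROI
    regardless of fit status, and stop when at least
    ``termination_window`` attempts exist and the rejected fraction among
    the most recent ones reaches ``termination_reject_fraction`` — or when
    no unclaimed seed remains.  Returns all attempts in order.
    """
    h = params.roi_half_width
    ny, nx = image.pixels.shape
    if nx < 2 * h + 1 or ny < 2 * h + 1:
        raise ValueError("image smaller than the ROI")
    unclaimed = np.ones_like(image.pixels, dtype=bool)
    fits: list[DomainFit] = []
    size = 2 * h + 1
    for _ in range(max_attempts):
        masked = np.where(unclaimed, image.pixels, 0.0)
        score = uniform_filter(masked, size=size, mode="constant") * size ** 2
        valid = unclaimed.copy()
        valid[:h, :] = valid[-h:, :] = False
        valid[:, :h] = valid[:, -h:] = False
        if not valid.any():
            break
        flat = np.where(valid, score, -np.inf)
        sy, sx = np.unravel_index(int(np.argmax(flat)), flat.shape)
        fits.append(fit_lorentzian2d(image, (sx, sy), params))
        unclaimed[max(0, sy - h):sy + h + 1, max(0, sx - h):sx + h + 1] = False
        if len(fits) >= params.termination_window:
            recent = fits[-params.termination_window:]
            frac_rej = sum(not f.accepted for f in recent) / len(recent)
            if frac_rej >= params.termination_reject_fraction:
                break
    return fits


FIT_TABLE_HEADER = ("model\tstatus\treject_reason\tcenter_x_nm\tcenter_y_nm\t"
                    "fwhm_x_nm\tfwhm_y_nm\tfwhm_mean_nm\tamplitude\t"
                    "frac_uncertainty")


def fit_table_row(f: DomainFit) -> str:
    """One TSV row per attempted fit.

    Rejected fits report NA for the numeric fields: their parameters are
    meaningless by definition (divergent fits can wander arbitrarily).
    """
    if f.accepted:
        return (f"{f.model}\t{f.status}\t{f.reject_reason}\t"
                f"{f.center_nm[0]:.1f}\t{f.center_nm[1]:.1f}\t"
                f"{f.fwhm_x:.2f}\t{f.fwhm_y:.2f}\t{f.fwhm_mean:.2f}\t"
                f"{f.amplitude:.4g}\t{f.frac_uncertainty_width:.3g}")
    return f"{f.model}\t{f.status}\t{f.reject_reason}" + "\tNA" * 7


@dataclass
class SizeDistribution:
    fwhm_means: np.ndarray   # nm, accepted fits only
    mean: float
    median: float
    sd: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray   # nm


def size_distribution(fits: list[DomainFit], n_bins: int = 20) -> SizeDistribution:
    """Summary of accepted-domain sizes (mean of X and Y FWHM per domain)."""
    sizes = np.array([f.fwhm_mean for f in fits if f.accepted])
    if len(sizes) == 0:
        raise ValueError("no accepted fits: size distribution undefined")
    counts, edges = np.histogram(sizes, bins=n_bins)
    sd = float(sizes.std(ddof=1)) if len(sizes) > 1 else 0.0
    return SizeDistribution(sizes, float(sizes.mean()), float(np.median(sizes)),
                            sd, counts, edges)
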