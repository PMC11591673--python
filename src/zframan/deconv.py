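"""Spectral deconvolution: background + sum of damped-harmonic-oscillator bands.

Each Raman band is modelled as the spectral response of a damped harmonic
oscillator (DHO) with natural frequency ``F`` (Omega, cm^-1) and damping
width ``W`` (Gamma, cm^-1):

    I(nu) = A0 * F^2 * W * nu / ((F^2 - nu^2)^2 + (W * nu)^2)

which is near-Lorentzian for W << F and vanishes at nu = 0 and nu -> inf.
The reported frequency is the natural frequency Omega, not the profile
argmax (which shifts below Omega at strong damping), and the reported width
is the damping constant Gamma, not the FWHM.  A spectrum is fit jointly as a
low-order polynomial background plus a sum of DHO profiles by bounded
nonlinear least squares; each band's area ``A`` is obtained by numerical
integration of its profile over the fit window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numpy.polynomial import chebyshev as cheb
from scipy import sparse
from scipy.optimize import least_squares
from scipy.signal import find_peaks, peak_widths, savgol_filter
from scipy.sparse.linalg import spsolve

from .io import SampleMeta, Spectrum

__all__ = [
    "DHOComponent",
    "BackgroundModel",
    "FitResult",
    "FitConfig",
    "dho_profile",
    "dho_area",
    "estimate_background",
    "initial_peaks",
    "fit_spectrum",
    "fit_dataset",
]


def dho_profile(
    nu: np.ndarray | float, F: float, W: float, amplitude: float
) -> np.ndarray | float:
    """Damped-harmonic-oscillator band profile evaluated at wavenumber ``nu``.

    Parameters
    ----------
    nu : array-like
        Wavenumber grid, cm^-1 (>= 0).
    F : float
        Natural frequency Omega, cm^-1 (> 0).
    W : float
        Damping width Gamma, cm^-1 (> 0).
    amplitude : float
        Scale factor A0, counts (>= 0).  On resonance the peak height is
        ``amplitude * F / W``.
    """
    if F <= 0 or W <= 0:
        raise ValueError(f"F and W must be positive (got F={F}, W={W})")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    nu = np.asarray(nu, dtype=float)
    denom = (F**2 - nu**2) ** 2 + (W * nu) ** 2
    out = amplitude * F**2 * W * nu / denom
    return out if out.ndim else float(out)


def _dho_jacobian(nu, F, W, A0):
    """d(profile)/d(F, W, A0); columns in that order."""
    D = (F**2 - nu**2) ** 2 + (W * nu) ** 2
    base = F**2 * W * nu / D
    dA = base
    dW = A0 * F**2 * nu * (D - 2 * W**2 * nu**2) / D**2
    dF = A0 * W * nu * 2 * F * (D - 2 * F**2 * (F**2 - nu**2)) / D**2
    return dF, dW, dA


def dho_area(
    F: float, W: float, amplitude: float, window: tuple[float, float], step: float = 0.5
) -> float:
    """Integrated band area over ``window``, trapezoid on a ``step`` cm^-1 grid."""
    lo, hi = window
    grid = np.arange(lo, hi + step / 2, step)
    return float(np.trapezoid(dho_profile(grid, F, W, amplitude), grid))


@dataclass
class BackgroundModel:
    """Smooth background under the bands.

    ``polynomial`` stores Chebyshev coefficients over ``domain``;
    ``asymmetric_smooth`` stores the baseline sampled on ``grid``.
    """

    kind: str  # "polynomial" | "asymmetric_smooth"
    coefficients: np.ndarray
    degree_or_lambda: float
    domain: tuple[float, float] | None = None
    grid: np.ndarray | None = None

    def __call__(self, nu: np.ndarray) -> np.ndarray:
        nu = np.asarray(nu, dtype=float)
        if self.kind == "polynomial":
            return cheb.chebval(_scale(nu, self.domain), self.coefficients)
        return np.interp(nu, self.grid, self.coefficients)


def _scale(nu, domain):
    lo, hi = domain
    return 2.0 * (nu - lo) / (hi - lo) - 1.0


@dataclass(frozen=True)
class DHOComponent:
    """One fitted band: natural frequency, damping width, integrated area."""

    F: float
    W: float
    A: float
    amplitude: float

    @property
    def peak_height(self) -> float:
        return self.amplitude * self.F / self.W


@dataclass
class FitResult:
    components: list[DHOComponent]
    background: BackgroundModel
    rms_residual: float
    converged: bool
    n_iterations: int

    def evaluate(self, nu: np.ndarray) -> np.ndarray:
        """Model = background + sum of band profiles at ``nu``."""
        y = self.background(nu).astype(float).copy()
        for c in self.components:
            y += dho_profile(nu, c.F, c.W, c.amplitude)
        return y


@dataclass(frozen=True)
class FitConfig:
    """Tunables of background estimation, peak seeding and the joint fit."""

    background_kind: str = "polynomial"
    background_degree: int = 3
    asls_lam: float = 1e6
    asls_p: float = 0.01
    asls_n_iter: int = 10
    prominence_k: float = 5.0
    max_bands: int = 40
    smooth_window: int = 11
    d2_window: int = 21
    d2_k: float = 10.0
    seed_min_sep: float = 6.0
    min_peak_snr: float = 2.0
    min_seed_width: float = 5.0
    max_width: float = 300.0
    f_window: float = 25.0  # allowed wander of F around its seed, cm^-1
    min_amplitude: float = 1e-6
    merge_cm1: float = 5.0
    restarts: int = 3
    seed: int = 0
    xtol: float = 1e-8
    ftol: float = 1e-8
    max_nfev: int | None = None

    def replace(self, **kw) -> "FitConfig":
        return replace(self, **kw)


def _asls(y: np.ndarray, lam: float, p: float, n_iter: int) -> np.ndarray:
    """Asymmetric least-squares baseline (second-difference penalty).

    Points above the current baseline get weight ``p`` (peaks), points below
    get ``1 - p``, so the solution hugs the lower envelope while staying
    smooth.
    """
    n = y.size
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = lam * (D.T @ D)
    w = np.ones(n)
    z = y.copy()
    for _ in range(n_iter):
        Wd = sparse.diags(w, format="csc")
        z = spsolve((Wd + penalty).tocsc(), w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def estimate_background(spectrum: Spectrum, config: FitConfig = FitConfig()) -> BackgroundModel:
    """Estimate a smooth baseline lying at or below the spectral envelope.

    Used to seed peak detection and to initialise the joint fit's polynomial
    background.  Always returns a model; a flat spectrum yields a constant.
    """
    nu, y = spectrum.wavenumbers, spectrum.intensities
    z = _asls(y, config.asls_lam, config.asls_p, config.asls_n_iter)
    return BackgroundModel(
        kind="asymmetric_smooth",
        coefficients=z,
        degree_or_lambda=config.asls_lam,
        grid=nu.copy(),
    )


def _noise_sigma(resid: np.ndarray) -> float:
    """Robust noise scale from first differences (insensitive to bands)."""
    d = np.diff(resid)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def initial_peaks(
    spectrum: Spectrum,
    background: BackgroundModel,
    config: FitConfig = FitConfig(),
) -> list[tuple[float, float, float]]:
    """Seed (F, W, amplitude) triplets from the background-subtracted signal.

    Two detectors are combined: local maxima of the smoothed residual with
    prominence above ``prominence_k`` times the robust noise scale, and
    maxima of the negative second derivative (which resolve shoulders of
    strongly overlapped bands) that also clear the height threshold.
    Candidates closer than ``seed_min_sep`` cm^-1 are deduplicated (taller
    kept); at most ``max_bands`` seeds, sorted by frequency.
    """
    nu, y = spectrum.wavenumbers, spectrum.intensities
    resid = y - background(nu)
    sigma = _noise_sigma(resid)
    win = min(config.smooth_window, resid.size // 2 * 2 - 1)
    smooth = savgol_filter(resid, win, 3) if win >= 5 else resid
    floor = max(config.prominence_k * sigma, 1e-12 * max(1.0, np.abs(y).max()))
    idx1, _ = find_peaks(smooth, prominence=floor)
    win2 = min(config.d2_window, resid.size // 2 * 2 - 1)
    if win2 >= 7:
        d2 = -savgol_filter(resid, win2, 3, deriv=2)
        sig_d2 = 1.4826 * np.median(np.abs(np.diff(d2))) / np.sqrt(2.0)
        idx2, _ = find_peaks(d2, prominence=config.d2_k * max(sig_d2, 1e-300))
        idx2 = idx2[smooth[idx2] > floor]
    else:
        idx2 = np.empty(0, dtype=int)
    merged: list[int] = []
    for i in sorted(set(idx1) | set(idx2)):
        if merged and nu[i] - nu[merged[-1]] < config.seed_min_sep:
            if smooth[i] > smooth[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(int(i))
    idx = np.array(merged, dtype=int)
    if idx.size == 0:
        return []
    if idx.size > config.max_bands:
        keep = np.argsort(smooth[idx])[::-1][: config.max_bands]
        idx = idx[np.sort(keep)]
    step = float(np.median(np.diff(nu)))
    with warnings.catch_warnings():
        # shoulder candidates need not be strict maxima of `smooth`; their
        # zero width falls back to min_seed_width below
        warnings.simplefilter("ignore")
        widths = peak_widths(smooth, idx, rel_height=0.5)[0] * step
    seeds = []
    for i, fwhm in zip(idx, widths):
        F = float(nu[i])
        W = float(np.clip(fwhm, config.min_seed_width, config.max_width))
        height = max(float(smooth[i]), floor)
        A0 = height * W / F  # on-resonance height = A0 * F / W
        seeds.append((F, W, A0))
    seeds.sort(key=lambda s: s[0])
    return seeds


def _pack(bg_coefs, comps):
    return np.concatenate([bg_coefs, np.ravel(comps)])


def _unpack(x, n_bg):
    bg = x[:n_bg]
    comps = x[n_bg:].reshape(-1, 3)  # columns F, W, A0
    return bg, comps


def _model_and_jac(nu, domain, n_bg):
    """Residual and Jacobian closures for the joint fit."""
    T = cheb.chebvander(_scale(nu, domain), n_bg - 1)  # (n, n_bg)

    def model(x):
        bg, comps = _unpack(x, n_bg)
        y = T @ bg
        for F, W, A0 in comps:
            y = y + dho_profile(nu, F, W, A0)
        return y

    def jac(x, y_obs):
        bg, comps = _unpack(x, n_bg)
        J = np.empty((nu.size, x.size))
        J[:, :n_bg] = T
        for k, (F, W, A0) in enumerate(comps):
            dF, dW, dA = _dho_jacobian(nu, F, W, A0)
            J[:, n_bg + 3 * k] = dF
            J[:, n_bg + 3 * k + 1] = dW
            J[:, n_bg + 3 * k + 2] = dA
        return J

    return model, jac


def _run_ls(nu, y, domain, n_bg, x0, lb, ub, config):
    model, jac = _model_and_jac(nu, domain, n_bg)
    res = least_squares(
        lambda x: model(x) - y,
        x0,
        jac=lambda x: jac(x, y),
        bounds=(lb, ub),
        method="trf",
        xtol=config.xtol,
        ftol=config.ftol,
        gtol=1e-12,
        max_nfev=config.max_nfev,
    )
    return res


def fit_spectrum(
    spectrum: Spectrum,
    seeds: list[tuple[float, float, float]] | None = None,
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Jointly fit background polynomial plus one DHO profile per seed.

    Components whose fitted amplitude drops below ``config.min_amplitude``
    or whose on-resonance height falls under ``min_peak_snr`` noise sigmas
    are pruned and the fit re-run once; components closer than
    ``config.merge_cm1`` are merged (areas summed, F and W amplitude-
    weighted).  Optimizer failure is reported via ``converged=False``, never
    an exception.  The fit is deterministic given spectrum, seeds and config.
    """
    nu, y = spectrum.wavenumbers, spectrum.intensities
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensities")
    if seeds is None:
        seeds = initial_peaks(spectrum, estimate_background(spectrum, config), config)
    domain = (float(nu[0]), float(nu[-1]))
    n_bg = config.background_degree + 1

    base = estimate_background(spectrum, config)
    bg0 = cheb.chebfit(_scale(nu, domain), base(nu), config.background_degree)

    def solve(seed_list, x_init=None):
        comps0 = np.array(seed_list, dtype=float).reshape(-1, 3)
        x0 = _pack(bg0, comps0) if x_init is None else x_init
        lb = np.full(x0.size, -np.inf)
        ub = np.full(x0.size, np.inf)
        for k, (F, _, _) in enumerate(comps0):
            j = n_bg + 3 * k
            lb[j] = max(F - config.f_window, nu[0], 1.0)
            ub[j] = min(F + config.f_window, nu[-1])
            lb[j + 1], ub[j + 1] = 0.5, config.max_width
            lb[j + 2], ub[j + 2] = 0.0, np.inf
        x0 = np.clip(x0, lb, ub)
        res = _run_ls(nu, y, domain, n_bg, x0, lb, ub, config)
        if res.status <= 0 and config.restarts > 0:
            rng = np.random.default_rng(config.seed)
            for _ in range(config.restarts):
                jitter = rng.normal(0.0, 0.02, x0.size) * np.maximum(np.abs(x0), 1.0)
                xj = np.clip(x0 + jitter, lb, ub)
                res2 = _run_ls(nu, y, domain, n_bg, xj, lb, ub, config)
                if res2.status > 0:
                    return res2
                if res2.cost < res.cost:
                    res = res2
        return res

    if len(seeds) == 0:
        # background-only: linear least squares suffices
        T = cheb.chebvander(_scale(nu, domain), config.background_degree)
        coefs, *_ = np.linalg.lstsq(T, y, rcond=None)
        fitted = T @ coefs
        return FitResult(
            components=[],
            background=BackgroundModel("polynomial", coefs, config.background_degree, domain=domain),
            rms_residual=float(np.sqrt(np.mean((fitted - y) ** 2))),
            converged=True,
            n_iterations=0,
        )

    res = solve(seeds)
    bg_c, comps = _unpack(res.x, n_bg)
    sigma = _noise_sigma(y - base(nu))
    heights = np.where(
        comps[:, 1] > 0, comps[:, 2] * comps[:, 0] / comps[:, 1], 0.0
    )
    keep = (comps[:, 2] >= config.min_amplitude) & (
        heights >= config.min_peak_snr * sigma
    )
    nfev = int(res.nfev)
    if not np.all(keep) and np.any(keep):
        res = solve(comps[keep].tolist())
        bg_c, comps = _unpack(res.x, n_bg)
        nfev += int(res.nfev)
    elif not np.any(keep):
        comps = np.empty((0, 3))

    window = domain
    comp_list = [
        DHOComponent(F=float(F), W=float(W), A=dho_area(F, W, A0, window), amplitude=float(A0))
        for F, W, A0 in comps
    ]
    comp_list.sort(key=lambda c: c.F)
    comp_list = _merge_close(comp_list, config.merge_cm1, window)

    bg_model = BackgroundModel("polynomial", bg_c, config.background_degree, domain=domain)
    fitted = bg_model(nu)
    for c in comp_list:
        fitted = fitted + dho_profile(nu, c.F, c.W, c.amplitude)
    return FitResult(
        components=comp_list,
        background=bg_model,
        rms_residual=float(np.sqrt(np.mean((fitted - y) ** 2))),
        converged=bool(res.status > 0),
        n_iterations=nfev,
    )


def _merge_close(
    comps: list[DHOComponent], merge_cm1: float, window: tuple[float, float]
) -> list[DHOComponent]:
    """Merge components closer than ``merge_cm1`` (degenerate splits)."""
    out = list(comps)
    merged = True
    while merged and len(out) > 1:
        merged = False
        for i in range(len(out) - 1):
            a, b = out[i], out[i + 1]
            if b.F - a.F < merge_cm1:
                wa, wb = max(a.amplitude, 1e-300), max(b.amplitude, 1e-300)
                F = (wa * a.F + wb * b.F) / (wa + wb)
                W = (wa * a.W + wb * b.W) / (wa + wb)
                A = a.A + b.A
                ref = dho_area(F, W, 1.0, window)
                amp = A / ref if ref > 0 else wa + wb
                out[i : i + 2] = [DHOComponent(F=F, W=W, A=A, amplitude=amp)]
                merged = True
                break
    return out


def fit_dataset(
    spectra: list[Spectrum],
    config: FitConfig = FitConfig(),
) -> pd.DataFrame:
    """Fit every spectrum; returns the long per-component report.

    Columns: file, organ, animal_id, clutch_id, stage_hpf, replicate,
    component_index, F, W, A, amplitude, rms_residual, converged.
    """
    rows = []
    for sp in spectra:
        meta: SampleMeta | None = sp.sample
        fit = fit_spectrum(sp, None, config)
        base = {
            "file": sp.source or "",
            "organ": meta.organ if meta else "",
            "animal_id": meta.animal_id if meta else "",
            "clutch_id": meta.clutch_id if meta else "",
            "stage_hpf": meta.stage_hpf if meta else -1,
            "replicate": meta.replicate if meta else 1,
        }
        if not fit.components:
            rows.append(
                base
                | {
                    "component_index": -1,
                    "F": np.nan,
                    "W": np.nan,
                    "A": np.nan,
                    "amplitude": np.nan,
                    "rms_residual": fit.rms_residual,
                    "converged": fit.converged,
                }
            )
        for k, c in enumerate(fit.components):
            rows.append(
                base
                | {
                    "component_index": k,
                    "F": c.F,
                    "W": c.W,
                    "A": c.A,
                    "amplitude": c.amplitude,
                    "rms_residual": fit.rms_residual,
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)
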