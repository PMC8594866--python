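"""Isothermal recrystallization kinetics from dielectric spectra.

During an isothermal hold above T_g, crystallization extinguishes the
dipolar relaxations of the supercooled liquid, so the static
permittivity eps_s (read as eps' at a low probe frequency) decays from
its supercooled-liquid plateau eps_s(SL) toward the crystal value
eps_s(C).  The chain implemented here:

1. :func:`extract_eps_s` — eps' at the probe frequency for each
   time-stamped spectrum (log-frequency interpolation off-grid);
2. :func:`detect_onset` — the time at which the initial plateau starts
   to decrease (3-sigma / 0.5% threshold with 3-point persistence,
   refined by back-extrapolating the early decay to the plateau level);
   a sample that never leaves its plateau returns ``None`` — the
   behavior of a material that does not recrystallize;
3. :func:`normalize_trace` — the normalized crystallized fraction
   eps_n(t) = (eps_s(SL) - eps_s(t)) / (eps_s(SL) - eps_s(C));
4. :func:`fit_avrami` — the Avrami (JMAK) law
   eps_n = 1 - exp(-Z (t - t_o)^n), fitted by the classical
   linearization ln(-ln(1 - eps_n)) vs ln(t - t_o) with a direct
   nonlinear fit reported alongside.  The growth rate is k = Z^(1/n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .permittivity_models import PermittivitySpectrum

__all__ = [
    "CrystallizationTrace",
    "NormalizedTrace",
    "AvramiFit",
    "extract_eps_s",
    "detect_onset",
    "normalize_trace",
    "fit_avrami",
    "compare_rates",
    "crystallization_pipeline",
    "refine_onset",
]

#: usable band of eps_n for the linearized fit; ln(-ln(1-x)) diverges
#: at both endpoints
AVRAMI_BAND = (0.03, 0.97)


@dataclass(frozen=True)
class CrystallizationTrace:
    """Static permittivity versus hold time at one temperature."""

    temperature: float
    probe_frequency: float
    times: np.ndarray
    eps_s: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.eps_s, dtype=float)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and eps_s must be 1-d and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(e)):
            raise ValueError("eps_s must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "eps_s", e)


@dataclass(frozen=True)
class NormalizedTrace:
    """Times rebased to the onset and normalized permittivity eps_n.

    ``eps_n`` is kept raw for fitting; ``eps_n_clipped`` (restricted to
    [0, 1]) is for reporting and plots.
    """

    times: np.ndarray          # t - t_onset, only points after onset
    eps_n: np.ndarray
    eps_sl: float
    eps_c: float
    t_onset: float

    @property
    def eps_n_clipped(self) -> np.ndarray:
        return np.clip(self.eps_n, 0.0, 1.0)


@dataclass(frozen=True)
class AvramiFit:
    """Avrami parameters: exponent n, constant Z, rate k = Z^(1/n)."""

    n_avrami: float
    Z: float
    k: float
    t_onset: float = math.nan
    eps_sl: float = math.nan
    eps_c: float = math.nan
    se_n: float = math.nan
    se_log_z: float = math.nan
    n_points: int = 0
    method: str = "linearized"
    refined: "AvramiFit | None" = None

    def __post_init__(self) -> None:
        if self.n_avrami <= 0 or self.Z <= 0:
            raise ValueError("Avrami parameters must be positive")


# ---------------------------------------------------------------------------


def extract_eps_s(spectra: Sequence[PermittivitySpectrum],
                  probe_frequency: float) -> CrystallizationTrace:
    """eps' at the probe frequency for each time-stamped spectrum.

    Spectra must share one temperature and carry ``elapsed`` times; the
    probe value is interpolated linearly in log-frequency when the
    probe is off-grid.  The output is sorted by elapsed time.
    """
    if not spectra:
        raise ValueError("no spectra given")
    temps = {round(s.temperature, 6) for s in spectra}
    if len(temps) > 1:
        raise ValueError(f"spectra span several temperatures: {sorted(temps)}")
    entries = []
    for s in spectra:
        if s.elapsed is None:
            raise ValueError("every spectrum needs an elapsed time")
        if not s.frequencies[0] <= probe_frequency <= s.frequencies[-1]:
            raise ValueError(
                f"probe frequency {probe_frequency} Hz outside the spectrum range "
                f"[{s.frequencies[0]}, {s.frequencies[-1]}] Hz")
        val = float(np.interp(math.log10(probe_frequency),
                              np.log10(s.frequencies), s.eps_real))
        entries.append((float(s.elapsed), val))
    entries.sort()
    t, e = map(np.asarray, zip(*entries))
    return CrystallizationTrace(
        temperature=float(spectra[0].temperature),
        probe_frequency=float(probe_frequency), times=t, eps_s=e)


def detect_onset(trace: CrystallizationTrace, plateau_points: int = 5,
                 sigma_mult: float = 3.0, rel_floor: float = 0.005,
                 persistence: int = 3, refine: bool = True) -> float | None:
    """Time at which the initial eps_s plateau starts to decrease.

    The plateau is the first ``plateau_points`` samples; a decrease is
    declared at the first sample falling below
    ``plateau_mean - max(sigma_mult * plateau_sd, rel_floor * plateau_mean)``
    and staying below for ``persistence`` consecutive samples.  With
    ``refine`` the reported onset is the crossing of the plateau mean
    by a line through the first decaying samples (back-extrapolation),
    which removes the detection lag of the threshold rule.  Returns
    ``None`` when no decrease is found — the sample did not
    crystallize within the observed window.
    """
    t, e = trace.times, trace.eps_s
    if t.size < 10:
        raise ValueError("onset detection needs at least 10 points")
    if t.size < plateau_points + persistence:
        raise ValueError("trace too short for the requested plateau")
    # adaptive plateau: once a candidate onset is found, every earlier
    # sample belongs to the plateau — re-estimating mean and sd from all
    # of them stabilizes the threshold against small-sample noise
    n_plateau = plateau_points
    hit = mean = None
    for _ in range(4):
        plateau = e[:n_plateau]
        mean, sd = float(plateau.mean()), float(plateau.std(ddof=1))
        thresh = mean - max(sigma_mult * sd, rel_floor * abs(mean))
        below = e < thresh
        hit = None
        for i in range(n_plateau, t.size - persistence + 1):
            if below[i:i + persistence].all():
                hit = i
                break
        if hit is None:
            return None
        if hit <= n_plateau:
            break
        n_plateau = hit
    if hit is None:
        return None
    if not refine:
        return float(t[hit])
    # back-extrapolate the early decay to the plateau level
    j = min(hit + persistence, t.size)
    seg_t, seg_e = t[hit:j], e[hit:j]
    if seg_t.size >= 2:
        slope, intercept = np.polyfit(seg_t, seg_e, 1)
        if slope < 0:
            t_cross = (mean - intercept) / slope
            if t[0] <= t_cross <= t[hit]:
                return float(t_cross)
    return float(t[hit])


def normalize_trace(trace: CrystallizationTrace, t_onset: float,
                    eps_sl: float, eps_c: float) -> NormalizedTrace:
    """Normalized crystallized fraction versus time since onset.

    eps_n(t) = (eps_s(SL) - eps_s(t)) / (eps_s(SL) - eps_s(C)); raw
    values are retained (clipping to [0, 1] happens only when
    reporting), and times are rebased to t - t_onset keeping only
    post-onset samples.
    """
    if not eps_sl > eps_c:
        raise ValueError("degenerate plateaus: eps_s(SL) must exceed eps_s(C)")
    mask = trace.times > t_onset
    eps_n = (eps_sl - trace.eps_s[mask]) / (eps_sl - eps_c)
    return NormalizedTrace(times=trace.times[mask] - t_onset, eps_n=eps_n,
                           eps_sl=eps_sl, eps_c=eps_c, t_onset=t_onset)


def _weighted_line(x: np.ndarray, y: np.ndarray,
                   w: np.ndarray) -> tuple[float, float, float, float]:
    """Weighted least-squares line; returns slope, intercept and SEs."""
    sw = w.sum()
    xb = float((w * x).sum() / sw)
    yb = float((w * y).sum() / sw)
    sxx = float((w * (x - xb) ** 2).sum())
    slope = float((w * (x - xb) * (y - yb)).sum() / sxx)
    intercept = yb - slope * xb
    resid = y - slope * x - intercept
    dof = max(x.size - 2, 1)
    s2 = float((w * resid ** 2).sum() / dof)
    se_slope = math.sqrt(s2 / sxx)
    se_intercept = math.sqrt(s2 * (1.0 / sw + xb ** 2 / sxx))
    return slope, intercept, se_slope, se_intercept


def _nonlinear_refine(t: np.ndarray, eps_n: np.ndarray,
                      n0: float, z0: float) -> tuple[float, float, float, float]:
    def model(tt, n, log_z):
        return 1.0 - np.exp(-np.exp(log_z) * tt ** n)

    popt, pcov = optimize.curve_fit(model, t, eps_n, p0=[n0, math.log(z0)],
                                    maxfev=20000)
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [math.nan] * 2
    return float(popt[0]), float(math.exp(popt[1])), float(perr[0]), float(perr[1])


def fit_avrami(normalized: NormalizedTrace, band: tuple[float, float] = AVRAMI_BAND,
               nonlinear: bool = True) -> AvramiFit:
    """Avrami fit of a normalized crystallization trace.

    Primary estimate: linear regression of ln(-ln(1 - eps_n)) on
    ln(t - t_o) over the usable band (slope = n, intercept = ln Z).
    With ``nonlinear`` a direct least-squares fit of
    1 - exp(-Z t^n) on the same points is attached as ``refined``.
    The rate k = Z^(1/n) satisfies the identity by construction.
    """
    t, eps_n = normalized.times, normalized.eps_n
    mask = (eps_n >= band[0]) & (eps_n <= band[1]) & (t > 0)
    if mask.sum() < 6:
        raise ValueError("fewer than 6 usable points in the Avrami band")
    tt, yy = t[mask], eps_n[mask]
    x = np.log(tt)
    y = np.log(-np.log(1.0 - yy))
    # delta-method weights for homoscedastic eps_n noise: the transform
    # amplifies errors by 1/((1-eps)|ln(1-eps)|), enormously so near the
    # band edges, which would otherwise dominate the regression
    w = ((1.0 - yy) * np.abs(np.log(1.0 - yy))) ** 2
    n, lnz, se_n, se_lnz = _weighted_line(x, y, w)
    z = float(math.exp(lnz))
    if n <= 0:
        raise ValueError("non-positive Avrami exponent: trace is not decaying")
    refined = None
    if nonlinear:
        try:
            n_nl, z_nl, se_n_nl, se_lz_nl = _nonlinear_refine(tt, yy, n, z)
            refined = AvramiFit(
                n_avrami=n_nl, Z=z_nl, k=z_nl ** (1.0 / n_nl),
                t_onset=normalized.t_onset, eps_sl=normalized.eps_sl,
                eps_c=normalized.eps_c, se_n=se_n_nl, se_log_z=se_lz_nl,
                n_points=int(mask.sum()), method="nonlinear",
            )
        except Exception:
            refined = None
    return AvramiFit(
        n_avrami=n, Z=z, k=z ** (1.0 / n),
        t_onset=normalized.t_onset, eps_sl=normalized.eps_sl, eps_c=normalized.eps_c,
        se_n=se_n, se_log_z=se_lnz,
        n_points=int(mask.sum()), method="linearized", refined=refined,
    )


def compare_rates(fits: Sequence[AvramiFit], ci_mult: float = 2.0) -> dict:
    """Rate comparison across materials / temperatures.

    Reports all growth rates, their ratios relative to the first fit,
    and whether the Avrami exponents are mutually compatible within
    ``ci_mult`` combined standard errors — in which case the vertical
    offset between Avrami plots reads directly as a rate ratio.
    A single fit passes through unchanged.
    """
    if not fits:
        raise ValueError("no fits to compare")
    report: dict = {
        "rates_per_s": [f.k for f in fits],
        "exponents": [f.n_avrami for f in fits],
    }
    if len(fits) == 1:
        report["ratios_to_first"] = [1.0]
        report["exponents_compatible"] = True
        return report
    k0 = fits[0].k
    report["ratios_to_first"] = [f.k / k0 for f in fits]
    compatible = True
    for i in range(len(fits)):
        for j in range(i + 1, len(fits)):
            se = math.hypot(
                0.0 if math.isnan(fits[i].se_n) else fits[i].se_n,
                0.0 if math.isnan(fits[j].se_n) else fits[j].se_n,
            )
            if se > 0 and abs(fits[i].n_avrami - fits[j].n_avrami) > ci_mult * se:
                compatible = False
    report["exponents_compatible"] = compatible
    if compatible:
        # with a common exponent the Avrami-plot offset is n*log10(k_i/k_j)
        n_mean = float(np.mean(report["exponents"]))
        report["avrami_plot_offsets_log10"] = [
            n_mean * math.log10(f.k / k0) for f in fits
        ]
    return report


# ---------------------------------------------------------------------------


def crystallization_pipeline(spectra: Sequence[PermittivitySpectrum],
                             probe_frequency: float,
                             plateau_points: int = 5,
                             flat_tail_rel: float = 0.002) -> dict:
    """Full extract -> onset -> normalize -> fit chain.

    eps_s(SL) is the pre-onset plateau mean.  eps_s(C) is the mean of
    the final 5 points when the tail has flattened (relative change
    below ``flat_tail_rel`` across them); otherwise crystallization did
    not complete within the hold and eps_s(C) is left free in a
    nonlinear fit of the raw trace, after which the linearized fit is
    rerun with that estimate.  Returns a dict with the trace, the
    onset (``None`` if the sample never left its plateau) and the
    :class:`AvramiFit` (``None`` without an onset).
    """
    trace = extract_eps_s(spectra, probe_frequency)
    t_onset = detect_onset(trace, plateau_points=plateau_points)
    out = {"trace": trace, "t_onset": t_onset, "fit": None,
           "status": "no crystallization detected"}
    if t_onset is None:
        return out
    pre = trace.eps_s[trace.times <= t_onset]
    if pre.size < plateau_points:
        pre = trace.eps_s[:plateau_points]
    eps_sl = float(pre.mean())
    tail = trace.eps_s[-5:]
    tail_flat = (tail.max() - tail.min()) / abs(tail.mean()) < flat_tail_rel
    if tail_flat:
        eps_c = float(tail.mean())
    else:
        eps_c = _fit_free_eps_c(trace, t_onset, eps_sl)
    # the threshold rule only brackets the onset (its lag/jitter is a few
    # sampling intervals, which would bias the Avrami slope); refine it by
    # fitting the raw decay with the onset time free before linearizing
    t_onset = refine_onset(trace, t_onset, eps_sl, eps_c)
    out["t_onset"] = t_onset
    normalized = normalize_trace(trace, t_onset, eps_sl, eps_c)
    fit = fit_avrami(normalized)
    out.update(fit=fit, normalized=normalized, status="crystallized",
               eps_sl=eps_sl, eps_c=eps_c, tail_flat=tail_flat)
    return out


def refine_onset(trace: CrystallizationTrace, t_onset: float,
                 eps_sl: float, eps_c: float) -> float:
    """Onset as a free parameter of a direct Avrami fit of eps_s(t).

    The threshold rule of :func:`detect_onset` only brackets the onset;
    its lag and jitter (a few sampling intervals) would bias the Avrami
    slope, so the pipeline re-estimates the onset jointly with the
    kinetics from the raw decay.
    """
    mask = trace.times > 0.3 * t_onset
    t = trace.times[mask]
    e = trace.eps_s[mask]
    span = eps_sl - eps_c

    def model(tt, n, log_k, t0):
        dt = np.clip(tt - t0, 0.0, None)
        return eps_sl - span * (1.0 - np.exp(-((np.exp(log_k) * dt) ** n)))

    k0 = 1.0 / max(t[-1] - t_onset, 1.0)
    try:
        popt, _ = optimize.curve_fit(
            model, t, e, p0=[1.0, math.log(k0), t_onset],
            bounds=([0.1, math.log(k0) - 12.0, t[0]],
                    [8.0, math.log(k0) + 12.0, t[-1]]),
            maxfev=40000)
    except Exception:
        return t_onset
    return float(popt[2])


def _fit_free_eps_c(trace: CrystallizationTrace, t_onset: float,
                    eps_sl: float) -> float:
    """Crystal plateau from an incomplete trace: free in a direct fit."""
    mask = trace.times > t_onset
    t = trace.times[mask] - t_onset
    e = trace.eps_s[mask]

    def model(tt, n, log_z, eps_c):
        return eps_sl - (eps_sl - eps_c) * (1.0 - np.exp(-np.exp(log_z) * tt ** n))

    e_min = float(e.min())
    p0 = [1.0, math.log(1.0 / max(t[-1], 1.0)), e_min - 0.1 * (eps_sl - e_min)]
    popt, _ = optimize.curve_fit(
        model, t, e, p0=p0,
        bounds=([0.1, -50.0, 1.0], [8.0, 10.0, eps_sl - 1e-6]), maxfev=40000)
    return float(popt[2])
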