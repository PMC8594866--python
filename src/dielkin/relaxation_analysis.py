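"""Relaxation-map analysis: temperature laws for relaxation times.

Takes per-temperature relaxation times (one process at a time) and fits
the temperature laws used to characterize glass-forming liquids:

* the Vogel-Fulcher-Tammann (VFT) law for the cooperative structural
  (alpha) relaxation,
* the Arrhenius law for thermally activated secondary relaxations,
* a two-segment Arrhenius fit to locate the kink the Johari-Goldstein
  (JG) beta relaxation shows at the glass transition.

Derived quantities: the kinetic glass-transition temperature T_g
(where tau_alpha extrapolates to 100 s), the fragility (steepness)
index m_p, the coupling-model prediction of the JG relaxation time from
the alpha lineshape, Angell-plot reduced coordinates, and T_g/T_m
ratios.

Two VFT exponent conventions are supported as first-class citizens and
every fit records which one it uses:

* ``natural``:  tau = tau0 * exp(D T0 / (T - T0)), i.e.
  log10 tau = log10 tau0 + D T0 / (ln 10 (T - T0))
* ``decadic``:  log10 tau = log10 tau0 + D T0 / (T - T0)

The two parametrizations describe the same curve with D differing by a
factor ln 10; published parameter tables are not always explicit about
which was used, so reports always state the convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GAS_CONSTANT",
    "LN10",
    "VFTFit",
    "ArrheniusFit",
    "KinkFit",
    "CouplingModelParams",
    "TgTmRatio",
    "fit_vft",
    "kinetic_tg",
    "fragility_index",
    "fit_arrhenius",
    "detect_kink",
    "coupling_parameter",
    "cm_predicted_jg_time",
    "angell_transform",
    "tg_tm_ratio",
    "summarize_relaxation_map",
]

#: Universal gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314
LN10 = math.log(10.0)

_CONVENTIONS = ("natural", "decadic")


def _convention_factor(convention: str) -> float:
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}")
    return LN10 if convention == "natural" else 1.0


def _as_temperature_tau(records, process: str | None = None):
    """Coerce records / table / (T, tau) arrays to sorted arrays."""
    if isinstance(records, tuple) and len(records) == 2:
        temps = np.asarray(records[0], dtype=float)
        tau = np.asarray(records[1], dtype=float)
    else:
        recs = getattr(records, "records", records)
        recs = [r for r in recs if process is None or r.process == process]
        temps = np.array([r.temperature for r in recs], dtype=float)
        tau = np.array([r.tau_max for r in recs], dtype=float)
    order = np.argsort(temps)
    temps, tau = temps[order], tau[order]
    if np.any(tau <= 0):
        raise ValueError("relaxation times must be positive")
    return temps, tau


@dataclass(frozen=True)
class VFTFit:
    """Fitted Vogel-Fulcher-Tammann law.

    ``D`` is the fragility-strength coefficient under the stated
    ``convention`` (see module docstring); ``T0`` the Vogel temperature.
    """

    log10_tau0: float
    D: float
    T0: float
    convention: str = "natural"
    stderr: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _convention_factor(self.convention)
        if self.T0 <= 0 or self.D <= 0:
            raise ValueError("T0 and D must be positive")

    def log10_tau(self, temperature) -> np.ndarray:
        """log10 of the relaxation time (s) at temperature(s) in K."""
        T = np.asarray(temperature, dtype=float)
        c = _convention_factor(self.convention)
        return self.log10_tau0 + self.D * self.T0 / (c * (T - self.T0))

    def to_convention(self, convention: str) -> "VFTFit":
        """Re-express the same curve under the other convention."""
        _convention_factor(convention)
        if convention == self.convention:
            return self
        scale = LN10 if convention == "natural" else 1.0 / LN10
        return VFTFit(self.log10_tau0, self.D * scale, self.T0, convention, dict(self.stderr))


@dataclass(frozen=True)
class ArrheniusFit:
    """Fitted Arrhenius law log10 tau = log10 tau_inf + Ea/(R ln10 T)."""

    log10_tau_inf: float
    ea_kj_mol: float
    t_range: tuple[float, float] = (0.0, np.inf)
    stderr: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ea_kj_mol <= 0:
            raise ValueError("activation energy must be positive")

    def log10_tau(self, temperature) -> np.ndarray:
        T = np.asarray(temperature, dtype=float)
        return self.log10_tau_inf + self.ea_kj_mol * 1e3 / (GAS_CONSTANT * LN10 * T)


@dataclass(frozen=True)
class KinkFit:
    """Two-segment Arrhenius fit with a breakpoint (the JG kink)."""

    t_break: float
    fit_below: ArrheniusFit
    fit_above: ArrheniusFit
    residual_norm: float

    @property
    def ea_below(self) -> float:
        return self.fit_below.ea_kj_mol

    @property
    def ea_above(self) -> float:
        return self.fit_above.ea_kj_mol


@dataclass(frozen=True)
class CouplingModelParams:
    """Coupling-model inputs: crossover time t_c and coupling n."""

    n_coupling: float
    t_c: float = 2e-12

    def __post_init__(self) -> None:
        if not 0.0 < self.n_coupling < 1.0:
            raise ValueError("coupling parameter must lie in (0, 1)")
        if self.t_c <= 0:
            raise ValueError("t_c must be positive")


class TgTmRatio(NamedTuple):
    """T_g/T_m with full precision plus the 2-decimal reported value."""

    value: float
    reported: float
    warning: bool


# ---------------------------------------------------------------------------
# VFT


def fit_vft(records, convention: str = "natural", process: str = "alpha") -> VFTFit:
    """Least-squares VFT fit of log10 tau versus temperature.

    ``records`` may be a RelaxationTable, an iterable of
    RelaxationRecord, or a ``(temperatures_K, tau_s)`` tuple of arrays.
    At least 4 points are required.  A coarse grid over candidate Vogel
    temperatures (each giving a linear sub-problem) seeds a full
    nonlinear refinement, so no user initialization is needed.
    """
    c = _convention_factor(convention)
    temps, tau = _as_temperature_tau(records, process)
    if temps.size < 4:
        raise ValueError("VFT fit needs at least 4 (T, tau) points")
    y = np.log10(tau)
    t_min = temps.min()

    # grid-seeded linear sub-fits: for fixed T0 the model is linear in
    # (log10 tau0, D*T0)
    best = None
    for T0 in np.linspace(1.0, t_min - 1.0, 400):
        x = 1.0 / (c * (temps - T0))
        A = np.vstack([np.ones_like(x), x]).T
        coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        if coef[1] <= 0:
            continue
        ssr = float(np.sum((A @ coef - y) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, T0, coef)
    if best is None:
        raise RuntimeError("VFT fit failed: no admissible Vogel temperature")
    _, T0_init, coef = best
    lo = np.array([-40.0, 1e-6, 1.0])
    hi = np.array([10.0, 1e6, t_min - 1e-6])
    p0 = np.clip([coef[0], coef[1] / T0_init, T0_init], lo, hi)

    def model(T, log10_tau0, D, T0):
        return log10_tau0 + D * T0 / (c * (T - T0))

    popt, pcov = optimize.curve_fit(
        model, temps, y, p0=p0, bounds=(lo, hi), maxfev=20000,
    )
    if popt[2] >= t_min:
        raise RuntimeError("VFT fit failed: T0 above the fitted range")
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
    return VFTFit(
        log10_tau0=float(popt[0]), D=float(popt[1]), T0=float(popt[2]),
        convention=convention,
        stderr={"log10_tau0": float(perr[0]), "D": float(perr[1]), "T0": float(perr[2])},
    )


def kinetic_tg(fit: VFTFit, log10_tau_target: float = 2.0) -> float:
    """Temperature (K) at which the VFT curve reaches tau = 100 s.

    Solved analytically: T_g = T0 + D*T0 / (c * (target - log10 tau0))
    with c = ln 10 for the natural convention and 1 for the decadic one.
    """
    c = _convention_factor(fit.convention)
    denom = c * (log10_tau_target - fit.log10_tau0)
    if denom <= 0:
        raise ValueError("no solution: tau0 already exceeds the target time")
    return fit.T0 + fit.D * fit.T0 / denom


def fragility_index(fit: VFTFit, tg: float | None = None) -> float:
    """Steepness (fragility) index m_p = d log10 tau / d(T_g/T) at T_g.

    Analytic from the fit: m_p = D T0 T_g / (c (T_g - T0)^2) with the
    same convention factor c as in :func:`kinetic_tg`.  An Arrhenius
    process evaluated this way gives the minimal fragility
    m_p = 2 - log10 tau0.
    """
    if tg is None:
        tg = kinetic_tg(fit)
    if tg <= fit.T0:
        raise ValueError("T_g must exceed the Vogel temperature T0")
    c = _convention_factor(fit.convention)
    return fit.D * fit.T0 * tg / (c * (tg - fit.T0) ** 2)


# ---------------------------------------------------------------------------
# Arrhenius / kink


def fit_arrhenius(records, t_range: tuple[float, float] | None = None,
                  process: str | None = None) -> ArrheniusFit:
    """Linear regression of ln tau on 1/T; Ea reported in kJ/mol."""
    temps, tau = _as_temperature_tau(records, process)
    if t_range is not None:
        mask = (temps >= t_range[0]) & (temps <= t_range[1])
        temps, tau = temps[mask], tau[mask]
    if temps.size < 3:
        raise ValueError("Arrhenius fit needs at least 3 points in range")
    res = stats.linregress(1.0 / temps, np.log(tau))
    return ArrheniusFit(
        log10_tau_inf=float(res.intercept / LN10),
        ea_kj_mol=float(res.slope * GAS_CONSTANT / 1e3),
        t_range=(float(temps.min()), float(temps.max())),
        stderr={
            "log10_tau_inf": float(res.intercept_stderr / LN10),
            "ea_kj_mol": float(res.stderr * GAS_CONSTANT / 1e3),
        },
    )


def _segment_ssr(fit: ArrheniusFit, temps: np.ndarray, tau: np.ndarray) -> float:
    return float(np.sum((fit.log10_tau(temps) - np.log10(tau)) ** 2))


def detect_kink(records, tg: float | None = None, process: str | None = None) -> KinkFit:
    """Two-segment Arrhenius fit locating a slope change (JG kink).

    The breakpoint is searched exhaustively over splits of the data
    temperatures (at least 3 points per segment); the reported kink
    temperature is the intersection of the two fitted Arrhenius lines
    when it falls between the straddling data points, otherwise their
    midpoint.  ``tg`` is accepted for interface symmetry but the search
    is data-driven.
    """
    temps, tau = _as_temperature_tau(records, process)
    if temps.size < 6:
        raise ValueError("kink detection needs at least 6 points")
    if tg is not None and not (temps.min() < tg < temps.max()):
        raise ValueError("no data on both sides of the stated T_g")
    best: tuple[float, KinkFit] | None = None
    for split in range(3, temps.size - 2):
        lo = (temps[:split], tau[:split])
        hi = (temps[split:], tau[split:])
        fit_lo = fit_arrhenius(lo)
        fit_hi = fit_arrhenius(hi)
        ssr = _segment_ssr(fit_lo, *lo) + _segment_ssr(fit_hi, *hi)
        t_left, t_right = temps[split - 1], temps[split]
        # intersection of the two log10 tau lines in 1/T
        dslope = (fit_hi.ea_kj_mol - fit_lo.ea_kj_mol) * 1e3 / (GAS_CONSTANT * LN10)
        dint = fit_lo.log10_tau_inf - fit_hi.log10_tau_inf
        t_break = 0.5 * (t_left + t_right)
        if dint != 0.0:
            t_cross = dslope / dint
            if t_left <= t_cross <= t_right:
                t_break = t_cross
        cand = KinkFit(float(t_break), fit_lo, fit_hi, ssr)
        if best is None or ssr < best[0]:
            best = (ssr, cand)
    assert best is not None
    return best[1]


# ---------------------------------------------------------------------------
# Coupling model


def coupling_parameter(a: float, b: float) -> float:
    """Coupling parameter n from the alpha HN exponents: 1 - (ab)^(1/1.23).

    For a Cole-Davidson alpha peak (a = 1) this is n = 1 - b^(1/1.23);
    a Debye peak (a = b = 1) gives n = 0 (no coupling).
    """
    ab = a * b
    if not 0.0 < ab <= 1.0:
        raise ValueError("product a*b must lie in (0, 1]")
    return 1.0 - ab ** (1.0 / 1.23)


def cm_predicted_jg_time(tau_alpha: float, n: float, t_c: float = 2e-12) -> float:
    """Coupling-model (primitive) JG relaxation time t_c^n tau_alpha^(1-n).

    Evaluated in log space for numerical safety; n = 0 returns
    tau_alpha, n = 1 returns t_c.
    """
    if not 0.0 <= n <= 1.0:
        raise ValueError("coupling parameter must lie in [0, 1]")
    if tau_alpha <= 0 or t_c <= 0:
        raise ValueError("times must be positive")
    return float(math.exp(n * math.log(t_c) + (1.0 - n) * math.log(tau_alpha)))


# ---------------------------------------------------------------------------
# Reduced-temperature (Angell) coordinates and reporting


def angell_transform(records, tg: float) -> pd.DataFrame:
    """Reduced-coordinate (Angell-plot) table: T_g/T versus log10 tau.

    Returns a DataFrame with columns ``process``, ``temperature_K``,
    ``tg_over_t`` and ``log10_tau``; by construction the alpha trace
    passes through (1, 2) when ``tg`` is the kinetic T_g.
    """
    if tg <= 0:
        raise ValueError("tg must be positive")
    recs = list(getattr(records, "records", records))
    rows = [
        {
            "process": r.process,
            "temperature_K": r.temperature,
            "tg_over_t": tg / r.temperature,
            "log10_tau": math.log10(r.tau_max),
        }
        for r in recs
    ]
    return pd.DataFrame(rows, columns=["process", "temperature_K", "tg_over_t", "log10_tau"])


def tg_tm_ratio(tg: float, tm: float) -> TgTmRatio:
    """T_g/T_m ratio; reported to 2 decimals, full precision retained.

    The reported figure is truncated (not rounded half-up) to the
    second decimal, the convention the published benchmark ratios for
    these materials follow.  A ratio >= 1 (T_g not below T_m) is
    physically suspect and sets the warning flag without raising.
    """
    if tg <= 0 or tm <= 0:
        raise ValueError("temperatures must be positive")
    warn = tg >= tm
    if warn:
        warnings.warn("T_g >= T_m: check the input temperatures", stacklevel=2)
    value = tg / tm
    return TgTmRatio(value=value, reported=math.floor(value * 100.0 + 1e-9) / 100.0, warning=warn)


def summarize_relaxation_map(table, convention: str = "natural",
                             tm: float | None = None,
                             t_c: float = 2e-12) -> dict:
    """Aggregate a relaxation table into a material summary.

    Fits the alpha process with a VFT law (deriving the kinetic T_g and
    fragility m_p), each secondary process with an Arrhenius law, and —
    when the alpha shape exponents are available — compares the
    measured beta time with the coupling-model prediction at T_g.
    The summary always states the VFT convention used.
    """
    recs = list(getattr(table, "records", table))
    by_process: dict[str, list] = {}
    for r in recs:
        by_process.setdefault(r.process, []).append(r)
    if "alpha" not in by_process:
        raise ValueError("relaxation table has no alpha records")

    vft = fit_vft(by_process["alpha"], convention=convention)
    tg = kinetic_tg(vft)
    summary: dict = {
        "convention": convention,
        "alpha": {
            "law": "vft",
            "log10_tau0": vft.log10_tau0,
            "D": vft.D,
            "T0": vft.T0,
            "stderr": dict(vft.stderr),
        },
        "tg_kinetic_K": tg,
        "fragility_mp": fragility_index(vft, tg),
    }
    if tm is not None:
        ratio = tg_tm_ratio(tg, tm)
        summary["tg_over_tm"] = ratio.reported
        summary["tm_K"] = tm

    for proc in ("beta", "gamma", "gamma_prime"):
        if proc not in by_process or len(by_process[proc]) < 3:
            continue
        arr = fit_arrhenius(by_process[proc])
        summary[proc] = {
            "law": "arrhenius",
            "log10_tau_inf": arr.log10_tau_inf,
            "ea_kj_mol": arr.ea_kj_mol,
            "stderr": dict(arr.stderr),
        }

    alpha_recs = by_process["alpha"]
    a_mean = float(np.mean([r.a for r in alpha_recs]))
    b_mean = float(np.mean([r.b for r in alpha_recs]))
    try:
        n = coupling_parameter(a_mean, b_mean)
    except ValueError:
        n = None
    if n is not None and 0.0 < n < 1.0:
        summary["coupling_model"] = {
            "n_coupling": n,
            "t_c_s": t_c,
            "predicted_jg_tau_at_tg_s": cm_predicted_jg_time(100.0, n, t_c),
        }
    return summary
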