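"""Decomposition of isothermal loss spectra into HN components.

Each spectrum is fitted as dc-conductivity plus at most two
Havriliak-Negami components (the two processes visible in any one
frequency window), with the lineshape constraints customary for
glass formers: the structural alpha peak is Cole-Davidson (a fixed at
1) and secondary peaks are Cole-Cole (b fixed at 1) unless a template
says otherwise.

The default objective is the logarithmic residual of the loss curve,
which balances the many decades of dynamic range of a broadband
spectrum; joint real+imaginary fitting is available as an option.
Initialization is automatic (median-smoothed peak picking), with a
bounded number of seeded multi-start retries on failure.

A whole temperature series can be fitted globally with one shared
shape exponent for a chosen process (time-temperature superposition in
fit form); :func:`master_curve` checks the superposition directly by
rescaling every loss curve to its peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import lmfit
import numpy as np
from scipy.signal import find_peaks, medfilt

from .permittivity_models import (
    PROCESS_LABELS,
    ConductivityTerm,
    HNComponent,
    PermittivitySpectrum,
    SpectrumModel,
    eval_component,
    tau_hn_from_max,
    tau_max_from_hn,
)

__all__ = [
    "FitTemplate",
    "ProcessShape",
    "RelaxationRecord",
    "RelaxationTable",
    "FitResult",
    "SharedShapeFit",
    "MasterCurveResult",
    "FitFailureError",
    "fit_spectrum",
    "fit_with_selection",
    "fit_series_shared_shape",
    "master_curve",
]

_TINY_LOSS = 1e-12
_TAU_BOUNDS = (-12.0, 6.0)      # log10 tau_hn, s
_DEPS_BOUNDS = (-4.0, 3.0)      # log10 delta_eps
_SHAPE_MIN = 0.05


class FitFailureError(RuntimeError):
    """Raised when a fit does not converge; carries the best residual."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass(frozen=True)
class ProcessShape:
    """Shape constraints for one fitted process.

    ``a_fixed`` / ``b_fixed`` pin an exponent; free exponents start at
    the ``*_init`` values.  ``shared`` ('a' or 'b') marks the exponent
    a series fit holds common across temperatures.
    """

    a_fixed: float | None = None
    b_fixed: float | None = None
    a_init: float = 0.5
    b_init: float = 0.7
    shared: str | None = None


@dataclass(frozen=True)
class FitTemplate:
    """What to fit in one frequency window.

    At most two HN processes; ``shapes`` maps process label to its
    :class:`ProcessShape`.  ``window`` restricts the fitted frequencies;
    ``objective`` is ``'loss'`` (default, log residuals on eps'') or
    ``'complex'`` (joint with relative residuals on eps').
    """

    processes: tuple[str, ...]
    shapes: dict = field(default_factory=dict)
    include_conductivity: bool = True
    window: tuple[float, float] | None = None
    objective: str = "loss"

    def __post_init__(self) -> None:
        procs = tuple(self.processes)
        object.__setattr__(self, "processes", procs)
        if not 1 <= len(procs) <= 2:
            raise ValueError("a template fits one or two HN components")
        for p in procs:
            if p not in PROCESS_LABELS:
                raise ValueError(f"unknown process {p!r}")
        if self.objective not in ("loss", "complex"):
            raise ValueError("objective must be 'loss' or 'complex'")
        shapes = dict(self.shapes)
        for p in procs:
            shapes.setdefault(p, _default_shape(p))
        object.__setattr__(self, "shapes", shapes)

    @classmethod
    def default(cls, processes: Sequence[str], *, shared: str | None = None,
                shared_process: str = "alpha", include_conductivity: bool = True,
                window: tuple[float, float] | None = None,
                objective: str = "loss") -> "FitTemplate":
        """Template with field-standard constraints (alpha CD, secondary CC)."""
        shapes = {p: _default_shape(p) for p in processes}
        if shared is not None:
            shapes[shared_process] = replace(shapes[shared_process], shared=shared)
        return cls(tuple(processes), shapes, include_conductivity, window, objective)


def _default_shape(process: str) -> ProcessShape:
    if process == "alpha":
        return ProcessShape(a_fixed=1.0, b_init=0.7)
    return ProcessShape(b_fixed=1.0, a_init=0.5)


@dataclass(frozen=True)
class RelaxationRecord:
    """Fitted parameters of one process at one temperature."""

    temperature: float
    process: str
    tau_max: float
    delta_eps: float
    a: float
    b: float
    se_tau: float = math.nan
    se_delta_eps: float = math.nan
    residual_norm: float = math.nan
    flag: str | None = None

    def __post_init__(self) -> None:
        if self.tau_max <= 0 or self.delta_eps <= 0:
            raise ValueError("tau_max and delta_eps must be positive")


@dataclass
class RelaxationTable:
    """Per-temperature, per-process relaxation parameters for one material."""

    records: list = field(default_factory=list)
    material: str | None = None

    def add(self, record: RelaxationRecord) -> None:
        for r in self.records:
            if r.process == record.process and r.temperature == record.temperature:
                raise ValueError(
                    f"duplicate record for {record.process} at {record.temperature} K")
        self.records.append(record)

    def process(self, label: str) -> list:
        return [r for r in self.records if r.process == label]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "temperature_K": r.temperature,
                    "process": r.process,
                    "tau_max_s": r.tau_max,
                    "delta_eps": r.delta_eps,
                    "a": r.a,
                    "b": r.b,
                    "se_tau": r.se_tau,
                    "se_deltaeps": r.se_delta_eps,
                    "flag": r.flag or "",
                }
                for r in self.records
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, material: str | None = None) -> "RelaxationTable":
        import pandas as pd

        df = pd.read_csv(path)
        table = cls(material=material)
        for _, row in df.iterrows():
            flag = row.get("flag", "")
            table.add(RelaxationRecord(
                temperature=float(row["temperature_K"]), process=str(row["process"]),
                tau_max=float(row["tau_max_s"]), delta_eps=float(row["delta_eps"]),
                a=float(row["a"]), b=float(row["b"]),
                se_tau=float(row.get("se_tau", math.nan)),
                se_delta_eps=float(row.get("se_deltaeps", math.nan)),
                flag=None if (isinstance(flag, float) and math.isnan(flag)) or flag == "" else str(flag),
            ))
        return table


@dataclass(frozen=True)
class FitResult:
    """Converged single-spectrum decomposition."""

    model: SpectrumModel
    records: tuple
    residual_norm: float
    success: bool
    result: object = None


@dataclass(frozen=True)
class SharedShapeFit:
    """Global series fit with one shared shape exponent."""

    table: RelaxationTable
    shared_process: str
    shared_param: str
    shared_value: float
    shared_stderr: float
    residual_norm: float
    result: object = None


@dataclass(frozen=True)
class MasterCurveResult:
    """Peak-rescaled loss curves and their maximum mutual deviation."""

    curves: tuple          # per spectrum: (log10(nu/nu_peak), loss/loss_peak)
    overlap_deviation: float
    excluded: tuple        # indices of spectra whose peak was not usable


# ---------------------------------------------------------------------------
# Parameter plumbing


def _param_names(label: str, suffix: str = "") -> dict:
    return {
        "lgtau": f"lgtau_{label}{suffix}",
        "lgde": f"lgde_{label}{suffix}",
        "a": f"a_{label}{suffix}",
        "b": f"b_{label}{suffix}",
    }


def _add_process_params(params: lmfit.Parameters, label: str, shape: ProcessShape,
                        lgtau0: float, lgde0: float, suffix: str = "",
                        shared_name: dict | None = None) -> None:
    names = _param_names(label, suffix)
    params.add(names["lgtau"], value=lgtau0, min=_TAU_BOUNDS[0], max=_TAU_BOUNDS[1])
    params.add(names["lgde"], value=lgde0, min=_DEPS_BOUNDS[0], max=_DEPS_BOUNDS[1])
    for exp_name, fixed, init in (("a", shape.a_fixed, shape.a_init),
                                  ("b", shape.b_fixed, shape.b_init)):
        pname = names[exp_name]
        if shared_name and shared_name.get(exp_name):
            params.add(pname, expr=shared_name[exp_name])
        elif fixed is not None:
            params.add(pname, value=fixed, vary=False)
        else:
            params.add(pname, value=init, min=_SHAPE_MIN, max=1.0)


def _components_from_params(params, template: FitTemplate, suffix: str = "") -> tuple:
    comps = []
    for label in template.processes:
        names = _param_names(label, suffix)
        comps.append(HNComponent(
            label=label,
            delta_eps=10.0 ** params[names["lgde"]].value
            if hasattr(params[names["lgde"]], "value") else 10.0 ** params[names["lgde"]],
            tau_hn=10.0 ** params[names["lgtau"]].value
            if hasattr(params[names["lgtau"]], "value") else 10.0 ** params[names["lgtau"]],
            a=params[names["a"]].value if hasattr(params[names["a"]], "value") else params[names["a"]],
            b=params[names["b"]].value if hasattr(params[names["b"]], "value") else params[names["b"]],
        ))
    return tuple(comps)


def _model_loss(pv: dict, template: FitTemplate, nu: np.ndarray, suffix: str = "") -> np.ndarray:
    omega = 2.0 * np.pi * nu
    loss = np.zeros_like(nu)
    for label in template.processes:
        names = _param_names(label, suffix)
        de = 10.0 ** pv[names["lgde"]]
        tau = 10.0 ** pv[names["lgtau"]]
        a, b = pv[names["a"]], pv[names["b"]]
        z = de / (1.0 + (1j * omega * tau) ** a) ** b
        loss = loss - z.imag
    if template.include_conductivity:
        loss = loss + 10.0 ** pv[f"lgA{suffix}"] / omega ** pv[f"s{suffix}"]
    return loss


def _model_real(pv: dict, template: FitTemplate, nu: np.ndarray, suffix: str = "") -> np.ndarray:
    omega = 2.0 * np.pi * nu
    re = np.zeros_like(nu)
    for label in template.processes:
        names = _param_names(label, suffix)
        de = 10.0 ** pv[names["lgde"]]
        tau = 10.0 ** pv[names["lgtau"]]
        a, b = pv[names["a"]], pv[names["b"]]
        z = de / (1.0 + (1j * omega * tau) ** a) ** b
        re = re + z.real
    return re


def _spectrum_residual(pv: dict, template: FitTemplate, nu, loss_data, real_data=None,
                       suffix: str = "") -> np.ndarray:
    model_loss = np.clip(_model_loss(pv, template, nu, suffix), _TINY_LOSS, None)
    data_loss = np.clip(loss_data, _TINY_LOSS, None)
    res = np.log(model_loss) - np.log(data_loss)
    if template.objective == "complex" and real_data is not None:
        model_re = pv[f"einf{suffix}"] + _model_real(pv, template, nu, suffix)
        res = np.concatenate([res, (model_re - real_data) / np.abs(real_data)])
    return res


# ---------------------------------------------------------------------------
# Initialization


def _pick_peaks(nu: np.ndarray, loss: np.ndarray, n_wanted: int) -> list:
    """Seed (nu_peak, height) pairs from median-smoothed local maxima.

    Peaks are ranked by prominence on the log-loss curve, where a weak
    secondary shoulder stands out against the power-law flank of a much
    stronger neighbor; noise wrinkles surviving the 5-point median
    filter have far smaller log-prominence than real processes.
    """
    k = 5 if loss.size >= 5 else (loss.size // 2) * 2 + 1
    smooth = np.log10(np.clip(medfilt(loss, kernel_size=k), _TINY_LOSS, None))
    idx, props = find_peaks(smooth, prominence=0.02)
    order = np.argsort(props["prominences"])[::-1]
    chosen = sorted(int(idx[j]) for j in order[:n_wanted])
    peaks = [(float(nu[i]), float(max(loss[i], _TINY_LOSS))) for i in chosen]
    if not peaks:
        # no interior maximum: seed mid-window
        mid = float(np.sqrt(nu[0] * nu[-1]))
        peaks = [(mid, float(np.median(loss)))]
    while len(peaks) < n_wanted:
        # place the missing (faster) process three decades above the last
        peaks.append((peaks[-1][0] * 1e3, peaks[-1][1] * 0.1))
    return peaks


def _initial_params(spectrum: PermittivitySpectrum, template: FitTemplate) -> lmfit.Parameters:
    nu, loss = spectrum.frequencies, spectrum.eps_imag
    peaks = _pick_peaks(nu, loss, len(template.processes))
    params = lmfit.Parameters()
    # slower process (lower peak frequency) first, in canonical order
    ordered = sorted(template.processes, key=PROCESS_LABELS.index)
    for label, (nu_pk, height) in zip(ordered, peaks):
        shape = template.shapes[label]
        a0 = shape.a_fixed if shape.a_fixed is not None else shape.a_init
        b0 = shape.b_fixed if shape.b_fixed is not None else shape.b_init
        tau_max0 = 1.0 / (2.0 * np.pi * nu_pk)
        lgtau0 = float(np.clip(math.log10(tau_hn_from_max(a0, b0, tau_max0)), *_TAU_BOUNDS))
        lgde0 = float(np.clip(math.log10(2.0 * height), *_DEPS_BOUNDS))
        _add_process_params(params, label, shape, lgtau0, lgde0)
    if template.include_conductivity:
        a_init = float(np.clip(math.log10(max(loss[0], _TINY_LOSS) * 2.0 * np.pi * nu[0]),
                               -8.0, 4.0))
        params.add("lgA", value=a_init, min=-8.0, max=4.0)
        params.add("s", value=1.0, min=0.51, max=1.2)
    if template.objective == "complex":
        params.add("einf", value=float(spectrum.eps_real[-1]), min=1.0, max=200.0)
    return params


def _count_offwindow(params, template: FitTemplate, nu_lo: float, nu_hi: float,
                     suffix: str = "") -> int:
    """Number of components whose loss peak is >2 decades off-window."""
    n = 0
    for label in template.processes:
        names = _param_names(label, suffix)
        tau_mx = tau_max_from_hn(params[names["a"]].value, params[names["b"]].value,
                                 10.0 ** params[names["lgtau"]].value)
        nu_pk = 1.0 / (2.0 * np.pi * tau_mx)
        if nu_pk < nu_lo / 100.0 or nu_pk > nu_hi * 100.0:
            n += 1
    return n


# ---------------------------------------------------------------------------
# Single-spectrum fit


def _windowed(spectrum: PermittivitySpectrum, template: FitTemplate) -> PermittivitySpectrum:
    if template.window is None:
        return spectrum
    return spectrum.window(*template.window)


def _estimate_eps_inf(spectrum: PermittivitySpectrum, comps: tuple) -> float:
    # mean over the five highest frequencies of (data eps' - model component eps')
    nu = spectrum.frequencies[-5:]
    re = spectrum.eps_real[-5:].copy()
    for c in comps:
        re = re - eval_component(c, nu).real
    return float(max(np.mean(re), 1.0))


def _records_from_fit(minimizer_result, template: FitTemplate,
                      spectrum: PermittivitySpectrum, residual_norm: float,
                      suffix: str = "") -> list:
    params = minimizer_result.params
    nu_lo, nu_hi = spectrum.frequencies[0], spectrum.frequencies[-1]
    records = []
    for label in template.processes:
        names = _param_names(label, suffix)
        a = params[names["a"]].value
        b = params[names["b"]].value
        tau_hn = 10.0 ** params[names["lgtau"]].value
        delta_eps = 10.0 ** params[names["lgde"]].value
        tau_mx = tau_max_from_hn(a, b, tau_hn)
        nu_pk = 1.0 / (2.0 * np.pi * tau_mx)
        flag = None
        if nu_pk < nu_lo / 100.0 or nu_pk > nu_hi * 100.0:
            flag = "ill_constrained"
        elif delta_eps <= 10.0 ** (_DEPS_BOUNDS[0] + 1.0):
            # amplitude collapsed to the bound: no such process in the data
            flag = "ill_constrained"
        se_lgtau = params[names["lgtau"]].stderr
        se_lgde = params[names["lgde"]].stderr
        records.append(RelaxationRecord(
            temperature=spectrum.temperature, process=label,
            tau_max=tau_mx, delta_eps=delta_eps, a=a, b=b,
            se_tau=tau_mx * math.log(10) * se_lgtau if se_lgtau else math.nan,
            se_delta_eps=delta_eps * math.log(10) * se_lgde if se_lgde else math.nan,
            residual_norm=residual_norm, flag=flag,
        ))
    return records


def fit_spectrum(spectrum: PermittivitySpectrum, template: FitTemplate,
                 seed: int | None = 0, max_restarts: int = 5) -> FitResult:
    """Least-squares decomposition of one spectrum.

    Peak-picking seeds the optimizer; on poor convergence up to
    ``max_restarts`` seeded multi-starts jitter the time parameters.
    Raises :class:`FitFailureError` (carrying the best residual) if no
    start converges.  Components whose fitted loss peak lies more than
    two decades outside the fitted window are flagged
    ``ill_constrained`` on their record.
    """
    spec = _windowed(spectrum, template)
    nu, loss = spec.frequencies, spec.eps_imag
    if nu.size < 8:
        raise ValueError("need at least 8 points in the fit window")
    real = spec.eps_real if template.objective == "complex" else None

    def residual(params):
        pv = params.valuesdict()
        return _spectrum_residual(pv, template, nu, loss, real)

    rng = np.random.default_rng(seed)
    best = None
    params0 = _initial_params(spec, template)
    lg_lo = math.log10(1.0 / (2.0 * np.pi * nu[-1])) - 1.0
    lg_hi = math.log10(1.0 / (2.0 * np.pi * nu[0])) + 1.0
    for attempt in range(max_restarts + 1):
        params = params0.copy()
        if attempt > 0:
            # resample free time parameters inside the window
            for name in params:
                if name.startswith("lgtau") and params[name].vary:
                    p = params[name]
                    if attempt <= 2:
                        p.value = float(np.clip(p.value + rng.normal(0.0, 1.0), p.min, p.max))
                    else:
                        p.value = float(np.clip(rng.uniform(lg_lo, lg_hi), p.min, p.max))
        try:
            out = lmfit.minimize(residual, params, method="least_squares")
        except Exception:
            continue
        norm = float(np.sqrt(np.mean(out.residual ** 2)))
        n_flags = _count_offwindow(out.params, template, nu[0], nu[-1])
        key = (not out.success, norm, n_flags)
        if best is None or key < best[0]:
            best = (key, out)
        if out.success and norm < 0.05:
            break
    if best is None:
        raise FitFailureError("spectrum fit did not converge", None)
    (failed, norm, _), out = best
    if failed:
        raise FitFailureError("spectrum fit did not converge", best_residual=norm)

    comps = _components_from_params(out.params, template)
    pv = out.params.valuesdict()
    if template.include_conductivity:
        cond = ConductivityTerm(10.0 ** pv["lgA"], pv["s"])
    else:
        cond = ConductivityTerm(0.0, 1.0)
    if template.objective == "complex":
        eps_inf = pv["einf"]
    else:
        eps_inf = _estimate_eps_inf(spec, comps)
    model = SpectrumModel(eps_inf=eps_inf, conductivity=cond, components=comps)
    records = _records_from_fit(out, template, spec, norm)
    return FitResult(model=model, records=tuple(records), residual_norm=norm,
                     success=bool(out.success), result=out)


def fit_with_selection(spectrum: PermittivitySpectrum, template_one: FitTemplate,
                       template_two: FitTemplate, seed: int | None = 0,
                       improvement: float = 0.20, merge_factor: float = 3.0) -> FitResult:
    """Choose between one- and two-component decompositions.

    The two-component fit is preferred only when it lowers the residual
    norm by more than ``improvement`` (default 20%) and both fitted
    peaks lie within two decades of the window; two components whose
    loss-peak times agree within ``merge_factor`` are considered one
    process and the single-component fit is returned instead.
    """
    one = fit_spectrum(spectrum, template_one, seed=seed)
    try:
        two = fit_spectrum(spectrum, template_two, seed=seed)
    except FitFailureError:
        return one
    taus = sorted(r.tau_max for r in two.records)
    overlapping = len(taus) == 2 and taus[1] / taus[0] < merge_factor
    any_flagged = any(r.flag for r in two.records)
    if overlapping or any_flagged:
        return one
    if two.residual_norm < (1.0 - improvement) * one.residual_norm:
        return two
    return one


# ---------------------------------------------------------------------------
# Shared-shape series fit


def fit_series_shared_shape(spectra: Sequence[PermittivitySpectrum],
                            template: FitTemplate,
                            seed: int | None = 0,
                            material: str | None = None) -> SharedShapeFit:
    """Global fit of a temperature series with one shared shape exponent.

    The template must mark exactly one process's exponent as shared
    (``ProcessShape.shared`` set to 'a' or 'b'); that exponent is a
    single parameter across all spectra while every time parameter and
    strength stays per-temperature.  Individual per-spectrum fits seed
    the global refinement.
    """
    if len(spectra) < 3:
        raise ValueError("a shared-shape fit needs at least 3 spectra")
    shared_proc = None
    shared_exp = None
    for label in template.processes:
        s = template.shapes[label].shared
        if s is not None:
            if shared_proc is not None:
                raise ValueError("exactly one shared exponent is supported")
            shared_proc, shared_exp = label, s
    if shared_proc is None:
        raise ValueError("template designates no shared shape exponent")

    # stage 1: independent fits (shared exponent free per spectrum)
    indiv_template = FitTemplate(
        template.processes,
        {
            label: replace(
                template.shapes[label], shared=None,
                **({f"{shared_exp}_fixed": None} if label == shared_proc else {}),
            )
            for label in template.processes
        },
        template.include_conductivity, template.window, template.objective,
    )
    indiv = [fit_spectrum(sp, indiv_template, seed=seed) for sp in spectra]

    # reseed components the individual fits left ill-constrained — or that
    # sit far off the temperature trend (label swaps between overlapping
    # processes) — from the trend of the well-determined ones
    seeds: list[dict] = [{} for _ in spectra]
    for label in template.processes:
        temps_inv = np.array([1.0 / sp.temperature for sp in spectra])
        lgtau = np.empty(len(spectra))
        lgde = np.empty(len(spectra))
        a_arr = np.empty(len(spectra))
        b_arr = np.empty(len(spectra))
        bad = np.zeros(len(spectra), dtype=bool)
        for i, fr in enumerate(indiv):
            rec = next(r for r in fr.records if r.process == label)
            comp = fr.model.component(label)
            lgtau[i] = math.log10(comp.tau_hn)
            lgde[i] = math.log10(comp.delta_eps)
            a_arr[i], b_arr[i] = comp.a, comp.b
            bad[i] = rec.flag is not None
        trend = None
        if (~bad).sum() >= 3:
            # robust pass: drop points >0.5 decade off the Arrhenius-like trend
            trend = np.polyfit(temps_inv[~bad], lgtau[~bad], 1)
            resid = lgtau - np.polyval(trend, temps_inv)
            bad |= np.abs(resid) > 0.5
            if (~bad).sum() >= 2:
                trend = np.polyfit(temps_inv[~bad], lgtau[~bad], 1)
        for i in range(len(spectra)):
            if bad[i] and trend is not None and (~bad).any():
                seeds[i][label] = dict(
                    lgtau=float(np.polyval(trend, temps_inv[i])),
                    lgde=float(np.median(lgde[~bad])),
                    a=float(np.median(a_arr[~bad])), b=float(np.median(b_arr[~bad])))
            else:
                seeds[i][label] = dict(lgtau=lgtau[i], lgde=lgde[i],
                                       a=a_arr[i], b=b_arr[i])

    shared_name = f"{shared_exp}_{shared_proc}_shared"
    params = lmfit.Parameters()
    init_shared = float(np.median([s[shared_proc][shared_exp] for s in seeds]))
    params.add(shared_name, value=np.clip(init_shared, _SHAPE_MIN + 1e-3, 1.0 - 1e-6),
               min=_SHAPE_MIN, max=1.0)

    windows = [_windowed(sp, template) for sp in spectra]
    for i, (spec, fr) in enumerate(zip(windows, indiv)):
        suffix = f"_{i}"
        for label in template.processes:
            sd = seeds[i][label]
            shape = template.shapes[label]
            share_map = {shared_exp: shared_name} if label == shared_proc else None
            _add_process_params(
                params, label, shape,
                lgtau0=float(np.clip(sd["lgtau"], *_TAU_BOUNDS)),
                lgde0=float(np.clip(sd["lgde"], *_DEPS_BOUNDS)),
                suffix=suffix, shared_name=share_map,
            )
        if template.include_conductivity:
            amp = max(fr.model.conductivity.amplitude, 1e-8)
            params.add(f"lgA{suffix}", value=float(np.clip(math.log10(amp), -8, 4)),
                       min=-8.0, max=4.0)
            params.add(f"s{suffix}", value=fr.model.conductivity.s_exponent,
                       min=0.51, max=1.2)
        if template.objective == "complex":
            params.add(f"einf{suffix}", value=fr.model.eps_inf, min=1.0, max=200.0)

    def residual(params):
        pv = params.valuesdict()
        parts = [
            _spectrum_residual(pv, template, spec.frequencies, spec.eps_imag,
                               spec.eps_real if template.objective == "complex" else None,
                               suffix=f"_{i}")
            for i, spec in enumerate(windows)
        ]
        return np.concatenate(parts)

    out = lmfit.minimize(residual, params, method="least_squares")
    if not out.success:
        raise FitFailureError("shared-shape series fit did not converge",
                              float(np.sqrt(np.mean(out.residual ** 2))))
    norm = float(np.sqrt(np.mean(out.residual ** 2)))

    table = RelaxationTable(material=material)
    for i, spec in enumerate(windows):
        for rec in _records_from_fit(out, template, spec, norm, suffix=f"_{i}"):
            table.add(rec)
    shared_par = out.params[shared_name]
    return SharedShapeFit(
        table=table, shared_process=shared_proc, shared_param=shared_exp,
        shared_value=float(shared_par.value),
        shared_stderr=float(shared_par.stderr) if shared_par.stderr else math.nan,
        residual_norm=norm, result=out,
    )


# ---------------------------------------------------------------------------
# Master curve


def _refine_peak(log_nu: np.ndarray, loss: np.ndarray, i: int) -> tuple[float, float]:
    """Parabolic refinement of a grid peak in (log nu, loss)."""
    x = log_nu[i - 1:i + 2]
    y = loss[i - 1:i + 2]
    denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
    a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
    if a >= 0:
        return float(log_nu[i]), float(loss[i])
    b = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0]) + x[0] ** 2 * (y[1] - y[2])) / denom
    xv = -b / (2 * a)
    c = y[0] - a * x[0] ** 2 - b * x[0]
    return float(xv), float(a * xv ** 2 + b * xv + c)


def master_curve(spectra: Sequence[PermittivitySpectrum],
                 process: str = "alpha",
                 window: tuple[float, float] | None = None,
                 grid_points: int = 201) -> MasterCurveResult:
    """Rescale loss curves to their peak and measure their overlap.

    Every curve is normalized by its loss-peak frequency and height
    (grid argmax with parabolic refinement); the overlap deviation is
    the maximum, over the common reduced-frequency support, of the
    pointwise standard deviation across the normalized curves.  Spectra whose peak sits at the
    window edge are excluded with a warning flag in ``excluded``.
    A temperature-independent lineshape (time-temperature
    superposition) gives deviation at the noise level.
    """
    curves = []
    excluded = []
    for idx, sp in enumerate(spectra):
        spec = sp if window is None else sp.window(*window)
        log_nu = np.log10(spec.frequencies)
        loss = spec.eps_imag
        # locate the peak on a median-smoothed copy so that noise does not
        # jitter the normalization point; rescale the raw curve
        k = 5 if loss.size >= 5 else (loss.size // 2) * 2 + 1
        smooth = medfilt(loss, kernel_size=k)
        i = int(np.argmax(smooth))
        if i == 0 or i == loss.size - 1:
            excluded.append(idx)
            continue
        log_pk, loss_pk = _refine_peak(log_nu, smooth, i)
        curves.append((log_nu - log_pk, loss / loss_pk))
    if len(curves) < 2:
        raise ValueError("need at least two spectra with interior loss peaks")
    lo = max(c[0][0] for c in curves)
    hi = min(c[0][-1] for c in curves)
    if hi <= lo:
        raise ValueError("rescaled curves share no common support")
    grid = np.linspace(lo, hi, grid_points)
    stack = np.vstack([np.interp(grid, x, y) for x, y in curves])
    deviation = float(np.max(np.std(stack, axis=0)))
    return MasterCurveResult(curves=tuple(curves), overlap_deviation=deviation,
                             excluded=tuple(excluded))
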