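"""Synthetic broadband-dielectric datasets from parameterized material cards.

A :class:`MaterialCard` bundles everything needed to emulate the
dielectric response of one amorphous glass-forming drug: a VFT law for
the cooperative alpha relaxation, a Johari-Goldstein beta process with
the characteristic kink at T_g, Arrhenius laws for the intramolecular
gamma / gamma' processes, a dc-conductivity tail, and (for materials
that recrystallize above T_g) Avrami parameters describing how the
amorphous fraction decays during an isothermal hold.

Three presets mimic the benzodiazepines studied by broadband dielectric
spectroscopy: ``dia_like`` (diazepam-like, does not recrystallize),
``nor_like`` (nordazepam-like) and ``tetra_like`` (tetrazepam-like).
Alpha-process VFT parameters, shape exponents, glass-transition /
melting temperatures and Avrami parameters follow published values for
those materials; dielectric strengths, secondary-process Arrhenius
parameters and the conductivity amplitude are plausible defaults (no
published values exist) and are flagged ``paper_derived=False`` on the
corresponding :class:`ProcessLaw`.

The beta process is generated from the coupling model: above T_g its
relaxation time tracks ``offset * t_c^n * tau_alpha^(1-n)`` (n from the
alpha lineshape), and below T_g it continues as an Arrhenius law
anchored at the T_g value — producing the kink at T_g that real JG
relaxations show.  A plain two-segment ``arrhenius_kink`` law is also
available.

Noise model: multiplicative log-normal noise on the loss and Gaussian
noise on eps' with standard deviation proportional to the model's
static permittivity, independent across frequencies.  Identical
(card, seed) inputs give bit-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .permittivity_models import (
    PROCESS_LABELS,
    ConductivityTerm,
    HNComponent,
    PermittivitySpectrum,
    SpectrumModel,
    eval_model,
    tau_hn_from_max,
)
from .relaxation_analysis import GAS_CONSTANT, LN10, VFTFit, coupling_parameter, cm_predicted_jg_time

__all__ = [
    "ProcessLaw",
    "AvramiTruth",
    "MaterialCard",
    "preset_card",
    "simulate_spectrum",
    "simulate_temperature_series",
    "simulate_crystallization_series",
    "default_frequency_grid",
    "default_crystallization_times",
]

_LAWS = ("vft", "arrhenius", "arrhenius_kink", "jg_cm")

#: processes whose loss peak lies more than this many decades outside
#: the simulated frequency grid are omitted from the spectral model
PEAK_DROP_DECADES = 4.0


@dataclass(frozen=True)
class ProcessLaw:
    """Temperature law + lineshape for one relaxation process.

    ``law`` is one of ``vft`` (cooperative alpha), ``arrhenius`` (local
    gamma / gamma'), ``arrhenius_kink`` (two activation energies with a
    breakpoint) or ``jg_cm`` (coupling-model-tied JG beta, see module
    docstring).  ``params`` holds the law parameters; ``a``/``b`` the HN
    shape; ``delta_eps`` the dielectric strength, which scales with the
    amorphous fraction during crystallization when
    ``delta_eps_scales`` is set.  ``paper_derived`` marks parameters
    taken from published tables versus package defaults.
    """

    process: str
    law: str
    params: dict
    a: float = 1.0
    b: float = 1.0
    delta_eps: float = 1.0
    delta_eps_scales: bool = True
    paper_derived: bool = True

    def __post_init__(self) -> None:
        if self.process not in PROCESS_LABELS:
            raise ValueError(f"unknown process {self.process!r}")
        if self.law not in _LAWS:
            raise ValueError(f"unknown law {self.law!r}")
        if self.process == "alpha" and self.law != "vft":
            raise ValueError("the alpha process must carry a VFT law")
        if self.process == "beta" and self.law not in ("arrhenius_kink", "jg_cm"):
            raise ValueError("the beta process must carry a kinked law")
        if self.process in ("gamma", "gamma_prime") and self.law != "arrhenius":
            raise ValueError("gamma processes must carry Arrhenius laws")


@dataclass(frozen=True)
class AvramiTruth:
    """Generating Avrami parameters for a crystallizing material."""

    n: float
    k_per_s: float
    t_onset_s: float

    def __post_init__(self) -> None:
        if self.n <= 0 or self.k_per_s <= 0 or self.t_onset_s < 0:
            raise ValueError("Avrami parameters must be positive")

    @property
    def Z(self) -> float:
        """Avrami constant Z = k^n (units s^-n)."""
        return self.k_per_s ** self.n

    def fraction(self, elapsed) -> np.ndarray:
        """Crystallized fraction X(t); zero before the onset time."""
        t = np.asarray(elapsed, dtype=float)
        dt = np.clip(t - self.t_onset_s, 0.0, None)
        return 1.0 - np.exp(-((self.k_per_s * dt) ** self.n))


@dataclass(frozen=True)
class MaterialCard:
    """Complete generator parameterization for one material."""

    name: str
    eps_inf: float
    conductivity: ConductivityTerm
    processes: tuple[ProcessLaw, ...]
    t_g: float
    t_m: float
    t_g_dsc: float | None = None
    avrami: AvramiTruth | None = None
    noise_loss: float = 0.01
    noise_real: float = 0.002
    t_c: float = 2e-12

    def __post_init__(self) -> None:
        object.__setattr__(self, "processes", tuple(self.processes))
        if not 0 < self.t_g < self.t_m:
            raise ValueError("need 0 < T_g < T_m")
        labels = [p.process for p in self.processes]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate process laws")

    def process_law(self, label: str) -> ProcessLaw:
        for p in self.processes:
            if p.process == label:
                return p
        raise KeyError(label)

    def coupling_n(self) -> float:
        """Coupling parameter from the card's alpha lineshape."""
        alpha = self.process_law("alpha")
        return coupling_parameter(alpha.a, alpha.b)

    def log10_tau(self, label: str, temperature: float) -> float:
        """log10 of the process's loss-peak relaxation time at T (K).

        Returns ``inf`` where the law diverges (alpha at or below the
        Vogel temperature).
        """
        law = self.process_law(label)
        T = float(temperature)
        if law.law == "vft":
            p = law.params
            if T <= p["T0"]:
                return math.inf
            fit = VFTFit(p["log10_tau0"], p["D"], p["T0"], p.get("convention", "decadic"))
            return float(fit.log10_tau(T))
        if law.law == "arrhenius":
            p = law.params
            return p["log10_tau_inf"] + p["ea_kj_mol"] * 1e3 / (GAS_CONSTANT * LN10 * T)
        if law.law == "arrhenius_kink":
            p = law.params
            ea = p["ea_below_kj_mol"] if T <= p["t_kink"] else p["ea_above_kj_mol"]
            return p["log10_tau_at_kink"] + ea * 1e3 / (GAS_CONSTANT * LN10) * (1.0 / T - 1.0 / p["t_kink"])
        # jg_cm: coupling-model-tied beta with Arrhenius continuation below T_g
        p = law.params
        n = self.coupling_n()
        offset = p.get("offset", 10.0)
        t_c = p.get("t_c", self.t_c)
        log10_tau_beta_tg = math.log10(offset * cm_predicted_jg_time(100.0, n, t_c))
        if T > self.t_g:
            log10_tau_alpha = self.log10_tau("alpha", T)
            tau_alpha = 10.0 ** log10_tau_alpha
            return math.log10(offset * cm_predicted_jg_time(tau_alpha, n, t_c))
        ea = p["ea_below_kj_mol"]
        return log10_tau_beta_tg + ea * 1e3 / (GAS_CONSTANT * LN10) * (1.0 / T - 1.0 / self.t_g)

    def tau_max(self, label: str, temperature: float) -> float:
        return 10.0 ** self.log10_tau(label, temperature)

    def noise_free(self) -> "MaterialCard":
        """Copy of the card with both noise levels set to zero."""
        return replace(self, noise_loss=0.0, noise_real=0.0)


# ---------------------------------------------------------------------------
# Presets


def _alpha(log10_tau0, D, T0, b, delta_eps):
    return ProcessLaw(
        "alpha", "vft",
        {"log10_tau0": log10_tau0, "D": D, "T0": T0, "convention": "decadic"},
        a=1.0, b=b, delta_eps=delta_eps,
    )


def preset_card(name: str) -> MaterialCard:
    """Preset material cards: ``dia_like``, ``nor_like``, ``tetra_like``.

    Alpha VFT parameters (decadic convention), alpha shape exponents,
    T_g / T_m and Avrami parameters follow published values for the
    corresponding benzodiazepine; everything else (dielectric
    strengths, secondary-relaxation parameters, conductivity) is a
    plausible default flagged via ``paper_derived=False``.
    """
    cond = ConductivityTerm(amplitude=0.05, s_exponent=1.0)
    if name == "dia_like":
        return MaterialCard(
            name="dia_like", eps_inf=3.0, conductivity=cond,
            processes=(
                _alpha(-21.0, 10.5, 214.0, b=0.59, delta_eps=5.0),
                ProcessLaw("beta", "jg_cm", {"offset": 10.0, "ea_below_kj_mol": 55.0},
                           a=0.4, b=1.0, delta_eps=0.3, paper_derived=False),
                ProcessLaw("gamma", "arrhenius", {"log10_tau_inf": -16.5, "ea_kj_mol": 50.0},
                           a=0.35, b=1.0, delta_eps=0.5, paper_derived=False),
                ProcessLaw("gamma_prime", "arrhenius", {"log10_tau_inf": -17.5, "ea_kj_mol": 30.0},
                           a=0.3, b=1.0, delta_eps=0.2, paper_derived=False),
            ),
            t_g=312.6, t_m=404.0, t_g_dsc=317.8, avrami=None,
        )
    if name == "nor_like":
        return MaterialCard(
            name="nor_like", eps_inf=3.0, conductivity=cond,
            processes=(
                _alpha(-21.0, 10.3, 239.0, b=0.50, delta_eps=6.0),
                ProcessLaw("beta", "jg_cm", {"offset": 10.0, "ea_below_kj_mol": 60.0},
                           a=0.4, b=1.0, delta_eps=0.3, paper_derived=False),
                ProcessLaw("gamma", "arrhenius", {"log10_tau_inf": -17.0, "ea_kj_mol": 52.0},
                           a=0.35, b=1.0, delta_eps=0.4, paper_derived=False),
                ProcessLaw("gamma_prime", "arrhenius", {"log10_tau_inf": -17.8, "ea_kj_mol": 32.0},
                           a=0.3, b=1.0, delta_eps=0.02, paper_derived=False),
            ),
            t_g=347.2, t_m=487.0, t_g_dsc=346.8,
            avrami=AvramiTruth(n=1.1, k_per_s=4e-5, t_onset_s=8000.0),
        )
    if name == "tetra_like":
        return MaterialCard(
            name="tetra_like", eps_inf=3.0, conductivity=cond,
            processes=(
                _alpha(-20.7, 11.0, 207.0, b=0.59, delta_eps=5.5),
                ProcessLaw("beta", "jg_cm", {"offset": 10.0, "ea_below_kj_mol": 55.0},
                           a=0.4, b=1.0, delta_eps=0.3, paper_derived=False),
                ProcessLaw("gamma", "arrhenius", {"log10_tau_inf": -16.4, "ea_kj_mol": 49.0},
                           a=0.35, b=1.0, delta_eps=0.5, paper_derived=False),
                ProcessLaw("gamma_prime", "arrhenius", {"log10_tau_inf": -17.3, "ea_kj_mol": 26.0},
                           a=0.3, b=1.0, delta_eps=0.3, paper_derived=False),
            ),
            t_g=309.0, t_m=415.6, t_g_dsc=313.0,
            avrami=AvramiTruth(n=1.01, k_per_s=7e-5, t_onset_s=5000.0),
        )
    raise ValueError(f"unknown preset card {name!r}")


# ---------------------------------------------------------------------------
# Simulation


def default_frequency_grid(points_per_decade: int = 8,
                           nu_min: float = 1e-2, nu_max: float = 1e7) -> np.ndarray:
    """Log-spaced measurement grid (default 10^-2 .. 10^7 Hz)."""
    n = int(round(points_per_decade * math.log10(nu_max / nu_min))) + 1
    return np.logspace(math.log10(nu_min), math.log10(nu_max), n)


def _build_model(card: MaterialCard, temperature: float,
                 frequencies: np.ndarray, crystallinity: float) -> tuple[SpectrumModel, dict]:
    if not 0.0 <= crystallinity <= 1.0:
        raise ValueError("crystallinity must lie in [0, 1]")
    amorphous = 1.0 - crystallinity
    log_lo = math.log10(frequencies[0]) - PEAK_DROP_DECADES
    log_hi = math.log10(frequencies[-1]) + PEAK_DROP_DECADES
    comps = []
    truth_proc = {}
    for law in card.processes:
        log10_tau = card.log10_tau(law.process, temperature)
        if not math.isfinite(log10_tau):
            continue
        tau_max = 10.0 ** log10_tau
        log10_peak = -math.log10(2.0 * math.pi * tau_max)
        if not log_lo <= log10_peak <= log_hi:
            continue
        d_eps = law.delta_eps * (amorphous if law.delta_eps_scales else 1.0)
        if d_eps <= 0:
            continue
        comps.append(HNComponent(
            label=law.process, delta_eps=d_eps,
            tau_hn=tau_hn_from_max(law.a, law.b, tau_max), a=law.a, b=law.b,
        ))
        truth_proc[law.process] = {
            "tau_max_s": tau_max, "delta_eps": d_eps, "a": law.a, "b": law.b,
        }
    cond = ConductivityTerm(card.conductivity.amplitude * amorphous,
                            card.conductivity.s_exponent)
    model = SpectrumModel(eps_inf=card.eps_inf, conductivity=cond, components=tuple(comps))
    truth = {
        "card": card.name,
        "temperature_K": temperature,
        "crystallinity": crystallinity,
        "eps_inf": card.eps_inf,
        "conductivity_amplitude": cond.amplitude,
        "conductivity_s": cond.s_exponent,
        "processes": truth_proc,
    }
    return model, truth


def simulate_spectrum(card: MaterialCard, temperature: float,
                      frequencies: np.ndarray | None = None,
                      seed=None, crystallinity: float = 0.0,
                      elapsed: float | None = None) -> PermittivitySpectrum:
    """Forward-simulate one isothermal spectrum from a card.

    Processes whose loss peak lies more than four decades outside the
    grid are omitted (their contribution there is flat or negligible).
    With ``seed=None`` or zero card noise levels the spectrum is exact;
    otherwise multiplicative log-normal noise perturbs the loss and
    Gaussian noise (sd = ``noise_real`` x static permittivity) the real
    part.  Generating ground truth is embedded in ``metadata['truth']``.
    """
    if not 100.0 < temperature < card.t_m:
        raise ValueError("temperature outside the card's validity range")
    nu = default_frequency_grid() if frequencies is None else np.asarray(frequencies, float)
    model, truth = _build_model(card, temperature, nu, crystallinity)
    spec = eval_model(model, nu)
    re, im = spec.eps_real.copy(), spec.eps_imag.copy()
    if seed is not None and (card.noise_loss > 0 or card.noise_real > 0):
        rng = np.random.default_rng(seed)
        if card.noise_loss > 0:
            im = im * np.exp(card.noise_loss * rng.standard_normal(nu.size))
        if card.noise_real > 0:
            re = re + card.noise_real * model.eps_static * rng.standard_normal(nu.size)
    return PermittivitySpectrum(
        temperature=float(temperature), frequencies=nu, eps_real=re, eps_imag=im,
        elapsed=elapsed, metadata={"truth": truth, "material": card.name},
    )


def _spawn_seeds(seed, count: int):
    if seed is None:
        return [None] * count
    return np.random.SeedSequence(seed).spawn(count)


def simulate_temperature_series(card: MaterialCard, temperatures: Sequence[float],
                                frequencies: np.ndarray | None = None,
                                seed=None) -> list[PermittivitySpectrum]:
    """Independent-noise spectra at each temperature (one seed stream)."""
    seeds = _spawn_seeds(seed, len(temperatures))
    return [
        simulate_spectrum(card, T, frequencies, seed=s)
        for T, s in zip(temperatures, seeds)
    ]


def default_crystallization_times(card: MaterialCard, n_points: int = 60,
                                  completion: float = 0.995) -> np.ndarray:
    """Log-spaced hold times covering plateau, decay and completion."""
    if card.avrami is None:
        raise ValueError(f"card {card.name!r} does not crystallize")
    av = card.avrami
    t_end = av.t_onset_s + (-math.log(1.0 - completion)) ** (1.0 / av.n) / av.k_per_s
    return np.logspace(math.log10(av.t_onset_s / 50.0), math.log10(t_end), n_points)


def simulate_crystallization_series(card: MaterialCard, temperature: float,
                                    times: Sequence[float] | None = None,
                                    frequencies: np.ndarray | None = None,
                                    seed=None) -> list[PermittivitySpectrum]:
    """Isothermal hold during which the amorphous fraction decays.

    The crystallized fraction follows the card's Avrami law; every
    process's dielectric strength and the conductivity amplitude scale
    with the surviving amorphous fraction while eps_inf stays constant,
    so the static permittivity decays toward eps_inf.
    """
    if card.avrami is None:
        raise ValueError(f"card {card.name!r} has no Avrami parameters (does not crystallize)")
    if not card.t_g < temperature < card.t_m:
        raise ValueError("crystallization requires T_g < T < T_m")
    t = default_crystallization_times(card) if times is None else np.asarray(times, float)
    fractions = card.avrami.fraction(t)
    seeds = _spawn_seeds(seed, len(t))
    return [
        simulate_spectrum(card, temperature, frequencies, seed=s,
                          crystallinity=float(x), elapsed=float(ti))
        for ti, x, s in zip(t, fractions, seeds)
    ]
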