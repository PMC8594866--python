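"""Forward models of complex dielectric permittivity.

The broadband dielectric response of an amorphous molecular solid is
modelled as a sum of Havriliak-Negami (HN) relaxation components plus a
dc-conductivity power law,

    eps*(omega) = eps_inf + sum_i  d_eps_i / (1 + (i omega tau_HN_i)^a_i)^b_i
                  - i A / omega^s ,

with omega = 2 pi nu the angular frequency.  Each HN component has a
dielectric strength ``delta_eps``, a time parameter ``tau_hn`` and two
shape exponents ``a`` (symmetric broadening) and ``b`` (asymmetric
broadening).  Special cases: Cole-Cole (b = 1), Cole-Davidson (a = 1),
Debye (a = b = 1).

Sign convention: the dielectric loss eps'' is reported positive
everywhere in this package; complex arrays returned by
:func:`eval_component` carry the loss in their (positive) imaginary part.
The conductivity constants (sigma_0 and the vacuum permittivity) are
absorbed into a single amplitude ``A`` with loss contribution A/omega^s,
because only the product is identifiable from a loss spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PROCESS_LABELS",
    "HNComponent",
    "ConductivityTerm",
    "SpectrumModel",
    "PermittivitySpectrum",
    "eval_component",
    "eval_model",
    "tau_max_from_hn",
    "tau_hn_from_max",
    "peak_frequency",
]

#: Canonical relaxation-process names, ordered slow to fast.
PROCESS_LABELS = ("alpha", "beta", "gamma", "gamma_prime")

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class HNComponent:
    """One Havriliak-Negami relaxation component.

    Parameters
    ----------
    label:
        Process name; one of ``alpha``, ``beta``, ``gamma``, ``gamma_prime``.
    delta_eps:
        Dielectric strength (relaxation intensity), > 0.
    tau_hn:
        HN time parameter in seconds, > 0.  Related to the loss-peak
        relaxation time by :func:`tau_max_from_hn`.
    a, b:
        Shape exponents in (0, 1].  a = 1 is Cole-Davidson, b = 1 is
        Cole-Cole, a = b = 1 is Debye.
    """

    label: str
    delta_eps: float
    tau_hn: float
    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in PROCESS_LABELS:
            raise ValueError(f"unknown process label {self.label!r}")
        if not self.delta_eps > 0:
            raise ValueError("delta_eps must be > 0")
        if not self.tau_hn > 0:
            raise ValueError("tau_hn must be > 0")
        for name, val in (("a", self.a), ("b", self.b)):
            if not 0.0 < val <= 1.0:
                raise ValueError(f"shape exponent {name} must lie in (0, 1]")

    @property
    def tau_max(self) -> float:
        """Relaxation time of the loss maximum (seconds)."""
        return tau_max_from_hn(self.a, self.b, self.tau_hn)

    @property
    def peak_frequency(self) -> float:
        """Loss-peak frequency in Hz."""
        return peak_frequency(self)


@dataclass(frozen=True)
class ConductivityTerm:
    """dc-conductivity contribution ``A / omega^s`` to the loss.

    ``amplitude`` absorbs sigma_0/eps_0 (units s^-s); ``s_exponent`` is
    close to unity for pure ohmic conduction.  The term contributes to
    the imaginary permittivity only.
    """

    amplitude: float = 0.0
    s_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("conductivity amplitude must be >= 0")
        if not 0.5 < self.s_exponent <= 1.2:
            raise ValueError("s_exponent must lie in (0.5, 1.2]")

    def loss(self, frequencies: np.ndarray) -> np.ndarray:
        """Evaluate the conductivity loss at frequencies in Hz."""
        nu = _check_frequencies(frequencies)
        if self.amplitude == 0.0:
            return np.zeros_like(nu)
        return self.amplitude / (TWO_PI * nu) ** self.s_exponent


@dataclass(frozen=True)
class SpectrumModel:
    """Full spectral model: eps_inf + conductivity + HN components."""

    eps_inf: float = 1.0
    conductivity: ConductivityTerm = field(default_factory=ConductivityTerm)
    components: tuple[HNComponent, ...] = ()

    def __post_init__(self) -> None:
        if self.eps_inf < 1.0:
            raise ValueError("eps_inf must be >= 1")
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        if len(comps) > 4:
            raise ValueError("at most four HN components are supported")
        labels = [c.label for c in comps]
        if len(set(labels)) != len(labels):
            raise ValueError("component labels must be unique")

    @property
    def eps_static(self) -> float:
        """Zero-frequency limit of eps' (conductivity-free)."""
        return self.eps_inf + sum(c.delta_eps for c in self.components)

    def component(self, label: str) -> HNComponent:
        for c in self.components:
            if c.label == label:
                return c
        raise KeyError(label)


@dataclass(frozen=True)
class PermittivitySpectrum:
    """One isothermal frequency sweep of complex permittivity.

    ``eps_imag`` holds the dielectric loss with positive sign.
    ``elapsed`` is the time in seconds since an isothermal hold began
    (used by crystallization series); ``metadata`` carries free-form
    provenance such as generator ground truth.
    """

    temperature: float
    frequencies: np.ndarray
    eps_real: np.ndarray
    eps_imag: np.ndarray
    elapsed: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        freq = np.asarray(self.frequencies, dtype=float)
        re = np.asarray(self.eps_real, dtype=float)
        im = np.asarray(self.eps_imag, dtype=float)
        if not (freq.shape == re.shape == im.shape) or freq.ndim != 1:
            raise ValueError("frequency/eps arrays must be 1-d and equal length")
        if freq.size < 8:
            raise ValueError("a spectrum needs at least 8 points")
        if np.any(freq <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(np.diff(freq) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", freq)
        object.__setattr__(self, "eps_real", re)
        object.__setattr__(self, "eps_imag", im)

    def window(self, nu_lo: float, nu_hi: float) -> "PermittivitySpectrum":
        """Restrict to frequencies in [nu_lo, nu_hi]."""
        mask = (self.frequencies >= nu_lo) & (self.frequencies <= nu_hi)
        if mask.sum() < 8:
            raise ValueError("fewer than 8 points in the requested window")
        return PermittivitySpectrum(
            temperature=self.temperature,
            frequencies=self.frequencies[mask],
            eps_real=self.eps_real[mask],
            eps_imag=self.eps_imag[mask],
            elapsed=self.elapsed,
            metadata=dict(self.metadata),
        )


def _check_frequencies(frequencies) -> np.ndarray:
    nu = np.asarray(frequencies, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("frequencies must be positive (Hz)")
    return nu


def eval_component(component: HNComponent, frequencies) -> np.ndarray:
    """Evaluate one HN component at frequencies in Hz.

    Returns a complex array whose real part is the component's
    contribution to eps' and whose imaginary part is the (positive)
    loss.  Principal-branch complex exponentiation is used.
    """
    nu = _check_frequencies(frequencies)
    omega = TWO_PI * nu
    z = component.delta_eps / (1.0 + (1j * omega * component.tau_hn) ** component.a) ** component.b
    # physical convention eps* = eps' - i eps''; flip to store loss positive
    return np.conj(z)


def eval_model(model: SpectrumModel, frequencies) -> PermittivitySpectrum:
    """Evaluate the full model on a frequency grid (Hz).

    Additivity is exact: the returned loss is the sum of the component
    losses plus the conductivity term; eps' is eps_inf plus the sum of
    the component real parts.
    """
    nu = _check_frequencies(frequencies)
    re = np.full_like(nu, float(model.eps_inf))
    im = model.conductivity.loss(nu)
    for comp in model.components:
        z = eval_component(comp, nu)
        re = re + z.real
        im = im + z.imag
    return PermittivitySpectrum(temperature=np.nan, frequencies=nu, eps_real=re, eps_imag=im)


def _hn_shape_factor(a: float, b: float) -> float:
    # tau_max / tau_hn for an HN component
    x = np.pi / (2.0 * (b + 1.0))
    return np.sin(a * x) ** (-1.0 / a) * np.sin(a * b * x) ** (1.0 / a)


def tau_max_from_hn(a: float, b: float, tau_hn: float) -> float:
    """Loss-peak relaxation time of an HN component.

    Closed form::

        tau_max = tau_hn * sin(a pi / (2 (b+1)))^(-1/a)
                         * sin(a b pi / (2 (b+1)))^(1/a)

    For Cole-Cole (b = 1) this reduces to tau_max = tau_hn; for Debye it
    is the identity.
    """
    if not 0.0 < a <= 1.0 or not 0.0 < b <= 1.0:
        raise ValueError("shape exponents must lie in (0, 1]")
    if not tau_hn > 0:
        raise ValueError("tau_hn must be > 0")
    return float(tau_hn * _hn_shape_factor(a, b))


def tau_hn_from_max(a: float, b: float, tau_max: float) -> float:
    """Inverse of :func:`tau_max_from_hn`."""
    if not 0.0 < a <= 1.0 or not 0.0 < b <= 1.0:
        raise ValueError("shape exponents must lie in (0, 1]")
    if not tau_max > 0:
        raise ValueError("tau_max must be > 0")
    return float(tau_max / _hn_shape_factor(a, b))


def peak_frequency(component: HNComponent) -> float:
    """Frequency (Hz) of the component's loss maximum: 1/(2 pi tau_max)."""
    return 1.0 / (TWO_PI * component.tau_max)
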