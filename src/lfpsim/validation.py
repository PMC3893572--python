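"""Independent analytic oracles for the forward-modeling pipeline.

This module deliberately shares no code with :mod:`lfpsim.cable` or
:mod:`lfpsim.forward` — it derives its answers from the continuous cable
equation and the fundamental volume-conductor kernel alone, so agreement
with the simulation pipeline is evidence, not tautology.

The primary oracle is the sinusoidally driven finite passive cable ("stick")
with sealed ends.  In the frequency domain the passive cable equation

    λ² d²V/dx² = (1 + iωτ) V,      λ = sqrt(r_m / r_i),  τ = r_m c_m,

with a current I₀ e^{iωt} injected intracellularly at x = 0 and sealed-end
boundary conditions (dV/dx = 0 at x = L; at x = 0 the axial current equals
the injected current) has the solution

    V(x) = (I₀ r_i / γ) · cosh(γ (L − x)) / sinh(γ L),
    γ = sqrt(1 + iωτ) / λ.

The transmembrane current density per unit length follows analytically,

    i_m(x) = (1 + iωτ) g_m V(x)     (capacitive + leak),

and integrates to exactly I₀ over the stick (current conservation).  The
extracellular potential at a point r is then the point-source kernel
integrated numerically along the stick,

    φ(r) = 1/(4πσ) ∫₀^L i_m(x) / |r − x ẑ| dx,

by composite Gauss–Legendre quadrature refined until successive estimates
change by < 1e-9 mV.  ω = 0 is handled as the DC steady-state limit
(γ → 1/λ).

Also provided: the current-dipole far field φ = p cosθ / (4πσ r²), the
leading multipole of any current-conserving neuron.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["StickSpec", "analytic_stick_lfp", "analytic_stick_vm", "dipole_far_field"]


@dataclass(frozen=True)
class StickSpec:
    """Uniform passive stick along +z from z = 0 to z = length.

    The sinusoidal drive current (``amplitude`` nA at ``frequency`` Hz) is
    injected intracellularly at ``inject_end`` (0.0 for the z = 0 end, 1.0
    for the z = length end).  Ra in Ω·cm, cm in μF/cm², g_pas in S/cm².
    """

    length: float = 1000.0       # μm
    diameter: float = 2.0        # μm
    Ra: float = 150.0
    cm: float = 1.0
    g_pas: float = 1.0 / 30000.0
    frequency: float = 100.0     # Hz
    amplitude: float = 1.0       # nA
    inject_end: float = 0.0

    def __post_init__(self):
        for name in ("length", "diameter", "Ra", "cm", "g_pas", "amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.frequency < 0:
            raise ValueError("frequency must be >= 0")
        if self.inject_end not in (0.0, 1.0):
            raise ValueError("inject_end must be 0.0 or 1.0")

    # per-unit-length cable constants, SI-flavored but lengths in μm
    @property
    def r_i(self) -> float:
        """Axial resistance per unit length, Ω/μm."""
        return 1e4 * self.Ra / (math.pi * self.diameter ** 2 / 4.0)

    @property
    def g_m(self) -> float:
        """Membrane conductance per unit length, S/μm."""
        return self.g_pas * math.pi * self.diameter * 1e-8

    @property
    def tau_m(self) -> float:
        """Membrane time constant, ms."""
        return 1e-3 * self.cm / self.g_pas

    @property
    def lambda_dc(self) -> float:
        """DC length constant, μm."""
        return math.sqrt(1.0 / (self.g_m * self.r_i))

    def gamma(self) -> complex:
        """Complex propagation constant γ = sqrt(1 + iωτ)/λ, 1/μm."""
        omega_tau = 2.0 * math.pi * self.frequency * 1e-3 * self.tau_m
        return complex(np.sqrt(1.0 + 1j * omega_tau)) / self.lambda_dc

    def vm_profile(self, x: np.ndarray) -> np.ndarray:
        """Complex membrane-potential amplitude (mV) at distance x (μm) from
        the injection end."""
        g = self.gamma()
        L = self.length
        I0 = self.amplitude * 1e-9  # A
        # cosh(γ(L−x))/sinh(γL), written with exponentials bounded by 1
        num = np.exp(-g * x) * (1.0 + np.exp(-2.0 * g * (L - x)))
        den = 1.0 - np.exp(-2.0 * g * L)
        v = I0 * self.r_i / g * num / den  # volts
        return v * 1e3

    def im_density(self, x: np.ndarray) -> np.ndarray:
        """Complex transmembrane current amplitude per unit length (nA/μm)
        at distance x from the injection end."""
        omega_tau = 2.0 * math.pi * self.frequency * 1e-3 * self.tau_m
        v_volts = self.vm_profile(x) * 1e-3
        i_a_per_um = (1.0 + 1j * omega_tau) * self.g_m * v_volts
        return i_a_per_um * 1e9


def analytic_stick_vm(spec: StickSpec, x: np.ndarray) -> np.ndarray:
    """Complex membrane-potential amplitude at axial positions x (μm from the
    injection end)."""
    return spec.vm_profile(np.asarray(x, dtype=float))


def _gauss_panels(f, a: float, b: float, n_panels: int, order: int = 12):
    """Composite Gauss–Legendre quadrature of a complex-valued integrand."""
    nodes, weights = np.polynomial.legendre.leggauss(order)
    edges = np.linspace(a, b, n_panels + 1)
    mid = (edges[:-1] + edges[1:]) / 2.0
    half = (edges[1:] - edges[:-1]) / 2.0
    xs = (mid[:, None] + half[:, None] * nodes[None, :]).ravel()
    ws = (half[:, None] * weights[None, :]).ravel()
    return np.sum(f(xs) * ws)


def analytic_stick_lfp(
    spec: StickSpec, eval_points, sigma: float, tol: float = 1e-9
) -> np.ndarray:
    """Complex extracellular-potential amplitude (mV) at the drive frequency.

    ``eval_points`` is an (M, 3) array of μm positions; the stick runs along
    +z from the origin.  The distributed membrane current (net equal to the
    injected current — the drive is an intracellular electrode, a monopole
    configuration) is integrated against the 1/(4πσr) kernel, with panel
    doubling until the estimate moves by less than ``tol`` mV.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    pts = np.atleast_2d(np.asarray(eval_points, dtype=float))
    out = np.empty(pts.shape[0], dtype=complex)

    for i, p in enumerate(pts):
        def integrand(x):
            # x is distance from the injection end; map to z coordinate
            z = x if spec.inject_end == 0.0 else spec.length - x
            dist = np.sqrt(p[0] ** 2 + p[1] ** 2 + (p[2] - z) ** 2)
            dist = np.maximum(dist, spec.diameter / 2.0)
            return spec.im_density(x) / dist

        n = 16
        prev = _gauss_panels(integrand, 0.0, spec.length, n)
        while True:
            n *= 2
            cur = _gauss_panels(integrand, 0.0, spec.length, n)
            if abs(cur - prev) < tol * 4.0 * math.pi * sigma or n > 4096:
                break
            prev = cur
        out[i] = cur / (4.0 * math.pi * sigma)
    return out


def dipole_far_field(p: float, r: float, theta: float, sigma: float) -> float:
    """Current-dipole potential φ = p·cosθ/(4πσ r²) in mV.

    p in nA·μm, r in μm, σ in S/m; θ is the angle from the dipole axis.
    """
    if r <= 0:
        raise ValueError("r must be > 0")
    return p * math.cos(theta) / (4.0 * math.pi * sigma * r * r)
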