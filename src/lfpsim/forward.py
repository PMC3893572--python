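"""Volume-conductor forward model: compartment currents → contact potentials.

The extracellular medium is an infinite, homogeneous, isotropic, purely
ohmic volume conductor with scalar conductivity σ (S/m), under the
quasistatic approximation.  A transmembrane current I (nA) at distance
r (μm) then contributes φ = I/(4πσr) millivolts — the unit closure carries
no conversion factor.

Three source models are provided:

* point source — each compartment's current exits at its midpoint;
* line source — the current is spread uniformly along the compartment's
  chord axis and integrated in closed form;
* soma-as-sphere — the root soma (a single spherical compartment) is a
  point/sphere source, all other compartments are line sources.

Singularities are avoided by clamping the relevant distance (radial for
point/sphere sources, perpendicular for line sources) to the compartment
radius.  Because the map from currents to potentials is linear, a contact's
kernel row can be precomputed once into a coefficient matrix C and reused at
every time step: Φ(tᵢ) = C · I(tᵢ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphology import CompartmentalizedCell

__all__ = [
    "ElectrodeArray",
    "CoefficientMatrix",
    "LFPOutput",
    "kernel_point_source",
    "kernel_line_source",
    "kernel_soma_as_point",
    "lfp_point_source",
    "lfp_line_source",
    "lfp_soma_as_point",
    "contact_average",
    "compute_coefficient_matrix",
    "apply_coefficients",
]

METHODS = ("point_source", "line_source", "soma_as_point")


# ---------------------------------------------------------------------------
# kernels: weight vectors w with φ = w · I_mem

def kernel_point_source(cell: CompartmentalizedCell, point, sigma: float) -> np.ndarray:
    """Point-source weights: w_n = 1/(4πσ·max(|r − r_n^mid|, radius_n))."""
    point = np.asarray(point, dtype=float)
    r = np.linalg.norm(cell.mid - point, axis=1)
    r = np.maximum(r, cell.radius)
    return 1.0 / (4.0 * np.pi * sigma * r)


def _line_integral(ds: np.ndarray, h: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """∫₀^Δs ds'/|r − r(s')| for a unit line charge density.

    ``h`` is the signed longitudinal distance from the segment *end* to the
    field point's axial projection (positive beyond the end), l = Δs + h the
    distance from the start, ρ the perpendicular distance.  The closed-form
    log is evaluated in a three-case split (projection beyond the end,
    before the start, or alongside the segment) so each branch is
    numerically stable.
    """
    l = ds + h
    out = np.empty_like(h)
    rho2 = rho * rho

    beyond = h >= 0           # projection past the end: h, l ≥ 0
    before = l <= 0           # projection before the start: h, l ≤ 0
    inside = ~(beyond | before)

    if np.any(beyond):
        hh, ll, r2 = h[beyond], l[beyond], rho2[beyond]
        out[beyond] = np.log(
            (ll + np.sqrt(ll * ll + r2)) / (hh + np.sqrt(hh * hh + r2))
        )
    if np.any(before):
        hh, ll, r2 = h[before], l[before], rho2[before]
        out[before] = np.log(
            (np.sqrt(hh * hh + r2) - hh) / (np.sqrt(ll * ll + r2) - ll)
        )
    if np.any(inside):
        hh, ll, r2 = h[inside], l[inside], rho2[inside]
        out[inside] = np.log(
            (np.sqrt(hh * hh + r2) - hh) * (ll + np.sqrt(ll * ll + r2)) / r2
        )
    return out


def _segment_geometry(cell: CompartmentalizedCell, point: np.ndarray):
    """Per-compartment (Δs, h, ρ) of a field point relative to each chord."""
    axis = cell.end - cell.start
    ds = cell.length
    ok = ds > 0
    unit = np.zeros_like(axis)
    unit[ok] = axis[ok] / ds[ok, None]
    rel_end = point - cell.end
    h = np.einsum("ij,ij->i", rel_end, unit)
    perp = rel_end - h[:, None] * unit
    rho = np.linalg.norm(perp, axis=1)
    return ds, h, rho, ok


def kernel_line_source(cell: CompartmentalizedCell, point, sigma: float) -> np.ndarray:
    """Line-source weights; zero-length segments fall back to point sources.

    The perpendicular distance ρ is clamped to the compartment radius before
    evaluating the closed form.
    """
    point = np.asarray(point, dtype=float)
    ds, h, rho, ok = _segment_geometry(cell, point)
    w = np.empty(cell.n_compartments)
    rho_c = np.maximum(rho, cell.radius)
    if np.any(ok):
        w[ok] = _line_integral(ds[ok], h[ok], rho_c[ok]) / ds[ok]
    if np.any(~ok):
        r = np.linalg.norm(cell.mid[~ok] - point, axis=1)
        w[~ok] = 1.0 / np.maximum(r, cell.radius[~ok])
    return w / (4.0 * np.pi * sigma)


def _require_root_single_soma(cell: CompartmentalizedCell) -> None:
    soma_secs = [
        i for i, nm in enumerate(cell.section_names)
        if nm == "soma" or nm.startswith("soma[")
    ]
    if len(soma_secs) != 1:
        raise ValueError(
            "soma_as_point requires exactly one soma section "
            f"(found {len(soma_secs)})"
        )
    idx = np.flatnonzero(cell.sec_of_comp == soma_secs[0])
    if idx.size != 1:
        raise ValueError(
            "soma_as_point requires a single-compartment soma "
            f"(soma has {idx.size} compartments)"
        )
    if idx[0] != 0 or cell.parent[0] != -1:
        raise ValueError("soma_as_point requires the soma to be the root (index 0)")


def kernel_soma_as_point(cell: CompartmentalizedCell, point, sigma: float) -> np.ndarray:
    """Mixed weights: spherical root soma as a point source (distance clamped
    at the soma's equivalent-sphere radius), dendrites as line sources.

    Raises unless the soma is the root of the morphology and represented by
    a single compartment.
    """
    _require_root_single_soma(cell)
    point = np.asarray(point, dtype=float)
    w = kernel_line_source(cell, point, sigma)
    r = np.linalg.norm(cell.mid[0] - point)
    r_eq = float(np.sqrt(cell.area[0] / (4.0 * np.pi)))
    w[0] = 1.0 / (4.0 * np.pi * sigma * max(r, r_eq))
    return w


_KERNELS = {
    "point_source": kernel_point_source,
    "line_source": kernel_line_source,
    "soma_as_point": kernel_soma_as_point,
}


def _apply(cell, I_mem, kernel) -> np.ndarray:
    I_mem = np.asarray(I_mem, dtype=float)
    if I_mem.shape[0] != cell.n_compartments:
        raise ValueError(
            f"I_mem has {I_mem.shape[0]} rows, cell has {cell.n_compartments} compartments"
        )
    return kernel @ I_mem


def lfp_point_source(cell, I_mem, point, sigma: float) -> np.ndarray:
    """φ(t) at ``point`` from the point-source approximation."""
    return _apply(cell, I_mem, kernel_point_source(cell, point, sigma))


def lfp_line_source(cell, I_mem, point, sigma: float) -> np.ndarray:
    """φ(t) at ``point`` from the line-source approximation."""
    return _apply(cell, I_mem, kernel_line_source(cell, point, sigma))


def lfp_soma_as_point(cell, I_mem, point, sigma: float) -> np.ndarray:
    """φ(t) at ``point`` from the mixed soma-sphere / line-source method."""
    return _apply(cell, I_mem, kernel_soma_as_point(cell, point, sigma))


# ---------------------------------------------------------------------------
# finite-size contacts

def disc_sample_points(
    center, radius: float, normal, m: int, rng: np.random.Generator
) -> np.ndarray:
    """``m`` points drawn uniformly on the flat disc of ``radius`` centered at
    ``center`` perpendicular to the unit ``normal`` (radial coordinate
    radius·√u)."""
    center = np.asarray(center, dtype=float)
    normal = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(normal)
    if not np.isclose(nn, 1.0, atol=1e-6):
        raise ValueError("contact normal must be unit length")
    # orthonormal in-plane basis
    a = np.array([1.0, 0.0, 0.0])
    if abs(normal @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, a)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    rad = radius * np.sqrt(rng.random(m))
    ang = 2.0 * np.pi * rng.random(m)
    return center + rad[:, None] * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v)


def contact_kernel(
    cell: CompartmentalizedCell,
    position,
    sigma: float,
    method: str = "line_source",
    radius: float = 0.0,
    normal=None,
    m: int = 1,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Kernel row for one contact, surface-averaged when radius > 0."""
    kernel = _KERNELS[method]
    if radius < 0:
        raise ValueError("contact radius must be >= 0")
    if radius == 0.0:
        return kernel(cell, position, sigma)
    if normal is None:
        raise ValueError("a contact with radius > 0 needs a surface normal")
    if m < 1:
        raise ValueError("n_average m must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    pts = disc_sample_points(position, radius, normal, m, rng)
    w = np.zeros(cell.n_compartments)
    for p in pts:
        w += kernel(cell, p, sigma)
    return w / m


def contact_average(
    cell, I_mem, position, sigma, method="line_source",
    radius=0.0, normal=None, m=1, rng=None,
) -> np.ndarray:
    """Surface-averaged potential of one finite circular contact.

    Averages the chosen method's potential over ``m`` random points on the
    flat disc; radius 0 degenerates to the single-point evaluation.
    """
    return _apply(
        cell, I_mem,
        contact_kernel(cell, position, sigma, method, radius, normal, m, rng),
    )


# ---------------------------------------------------------------------------
# electrode arrays and the coefficient-matrix scheme

@dataclass
class ElectrodeArray:
    """Extracellular recording geometry.

    positions : (n_contacts, 3) μm.  sigma : S/m.  method : one of
    ``point_source | line_source | soma_as_point``.  Optional finite-contact
    parameters: common ``radius`` (μm), per-array unit ``normal``, and
    ``n_average`` surface sample count; ``seed`` feeds a dedicated RNG stream
    for disc sampling (independent of all simulation randomness), with the
    sample locations fixed per contact.
    """

    positions: np.ndarray
    sigma: float = 0.3
    method: str = "line_source"
    radius: float = 0.0
    normal: np.ndarray | None = None
    n_average: int = 1
    seed: int = 0

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[1] != 3:
            raise ValueError("contact positions must be (n, 3)")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.radius < 0:
            raise ValueError("contact radius must be >= 0")
        if self.n_average < 1:
            raise ValueError("n_average must be >= 1")
        if self.normal is not None:
            self.normal = np.asarray(self.normal, dtype=float)

    @property
    def n_contacts(self) -> int:
        return self.positions.shape[0]

    def kernel_matrix(self, cell: CompartmentalizedCell) -> np.ndarray:
        K = np.empty((self.n_contacts, cell.n_compartments))
        for k, pos in enumerate(self.positions):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=self.seed, spawn_key=(k,))
            )
            K[k] = contact_kernel(
                cell, pos, self.sigma, self.method,
                self.radius, self.normal, self.n_average, rng,
            )
        return K

    def lfp(self, cell: CompartmentalizedCell, I_mem: np.ndarray) -> np.ndarray:
        """(n_contacts, T) potentials from recorded membrane currents."""
        return _apply(cell, I_mem, self.kernel_matrix(cell))


@dataclass(frozen=True)
class CoefficientMatrix:
    """Linear map from compartment currents to contact potentials (mV/nA).

    Column n holds the contact potentials generated by a unit 1 nA current in
    compartment n alone — equivalently the result of pushing an N×N identity
    current matrix through the forward model.
    """

    matrix: np.ndarray
    method: str
    sigma: float
    cell_hash: str = ""

    @property
    def shape(self):
        return self.matrix.shape


@dataclass
class LFPOutput:
    """Contact potentials φ (n_contacts × T, mV) on a shared time axis."""

    t: np.ndarray
    phi: np.ndarray


def compute_coefficient_matrix(
    cell: CompartmentalizedCell, electrode: ElectrodeArray
) -> CoefficientMatrix:
    """Precompute C with C[k, n] = φ at contact k from 1 nA in compartment n."""
    return CoefficientMatrix(
        matrix=electrode.kernel_matrix(cell),
        method=electrode.method,
        sigma=electrode.sigma,
        cell_hash=cell.geometry_hash(),
    )


def apply_coefficients(C: CoefficientMatrix | np.ndarray, I) -> np.ndarray:
    """Φ = C · I for a length-N current vector or an N×T current matrix."""
    M = getattr(C, "matrix", C)
    I = np.asarray(I, dtype=float)
    if I.shape[0] != M.shape[1]:
        raise ValueError(f"current has {I.shape[0]} rows, C expects {M.shape[1]}")
    return M @ I
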