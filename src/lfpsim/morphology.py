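"""Neuronal morphologies: SWC I/O, synthetic fixtures, and compartmentalization.

A morphology is a rooted tree of 3D sample points with diameters
(:class:`Morphology3D`).  Before simulation it is discretized into straight
line-source compartments (:class:`CompartmentalizedCell`): every section is
split into ``nseg`` equal-arc-length pieces, and each piece is represented by
the straight chord between the linearly interpolated 3D path positions at its
arc-length breakpoints.  The chord is what the extracellular forward model
sees; membrane area and axial resistance are computed from the original
arc-length diameter profile so the electrical cable is preserved even when
the chord is shorter than the arc.

Units: μm (length), Ω·cm (axial resistivity), μF/cm² (specific capacitance),
S/cm² (leak density), mV, nF, μS.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Morphology3D",
    "CompartmentalizationParams",
    "CompartmentalizedCell",
    "SWCError",
    "read_swc",
    "write_swc",
    "read_rot_file",
    "make_ball_and_stick",
    "make_stick",
    "nseg_d_lambda",
    "compartmentalize",
    "set_rotation",
    "set_position",
    "load_cell",
]

#: SWC structure-identifier → section base name.
SWC_TYPE_NAMES = {1: "soma", 2: "axon", 3: "dend", 4: "apic"}


class SWCError(ValueError):
    """Raised for malformed or structurally invalid SWC input."""


@dataclass(frozen=True)
class Morphology3D:
    """Raw reconstructed tree of 3D sample points.

    Attributes
    ----------
    xyz : (P, 3) float array, μm
    diameter : (P,) float array, μm
    type_label : (P,) int array (SWC structure identifiers)
    parent_index : (P,) int array; −1 marks the single root
    sections : list of (name, point-index array); every point belongs to
        exactly one section, sections are contiguous unbranched runs.
    """

    xyz: np.ndarray
    diameter: np.ndarray
    type_label: np.ndarray
    parent_index: np.ndarray
    sections: list[tuple[str, np.ndarray]] = field(default_factory=list)

    @property
    def n_points(self) -> int:
        return self.xyz.shape[0]

    def validate(self) -> None:
        p = self.parent_index
        roots = np.flatnonzero(p == -1)
        if roots.size != 1:
            raise SWCError(f"expected exactly one root point, found {roots.size}")
        later = np.flatnonzero(p >= np.arange(self.n_points))
        later = later[p[later] != -1]
        if later.size:
            raise SWCError(
                f"point {later[0]} references parent {p[later[0]]} "
                "which is not an earlier point (forward reference or cycle)"
            )
        if np.any(self.diameter <= 0):
            raise SWCError("all diameters must be > 0")
        seen = np.concatenate([idx for _, idx in self.sections]) if self.sections else np.array([], int)
        if not np.array_equal(np.sort(seen), np.arange(self.n_points)):
            raise SWCError("sections must partition the point set")


@dataclass(frozen=True)
class CompartmentalizationParams:
    """Spatial-discretization and passive-membrane parameters.

    d_lambda : maximum internode spacing as a fraction of the AC length
        constant λ_f evaluated at frequency ``f`` (the d_lambda rule).
    Ra : axial resistivity, Ω·cm.  cm : specific capacitance, μF/cm².
    g_pas : leak conductance density, S/cm².  e_pas : leak reversal, mV.
    """

    d_lambda: float = 0.1
    f: float = 100.0
    Ra: float = 150.0
    cm: float = 1.0
    g_pas: float = 1.0 / 30000.0
    e_pas: float = -65.0

    def __post_init__(self) -> None:
        if not (0.0 < self.d_lambda <= 1.0):
            raise ValueError("d_lambda must be in (0, 1]")
        if self.f <= 0 or self.Ra <= 0 or self.cm <= 0 or self.g_pas <= 0:
            raise ValueError("f, Ra, cm and g_pas must be > 0")


@dataclass
class CompartmentalizedCell:
    """N indexed line-source compartments with passive electrical parameters.

    Global compartment indices follow a counter in a nested loop over sections
    (in declaration order) then within-section compartments, so the first
    compartment of the first section has index 0.

    Geometry arrays are (N, 3) start/mid/end chord coordinates in μm; ``length``
    is the chord length used by the line-source formula, ``arc_length`` the
    cable arc span used for axial resistance, ``area`` the frustum membrane
    area from the diameter profile.  ``g_axial`` is the conductance (μS) of the
    edge from each compartment to its parent compartment (0 for the root).
    """

    start: np.ndarray
    mid: np.ndarray
    end: np.ndarray
    radius: np.ndarray
    length: np.ndarray
    arc_length: np.ndarray
    area: np.ndarray
    capacitance: np.ndarray   # nF
    g_leak: np.ndarray        # μS
    e_pas: float
    parent: np.ndarray        # (N,) int, −1 for root compartment
    g_axial: np.ndarray       # μS, per compartment edge to parent
    section_names: list[str]
    sec_of_comp: np.ndarray   # (N,) int → index into section_names
    relpos: np.ndarray        # (N,) float in (0, 1): within-section position
    soma_center: np.ndarray   # (3,)
    is_sphere: np.ndarray     # (N,) bool: single-point spherical soma
    params: CompartmentalizationParams | None = None

    @property
    def n_compartments(self) -> int:
        return self.start.shape[0]

    # -- lookups -----------------------------------------------------------

    def section_indices(self, name: str) -> np.ndarray:
        """Sorted global indices of the compartments in section ``name``."""
        if name not in self.section_names:
            raise KeyError(f"unknown section {name!r}")
        s = self.section_names.index(name)
        return np.flatnonzero(self.sec_of_comp == s)

    def compartment_info(self, idx: int) -> tuple[str, float]:
        """Map a global index to (section name, relative position in (0,1))."""
        if not 0 <= idx < self.n_compartments:
            raise IndexError(f"compartment index {idx} out of range")
        return self.section_names[self.sec_of_comp[idx]], float(self.relpos[idx])

    def closest_idx(self, name: str, rel: float) -> int:
        """Global index of the compartment in ``name`` closest to position rel."""
        idx = self.section_indices(name)
        return int(idx[np.argmin(np.abs(self.relpos[idx] - rel))])

    def geometry_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for a in (self.start, self.end, self.radius, self.length):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()


def index_lookup(cell: CompartmentalizedCell, query):
    """Section name → global indices, or global index → (section, relpos)."""
    if isinstance(query, str):
        return cell.section_indices(query)
    return cell.compartment_info(int(query))


# ---------------------------------------------------------------------------
# SWC I/O

def read_swc(path) -> Morphology3D:
    """Read a standard 7-column SWC file into a :class:`Morphology3D`.

    The SWC radius column is doubled into a diameter.  Sample identifiers may
    be arbitrary positive integers; they are remapped to 0-based order of
    appearance.  Parents must appear before their children.
    """
    ids: list[int] = []
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) != 7:
                raise SWCError(f"{path}:{lineno}: expected 7 columns, got {len(cols)}")
            try:
                sid = int(cols[0])
                t = int(cols[1])
                x, y, z, r = (float(c) for c in cols[2:6])
                parent = int(cols[6])
            except ValueError as exc:
                raise SWCError(f"{path}:{lineno}: {exc}") from None
            ids.append(sid)
            rows.append((t, x, y, z, r, parent, lineno))

    if not rows:
        raise SWCError(f"{path}: no sample points")
    id_map = {sid: i for i, sid in enumerate(ids)}
    if len(id_map) != len(ids):
        raise SWCError(f"{path}: duplicate sample identifiers")

    n = len(rows)
    xyz = np.empty((n, 3))
    diam = np.empty(n)
    types = np.empty(n, dtype=int)
    parents = np.empty(n, dtype=int)
    for i, (t, x, y, z, r, parent, lineno) in enumerate(rows):
        xyz[i] = (x, y, z)
        if r <= 0:
            raise SWCError(f"{path}:{lineno}: non-positive radius")
        diam[i] = 2.0 * r
        types[i] = t
        if parent == -1:
            parents[i] = -1
        else:
            if parent not in id_map:
                raise SWCError(f"{path}:{lineno}: parent {parent} not defined")
            pi = id_map[parent]
            if pi >= i:
                raise SWCError(
                    f"{path}:{lineno}: parent {parent} is not an earlier point"
                )
            parents[i] = pi

    m = Morphology3D(xyz, diam, types, parents, _partition_sections(types, parents))
    m.validate()
    return m


def write_swc(m: Morphology3D, path) -> None:
    """Write a :class:`Morphology3D` as a 7-column SWC file (1-based ids)."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in range(m.n_points):
            parent = m.parent_index[i]
            fh.write(
                f"{i + 1} {m.type_label[i]} "
                f"{m.xyz[i, 0]:.10g} {m.xyz[i, 1]:.10g} {m.xyz[i, 2]:.10g} "
                f"{m.diameter[i] / 2.0:.10g} {parent + 1 if parent >= 0 else -1}\n"
            )


_ROT_LINE = re.compile(r"^\s*([xyz])\s*=\s*([-+0-9.eE]+)\s*$")


def read_rot_file(path) -> tuple[float, float, float]:
    """Parse a plain-text ``.rot`` sidecar with lines like ``x = 4.729``.

    Returns (x, y, z) rotation angles in radians; missing axes default to 0.
    """
    angles = {"x": 0.0, "y": 0.0, "z": 0.0}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            mobj = _ROT_LINE.match(line)
            if mobj is None:
                raise ValueError(f"{path}: cannot parse rotation line {line!r}")
            angles[mobj.group(1)] = float(mobj.group(2))
    return angles["x"], angles["y"], angles["z"]


def _partition_sections(types: np.ndarray, parents: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """Group points into contiguous unbranched runs of a single type.

    A new section starts at the root, wherever the type changes, at every
    branch child, and wherever a point's parent is not the preceding point in
    file order (re-rooted continuation).  Section names follow SWC type codes;
    repeated sections of a type get bracketed suffixes (dend[0], dend[1], …).
    """
    n = len(types)
    child_count = np.zeros(n, dtype=int)
    for i in range(n):
        if parents[i] >= 0:
            child_count[parents[i]] += 1

    runs: list[list[int]] = []
    run: list[int] = []
    for i in range(n):
        p = parents[i]
        new = (
            p == -1
            or not run
            or p != run[-1]
            or types[i] != types[p]
            or child_count[p] > 1
        )
        if new and run:
            runs.append(run)
            run = []
        run.append(i)
    if run:
        runs.append(run)

    counts: dict[str, int] = {}
    out: list[tuple[str, np.ndarray]] = []
    n_of_type: dict[str, int] = {}
    for r in runs:
        base = SWC_TYPE_NAMES.get(int(types[r[0]]), f"type{types[r[0]]}")
        n_of_type[base] = n_of_type.get(base, 0) + 1
    for r in runs:
        base = SWC_TYPE_NAMES.get(int(types[r[0]]), f"type{types[r[0]]}")
        k = counts.get(base, 0)
        counts[base] = k + 1
        name = base if n_of_type[base] == 1 else f"{base}[{k}]"
        out.append((name, np.asarray(r, dtype=int)))
    return out


# ---------------------------------------------------------------------------
# Synthetic fixtures

def make_ball_and_stick(
    soma_diameter: float,
    stick_length: float,
    stick_diameter: float,
    n_points: int,
) -> Morphology3D:
    """Single-point spherical soma at the origin plus a straight dendritic
    stick of ``n_points`` collinear samples along +z starting at the soma
    surface.  Deterministic; the stick section's arc length equals
    ``stick_length`` exactly."""
    if soma_diameter <= 0 or stick_length <= 0 or stick_diameter <= 0:
        raise ValueError("all dimensions must be > 0")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    z0 = soma_diameter / 2.0
    zs = z0 + np.linspace(0.0, stick_length, n_points)
    xyz = np.zeros((n_points + 1, 3))
    xyz[1:, 2] = zs
    diam = np.full(n_points + 1, stick_diameter)
    diam[0] = soma_diameter
    types = np.full(n_points + 1, 3, dtype=int)
    types[0] = 1
    parents = np.arange(n_points + 1) - 1
    m = Morphology3D(
        xyz, diam, types, parents,
        [("soma", np.array([0])), ("dend", np.arange(1, n_points + 1))],
    )
    m.validate()
    return m


def make_stick(length: float, diameter: float, n_points: int = 2) -> Morphology3D:
    """A pure uniform dendritic cable along +z rooted at the origin.

    All points carry the dendrite type so the whole cell is one cylindrical
    section — the geometry of the analytic cable validation fixture."""
    if length <= 0 or diameter <= 0:
        raise ValueError("all dimensions must be > 0")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    xyz = np.zeros((n_points, 3))
    xyz[:, 2] = np.linspace(0.0, length, n_points)
    diam = np.full(n_points, diameter)
    types = np.full(n_points, 3, dtype=int)
    parents = np.arange(n_points) - 1
    m = Morphology3D(xyz, diam, types, parents, [("dend", np.arange(n_points))])
    m.validate()
    return m


# ---------------------------------------------------------------------------
# Discretization

def nseg_d_lambda(
    L: float, diam: float, Ra: float, cm: float,
    f: float = 100.0, d_lambda: float = 0.1,
) -> int:
    """Number of compartments for a section by the d_lambda rule.

    λ_f = 1e5·sqrt(diam / (4π f Ra cm)) μm (diam μm, Ra Ω·cm, cm μF/cm²,
    f Hz); the section is split so internode spacing stays below
    d_lambda·λ_f, rounded to an odd count ≥ 1.
    """
    if diam <= 0 or Ra <= 0 or cm <= 0 or f <= 0 or d_lambda <= 0:
        raise ValueError("all arguments must be > 0")
    if L < 0:
        raise ValueError("L must be >= 0")
    lam = 1e5 * math.sqrt(diam / (4.0 * math.pi * f * Ra * cm))
    return int((L / (d_lambda * lam) + 0.9) / 2.0) * 2 + 1


def _section_path(m: Morphology3D, sec_idx: int) -> tuple[np.ndarray, np.ndarray]:
    """3D path and diameter profile of a section.

    When the section's first point continues a parent point of the *same*
    type (a branch continuation), the parent point is prepended so the cable
    spans the full reconstructed arc.  Connections across types (e.g. a
    dendrite hanging off the soma) do not extend the path.
    """
    name, pts = m.sections[sec_idx]
    first = pts[0]
    p = m.parent_index[first]
    if p >= 0 and m.type_label[p] == m.type_label[first]:
        pts = np.concatenate([[p], pts])
    return m.xyz[pts], m.diameter[pts]


def _owner_of_point(m: Morphology3D, point: int) -> tuple[int, float]:
    """Section index owning a point and the point's relative arc position."""
    for s, (name, pts) in enumerate(m.sections):
        where = np.flatnonzero(pts == point)
        if where.size:
            xyz, _ = _section_path(m, s)
            seg = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
            arc = np.concatenate([[0.0], np.cumsum(seg)])
            # offset if the parent point was prepended
            off = xyz.shape[0] - pts.shape[0]
            total = arc[-1]
            if total == 0.0:
                return s, 0.5
            return s, float(arc[where[0] + off] / total)
    raise SWCError(f"point {point} not in any section")


def compartmentalize(
    m: Morphology3D,
    p: CompartmentalizationParams | None = None,
    nseg_override: dict[str, int] | None = None,
) -> CompartmentalizedCell:
    """Discretize a morphology into an indexed passive compartment cell.

    Each section is split into nseg equal-arc-length compartments (nseg from
    the d_lambda rule unless overridden).  Chord start/end points come from
    linear interpolation of the 3D path at the arc breakpoints; membrane area
    uses the frustum formula on the arc-length diameter profile; compartment
    radius is the arc-weighted mean diameter over the span divided by two.
    A single-point soma becomes one spherical compartment of area π·d².
    """
    m.validate()
    if m.n_points == 0:
        raise SWCError("empty morphology")
    p = p or CompartmentalizationParams()
    nseg_override = nseg_override or {}

    start, mid, end = [], [], []
    radius, length, arc_len, area = [], [], [], []
    parent_comp, g_ax = [], []
    sec_names: list[str] = []
    sec_of_comp, relpos, sphere = [], [], []

    # first compartment index of each section, for parent resolution
    first_idx_of_sec: dict[int, int] = {}
    nseg_of_sec: dict[int, int] = {}
    counter = 0

    # half-edge axial resistances (Ω) per compartment, filled as we go
    r_half: list[float] = []

    root_point = int(np.flatnonzero(m.parent_index == -1)[0])
    soma_center = None

    for s, (name, pts) in enumerate(m.sections):
        sec_names.append(name)
        xyz, diam = _section_path(m, s)
        seg = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        L = float(arc[-1])

        single_point_soma = (
            len(pts) == 1 and m.type_label[pts[0]] == 1 and L == 0.0
        )
        if single_point_soma:
            d = float(m.diameter[pts[0]])
            c = m.xyz[pts[0]].astype(float)
            if soma_center is None and pts[0] == root_point:
                soma_center = c.copy()
            first_idx_of_sec[s] = counter
            nseg_of_sec[s] = 1
            a = math.pi * d * d  # sphere surface
            start.append(c.copy()); mid.append(c.copy()); end.append(c.copy())
            radius.append(d / 2.0)
            length.append(d)        # nominal: sphere treated as L=d cylinder
            arc_len.append(d)
            area.append(a)
            sphere.append(True)
            # half-edge resistance of an L=d equivalent cylinder
            r_half.append(1e4 * p.Ra * (d / 2.0) / (math.pi * d * d / 4.0))
            parent_comp.append(-1 if m.parent_index[pts[0]] == -1 else None)
            g_ax.append(0.0)
            sec_of_comp.append(s)
            relpos.append(0.5)
            counter += 1
            continue

        if L <= 0.0:
            raise SWCError(f"section {name!r} has zero arc length")

        if name in nseg_override:
            nseg = int(nseg_override[name])
            if nseg < 1:
                raise ValueError("nseg override must be >= 1")
        else:
            mean_d = float(np.trapezoid(diam, arc) / L) if len(arc) > 1 else float(diam[0])
            nseg = nseg_d_lambda(L, mean_d, p.Ra, p.cm, p.f, p.d_lambda)
        first_idx_of_sec[s] = counter
        nseg_of_sec[s] = nseg

        breaks = np.linspace(0.0, L, nseg + 1)
        bx = np.interp(breaks, arc, xyz[:, 0])
        by = np.interp(breaks, arc, xyz[:, 1])
        bz = np.interp(breaks, arc, xyz[:, 2])
        # refined arc grid: original samples plus breakpoints, for exact
        # piecewise-linear diameter integrals per compartment
        grid = np.union1d(arc, breaks)
        dgrid = np.interp(grid, arc, diam)

        for j in range(nseg):
            a0, a1 = breaks[j], breaks[j + 1]
            p0 = np.array([bx[j], by[j], bz[j]])
            p1 = np.array([bx[j + 1], by[j + 1], bz[j + 1]])
            mask = (grid >= a0 - 1e-12) & (grid <= a1 + 1e-12)
            g = grid[mask]
            dg = dgrid[mask]
            dl = np.diff(g)
            span = a1 - a0
            if dl.size == 0 or span <= 0:
                raise SWCError(f"degenerate compartment in section {name!r}")
            davg = float(np.sum((dg[:-1] + dg[1:]) / 2.0 * dl) / span)
            # frustum lateral surface over each sub-interval
            r0, r1 = dg[:-1] / 2.0, dg[1:] / 2.0
            a_frust = float(np.sum(math.pi * (r0 + r1) * np.sqrt(dl ** 2 + (r1 - r0) ** 2)))

            start.append(p0)
            end.append(p1)
            mid.append((p0 + p1) / 2.0)
            radius.append(davg / 2.0)
            length.append(float(np.linalg.norm(p1 - p0)))
            arc_len.append(span)
            area.append(a_frust)
            sphere.append(False)
            r_half.append(1e4 * p.Ra * (span / 2.0) / (math.pi * davg * davg / 4.0))
            parent_comp.append(counter - 1 if j > 0 else None)
            g_ax.append(0.0)
            sec_of_comp.append(s)
            relpos.append((j + 0.5) / nseg)
            counter += 1

    # resolve cross-section parents and axial conductances
    for s, (name, pts) in enumerate(m.sections):
        c0 = first_idx_of_sec[s]
        if parent_comp[c0] is not None:
            continue
        pp = int(m.parent_index[pts[0]])
        if pp == -1:
            parent_comp[c0] = -1
            continue
        t, relarc = _owner_of_point(m, pp)
        nseg_t = nseg_of_sec[t]
        j = min(int(relarc * nseg_t), nseg_t - 1)
        parent_comp[c0] = first_idx_of_sec[t] + j

    N = counter
    parent_arr = np.asarray(parent_comp, dtype=int)
    g_axial = np.zeros(N)
    for n in range(N):
        q = parent_arr[n]
        if q >= 0:
            g_axial[n] = 1e6 / (r_half[n] + r_half[q])  # μS

    if soma_center is None:
        # no single-point soma: use the root point's position
        soma_center = m.xyz[root_point].astype(float).copy()

    area_arr = np.asarray(area)
    cell = CompartmentalizedCell(
        start=np.asarray(start),
        mid=np.asarray(mid),
        end=np.asarray(end),
        radius=np.asarray(radius),
        length=np.asarray(length),
        arc_length=np.asarray(arc_len),
        area=area_arr,
        capacitance=p.cm * area_arr * 1e-5,  # μF/cm² · μm² → nF
        g_leak=p.g_pas * area_arr * 1e-2,    # S/cm² · μm² → μS
        e_pas=p.e_pas,
        parent=parent_arr,
        g_axial=g_axial,
        section_names=sec_names,
        sec_of_comp=np.asarray(sec_of_comp, dtype=int),
        relpos=np.asarray(relpos),
        soma_center=np.asarray(soma_center, dtype=float),
        is_sphere=np.asarray(sphere, dtype=bool),
        params=p,
    )
    return cell


# ---------------------------------------------------------------------------
# Rigid transforms (geometry only; electrical parameters untouched)

def _rotation_matrix(x: float, y: float, z: float) -> np.ndarray:
    cx, sx = math.cos(x), math.sin(x)
    cy, sy = math.cos(y), math.sin(y)
    cz, sz = math.cos(z), math.sin(z)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def set_rotation(cell: CompartmentalizedCell, x: float = 0.0, y: float = 0.0,
                 z: float = 0.0) -> CompartmentalizedCell:
    """Rotate the cell about its soma center: right-handed rotations about the
    fixed x, then y, then z axes.  Returns a new cell; electrical parameters
    are shared untouched."""
    for a in (x, y, z):
        if not math.isfinite(a):
            raise ValueError("rotation angles must be finite")
    R = _rotation_matrix(x, y, z)
    c = cell.soma_center

    def rot(a: np.ndarray) -> np.ndarray:
        return (a - c) @ R.T + c

    return replace(cell, start=rot(cell.start), mid=rot(cell.mid),
                   end=rot(cell.end), soma_center=c.copy())


def set_position(cell: CompartmentalizedCell, x: float, y: float,
                 z: float) -> CompartmentalizedCell:
    """Rigidly translate the cell so its soma center sits at (x, y, z)."""
    target = np.array([x, y, z], dtype=float)
    if not np.all(np.isfinite(target)):
        raise ValueError("target position must be finite")
    shift = target - cell.soma_center
    return replace(cell, start=cell.start + shift, mid=cell.mid + shift,
                   end=cell.end + shift, soma_center=target)


def load_cell(
    path,
    params: CompartmentalizationParams | None = None,
    nseg_override: dict[str, int] | None = None,
    apply_rot: bool = True,
) -> CompartmentalizedCell:
    """Read an SWC morphology, compartmentalize it, and apply a ``.rot``
    sidecar file (same stem, ``.rot`` suffix) when present.  The sidecar's
    default orientation is applied before any user rotation."""
    m = read_swc(path)
    cell = compartmentalize(m, params, nseg_override)
    if apply_rot:
        rot_path = Path(path).with_suffix(".rot")
        if rot_path.exists():
            cell = set_rotation(cell, *read_rot_file(rot_path))
    return cell
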