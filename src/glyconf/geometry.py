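"""Dihedral-angle mathematics and an idealized fragment builder.

The conformation of a glycosidic linkage is described by the two torsions

    phi = H1-C1-O-Cx      psi = C1-O-Cx-Hx

where C1 is the anomeric carbon of the glycosylating residue, O the
glycosidic oxygen and Cx the aglycon carbon at position x (the x of a
1->x linkage).  This NMR-oriented proton-based convention is the one
compatible with Karplus analysis of trans-glycosidic 3J(C-H) couplings.

Angles are degrees at every API boundary, in the range (-180, +180] with
the IUPAC sign convention (cis = 0 deg, sign by the right-hand rule about
the central bond).  Coordinates are Angstroms.

:func:`build_fragment` converts a (phi, psi) pair into Cartesian
coordinates of a minimal idealized fragment (plus optional extra protons
placed by fixed internal coordinates), which is what the NOE machinery
and the synthetic-ensemble generator consume.  It is a deliberately
simple stand-in for real sugar rings: only relative quantities (torsions
and distance ratios) are used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import yaml

from .errors import (
    AtomLookupError,
    ConfigurationError,
    DegenerateGeometryError,
    ValidationError,
)

__all__ = [
    "Point3",
    "LinkageSpec",
    "ExtraSite",
    "FragmentGeometry",
    "dihedral",
    "linkage_torsions",
    "build_fragment",
    "wrap_angle",
    "default_linkage_spec",
    "default_geometry",
]

_COLLINEAR_EPS = 1e-10


def as_xyz(p) -> np.ndarray:
    """Coerce a point-like object to a float (3,) array, checking finiteness."""
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValidationError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValidationError(f"non-finite coordinates: {a}")
    return a


@dataclass(frozen=True)
class Point3:
    """A point in 3-space (Angstroms)."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValidationError(f"non-finite Point3 components: {self}")

    def __array__(self, dtype=None, copy=None):
        return np.array([self.x, self.y, self.z], dtype=dtype or float)


PointLike = Union[Point3, Sequence[float], np.ndarray]


def wrap_angle(theta):
    """Wrap angle(s) in degrees into (-180, +180]."""
    wrapped = -np.remainder(-np.asarray(theta, dtype=float) + 180.0, 360.0) + 180.0
    return wrapped if np.ndim(theta) else float(wrapped)


# ---------------------------------------------------------------------------
# linkage specification


@dataclass(frozen=True)
class LinkageSpec:
    """Four-atom definitions of phi and psi for one glycosidic linkage.

    ``phi_atoms`` is the ordered quadruple (H1, C1, O, Cx) and
    ``psi_atoms`` is (C1, O, Cx, Hx); the two share C1, O and Cx.
    ``aglycon_position`` is the x of the 1->x linkage.
    """

    name: str
    phi_atoms: tuple[str, str, str, str]
    psi_atoms: tuple[str, str, str, str]
    aglycon_position: int

    def __post_init__(self) -> None:
        phi = tuple(self.phi_atoms)
        psi = tuple(self.psi_atoms)
        object.__setattr__(self, "phi_atoms", phi)
        object.__setattr__(self, "psi_atoms", psi)
        if len(phi) != 4 or len(psi) != 4:
            raise ValidationError("phi_atoms and psi_atoms must each have 4 ids")
        if len(set(phi)) != 4 or len(set(psi)) != 4:
            raise ValidationError(
                f"atom ids must be distinct within each torsion: phi={phi} psi={psi}"
            )
        if phi[2] != psi[1]:
            raise ValidationError(
                f"phi_atoms[2] ({phi[2]}) must be the glycosidic O shared with "
                f"psi_atoms[1] ({psi[1]})"
            )
        if phi[1] != psi[0]:
            raise ValidationError(
                f"phi_atoms[1] ({phi[1]}) must be the anomeric C1 shared with "
                f"psi_atoms[0] ({psi[0]})"
            )

    @property
    def atom_ids(self) -> tuple[str, ...]:
        """All distinct atom ids of the linkage, in placement order."""
        seen: dict[str, None] = {}
        for a in self.phi_atoms + self.psi_atoms:
            seen.setdefault(a)
        return tuple(seen)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "phi_atoms": list(self.phi_atoms),
            "psi_atoms": list(self.psi_atoms),
            "aglycon_position": self.aglycon_position,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinkageSpec":
        try:
            return cls(
                name=str(d["name"]),
                phi_atoms=tuple(d["phi_atoms"]),
                psi_atoms=tuple(d["psi_atoms"]),
                aglycon_position=int(d["aglycon_position"]),
            )
        except KeyError as e:
            raise ConfigurationError(f"linkage spec missing key {e}") from e

    @classmethod
    def from_yaml(cls, path) -> "LinkageSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_linkage_spec(aglycon_position: int = 3, name: str | None = None) -> LinkageSpec:
    """The 1->x linkage spec with conventional atom names (H1, C1, O, Cx, Hx)."""
    x = int(aglycon_position)
    return LinkageSpec(
        name=name or f"1->{x} linkage",
        phi_atoms=("H1", "C1", "O", f"C{x}"),
        psi_atoms=("C1", "O", f"C{x}", f"H{x}"),
        aglycon_position=x,
    )


# ---------------------------------------------------------------------------
# dihedral math


def _dihedral_array(p1, p2, p3, p4) -> np.ndarray:
    """Signed dihedral(s) in degrees for stacked (..., 3) coordinate arrays."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(b2 / b2n, n1)
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m1, n2)
    return np.degrees(np.arctan2(y, x))


def dihedral(p1: PointLike, p2: PointLike, p3: PointLike, p4: PointLike) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, range (-180, +180].

    IUPAC convention: 0 deg is cis (p1 and p4 eclipsed), positive angles
    clockwise when looking from p2 towards p3.  Invariant under rigid
    rotation+translation of all four points.

    Raises
    ------
    DegenerateGeometryError
        If p2 == p3 or either bonded triple is collinear.
    """
    a1, a2, a3, a4 = (as_xyz(p) for p in (p1, p2, p3, p4))
    b1, b2, b3 = a2 - a1, a3 - a2, a4 - a3
    if np.linalg.norm(b2) < _COLLINEAR_EPS:
        raise DegenerateGeometryError(
            f"central atoms coincide: p2={a2.tolist()} p3={a3.tolist()}"
        )
    for label, n in (("p1-p2-p3", np.cross(b1, b2)), ("p2-p3-p4", np.cross(b2, b3))):
        if np.linalg.norm(n) < _COLLINEAR_EPS:
            raise DegenerateGeometryError(
                f"collinear or coincident atoms in triple {label}; dihedral undefined"
            )
    return wrap_angle(_dihedral_array(a1, a2, a3, a4))


def linkage_torsions(frame: Mapping[str, PointLike], spec: LinkageSpec) -> tuple[float, float]:
    """(phi, psi) in degrees for one coordinate frame under ``spec``."""

    def get(atom_id: str) -> np.ndarray:
        try:
            return as_xyz(frame[atom_id])
        except KeyError:
            raise AtomLookupError(
                f"atom {atom_id!r} required by linkage {spec.name!r} "
                f"is missing from the frame (present: {sorted(frame)})"
            ) from None

    phi = dihedral(*(get(a) for a in spec.phi_atoms))
    psi = dihedral(*(get(a) for a in spec.psi_atoms))
    return phi, psi


# ---------------------------------------------------------------------------
# fragment construction from internal coordinates


def place_atom(a: PointLike, b: PointLike, c: PointLike,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d from references a-b-c and internal coordinates.

    d is at distance ``bond`` (Angstrom) from c, with angle(b, c, d) ==
    ``angle`` (degrees) and dihedral(a, b, c, d) == ``torsion`` (degrees).
    """
    a, b, c = as_xyz(a), as_xyz(b), as_xyz(c)
    if bond <= 0:
        raise ValidationError(f"bond length must be positive, got {bond}")
    if not 0.0 < angle < 180.0:
        raise ValidationError(f"bond angle must be in (0, 180) deg, got {angle}")
    th = np.radians(angle)
    chi = np.radians(torsion)
    bc = c - b
    bc_n = np.linalg.norm(bc)
    if bc_n < _COLLINEAR_EPS:
        raise DegenerateGeometryError("reference atoms b and c coincide")
    bc = bc / bc_n
    n = np.cross(b - a, bc)
    n_n = np.linalg.norm(n)
    if n_n < _COLLINEAR_EPS:
        raise DegenerateGeometryError("reference atoms a, b, c are collinear")
    n = n / n_n
    m = np.cross(n, bc)
    # local frame (bc, m, n); sign of the n-component chosen so that
    # dihedral(a, b, c, d) equals the requested torsion under the IUPAC rule
    d_local = bond * np.array([-np.cos(th), np.sin(th) * np.cos(chi), np.sin(th) * np.sin(chi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


TorsionRef = Union[float, tuple[str, float]]


@dataclass(frozen=True)
class ExtraSite:
    """An extra atom placed by fixed internal coordinates.

    ``refs`` are three already-placed atom ids (dihedral ref, angle ref,
    attachment); ``torsion`` is either a fixed dihedral in degrees or a
    pair ("phi"|"psi", offset) meaning the linkage torsion plus an offset
    — that is how ring-neighbour sites track the glycosidic conformation.
    """

    name: str
    refs: tuple[str, str, str]
    bond: float
    angle: float
    torsion: TorsionRef

    def resolve_torsion(self, phi: float, psi: float) -> float:
        if isinstance(self.torsion, (int, float)):
            return float(self.torsion)
        kind, offset = self.torsion
        if kind == "phi":
            return phi + float(offset)
        if kind == "psi":
            return psi + float(offset)
        raise ConfigurationError(f"unknown torsion reference {kind!r} in site {self.name!r}")


@dataclass
class FragmentGeometry:
    """Idealized internal geometry for a linkage fragment.

    ``bond_lengths`` maps unordered atom-id pairs to Angstroms,
    ``bond_angles`` maps atom-id triples (order-insensitive end swap) to
    degrees, and ``extra_sites`` lists additional atoms (typically the
    protons observed in NOE) with their placement rules.
    """

    bond_lengths: dict[tuple[str, str], float] = field(default_factory=dict)
    bond_angles: dict[tuple[str, str, str], float] = field(default_factory=dict)
    extra_sites: list[ExtraSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        for pair, r in self.bond_lengths.items():
            if r <= 0:
                raise ValidationError(f"bond length {pair} must be > 0, got {r}")
        for triple, a in self.bond_angles.items():
            if not 0.0 < a < 180.0:
                raise ValidationError(f"bond angle {triple} must be in (0, 180), got {a}")

    def bond(self, a: str, b: str) -> float:
        for key in ((a, b), (b, a)):
            if key in self.bond_lengths:
                return self.bond_lengths[key]
        raise ConfigurationError(f"missing bond length for pair ({a}, {b})")

    def angle(self, a: str, b: str, c: str) -> float:
        for key in ((a, b, c), (c, b, a)):
            if key in self.bond_angles:
                return self.bond_angles[key]
        raise ConfigurationError(f"missing bond angle for triple ({a}, {b}, {c})")


def default_geometry(spec: LinkageSpec) -> FragmentGeometry:
    """Idealized geometry: C-H 1.09 A, C-O 1.43 A, C-C 1.53 A, tetrahedral
    angles at carbon, 117 deg at the glycosidic oxygen.

    Extra protons emulate the aglycon ring neighbours seen in NOE work: for
    a 1->x linkage, pseudo ring carbons C(x-1)/C(x+1) are attached to Cx at
    psi -/+ 120 deg and carry one proton each, so H1...H(x-1)/H(x+1)
    distances depend on the linkage conformation the way H2/H4 analogues do.
    """
    h1, c1, o, cx = spec.phi_atoms
    hx = spec.psi_atoms[3]
    x = spec.aglycon_position
    c_lo, c_hi = f"C{x - 1}", f"C{x + 1}"
    h_lo, h_hi = f"H{x - 1}", f"H{x + 1}"
    tet = 109.47
    geom = FragmentGeometry(
        bond_lengths={(h1, c1): 1.09, (c1, o): 1.43, (o, cx): 1.43, (cx, hx): 1.09},
        bond_angles={(h1, c1, o): tet, (c1, o, cx): 117.0, (o, cx, hx): tet},
        extra_sites=[
            ExtraSite(c_lo, (c1, o, cx), 1.53, tet, ("psi", -120.0)),
            ExtraSite(c_hi, (c1, o, cx), 1.53, tet, ("psi", +120.0)),
            # proton torsions chosen so the H1...H(x+1) contact is short only
            # in the inverted (psi ~ 180) state, mimicking the NOE signature
            # that distinguishes conformer populations
            ExtraSite(h_lo, (o, cx, c_lo), 1.09, tet, 180.0),
            ExtraSite(h_hi, (o, cx, c_hi), 1.09, tet, 60.0),
        ],
    )
    return geom


def build_fragment(phi: float, psi: float, geom: FragmentGeometry | None = None,
                   spec: LinkageSpec | None = None) -> dict[str, np.ndarray]:
    """Cartesian coordinates (id -> (3,) array, Angstrom) realizing (phi, psi).

    The returned frame reproduces the requested torsions exactly under
    :func:`linkage_torsions` (round-trip error < 1e-6 deg) and is
    deterministic for fixed inputs.
    """
    if not (np.isfinite(phi) and np.isfinite(psi)):
        raise ValidationError(f"phi and psi must be finite, got ({phi}, {psi})")
    spec = spec if spec is not None else default_linkage_spec()
    geom = geom if geom is not None else default_geometry(spec)

    h1, c1, o, cx = spec.phi_atoms
    hx = spec.psi_atoms[3]
    frame: dict[str, np.ndarray] = {}
    frame[c1] = np.zeros(3)
    frame[o] = np.array([geom.bond(c1, o), 0.0, 0.0])
    a_h1 = np.radians(geom.angle(h1, c1, o))
    frame[h1] = np.array([np.cos(a_h1), np.sin(a_h1), 0.0]) * geom.bond(h1, c1)
    frame[cx] = place_atom(frame[h1], frame[c1], frame[o],
                           geom.bond(o, cx), geom.angle(c1, o, cx), phi)
    frame[hx] = place_atom(frame[c1], frame[o], frame[cx],
                           geom.bond(cx, hx), geom.angle(o, cx, hx), psi)
    for site in geom.extra_sites:
        missing = [r for r in site.refs if r not in frame]
        if missing:
            raise ConfigurationError(
                f"extra site {site.name!r} references atoms not yet placed: {missing}"
            )
        a, b, c = (frame[r] for r in site.refs)
        frame[site.name] = place_atom(a, b, c, site.bond, site.angle,
                                      site.resolve_torsion(phi, psi))
    return frame
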