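"""Conformational-ensemble containers and I/O.

Two ensemble flavours are supported:

* :class:`TorsionEnsemble` — per-snapshot (phi, psi) series for one
  linkage, read/written as a plain CSV torsion table.  This is a
  first-class input: the whole J-coupling / conformer pipeline runs from
  torsions alone.
* :class:`CoordinateEnsemble` — multi-frame Cartesian coordinates, read
  from multi-frame XYZ or multi-MODEL PDB (via MDAnalysis).  Required for
  NOE work, where interatomic distances matter.

:class:`SimulationPlan` does the bookkeeping for a constant-temperature
sampling protocol (run length, snapshot interval, equilibration discard):
a 20,000 ps run sampled every 2 ps yields 10,000 snapshots.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AtomLookupError,
    EmptyInputError,
    EnsembleParseError,
    ValidationError,
)
from .geometry import LinkageSpec, _dihedral_array, wrap_angle

__all__ = [
    "SimulationPlan",
    "TorsionEnsemble",
    "CoordinateEnsemble",
    "expected_snapshots",
    "read_coordinate_ensemble",
    "write_coordinate_ensemble",
    "read_torsion_table",
    "write_torsion_table",
    "extract_torsion_ensemble",
]


@dataclass(frozen=True)
class SimulationPlan:
    """Sampling plan of a constant-temperature run.

    Parameters are picoseconds (run_length, snapshot_interval,
    equilibration) and Kelvin (temperature).  ``equilibration`` is a
    discarded prefix of the run; it defaults to 0 because supplied
    ensembles are normally already production-only.
    """

    run_length: float
    snapshot_interval: float
    temperature: float = 298.0
    equilibration: float = 0.0

    def __post_init__(self) -> None:
        if self.run_length <= 0:
            raise ValidationError(f"run_length must be > 0 ps, got {self.run_length}")
        if not 0 < self.snapshot_interval <= self.run_length:
            raise ValidationError(
                f"snapshot_interval must be in (0, run_length], got {self.snapshot_interval}"
            )
        if self.temperature <= 0:
            raise ValidationError(f"temperature must be > 0 K, got {self.temperature}")
        if not 0 <= self.equilibration < self.run_length:
            raise ValidationError(
                f"equilibration must be in [0, run_length), got {self.equilibration}"
            )


def expected_snapshots(plan: SimulationPlan) -> int:
    """Number of snapshots the plan produces after the equilibration discard."""
    return math.floor((plan.run_length - plan.equilibration) / plan.snapshot_interval)


@dataclass
class TorsionEnsemble:
    """Ordered per-snapshot (phi, psi) series for one glycosidic linkage."""

    linkage: str
    frames: np.ndarray  # frame indices or times (ps)
    phi: np.ndarray  # degrees, (-180, 180]
    psi: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.phi = wrap_angle(np.asarray(self.phi, dtype=float))
        self.psi = wrap_angle(np.asarray(self.psi, dtype=float))
        if not (len(self.frames) == len(self.phi) == len(self.psi)):
            raise ValidationError("frames, phi and psi must have equal length")
        if len(self.frames) == 0:
            raise EmptyInputError("a torsion ensemble needs at least one frame")
        if np.any(np.diff(self.frames) <= 0):
            raise ValidationError("frame indices/times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def subset(self, indices) -> "TorsionEnsemble":
        idx = np.asarray(indices)
        return TorsionEnsemble(self.linkage, self.frames[idx], self.phi[idx],
                               self.psi[idx], self.provenance)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": self.frames, "phi_deg": self.phi, "psi_deg": self.psi}
        )


@dataclass
class CoordinateEnsemble:
    """Multi-frame Cartesian coordinates with a stable atom order (Angstrom)."""

    atom_ids: list[str]
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if self.coords.shape[1] != len(self.atom_ids):
            raise ValidationError(
                f"{len(self.atom_ids)} atom ids but frames have {self.coords.shape[1]} atoms"
            )
        if len(set(self.atom_ids)) != len(self.atom_ids):
            raise ValidationError(f"duplicate atom ids: {self.atom_ids}")
        if self.n_frames == 0:
            raise EmptyInputError("a coordinate ensemble needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def index_of(self, atom_id: str) -> int:
        try:
            return self.atom_ids.index(atom_id)
        except ValueError:
            raise AtomLookupError(
                f"atom {atom_id!r} not in ensemble (atoms: {self.atom_ids})"
            ) from None

    def frame(self, i: int) -> dict[str, np.ndarray]:
        return dict(zip(self.atom_ids, self.coords[i]))

    def iter_frames(self) -> Iterator[dict[str, np.ndarray]]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def subset(self, indices) -> "CoordinateEnsemble":
        idx = np.asarray(indices)
        return CoordinateEnsemble(list(self.atom_ids), self.coords[idx], self.provenance)

    @classmethod
    def from_frames(cls, frames: Sequence[dict[str, np.ndarray]],
                    atom_ids: Sequence[str] | None = None,
                    provenance: str = "") -> "CoordinateEnsemble":
        if len(frames) == 0:
            raise EmptyInputError("no frames supplied")
        ids = list(atom_ids) if atom_ids is not None else list(frames[0])
        coords = np.empty((len(frames), len(ids), 3))
        for i, fr in enumerate(frames):
            for j, a in enumerate(ids):
                if a not in fr:
                    raise AtomLookupError(f"atom {a!r} missing from frame {i}")
                coords[i, j] = fr[a]
        return cls(ids, coords, provenance)


# ---------------------------------------------------------------------------
# coordinate I/O (MDAnalysis-backed)


def _guess_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower()
    else:
        f = path.suffix.lstrip(".").lower()
    if f not in ("xyz", "pdb"):
        raise ValidationError(f"unsupported ensemble format {f!r} (use 'xyz' or 'pdb')")
    return f


def _universe_atom_ids(u) -> list[str]:
    """Atom ids: bare atom names when unique, name@resid otherwise."""
    names = [str(n) for n in u.atoms.names]
    if len(set(names)) == len(names):
        return names
    resids = u.atoms.resids
    return [f"{n}@{r}" for n, r in zip(names, resids)]


def _precheck_structure(path: Path, fmt: str) -> None:
    """Cheap structural validation; trajectory readers silently drop a
    truncated trailing frame, which must instead be a parse error."""
    text = path.read_text()
    lines = text.splitlines()
    while lines and not lines[-1].strip():
        lines.pop()
    if fmt == "xyz":
        i, frame = 0, 0
        while i < len(lines):
            try:
                natoms = int(lines[i].split()[0])
            except (ValueError, IndexError):
                raise EnsembleParseError(
                    f"{path}: line {i + 1}: expected an atom count starting frame {frame}"
                ) from None
            if i + 2 + natoms > len(lines):
                raise EnsembleParseError(
                    f"{path}: truncated frame {frame} (expected {natoms} atom lines)"
                )
            i += natoms + 2
            frame += 1
    elif fmt == "pdb":
        n_model = sum(1 for ln in lines if ln.startswith("MODEL"))
        n_end = sum(1 for ln in lines if ln.startswith("ENDMDL"))
        if n_model != n_end:
            raise EnsembleParseError(
                f"{path}: truncated frame {n_end} ({n_model} MODEL vs {n_end} ENDMDL records)"
            )


def read_coordinate_ensemble(path, format: str | None = None) -> CoordinateEnsemble:
    """Read a multi-frame XYZ or multi-MODEL PDB file.

    Frames are returned in file order; atom ids come from the name column
    (XYZ) or atom name + residue (PDB).  A truncated or malformed frame
    raises :class:`EnsembleParseError` identifying the frame.
    """
    import MDAnalysis as mda

    path = Path(path)
    fmt = _guess_format(path, format)
    _precheck_structure(path, fmt)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt, topology_format=fmt)
    except (OSError,) as e:
        raise EnsembleParseError(f"cannot open {path}: {e}") from e
    except Exception as e:  # malformed header / first frame
        raise EnsembleParseError(f"cannot parse {path} as {fmt}: {e}") from e

    atom_ids = _universe_atom_ids(u)
    frames = []
    try:
        for ts in u.trajectory:
            if ts.positions.shape[0] != len(atom_ids):
                raise EnsembleParseError(
                    f"{path}: frame {len(frames)} has {ts.positions.shape[0]} atoms, "
                    f"expected {len(atom_ids)}"
                )
            frames.append(ts.positions.astype(float).copy())
    except EnsembleParseError:
        raise
    except Exception as e:
        raise EnsembleParseError(
            f"{path}: failed reading frame {len(frames)}: {e}"
        ) from e
    if not frames:
        raise EnsembleParseError(f"{path}: no frames found")
    return CoordinateEnsemble(atom_ids, np.stack(frames), provenance=str(path))


def write_coordinate_ensemble(ens: CoordinateEnsemble, path, format: str | None = None) -> None:
    """Write an ensemble as multi-frame XYZ or multi-MODEL PDB."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    path = Path(path)
    fmt = _guess_format(path, format)
    n = ens.n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=1, atom_resindex=np.zeros(n, dtype=int),
                               trajectory=True)
        u.add_TopologyAttr("names", ens.atom_ids)
        u.add_TopologyAttr("resnames", ["FRG"])
        u.add_TopologyAttr("resids", [1])
        u.load_new(ens.coords.astype(np.float32), format=MemoryReader)
        with mda.Writer(str(path), n_atoms=n, format=fmt, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# torsion-table I/O (CSV: frame, phi_deg, psi_deg)


def read_torsion_table(path, linkage: str = "") -> TorsionEnsemble:
    """Read a torsion-table CSV with columns frame, phi_deg, psi_deg."""
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as e:
        raise EnsembleParseError(f"cannot parse torsion table {path}: {e}") from e
    missing = {"frame", "phi_deg", "psi_deg"} - set(df.columns)
    if missing:
        raise EnsembleParseError(
            f"torsion table {path} lacks columns {sorted(missing)} (found {list(df.columns)})"
        )
    return TorsionEnsemble(
        linkage=linkage or str(path),
        frames=df["frame"].to_numpy(),
        phi=df["phi_deg"].to_numpy(),
        psi=df["psi_deg"].to_numpy(),
        provenance=str(path),
    )


def write_torsion_table(ens: TorsionEnsemble, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        ens.to_dataframe().to_csv(fh, index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# torsion extraction


def extract_torsion_ensemble(coords: CoordinateEnsemble, spec: LinkageSpec) -> TorsionEnsemble:
    """Per-frame (phi, psi) of ``spec`` over a coordinate ensemble.

    Vectorized over frames; order preserved.  Raises
    :class:`AtomLookupError` naming any missing atom.
    """
    idx = {a: coords.index_of(a) for a in spec.atom_ids}
    phi_pts = [coords.coords[:, idx[a], :] for a in spec.phi_atoms]
    psi_pts = [coords.coords[:, idx[a], :] for a in spec.psi_atoms]
    phi = wrap_angle(_dihedral_array(*phi_pts))
    psi = wrap_angle(_dihedral_array(*psi_pts))
    return TorsionEnsemble(
        linkage=spec.name,
        frames=np.arange(coords.n_frames, dtype=float),
        phi=phi,
        psi=psi,
        provenance=f"extracted from {coords.provenance or 'coordinate ensemble'}",
    )
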