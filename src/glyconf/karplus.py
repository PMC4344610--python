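"""Karplus evaluation, ensemble averaging and experiment comparison.

Trans-glycosidic three-bond coupling constants 3J(C-O-C-H) report on the
intervening torsion theta through the empirical Karplus relation

    J(theta) = A cos^2(theta) + B cos(theta) + C        [Hz]

Coefficient sets are data, not constants: they ship in a packaged YAML
config (default set ``tvaroska1989``: A=5.7, B=-0.6, C=0.5 Hz, the
standard parameterization for C-O-C-H fragments) and users may register
alternates.

Ensemble averaging is over snapshots: the predicted coupling is the
arithmetic (optionally weighted) mean <J(theta)> across frames — NOT
J(<theta>).  The distinction matters for multimodal torsion
distributions, which is exactly the situation flexible glycosidic
linkages are in.

Comparison against measured couplings uses a default tolerance of 0.5 Hz,
the experimental uncertainty of J-HMBC-derived 3J(C-H).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyInputError, PairingError, ValidationError

__all__ = [
    "KarplusParams",
    "CouplingRecord",
    "ComparisonTable",
    "karplus_j",
    "ensemble_j",
    "compare_couplings",
    "mean_absolute_deviation",
    "load_karplus_sets",
    "get_karplus_params",
    "read_coupling_records",
    "write_coupling_records",
    "packaged_coupling_records",
    "COUPLING_SOURCES",
    "DEFAULT_TOLERANCE_HZ",
]

COUPLING_SOURCES = ("experimental", "in_vacuo", "SASA", "water", "synthetic")
DEFAULT_TOLERANCE_HZ = 0.5
DEFAULT_PARAM_SET = "tvaroska1989"


@dataclass(frozen=True)
class KarplusParams:
    """Named coefficient set for J(theta) = A cos^2 + B cos + C (Hz)."""

    name: str
    A: float
    B: float
    C: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("parameter set name must be nonempty")
        if not all(np.isfinite(v) for v in (self.A, self.B, self.C)):
            raise ValidationError(f"non-finite Karplus coefficients in {self.name!r}")


def load_karplus_sets(path=None) -> dict[str, KarplusParams]:
    """Load named coefficient sets from YAML (name -> {A, B, C}).

    With no path, the packaged defaults are loaded.
    """
    if path is None:
        text = resources.files("glyconf.data").joinpath("karplus_sets.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    sets = {}
    for name, abc in raw.items():
        try:
            sets[name] = KarplusParams(name, float(abc["A"]), float(abc["B"]), float(abc["C"]))
        except (KeyError, TypeError) as e:
            raise ValidationError(f"malformed Karplus set {name!r}: {e}") from e
    return sets


def get_karplus_params(name: str = DEFAULT_PARAM_SET, path=None) -> KarplusParams:
    sets = load_karplus_sets(path)
    if name not in sets:
        raise ValidationError(f"unknown Karplus set {name!r}; available: {sorted(sets)}")
    return sets[name]


def karplus_j(theta, params: KarplusParams):
    """Coupling J(theta) in Hz; theta in degrees (scalar or array).

    Even and 360-degree periodic in theta.
    """
    t = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValidationError("theta must be finite")
    c = np.cos(np.radians(t))
    j = params.A * c * c + params.B * c + params.C
    return j if j.ndim else float(j)


def ensemble_j(torsions, params: KarplusParams, weights=None) -> float:
    """Snapshot-averaged coupling <J(theta)> in Hz.

    ``torsions`` is a sequence of dihedral angles in degrees (one per
    snapshot); ``weights``, if given, are nonnegative per-snapshot weights
    with a positive sum.  Averaging J values (rather than angles) is what
    makes multimodal ensembles come out right.
    """
    t = np.atleast_1d(np.asarray(torsions, dtype=float))
    if t.size == 0:
        raise EmptyInputError("cannot average couplings over an empty ensemble")
    j = karplus_j(t, params)
    if weights is None:
        return float(np.mean(j))
    w = np.asarray(weights, dtype=float)
    if w.shape != t.shape:
        raise ValidationError(f"weights shape {w.shape} != torsions shape {t.shape}")
    if np.any(w < 0):
        raise ValidationError("weights must be nonnegative")
    if w.sum() <= 0:
        raise ValidationError("weights must have positive sum")
    return float(np.average(j, weights=w))


# ---------------------------------------------------------------------------
# coupling records and comparison tables


@dataclass(frozen=True)
class CouplingRecord:
    """One measured or calculated 3J(C-H) value."""

    compound: str
    linkage: str
    torsion_kind: str  # "phi" or "psi"
    source: str  # experimental | in_vacuo | SASA | water | synthetic
    value_hz: float

    def __post_init__(self) -> None:
        if self.torsion_kind not in ("phi", "psi"):
            raise ValidationError(f"torsion_kind must be phi/psi, got {self.torsion_kind!r}")
        if self.source not in COUPLING_SOURCES:
            raise ValidationError(
                f"source {self.source!r} not in {COUPLING_SOURCES}"
            )
        if not (np.isfinite(self.value_hz) and self.value_hz >= 0):
            raise ValidationError(f"coupling must be finite and >= 0, got {self.value_hz}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.compound, self.linkage, self.torsion_kind)


def read_coupling_records(path, source: str | None = None) -> list[CouplingRecord]:
    """Read CouplingRecords from CSV (compound, linkage, torsion_kind, source, value_hz).

    ``source`` optionally filters to one source column of the table.
    """
    df = pd.read_csv(path, comment="#", dtype={"compound": str})
    required = {"compound", "linkage", "torsion_kind", "source", "value_hz"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"coupling CSV {path} lacks columns {sorted(missing)}")
    df = df.dropna(subset=["value_hz"])
    if source is not None:
        df = df[df["source"] == source]
    return [
        CouplingRecord(str(r.compound), str(r.linkage), str(r.torsion_kind),
                       str(r.source), float(r.value_hz))
        for r in df.itertuples(index=False)
    ]


def write_coupling_records(records: Iterable[CouplingRecord], path) -> None:
    df = pd.DataFrame([r.__dict__ for r in records])
    df.to_csv(path, index=False, float_format="%.4f")


def packaged_coupling_records(source: str | None = None) -> list[CouplingRecord]:
    """The packaged experimental/calculated coupling fixture table.

    ``source`` optionally filters to one source (e.g. "experimental",
    "SASA", "in_vacuo", "water").
    """
    with resources.files("glyconf.data").joinpath("table1_couplings.csv").open() as fh:
        return read_coupling_records(fh, source=source)


@dataclass
class ComparisonTable:
    """Experimental vs calculated couplings with per-row deviations.

    ``rows`` columns: compound, linkage, torsion_kind, experimental_hz,
    calculated_hz, deviation_hz, within_error.  Row order is the
    deterministic sort (compound, linkage, torsion_kind).
    """

    rows: pd.DataFrame
    tolerance_hz: float

    def __len__(self) -> int:
        return len(self.rows)


def compare_couplings(experimental: Sequence[CouplingRecord],
                      calculated: Sequence[CouplingRecord],
                      tolerance_hz: float = DEFAULT_TOLERANCE_HZ) -> ComparisonTable:
    """Pair experimental with calculated records and tabulate deviations.

    Each experimental row must have exactly one calculated partner with
    the same (compound, linkage, torsion_kind); orphans on either side
    raise :class:`PairingError`.
    """
    if tolerance_hz <= 0:
        raise ValidationError(f"tolerance must be > 0 Hz, got {tolerance_hz}")
    exp = {r.key: r for r in experimental}
    calc = {r.key: r for r in calculated}
    if len(exp) != len(experimental):
        raise PairingError("duplicate (compound, linkage, torsion_kind) in experimental records")
    if len(calc) != len(calculated):
        raise PairingError("duplicate (compound, linkage, torsion_kind) in calculated records")
    orphans_exp = sorted(set(exp) - set(calc))
    orphans_calc = sorted(set(calc) - set(exp))
    if orphans_exp or orphans_calc:
        raise PairingError(
            f"unmatched rows — experimental without partner: {orphans_exp}; "
            f"calculated without partner: {orphans_calc}"
        )
    keys = sorted(exp)
    rows = pd.DataFrame(
        {
            "compound": [k[0] for k in keys],
            "linkage": [k[1] for k in keys],
            "torsion_kind": [k[2] for k in keys],
            "experimental_hz": [exp[k].value_hz for k in keys],
            "calculated_hz": [calc[k].value_hz for k in keys],
        }
    )
    rows["deviation_hz"] = (rows["experimental_hz"] - rows["calculated_hz"]).abs()
    rows["within_error"] = rows["deviation_hz"] <= tolerance_hz
    return ComparisonTable(rows=rows, tolerance_hz=tolerance_hz)


def mean_absolute_deviation(table: ComparisonTable) -> float:
    """Mean of the |experimental - calculated| column, in Hz (unrounded)."""
    if len(table) == 0:
        raise EmptyInputError("comparison table is empty")
    return float(table.rows["deviation_hz"].mean())
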