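"""Conformer classification and population analysis on the phi/psi torus.

Flexible glycosidic linkages populate a small number of localized states:
phi sits near +20..40 deg (pinned by the exo-anomeric effect) while psi
distinguishes the conformers — near +40 deg (state I), near 0 deg
(state II), and the "inverted" region near +/-170..180 deg (state III).
States are declared regions (circular center + acceptance radius per
coordinate), not discovered clusters; a snapshot is assigned to the
nearest declared state it falls inside, or to "unassigned".

Because state III straddles the +/-180 boundary, all distances are
circular.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .ensembles import TorsionEnsemble
from .errors import EmptyInputError, ValidationError
from .geometry import wrap_angle

__all__ = [
    "ConformerState",
    "ConformerStateSet",
    "PopulationReport",
    "circular_distance",
    "classify",
    "classify_ensemble",
    "populations",
    "torsion_timeseries",
    "default_states",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"


def circular_distance(a, b):
    """Shortest angular distance |a - b| on the circle, in [0, 180] degrees."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    out = np.minimum(d, 360.0 - d)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ConformerState:
    """A labeled region on the (phi, psi) torus.

    ``radius`` is the per-coordinate circular acceptance radius: a
    snapshot belongs to the region iff both its phi and psi are within
    ``radius`` of the center.
    """

    label: str
    phi_center: float
    psi_center: float
    radius: float = 35.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError(f"state {self.label!r}: radius must be > 0")
        if not (np.isfinite(self.phi_center) and np.isfinite(self.psi_center)):
            raise ValidationError(f"state {self.label!r}: non-finite center")

    @property
    def center(self) -> tuple[float, float]:
        return (wrap_angle(self.phi_center), wrap_angle(self.psi_center))

    def contains(self, phi, psi):
        return (circular_distance(phi, self.phi_center) <= self.radius) & (
            circular_distance(psi, self.psi_center) <= self.radius
        )

    def distance(self, phi, psi):
        """Combined circular distance sqrt(dphi^2 + dpsi^2) to the center."""
        return np.hypot(
            circular_distance(phi, self.phi_center),
            circular_distance(psi, self.psi_center),
        )


@dataclass
class ConformerStateSet:
    """An ordered set of declared conformer states.

    Declaration order is the tie-break: when a snapshot is equidistant
    from (and inside) several states, the first declared wins.
    """

    states: list[ConformerState] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.states:
            raise ValidationError("a state set needs at least one state")
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate state labels: {labels}")
        centers = [s.center for s in self.states]
        if len(set(centers)) != len(centers):
            raise ValidationError("state centers must be distinct")

    def __iter__(self):
        return iter(self.states)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]

    @classmethod
    def from_yaml(cls, path) -> "ConformerStateSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw) -> "ConformerStateSet":
        states = [
            ConformerState(
                label=str(s["label"]),
                phi_center=float(s["phi_center"]),
                psi_center=float(s["psi_center"]),
                radius=float(s.get("radius", 35.0)),
            )
            for s in raw["states"]
        ]
        return cls(states)


def default_states(radius: float = 35.0) -> ConformerStateSet:
    """The standard three-state taxonomy of a 1->x glycosidic linkage.

    I = (30, +40), II = (30, 0), III = (30, 180); the default radius keeps
    assignment unambiguous via the nearest-center rule even where the I
    and II acceptance boxes meet.
    """
    return ConformerStateSet(
        [
            ConformerState("I", 30.0, 40.0, radius),
            ConformerState("II", 30.0, 0.0, radius),
            ConformerState("III", 30.0, 180.0, radius),
        ]
    )


def classify(phi: float, psi: float, states: ConformerStateSet) -> str:
    """State label for one snapshot, or "unassigned" if outside all radii.

    The nearest state (combined circular distance) among those whose
    acceptance box contains the point wins; exact ties go to the earlier
    declared state.
    """
    best_label, best_d = UNASSIGNED, np.inf
    for s in states:
        if s.contains(phi, psi):
            d = s.distance(phi, psi)
            if d < best_d - 1e-12:
                best_label, best_d = s.label, d
    return best_label


def classify_ensemble(ensemble: TorsionEnsemble, states: ConformerStateSet) -> np.ndarray:
    """Vectorized per-frame state labels for a torsion ensemble."""
    n = len(ensemble)
    dists = np.full((len(states), n), np.inf)
    for k, s in enumerate(states):
        inside = s.contains(ensemble.phi, ensemble.psi)
        d = s.distance(ensemble.phi, ensemble.psi)
        dists[k] = np.where(inside, d, np.inf)
    labels = np.array([UNASSIGNED] * n, dtype=object)
    any_inside = np.isfinite(dists).any(axis=0)
    # argmin returns the first (declaration-order) index on ties
    best = np.argmin(dists, axis=0)
    state_labels = np.array(states.labels, dtype=object)
    labels[any_inside] = state_labels[best[any_inside]]
    return labels


@dataclass
class PopulationReport:
    """Counts and fractions per conformer state plus an unassigned bucket."""

    counts: dict[str, int]
    fractions: dict[str, float]
    total: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValidationError("state counts do not sum to the total frame count")
        if abs(sum(self.fractions.values()) - 1.0) > 1e-12:
            raise ValidationError("fractions must sum to 1")

    def fraction(self, label: str) -> float:
        return self.fractions.get(label, 0.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": list(self.counts),
                "count": list(self.counts.values()),
                "fraction": [self.fractions[k] for k in self.counts],
            }
        )


def populations(labels: Sequence[str],
                state_order: Sequence[str] | None = None) -> PopulationReport:
    """Exact per-state counts and fractions from a label sequence.

    ``state_order`` fixes the report ordering (and forces zero-count rows
    for declared-but-unpopulated states); the unassigned bucket is always
    reported last.
    """
    labels = list(labels)
    if not labels:
        raise EmptyInputError("cannot compute populations of an empty label sequence")
    counts: dict[str, int] = {}
    if state_order is not None:
        for s in state_order:
            counts[s] = 0
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    counts.setdefault(UNASSIGNED, 0)
    # keep unassigned last
    ordered = {k: v for k, v in counts.items() if k != UNASSIGNED}
    ordered[UNASSIGNED] = counts[UNASSIGNED]
    total = len(labels)
    fractions = {k: v / total for k, v in ordered.items()}
    return PopulationReport(counts=ordered, fractions=fractions, total=total)


def torsion_timeseries(ensemble: TorsionEnsemble) -> pd.DataFrame:
    """Ordered (frame, phi_deg, psi_deg) rows for time-series/scatter plots."""
    return ensemble.to_dataframe()
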