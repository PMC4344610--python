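"""Relative NOE prediction from coordinate ensembles.

Cross-relaxation between an isolated proton pair scales as the ensemble
average of r^-6 of their distance.  Relative NOEs are therefore computed
as the ratio

    NOE(pair) / NOE(ref) = <r_pair^-6> / <r_ref^-6>

with the reference pair (conventionally the anomeric H1 of the
glycosylating residue to the linkage proton Hx) normalized to exactly 1.
This isolated two-spin approximation neglects spin diffusion and
mixing-time effects; it is adequate in the linear build-up regime.

An observed intensity of literal 0 encodes the absence of a cross-peak.
:func:`flag_incompatible_noes` compares predicted against observed tables
and flags pairs predicted above a threshold but absent in the spectrum
(and vice versa) — the logic used to discriminate between solvent models.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .ensembles import CoordinateEnsemble
from .errors import (
    DegenerateGeometryError,
    NormalizationError,
    PairingError,
    ValidationError,
)

__all__ = [
    "ProtonPair",
    "NoeTable",
    "NoeDiscrepancy",
    "mean_inv_r6",
    "relative_noe",
    "flag_incompatible_noes",
    "read_noe_table",
    "write_noe_table",
    "packaged_noe_table",
    "DEFAULT_ABSENCE_THRESHOLD",
]

#: smallest predicted relative intensity treated as consistent with an
#: absent cross-peak (configurable per call)
DEFAULT_ABSENCE_THRESHOLD = 0.05


@dataclass(frozen=True)
class ProtonPair:
    """A proton pair whose NOE is predicted; donor is the anomeric H1."""

    donor: str
    acceptor: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.donor == self.acceptor:
            raise ValidationError(f"donor and acceptor coincide: {self.donor!r}")
        if not self.label:
            object.__setattr__(self, "label", f"{self.donor}-{self.acceptor}")


@dataclass
class NoeTable:
    """Relative NOE intensities.

    ``rows`` columns: compound, pair, source, intensity, reference.
    The reference pair's own intensity is 1 in every source; intensities
    are nonnegative and 0 encodes an absent cross-peak.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"compound", "pair", "source", "intensity", "reference"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValidationError(f"NOE table lacks columns {sorted(missing)}")
        if (self.rows["intensity"] < 0).any():
            raise ValidationError("NOE intensities must be nonnegative")
        is_ref = self.rows["pair"] == self.rows["reference"]
        if not np.allclose(self.rows.loc[is_ref, "intensity"], 1.0):
            raise ValidationError("the reference pair's own relative intensity must be 1")

    def __len__(self) -> int:
        return len(self.rows)


def read_noe_table(path) -> NoeTable:
    df = pd.read_csv(path, comment="#", dtype={"compound": str})
    return NoeTable(df)


def write_noe_table(table: NoeTable, path) -> None:
    table.rows.to_csv(path, index=False, float_format="%.4f")


def packaged_noe_table() -> NoeTable:
    """The packaged experimental/calculated relative-NOE fixture table."""
    with resources.files("glyconf.data").joinpath("table2_noe.csv").open() as fh:
        return read_noe_table(fh)


def _pair_distances(frames: CoordinateEnsemble, pair: ProtonPair) -> np.ndarray:
    i = frames.index_of(pair.donor)
    j = frames.index_of(pair.acceptor)
    d = np.linalg.norm(frames.coords[:, i, :] - frames.coords[:, j, :], axis=1)
    zero = np.nonzero(d <= 0)[0]
    if zero.size:
        raise DegenerateGeometryError(
            f"zero distance for pair {pair.label} in frame(s) {zero[:5].tolist()}"
        )
    return d


def mean_inv_r6(frames: CoordinateEnsemble, pair: ProtonPair, weights=None) -> float:
    """Weighted ensemble average of r^-6 for one proton pair (Angstrom^-6).

    Invariant under per-frame rigid motions (only distances enter).
    """
    d = _pair_distances(frames, pair)
    inv6 = d ** -6.0
    if weights is None:
        return float(np.mean(inv6))
    w = np.asarray(weights, dtype=float)
    if w.shape != inv6.shape:
        raise ValidationError(f"weights shape {w.shape} != frame count {inv6.shape}")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValidationError("weights must be nonnegative with positive sum")
    return float(np.average(inv6, weights=w))


def relative_noe(frames: CoordinateEnsemble, pairs: Sequence[ProtonPair],
                 reference: ProtonPair, weights=None,
                 compound: str = "", source: str = "synthetic") -> NoeTable:
    """Relative NOE of each pair against ``reference`` over an ensemble.

    Row value = <r_pair^-6> / <r_ref^-6>; the reference row (appended if
    not already among ``pairs``) is exactly 1.
    """
    ref_inv6 = mean_inv_r6(frames, reference, weights)
    if not (np.isfinite(ref_inv6) and ref_inv6 > 0):
        raise NormalizationError(
            f"reference pair {reference.label} has non-positive <r^-6> = {ref_inv6}"
        )
    all_pairs = list(pairs)
    if reference.label not in [p.label for p in all_pairs]:
        all_pairs.append(reference)
    records = []
    for p in all_pairs:
        if p.label == reference.label:
            val = 1.0
        else:
            val = mean_inv_r6(frames, p, weights) / ref_inv6
        records.append(
            {"compound": compound, "pair": p.label, "source": source,
             "intensity": val, "reference": reference.label}
        )
    return NoeTable(pd.DataFrame(records))


class NoeDiscrepancy(NamedTuple):
    compound: str
    pair: str
    predicted: float
    observed: float
    kind: str  # "predicted_but_absent" | "observed_but_not_predicted"


def flag_incompatible_noes(predicted: NoeTable, observed: NoeTable,
                           threshold: float = DEFAULT_ABSENCE_THRESHOLD
                           ) -> list[NoeDiscrepancy]:
    """Pairs where prediction and observation disagree about presence.

    Flags (compound, pair) entries where the predicted intensity is at or
    above ``threshold`` but the observed intensity is 0 (no cross-peak),
    and conversely where a pair observed at or above threshold is
    predicted 0.  Unmatched labels raise :class:`PairingError`.
    """
    if threshold <= 0:
        raise ValidationError(f"threshold must be > 0, got {threshold}")
    p = predicted.rows.set_index(["compound", "pair"])
    o = observed.rows.set_index(["compound", "pair"])
    if p.index.has_duplicates or o.index.has_duplicates:
        raise PairingError("duplicate (compound, pair) entries in NOE tables")
    missing = sorted(set(p.index) ^ set(o.index))
    if missing:
        raise PairingError(f"unmatched (compound, pair) labels: {missing}")
    out: list[NoeDiscrepancy] = []
    for key in sorted(p.index):
        pv = float(p.loc[key, "intensity"])
        ov = float(o.loc[key, "intensity"])
        if pv >= threshold and ov == 0:
            out.append(NoeDiscrepancy(key[0], key[1], pv, ov, "predicted_but_absent"))
        elif ov >= threshold and pv == 0:
            out.append(NoeDiscrepancy(key[0], key[1], pv, ov, "observed_but_not_predicted"))
    return out
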