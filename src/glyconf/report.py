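"""Run configuration and report assembly behind the command-line tools.

A single YAML config can drive the whole analysis: torsion or coordinate
input, linkage definition, Karplus set, conformer state set, comparison
tolerance and NOE pair list.  Outputs are deterministic CSV files (fixed
4-decimal float formatting) whose comment headers carry the package
version and a hash of the effective configuration, plus a machine-
readable JSON summary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .conformers import (
    ConformerStateSet,
    classify_ensemble,
    default_states,
    populations,
    torsion_timeseries,
)
from .ensembles import (
    extract_torsion_ensemble,
    read_coordinate_ensemble,
    read_torsion_table,
)
from .errors import CapabilityError, ConfigurationError, ValidationError
from .geometry import LinkageSpec, default_linkage_spec
from .karplus import (
    DEFAULT_TOLERANCE_HZ,
    compare_couplings,
    ensemble_j,
    get_karplus_params,
    mean_absolute_deviation,
    read_coupling_records,
)
from .noe import ProtonPair, relative_noe

__all__ = ["RunConfig", "analyze", "config_hash", "write_csv", "mad_per_source"]


def config_hash(payload: Any) -> str:
    """Short stable hash of a config payload (canonical JSON, sha256/12)."""
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, cfg_hash: str, float_format: str = "%.4f") -> None:
    """Write a CSV with a provenance comment header."""
    with open(path, "w") as fh:
        fh.write(f"# glyconf v{__version__} config={cfg_hash}\n")
        df.to_csv(fh, index=False, float_format=float_format)


@dataclass
class RunConfig:
    """Validated inputs of one analysis run."""

    torsions: str | None = None  # torsion-table CSV
    coordinates: str | None = None  # multi-frame XYZ / multi-MODEL PDB
    coordinates_format: str | None = None
    linkage: LinkageSpec = field(default_factory=default_linkage_spec)
    karplus_set: str = "tvaroska1989"
    karplus_file: str | None = None
    states: ConformerStateSet = field(default_factory=default_states)
    tolerance_hz: float = DEFAULT_TOLERANCE_HZ
    couplings: str | None = None  # experimental/calculated coupling CSV
    calculated_sources: tuple[str, ...] = ("in_vacuo", "SASA", "water")
    noe_pairs: tuple[tuple[str, str], ...] = ()
    noe_reference: tuple[str, str] | None = None
    compound: str = ""
    seed: int = 0
    out_dir: str = "glyconf_out"

    def __post_init__(self) -> None:
        if self.tolerance_hz <= 0:
            raise ValidationError(f"tolerance must be > 0 Hz, got {self.tolerance_hz}")
        if self.torsions is None and self.coordinates is None and self.couplings is None:
            raise ConfigurationError(
                "config needs at least one input: torsions, coordinates or couplings"
            )
        for label, p in (("torsions", self.torsions), ("coordinates", self.coordinates),
                         ("couplings", self.couplings), ("karplus_file", self.karplus_file)):
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{label} file does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}

        def respath(p):
            return None if p is None else str((base / p) if not Path(p).is_absolute() else Path(p))

        linkage = raw.get("linkage")
        if linkage is None:
            spec = default_linkage_spec()
        elif isinstance(linkage, str):
            spec = LinkageSpec.from_yaml(respath(linkage))
        else:
            spec = LinkageSpec.from_dict(linkage)
        states = raw.get("states")
        if states is None:
            state_set = default_states()
        elif isinstance(states, str):
            state_set = ConformerStateSet.from_yaml(respath(states))
        else:
            state_set = ConformerStateSet.from_dict(states)
        noe = raw.get("noe") or {}
        pairs = tuple(tuple(p) for p in noe.get("pairs", ()))
        reference = tuple(noe["reference"]) if "reference" in noe else None
        return cls(
            torsions=respath(raw.get("torsions")),
            coordinates=respath(raw.get("coordinates")),
            coordinates_format=raw.get("coordinates_format"),
            linkage=spec,
            karplus_set=raw.get("karplus_set", "tvaroska1989"),
            karplus_file=respath(raw.get("karplus_file")),
            states=state_set,
            tolerance_hz=float(raw.get("tolerance_hz", DEFAULT_TOLERANCE_HZ)),
            couplings=respath(raw.get("couplings")),
            calculated_sources=tuple(raw.get("calculated_sources",
                                             ("in_vacuo", "SASA", "water"))),
            noe_pairs=pairs,
            noe_reference=reference,
            compound=str(raw.get("compound", "")),
            seed=int(raw.get("seed", 0)),
            out_dir=raw.get("out_dir", "glyconf_out"),
        )

    def payload(self) -> dict:
        d = dict(self.__dict__)
        d["linkage"] = self.linkage.to_dict()
        d["states"] = [s.__dict__ for s in self.states]
        return d


def mad_per_source(records, tolerance_hz: float = DEFAULT_TOLERANCE_HZ,
                   calculated_sources=("in_vacuo", "SASA", "water")) -> pd.DataFrame:
    """Mean absolute deviation of each calculated source vs experiment.

    ``records`` is a CouplingRecord list containing an ``experimental``
    source plus one or more calculated sources.  Rows: source, n_pairs,
    mad_hz (unrounded), mad_hz_2dp, n_within_error.
    """
    exp = [r for r in records if r.source == "experimental"]
    rows = []
    for src in calculated_sources:
        calc = [r for r in records if r.source == src]
        if not calc:
            continue
        table = compare_couplings(exp, calc, tolerance_hz=tolerance_hz)
        mad = mean_absolute_deviation(table)
        rows.append(
            {
                "source": src,
                "n_pairs": len(table),
                "mad_hz": mad,
                "mad_hz_2dp": round(mad, 2),
                "n_within_error": int(table.rows["within_error"].sum()),
            }
        )
    return pd.DataFrame(rows)


def _load_torsion_ensemble(config: RunConfig):
    """(torsion ensemble, coordinate ensemble or None) from the config inputs."""
    coords = None
    if config.coordinates is not None:
        coords = read_coordinate_ensemble(config.coordinates, format=config.coordinates_format)
        tors = extract_torsion_ensemble(coords, config.linkage)
    elif config.torsions is not None:
        tors = read_torsion_table(config.torsions, linkage=config.linkage.name)
    else:
        tors = None
    return tors, coords


def analyze(config: RunConfig) -> dict:
    """Run the configured pipeline and write the report bundle.

    Returns a summary dict (also written as ``summary.json``): mean
    couplings per torsion, conformer populations, NOE table path, and —
    when a coupling table with experimental values is supplied — the MAD
    of every calculated source against experiment.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config_hash(config.payload())
    summary: dict[str, Any] = {"glyconf_version": __version__, "config_hash": h}
    files: dict[str, str] = {}

    tors, coords = _load_torsion_ensemble(config)

    if tors is not None:
        params = get_karplus_params(config.karplus_set, path=config.karplus_file)
        j_phi = ensemble_j(tors.phi, params)
        j_psi = ensemble_j(tors.psi, params)
        couplings = pd.DataFrame(
            {
                "linkage": [config.linkage.name] * 2,
                "torsion_kind": ["phi", "psi"],
                "karplus_set": [params.name] * 2,
                "mean_j_hz": [j_phi, j_psi],
                "n_frames": [len(tors)] * 2,
            }
        )
        write_csv(couplings, out / "couplings.csv", h)
        files["couplings"] = str(out / "couplings.csv")
        summary["mean_j_hz"] = {"phi": round(j_phi, 4), "psi": round(j_psi, 4)}

        labels = classify_ensemble(tors, config.states)
        report = populations(labels, state_order=config.states.labels)
        write_csv(report.to_dataframe(), out / "populations.csv", h)
        files["populations"] = str(out / "populations.csv")
        summary["populations"] = {k: round(v, 6) for k, v in report.fractions.items()}

        ts = torsion_timeseries(tors)
        ts["state"] = labels
        write_csv(ts, out / "torsion_timeseries.csv", h)
        files["torsion_timeseries"] = str(out / "torsion_timeseries.csv")

    if config.noe_pairs:
        if coords is None:
            raise CapabilityError(
                "NOE prediction needs a coordinate ensemble; the config supplies "
                "only a torsion table"
            )
        pairs = [ProtonPair(a, b) for a, b in config.noe_pairs]
        ref = (ProtonPair(*config.noe_reference) if config.noe_reference
               else pairs[0])
        table = relative_noe(coords, pairs, ref, compound=config.compound)
        write_csv(table.rows, out / "noe.csv", h)
        files["noe"] = str(out / "noe.csv")
        summary["relative_noe"] = {
            row["pair"]: round(float(row["intensity"]), 4)
            for _, row in table.rows.iterrows()
        }

    if config.couplings is not None:
        records = read_coupling_records(config.couplings)
        mads = mad_per_source(records, tolerance_hz=config.tolerance_hz,
                              calculated_sources=config.calculated_sources)
        write_csv(mads, out / "comparison_mad.csv", h)
        files["comparison_mad"] = str(out / "comparison_mad.csv")
        exp = [r for r in records if r.source == "experimental"]
        for src in config.calculated_sources:
            calc = [r for r in records if r.source == src]
            if not calc:
                continue
            table = compare_couplings(exp, calc, tolerance_hz=config.tolerance_hz)
            p = out / f"comparison_{src}.csv"
            write_csv(table.rows, p, h)
            files[f"comparison_{src}"] = str(p)
        summary["mad_hz"] = {
            row["source"]: round(float(row["mad_hz"]), 4) for _, row in mads.iterrows()
        }

    summary["files"] = files
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
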