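"""Readers and writers for the experiment CSV dialect and result JSON.

Experiments travel as a long-format CSV with columns
``experiment_id, time, <species...>`` (observed species only) plus a JSON
sidecar carrying the full initial-condition vectors, species lists and
units.  Discovery results serialize to a schema-versioned JSON document
with stable key order so runs diff cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .discovery import DiscoveryResult, IterationRecord
from .enumeration import MechanismMatrix, StoichiometrySpec
from .estimation import Experiment, ExperimentSet, FitResult

__all__ = [
    "parse_stoichiometry",
    "read_experiments",
    "write_experiments",
    "write_result",
    "read_result",
]

RESULT_SCHEMA_VERSION = 1


def parse_stoichiometry(text: str, n_intermediates: int = 0) -> StoichiometrySpec:
    """Parse ``"A:-4,B:1,C:1"`` into a stoichiometry spec.

    Species keep the order written; coefficients must be non-zero signed
    integers (intermediates are declared by count, not by zeros).
    """
    if not text or not text.strip():
        raise ValueError("empty stoichiometry string")
    names, coeffs = [], []
    for token in text.split(","):
        token = token.strip()
        parts = token.split(":")
        if len(parts) != 2 or not parts[0].strip():
            raise ValueError(f"malformed stoichiometry token {token!r}")
        name = parts[0].strip()
        try:
            coeff = int(parts[1])
        except ValueError:
            raise ValueError(
                f"non-integer coefficient in token {token!r}"
            ) from None
        if name in names:
            raise ValueError(f"duplicate species {name!r}")
        if coeff == 0:
            raise ValueError(
                f"zero coefficient for {name!r}: declare intermediates by count"
            )
        names.append(name)
        coeffs.append(coeff)
    return StoichiometrySpec(tuple(names), tuple(coeffs), n_intermediates)


# ---------------------------------------------------------------------------
# experiment CSV + sidecar


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_experiments(
    data: ExperimentSet,
    csv_path,
    sidecar_path=None,
    metadata: dict | None = None,
) -> None:
    """Write the CSV table and its JSON sidecar (C0 vectors, species, units)."""
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else _sidecar_path(csv_path)
    frames = []
    for i, exp in enumerate(data):
        df = pd.DataFrame(exp.y, columns=list(exp.observed_names))
        df.insert(0, "time", exp.t)
        df.insert(0, "experiment_id", i)
        frames.append(df)
    # %.17g guarantees float64 round-trip through text
    pd.concat(frames, ignore_index=True).to_csv(
        csv_path, index=False, float_format="%.17g"
    )

    sidecar = {
        "observed_species": list(data.observed_names),
        "experiments": [
            {
                "experiment_id": i,
                "species_names_full": list(exp.species_names_full),
                "C0_full": [float(v) for v in exp.C0_full],
            }
            for i, exp in enumerate(data)
        ],
    }
    if metadata:
        sidecar["metadata"] = metadata
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=False))


def read_experiments(csv_path, sidecar_path=None) -> ExperimentSet:
    """Read the experiment CSV (+ sidecar) back into an ExperimentSet.

    Rows are grouped by ``experiment_id`` (input order irrelevant); time
    must be strictly increasing within each experiment.  Without a sidecar,
    initial conditions default to the first observed row.
    """
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, float_precision="round_trip")
    required = {"experiment_id", "time"}
    if not required <= set(df.columns):
        raise ValueError(f"missing required columns {sorted(required - set(df.columns))}")
    species = [c for c in df.columns if c not in required]
    if not species:
        raise ValueError("no species columns found")
    for col in ["time", *species]:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise ValueError(
                f"non-numeric value in column {col!r} at row(s) {list(bad[:5])}"
            )

    sidecar = None
    sidecar_path = Path(sidecar_path) if sidecar_path else _sidecar_path(csv_path)
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())

    experiments = []
    for exp_id, group in df.groupby("experiment_id", sort=True):
        group = group.sort_values("time", kind="stable")
        t = group["time"].to_numpy(dtype=float)
        dup = np.flatnonzero(np.diff(t) <= 0)
        if len(dup):
            row = group.index[dup[0] + 1]
            raise ValueError(
                f"experiment {exp_id}: non-increasing time at input row {row}"
            )
        y = group[species].to_numpy(dtype=float)
        if sidecar is not None:
            entry = next(
                (e for e in sidecar["experiments"] if e["experiment_id"] == exp_id),
                None,
            )
            if entry is None:
                raise ValueError(f"sidecar lacks experiment_id {exp_id}")
            names_full = tuple(entry["species_names_full"])
            c0 = np.asarray(entry["C0_full"], dtype=float)
        else:
            names_full = tuple(species)
            c0 = y[0].copy()
        experiments.append(
            Experiment(
                t=t,
                y=y,
                observed_names=tuple(species),
                C0_full=c0,
                species_names_full=names_full,
            )
        )
    return ExperimentSet(experiments)


# ---------------------------------------------------------------------------
# discovery result JSON


def _record_to_dict(rec: IterationRecord) -> dict:
    return {
        "iteration_index": rec.iteration_index,
        "n_steps": rec.n_steps,
        "n_species": rec.n_species,
        "n_candidates": rec.n_candidates,
        "enumeration_complete": rec.enumeration_complete,
        "species_names": list(rec.species_names),
        "best_matrix": None
        if rec.best_matrix is None
        else [list(r) for r in rec.best_matrix.entries],
        "reaction_strings": rec.reaction_strings(),
        "best_fit": None if rec.best_fit is None else rec.best_fit.to_dict(),
    }


def _record_from_dict(d: dict) -> IterationRecord:
    best_fit = None
    if d["best_fit"] is not None:
        f = d["best_fit"]
        best_fit = FitResult(
            k_hat=np.asarray(f["k_hat"], dtype=float),
            sse=f["sse"],
            nll=f["nll"],
            aic=f["aic"],
            d=f["d"],
            success=f["success"],
        )
    return IterationRecord(
        iteration_index=d["iteration_index"],
        n_steps=d["n_steps"],
        n_species=d["n_species"],
        n_candidates=d["n_candidates"],
        best_matrix=None
        if d["best_matrix"] is None
        else MechanismMatrix(d["best_matrix"]),
        best_fit=best_fit,
        enumeration_complete=d["enumeration_complete"],
        species_names=tuple(d["species_names"]),
    )


def write_result(result: DiscoveryResult, path, config_echo: dict | None = None) -> None:
    """Serialize a discovery trace (all iterations, winner, reason) to JSON."""
    doc = {
        "schema_version": RESULT_SCHEMA_VERSION,
        "config": config_echo or {},
        "records": [_record_to_dict(r) for r in result.records],
        "winner_index": result.winner_index,
        "termination_reason": result.termination_reason,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_result(path) -> DiscoveryResult:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != RESULT_SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {doc.get('schema_version')}")
    result = DiscoveryResult(
        records=[_record_from_dict(d) for d in doc["records"]],
        termination_reason=doc["termination_reason"],
    )
    if doc["winner_index"] is not None:
        result.winner = next(
            r for r in result.records if r.iteration_index == doc["winner_index"]
        )
    return result
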