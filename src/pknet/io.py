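"""Readers and writers for the pipeline's plain-text dialects.

Concentration–time CSV columns: subject, group, time_h, conc_ug_L,
dose_ug_kg (one row per sample). Protein sets: one identifier per line,
or a two-column TSV of (set label, identifier) carrying several sets.
"""

from __future__ import annotations

import json
import os
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .interactome import ProteinSet
from .nca import ConcentrationTimeProfile

__all__ = [
    "read_profiles_csv",
    "write_profiles_csv",
    "read_protein_set",
    "read_protein_sets_tsv",
    "write_protein_set",
    "write_json",
]

PROFILE_COLUMNS = ["subject", "group", "time_h", "conc_ug_L", "dose_ug_kg"]


def read_profiles_csv(path: str | os.PathLike) -> list[ConcentrationTimeProfile]:
    df = pd.read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profiles CSV is missing columns: {missing}")
    profiles = []
    for subject, sub in df.groupby("subject", sort=False):
        sub = sub.sort_values("time_h")
        dose = sub["dose_ug_kg"].unique()
        if dose.size != 1:
            raise ValueError(f"subject {subject!r} has inconsistent dose entries")
        bloq = sub["bloq"].astype(bool).to_numpy() if "bloq" in sub.columns else None
        profiles.append(
            ConcentrationTimeProfile(
                subject_id=str(subject),
                group=str(sub["group"].iloc[0]),
                dose=float(dose[0]),
                times=sub["time_h"].to_numpy(dtype=float),
                concentrations=sub["conc_ug_L"].to_numpy(dtype=float),
                bloq=bloq,
            )
        )
    if not profiles:
        raise ValueError("profiles CSV contains no subjects")
    return profiles


def write_profiles_csv(
    profiles: Iterable[ConcentrationTimeProfile], path: str | os.PathLike
) -> None:
    rows = []
    for p in profiles:
        for t, c, q in zip(p.times, p.concentrations, p.bloq):
            rows.append(
                {
                    "subject": p.subject_id,
                    "group": p.group,
                    "time_h": t,
                    "conc_ug_L": c,
                    "dose_ug_kg": p.dose,
                    "bloq": bool(q),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_protein_set(path: str | os.PathLike, label: str | None = None) -> ProteinSet:
    """One identifier per line; '#' comments and blank lines ignored."""
    members = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                members.append(line)
    if label is None:
        label = os.path.splitext(os.path.basename(path))[0]
    return ProteinSet(label=label, members=frozenset(members))


def read_protein_sets_tsv(path: str | os.PathLike) -> list[ProteinSet]:
    """Two-column TSV (set label, identifier), several sets per file;
    sets appear in first-seen order."""
    groups: dict[str, set[str]] = {}
    order: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected 'label<TAB>identifier'")
            label, ident = fields[0], fields[1]
            if label not in groups:
                groups[label] = set()
                order.append(label)
            groups[label].add(ident)
    if not groups:
        raise ValueError("no protein sets found")
    return [ProteinSet(label=l, members=frozenset(groups[l])) for l in order]


def write_protein_set(s: ProteinSet, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in sorted(s.members):
            fh.write(m + "\n")


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_json(payload: Any, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonify(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")
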