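"""File I/O: FASTA/Clustal sequences, CSV measurement tables, TSV/JSON reports.

CSV dialects: header row required, UTF-8, '.' decimal separator.  Every
reader validates and reports the offending row on rejection; write -> read
round-trips are lossless for the internal record types.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .nmr import HDXSeries, HetNOEPair, RelaxationSeries
from .seqvar import MSA, SelectionAnnotation
from .ssbond import MassObservation, TreatmentCondition


def read_fasta(path) -> list[tuple[str, str]]:
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    SeqIO.write([SeqRecord(Seq(seq), id=name, description="")
                 for name, seq in records], str(path), "fasta")


def read_msa(path, fmt: str = "fasta") -> MSA:
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise ValueError(f"cannot read alignment {path}: {exc}") from None
    return MSA(tuple(rec.id for rec in aln),
               tuple(str(rec.seq).upper() for rec in aln))


def write_msa(msa: MSA, path, fmt: str = "fasta") -> None:
    aln = [SeqRecord(Seq(row), id=name, description="")
           for name, row in zip(msa.ids, msa.rows)]
    SeqIO.write(aln, str(path), fmt)


# --- mass observations -------------------------------------------------------

OBS_COLUMNS = ["mass", "tol_ppm", "enzyme", "dtt", "iaa", "n_reduced", "annotation"]


def _parse_bool(value: str, row: int, col: str) -> bool:
    v = str(value).strip().lower()
    if v in ("1", "true", "yes"):
        return True
    if v in ("0", "false", "no"):
        return False
    raise ValueError(f"row {row}: column {col!r} has non-boolean value {value!r}")


def read_observations_csv(path) -> list[MassObservation]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in OBS_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            mass = float(row["mass"])
            tol = float(row["tol_ppm"])
            tr = TreatmentCondition(enzyme=row["enzyme"].strip(),
                                    dtt=_parse_bool(row["dtt"], i + 2, "dtt"),
                                    iaa=_parse_bool(row["iaa"], i + 2, "iaa"),
                                    n_reduced=int(row["n_reduced"]))
            annotation = row.get("annotation", "").strip() or None
            out.append(MassObservation(mass, tol, tr, annotation))
        except ValueError as exc:
            raise ValueError(f"{path} row {i + 2}: {exc}") from None
    return out


def write_observations_csv(observations: Sequence[MassObservation], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(OBS_COLUMNS)
        for obs in observations:
            tr = obs.treatment
            w.writerow([f"{obs.mass:.6f}", obs.tol_ppm, tr.enzyme,
                        int(tr.dtt), int(tr.iaa), tr.n_reduced,
                        obs.annotation or ""])


# --- relaxation / NOE / HDX --------------------------------------------------

def read_relaxation_csv(path, experiment: str | None = None) -> list[RelaxationSeries]:
    """Columns: residue, delay_s, intensity [, experiment]."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("residue", "delay_s", "intensity"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if experiment is None:
        experiment = str(df["experiment"].iloc[0]) if "experiment" in df.columns else "R2"
    out = []
    for res, grp in df.groupby("residue", sort=True):
        out.append(RelaxationSeries(int(res), tuple(grp["delay_s"].astype(float)),
                                    tuple(grp["intensity"].astype(float)),
                                    experiment))
    return out


def write_relaxation_csv(series: Sequence[RelaxationSeries], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["residue", "delay_s", "intensity", "experiment"])
        for s in series:
            for t, v in zip(s.delays_s, s.intensities):
                w.writerow([s.residue, t, repr(v), s.experiment])


def read_noe_csv(path) -> list[HetNOEPair]:
    """Columns: residue, vol_sat, vol_unsat."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("residue", "vol_sat", "vol_unsat"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return [HetNOEPair(int(r.residue), float(r.vol_sat), float(r.vol_unsat))
            for r in df.itertuples(index=False)]


def write_noe_csv(pairs: Sequence[HetNOEPair], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["residue", "vol_sat", "vol_unsat"])
        for p in pairs:
            w.writerow([p.residue, repr(p.vol_saturated), repr(p.vol_unsaturated)])


def read_hdx_csv(path) -> list[HDXSeries]:
    """Columns: residue, time_h, integral."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("residue", "time_h", "integral"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return [HDXSeries(int(res), tuple(grp["time_h"].astype(float)),
                      tuple(grp["integral"].astype(float)))
            for res, grp in df.groupby("residue", sort=True)]


def write_hdx_csv(series: Sequence[HDXSeries], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["residue", "time_h", "integral"])
        for s in series:
            for t, v in zip(s.times_h, s.integrals):
                w.writerow([s.residue, t, repr(v)])


def read_selection_tsv(path) -> SelectionAnnotation:
    """TSV columns: site, class."""
    df = pd.read_csv(path, sep="\t")
    for col in ("site", "class"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return SelectionAnnotation({int(row["site"]): str(row["class"])
                                for _, row in df.iterrows()})


# --- reports -----------------------------------------------------------------

REPORT_SCHEMA_VERSION = 1


def write_report(payload: dict, path, parameters: dict | None = None) -> None:
    report = {"schema_version": REPORT_SCHEMA_VERSION,
              "parameters": parameters or {}}
    report.update(payload)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=_jsonify) + "\n")


def _jsonify(obj):
    import numpy as np
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
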