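"""Readers and writers for the pipeline's tabular and sequence formats.

Everything is plain TSV (UTF-8, header row) or FASTA.  Time-course tables
use ``feature_id`` followed by ``ZT<t>_r<k>`` sample columns; floats are
written with ``repr`` so that write-then-read is the identity.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO

from .types import (
    AMINO_ACIDS,
    ComplexRecord,
    InputError,
    KinaseMotifEntry,
    MotifPattern,
    SiteRecord,
    TimeCourseTable,
    parse_sample_label,
    sample_label,
)

log = logging.getLogger("ptmrhythm")

#: every tunable threshold in one place; CLI flags / YAML override these
DEFAULT_CONFIG: dict = {
    "alpha": 0.05,            # identification t-test level
    "q_cutoff": 0.2,          # rhythm FDR gate (strict <)
    "fold_change_pct": 20.0,  # day-night differential threshold (strict >)
    "p_gate_daynight": None,  # optional p co-gate for day-night calls
    "phase_lock_h": 2.0,      # circular delta <= 2 h
    "phase_shift_h": 8.0,     # circular delta >= 8 h
    "proximity_aa": 10,       # residue-pair window (inclusive)
    "kinase_phase_window_h": 4.0,
    "permutations": 10000,
    "min_replicates": 2,
    "rhythm_method": "jtk",   # jtk | umbrella | both
    "day_timepoint": 11.0,
    "night_timepoint": 23.0,
    "normalization_order": ["input_amount", "channel_sum", "protein"],
    "zero_denominator_policy": "missing",
    "seed": 0,
}


def _fmt_cell(v) -> str:
    if pd.isna(v):
        return ""
    f = float(v)
    if f == int(f) and abs(f) < 1e15:
        return str(int(f))
    return repr(f)


# --- time-course tables -----------------------------------------------------

def read_timecourse(path, condition: str, regime: str = "NA") -> TimeCourseTable:
    """Read a ``feature_id`` + ``ZT<t>_r<k>`` TSV into a TimeCourseTable."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if df.columns[0] != "feature_id":
        raise InputError(f"{path.name}: first column must be 'feature_id', "
                         f"got {df.columns[0]!r}")
    pairs = [parse_sample_label(c) for c in df.columns[1:]]
    if not pairs:
        raise InputError(f"{path.name}: no sample columns")
    df = df.set_index("feature_id")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise InputError(f"{path.name}: duplicate feature_id {dup!r}")
    data = df.apply(pd.to_numeric, errors="coerce")
    # numeric coercion must not silently eat malformed cells
    bad = data.isna() & df.notna() & (df.astype(str) != "")
    if bad.any().any():
        col = bad.any().idxmax()
        row = bad[col].idxmax()
        raise InputError(f"{path.name}: non-numeric cell at {row!r}/{col}")
    neg = data.lt(0)
    if neg.any().any():
        col = neg.any().idxmax()
        row = neg[col].idxmax()
        raise InputError(f"{path.name}: negative value at feature {row!r}, "
                         f"column {col}")
    data.columns = pd.MultiIndex.from_tuples(pairs, names=["timepoint", "replicate"])
    table = TimeCourseTable(data, condition=condition, regime=regime)
    log.info("read %s: %d features, %d samples (%s)",
             path.name, data.shape[0], data.shape[1], condition)
    return table


def write_timecourse(table: TimeCourseTable, path) -> None:
    path = Path(path)
    cols = ["feature_id"] + [sample_label(t, r) for t, r in table.data.columns]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for fid, row in table.data.iterrows():
            cells = [str(fid)] + [_fmt_cell(v) for v in row.to_numpy()]
            fh.write("\t".join(cells) + "\n")


# --- FASTA ------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """FASTA -> {accession: uppercase sequence}; accession is the first
    whitespace-delimited header token."""
    sequences: dict[str, str] = {}
    allowed = set(AMINO_ACIDS) | {"X"}
    for record in SeqIO.parse(str(path), "fasta"):
        acc = record.id
        seq = str(record.seq).upper()
        if not seq:
            raise InputError(f"empty FASTA record {acc!r}")
        if acc in sequences:
            raise InputError(f"duplicate FASTA accession {acc!r}")
        extra = set(seq) - allowed
        if extra:
            raise InputError(f"non-amino-acid characters {sorted(extra)} in {acc!r}")
        sequences[acc] = seq
    return sequences


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for acc in sequences:
            fh.write(f">{acc}\n")
            seq = sequences[acc]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --- site records -----------------------------------------------------------

def read_sites(path, sequences: Mapping[str, str] | None = None) -> list[SiteRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["accession", "position", "residue", "ptm", "feature_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"site table missing columns {missing}")
    sites = [
        SiteRecord(row.accession, int(row.position), row.residue, row.ptm,
                   row.feature_id)
        for row in df.itertuples()
    ]
    if sequences is not None:
        for s in sites:
            s.validate_against(dict(sequences))
    return sites


def write_sites(sites: Iterable[SiteRecord], path) -> None:
    rows = [
        {"accession": s.accession, "position": s.position, "residue": s.residue,
         "ptm": s.ptm, "feature_id": s.feature_id}
        for s in sites
    ]
    pd.DataFrame(rows, columns=["accession", "position", "residue", "ptm",
                                "feature_id"]).to_csv(path, sep="\t", index=False)


# --- complexes --------------------------------------------------------------

def read_complex_table(path) -> list[ComplexRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["complex_id", "complex_name", "members"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"complex table missing columns {missing}")
    records = []
    for row in df.itertuples():
        members = [m for m in row.members.split(";") if m]
        if len(members) != len(set(members)):
            raise InputError(f"complex {row.complex_id!r} lists a member twice")
        records.append(
            ComplexRecord(row.complex_id, row.complex_name, frozenset(members),
                          getattr(row, "function_label", ""))
        )
    return records


def write_complex_table(records: Iterable[ComplexRecord], path) -> None:
    rows = [
        {"complex_id": c.complex_id, "complex_name": c.complex_name,
         "members": ";".join(sorted(c.members)), "function_label": c.function_label}
        for c in records
    ]
    pd.DataFrame(rows, columns=["complex_id", "complex_name", "members",
                                "function_label"]).to_csv(path, sep="\t", index=False)


# --- motifs -----------------------------------------------------------------

def read_motifs(path) -> list[MotifPattern]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["pattern", "phospho_offset", "glyco_offset", "mode"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"motif table missing columns {missing}")
    return [
        MotifPattern(row.pattern, int(row.phospho_offset), int(row.glyco_offset),
                     row.mode)
        for row in df.itertuples()
    ]


def write_motifs(motifs: Iterable[MotifPattern], path) -> None:
    rows = [
        {"pattern": m.pattern, "phospho_offset": m.phospho_offset,
         "glyco_offset": m.glyco_offset, "mode": m.mode}
        for m in motifs
    ]
    pd.DataFrame(rows, columns=["pattern", "phospho_offset", "glyco_offset",
                                "mode"]).to_csv(path, sep="\t", index=False)


def read_kinase_motifs(path) -> list[KinaseMotifEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["kinase", "pattern"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"kinase motif table missing columns {missing}")
    out = []
    for row in df.itertuples():
        src = getattr(row, "source_feature", None)
        if src is not None and pd.isna(src):
            src = None
        out.append(KinaseMotifEntry(row.kinase, row.pattern, src))
    return out


def write_kinase_motifs(entries: Iterable[KinaseMotifEntry], path) -> None:
    rows = [
        {"kinase": e.kinase, "pattern": e.pattern,
         "source_feature": e.source_feature or ""}
        for e in entries
    ]
    pd.DataFrame(rows, columns=["kinase", "pattern", "source_feature"]).to_csv(
        path, sep="\t", index=False)


# --- config -----------------------------------------------------------------

def load_config(path=None, overrides: Mapping | None = None) -> dict:
    """Merge DEFAULT_CONFIG <- YAML file <- explicit overrides."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        unknown = set(loaded) - set(DEFAULT_CONFIG)
        if unknown:
            raise InputError(f"unknown config keys {sorted(unknown)}")
        cfg.update(loaded)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg
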