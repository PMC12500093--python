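"""Mapping rhythmically modified proteins onto protein-complex membership.

Complexes follow CORUM semantics: a protein may belong to several
complexes and then appears in each one's summary (no deduplication).
Membership is reported, not enrichment; a hypergeometric enrichment option
is a documented extension left off by default.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import ComplexRecord, InputError, TimeCourseTable

log = logging.getLogger("ptmrhythm")


def map_to_complexes(rhythmic_accessions: Iterable[str],
                     complexes: Sequence[ComplexRecord],
                     phases: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Summarize every complex with at least one rhythmic member.

    Ordered by descending rhythmic-member count, then complex_id.  When
    ``phases`` is given, per-member peak phases are listed alongside.
    """
    rhythmic = set(rhythmic_accessions)
    rows = []
    for c in complexes:
        members = sorted(c.members & rhythmic)
        if not members:
            continue
        row = {
            "complex_id": c.complex_id, "complex_name": c.complex_name,
            "n_members": len(c.members), "n_rhythmic_members": len(members),
            "rhythmic_members": ";".join(members),
            "function_label": c.function_label,
        }
        if phases is not None:
            row["member_phases"] = ";".join(
                f"{phases[m]:g}" if m in phases else "" for m in members)
        rows.append(row)
    cols = ["complex_id", "complex_name", "n_members", "n_rhythmic_members",
            "rhythmic_members", "function_label"]
    if phases is not None:
        cols.append("member_phases")
    out = pd.DataFrame(rows, columns=cols)
    out = out.sort_values(["n_rhythmic_members", "complex_id"],
                          ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    log.info("map_to_complexes: %d complexes with rhythmic members", len(out))
    return out


def complex_mean_profile(table: TimeCourseTable,
                         members: Iterable[str]) -> tuple[pd.Series, pd.DataFrame]:
    """Missing-aware per-timepoint average across complex members.

    Returns (mean profile indexed by timepoint, per-member per-timepoint
    trace matrix).  Each member trace is itself the mean over replicates.
    """
    present = [m for m in members if m in table.data.index]
    if not present:
        raise InputError("no complex member has data")
    traces = (table.data.loc[present]
              .T.groupby(level="timepoint").mean().T)  # members x timepoints
    mean_profile = traces.mean(axis=0, skipna=True)
    mean_profile.name = "mean"
    return mean_profile, traces
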