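"""The three normalization rules used by the pipeline.

1. Channel-sum normalization (TMT): every channel is rescaled so its summed
   abundance equals the mean of the original channel sums, removing
   per-channel loading differences.
2. PTM-to-protein normalization: each PTM feature is divided, cell-wise per
   sample, by its master protein's abundance when the protein was
   quantified; otherwise the values pass through unchanged and the feature
   is flagged not-normalized.  This removes protein-level rhythm so that a
   PTM-level rhythm reflects modification stoichiometry.
3. Input-amount normalization (label-free): counts divided by the protein
   mass that went into each capture.

Missingness is preserved throughout; a zero or missing protein denominator
makes the cell missing (never infinite) and is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .types import InputError, TimeCourseTable, sample_label

log = logging.getLogger("ptmrhythm")


@dataclass
class NormalizationReport:
    channel_factors: pd.Series | None = None
    feature_normalized: pd.Series | None = None
    n_zero_denominator_cells: int = 0
    notes: list[str] = field(default_factory=list)


def channel_sum_normalize(table: TimeCourseTable) -> tuple[TimeCourseTable, NormalizationReport]:
    """Scale each sample channel so all column sums equal the mean sum."""
    data = table.data
    if data.isna().all(axis=0).any():
        col = data.columns[data.isna().all(axis=0).argmax()]
        raise InputError(f"channel {sample_label(*col)} is all-missing")
    sums = data.sum(axis=0, skipna=True)
    if (sums == 0).any():
        col = sums.index[(sums == 0).argmax()]
        raise InputError(f"channel {sample_label(*col)} has zero summed abundance")
    factors = sums.mean() / sums
    out = table.with_data(data.mul(factors, axis=1))
    report = NormalizationReport(channel_factors=factors)
    log.info("channel_sum_normalize: %d channels, factors in [%.4g, %.4g]",
             len(factors), factors.min(), factors.max())
    return out, report


def apply_channel_factors(table: TimeCourseTable,
                          factors: pd.Series) -> TimeCourseTable:
    """Rescale a table with channel factors derived from another run.

    TMT channel factors are computed on the deep proteome run (whose sums
    are dominated by unmodified peptides and therefore stable) and then
    applied unchanged to the PTM-level tables from the same channels;
    deriving factors from a small PTM table itself would let strong shared
    rhythms leak inverted rhythms into flat features (composition bias).
    """
    missing = [c for c in table.data.columns if c not in factors.index]
    if missing:
        raise InputError(f"no channel factor for sample {sample_label(*missing[0])}")
    return table.with_data(table.data.mul(factors, axis=1))


def normalize_to_protein(ptm: TimeCourseTable, proteome: TimeCourseTable,
                         link: Mapping[str, str]) -> tuple[TimeCourseTable, NormalizationReport]:
    """Divide each PTM feature cell-wise by its master protein's abundance.

    ``link`` maps PTM feature_id -> protein accession (the proteome table's
    feature_id).  Features whose accession is absent from the proteome pass
    through unchanged with flag False.  Zero/missing denominators produce
    missing cells.
    """
    if list(ptm.data.columns) != list(proteome.data.columns):
        raise InputError("PTM and proteome tables must share the same samples")
    out = ptm.data.copy()
    flags = pd.Series(False, index=ptm.data.index, dtype=bool)
    n_zero = 0
    for fid in ptm.data.index:
        acc = link.get(str(fid))
        if acc is None or acc not in proteome.data.index:
            continue
        denom = proteome.data.loc[acc].to_numpy(dtype=float)
        bad = ~np.isfinite(denom) | (denom == 0)
        vals = ptm.data.loc[fid].to_numpy(dtype=float)
        res = np.where(bad, np.nan, vals / np.where(bad, 1.0, denom))
        n_zero += int((bad & np.isfinite(vals)).sum())
        out.loc[fid] = res
        flags.loc[fid] = True
    report = NormalizationReport(feature_normalized=flags,
                                 n_zero_denominator_cells=n_zero)
    if n_zero:
        report.notes.append(f"{n_zero} cells dropped (zero/missing protein denominator)")
        log.warning("normalize_to_protein: %d zero/missing-denominator cells", n_zero)
    log.info("normalize_to_protein: %d/%d features normalized",
             int(flags.sum()), len(flags))
    return ptm.with_data(out), report


def input_amount_normalize(counts: TimeCourseTable,
                           input_amounts: Mapping | pd.Series) -> TimeCourseTable:
    """Divide each sample column by the protein amount loaded for it.

    ``input_amounts`` is keyed by sample label ('ZT3_r1') or by
    (timepoint, replicate) tuple; every sample must have a positive amount.
    """
    amounts = []
    for col in counts.data.columns:
        key_tuple = (float(col[0]), int(col[1]))
        label = sample_label(*col)
        if isinstance(input_amounts, pd.Series):
            pool = input_amounts.to_dict()
        else:
            pool = dict(input_amounts)
        val = pool.get(label, pool.get(key_tuple))
        if val is None:
            raise InputError(f"missing input amount for sample {label}")
        val = float(val)
        if not val > 0:
            raise InputError(f"input amount for sample {label} must be > 0")
        amounts.append(val)
    out = counts.data.div(pd.Series(amounts, index=counts.data.columns), axis=1)
    return counts.with_data(out)
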