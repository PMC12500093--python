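"""Glycosylation-phosphorylation (G-P) crosstalk inference.

Candidate crosstalk is assembled from four independent lines of evidence:

* circular phase relations between rhythmic O-GlcNAcylation and rhythmic
  phosphorylation on the same protein (phase-locked: |delta| <= 2 h;
  phase-shifted: |delta| >= 8 h, both inclusive);
* residue proximity of O-GlcNAc sites and phosphosites on the primary
  sequence (within 10 amino acids, inclusive; distance 0 = same-site
  competition);
* interplay-motif occurrences covering both acceptor positions;
* phase-matched rhythmic kinases whose recognition motif matches the
  phosphosite's flanking sequence.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import InputError, KinaseMotifEntry, MotifPattern, SiteRecord

log = logging.getLogger("ptmrhythm")


def phase_difference(phi_a: float, phi_b: float, period: float = 24.0) -> float:
    """Circular phase difference in hours, folded to [0, period/2]."""
    if not (0.0 <= phi_a < period and 0.0 <= phi_b < period):
        raise InputError("phases must lie in [0, period)")
    d = abs(phi_a - phi_b)
    return min(d, period - d)


def classify_phase_relation(delta_h: float, lock_h: float = 2.0,
                            shift_h: float = 8.0) -> str:
    """phase-locked (<= lock_h), phase-shifted (>= shift_h), else intermediate.

    Both boundaries are inclusive.
    """
    if not 0.0 <= delta_h <= 12.0:
        raise InputError(f"delta_h {delta_h} outside [0, 12]")
    if delta_h <= lock_h:
        return "phase-locked"
    if delta_h >= shift_h:
        return "phase-shifted"
    return "intermediate"


def proximal_pairs(glyco: Sequence[SiteRecord], phospho: Sequence[SiteRecord],
                   window_aa: int = 10,
                   sequences: Mapping[str, str] | None = None) -> pd.DataFrame:
    """All same-accession glyco/phospho site pairs within ``window_aa``.

    Distance is |position difference| in residues on the primary sequence,
    inclusive at the window; distance 0 marks same-site competition.
    Output is sorted by (accession, glyco position, phospho position) and
    is invariant to input ordering.
    """
    if sequences is not None:
        for s in list(glyco) + list(phospho):
            s.validate_against(dict(sequences))
    by_acc: dict[str, list[SiteRecord]] = {}
    for s in phospho:
        by_acc.setdefault(s.accession, []).append(s)
    rows = []
    for g in glyco:
        for p in by_acc.get(g.accession, ()):
            dist = abs(g.position - p.position)
            if dist <= window_aa:
                rows.append({
                    "accession": g.accession,
                    "glyco_feature": g.feature_id, "glyco_position": g.position,
                    "glyco_residue": g.residue,
                    "phospho_feature": p.feature_id,
                    "phospho_position": p.position, "phospho_residue": p.residue,
                    "distance_aa": dist,
                    "same_site": dist == 0,
                })
    cols = ["accession", "glyco_feature", "glyco_position", "glyco_residue",
            "phospho_feature", "phospho_position", "phospho_residue",
            "distance_aa", "same_site"]
    out = pd.DataFrame(rows, columns=cols)
    out = out.sort_values(["accession", "glyco_position", "phospho_position",
                           "glyco_feature", "phospho_feature"],
                          kind="mergesort").reset_index(drop=True)
    log.info("proximal_pairs: %d pairs within %d aa", len(out), window_aa)
    return out


def scan_interplay_motifs(sequences: Mapping[str, str],
                          motifs: Iterable[MotifPattern],
                          sites: Sequence[SiteRecord] = ()) -> pd.DataFrame:
    """Scan every sequence for interplay motifs and their acceptor positions.

    Reports one row per (sequence, motif, match start) with the implied
    phospho and glyco acceptor positions; acceptors coinciding with an
    observed SiteRecord of the matching PTM kind are flagged observed.
    """
    observed = {(s.accession, s.position, s.ptm) for s in sites}
    rows = []
    for acc in sorted(sequences):
        seq = sequences[acc]
        for mi, motif in enumerate(motifs):
            for start in motif.matches(seq):
                ppos = start + motif.phospho_offset
                gpos = start + motif.glyco_offset
                rows.append({
                    "accession": acc, "pattern": motif.pattern, "mode": motif.mode,
                    "match_start": start,
                    "phospho_position": ppos, "glyco_position": gpos,
                    "phospho_observed": (acc, ppos, "phospho") in observed,
                    "glyco_observed": (acc, gpos, "O-GlcNAc") in observed,
                })
    cols = ["accession", "pattern", "mode", "match_start", "phospho_position",
            "glyco_position", "phospho_observed", "glyco_observed"]
    out = pd.DataFrame(rows, columns=cols)
    log.info("scan_interplay_motifs: %d matches over %d sequences",
             len(out), len(sequences))
    return out


def rhythmic_both(glyco_results: pd.DataFrame, phospho_results: pd.DataFrame,
                  phospho_accessions: Mapping[str, str],
                  q_cutoff: float = 0.2, lock_h: float = 2.0,
                  shift_h: float = 8.0) -> tuple[set[str], pd.DataFrame]:
    """Proteins rhythmic in both PTMs, with per-phosphopeptide phase relations.

    ``glyco_results`` carries protein-level rhythm calls (feature_id =
    accession); ``phospho_results`` carries site-level calls whose
    accessions come from ``phospho_accessions``.  Phase relations pair the
    protein-level O-GlcNAc phase against each rhythmic phosphopeptide's
    phase.
    """
    g = glyco_results[glyco_results["q"] < q_cutoff].set_index("feature_id")
    p = phospho_results[phospho_results["q"] < q_cutoff]
    rows = []
    accs: set[str] = set()
    for row in p.itertuples():
        acc = phospho_accessions.get(str(row.feature_id))
        if acc is None or acc not in g.index:
            continue
        accs.add(acc)
        delta = phase_difference(float(g.loc[acc, "phase"]), float(row.phase))
        rows.append({
            "accession": acc, "phospho_feature": row.feature_id,
            "glyco_phase": float(g.loc[acc, "phase"]),
            "phospho_phase": float(row.phase),
            "delta_h": delta,
            "relation": classify_phase_relation(delta, lock_h, shift_h),
        })
    cols = ["accession", "phospho_feature", "glyco_phase", "phospho_phase",
            "delta_h", "relation"]
    out = pd.DataFrame(rows, columns=cols).sort_values(
        ["accession", "phospho_feature"], kind="mergesort").reset_index(drop=True)
    log.info("rhythmic_both: %d proteins, %d phosphopeptide pairs",
             len(accs), len(out))
    return accs, out


def extract_flank(site: SiteRecord, sequences: Mapping[str, str],
                  half_window: int = 7) -> str:
    """(2*half_window+1)-mer centered on the acceptor, '-'-padded at termini."""
    site.validate_against(dict(sequences))
    seq = sequences[site.accession]
    i = site.position - 1
    lo, hi = i - half_window, i + half_window + 1
    left = "-" * max(0, -lo)
    right = "-" * max(0, hi - len(seq))
    return left + seq[max(0, lo):min(len(seq), hi)] + right


def phase_matched_kinases(flanks: Iterable[str],
                          kinase_motifs: Sequence[KinaseMotifEntry],
                          kinase_rhythms: pd.DataFrame,
                          substrate_phase: float, window_h: float = 4.0,
                          q_cutoff: float = 0.2,
                          period: float = 24.0) -> list[str]:
    """Kinases passing all three filters: motif match on >= 1 substrate
    flank, significant own rhythm (q < cutoff), and circular phase within
    ``window_h`` of the substrate phase."""
    kr = kinase_rhythms.set_index("feature_id")
    flanks = list(flanks)
    selected = []
    for entry in kinase_motifs:
        if not any(entry.matches_flank(f) for f in flanks):
            continue
        key = entry.source_feature or entry.kinase
        if key not in kr.index:
            continue
        if not float(kr.loc[key, "q"]) < q_cutoff:
            continue
        delta = phase_difference(float(kr.loc[key, "phase"]) % period,
                                 substrate_phase % period, period)
        if delta <= window_h:
            selected.append(entry.kinase)
    return sorted(set(selected))
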