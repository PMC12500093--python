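"""Orchestration of the two study workflows.

``run_nrf`` chains the night-restricted-feeding characterization:
identification (labeled vs no-enzyme control) -> normalization -> rhythm
detection at q < 0.2 -> G-P crosstalk (phase relations, proximity pairs,
motif scan, kinase intersection) -> protein-complex mapping.

``run_regimes`` chains the feeding-regime comparison: day-night
differential calls per regime -> inverted/dampened/unaltered/emergent/
absent classification -> global median comparison.

Every run writes a ``manifest.json`` snapshot of the config, seed, and
per-stage feature counts so any reported number can be reproduced.
"""

from __future__ import annotations

import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import complexes as cx
from . import crosstalk as ct
from . import diffsites as ds
from . import identify as idf
from . import io as pio
from . import normalize as nm
from . import rhythm as rh
from .types import InputError, SiteRecord

log = logging.getLogger("ptmrhythm")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except InputError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _write_manifest(out_dir: Path, config: dict, counts: dict) -> None:
    manifest = {
        "software": f"ptmrhythm {__version__}",
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in config.items()},
        "seed": config.get("seed"),
        "stage_counts": counts,
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _load_nrf_inputs(in_dir: Path) -> dict:
    seqs = pio.read_fasta(in_dir / "sequences.fasta")
    inputs = {
        "labeled": pio.read_timecourse(in_dir / "labeled.tsv", "labeled"),
        "unlabeled": pio.read_timecourse(in_dir / "unlabeled.tsv", "unlabeled"),
        "proteome": pio.read_timecourse(in_dir / "proteome.tsv", "proteome"),
        "phospho": pio.read_timecourse(in_dir / "phospho.tsv", "phospho"),
        "glyco_sites": pio.read_timecourse(in_dir / "glyco_sites.tsv",
                                           "glyco_site"),
        "sequences": seqs,
        "sites": pio.read_sites(in_dir / "sites.tsv", seqs),
    }
    for key, fname, reader in (
            ("complexes", "complexes.tsv", pio.read_complex_table),
            ("motifs", "motifs.tsv", pio.read_motifs),
            ("kinase_motifs", "kinase_motifs.tsv", pio.read_kinase_motifs)):
        path = in_dir / fname
        inputs[key] = reader(path) if path.exists() else []
    amounts = in_dir / "input_amounts.tsv"
    if amounts.exists():
        df = pd.read_csv(amounts, sep="\t")
        inputs["input_amounts"] = dict(zip(df["sample"], df["amount"]))
    else:
        inputs["input_amounts"] = None
    return inputs


def run_nrf(in_dir, out_dir, config: dict) -> dict:
    """Run the full NRF characterization; returns the result bundle."""
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = _load_nrf_inputs(in_dir)
    seed = int(config["seed"])
    n_perm = int(config["permutations"])
    method = config["rhythm_method"]
    primary = "jtk" if method == "both" else method
    q_cut = float(config["q_cutoff"])
    counts: dict = {}

    # 1. identification ------------------------------------------------------
    ident = _stage("identify")(idf.call_oglcnac)(
        inputs["labeled"], inputs["unlabeled"], alpha=float(config["alpha"]),
        min_replicates=int(config["min_replicates"]))
    called = ident.loc[ident["called"], "feature_id"].astype(str).tolist()
    counts["identified_oglcnac"] = len(called)

    # 2. normalization -------------------------------------------------------
    labeled = inputs["labeled"].subset(called)
    if inputs["input_amounts"] is not None:
        labeled = nm.input_amount_normalize(labeled, inputs["input_amounts"])
    # channel factors come from the proteome run and are re-applied to the
    # PTM tables from the same channels
    proteome_norm, prot_report = _stage("normalize")(nm.channel_sum_normalize)(
        inputs["proteome"])
    factors = prot_report.channel_factors
    glyco_prot, _ = nm.normalize_to_protein(
        labeled, proteome_norm, {f: f for f in labeled.feature_ids})
    phospho_cs = nm.apply_channel_factors(inputs["phospho"], factors)
    site_acc = {s.feature_id: s.accession for s in inputs["sites"]}
    phospho_norm, _ = nm.normalize_to_protein(phospho_cs, proteome_norm, site_acc)
    glyco_sites_cs = nm.apply_channel_factors(inputs["glyco_sites"], factors)
    glyco_sites_norm, _ = nm.normalize_to_protein(glyco_sites_cs, proteome_norm,
                                                  site_acc)

    # 3. rhythm detection ----------------------------------------------------
    scan = _stage("rhythm")(rh.rhythm_scan)
    glyco_prot_rhy = scan(glyco_prot, method=method, n_perm=n_perm, seed=seed)
    phospho_rhy = scan(phospho_norm, method=method, n_perm=n_perm, seed=seed + 1)
    glyco_site_rhy = scan(glyco_sites_norm, method=method, n_perm=n_perm,
                          seed=seed + 2)
    gp = glyco_prot_rhy[glyco_prot_rhy["method"] == primary]
    pp = phospho_rhy[phospho_rhy["method"] == primary]
    gs = glyco_site_rhy[glyco_site_rhy["method"] == primary]
    counts["rhythmic_glyco_proteins"] = len(rh.gate_rhythmic(gp, q_cut))
    counts["rhythmic_phospho_sites"] = len(rh.gate_rhythmic(pp, q_cut))
    counts["rhythmic_glyco_sites"] = len(rh.gate_rhythmic(gs, q_cut))

    # 4. crosstalk -----------------------------------------------------------
    both_accs, both_pairs = _stage("crosstalk")(ct.rhythmic_both)(
        gp, pp, site_acc, q_cutoff=q_cut,
        lock_h=float(config["phase_lock_h"]),
        shift_h=float(config["phase_shift_h"]))
    counts["both_rhythmic_proteins"] = len(both_accs)

    glyco_site_recs = [s for s in inputs["sites"] if s.ptm == "O-GlcNAc"]
    phospho_site_recs = [s for s in inputs["sites"] if s.ptm == "phospho"]
    pairs = ct.proximal_pairs(glyco_site_recs, phospho_site_recs,
                              window_aa=int(config["proximity_aa"]),
                              sequences=inputs["sequences"])
    gated_g = set(rh.gate_rhythmic(gs, q_cut))
    gated_p = set(rh.gate_rhythmic(pp, q_cut))
    gphase = gs.set_index("feature_id")["phase"]
    pphase = pp.set_index("feature_id")["phase"]
    pairs["glyco_rhythmic"] = pairs["glyco_feature"].isin(gated_g)
    pairs["phospho_rhythmic"] = pairs["phospho_feature"].isin(gated_p)
    pairs["both_rhythmic"] = pairs["glyco_rhythmic"] & pairs["phospho_rhythmic"]
    delta, relation = [], []
    for row in pairs.itertuples():
        if row.both_rhythmic:
            d = ct.phase_difference(float(gphase[row.glyco_feature]),
                                    float(pphase[row.phospho_feature]))
            delta.append(d)
            relation.append(ct.classify_phase_relation(
                d, float(config["phase_lock_h"]), float(config["phase_shift_h"])))
        else:
            delta.append(float("nan"))
            relation.append("")
    pairs["delta_h"] = delta
    pairs["relation"] = relation
    counts["proximal_pairs"] = len(pairs)
    counts["proximal_pairs_both_rhythmic"] = int(pairs["both_rhythmic"].sum())

    motif_hits = ct.scan_interplay_motifs(inputs["sequences"], inputs["motifs"],
                                          inputs["sites"])
    counts["motif_hits"] = len(motif_hits)

    # kinase intersection: per rhythmic phosphosite, phase-matched motif kinases
    kin_entries = inputs["kinase_motifs"]
    kin_ids = sorted({e.source_feature or e.kinase for e in kin_entries})
    kin_rows = []
    if kin_entries and set(kin_ids) <= set(map(str, proteome_norm.feature_ids)):
        kin_rhy = scan(proteome_norm.subset(kin_ids), method=primary,
                       n_perm=n_perm, seed=seed + 3)
        site_by_feature = {s.feature_id: s for s in phospho_site_recs}
        for fid in sorted(gated_p):
            site = site_by_feature.get(fid)
            if site is None:
                continue
            flank = ct.extract_flank(site, inputs["sequences"])
            kinases = ct.phase_matched_kinases(
                [flank], kin_entries, kin_rhy,
                substrate_phase=float(pphase[fid]),
                window_h=float(config["kinase_phase_window_h"]),
                q_cutoff=q_cut)
            kin_rows.append({"phospho_feature": fid, "accession": site.accession,
                             "position": site.position, "flank": flank,
                             "kinases": ";".join(kinases)})
    kinase_report = pd.DataFrame(
        kin_rows, columns=["phospho_feature", "accession", "position", "flank",
                           "kinases"])

    # 5. complexes -----------------------------------------------------------
    rhythmic_accs = set(rh.gate_rhythmic(gp, q_cut)) | {
        site_acc[f] for f in gated_p if f in site_acc}
    complex_summary = _stage("complexes")(cx.map_to_complexes)(
        rhythmic_accs, inputs["complexes"],
        phases=gp.set_index("feature_id")["phase"].to_dict())
    counts["complexes_with_rhythmic_members"] = len(complex_summary)

    results = {
        "identification": ident, "glyco_protein_rhythms": glyco_prot_rhy,
        "phospho_rhythms": phospho_rhy, "glyco_site_rhythms": glyco_site_rhy,
        "both_rhythmic_pairs": both_pairs, "proximal_pairs": pairs,
        "motif_hits": motif_hits, "kinase_report": kinase_report,
        "complex_summary": complex_summary,
    }
    for name, df in results.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False,
                  float_format="%.10g")
    _write_manifest(out_dir, config, counts)
    log.info("run_nrf complete: %s", counts)
    results["counts"] = counts
    return results


def run_regimes(in_dir, out_dir, config: dict) -> dict:
    """Run the NRF-vs-DRF feeding-regime comparison."""
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nrf = pio.read_timecourse(in_dir / "nrf_sites.tsv", "glyco_site", "NRF")
    drf = pio.read_timecourse(in_dir / "drf_sites.tsv", "glyco_site", "DRF")
    if set(nrf.feature_ids) != set(drf.feature_ids):
        offenders = sorted(set(map(str, nrf.feature_ids))
                           ^ set(map(str, drf.feature_ids)))
        raise InputError(f"mismatched NRF/DRF feature universes: {offenders[:10]}")

    kwargs = dict(day=float(config["day_timepoint"]),
                  night=float(config["night_timepoint"]),
                  fold_threshold_pct=float(config["fold_change_pct"]),
                  p_gate=config["p_gate_daynight"])
    nrf_res = _stage("diffsites")(ds.daynight_test)(nrf, **kwargs)
    drf_res = ds.daynight_test(drf, **kwargs)
    classified = ds.classify_regimes(nrf_res, drf_res)

    nrf_diff = set(nrf_res.loc[nrf_res["differential"], "feature_id"])
    drf_diff = set(drf_res.loc[drf_res["differential"], "feature_id"])
    med_nrf, med_drf, med_p = ds.compare_regime_medians(
        nrf.data.mean(axis=0, skipna=True).to_numpy(),
        drf.data.mean(axis=0, skipna=True).to_numpy())
    summary = {
        "n_sites": len(classified),
        "nrf_differential": len(nrf_diff),
        "drf_differential": len(drf_diff),
        "venn_nrf_only": len(nrf_diff - drf_diff),
        "venn_shared": len(nrf_diff & drf_diff),
        "venn_drf_only": len(drf_diff - nrf_diff),
        **{f"class_{k}": int((classified["klass"] == k).sum())
           for k in ds.REGIME_CLASSES},
        "median_nrf": med_nrf, "median_drf": med_drf, "median_t_p": med_p,
    }
    classified.to_csv(out_dir / "regime_sites.tsv", sep="\t", index=False,
                      float_format="%.10g")
    pd.DataFrame([summary]).to_csv(out_dir / "regime_summary.tsv", sep="\t",
                                   index=False, float_format="%.10g")
    _write_manifest(out_dir, config, summary)
    log.info("run_regimes complete: %s", summary)
    return {"sites": classified, "summary": summary,
            "nrf": nrf_res, "drf": drf_res}
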