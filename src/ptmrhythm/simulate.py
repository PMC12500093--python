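"""Synthetic time-course PTM proteomics with known ground truth.

The generator emulates the study design the pipeline targets: liver
nuclear samples collected every 4 h over one 24-h day-night cycle (ZT3,
ZT7, ..., ZT23; n = 3 replicates), a two-timepoint (ZT11/ZT23, n = 4)
site-specific design under two feeding regimes, labeled-vs-unlabeled
capture pairs, and a site universe with planted G-P crosstalk pairs and
interplay motifs.

The signal model is a relative-amplitude cosine with multiplicative
lognormal noise:

    value = B * (1 + a * cos(2*pi*(t - phi)/24)) * exp(eps),
    eps ~ Normal(0, noise_sd^2)

with B lognormal across features, a in (0, 1] (a = 0 for arrhythmic
features, so the mean never goes negative) and phi the peak phase in ZT
hours.  No generative model for these data exists in the literature the
pipeline implements; this cosine-plus-lognormal form is an explicit
stand-in chosen so every downstream stage has a computable truth.

One global seed spawns per-operation substreams keyed by a stable hash of
the operation name, so adding a stage never perturbs another stage's draws.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .types import (
    ComplexRecord,
    InputError,
    KinaseMotifEntry,
    MotifPattern,
    SiteRecord,
    TimeCourseTable,
)

log = logging.getLogger("ptmrhythm")

DEFAULT_TIMEPOINTS = (3.0, 7.0, 11.0, 15.0, 19.0, 23.0)
PERIOD = 24.0


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-operation RNG substream (stable across platforms)."""
    h = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little")
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, h])


@dataclass
class SimParams:
    """Study-design and noise parameters for all generators."""

    n_features: int = 200
    frac_rhythmic: float = 0.3
    timepoints: tuple = DEFAULT_TIMEPOINTS
    replicates: int = 3
    baseline_log_mean: float = 7.0
    baseline_log_sd: float = 1.0
    rel_amplitude_range: tuple = (0.3, 0.8)
    noise_sd: float = 0.2
    phase_distribution: tuple | str = "uniform"  # or ("concentrated", mu, sd)
    count_mode: str = "continuous"  # "continuous" | "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_rhythmic <= 1.0:
            raise InputError("frac_rhythmic must lie in [0, 1]")
        lo, hi = self.rel_amplitude_range
        if not (0.0 < lo <= hi <= 1.0):
            raise InputError("rel_amplitude_range must satisfy 0 < lo <= hi <= 1")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        for t in self.timepoints:
            if not 0.0 <= float(t) < 24.0:
                raise InputError(f"timepoint {t} outside [0, 24)")
        if self.count_mode not in ("continuous", "poisson"):
            raise InputError(f"unknown count_mode {self.count_mode!r}")


def _draw_phases(params: SimParams, n: int, rng) -> np.ndarray:
    spec = params.phase_distribution
    if spec == "uniform":
        return rng.uniform(0.0, PERIOD, size=n)
    if isinstance(spec, (tuple, list)) and spec[0] == "concentrated":
        _, mu, sd = spec
        return np.mod(rng.normal(mu, sd, size=n), PERIOD)
    raise InputError(f"unknown phase_distribution {spec!r}")


def _feature_truth(params: SimParams, rng, prefix: str = "F") -> pd.DataFrame:
    n = params.n_features
    n_rhythmic = int(round(params.frac_rhythmic * n))
    rhythmic = np.zeros(n, dtype=bool)
    rhythmic[:n_rhythmic] = True
    rng.shuffle(rhythmic)
    lo, hi = params.rel_amplitude_range
    amplitude = np.where(rhythmic, rng.uniform(lo, hi, size=n), 0.0)
    return pd.DataFrame({
        "feature_id": [f"{prefix}{i + 1:04d}" for i in range(n)],
        "rhythmic": rhythmic,
        "baseline": rng.lognormal(params.baseline_log_mean,
                                  params.baseline_log_sd, size=n),
        "rel_amplitude": amplitude,
        "phase": _draw_phases(params, n, rng),
        "noise_sd": params.noise_sd,
    })


def cosine_mean(baseline, amplitude, phase, t) -> np.ndarray:
    """Deterministic mean of the signal model at ZT hour(s) t."""
    return np.asarray(baseline) * (
        1.0 + np.asarray(amplitude) * np.cos(
            2.0 * np.pi * (np.asarray(t) - np.asarray(phase)) / PERIOD)
    )


def _sample_values(truth: pd.DataFrame, params: SimParams, rng,
                   scale: np.ndarray | float = 1.0) -> pd.DataFrame:
    cols = pd.MultiIndex.from_tuples(
        [(float(t), r) for t in params.timepoints
         for r in range(1, params.replicates + 1)],
        names=["timepoint", "replicate"])
    tvec = np.array([c[0] for c in cols])
    mean = cosine_mean(truth["baseline"].to_numpy()[:, None],
                       truth["rel_amplitude"].to_numpy()[:, None],
                       truth["phase"].to_numpy()[:, None], tvec[None, :])
    mean = mean * np.broadcast_to(np.asarray(scale, dtype=float).reshape(-1, 1)
                                  if np.ndim(scale) else scale, mean.shape)
    if params.noise_sd > 0:
        mean = mean * np.exp(rng.normal(0.0, params.noise_sd, size=mean.shape))
    if params.count_mode == "poisson":
        mean = rng.poisson(mean).astype(float)
    return pd.DataFrame(mean, index=pd.Index(truth["feature_id"], name="feature_id"),
                        columns=cols)


def simulate_timecourse(params: SimParams, condition: str = "labeled",
                        stream: str = "timecourse") -> tuple[TimeCourseTable, pd.DataFrame]:
    """One feature x (timepoint, replicate) table plus its planted truth."""
    rng = substream(params.seed, stream)
    truth = _feature_truth(params, rng)
    data = _sample_values(truth, params, rng)
    return TimeCourseTable(data, condition=condition), truth


def simulate_capture_pair(params: SimParams, capture_efficiency: float = 0.8,
                          background_rate: float = 0.05,
                          true_fraction: float = 0.5
                          ) -> tuple[TimeCourseTable, TimeCourseTable, pd.DataFrame]:
    """Labeled + no-enzyme control tables for the identification stage.

    True O-GlcNAc features appear in the labeled capture at
    ``capture_efficiency`` x signal and in the control at
    ``background_rate`` x signal; decoy (non-O-GlcNAc) features sit at
    background level in both.  Setting the two rates equal makes the two
    tables exchangeable (the identification null).
    """
    if not (0.0 <= background_rate <= capture_efficiency <= 1.0):
        raise InputError("need 0 <= background_rate <= capture_efficiency <= 1")
    rng = substream(params.seed, "capture_pair")
    truth = _feature_truth(params, rng)
    n = len(truth)
    is_target = np.zeros(n, dtype=bool)
    is_target[: int(round(true_fraction * n))] = True
    rng.shuffle(is_target)
    truth["is_oglcnac"] = is_target
    labeled_scale = np.where(is_target, capture_efficiency, background_rate)
    unlabeled_scale = np.full(n, background_rate)
    labeled = _sample_values(truth, params, rng, scale=labeled_scale)
    unlabeled = _sample_values(truth, params, rng, scale=unlabeled_scale)
    return (TimeCourseTable(labeled, condition="labeled"),
            TimeCourseTable(unlabeled, condition="unlabeled"), truth)


# --- site universe ----------------------------------------------------------

@dataclass
class CrosstalkSpec:
    """How many G-P crosstalk pairs to plant and with what geometry.

    Planted phases sit on the sampling grid: locked pairs share a peak
    phase (delta = 0 <= 2 h) and shifted pairs are offset by 8 or 12 h
    (>= 8 h), so the planted class is recoverable from grid-valued phase
    estimates.
    """

    n_locked: int = 10
    n_shifted: int = 10
    distance_range: tuple = (1, 10)
    shifted_offsets: tuple = (8.0, 12.0)

    @property
    def n_pairs(self) -> int:
        return self.n_locked + self.n_shifted


#: three interplay-motif archetypes: same-site competition at a Pro-directed
#: acceptor, proximal S/T pair, and same-site within a PV context
DEFAULT_MOTIFS = (
    MotifPattern("[ST]P", 0, 0, "same-site"),
    MotifPattern("[ST].{2}[ST]", 3, 0, "proximal"),
    MotifPattern("PV[ST]", 2, 2, "same-site"),
)

SEQ_LENGTH = 120
_MOTIF_PLANT_START = 95  # clear of all planted site positions


def _instantiate(motif: MotifPattern, rng) -> str:
    from .types import ACCEPTOR_RESIDUES, AMINO_ACIDS
    out = []
    for k, slot in enumerate(motif.slots):
        if k in (motif.phospho_offset, motif.glyco_offset):
            pool = sorted((slot or set(AMINO_ACIDS)) & ACCEPTOR_RESIDUES)
        else:
            pool = sorted(slot) if slot is not None else list(AMINO_ACIDS)
        out.append(pool[int(rng.integers(len(pool)))])
    return "".join(out)


def simulate_site_universe(n_proteins: int = 40, sites_per_protein: int = 2,
                           crosstalk: CrosstalkSpec | None = None,
                           motifs=DEFAULT_MOTIFS,
                           params: SimParams | None = None):
    """Random proteins with planted crosstalk pairs and interplay motifs.

    Returns ``(sequences, sites, glyco_table, phospho_table, truth)`` where
    ``truth`` is a dict with ``sites`` (per-site planted parameters),
    ``pairs`` (planted crosstalk pairs), and ``motifs`` (planted motif
    occurrences).  Crosstalk pairs live on dedicated proteins with both
    sites rhythmic; background proteins carry a glyco/phospho site pair at
    proximal distance but never rhythmic on both sides, so a recovered
    pair is planted truth, not coincidence.
    """
    from .types import AMINO_ACIDS

    params = params or SimParams()
    crosstalk = crosstalk or CrosstalkSpec()
    if crosstalk.n_pairs > n_proteins:
        raise InputError("more crosstalk pairs than proteins")
    if sites_per_protein < 2:
        raise InputError("need >= 2 sites per protein to form pairs")
    rng = substream(params.seed, "site_universe")
    grid = np.asarray(params.timepoints, dtype=float)
    lo, hi = params.rel_amplitude_range
    lo_d, hi_d = crosstalk.distance_range

    accs = [f"P{i + 1:04d}" for i in range(n_proteins)]
    site_rows = []
    pair_rows = []
    gi = fi = 0

    def _new_site(acc, pos, ptm, rhythmic, phase, pair_id=None, klass=None):
        nonlocal gi, fi
        if ptm == "O-GlcNAc":
            gi += 1
            fid = f"G{gi:04d}"
        else:
            fi += 1
            fid = f"F{fi:04d}"
        site_rows.append({
            "feature_id": fid, "accession": acc, "position": int(pos),
            "residue": "ST"[int(rng.integers(2))], "ptm": ptm,
            "rhythmic": bool(rhythmic),
            "baseline": float(rng.lognormal(params.baseline_log_mean,
                                            params.baseline_log_sd)),
            "rel_amplitude": float(rng.uniform(lo, hi)) if rhythmic else 0.0,
            "phase": float(phase),
            "pair_id": pair_id, "pair_class": klass,
        })
        return fid

    for pi in range(crosstalk.n_pairs):
        acc = accs[pi]
        klass = "phase-locked" if pi < crosstalk.n_locked else "phase-shifted"
        gpos = int(rng.integers(30, 60))
        dist = int(rng.integers(lo_d, hi_d + 1))
        gphase = float(grid[int(rng.integers(grid.size))])
        if klass == "phase-locked":
            pphase = gphase
        else:
            off = float(crosstalk.shifted_offsets[
                int(rng.integers(len(crosstalk.shifted_offsets)))])
            pphase = float(np.mod(gphase + off, PERIOD))
        pair_id = f"pair{pi + 1:03d}"
        gfid = _new_site(acc, gpos, "O-GlcNAc", True, gphase, pair_id, klass)
        pfid = _new_site(acc, gpos + dist, "phospho", True, pphase, pair_id, klass)
        pair_rows.append({"pair_id": pair_id, "accession": acc,
                          "glyco_feature": gfid, "phospho_feature": pfid,
                          "distance_aa": dist, "delta_h": min(
                              abs(pphase - gphase), PERIOD - abs(pphase - gphase)),
                          "klass": klass})

    for acc in accs[crosstalk.n_pairs:]:
        # a proximal decoy pair, arrhythmic on both sides: a single-site FDR
        # gate cannot certify pairs whose partner is a truly rhythmic site,
        # so rhythmic background sites are planted only at distant positions
        gpos = int(rng.integers(30, 60))
        dist = int(rng.integers(3, 9))
        _new_site(acc, gpos, "O-GlcNAc", False, rng.uniform(0, PERIOD))
        _new_site(acc, gpos + dist, "phospho", False, rng.uniform(0, PERIOD))
        for extra in range(sites_per_protein - 2):
            pos = 80 + 12 * extra
            ptm = ("O-GlcNAc", "phospho")[int(rng.integers(2))]
            _new_site(acc, pos, ptm, bool(rng.uniform() < params.frac_rhythmic),
                      rng.uniform(0, PERIOD))

    truth_sites = pd.DataFrame(site_rows)

    # sequences: uniform random residues, then planted sites and motifs
    sequences: dict[str, str] = {}
    aa = np.array(list(AMINO_ACIDS))
    for acc in accs:
        sequences[acc] = "".join(aa[rng.integers(0, len(aa), size=SEQ_LENGTH)])
    for row in truth_sites.itertuples():
        seq = sequences[row.accession]
        sequences[row.accession] = (seq[: row.position - 1] + row.residue
                                    + seq[row.position:])
    motif_rows = []
    for mi, motif in enumerate(motifs or ()):
        acc = accs[mi % n_proteins]
        start = _MOTIF_PLANT_START
        inst = _instantiate(motif, rng)
        seq = sequences[acc]
        sequences[acc] = seq[: start - 1] + inst + seq[start - 1 + len(inst):]
        motif_rows.append({"accession": acc, "pattern": motif.pattern,
                           "start": start,
                           "phospho_position": start + motif.phospho_offset,
                           "glyco_position": start + motif.glyco_offset})

    sites = [SiteRecord(r.accession, r.position, r.residue, r.ptm, r.feature_id)
             for r in truth_sites.itertuples()]

    def _table(ptm: str, condition: str) -> TimeCourseTable:
        sub = truth_sites[truth_sites["ptm"] == ptm].reset_index(drop=True)
        data = _sample_values(sub, params, rng)
        return TimeCourseTable(data, condition=condition)

    glyco_table = _table("O-GlcNAc", "glyco_site")
    phospho_table = _table("phospho", "phospho")
    truth = {"sites": truth_sites, "pairs": pd.DataFrame(pair_rows),
             "motifs": pd.DataFrame(motif_rows)}
    log.info("site_universe: %d proteins, %d sites, %d planted pairs",
             n_proteins, len(truth_sites), len(pair_rows))
    return sequences, sites, glyco_table, phospho_table, truth


# --- feeding-regime comparison ---------------------------------------------

REGIME_TIMEPOINTS = (11.0, 23.0)
REGIME_REPLICATES = 4


def simulate_regimes(params: SimParams, inversion_fraction: float = 0.3,
                     dampen_fraction: float = 0.3, effect_pct: float = 60.0,
                     dampened_pct: float = 5.0
                     ) -> tuple[TimeCourseTable, TimeCourseTable, pd.DataFrame]:
    """Two-timepoint (ZT11/ZT23 x 4) site tables under NRF and DRF.

    Every feature has a planted day-night difference of ``effect_pct`` in
    NRF; under DRF an ``inversion_fraction`` of features flip the sign of
    the day-night log-ratio, a ``dampen_fraction`` drop to ``dampened_pct``
    (below the 20% differential threshold), and the rest keep their NRF
    pattern.
    """
    if inversion_fraction + dampen_fraction > 1.0 + 1e-12:
        raise InputError("class fractions must sum to <= 1")
    rng = substream(params.seed, "regimes")
    n = params.n_features
    n_inv = int(round(inversion_fraction * n))
    n_damp = int(round(dampen_fraction * n))
    klass = np.array(["inverted"] * n_inv + ["dampened"] * n_damp
                     + ["unaltered"] * (n - n_inv - n_damp))
    rng.shuffle(klass)
    baseline = rng.lognormal(params.baseline_log_mean, params.baseline_log_sd, n)
    night_high = rng.uniform(size=n) < 0.5
    truth = pd.DataFrame({
        "feature_id": [f"S{i + 1:04d}" for i in range(n)],
        "klass": klass,
        "nrf_direction": np.where(night_high, "night-high", "day-high"),
        "baseline": baseline,
    })

    cols = pd.MultiIndex.from_tuples(
        [(t, r) for t in REGIME_TIMEPOINTS
         for r in range(1, REGIME_REPLICATES + 1)],
        names=["timepoint", "replicate"])

    def _regime_table(day_mean, night_mean, regime) -> TimeCourseTable:
        mean = np.column_stack([
            np.repeat(day_mean[:, None], REGIME_REPLICATES, axis=1),
            np.repeat(night_mean[:, None], REGIME_REPLICATES, axis=1)])
        if params.noise_sd > 0:
            mean = mean * np.exp(rng.normal(0.0, params.noise_sd, mean.shape))
        data = pd.DataFrame(mean, index=pd.Index(truth["feature_id"],
                                                 name="feature_id"), columns=cols)
        return TimeCourseTable(data, condition="glyco_site", regime=regime)

    e = effect_pct / 100.0
    d = dampened_pct / 100.0
    nrf_day = np.where(night_high, baseline, baseline * (1 + e))
    nrf_night = np.where(night_high, baseline * (1 + e), baseline)
    drf_day = nrf_day.copy()
    drf_night = nrf_night.copy()
    inv = klass == "inverted"
    drf_day[inv], drf_night[inv] = nrf_night[inv], nrf_day[inv]
    damp = klass == "dampened"
    drf_day[damp] = np.where(night_high[damp], baseline[damp],
                             baseline[damp] * (1 + d))
    drf_night[damp] = np.where(night_high[damp], baseline[damp] * (1 + d),
                               baseline[damp])
    nrf = _regime_table(nrf_day, nrf_night, "NRF")
    drf = _regime_table(drf_day, drf_night, "DRF")
    return nrf, drf, truth


# --- full input bundle -------------------------------------------------------

DEFAULT_KINASE_MOTIFS = (
    KinaseMotifEntry("KIN_proline", "...[ST]P..", source_feature="KIN1"),
    KinaseMotifEntry("KIN_basophilic", "R..[ST]...", source_feature="KIN2"),
    KinaseMotifEntry("KIN_acidic", "E..[ST]...", source_feature="KIN3"),
)

KINASE_PHASES = {"KIN1": 15.0, "KIN2": 3.0, "KIN3": 23.0}


def simulate_bundle(params: SimParams | None = None, n_proteins: int = 40,
                    sites_per_protein: int = 3,
                    crosstalk: CrosstalkSpec | None = None,
                    capture_efficiency: float = 0.8,
                    background_rate: float = 0.05) -> dict:
    """Generate every input the full NRF workflow consumes, with truth.

    Protein-level labeled/unlabeled capture tables are derived from the
    same site universe: a protein's O-GlcNAc signal is rhythmic when it
    carries a rhythmic glyco site (inheriting that site's phase).  The
    proteome reference is flat (arrhythmic) except for three planted
    rhythmic kinases, so protein-level normalization cannot manufacture
    PTM rhythms.
    """
    params = params or SimParams()
    crosstalk = crosstalk or CrosstalkSpec()
    sequences, sites, glyco_table, phospho_table, truth = simulate_site_universe(
        n_proteins, sites_per_protein, crosstalk, DEFAULT_MOTIFS, params)
    rng = substream(params.seed, "bundle")
    ts = truth["sites"]

    # per-protein O-GlcNAc truth from the glyco sites
    prot_rows = []
    for acc, sub in ts[ts["ptm"] == "O-GlcNAc"].groupby("accession"):
        rhythmic = bool(sub["rhythmic"].any())
        lead = sub[sub["rhythmic"]].iloc[0] if rhythmic else sub.iloc[0]
        prot_rows.append({"feature_id": acc, "rhythmic": rhythmic,
                          "baseline": float(lead["baseline"]),
                          "rel_amplitude": float(lead["rel_amplitude"]),
                          "phase": float(lead["phase"]),
                          "noise_sd": params.noise_sd, "is_oglcnac": True})
    # decoy proteins without glyco sites, at background level in both captures
    n_decoys = max(5, n_proteins // 4)
    for di in range(n_decoys):
        prot_rows.append({"feature_id": f"D{di + 1:04d}", "rhythmic": False,
                          "baseline": float(rng.lognormal(
                              params.baseline_log_mean, params.baseline_log_sd)),
                          "rel_amplitude": 0.0,
                          "phase": 0.0, "noise_sd": params.noise_sd,
                          "is_oglcnac": False})
    prot_truth = pd.DataFrame(prot_rows)
    scale_l = np.where(prot_truth["is_oglcnac"], capture_efficiency,
                       background_rate)
    scale_u = np.full(len(prot_truth), background_rate)
    labeled = TimeCourseTable(
        _sample_values(prot_truth, params, rng, scale=scale_l),
        condition="labeled")
    unlabeled = TimeCourseTable(
        _sample_values(prot_truth, params, rng, scale=scale_u),
        condition="unlabeled")

    # proteome: flat for substrates, rhythmic for the kinase panel
    proteome_rows = [{"feature_id": acc, "rhythmic": False, "baseline":
                      float(rng.lognormal(params.baseline_log_mean,
                                          params.baseline_log_sd)),
                      "rel_amplitude": 0.0, "phase": 0.0}
                     for acc in sequences]
    for kin, phase in KINASE_PHASES.items():
        proteome_rows.append({"feature_id": kin, "rhythmic": True,
                              "baseline": float(rng.lognormal(
                                  params.baseline_log_mean,
                                  params.baseline_log_sd)),
                              "rel_amplitude": 0.6, "phase": phase})
    proteome_truth = pd.DataFrame(proteome_rows)
    proteome = TimeCourseTable(
        _sample_values(proteome_truth, params, rng), condition="proteome")

    complexes = []
    pair_accs = sorted(truth["pairs"]["accession"].unique()) if len(
        truth["pairs"]) else []
    for ci in range(0, len(pair_accs) - 2, 3):
        complexes.append(ComplexRecord(
            f"C{ci // 3 + 1:03d}", f"planted complex {ci // 3 + 1}",
            frozenset(pair_accs[ci: ci + 3]), "transcriptional regulation"))

    truth["proteins"] = prot_truth
    truth["proteome"] = proteome_truth
    return {
        "labeled": labeled, "unlabeled": unlabeled, "proteome": proteome,
        "phospho": phospho_table, "glyco_sites": glyco_table,
        "sequences": sequences, "sites": sites, "complexes": complexes,
        "motifs": list(DEFAULT_MOTIFS),
        "kinase_motifs": list(DEFAULT_KINASE_MOTIFS),
        "truth": truth,
    }


BUNDLE_FILES = {
    "labeled": "labeled.tsv", "unlabeled": "unlabeled.tsv",
    "proteome": "proteome.tsv", "phospho": "phospho.tsv",
    "glyco_sites": "glyco_sites.tsv",
}


def write_bundle(bundle: dict, out_dir) -> None:
    """Write a simulated bundle as the TSV/FASTA layout the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, fname in BUNDLE_FILES.items():
        pio.write_timecourse(bundle[key], out / fname)
    pio.write_fasta(bundle["sequences"], out / "sequences.fasta")
    pio.write_sites(bundle["sites"], out / "sites.tsv")
    pio.write_complex_table(bundle["complexes"], out / "complexes.tsv")
    pio.write_motifs(bundle["motifs"], out / "motifs.tsv")
    pio.write_kinase_motifs(bundle["kinase_motifs"], out / "kinase_motifs.tsv")
    truth = bundle["truth"]
    truth["sites"].to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    truth["pairs"].to_csv(out / "truth_pairs.tsv", sep="\t", index=False)
    truth["motifs"].to_csv(out / "truth_motifs.tsv", sep="\t", index=False)
    truth["proteins"].to_csv(out / "truth_proteins.tsv", sep="\t", index=False)
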