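"""Synthetic inputs for every pipeline stage.

Three generators emulate the three experimental data kinds the pipeline
consumes:

* :func:`simulate_screen` — plate-reader luminescence tables from a
  384-well phenotypic necroptosis-rescue screen (DMSO negative and
  Nec-1-like positive controls on every plate, drugs in duplicate at two
  concentrations, planted true rescuers).
* :func:`simulate_curve` — replicated dose-response series from a Hill
  generator over a serial-dilution design (4PL viability curves or
  one-site competition-binding curves with slope -1).
* :func:`simulate_pulldown` — dual-engine PSM tables from a competition
  affinity-purification experiment: a background proteome, planted true
  targets whose spectral counts and peptide scores drop under free-drug
  competition, reversed-sequence decoys, and linearly distorted
  precursor/fragment masses.  :func:`simulate_profiles` emits the same
  experiment collapsed to per-protein spectral-count/engine-score
  profiles, for Monte-Carlo studies of the competition statistic alone.

Spectral counts are negative-binomial (overdispersed relative to
Poisson); engine scores are increasing noisy functions of the log
expected count, so competition reduces counts and scores coherently
while score noise stays independent of count noise under the null.
All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from pyteomics import mass as pmass

from .dose_response import DoseResponseSeries, hill_response, serial_dilution_doses

__all__ = [
    "ScreenSimConfig",
    "CurveSimConfig",
    "PulldownSimConfig",
    "CountModel",
    "ScoreModel",
    "PeptideModel",
    "MassErrorModel",
    "simulate_screen",
    "simulate_curve",
    "simulate_pulldown",
    "simulate_profiles",
]

CONDITIONS = ("non_competed", "competed")


# ------------------------------------------------------------------
# screen
# ------------------------------------------------------------------


@dataclass
class ScreenSimConfig:
    """Plate-screen generator settings.

    Defaults mirror the screen design: 384-well plates, compounds at
    1.5 uM and 0.5 uM in duplicate, luminescent viability readout with
    necroptotic death as baseline and full rescue as the positive
    control level.
    """

    n_drugs: int = 50
    concentrations: tuple = (1.5e-6, 0.5e-6)  # molar
    n_replicates: int = 2
    plate_format: int = 384
    control_fractions: tuple = (0.05, 0.05)  # (DMSO, positive) fraction of wells
    baseline_signal: float = 1000.0
    rescue_signal: float = 5000.0
    noise_cv: float = 0.1
    planted_hits: Mapping = field(default_factory=dict)  # drug -> fraction or {conc: fraction}
    seed: int = 0

    def validate(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.rescue_signal <= self.baseline_signal:
            raise ValueError("rescue_signal must exceed baseline_signal")
        for drug, frac in self.planted_hits.items():
            fracs = frac.values() if isinstance(frac, Mapping) else [frac]
            if any(not (0.0 <= f <= 1.0) for f in fracs):
                raise ValueError(f"planted rescue fraction for {drug!r} outside [0, 1]")
        if min(self.control_fractions) < 0:
            raise ValueError("control fractions must be >= 0")

    def n_controls(self):
        n_dmso = max(2, int(round(self.control_fractions[0] * self.plate_format)))
        n_pos = max(2, int(round(self.control_fractions[1] * self.plate_format)))
        return n_dmso, n_pos


def _well_labels(plate_format: int) -> list[str]:
    layouts = {96: (8, 12), 384: (16, 24), 1536: (32, 48)}
    if plate_format in layouts:
        rows, cols = layouts[plate_format]
        letters = [string.ascii_uppercase[i] if i < 26 else "A" + string.ascii_uppercase[i - 26]
                   for i in range(rows)]
        return [f"{r}{c:02d}" for r in letters for c in range(1, cols + 1)]
    return [f"W{i:04d}" for i in range(1, plate_format + 1)]


def _rescue_fraction(cfg: ScreenSimConfig, drug: str, conc: float) -> float:
    spec = cfg.planted_hits.get(drug)
    if spec is None:
        return 0.0
    if isinstance(spec, Mapping):
        return float(spec.get(conc, 0.0))
    return float(spec)


def simulate_screen(cfg: ScreenSimConfig) -> pd.DataFrame:
    """Generate plate-reader well records for a rescue screen.

    Returns a frame with columns ``plate_id, well, compound, role,
    concentration, replicate, signal``.  DMSO wells fluctuate around the
    baseline (death) signal, positive-control wells around the full-rescue
    signal, and drug wells interpolate linearly between the two by the
    planted rescue fraction.  Noise is Normal with s.d. = noise_cv x mean.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_dmso, n_pos = cfg.n_controls()
    capacity = cfg.plate_format - n_dmso - n_pos
    if capacity <= 0:
        raise ValueError("plate_format leaves no room for drug wells next to controls")

    drug_wells = [
        (f"drug_{i:03d}", conc, rep)
        for i in range(cfg.n_drugs)
        for conc in cfg.concentrations
        for rep in range(cfg.n_replicates)
    ]
    labels = _well_labels(cfg.plate_format)
    records = []
    n_plates = max(1, -(-len(drug_wells) // capacity))
    for p in range(n_plates):
        plate_id = f"plate_{p + 1:02d}"
        chunk = drug_wells[p * capacity:(p + 1) * capacity]
        cursor = 0
        for _ in range(n_dmso):
            sig = rng.normal(cfg.baseline_signal, cfg.noise_cv * cfg.baseline_signal)
            records.append((plate_id, labels[cursor], "DMSO", "dmso", 0.0, 0, max(sig, 0.0)))
            cursor += 1
        for _ in range(n_pos):
            sig = rng.normal(cfg.rescue_signal, cfg.noise_cv * cfg.rescue_signal)
            records.append((plate_id, labels[cursor], "Nec-1", "positive", 1e-5, 0, max(sig, 0.0)))
            cursor += 1
        for drug, conc, rep in chunk:
            frac = _rescue_fraction(cfg, drug, conc)
            mu = cfg.baseline_signal + frac * (cfg.rescue_signal - cfg.baseline_signal)
            sig = rng.normal(mu, cfg.noise_cv * mu)
            records.append((plate_id, labels[cursor], drug, "drug", conc, rep, max(sig, 0.0)))
            cursor += 1
    return pd.DataFrame(
        records,
        columns=["plate_id", "well", "compound", "role", "concentration", "replicate", "signal"],
    )


# ------------------------------------------------------------------
# dose-response curves
# ------------------------------------------------------------------


@dataclass
class CurveSimConfig:
    """Hill-curve generator settings.

    ``true_params`` is (background, signal, midpoint [molar], slope).
    ``dose_design`` is (top_dose [molar], dilution_factor, n_points);
    the binding default is the 11-point 3-fold dilution from 30 uM.
    For ``model == 'hill_binding'`` the slope is forced to -1.
    """

    model: str = "hill_4pl"
    true_params: tuple = (0.0, 100.0, 1e-7, 1.0)
    dose_design: tuple = (3e-5, 3.0, 11)
    n_replicates: int = 3
    noise_cv: float = 0.1
    seed: int = 0

    def validate(self):
        if self.model not in ("hill_4pl", "hill_binding"):
            raise ValueError(f"unknown curve model {self.model!r}")
        top, factor, n = self.dose_design
        if factor <= 1:
            raise ValueError("dilution_factor must be > 1")
        if n < 4:
            raise ValueError("n_points must be >= 4")
        if self.true_params[2] <= 0:
            raise ValueError("midpoint must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def params(self) -> tuple:
        b, s, m, h = self.true_params
        if self.model == "hill_binding":
            h = -1.0
        return b, s, m, h


def simulate_curve(cfg: CurveSimConfig) -> DoseResponseSeries:
    """Draw replicated responses around the exact Hill value at each dose.

    Dose 0 is never included (log-scale serial-dilution design).  With
    ``noise_cv == 0`` responses equal the model values exactly.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    doses = serial_dilution_doses(*cfg.dose_design)
    b, s, m, h = cfg.params()
    mu = hill_response(doses, b, s, m, h)
    rows = []
    for rep in range(cfg.n_replicates):
        noise = rng.normal(0.0, 1.0, size=doses.size) if cfg.noise_cv > 0 else 0.0
        resp = mu + cfg.noise_cv * np.abs(mu) * noise
        for d, r in zip(doses, np.atleast_1d(resp)):
            rows.append((d, float(r), rep))
    pts = pd.DataFrame(rows, columns=["dose", "response", "replicate"])
    readout = "binding_signal" if cfg.model == "hill_binding" else "viability_protection"
    return DoseResponseSeries(compound="simulated", readout=readout, points=pts)


# ------------------------------------------------------------------
# pull-down PSM tables
# ------------------------------------------------------------------


@dataclass
class CountModel:
    """Per-protein negative-binomial spectral-count model.

    Protein mean counts are log-normal: ``exp(Normal(log_mean, log_sd))``;
    ``dispersion`` is the NB overdispersion (variance = mu + dispersion * mu^2).
    """

    log_mean: float = 2.3
    log_sd: float = 0.8
    dispersion: float = 0.3


@dataclass
class ScoreModel:
    """Engine protein scores as noisy increasing functions of log expected count.

    score = intercept + slope * log1p(expected_count) + Normal(0, sd),
    drawn independently per condition x replicate and per engine.
    """

    intercept_a: float = 10.0
    slope_a: float = 60.0
    sd_a: float = 15.0
    intercept_b: float = 1.0
    slope_b: float = 1.5
    sd_b: float = 0.5


@dataclass
class PeptideModel:
    """Peptide repertoire and peptide-score distributions.

    Confident (true/background) identifications score well above the
    dual-engine validation thresholds; spurious and decoy matches draw
    from null distributions straddling them.
    """

    mean_peptides: float = 6.0
    shared_prob: float = 0.05
    conflict_prob: float = 0.02
    true_score_mu_a: float = 45.0
    true_score_sd_a: float = 12.0
    true_score_mu_b: float = 6.0
    true_score_sd_b: float = 1.5
    null_score_mu_a: float = 7.5
    null_score_sd_a: float = 3.0
    null_score_mu_b: float = 3.0
    null_score_sd_b: float = 0.5


@dataclass
class MassErrorModel:
    """Linear distortion of measured vs theoretical masses.

    measured = slope * theoretical + offset (+ jitter); precursor jitter
    is relative (ppm), fragment jitter absolute (Da).  With zero jitter
    the distortion is exactly invertible by linear recalibration.
    """

    precursor_slope: float = 1.000003
    precursor_offset: float = 0.0015
    precursor_jitter_ppm: float = 0.8
    fragment_slope: float = 1.00002
    fragment_offset: float = 0.02
    fragment_jitter_da: float = 0.01

    def apply_precursor(self, theo, rng=None):
        m = self.precursor_slope * np.asarray(theo) + self.precursor_offset
        if rng is not None and self.precursor_jitter_ppm > 0:
            m = m * (1.0 + rng.normal(0.0, self.precursor_jitter_ppm * 1e-6, size=np.shape(theo)))
        return m

    def apply_fragment(self, theo, rng=None):
        m = self.fragment_slope * np.asarray(theo) + self.fragment_offset
        if rng is not None and self.fragment_jitter_da > 0:
            m = m + rng.normal(0.0, self.fragment_jitter_da, size=np.shape(theo))
        return m


@dataclass
class PulldownSimConfig:
    """Competition pull-down generator settings.

    The defaults encode the study conditions of a single-drug
    competition experiment: four exchangeable replicates per condition
    (two biological x two technical collapsed), a background proteome
    unchanged by competition, a handful of true targets whose counts and
    scores are multiplied by ``competition_effect`` under competition,
    and reversed-accession decoys.  ``n_spurious_proteins`` adds
    incorrect target-database matches drawn from the same null score
    distribution as decoys, so realized false-target rates can be
    compared with decoy-based FDR estimates.
    """

    n_background_proteins: int = 80
    n_true_targets: int = 8
    n_decoys: int = 40
    n_spurious_proteins: int = 0
    replicates_per_condition: int = 4
    count_model: CountModel = field(default_factory=CountModel)
    competition_effect: float = 0.1
    score_model: ScoreModel = field(default_factory=ScoreModel)
    peptide_model: PeptideModel = field(default_factory=PeptideModel)
    mass_error_model: MassErrorModel = field(default_factory=MassErrorModel)
    seed: int = 0

    def validate(self):
        if not (0.0 <= self.competition_effect < 1.0) and self.n_true_targets > 0:
            raise ValueError("competition_effect must lie in [0, 1) for true targets")
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be >= 1")
        if min(self.n_background_proteins, self.n_true_targets, self.n_decoys,
               self.n_spurious_proteins) < 0:
            raise ValueError("protein counts must be >= 0")


_AA = np.array(list("ACDEFGHILMNPQSTVWY"))  # K/R reserved for the tryptic terminus


def _random_peptide(rng) -> str:
    length = int(rng.integers(7, 16))
    body = "".join(rng.choice(_AA, size=length - 1))
    return body + ("K" if rng.random() < 0.5 else "R")


def _nb_draw(rng, mu: float, dispersion: float) -> int:
    if mu <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mu))
    r = 1.0 / dispersion
    return int(rng.negative_binomial(r, r / (r + mu)))


def _protein_frame(cfg: PulldownSimConfig, rng) -> pd.DataFrame:
    cm = cfg.count_model
    rows = []
    for i in range(cfg.n_background_proteins):
        rows.append((f"BG{i:04d}", "background", False, 1.0))
    for i in range(cfg.n_true_targets):
        rows.append((f"TGT{i:02d}", "target", False, cfg.competition_effect))
    for i in range(cfg.n_spurious_proteins):
        rows.append((f"SPUR{i:03d}", "spurious", False, 1.0))
    for i in range(cfg.n_decoys):
        rows.append((f"REV_D{i:04d}", "decoy", True, 1.0))
    df = pd.DataFrame(rows, columns=["accession", "kind", "decoy", "effect"])
    mu = np.where(
        df["kind"].isin(["background", "target"]),
        np.exp(rng.normal(cm.log_mean, cm.log_sd, size=len(df))),
        np.exp(rng.normal(-0.3, 0.5, size=len(df))),
    )
    df["mean_count"] = mu
    return df


def simulate_profiles(cfg: PulldownSimConfig):
    """Per-protein competition profiles without PSM-level detail.

    Returns ``(profiles, truth)`` where ``profiles`` is long-form with
    columns ``group_id, condition, replicate, spectral_count, score_a,
    score_b`` — the same shape the protein-inference stage produces —
    and ``truth`` describes each simulated protein.  Decoy and spurious
    proteins are omitted (they would not survive validation).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    proteins = _protein_frame(cfg, rng)
    real = proteins[proteins["kind"].isin(["background", "target"])].reset_index(drop=True)
    sm, cm = cfg.score_model, cfg.count_model
    rows = []
    for _, p in real.iterrows():
        for cond in CONDITIONS:
            eff = p["effect"] if cond == "competed" else 1.0
            mu = p["mean_count"] * eff
            for rep in range(cfg.replicates_per_condition):
                count = _nb_draw(rng, mu, cm.dispersion)
                sa = sm.intercept_a + sm.slope_a * np.log1p(mu) + rng.normal(0, sm.sd_a)
                sb = sm.intercept_b + sm.slope_b * np.log1p(mu) + rng.normal(0, sm.sd_b)
                rows.append((p["accession"], cond, rep, count, max(sa, 0.0), max(sb, 0.0)))
    profiles = pd.DataFrame(
        rows, columns=["group_id", "condition", "replicate", "spectral_count", "score_a", "score_b"]
    )
    return profiles, proteins


def _peptide_repertoire(cfg: PulldownSimConfig, proteins: pd.DataFrame, rng):
    """Assign peptides (with masses and fragment ions) to proteins.

    Returns (peptides_by_protein, peptide_info) where peptide_info maps
    sequence -> dict(proteins=[...], precursor_theo, fragments_theo).
    Shared peptides are only shared within the same database half
    (target with target, decoy with decoy).
    """
    pm = cfg.peptide_model
    peptides_by_protein: dict[str, list[str]] = {}
    info: dict[str, dict] = {}
    seen: set[str] = set()
    for _, p in proteins.iterrows():
        acc = p["accession"]
        k = 1 + int(rng.poisson(max(pm.mean_peptides - 1, 0)))
        peps = []
        for _ in range(k):
            seq = _random_peptide(rng)
            while seq in seen:
                seq = _random_peptide(rng)
            seen.add(seq)
            peps.append(seq)
            n = len(seq)
            frags = [
                pmass.fast_mass(seq[:2], ion_type="b", charge=1),
                pmass.fast_mass(seq[n // 2:], ion_type="y", charge=1),
                pmass.fast_mass(seq[: max(n - 2, 2)], ion_type="b", charge=1),
            ]
            info[seq] = {
                "proteins": [acc],
                "precursor_theo": pmass.fast_mass(seq),
                "fragments_theo": frags,
            }
        peptides_by_protein[acc] = peps
    # introduce shared peptides within each database half
    decoy_flag = dict(zip(proteins["accession"], proteins["decoy"]))
    accs = list(peptides_by_protein)
    for seq, meta in info.items():
        if rng.random() < pm.shared_prob:
            owner = meta["proteins"][0]
            pool = [a for a in accs if a != owner and decoy_flag[a] == decoy_flag[owner]]
            if pool:
                other = pool[int(rng.integers(len(pool)))]
                meta["proteins"].append(other)
                peptides_by_protein[other].append(seq)
    return peptides_by_protein, info


def simulate_pulldown(cfg: PulldownSimConfig):
    """Dual-engine PSM tables for a competition pull-down.

    Returns ``(psms, truth)``.  ``psms`` columns: ``spectrum_id, peptide,
    proteins`` (';'-joined accessions), ``engine`` ('A' Mascot-like, 'B'
    Phenyx-like), ``score, decoy, condition, replicate,
    precursor_measured, precursor_theoretical, fragment_pairs`` (list of
    (measured, theoretical) tuples), ``missed_cleavages``.  Both engines
    report every spectrum; with a small probability the second engine
    assigns a different peptide (a spectral conflict).  True targets have
    count and score means multiplied by ``competition_effect`` in the
    competed condition; background and decoys are exchangeable across
    conditions.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    proteins = _protein_frame(cfg, rng)
    peptides_by_protein, pep_info = _peptide_repertoire(cfg, proteins, rng)
    pm, cm, mem = cfg.peptide_model, cfg.count_model, cfg.mass_error_model

    all_peps = list(pep_info)
    rows = []
    spectrum_counter = 0
    for _, p in proteins.iterrows():
        acc = p["accession"]
        confident = p["kind"] in ("background", "target")
        for cond in CONDITIONS:
            eff = p["effect"] if (cond == "competed" and p["kind"] == "target") else 1.0
            count = 0
            for rep in range(cfg.replicates_per_condition):
                count = _nb_draw(rng, p["mean_count"] * eff, cm.dispersion)
                for _ in range(count):
                    spectrum_counter += 1
                    sid = f"sp{spectrum_counter:07d}"
                    pep = peptides_by_protein[acc][int(rng.integers(len(peptides_by_protein[acc])))]
                    meta = pep_info[pep]
                    theo = meta["precursor_theo"]
                    meas = float(mem.apply_precursor(theo, rng))
                    fr_theo = meta["fragments_theo"]
                    fr_meas = mem.apply_fragment(np.asarray(fr_theo), rng)
                    frag_pairs = [(float(m), float(t)) for m, t in zip(fr_meas, fr_theo)]
                    mc = int(rng.random() < 0.2)
                    if confident:
                        mu_a, sd_a = pm.true_score_mu_a * eff, pm.true_score_sd_a
                        mu_b, sd_b = pm.true_score_mu_b * eff, pm.true_score_sd_b
                    else:
                        mu_a, sd_a = pm.null_score_mu_a, pm.null_score_sd_a
                        mu_b, sd_b = pm.null_score_mu_b, pm.null_score_sd_b
                    score_a = max(rng.normal(mu_a, sd_a), 0.0)
                    score_b = max(rng.normal(mu_b, sd_b), 0.0)
                    prot_str = ";".join(sorted(meta["proteins"]))
                    rows.append((sid, pep, prot_str, "A", score_a, bool(p["decoy"]), cond, rep,
                                 meas, theo, frag_pairs, mc))
                    # engine B: usually the same peptide, occasionally a conflict
                    pep_b = pep
                    if rng.random() < pm.conflict_prob:
                        alt = all_peps[int(rng.integers(len(all_peps)))]
                        if alt != pep:
                            pep_b = alt
                    meta_b = pep_info[pep_b]
                    prot_b = ";".join(sorted(meta_b["proteins"]))
                    rows.append((sid, pep_b, prot_b, "B", score_b, bool(p["decoy"]), cond, rep,
                                 meas, meta_b["precursor_theo"], frag_pairs, mc))
    psms = pd.DataFrame(
        rows,
        columns=[
            "spectrum_id", "peptide", "proteins", "engine", "score", "decoy", "condition",
            "replicate", "precursor_measured", "precursor_theoretical", "fragment_pairs",
            "missed_cleavages",
        ],
    )
    return psms, proteins
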