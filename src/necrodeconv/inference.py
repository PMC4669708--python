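"""Dual-engine protein inference with mass recalibration and decoy FDR.

The chain mirrors a classic two-search workflow:

1. an initial broad-tolerance search supplies a confident *anchor set*
   (engine-A peptide score >= 30, proteins with >= 3 distinct peptide
   identifications);
2. independent linear transformations for precursor and fragment masses
   are fitted on the anchors to minimize the mean-square deviation of
   measured from theoretical masses, then applied to every PSM; PSMs
   outside the narrow tolerances (±4 p.p.m. precursor, ±0.3 Da fragment)
   are dropped;
3. each engine validates proteins on its own score scale: >= 2 unique
   peptides above T1, or a single peptide above T2, with additional
   peptides above T3 attached to validated proteins;
4. the two validated sets are merged, spectra assigned different peptide
   sequences by the two engines are discarded entirely, and proteins
   sharing any accepted peptide are grouped by single linkage;
5. running the identical procedure on the reversed-sequence (decoy) half
   yields protein- and peptide-level FDR estimates, judged against the
   <1% protein / <0.1% peptide acceptance gates.

Score comparisons against T1/T2/T3 are strict (> T); the calibration
anchor filter is inclusive (>= 30).  Both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "EngineThresholds",
    "MASCOT_LIKE_THRESHOLDS",
    "PHENYX_LIKE_THRESHOLDS",
    "DEFAULT_THRESHOLDS",
    "MassCalibration",
    "MassRecalibrator",
    "ProteinGroupTable",
    "FdrEstimate",
    "calibration_filter",
    "recalibrate",
    "validate_proteins",
    "merge_and_group",
    "estimate_fdr",
    "infer_proteins",
    "InferenceResult",
]


@dataclass(frozen=True)
class EngineThresholds:
    """Per-engine validation score thresholds (T3 <= T1 <= T2)."""

    engine: str
    t1: float
    t2: float
    t3: float

    def __post_init__(self):
        if not (self.t3 <= self.t1 <= self.t2):
            raise ValueError("thresholds must satisfy T3 <= T1 <= T2")


MASCOT_LIKE_THRESHOLDS = EngineThresholds("A", t1=14.0, t2=40.0, t3=10.0)
PHENYX_LIKE_THRESHOLDS = EngineThresholds("B", t1=4.2, t2=4.75, t3=3.5)
DEFAULT_THRESHOLDS = {"A": MASCOT_LIKE_THRESHOLDS, "B": PHENYX_LIKE_THRESHOLDS}


# ------------------------------------------------------------------
# calibration
# ------------------------------------------------------------------


def calibration_filter(psms: pd.DataFrame, min_score: float = 30.0, min_peptides: int = 3,
                       engine: str = "A") -> pd.DataFrame:
    """Select the confident anchor set for mass recalibration.

    Keeps engine-A (Mascot-like) PSMs with score >= ``min_score`` whose
    protein has at least ``min_peptides`` distinct peptide
    identifications at that score level.
    """
    sub = psms[(psms["engine"] == engine) & (psms["score"] >= min_score)]
    if sub.empty:
        raise ValueError("empty calibration anchor set: no PSMs pass the score filter")
    exploded = sub.assign(_prot=sub["proteins"].str.split(";")).explode("_prot")
    pep_counts = exploded.groupby("_prot")["peptide"].nunique()
    good = set(pep_counts[pep_counts >= min_peptides].index)
    keep = exploded[exploded["_prot"].isin(good)].index.unique()
    anchors = sub.loc[sub.index.intersection(keep)]
    if anchors.empty:
        raise ValueError("empty calibration anchor set: no protein has enough peptides")
    return anchors


@dataclass
class MassCalibration:
    """Fitted linear mass transformations and their effect on the anchors.

    ``precursor``/``fragment`` are (slope, offset) applied as
    ``corrected = slope * measured + offset``.  Mean-square deviations
    are on the anchor set, precursor in p.p.m.^2 and fragment in Da^2.
    """

    precursor: tuple
    fragment: tuple
    pre_msd_ppm2: float
    post_msd_ppm2: float
    pre_msd_da2: float
    post_msd_da2: float


def _fit_linear_ppm(measured: np.ndarray, theoretical: np.ndarray) -> tuple:
    """WLS of corrected ppm error: minimize sum(((a*m+b-t)/t)^2)."""
    if np.ptp(measured) == 0:
        raise ValueError("rank-deficient calibration fit: all anchor masses equal")
    A = np.column_stack([measured / theoretical, 1.0 / theoretical])
    coef, *_ = np.linalg.lstsq(A, np.ones_like(theoretical), rcond=None)
    return float(coef[0]), float(coef[1])


def _fit_linear_da(measured: np.ndarray, theoretical: np.ndarray) -> tuple:
    """OLS of theoretical on measured mass (Da space)."""
    if np.ptp(measured) == 0:
        raise ValueError("rank-deficient calibration fit: all anchor masses equal")
    A = np.column_stack([measured, np.ones_like(measured)])
    coef, *_ = np.linalg.lstsq(A, theoretical, rcond=None)
    return float(coef[0]), float(coef[1])


def _frag_arrays(psms: pd.DataFrame):
    meas, theo = [], []
    for pairs in psms["fragment_pairs"]:
        for m, t in pairs:
            meas.append(m)
            theo.append(t)
    return np.asarray(meas, float), np.asarray(theo, float)


class MassRecalibrator(BaseEstimator, TransformerMixin):
    """Linear mass recalibration fitted on anchors, applied to all PSMs.

    ``fit`` estimates independent (slope, offset) pairs for precursor
    masses (least squares in relative p.p.m.-error space) and fragment
    masses (ordinary least squares in Da).  ``transform`` replaces
    measured masses with corrected ones and drops PSMs outside the final
    tolerances.

    Parameters
    ----------
    precursor_tol_ppm, fragment_tol_da : float
        Narrow post-calibration acceptance windows.
    """

    def __init__(self, precursor_tol_ppm: float = 4.0, fragment_tol_da: float = 0.3):
        self.precursor_tol_ppm = precursor_tol_ppm
        self.fragment_tol_da = fragment_tol_da

    def fit(self, anchors: pd.DataFrame, y=None):
        if anchors.empty:
            raise ValueError("cannot calibrate on an empty anchor set")
        pm = anchors["precursor_measured"].to_numpy(float)
        pt = anchors["precursor_theoretical"].to_numpy(float)
        fa_m, fa_t = _frag_arrays(anchors)
        prec = _fit_linear_ppm(pm, pt)
        frag = _fit_linear_da(fa_m, fa_t) if fa_m.size else (1.0, 0.0)

        def ppm2(m, t):
            return float(np.mean(((m - t) / t * 1e6) ** 2)) if m.size else 0.0

        def da2(m, t):
            return float(np.mean((m - t) ** 2)) if m.size else 0.0

        self.calibration_ = MassCalibration(
            precursor=prec,
            fragment=frag,
            pre_msd_ppm2=ppm2(pm, pt),
            post_msd_ppm2=ppm2(prec[0] * pm + prec[1], pt),
            pre_msd_da2=da2(fa_m, fa_t),
            post_msd_da2=da2(frag[0] * fa_m + frag[1], fa_t) if fa_m.size else 0.0,
        )
        return self

    def transform(self, psms: pd.DataFrame) -> pd.DataFrame:
        cal = self.calibration_
        out = psms.copy()
        a, b = cal.precursor
        out["precursor_measured"] = a * out["precursor_measured"] + b
        fa, fb = cal.fragment
        out["fragment_pairs"] = out["fragment_pairs"].map(
            lambda pairs: [(fa * m + fb, t) for m, t in pairs]
        )
        ppm_err = (out["precursor_measured"] - out["precursor_theoretical"]).abs() \
            / out["precursor_theoretical"] * 1e6
        frag_ok = out["fragment_pairs"].map(
            lambda pairs: all(abs(m - t) <= self.fragment_tol_da for m, t in pairs)
        )
        return out[(ppm_err <= self.precursor_tol_ppm) & frag_ok].reset_index(drop=True)


def recalibrate(psms: pd.DataFrame, anchors: pd.DataFrame, **kwargs):
    """Fit linear mass corrections on ``anchors`` and apply them to ``psms``.

    Returns ``(MassCalibration, corrected PSM table)``; PSMs outside the
    final tolerances are dropped from the corrected table.
    """
    rec = MassRecalibrator(**kwargs).fit(anchors)
    return rec.calibration_, rec.transform(psms)


# ------------------------------------------------------------------
# validation, merging, grouping
# ------------------------------------------------------------------


def validate_proteins(psms: pd.DataFrame, thresholds: dict | None = None) -> dict:
    """Per-engine protein validation.

    A protein is validated by an engine iff it has >= 2 unique peptides
    scoring > T1, or any peptide scoring > T2.  For validated proteins,
    all peptides scoring > T3 are accepted.  A peptide is *unique* when
    its accession list has a single member.

    Returns ``{engine: {protein: accepted peptide set}}``.
    """
    thresholds = thresholds or DEFAULT_THRESHOLDS
    unknown = set(psms["engine"].unique()) - set(thresholds)
    if unknown:
        raise ValueError(f"unknown engine id(s): {sorted(unknown)}")
    result: dict[str, dict[str, set]] = {}
    for engine, thr in thresholds.items():
        sub = psms[psms["engine"] == engine]
        result[engine] = {}
        if sub.empty:
            continue
        ex = sub.assign(_prot=sub["proteins"].str.split(";")).explode("_prot")
        best = ex.groupby(["_prot", "peptide"]).agg(
            score=("score", "max"), n_acc=("proteins", lambda s: s.iloc[0].count(";") + 1)
        ).reset_index()
        for prot, grp in best.groupby("_prot"):
            unique_t1 = ((grp["n_acc"] == 1) & (grp["score"] > thr.t1)).sum()
            any_t2 = (grp["score"] > thr.t2).any()
            if unique_t1 >= 2 or any_t2:
                accepted = set(grp.loc[grp["score"] > thr.t3, "peptide"])
                if accepted:
                    result[engine][prot] = accepted
    return result


@dataclass
class ProteinGroupTable:
    """Validated protein groups with per-cell spectral counts and scores.

    ``groups``: one row per group (``group_id, members, representative,
    peptides, n_unique_peptides, decoy``).  ``profiles``: long form, one
    row per group x condition x replicate with ``spectral_count,
    score_a, score_b``.  ``accepted_peptides``: all distinct accepted
    peptide sequences (including T3-level additions).
    """

    groups: pd.DataFrame
    profiles: pd.DataFrame
    accepted_peptides: set = field(default_factory=set)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def merge_and_group(validated: dict, psms: pd.DataFrame,
                    conditions=("non_competed", "competed")) -> ProteinGroupTable:
    """Merge per-engine validations into peptide-sharing protein groups.

    Spectra assigned different peptide sequences by the two engines are
    discarded entirely before counting.  Proteins linked by any shared
    accepted peptide collapse into one group (single-linkage closure);
    the representative is the member with the highest summed peptide
    score.  Spectral counts per condition x replicate count each
    spectrum once even when both engines matched it; engine protein
    scores are the per-cell sums of best peptide scores.
    """
    # spectral conflicts: one spectrum, two peptide sequences
    pep_per_spec = psms.groupby("spectrum_id")["peptide"].nunique()
    conflicted = set(pep_per_spec[pep_per_spec > 1].index)
    clean = psms[~psms["spectrum_id"].isin(conflicted)]

    proteins = sorted(set().union(*[set(v) for v in validated.values()])) \
        if validated else []
    accepted: dict[str, set] = {}
    for engine_map in validated.values():
        for prot, peps in engine_map.items():
            accepted.setdefault(prot, set()).update(peps)
    if not proteins:
        empty_g = pd.DataFrame(columns=["group_id", "members", "representative", "peptides",
                                        "n_unique_peptides", "decoy"])
        empty_p = pd.DataFrame(columns=["group_id", "condition", "replicate",
                                        "spectral_count", "score_a", "score_b"])
        return ProteinGroupTable(groups=empty_g, profiles=empty_p)

    # retained records: engine-specific accepted peptide for a validated protein
    frames = []
    for engine, engine_map in validated.items():
        sub = clean[clean["engine"] == engine]
        if sub.empty or not engine_map:
            continue
        ex = sub.assign(_prot=sub["proteins"].str.split(";")).explode("_prot")
        pairs = pd.DataFrame(
            [(p, pep) for p, peps in engine_map.items() for pep in peps],
            columns=["_prot", "peptide"],
        )
        frames.append(ex.merge(pairs, on=["_prot", "peptide"]))
    retained = pd.concat(frames, ignore_index=True) if frames else clean.iloc[0:0].assign(_prot="")

    # single-linkage grouping on shared accepted peptides
    g = nx.Graph()
    g.add_nodes_from(proteins)
    by_pep: dict[str, list] = {}
    for prot in proteins:
        for pep in accepted[prot]:
            by_pep.setdefault(pep, []).append(prot)
    for members in by_pep.values():
        for a, b in zip(members, members[1:]):
            g.add_edge(a, b)

    total_score = retained.groupby("_prot")["score"].sum() if not retained.empty else pd.Series(dtype=float)
    decoy_by_prot = {}
    if not retained.empty:
        decoy_by_prot = retained.groupby("_prot")["decoy"].first().to_dict()

    group_rows = []
    prot_to_group = {}
    replicates = sorted(psms["replicate"].unique()) if not psms.empty else []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        rep_prot = max(members, key=lambda p: (total_score.get(p, 0.0), p))
        peps = sorted(set().union(*[accepted[m] for m in members]))
        unique_peps = [p for p in peps if len(by_pep.get(p, [])) == 1]
        decoy = any(bool(decoy_by_prot.get(m, False)) for m in members)
        group_rows.append((rep_prot, ";".join(members), rep_prot, ";".join(peps),
                           len(unique_peps), decoy))
        for m in members:
            prot_to_group[m] = rep_prot
    groups = pd.DataFrame(group_rows, columns=["group_id", "members", "representative",
                                               "peptides", "n_unique_peptides", "decoy"])

    # per-cell measures, vectorized over the retained records
    grid = pd.MultiIndex.from_product(
        [groups["group_id"], conditions, replicates],
        names=["group_id", "condition", "replicate"],
    )
    profiles = pd.DataFrame(index=grid).reset_index()
    if not retained.empty:
        ret = retained.assign(_gid=retained["_prot"].map(prot_to_group))
        key = ["_gid", "condition", "replicate"]
        counts = ret.drop_duplicates(["_gid", "condition", "replicate", "spectrum_id"]) \
            .groupby(key).size()
        pep_best = ret.groupby(key + ["engine", "peptide"])["score"].max()
        scores = pep_best.groupby(key + ["engine"]).sum().unstack("engine")
        profiles["spectral_count"] = profiles.set_index(["group_id", "condition", "replicate"]) \
            .index.map(counts).fillna(0).astype(int) if len(counts) else 0
        for col, eng in (("score_a", "A"), ("score_b", "B")):
            series = scores[eng] if eng in scores.columns else pd.Series(dtype=float)
            profiles[col] = profiles.set_index(["group_id", "condition", "replicate"]) \
                .index.map(series).fillna(0.0).astype(float)
    else:
        profiles["spectral_count"] = 0
        profiles["score_a"] = 0.0
        profiles["score_b"] = 0.0
    all_peps = set().union(*accepted.values()) if accepted else set()
    return ProteinGroupTable(groups=groups, profiles=profiles, accepted_peptides=all_peps)


# ------------------------------------------------------------------
# FDR
# ------------------------------------------------------------------


@dataclass
class FdrEstimate:
    """Decoy-based FDR estimates and the acceptance-gate verdicts."""

    protein_fdr: float
    peptide_fdr: float
    n_target_groups: int
    n_decoy_groups: int
    n_target_peptides: int
    n_decoy_peptides: int
    protein_pass: bool
    peptide_pass: bool


def estimate_fdr(target: ProteinGroupTable, decoy: ProteinGroupTable,
                 protein_threshold: float = 0.01,
                 peptide_threshold: float = 0.001) -> FdrEstimate:
    """Protein- and peptide-level FDR from a reversed-database search.

    protein FDR = validated decoy groups / validated target groups;
    peptide FDR = accepted decoy peptides / accepted target peptides
    (T3-level additions included on both sides).  Peptides occurring in
    both halves are excluded from the decoy numerator.
    """
    if target.n_groups == 0:
        raise ValueError("undefined FDR: zero target identifications")
    shared = target.accepted_peptides & decoy.accepted_peptides
    n_decoy_peps = len(decoy.accepted_peptides - shared)
    n_target_peps = len(target.accepted_peptides)
    protein_fdr = decoy.n_groups / target.n_groups
    peptide_fdr = n_decoy_peps / n_target_peps if n_target_peps else 0.0
    return FdrEstimate(
        protein_fdr=protein_fdr,
        peptide_fdr=peptide_fdr,
        n_target_groups=target.n_groups,
        n_decoy_groups=decoy.n_groups,
        n_target_peptides=n_target_peps,
        n_decoy_peptides=n_decoy_peps,
        protein_pass=protein_fdr < protein_threshold,
        peptide_pass=peptide_fdr < peptide_threshold,
    )


# ------------------------------------------------------------------
# end-to-end convenience
# ------------------------------------------------------------------


@dataclass
class InferenceResult:
    calibration: MassCalibration | None
    target: ProteinGroupTable
    decoy: ProteinGroupTable
    fdr: FdrEstimate


def infer_proteins(psms: pd.DataFrame, thresholds: dict | None = None,
                   do_recalibrate: bool = True, **recal_kwargs) -> InferenceResult:
    """Run the full inference chain on a mixed target+decoy PSM table.

    Recalibration is fitted once on the anchor set of the whole table
    and applied to all PSMs; validation, merging and grouping then run
    separately on the target and reversed-database halves under
    identical thresholds, and the decoy half yields the FDR estimate.
    """
    thresholds = thresholds or DEFAULT_THRESHOLDS
    calibration = None
    if do_recalibrate:
        anchors = calibration_filter(psms)
        calibration, psms = recalibrate(psms, anchors, **recal_kwargs)
    halves = {}
    for name, flag in (("target", False), ("decoy", True)):
        half = psms[psms["decoy"] == flag]
        validated = validate_proteins(half, thresholds) if not half.empty else {}
        halves[name] = merge_and_group(validated, half)
    fdr = estimate_fdr(halves["target"], halves["decoy"])
    return InferenceResult(calibration=calibration, target=halves["target"],
                           decoy=halves["decoy"], fdr=fdr)
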