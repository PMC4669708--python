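"""Plate normalization and hit calling for the phenotypic rescue screen.

Raw luminescence is rescaled plate-by-plate to percent-of-control (poc):
the mean of a plate's DMSO (negative) wells is anchored at 0% and the
mean of its positive-control wells at 100%.  A compound concentration is
a *hit* when its replicate-mean poc is (i) at least ``sd_multiplier``
(default 3) DMSO standard deviations above 0 on the poc scale and
(ii) above the absolute rescue floor (default 20%).  Both parts are
one-sided toward rescue: the screen looks for protection, not loss.
A *robust hit* is a hit at every tested concentration.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "PlateNormalizer",
    "normalize_plate",
    "call_hits",
    "recover_planted_hits",
]


class PlateNormalizer(BaseEstimator, TransformerMixin):
    """Per-plate percent-of-control transformer.

    ``fit`` learns each plate's DMSO and positive-control means;
    ``transform`` appends a ``poc`` column:
    ``poc = 100 * (signal - mean_dmso) / (mean_positive - mean_dmso)``.

    Parameters
    ----------
    dmso_role, positive_role : str
        Values of the ``role`` column identifying the two control kinds.
    min_controls : int
        Minimum wells of each control role per plate.
    """

    def __init__(self, dmso_role: str = "dmso", positive_role: str = "positive",
                 min_controls: int = 2):
        self.dmso_role = dmso_role
        self.positive_role = positive_role
        self.min_controls = min_controls

    def fit(self, X: pd.DataFrame, y=None):
        stats = {}
        for plate, grp in X.groupby("plate_id"):
            dmso = grp.loc[grp["role"] == self.dmso_role, "signal"]
            pos = grp.loc[grp["role"] == self.positive_role, "signal"]
            if len(dmso) < self.min_controls or len(pos) < self.min_controls:
                raise ValueError(
                    f"plate {plate!r} lacks {self.min_controls} wells of each control role"
                )
            lo, hi = float(dmso.mean()), float(pos.mean())
            if np.isclose(hi, lo):
                raise ValueError(f"degenerate controls on plate {plate!r}: equal control means")
            stats[plate] = (lo, hi)
            logger.info("plate %s: DMSO mean %.1f, positive mean %.1f, DMSO sd %.1f",
                        plate, lo, hi, float(dmso.std(ddof=1)))
        self.plate_stats_ = stats
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        unknown = set(out["plate_id"]) - set(self.plate_stats_)
        if unknown:
            raise ValueError(f"plates not seen in fit: {sorted(unknown)}")
        lo = out["plate_id"].map({p: s[0] for p, s in self.plate_stats_.items()})
        hi = out["plate_id"].map({p: s[1] for p, s in self.plate_stats_.items()})
        out["poc"] = 100.0 * (out["signal"] - lo) / (hi - lo)
        return out


def normalize_plate(wells: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Normalize well signals to percent-of-control, plate by plate."""
    return PlateNormalizer(**kwargs).fit(wells).transform(wells)


def call_hits(norm: pd.DataFrame, sd_multiplier: float = 3.0, min_rescue: float = 20.0,
              dmso_role: str = "dmso") -> pd.DataFrame:
    """Apply the two-part hit rule to normalized wells.

    Replicate wells are averaged per compound x concentration before the
    rule is applied.  The DMSO spread is estimated per plate on the poc
    scale with the unbiased (n-1) standard deviation; a compound's
    threshold uses the spread of the plate(s) its wells sit on (mean
    across plates when replicates are split).

    Returns one row per compound x concentration with columns
    ``compound, concentration, mean_poc, n_replicates, dmso_sd, hit,
    robust_hit``.
    """
    if "poc" not in norm.columns:
        raise ValueError("input lacks a 'poc' column; normalize first")
    sd_by_plate = {}
    for plate, grp in norm.groupby("plate_id"):
        dmso = grp.loc[grp["role"] == dmso_role, "poc"]
        if len(dmso) < 2:
            raise ValueError(f"plate {plate!r} has fewer than 2 DMSO wells; S.D. undefined")
        sd_by_plate[plate] = float(dmso.std(ddof=1))

    drugs = norm[norm["role"] == "drug"]
    if drugs.empty:
        return pd.DataFrame(columns=["compound", "concentration", "mean_poc", "n_replicates",
                                     "dmso_sd", "hit", "robust_hit"])
    rows = []
    for (comp, conc), grp in drugs.groupby(["compound", "concentration"], sort=True):
        sd = float(np.mean([sd_by_plate[p] for p in grp["plate_id"]]))
        mean_poc = float(grp["poc"].mean())
        hit = bool(mean_poc >= sd_multiplier * sd and mean_poc > min_rescue)
        rows.append((comp, conc, mean_poc, len(grp), sd, hit))
    calls = pd.DataFrame(rows, columns=["compound", "concentration", "mean_poc",
                                        "n_replicates", "dmso_sd", "hit"])
    robust = calls.groupby("compound")["hit"].transform("all")
    calls["robust_hit"] = robust & calls["hit"]
    return calls


def recover_planted_hits(calls: pd.DataFrame, truth) -> pd.DataFrame:
    """Confusion counts of hit calls against the planted ground truth.

    ``truth`` is the set/list of compound names planted as true rescuers
    (or a mapping compound -> rescue fraction, of which the keys are
    used).  Returns per-concentration rows with ``tp, fp, fn, tn,
    precision, recall``.
    """
    planted = set(truth.keys() if hasattr(truth, "keys") else truth)
    if calls.empty:
        return pd.DataFrame(columns=["concentration", "tp", "fp", "fn", "tn",
                                     "precision", "recall"])
    rows = []
    for conc, grp in calls.groupby("concentration"):
        is_hit = grp["hit"].to_numpy(bool)
        is_true = grp["compound"].isin(planted).to_numpy()
        tp = int((is_hit & is_true).sum())
        fp = int((is_hit & ~is_true).sum())
        fn = int((~is_hit & is_true).sum())
        tn = int((~is_hit & ~is_true).sum())
        precision = tp / (tp + fp) if tp + fp else float("nan")
        recall = tp / (tp + fn) if tp + fn else float("nan")
        rows.append((conc, tp, fp, fn, tn, precision, recall))
    return pd.DataFrame(rows, columns=["concentration", "tp", "fp", "fn", "tn",
                                       "precision", "recall"])
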