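"""Readers and writers for the pipeline's plain-text table formats.

* plate tables — CSV with columns ``plate_id, well, compound, role,
  concentration, replicate, signal``;
* dose-response tables — CSV with columns ``compound, dose_M, response,
  replicate``;
* PSM tables — tab-delimited with ';'-joined accession lists and
  fragment pairs serialized as ``measured:theoretical|...``;
* protein-group and target-score tables — tab-delimited;
* configs — YAML mappings.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .dose_response import DoseResponseSeries

PSM_COLUMNS = [
    "spectrum_id", "peptide", "proteins", "engine", "score", "decoy", "condition",
    "replicate", "precursor_measured", "precursor_theoretical", "fragment_pairs",
    "missed_cleavages",
]


def write_wells(wells: pd.DataFrame, path) -> None:
    wells.to_csv(path, index=False)


def read_wells(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_curve(series: DoseResponseSeries, path) -> None:
    df = series.points.rename(columns={"dose": "dose_M"}).copy()
    df.insert(0, "compound", series.compound)
    df["readout"] = series.readout
    df.to_csv(path, index=False)


def read_curve(path) -> DoseResponseSeries:
    df = pd.read_csv(path)
    compound = str(df["compound"].iloc[0]) if "compound" in df else "compound"
    readout = str(df["readout"].iloc[0]) if "readout" in df else "viability_protection"
    pts = df.rename(columns={"dose_M": "dose"})[["dose", "response", "replicate"]]
    return DoseResponseSeries(compound=compound, readout=readout, points=pts)


def _pack_fragments(pairs) -> str:
    return "|".join(f"{m:.6f}:{t:.6f}" for m, t in pairs)


def _unpack_fragments(s: str):
    if not isinstance(s, str) or not s:
        return []
    return [tuple(float(x) for x in pair.split(":")) for pair in s.split("|")]


def write_psms(psms: pd.DataFrame, path) -> None:
    out = psms.copy()
    out["fragment_pairs"] = out["fragment_pairs"].map(_pack_fragments)
    out.to_csv(path, sep="\t", index=False)


def read_psms(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["fragment_pairs"] = df["fragment_pairs"].map(_unpack_fragments)
    df["decoy"] = df["decoy"].astype(bool)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def dump_config(cfg: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
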