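"""Readers and writers for the plain-text interchange formats.

All tables are tab-separated.  Segment coordinates are 1-based inclusive
(SEG convention); BED-style half-open input can be converted on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .copy_number import SegmentProfile


def read_segments_tsv(
    path: str | Path, zero_based: bool = False, fill_gaps: bool = True
) -> dict[str, SegmentProfile]:
    """Load per-sample segment profiles from a multi-sample TSV
    (sample, chrom, start, end, copy, loh).

    ``zero_based=True`` converts BED-style half-open coordinates to 1-based
    inclusive.  Internal gaps are filled at the profile's length-weighted
    median copy so downstream grids are gap-free.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    if zero_based:
        df = df.assign(start=df["start"] + 1)
    profiles = {}
    for sid, sub in df.groupby("sample", sort=True):
        profile = SegmentProfile(str(sid), sub.drop(columns="sample"))
        profiles[str(sid)] = profile.fill_gaps() if fill_gaps else profile
    return profiles


def write_segments_tsv(profiles: dict[str, SegmentProfile], path: str | Path) -> None:
    frames = []
    for sid, profile in profiles.items():
        df = profile.segments.copy()
        df.insert(0, "sample", sid)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_snvs_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    if "vaf" not in df.columns and {"alt_reads", "depth"}.issubset(df.columns):
        df["vaf"] = df["alt_reads"] / df["depth"]
    return df


def read_svs_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom_a": str, "chrom_b": str, "sample": str})


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str}).set_index("sample")


def read_truth_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
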