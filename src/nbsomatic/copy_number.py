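"""Arm-level and whole-chromosome somatic copy-number calling.

Works on absolute (non-logged) copy levels where 2.0 is diploid.  The
segmental caller samples the copy level on a 250 kb grid over the terminal
30 Mb of each autosomal arm (the whole arm when shorter; a shorter window
for acrocentric q arms) and applies median thresholds:

* gain: terminal-window median >= 2.3 and the opposing (control) arm median
  at least 0.3 copies lower than the window median;
* loss: window median at least 0.3 copies below the sample median and the
  control-arm median at least 0.3 copies above the window median.

The control-arm criterion deliberately excludes whole-chromosome gains and
losses from the segmental calls; those are captured separately by the
whole-chromosome classifier (an arm counts as gained when >= 80% of its grid
points are at copy >= 2.25; a chromosome when both arms are; a sample is
"9+ WC gain" at nine or more gained chromosomes).  The 11q13.3 hotspot gain
uses the fixed GRCh37 window 68.5–69.5 Mb with the terminal 30 Mb of 11q as
control, because 11q13.3 gains frequently extend across the centromere and
make the p arm a poor control.

Profiles are recentered before calling: the presumed-diploid baseline is the
lowest copy level (rounded to 0.1, length-weighted, carrying a minimum share
of non-LOH length) among non-LOH segments, and is shifted to 2.0.  LOH
regions are excluded because in shifted profiles the presumed haploid and
triploid levels obligately carry LOH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Arm, Genome, make_genome_spec

GRID_STEP_BP = 250_000
ARM_WINDOW_BP = 30_000_000
ACROCENTRIC_WINDOW_BP = 20_000_000  # configurable 15–25 Mb
GAIN_MEDIAN_MIN = 2.3
CONTROL_DELTA = 0.3
LOSS_DELTA = 0.3
WC_ARM_COPY_MIN = 2.25
WC_ARM_FRACTION = 0.80
WC_MIN_CHROMS = 9
REGION_11Q13 = ("11", 68_500_000, 69_500_000)

SEGMENT_COLUMNS = ["chrom", "start", "end", "copy", "loh"]


class UncenterableProfileError(ValueError):
    """Raised when a profile has no non-LOH segment to anchor the diploid baseline."""


class EmptyOverlapError(ValueError):
    """Raised when a queried locus overlaps no segment of the profile."""


@dataclass
class SegmentProfile:
    """Per-sample genomic segments with absolute copy level and LOH flag.

    ``segments`` columns: chrom (str), start (int, 1-based), end (int,
    inclusive), copy (float, >= 0, 2.0 = diploid), loh (bool).  Segments on
    one chromosome must not overlap.
    """

    sample: str
    segments: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.segments.copy()
        missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"segment table missing columns: {missing}")
        df = df[SEGMENT_COLUMNS].astype(
            {"chrom": str, "start": np.int64, "end": np.int64, "copy": float, "loh": bool}
        )
        if (df["start"] > df["end"]).any():
            raise ValueError("segment with start > end")
        if (df["copy"] < 0).any():
            raise ValueError("negative copy level")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            if (sub["start"].to_numpy()[1:] <= sub["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping segments on chromosome {chrom}")
        self.segments = df

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.segments["chrom"]))

    @property
    def lengths(self) -> np.ndarray:
        return (self.segments["end"] - self.segments["start"] + 1).to_numpy(float)

    def copy_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Copy level of the segment containing each position; NaN outside coverage."""
        positions = np.asarray(positions, dtype=np.int64)
        sub = self.segments[self.segments["chrom"] == chrom]
        out = np.full(positions.shape, np.nan)
        if sub.empty:
            return out
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        copies = sub["copy"].to_numpy()
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = (idx >= 0) & (positions <= ends[np.clip(idx, 0, len(ends) - 1)])
        out[ok] = copies[idx[ok]]
        return out

    def fill_gaps(self) -> "SegmentProfile":
        """Fill internal per-chromosome gaps at the profile's length-weighted median copy."""
        med = weighted_median(self.segments["copy"].to_numpy(), self.lengths)
        rows = []
        for chrom, sub in self.segments.groupby("chrom", sort=False):
            prev_end = None
            for row in sub.itertuples(index=False):
                if prev_end is not None and row.start > prev_end + 1:
                    rows.append((chrom, prev_end + 1, row.start - 1, med, False))
                rows.append(tuple(row))
                prev_end = row.end
        return SegmentProfile(self.sample, pd.DataFrame(rows, columns=SEGMENT_COLUMNS))

    def shifted(self, offset: float) -> "SegmentProfile":
        df = self.segments.copy()
        df["copy"] = np.maximum(df["copy"] + offset, 0.0)
        return SegmentProfile(self.sample, df)


@dataclass
class ArmCall:
    """Result of the segmental caller for one arm (or the 11q13.3 window)."""

    sample: str
    chrom: str
    arm: str  # "p", "q" or "11q13.3"
    direction: str  # "gain", "loss" or "none"
    window_median: float
    control_median: float
    sample_median: float
    window: tuple[int, int]
    flags: list[str] = field(default_factory=list)

    @property
    def is_call(self) -> bool:
        return self.direction != "none"


@dataclass
class PloidyCall:
    """Whole-chromosome gain classification for one sample."""

    sample: str
    n_whole_chrom_gains: int
    is_9plus: bool
    chrom_gained: dict[str, bool]
    arm_fractions: dict[tuple[str, str], float]


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Length-weighted median; averages the two straddling values at an exact tie."""
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    order = np.argsort(values, kind="mergesort")
    values, weights = values[order], weights[order]
    cum = np.cumsum(weights)
    half = 0.5 * cum[-1]
    idx = int(np.searchsorted(cum, half))
    if idx + 1 < len(values) and abs(cum[idx] - half) < 1e-9 * cum[-1]:
        return float(0.5 * (values[idx] + values[idx + 1]))
    return float(values[min(idx, len(values) - 1)])


def recenter_profile(
    profile: SegmentProfile,
    min_weight_fraction: float = 0.05,
    cluster_gap: float = 0.25,
) -> tuple[SegmentProfile, float]:
    """Shift a profile so its presumed-diploid level sits at copy 2.0.

    Non-LOH segment copy levels are clustered (levels closer than
    ``cluster_gap`` merge, so measurement noise around one biological level
    forms a single cluster); the baseline is the length-weighted center of
    the *lowest* cluster carrying at least ``min_weight_fraction`` of the
    non-LOH genomic length, and is shifted to 2.0.  LOH segments are
    excluded: in off-center profiles the presumed haploid and triploid
    levels obligately carry LOH.  Offsets smaller than half the cluster gap
    are treated as 0, which makes the operation idempotent.
    """
    nonloh = profile.segments[~profile.segments["loh"]]
    if nonloh.empty:
        raise UncenterableProfileError(
            f"sample {profile.sample}: every segment carries LOH; cannot anchor a diploid baseline"
        )
    lengths = (nonloh["end"] - nonloh["start"] + 1).to_numpy(float)
    copies = nonloh["copy"].to_numpy()
    order = np.argsort(copies, kind="mergesort")
    copies, lengths = copies[order], lengths[order]
    # greedy 1-d clustering over sorted levels
    clusters: list[tuple[float, float]] = []  # (weighted center, weight)
    c_start = 0
    for i in range(1, len(copies) + 1):
        if i == len(copies) or copies[i] - copies[i - 1] >= cluster_gap:
            w = lengths[c_start:i].sum()
            center = float(np.average(copies[c_start:i], weights=lengths[c_start:i]))
            clusters.append((center, w))
            c_start = i
    total = lengths.sum()
    eligible = [c for c, w in clusters if w >= min_weight_fraction * total]
    baseline = min(eligible) if eligible else max(clusters, key=lambda cw: cw[1])[0]
    offset = 2.0 - baseline
    if abs(offset) < cluster_gap / 2.0:
        return profile, 0.0
    return profile.shifted(offset), offset


def sample_copy_grid(
    profile: SegmentProfile,
    chrom: str,
    window: tuple[int, int],
    step: int = GRID_STEP_BP,
    anchor: str = "start",
) -> np.ndarray:
    """Copy levels sampled every ``step`` bp across ``window`` (1-based inclusive).

    ``anchor`` selects which end of the window the grid starts from ("start"
    steps right, "end" steps left), so the arm terminus is always sampled.
    Positions without segment coverage are dropped.  Raises if the window
    lies entirely outside the profile's extent on that chromosome.
    """
    start, end = window
    if start > end:
        raise ValueError("window start > end")
    if anchor == "start":
        positions = np.arange(start, end + 1, step, dtype=np.int64)
    elif anchor == "end":
        positions = np.arange(end, start - 1, -step, dtype=np.int64)[::-1]
    else:
        raise ValueError("anchor must be 'start' or 'end'")
    values = profile.copy_at(chrom, positions)
    sub = profile.segments[profile.segments["chrom"] == chrom]
    if sub.empty or end < sub["start"].min() or start > sub["end"].max():
        raise ValueError(
            f"window {window} on chromosome {chrom} outside profile extent for {profile.sample}"
        )
    return values[~np.isnan(values)]


def _arm_window(arm: Arm, window_bp: int, acro_window_bp: int) -> tuple[int, int]:
    """Terminal query window of an arm, anchored at the telomeric terminus."""
    span = acro_window_bp if (arm.acrocentric and arm.name == "q") else window_bp
    span = min(span, arm.length - 1)
    if arm.terminus == "start":
        return (arm.start, arm.start + span)
    return (arm.end - span, arm.end)


def _arm_grid(profile: SegmentProfile, arm: Arm, step: int) -> np.ndarray:
    return sample_copy_grid(profile, arm.chrom, (arm.start, arm.end), step, anchor=arm.terminus)


def autosomal_median_copy(profile: SegmentProfile, genome: Genome, step: int = GRID_STEP_BP) -> float:
    """Sample median copy over the 250 kb grid of every autosomal arm with data."""
    values = []
    for arm in genome.arms():
        if arm.chrom not in profile.chromosomes:
            continue
        try:
            values.append(_arm_grid(profile, arm, step))
        except ValueError:
            continue
    if not values:
        raise ValueError(f"sample {profile.sample}: no autosomal arm data")
    return float(np.median(np.concatenate(values)))


def call_arm_alteration(
    profile: SegmentProfile,
    chrom: str,
    arm_name: str,
    genome: Genome,
    sample_median: float | None = None,
    window_bp: int = ARM_WINDOW_BP,
    acro_window_bp: int = ACROCENTRIC_WINDOW_BP,
    step: int = GRID_STEP_BP,
) -> ArmCall:
    """Segmental gain/loss call for one arm; expects a recentered profile."""
    spec = genome[chrom]
    arm = spec.p if arm_name == "p" else spec.q
    opposing = spec.q if arm_name == "p" else spec.p
    if sample_median is None:
        sample_median = autosomal_median_copy(profile, genome, step)

    window = _arm_window(arm, window_bp, acro_window_bp)
    grid = sample_copy_grid(profile, chrom, window, step, anchor=arm.terminus)
    window_median = float(np.median(grid))

    flags: list[str] = []
    try:
        control_grid = _arm_grid(profile, opposing, step)
        control_median = float(np.median(control_grid))
    except ValueError:
        control_median = math.nan
        flags.append("no_control")

    direction = "none"
    if not math.isnan(control_median):
        if window_median >= GAIN_MEDIAN_MIN and control_median <= window_median - CONTROL_DELTA:
            direction = "gain"
        elif (
            window_median <= sample_median - LOSS_DELTA
            and control_median >= window_median + CONTROL_DELTA
        ):
            direction = "loss"
    return ArmCall(
        sample=profile.sample,
        chrom=chrom,
        arm=arm_name,
        direction=direction,
        window_median=window_median,
        control_median=control_median,
        sample_median=sample_median,
        window=window,
        flags=flags,
    )


def call_11q13_gain(
    profile: SegmentProfile,
    genome: Genome | None = None,
    sample_median: float | None = None,
    step: int = GRID_STEP_BP,
) -> ArmCall:
    """Hotspot 11q13.3 gain call (GRCh37 window 68.5–69.5 Mb, control = terminal 30 Mb of 11q)."""
    if genome is None:
        genome = make_genome_spec("grch37-arms")
    chrom, start, end = REGION_11Q13
    if chrom not in genome:
        raise ValueError("chromosome 11 absent from genome spec")
    if sample_median is None:
        sample_median = autosomal_median_copy(profile, genome, step)
    q = genome[chrom].q
    grid = sample_copy_grid(profile, chrom, (start, end), step, anchor="start")
    window_median = float(np.median(grid))
    control_window = (q.end - ARM_WINDOW_BP, q.end)
    control = sample_copy_grid(profile, chrom, control_window, step, anchor="end")
    control_median = float(np.median(control))
    direction = (
        "gain"
        if window_median >= GAIN_MEDIAN_MIN and control_median <= window_median - CONTROL_DELTA
        else "none"
    )
    return ArmCall(
        sample=profile.sample,
        chrom=chrom,
        arm="11q13.3",
        direction=direction,
        window_median=window_median,
        control_median=control_median,
        sample_median=sample_median,
        window=(start, end),
    )


def classify_9plus_wc(
    profile: SegmentProfile,
    genome: Genome,
    step: int = GRID_STEP_BP,
    copy_min: float = WC_ARM_COPY_MIN,
    arm_fraction: float = WC_ARM_FRACTION,
    min_chroms: int = WC_MIN_CHROMS,
) -> PloidyCall:
    """Count whole-chromosome gains; a sample with >= 9 is classed 9+ WC gain."""
    arm_fractions: dict[tuple[str, str], float] = {}
    chrom_gained: dict[str, bool] = {}
    for spec in genome:
        gained_arms = []
        for arm in spec.arms:
            if arm.chrom not in profile.chromosomes:
                gained_arms.append(False)
                continue
            try:
                grid = _arm_grid(profile, arm, step)
            except ValueError:
                gained_arms.append(False)
                continue
            frac = float(np.mean(grid >= copy_min)) if grid.size else 0.0
            arm_fractions[(spec.name, arm.name)] = frac
            gained_arms.append(frac >= arm_fraction)
        chrom_gained[spec.name] = all(gained_arms) and len(gained_arms) == 2
    n = sum(chrom_gained.values())
    return PloidyCall(
        sample=profile.sample,
        n_whole_chrom_gains=n,
        is_9plus=n >= min_chroms,
        chrom_gained=chrom_gained,
        arm_fractions=arm_fractions,
    )


def focal_amplification(
    profile: SegmentProfile,
    locus: tuple[str, int, int],
    log2fc_threshold: float = 2.0,
) -> tuple[bool, float]:
    """Focal amplification test at a locus: any overlapping segment with
    log2(copy / 2) strictly above the threshold (> ~8 copies at the default)."""
    chrom, start, end = locus
    sub = profile.segments
    hit = sub[(sub["chrom"] == chrom) & (sub["start"] <= end) & (sub["end"] >= start)]
    if hit.empty:
        raise EmptyOverlapError(f"locus {locus} overlaps no segment in sample {profile.sample}")
    max_copy = float(hit["copy"].max())
    cutoff = 2.0 * 2.0**log2fc_threshold
    return max_copy > cutoff, max_copy


def call_all_arms(
    profile: SegmentProfile,
    genome: Genome,
    include_11q13: bool | None = None,
    window_bp: int = ARM_WINDOW_BP,
    acro_window_bp: int = ACROCENTRIC_WINDOW_BP,
    step: int = GRID_STEP_BP,
) -> tuple[list[ArmCall], PloidyCall]:
    """Run the segmental caller over every autosomal arm (plus 11q13.3 on
    GRCh37 genomes) and the whole-chromosome classifier.  Expects a
    recentered profile."""
    sample_median = autosomal_median_copy(profile, genome, step)
    calls: list[ArmCall] = []
    for spec in genome:
        if spec.name not in profile.chromosomes:
            continue
        for arm_name in ("p", "q"):
            calls.append(
                call_arm_alteration(
                    profile, spec.name, arm_name, genome,
                    sample_median=sample_median,
                    window_bp=window_bp, acro_window_bp=acro_window_bp, step=step,
                )
            )
    if include_11q13 is None:
        include_11q13 = genome.mode == "grch37-arms"
    if include_11q13 and "11" in genome and "11" in profile.chromosomes:
        calls.append(call_11q13_gain(profile, genome, sample_median=sample_median, step=step))
    ploidy = classify_9plus_wc(profile, genome, step=step)
    return calls, ploidy


def arm_calls_table(calls: list[ArmCall]) -> pd.DataFrame:
    """Tidy table of arm calls (one row per arm queried)."""
    return pd.DataFrame(
        {
            "sample": [c.sample for c in calls],
            "chrom": [c.chrom for c in calls],
            "arm": [c.arm for c in calls],
            "direction": [c.direction for c in calls],
            "window_median": [c.window_median for c in calls],
            "control_median": [c.control_median for c in calls],
            "sample_median": [c.sample_median for c in calls],
            "window_start": [c.window[0] for c in calls],
            "window_end": [c.window[1] for c in calls],
            "flags": [";".join(c.flags) for c in calls],
        }
    )
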