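"""Synthetic tumor-cohort generator with full ground truth.

Generates cohorts of neuroblastoma-like tumor samples — copy-number segment
profiles, SNV catalogs, SV breakpoints and clinical metadata — with every
generated event recorded in a truth bundle, so the downstream callers and
statistics can be validated without access to controlled patient data.

What is emulated
----------------
* Segment profiles on the 22 GRCh37 autosomes: terminal arm-level gains and
  losses (17q gain, 1p/11q deletion), the 11q13.3 hotspot gain, focal MYCN
  amplification, whole-chromosome gains (hyperdiploid samples gain 9–14
  chromosomes), per-segment Gaussian noise and an optional global
  ploidy-centering offset that exercises recentering.
* SNV catalogs drawn from mixtures of signature spectra.  Each mutation's
  96-class context comes from its true signature; its position is uniform
  over the genome; in 3-copy regions a pre-gain mutation lands on the
  duplicated chromosome (multiplicity 2) with probability 1/2, a post-gain
  mutation always has multiplicity 1; the observed alt-read count is
  Binomial(depth, expected VAF) under the purity/copy-state model.
* SV records: translocations that directly join CNA termini (so the
  independence filter has something to catch), multi-hop chains with
  configurable spacing, the t(11;17) hotspot, and background noise SVs.
* Metadata with age-group-dependent alteration prevalences (MYCN enriched
  in the younger groups, ATRX in the oldest), purity, stage and
  diagnosis/relapse status.

A single global seed drives independent per-sample substreams
(``numpy.random.SeedSequence.spawn``), so enlarging the cohort never
perturbs earlier samples and identical seeds give identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .copy_number import SEGMENT_COLUMNS, SegmentProfile
from .genome import Genome, make_genome_spec
from .signatures import CONTEXT_CLASSES, SignatureMatrix
from .sv_integration import SvRecord
from .synthetic_signatures import synthetic_signature_matrix
from .timing_clonality import expected_vaf

MYCN_LOCUS = ("2", 16_080_000, 16_088_000)
ALK_F1174_POS = ("2", 29_443_695)
AGE_GROUPS = ("A", "B", "C")

# chromosomes reserved for targeted arm/focal events; whole-chromosome gains
# are drawn from the remaining autosomes so events never contradict
_RESERVED_CHROMS = {"1", "2", "11", "17"}


@dataclass(frozen=True)
class CopyEvent:
    """One copy-number event to inject into a profile.

    kinds: ``arm_gain`` / ``arm_loss`` (terminal window of ``chrom``/``arm``,
    ``length_bp`` long), ``wc_gain`` (whole chromosome), ``region`` (explicit
    start/end).
    """

    kind: str
    chrom: str
    arm: str | None = None
    copy: float = 3.0
    loh: bool = False
    start: int | None = None
    end: int | None = None
    length_bp: int | None = None


DEFAULT_ARM_EVENT_BP = 45_000_000


def _event_interval(event: CopyEvent, genome: Genome) -> tuple[int, int]:
    spec = genome[event.chrom]
    if event.kind == "wc_gain":
        return (1, spec.length)
    if event.kind == "region":
        if event.start is None or event.end is None:
            raise ValueError("region event needs explicit start/end")
        return (event.start, event.end)
    if event.kind in ("arm_gain", "arm_loss"):
        arm = spec.p if event.arm == "p" else spec.q
        span = min(event.length_bp or DEFAULT_ARM_EVENT_BP, arm.length)
        if arm.terminus == "start":
            return (arm.start, arm.start + span - 1)
        return (arm.end - span + 1, arm.end)
    raise ValueError(f"unknown event kind {event.kind!r}")


def simulate_copy_profile(
    genome: Genome,
    events: Sequence[CopyEvent],
    sample: str = "sim",
    centering_offset: float = 0.0,
    noise_sd: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[SegmentProfile, SegmentProfile]:
    """Build a segment profile carrying the requested events.

    Returns ``(observed, clean)``: the observed profile has per-segment
    Gaussian noise and the centering offset applied; the clean profile holds
    the exact generating copy levels (used as SNV ground truth).  Segments
    tile each chromosome without gaps or overlaps.  Overlapping events with
    different copy levels on one chromosome are rejected.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for event in events:
        if event.chrom not in genome:
            raise ValueError(f"event references unknown chromosome {event.chrom}")

    per_chrom: dict[str, list[tuple[int, int, float, bool]]] = {c.name: [] for c in genome}
    for event in events:
        start, end = _event_interval(event, genome)
        spec = genome[event.chrom]
        if not (1 <= start <= end <= spec.length):
            raise ValueError(f"event window {start}-{end} outside chromosome {event.chrom}")
        for s, e, c, _ in per_chrom[event.chrom]:
            if start <= e and end >= s and c != event.copy:
                raise ValueError(
                    f"contradictory overlapping events on chromosome {event.chrom}"
                )
        per_chrom[event.chrom].append((start, end, event.copy, event.loh))

    rows = []
    for spec in genome:
        intervals = sorted(per_chrom[spec.name])
        cursor = 1
        for s, e, c, loh in intervals:
            if s > cursor:
                rows.append((spec.name, cursor, s - 1, 2.0, False))
            rows.append((spec.name, s, e, c, loh))
            cursor = e + 1
        if cursor <= spec.length:
            rows.append((spec.name, cursor, spec.length, 2.0, False))

    clean = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    noisy = clean.copy()
    noisy["copy"] = np.maximum(
        noisy["copy"] + rng.normal(0.0, noise_sd, size=len(noisy)) + centering_offset, 0.0
    )
    return SegmentProfile(sample, noisy), SegmentProfile(sample, clean)


def _parse_context(label: str) -> tuple[str, str, str, str]:
    # "T[C>A]A" -> (ref, alt, left, right)
    return label[2], label[4], label[0], label[6]


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def simulate_snvs(
    exposures: Mapping[str, int],
    signatures: SignatureMatrix,
    profile: SegmentProfile,
    purity: float,
    fraction_pre_gain: float,
    depth: int,
    seed: int | np.random.Generator = 0,
    sample: str = "sim",
) -> pd.DataFrame:
    """Draw a sample's SNV catalog from a signature mixture.

    Returns one table holding both the observable record (chrom, pos,
    ref/alt with flanks on a random strand, context96, alt_reads, depth,
    vaf) and the ground truth per mutation (true_signature, multiplicity,
    pre_gain, local_copies, expected_vaf).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    unknown = set(exposures) - set(signatures.names)
    if unknown:
        raise ValueError(f"exposure signatures absent from matrix: {sorted(unknown)}")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0.0 < purity <= 1.0):
        raise ValueError("purity must be in (0, 1]")

    chroms = profile.chromosomes
    chrom_len = np.array(
        [
            int(profile.segments.loc[profile.segments["chrom"] == c, "end"].max())
            for c in chroms
        ],
        dtype=np.int64,
    )
    chrom_p = chrom_len / chrom_len.sum()

    sig_blocks, ctx_blocks = [], []
    for sig_name in signatures.names:  # fixed iteration order for determinism
        n_k = int(exposures.get(sig_name, 0))
        if n_k < 0:
            raise ValueError("exposures must be non-negative")
        if n_k == 0:
            continue
        sig_blocks += [sig_name] * n_k
        ctx_blocks.append(rng.choice(96, size=n_k, p=signatures[sig_name].to_numpy()))
    n = len(sig_blocks)
    if n == 0:
        return pd.DataFrame()
    ctx_idx = np.concatenate(ctx_blocks)

    chrom_idx = rng.choice(len(chroms), size=n, p=chrom_p)
    pos = 1 + np.floor(rng.random(n) * chrom_len[chrom_idx]).astype(np.int64)
    local = np.full(n, np.nan)
    for ci, chrom in enumerate(chroms):
        mask = chrom_idx == ci
        if mask.any():
            local[mask] = profile.copy_at(chrom, pos[mask])
    copies = np.where(np.isfinite(local), np.round(local), 2.0).astype(int)
    copies = np.maximum(copies, 1)

    pre_draw = rng.random(n) < fraction_pre_gain
    dup_draw = rng.random(n) < 0.5
    in_3copy = copies == 3
    pre_gain = in_3copy & pre_draw
    mult = np.where(pre_gain & dup_draw, 2, 1)

    ev = mult * purity / (copies * purity + 2.0 * (1.0 - purity))
    alt_reads = rng.binomial(depth, ev)

    # precomputed per-class (ref, alt, left, right) and purine-strand forms
    pyr = np.array([_parse_context(c) for c in CONTEXT_CLASSES])
    pur = np.array(
        [
            [
                r.translate(_COMPLEMENT),
                a.translate(_COMPLEMENT),
                rt.translate(_COMPLEMENT),
                lf.translate(_COMPLEMENT),
            ]
            for r, a, lf, rt in pyr
        ]
    )
    flip = rng.random(n) < 0.5
    bases = np.where(flip[:, None], pur[ctx_idx], pyr[ctx_idx])

    return pd.DataFrame(
        {
            "sample": sample,
            "chrom": np.asarray(chroms, dtype=object)[chrom_idx],
            "pos": pos,
            "ref": bases[:, 0],
            "alt": bases[:, 1],
            "left": bases[:, 2],
            "right": bases[:, 3],
            "context96": np.asarray(CONTEXT_CLASSES, dtype=object)[ctx_idx],
            "alt_reads": alt_reads,
            "depth": depth,
            "vaf": alt_reads / depth,
            "driver": "",
            "true_signature": sig_blocks,
            "multiplicity": mult,
            "pre_gain": pre_gain,
            "local_copies": copies,
            "expected_vaf": ev,
        }
    )


@dataclass(frozen=True)
class SvPlanEntry:
    """One planned SV construct.

    kinds: ``direct_join`` (one SV within ``window`` of both boundaries),
    ``chain`` (boundary A -> via chromosome -> boundary B with a hop of
    ``spacing`` bp between consecutive breakpoints), ``hotspot_t11_17``,
    ``random`` (background noise SVs).
    """

    kind: str
    boundary_a: tuple[str, int] | None = None
    boundary_b: tuple[str, int] | None = None
    via_chrom: str | None = None
    via_pos: int | None = None
    spacing: int | None = None
    svtype: str = "translocation"
    n: int = 1


def simulate_svs(
    plan: Sequence[SvPlanEntry],
    sample: str = "sim",
    seed: int | np.random.Generator = 0,
    genome: Genome | None = None,
    window: int = 5_000,
) -> list[SvRecord]:
    """Emit SV records for a linkage plan (see :class:`SvPlanEntry`)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if genome is None:
        genome = make_genome_spec("grch37-arms")

    def jitter(pos: int) -> int:
        return max(1, pos + int(rng.integers(-window // 2, window // 2 + 1)))

    svs: list[SvRecord] = []
    for entry in plan:
        if entry.kind == "direct_join":
            (ca, pa), (cb, pb) = entry.boundary_a, entry.boundary_b
            svs.append(SvRecord(sample, ca, jitter(pa), cb, jitter(pb), entry.svtype))
        elif entry.kind == "chain":
            (ca, pa), (cb, pb) = entry.boundary_a, entry.boundary_b
            via_pos = entry.via_pos or 50_000_000
            spacing = entry.spacing or 10_000_000
            svs.append(
                SvRecord(sample, ca, jitter(pa), entry.via_chrom, via_pos, entry.svtype)
            )
            svs.append(
                SvRecord(
                    sample, entry.via_chrom, via_pos + spacing, cb, jitter(pb), entry.svtype
                )
            )
        elif entry.kind == "hotspot_t11_17":
            pos17 = entry.boundary_a[1] if entry.boundary_a else int(rng.integers(30_000_000, 81_000_000))
            pos11 = entry.boundary_b[1] if entry.boundary_b else int(rng.integers(60_000_000, 80_000_001))
            svs.append(SvRecord(sample, "17", jitter(pos17), "11", jitter(pos11), "translocation"))
        elif entry.kind == "random":
            names = genome.chromosomes
            for _ in range(entry.n):
                ca, cb = rng.choice(names, size=2, replace=True)
                pa = int(rng.integers(1, genome[str(ca)].length + 1))
                pb = int(rng.integers(1, genome[str(cb)].length + 1))
                if ca == cb and pa == pb:
                    pb += 1
                svtype = str(rng.choice(["deletion", "duplication", "inversion"]))
                svs.append(SvRecord(sample, str(ca), pa, str(cb), pb, svtype))
        else:
            raise ValueError(f"unknown SV plan kind {entry.kind!r}")
    return svs


DEFAULT_EVENT_PREVALENCES: dict[str, float | dict[str, float]] = {
    "MYCN_amp": {"A": 0.40, "B": 0.35, "C": 0.03},
    "ATRX": {"A": 0.0, "B": 0.07, "C": 0.45},
    "gain_17q": 0.55,
    "del_11q": {"A": 0.15, "B": 0.30, "C": 0.35},
    "del_1p": 0.25,
    "gain_11q13.3": 0.05,
    "t_11_17": 0.08,
    "wc_9plus": {"A": 0.65, "B": 0.50, "C": 0.35},
    "ALK_F1174L": 0.10,
}

DEFAULT_SIGNATURE_PRIORS: dict[str, tuple[int, int]] = {
    "SBS1": (30, 120),
    "SBS3": (0, 200),
    "SBS5": (80, 300),
    "SBS18": (100, 700),
}


@dataclass
class CohortConfig:
    """Study conditions of a simulated cohort; defaults give a
    neuroblastoma-like landscape (see docs/methods.md for rationale)."""

    n_samples: int = 60
    seed: int = 0
    purity_range: tuple[float, float] = (0.4, 1.0)
    age_distribution: dict[str, float] = field(
        default_factory=lambda: {"A": 0.30, "B": 0.47, "C": 0.23}
    )
    event_prevalences: dict[str, float | dict[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_PREVALENCES)
    )
    signature_mixture_priors: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURE_PRIORS)
    )
    coverage_depth: int = 60
    fraction_pre_gain: float = 0.5
    noise_sd: float = 0.05
    offset_prob: float = 0.25
    relapse_prob: float = 0.10
    stage4_prob: float = 0.50

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.coverage_depth < 1:
            raise ValueError("coverage_depth must be >= 1")
        if not (0.0 <= self.fraction_pre_gain <= 1.0):
            raise ValueError("fraction_pre_gain must be in [0, 1]")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("purity_range must satisfy 0 < lo <= hi <= 1")
        if set(self.age_distribution) != set(AGE_GROUPS):
            raise ValueError("age_distribution must have exactly the groups A, B, C")
        for name, prev in self.event_prevalences.items():
            vals = prev.values() if isinstance(prev, dict) else [prev]
            if not all(0.0 <= v <= 1.0 for v in vals):
                raise ValueError(f"prevalence for {name} outside [0, 1]")


def _prevalence(config: CohortConfig, name: str, group: str) -> float:
    prev = config.event_prevalences.get(name, 0.0)
    if isinstance(prev, dict):
        return float(prev.get(group, 0.0))
    return float(prev)


@dataclass
class Cohort:
    """Bundle of generated data plus complete ground truth."""

    config: CohortConfig
    genome: Genome
    profiles: dict[str, SegmentProfile]          # observed (noise + offset)
    clean_profiles: dict[str, SegmentProfile]    # generating truth
    snvs: pd.DataFrame                           # observable SNV columns + per-SNV truth
    svs: pd.DataFrame
    metadata: pd.DataFrame
    gene_events: pd.DataFrame                    # sample, alteration (SNV/SV gene level)
    truth: dict


def _draw_age(group: str, rng: np.random.Generator) -> float:
    if group == "A":
        return float(rng.uniform(0.05, 1.5))
    if group == "B":
        return float(rng.uniform(1.5, 5.0))
    return float(rng.uniform(5.0, 15.0))


def simulate_cohort(
    config: CohortConfig,
    signatures: SignatureMatrix | None = None,
) -> Cohort:
    """Generate a full cohort (profiles, SNVs, SVs, metadata, truth).

    Deterministic for a given config: per-sample RNG substreams are spawned
    from the single global seed.
    """
    genome = make_genome_spec("grch37-arms")
    if signatures is None:
        signatures = synthetic_signature_matrix()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_samples)

    groups = sorted(AGE_GROUPS)
    group_p = np.array([config.age_distribution[g] for g in groups], dtype=float)
    group_p = group_p / group_p.sum()

    profiles: dict[str, SegmentProfile] = {}
    clean_profiles: dict[str, SegmentProfile] = {}
    snv_frames: list[pd.DataFrame] = []
    sv_rows: list[SvRecord] = []
    meta_rows = []
    gene_rows = []
    truth: dict[str, dict] = {}

    wc_pool = sorted(set(genome.chromosomes) - _RESERVED_CHROMS, key=lambda c: int(c))

    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        sid = f"S{i + 1:04d}"
        group = groups[int(rng.choice(len(groups), p=group_p))]
        age = _draw_age(group, rng)
        purity = float(rng.uniform(*config.purity_range))
        timepoint = "relapse" if rng.random() < config.relapse_prob else "diagnosis"
        stage = 4 if rng.random() < config.stage4_prob else int(rng.choice([1, 2, 3]))

        has = {
            name: bool(rng.random() < _prevalence(config, name, group))
            for name in config.event_prevalences
        }
        if has.get("t_11_17"):
            has["gain_17q"] = True
            has["gain_11q13.3"] = True

        events: list[CopyEvent] = []
        event_names: list[str] = []
        wc_chroms: list[str] = []
        if has.get("wc_9plus"):
            n_wc = int(rng.integers(9, 15))
            wc_chroms = sorted(
                rng.choice(wc_pool, size=n_wc, replace=False).tolist(), key=lambda c: int(c)
            )
            events += [CopyEvent("wc_gain", c, copy=3.0) for c in wc_chroms]
            event_names.append("wc_9plus")
        if has.get("gain_17q"):
            events.append(CopyEvent("arm_gain", "17", arm="q", copy=3.0))
            event_names.append("gain_17q")
        if has.get("del_1p"):
            events.append(CopyEvent("arm_loss", "1", arm="p", copy=1.0, loh=True))
            event_names.append("del_1p")
        if has.get("del_11q"):
            q_end = genome["11"].length
            events.append(
                CopyEvent("region", "11", copy=1.0, loh=True, start=q_end - 45_000_000 + 1, end=q_end)
            )
            event_names.append("del_11q")
        if has.get("gain_11q13.3"):
            events.append(CopyEvent("region", "11", copy=4.0, start=67_500_000, end=70_500_000))
            event_names.append("gain_11q13.3")
        mycn_copy = None
        if has.get("MYCN_amp"):
            mycn_copy = float(rng.uniform(20.0, 60.0))
            events.append(
                CopyEvent("region", "2", copy=mycn_copy, start=MYCN_LOCUS[1], end=MYCN_LOCUS[2])
            )
            event_names.append("MYCN_amp")

        offset = 0.0
        if rng.random() < config.offset_prob:
            offset = float(rng.choice([-0.2, 0.3, 0.5, 0.7, 1.0]))

        observed, clean = simulate_copy_profile(
            genome, events, sample=sid, centering_offset=offset,
            noise_sd=config.noise_sd, seed=rng,
        )
        profiles[sid] = observed
        clean_profiles[sid] = clean

        exposures = {
            name: int(rng.integers(lo, hi + 1))
            for name, (lo, hi) in config.signature_mixture_priors.items()
        }
        snvs = simulate_snvs(
            exposures, signatures, clean, purity,
            config.fraction_pre_gain, config.coverage_depth, seed=rng, sample=sid,
        )

        if has.get("ALK_F1174L"):
            chrom, pos = ALK_F1174_POS
            local = clean.copy_at(chrom, np.array([pos]))[0]
            copies = max(int(round(local)) if np.isfinite(local) else 2, 1)
            ev = expected_vaf(purity, copies, 1)
            alt_reads = int(rng.binomial(config.coverage_depth, ev))
            driver_row = pd.DataFrame(
                [
                    {
                        "sample": sid, "chrom": chrom, "pos": pos,
                        "ref": "C", "alt": "A", "left": "T", "right": "A",
                        "context96": "T[C>A]A",
                        "alt_reads": alt_reads, "depth": config.coverage_depth,
                        "vaf": alt_reads / config.coverage_depth,
                        "driver": "ALK_F1174L",
                        "true_signature": "SBS18", "multiplicity": 1,
                        "pre_gain": False, "local_copies": copies, "expected_vaf": ev,
                    }
                ]
            )
            snvs = pd.concat([snvs, driver_row], ignore_index=True)
            gene_rows.append({"sample": sid, "alteration": "ALK_F1174L"})
            event_names.append("ALK_F1174L")
        if has.get("ATRX"):
            gene_rows.append({"sample": sid, "alteration": "ATRX"})
            event_names.append("ATRX")
        snv_frames.append(snvs)

        plan: list[SvPlanEntry] = []
        sv_truth: list[str] = []
        if has.get("t_11_17"):
            gain17_start = genome["17"].length - min(DEFAULT_ARM_EVENT_BP, genome["17"].q.length) + 1
            plan.append(
                SvPlanEntry(
                    "direct_join",
                    boundary_a=("17", gain17_start),
                    boundary_b=("11", 70_500_000),
                    svtype="translocation",
                )
            )
            sv_truth.append("t_11_17_join")
            event_names.append("t_11_17")
        if has.get("del_11q") and has.get("gain_17q") and rng.random() < 0.5:
            # unbalanced-translocation origin: 11q loss and 17q gain from one event
            gain17_start = genome["17"].length - min(DEFAULT_ARM_EVENT_BP, genome["17"].q.length) + 1
            del11_start = genome["11"].length - 45_000_000 + 1
            plan.append(
                SvPlanEntry(
                    "direct_join",
                    boundary_a=("11", del11_start),
                    boundary_b=("17", gain17_start),
                    svtype="translocation",
                )
            )
            sv_truth.append("unbalanced_11q_17q_join")
        n_background = int(rng.poisson(2))
        if n_background:
            plan.append(SvPlanEntry("random", n=n_background))
            sv_truth += ["background"] * n_background
        sample_svs = simulate_svs(plan, sample=sid, seed=rng, genome=genome)
        sv_rows += sample_svs

        meta_rows.append(
            {
                "sample": sid,
                "age_years": age,
                "age_group": group,
                "purity": purity,
                "timepoint": timepoint,
                "stage": stage,
            }
        )
        truth[sid] = {
            "age_years": age,
            "age_group": group,
            "purity": purity,
            "centering_offset": offset,
            "events": sorted(event_names),
            "wc_chromosomes": wc_chroms,
            "mycn_copy": mycn_copy,
            "exposures": exposures,
            "n_snvs": int(len(snvs)),
            "svs": sv_truth,
            "fraction_pre_gain": config.fraction_pre_gain,
        }

    snvs_all = (
        pd.concat(snv_frames, ignore_index=True)
        if snv_frames
        else pd.DataFrame()
    )
    svs_all = pd.DataFrame(
        [
            {
                "sample": sv.sample,
                "chrom_a": sv.chrom_a,
                "pos_a": sv.pos_a,
                "chrom_b": sv.chrom_b,
                "pos_b": sv.pos_b,
                "svtype": sv.svtype,
            }
            for sv in sv_rows
        ],
        columns=["sample", "chrom_a", "pos_a", "chrom_b", "pos_b", "svtype"],
    )
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    gene_events = pd.DataFrame(gene_rows, columns=["sample", "alteration"])
    return Cohort(
        config=config,
        genome=genome,
        profiles=profiles,
        clean_profiles=clean_profiles,
        snvs=snvs_all,
        svs=svs_all,
        metadata=metadata,
        gene_events=gene_events,
        truth=truth,
    )


SNV_OUTPUT_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt", "left", "right",
    "context96", "alt_reads", "depth", "driver",
]


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write the cohort in the standard plain-text formats.

    segments.tsv (sample, chrom, start, end, copy, loh; 1-based inclusive),
    snvs.tsv, svs.tsv (BEDPE-like), metadata.tsv, gene_events.tsv and
    truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seg_rows = []
    for sid, profile in cohort.profiles.items():
        df = profile.segments.copy()
        df.insert(0, "sample", sid)
        seg_rows.append(df)
    pd.concat(seg_rows, ignore_index=True).to_csv(outdir / "segments.tsv", sep="\t", index=False)
    cohort.snvs[SNV_OUTPUT_COLUMNS].to_csv(outdir / "snvs.tsv", sep="\t", index=False)
    cohort.svs.to_csv(outdir / "svs.tsv", sep="\t", index=False)
    cohort.metadata.to_csv(outdir / "metadata.tsv", sep="\t")
    cohort.gene_events.to_csv(outdir / "gene_events.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
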