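"""End-to-end cohort analysis: profiles + SNVs + SVs + metadata in,
alteration matrix, co-occurrence, age associations, signature exposures and
copy-gain timing out.

This is plumbing over the analysis modules; each step delegates to the
module that owns it.  Alteration names emitted by the copy-number stage
match the generator's event names (``gain_17q``, ``del_1p``, ``del_11q``,
``gain_11q13.3``, ``MYCN_amp``, ``wc_9plus``, ``t_11_17``) so simulated
cohorts round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import association_stats as assoc
from .copy_number import (
    ArmCall,
    PloidyCall,
    SegmentProfile,
    arm_calls_table,
    call_all_arms,
    EmptyOverlapError,
    focal_amplification,
    recenter_profile,
)
from .genome import Genome
from .signatures import SignatureMatrix, build_spectrum, refit_exposures, ExposureVector
from .sv_integration import (
    Alteration,
    SvRecord,
    build_linkage_graph,
    classify_t11_17,
    linked_lookup,
    svs_from_table,
)
from .synthetic_cohort import MYCN_LOCUS
from .timing_clonality import TimingResult, timing_fraction

FORCED_SIGNATURES = ("SBS1", "SBS3", "SBS5")


@dataclass
class SampleAnalysis:
    sample: str
    offset: float
    arm_calls: list[ArmCall]
    ploidy: PloidyCall
    alterations: list[str]
    linkage_graph: nx.Graph
    timing: TimingResult | None
    exposures: ExposureVector | None


@dataclass
class CohortAnalysis:
    samples: dict[str, SampleAnalysis]
    arm_calls: pd.DataFrame
    matrix: assoc.AlterationMatrix
    pair_tests: pd.DataFrame
    timing: pd.DataFrame
    exposures: pd.DataFrame
    dropped_alterations: list[str] = field(default_factory=list)


def _call_to_name(call: ArmCall) -> str | None:
    if call.arm == "11q13.3":
        return "gain_11q13.3" if call.direction == "gain" else None
    if call.direction == "none":
        return None
    prefix = "gain" if call.direction == "gain" else "del"
    return f"{prefix}_{call.chrom}{call.arm}"


def _cna_boundaries(
    profile: SegmentProfile, call: ArmCall, min_dev: float = 0.25
) -> tuple[tuple[str, int], ...]:
    """Boundary points of the altered segments inside a called window."""
    start, end = call.window
    sub = profile.segments
    sub = sub[
        (sub["chrom"] == call.chrom)
        & (sub["start"] <= end)
        & (sub["end"] >= start)
        & ((sub["copy"] - 2.0).abs() >= min_dev)
    ]
    points = []
    for row in sub.itertuples(index=False):
        points.append((call.chrom, int(row.start)))
        points.append((call.chrom, int(row.end)))
    return tuple(points)


def analyze_sample(
    profile: SegmentProfile,
    genome: Genome,
    svs: list[SvRecord],
    snvs: pd.DataFrame,
    purity: float,
    signatures: SignatureMatrix | None = None,
    gene_alterations: tuple[str, ...] = (),
) -> SampleAnalysis:
    """Recenter one profile, call alterations, build the linkage graph,
    fit signatures and time copy gains."""
    recentered, offset = recenter_profile(profile)
    arm_calls, ploidy = call_all_arms(recentered, genome)

    alterations: list[str] = list(gene_alterations)
    alt_objects: list[Alteration] = []
    for call in arm_calls:
        name = _call_to_name(call)
        if name is None:
            continue
        alterations.append(name)
        alt_objects.append(Alteration(name, _cna_boundaries(recentered, call)))
    if ploidy.is_9plus:
        alterations.append("wc_9plus")

    try:
        amplified, _ = focal_amplification(recentered, MYCN_LOCUS)
    except EmptyOverlapError:
        amplified = False
    if amplified:
        name = "MYCN_amp"
        alterations.append(name)
        sub = recentered.segments
        hit = sub[
            (sub["chrom"] == MYCN_LOCUS[0])
            & (sub["start"] <= MYCN_LOCUS[2])
            & (sub["end"] >= MYCN_LOCUS[1])
            & (sub["copy"] > 8.0)
        ]
        bounds = tuple(
            pt for row in hit.itertuples(index=False)
            for pt in ((MYCN_LOCUS[0], int(row.start)), (MYCN_LOCUS[0], int(row.end)))
        )
        alt_objects.append(Alteration(name, bounds))

    translocs = [
        sv for sv in svs if sv.svtype == "translocation" and classify_t11_17(sv)
    ]
    if translocs:
        alterations.append("t_11_17")
        bounds = tuple(bp for sv in translocs for bp in sv.breakpoints)
        alt_objects.append(Alteration("t_11_17", bounds))

    graph = build_linkage_graph(svs, alt_objects)

    timing = None
    exposures = None
    if snvs is not None and not snvs.empty:
        three_copy = _snvs_in_3copy_regions(recentered, snvs)
        timing = timing_fraction(three_copy["vaf"], purity, sample=profile.sample)
        if signatures is not None:
            spectrum, _ = build_spectrum(snvs, sample=profile.sample)
            forced = tuple(s for s in FORCED_SIGNATURES if s in signatures.names)
            exposures = refit_exposures(spectrum, signatures, forced=forced)

    return SampleAnalysis(
        sample=profile.sample,
        offset=offset,
        arm_calls=arm_calls,
        ploidy=ploidy,
        alterations=sorted(set(alterations)),
        linkage_graph=graph,
        timing=timing,
        exposures=exposures,
    )


def _snvs_in_3copy_regions(profile: SegmentProfile, snvs: pd.DataFrame) -> pd.DataFrame:
    """Subset of a sample's SNVs lying in segments called at copy 3 (rounded)."""
    if snvs.empty:
        return snvs
    copies = np.concatenate(
        [
            profile.copy_at(chrom, sub["pos"].to_numpy())
            for chrom, sub in snvs.groupby("chrom", sort=False)
        ]
    )
    order = np.concatenate(
        [sub.index.to_numpy() for _, sub in snvs.groupby("chrom", sort=False)]
    )
    rounded = pd.Series(np.round(copies), index=order).reindex(snvs.index)
    return snvs[rounded == 3]


def run_cohort_analysis(
    profiles: dict[str, SegmentProfile],
    snvs: pd.DataFrame,
    svs: pd.DataFrame,
    metadata: pd.DataFrame,
    genome: Genome,
    signatures: SignatureMatrix | None = None,
    gene_events: pd.DataFrame | None = None,
    min_recurrence: int = assoc.MIN_RECURRENCE,
    stage4_only: bool = False,
) -> CohortAnalysis:
    """Analyze a whole cohort and run the cross-sample statistics."""
    sv_records = svs_from_table(svs) if not svs.empty else []
    svs_by_sample: dict[str, list[SvRecord]] = {}
    for sv in sv_records:
        svs_by_sample.setdefault(sv.sample, []).append(sv)
    gene_by_sample: dict[str, tuple[str, ...]] = {}
    if gene_events is not None and not gene_events.empty:
        for sid, sub in gene_events.groupby("sample"):
            gene_by_sample[str(sid)] = tuple(sub["alteration"])

    analyses: dict[str, SampleAnalysis] = {}
    event_rows = []
    for sid, profile in profiles.items():
        sample_snvs = snvs[snvs["sample"] == sid] if not snvs.empty else pd.DataFrame()
        purity = float(metadata.loc[sid, "purity"])
        analysis = analyze_sample(
            profile,
            genome,
            svs_by_sample.get(sid, []),
            sample_snvs,
            purity,
            signatures=signatures,
            gene_alterations=gene_by_sample.get(sid, ()),
        )
        analyses[sid] = analysis
        event_rows += [{"sample": sid, "alteration": a} for a in analysis.alterations]

    events = pd.DataFrame(event_rows, columns=["sample", "alteration"])
    matrix = assoc.build_alteration_matrix(
        events, metadata, min_recurrence=min_recurrence, stage4_only=stage4_only
    )
    graphs = {sid: a.linkage_graph for sid, a in analyses.items()}
    pair_results = assoc.pairwise_fisher(matrix, linked=linked_lookup(graphs))

    timing_df = pd.DataFrame(
        [
            {
                "sample": sid,
                "n_3copy_snvs": a.timing.n_3copy_snvs,
                "fraction_single_allele": a.timing.fraction_single_allele,
                "cutoff_used": a.timing.cutoff_used,
                "purity": a.timing.purity,
                "eligible": a.timing.eligible,
                "gain_early": a.timing.gain_early,
                "pre_gain_fraction": a.timing.pre_gain_fraction,
            }
            for sid, a in analyses.items()
            if a.timing is not None
        ]
    )
    expo_rows = []
    for sid, a in analyses.items():
        if a.exposures is None:
            continue
        row = {"sample": sid, "reconstruction_cosine": a.exposures.reconstruction_cosine}
        row.update({k: float(v) for k, v in a.exposures.exposures.items()})
        expo_rows.append(row)

    return CohortAnalysis(
        samples=analyses,
        arm_calls=pd.concat(
            [arm_calls_table(a.arm_calls) for a in analyses.values()], ignore_index=True
        ),
        matrix=matrix,
        pair_tests=assoc.pair_tests_table(pair_results),
        timing=timing_df,
        exposures=pd.DataFrame(expo_rows),
        dropped_alterations=matrix.dropped,
    )
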