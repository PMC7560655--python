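"""Purity-adjusted VAF model, copy-gain timing and clonality classification.

For a mutation on ``m`` of ``T`` tumor copies in a specimen of purity ``rho``
(tumor-cell fraction), with ``N`` copies in admixed normal cells (2 for an
autosomal locus), the expected variant allele fraction is

    E[VAF] = m * rho / (T * rho + N * (1 - rho))

At purity 1 this reduces to m/T: 1/3 (0.33) and 2/3 (0.67) for single- and
double-copy mutations in a trisomic (3-copy) region.  The midpoint of those
two expectations is the cutoff separating single-allele (VAF <= cutoff,
inclusive) from multi-allele mutations; it equals 0.5 at purity 1.

Timing of a single-copy gain from its 3-copy mutations assumes mutations
accrue at an equal per-copy rate before and after the gain.  A pre-gain
mutation sits on the duplicated chromosome with probability 1/2 (then on 2
of 3 copies) and on the non-duplicated one otherwise; every post-gain
mutation sits on 1 of 3 copies.  Writing ``f`` for the fraction of 3-copy
mutations that predate the gain, the expected single-allele fraction is
``1 - f/2``: 50% when every mutation predates the gain (f = 1), 75% when the
molecular time before and after the gain is equal (f = 1/2).  A sample whose
observed single-allele fraction exceeds 75% therefore acquired its gain
earlier than the majority of its point mutations ("gain_early").  Samples
are eligible for timing only at purity >= 70% and with >= 20 mutations in
autosomal 3-copy regions.

Clonality of an individual mutation is classified against 0.8x the expected
clonal VAF for its copy state (at the default this reproduces the VAF > 0.4
rule for clonal mutations in 2- or 4-copy regions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

MIN_TIMING_PURITY = 0.70
MIN_TIMING_SNVS = 20
GAIN_EARLY_THRESHOLD = 0.75


@dataclass(frozen=True)
class VafModelInput:
    """Inputs of the expected-VAF mixture model."""

    purity: float
    tumor_total_copies: int
    mutated_copies: int
    normal_total_copies: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must be in (0, 1]")
        if self.tumor_total_copies < 1:
            raise ValueError("tumor copy number must be >= 1")
        if not (1 <= self.mutated_copies <= self.tumor_total_copies):
            raise ValueError("mutated copies must be in 1..tumor total copies")
        if self.normal_total_copies < 0:
            raise ValueError("normal copy number must be >= 0")


@dataclass
class TimingResult:
    """Per-sample copy-gain timing summary."""

    sample: str
    n_3copy_snvs: int
    fraction_single_allele: float
    cutoff_used: float
    purity: float
    eligible: bool
    gain_early: bool | None
    pre_gain_fraction: float | None


def expected_vaf(
    purity: float,
    tumor_total_copies: int = 3,
    mutated_copies: int = 1,
    normal_total_copies: int = 2,
) -> float:
    """Expected VAF under the purity/copy-state mixture model (see module docstring)."""
    inp = VafModelInput(purity, tumor_total_copies, mutated_copies, normal_total_copies)
    return (
        inp.mutated_copies
        * inp.purity
        / (inp.tumor_total_copies * inp.purity + inp.normal_total_copies * (1.0 - inp.purity))
    )


def vaf_cutoff(purity: float, tumor_total_copies: int = 3) -> float:
    """Midpoint of the 1-copy and 2-copy expected VAFs: the single- vs
    multi-allele boundary (0.5 at purity 1)."""
    lo = expected_vaf(purity, tumor_total_copies, 1)
    hi = expected_vaf(purity, tumor_total_copies, 2)
    return 0.5 * (lo + hi)


def classify_multiplicity(vaf: float, purity: float, tumor_total_copies: int = 3) -> str:
    """``single_allele`` iff VAF <= cutoff (inclusive), else ``multi_allele``."""
    if not (0.0 <= vaf <= 1.0):
        raise ValueError("VAF must be in [0, 1]")
    return "single_allele" if vaf <= vaf_cutoff(purity, tumor_total_copies) else "multi_allele"


def expected_single_allele_fraction(fraction_pre_gain: float) -> float:
    """Expected single-allele fraction among 3-copy mutations when a
    fraction ``f`` of them predates the gain: 1 - f/2."""
    if not (0.0 <= fraction_pre_gain <= 1.0):
        raise ValueError("fraction_pre_gain must be in [0, 1]")
    return 1.0 - fraction_pre_gain / 2.0


def pre_gain_fraction_estimate(fraction_single_allele: float) -> float:
    """Invert the timing model: estimate the pre-gain mutation fraction as
    2 * (1 - single-allele fraction), clipped to [0, 1].

    Single-allele fractions below 0.5 violate the model (they would imply a
    pre-gain fraction above 1) and are clipped with a warning.
    """
    if not (0.0 <= fraction_single_allele <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    if fraction_single_allele < 0.5:
        warnings.warn(
            "single-allele fraction below 0.5 violates the timing model; clipping to 1.0",
            stacklevel=2,
        )
        return 1.0
    return min(1.0, max(0.0, 2.0 * (1.0 - fraction_single_allele)))


def timing_fraction(
    vafs,
    purity: float,
    sample: str = "",
    min_purity: float = MIN_TIMING_PURITY,
    min_snvs: int = MIN_TIMING_SNVS,
) -> TimingResult:
    """Time a copy gain from the VAFs of a sample's mutations in 3-copy regions.

    ``vafs`` must already be restricted to autosomal 3-copy segments.
    Ineligible samples (purity < ``min_purity`` or fewer than ``min_snvs``
    mutations) are flagged, not rejected; their gain_early call is None.
    """
    vafs = np.asarray(list(vafs), dtype=float)
    n = int(vafs.size)
    cutoff = vaf_cutoff(purity)
    frac = float(np.mean(vafs <= cutoff)) if n else float("nan")
    eligible = purity >= min_purity and n >= min_snvs
    gain_early = bool(frac > GAIN_EARLY_THRESHOLD) if eligible else None
    pre_frac = None
    if eligible:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pre_frac = pre_gain_fraction_estimate(frac)
    return TimingResult(
        sample=sample,
        n_3copy_snvs=n,
        fraction_single_allele=frac,
        cutoff_used=cutoff,
        purity=purity,
        eligible=eligible,
        gain_early=gain_early,
        pre_gain_fraction=pre_frac,
    )


def classify_clonality(
    vaf: float,
    purity: float = 1.0,
    local_copies: int = 2,
    factor: float = 0.8,
) -> str:
    """``clonal`` iff VAF exceeds ``factor`` x the expected clonal VAF for the
    copy state (mutated copies = max(local_copies // 2, 1)).

    At the defaults (purity 1, 2 copies) this reproduces the VAF > 0.4
    clonal rule; in a 3-copy region the expected single-copy VAF is 1/3 and
    the boundary 0.267, so a VAF of 0.32 still classifies as clonal.
    """
    if not (0.0 <= vaf <= 1.0):
        raise ValueError("VAF must be in [0, 1]")
    m = max(local_copies // 2, 1)
    return "clonal" if vaf > factor * expected_vaf(purity, local_copies, m) else "subclonal"
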