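"""Trinucleotide mutation classes, signature refitting and per-mutation attribution.

Single-base substitutions are classified into the 96 standard classes
(6 pyrimidine-strand substitution types x 16 flanking-base contexts).  Known
signature definitions (COSMIC-style 96 x K probability matrices, columns
summing to 1) are refit to per-sample spectra by non-negative least squares
followed by greedy backward elimination: a non-forced signature is dropped
whenever its removal costs less than a fixed reconstruction-cosine tolerance
(default 0.01).  Exposures are rescaled so their sum equals the sample's SNV
count, i.e. they are measured in mutations attributed to each process.

Given fitted exposures ``s_k`` and signature context probabilities
``P[c, k]``, the probability that a particular mutation at context ``c`` was
caused by signature ``i`` is

    P(i | m) = s_i * P[c, i] / sum_k s_k * P[c, k]

with the sum running over the signatures detected in the sample (s_k > 0).
The numerator is the expected number of the sample's mutations caused by
signature ``i`` at that context, the denominator the expected number caused
by any detected signature at that context.

Driver-mutation attribution is restricted to samples whose spectrum is
reconstructed with cosine similarity >= 0.9, the quality gate below which
per-mutation probabilities are not considered reliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
CONTEXT_CLASSES: tuple[str, ...] = tuple(
    f"{left}[{sub}]{right}"
    for sub in SUBSTITUTION_TYPES
    for left in _BASES
    for right in _BASES
)
_CLASS_INDEX = {label: i for i, label in enumerate(CONTEXT_CLASSES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AmbiguousBaseError(ValueError):
    """Raised for records with non-ACGT bases or ref == alt."""


class UndefinedAttributionError(ValueError):
    """Raised when no detected signature can produce the queried context."""


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_context(ref: str, alt: str, left: str, right: str) -> str:
    """96-class label of a substitution, normalized to the pyrimidine strand.

    Purine-reference mutations are reverse-complemented so the mutated base
    is C or T; e.g. ``G>T`` flanked by T/A maps to ``T[C>A]A``.
    """
    ref, alt, left, right = (b.upper() for b in (ref, alt, left, right))
    for b in (ref, alt, left, right):
        if b not in _BASES:
            raise AmbiguousBaseError(f"ambiguous base {b!r}")
    if ref == alt:
        raise AmbiguousBaseError("ref == alt is not a substitution")
    if ref in "AG":
        ref, alt = _revcomp(ref), _revcomp(alt)
        left, right = _revcomp(right), _revcomp(left)
    return f"{left}[{ref}>{alt}]{right}"


@dataclass
class TrinucleotideSpectrum:
    """96-class SNV counts for one sample."""

    sample: str
    counts: pd.Series  # indexed by CONTEXT_CLASSES

    def __post_init__(self) -> None:
        counts = self.counts.reindex(CONTEXT_CLASSES)
        if counts.isna().any():
            raise ValueError("spectrum must be indexed by the 96 context classes")
        if (counts < 0).any():
            raise ValueError("negative spectrum counts")
        self.counts = counts.astype(float)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def build_spectrum(
    snvs: pd.DataFrame | Iterable[Mapping],
    sample: str = "",
) -> tuple[TrinucleotideSpectrum, int]:
    """Count SNVs into the 96 classes; returns the spectrum and the number of
    rejected records (ambiguous bases).

    Accepts a table with either a precomputed ``context96`` column or the
    four columns ``ref``/``alt``/``left``/``right`` from which the class is
    derived.
    """
    df = pd.DataFrame(snvs)
    counts = pd.Series(0.0, index=list(CONTEXT_CLASSES))
    rejected = 0
    if df.empty:
        return TrinucleotideSpectrum(sample, counts), 0
    if "context96" in df.columns:
        labels = df["context96"]
        valid = labels.isin(_CLASS_INDEX)
        rejected = int((~valid).sum())
        vc = labels[valid].value_counts()
        counts.loc[vc.index] = vc.to_numpy(float)
    else:
        needed = {"ref", "alt", "left", "right"}
        if not needed.issubset(df.columns):
            raise ValueError("SNV table needs a context96 column or ref/alt/left/right columns")
        for row in df.itertuples(index=False):
            try:
                counts[classify_context(row.ref, row.alt, row.left, row.right)] += 1
            except AmbiguousBaseError:
                rejected += 1
    return TrinucleotideSpectrum(sample, counts), rejected


class SignatureMatrix:
    """96 x K signature definition matrix; columns are probability vectors."""

    def __init__(self, probs: pd.DataFrame) -> None:
        probs = probs.reindex(CONTEXT_CLASSES)
        if probs.isna().any().any():
            raise ValueError("signature matrix must cover all 96 context classes")
        if (probs.to_numpy() < 0).any():
            raise ValueError("negative signature probabilities")
        colsums = probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError("each signature column must sum to 1")
        self.probs = probs.astype(float)

    @property
    def names(self) -> list[str]:
        return list(self.probs.columns)

    def __getitem__(self, name: str) -> pd.Series:
        return self.probs[name]

    def subset(self, names: Iterable[str]) -> "SignatureMatrix":
        return SignatureMatrix(self.probs[list(names)])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureMatrix":
        """Read a COSMIC v3-style tab-delimited file: first column holds the
        96 class labels, remaining columns one signature each."""
        df = pd.read_csv(path, sep="\t")
        df = df.set_index(df.columns[0])
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        out = self.probs.copy()
        out.index.name = "Type"
        out.to_csv(path, sep="\t")


@dataclass
class ExposureVector:
    """Per-sample signature activities in SNV counts, with reconstruction QC."""

    sample: str
    exposures: pd.Series  # indexed by signature names; zeros for undetected
    reconstruction_cosine: float
    dropped: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def detected(self) -> pd.Series:
        return self.exposures[self.exposures > 0]

    @property
    def total(self) -> float:
        return float(self.exposures.sum())


@dataclass
class AttributionRow:
    """Eq.-style per-mutation signature attribution for one mutation."""

    mutation_id: str
    context: str
    probabilities: pd.Series  # over detected signatures, sums to 1
    best_signature: str
    best_probability: float


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return float("nan")
    return float(a @ b / (na * nb))


def _nnls_fit(counts: np.ndarray, matrix: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _ = nnls(matrix, counts)
    recon = matrix @ coef
    return coef, cosine_similarity(counts, recon)


def refit_exposures(
    spectrum: TrinucleotideSpectrum,
    signatures: SignatureMatrix,
    forced: Iterable[str] = (),
    cosine_drop_tol: float = 0.01,
) -> ExposureVector:
    """Fit signature activities to a sample spectrum.

    Non-negative least squares over the full signature set, then greedy
    backward elimination: repeatedly remove the non-forced signature whose
    removal costs the least reconstruction cosine, as long as that cost is
    below ``cosine_drop_tol``.  Forced signatures are never eliminated.
    Exposures are rescaled so they sum to the sample's SNV count.
    """
    forced = set(forced)
    unknown = forced - set(signatures.names)
    if unknown:
        raise ValueError(f"forced signatures absent from matrix: {sorted(unknown)}")
    names = signatures.names
    counts = spectrum.counts.to_numpy()
    total = counts.sum()
    if total == 0:
        return ExposureVector(
            spectrum.sample,
            pd.Series(0.0, index=names),
            float("nan"),
            flags=["zero_count_spectrum"],
        )

    active = list(names)
    matrix = signatures.probs.to_numpy()
    coef, cos = _nnls_fit(counts, matrix)
    # drop exactly-zero coefficients outright (no reconstruction change)
    keep = [n for n, c in zip(active, coef) if c > 0 or n in forced]
    dropped = [n for n in active if n not in keep]
    active = keep

    while True:
        removable = [n for n in active if n not in forced]
        if not removable or len(active) <= 1:
            break
        best_name, best_cos, best_drop = None, None, None
        for name in removable:
            trial = [n for n in active if n != name]
            sub = signatures.probs[trial].to_numpy()
            _, cos_trial = _nnls_fit(counts, sub)
            drop = cos - cos_trial
            if best_drop is None or drop < best_drop:
                best_name, best_cos, best_drop = name, cos_trial, drop
        if best_drop is not None and best_drop < cosine_drop_tol:
            active.remove(best_name)
            dropped.append(best_name)
            cos = best_cos
        else:
            break

    sub = signatures.probs[active].to_numpy()
    coef, cos = _nnls_fit(counts, sub)
    exposures = pd.Series(0.0, index=names)
    exposures[active] = coef
    if exposures.sum() > 0:
        exposures *= total / exposures.sum()
    return ExposureVector(spectrum.sample, exposures, cos, dropped=dropped)


def attribute_mutation(
    context: str,
    exposures: ExposureVector | pd.Series,
    signatures: SignatureMatrix,
    mutation_id: str = "",
) -> AttributionRow:
    """Probability that a mutation at ``context`` arose from each detected signature."""
    if context not in _CLASS_INDEX:
        raise ValueError(f"unknown context class {context!r}")
    s = exposures.detected if isinstance(exposures, ExposureVector) else exposures[exposures > 0]
    if s.empty:
        raise UndefinedAttributionError("no detected signature in this sample")
    p_row = signatures.probs.loc[context, s.index]
    weights = s.to_numpy() * p_row.to_numpy()
    denom = weights.sum()
    if denom <= 0:
        raise UndefinedAttributionError(
            f"no detected signature can produce context {context}"
        )
    probs = pd.Series(weights / denom, index=s.index)
    best = str(probs.idxmax())
    return AttributionRow(
        mutation_id=mutation_id,
        context=context,
        probabilities=probs,
        best_signature=best,
        best_probability=float(probs[best]),
    )


def attribute_drivers(
    drivers: pd.DataFrame,
    exposures: Mapping[str, ExposureVector],
    signatures: SignatureMatrix,
    min_cosine: float = 0.9,
    majority_threshold: float = 0.5,
) -> pd.DataFrame:
    """Attribute driver SNVs to signatures, restricted to samples whose
    spectrum reconstruction cosine is at or above ``min_cosine``.

    ``drivers`` columns: sample, mutation_id, context96.  The output flags
    mutations whose best signature carries more than ``majority_threshold``
    probability.
    """
    rows = []
    for row in drivers.itertuples(index=False):
        expo = exposures.get(row.sample)
        if expo is None or not np.isfinite(expo.reconstruction_cosine):
            continue
        if expo.reconstruction_cosine < min_cosine:
            continue
        att = attribute_mutation(row.context96, expo, signatures, mutation_id=str(row.mutation_id))
        rows.append(
            {
                "sample": row.sample,
                "mutation_id": att.mutation_id,
                "context96": att.context,
                "best_signature": att.best_signature,
                "best_probability": att.best_probability,
                "majority": att.best_probability > majority_threshold,
                **{f"p_{k}": v for k, v in att.probabilities.items()},
            }
        )
    return pd.DataFrame(rows)


def signature_proportions(exposures: ExposureVector) -> pd.Series:
    """Share of the sample's mutations attributed to each signature."""
    total = exposures.total
    if total <= 0:
        raise ValueError("zero total exposure")
    return exposures.exposures / total


def c_to_a_fraction(spectrum: TrinucleotideSpectrum) -> float:
    """Fraction of a sample's SNVs that are C>A substitutions (16 classes)."""
    if spectrum.total <= 0:
        raise ValueError("zero-count spectrum")
    mask = [label for label in CONTEXT_CLASSES if "[C>A]" in label]
    return float(spectrum.counts[mask].sum() / spectrum.total)
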