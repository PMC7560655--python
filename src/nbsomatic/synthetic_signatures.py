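"""Synthetic bundled signature definitions.

A small 96 x 5 signature set constructed programmatically so the package and
its tests run without downloading reference files.  The five signatures are
*synthetic stand-ins* that qualitatively mimic well-known mutational
processes — they are NOT the published COSMIC definitions:

* ``SBS1``  — deamination-like: C>T concentrated at NpCpG contexts.
* ``SBS3``  — near-flat (double-strand-break-repair-deficiency-like).
* ``SBS5``  — near-flat "clock-like" background with a mild C>T/T>C tilt.
* ``SBS18`` — C>A dominated (reactive-oxygen-species-like), peaking at
  T[C>A]A / T[C>A]T, the contexts of recurrent neuroblastoma driver SNVs.
* ``SBS31`` — platinum-chemotherapy-like: C>T and T>A at CpC/CpT contexts.

Real COSMIC v3 matrices in the standard tab-delimited layout can be loaded
with :meth:`nbsomatic.signatures.SignatureMatrix.from_tsv` and used
anywhere this set is used.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .signatures import CONTEXT_CLASSES, SignatureMatrix

# fixed ripple seed: makes the two near-flat signatures linearly independent
_RIPPLE_SEED = 20230917


def _blank() -> pd.Series:
    return pd.Series(0.0, index=list(CONTEXT_CLASSES))


def _classes(sub: str) -> list[str]:
    return [c for c in CONTEXT_CLASSES if f"[{sub}]" in c]


def _sbs1() -> pd.Series:
    v = _blank()
    for left in "ACGT":
        v[f"{left}[C>T]G"] = 0.19
    others = [c for c in _classes("C>T") if not c.endswith("G")]
    v[others] = 0.24 / len(others)
    return v


def _flat(
    tilt: dict[str, float],
    seed_offset: int,
    peaks: list[str],
    peak_mass: float = 0.30,
) -> pd.Series:
    """Broad background signature with a few distinctive anchor peaks.

    The anchors keep the two background signatures mutually identifiable
    (pairwise cosine ~0.27); fully flat definitions would be unresolvable by
    any refitting method.
    """
    rng = np.random.default_rng(_RIPPLE_SEED + seed_offset)
    v = pd.Series(1.0, index=list(CONTEXT_CLASSES))
    for sub, w in tilt.items():
        v[_classes(sub)] *= w
    v *= rng.uniform(0.3, 1.9, size=96)
    v = v / v.sum() * (1.0 - peak_mass)
    for c in peaks:
        v[c] += peak_mass / len(peaks)
    return v / v.sum()


def _sbs18() -> pd.Series:
    v = _blank()
    ca = _classes("C>A")
    v[ca] = 0.55 / len(ca)
    v["T[C>A]A"] += 0.20
    v["T[C>A]T"] += 0.12
    v["G[C>A]A"] += 0.03
    rest = [c for c in CONTEXT_CLASSES if "[C>A]" not in c]
    v[rest] = 0.10 / len(rest)
    return v / v.sum()


def _sbs31() -> pd.Series:
    v = _blank()
    for left in "ACGT":
        v[f"{left}[C>T]C"] = 0.08
        v[f"{left}[C>T]T"] = 0.06
    ta = _classes("T>A")
    v[ta] += 0.30 / len(ta)
    v /= v.sum()
    return v


def synthetic_signature_matrix() -> SignatureMatrix:
    """Deterministic 96 x 5 synthetic signature set (see module docstring)."""
    probs = pd.DataFrame(
        {
            "SBS1": _sbs1(),
            "SBS3": _flat(
                {"T>A": 1.8, "T>C": 1.4, "C>T": 0.6},
                seed_offset=1,
                peaks=["A[T>A]A", "C[T>A]G", "G[T>C]C", "T[T>A]T", "C[T>C]A"],
            ),
            "SBS5": _flat(
                {"C>T": 1.9, "T>C": 1.2, "T>A": 0.6},
                seed_offset=2,
                peaks=["A[T>C]T", "T[C>T]A", "G[C>T]A", "C[T>C]T", "A[C>T]A"],
            ),
            "SBS18": _sbs18(),
            "SBS31": _sbs31(),
        }
    )
    return SignatureMatrix(probs)
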