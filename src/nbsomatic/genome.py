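"""Autosomal chromosome-arm geometry.

Arm-level copy-number calling needs, for every autosome, where the p and q
arms begin and end and whether the chromosome is acrocentric (acrocentric
q arms are queried with a shorter terminal window).  Two genome builds are
provided: the 22 GRCh37 autosomes with arm boundaries taken from the
standard hg19 cytoband centromere annotation, and a small "toy" genome for
fast tests that still exercises the geometric corner cases (an arm shorter
than the 30 Mb window, an acrocentric chromosome).

Coordinates are 1-based inclusive throughout (SEG convention).  The p arm
spans ``[1, cen_start]`` and the q arm ``[cen_end + 1, length]``; the
centromeric gap belongs to neither arm and is never sampled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator


@dataclass(frozen=True)
class Arm:
    """One chromosome arm, 1-based inclusive coordinates."""

    chrom: str
    name: str  # "p" or "q"
    start: int
    end: int
    acrocentric: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def terminus(self) -> str:
        """Which end of the arm is the telomeric terminus: 'start' for p, 'end' for q."""
        return "start" if self.name == "p" else "end"


@dataclass(frozen=True)
class ChromSpec:
    """Arm geometry of a single autosome."""

    name: str
    p_end: int          # last base of the p arm (centromere start)
    q_start: int        # first base of the q arm (centromere end + 1)
    length: int         # chromosome length
    acrocentric: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.p_end < self.q_start <= self.length):
            raise ValueError(f"inconsistent arm geometry for chromosome {self.name}")

    @property
    def p_arm_length(self) -> int:
        return self.p_end

    @property
    def q_arm_length(self) -> int:
        return self.length - self.q_start + 1

    @property
    def p(self) -> Arm:
        return Arm(self.name, "p", 1, self.p_end, self.acrocentric)

    @property
    def q(self) -> Arm:
        return Arm(self.name, "q", self.q_start, self.length, self.acrocentric)

    @property
    def arms(self) -> tuple[Arm, Arm]:
        return (self.p, self.q)


class Genome:
    """An ordered collection of autosome specs keyed by chromosome name."""

    def __init__(self, chroms: list[ChromSpec], mode: str = "custom") -> None:
        names = [c.name for c in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        self.mode = mode
        self._chroms: dict[str, ChromSpec] = {c.name: c for c in chroms}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def __getitem__(self, chrom: str) -> ChromSpec:
        return self._chroms[chrom]

    def __iter__(self) -> Iterator[ChromSpec]:
        return iter(self._chroms.values())

    def __len__(self) -> int:
        return len(self._chroms)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chroms)

    def arms(self) -> Iterator[Arm]:
        for spec in self:
            yield spec.p
            yield spec.q

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self)


# hg19 autosome lengths and centromere (acen) boundaries, UCSC cytoband track.
# (length, cen_start, cen_end); p arm = [1, cen_start], q arm = [cen_end+1, length].
_GRCH37_AUTOSOMES: dict[str, tuple[int, int, int]] = {
    "1": (249250621, 121535434, 124535434),
    "2": (243199373, 92326171, 95326171),
    "3": (198022430, 90504854, 93504854),
    "4": (191154276, 49660117, 52660117),
    "5": (180915260, 46405641, 49405641),
    "6": (171115067, 58830166, 61830166),
    "7": (159138663, 58054331, 61054331),
    "8": (146364022, 43838887, 46838887),
    "9": (141213431, 47367679, 50367679),
    "10": (135534747, 39254935, 42254935),
    "11": (135006516, 51644205, 54644205),
    "12": (133851895, 34856694, 37856694),
    "13": (115169878, 16000000, 19000000),
    "14": (107349540, 16000000, 19000000),
    "15": (102531392, 17000000, 20000000),
    "16": (90354753, 35335801, 38335801),
    "17": (81195210, 22263006, 25263006),
    "18": (78077248, 15460898, 18460898),
    "19": (59128983, 24681782, 27681782),
    "20": (63025520, 26369569, 29369569),
    "21": (48129895, 11288129, 14288129),
    "22": (51304566, 13000000, 16000000),
}

ACROCENTRIC_AUTOSOMES = frozenset({"13", "14", "15", "21", "22"})


def _grch37_genome() -> Genome:
    chroms = [
        ChromSpec(
            name=name,
            p_end=cen_start,
            q_start=cen_end + 1,
            length=length,
            acrocentric=name in ACROCENTRIC_AUTOSOMES,
        )
        for name, (length, cen_start, cen_end) in _GRCH37_AUTOSOMES.items()
    ]
    return Genome(chroms, mode="grch37-arms")


def _toy_genome() -> Genome:
    # Four chromosomes covering the geometric corner cases:
    #  T1 — both arms longer than the 30 Mb window
    #  T2 — q arm of 20 Mb (< 30 Mb: whole arm analyzed)
    #  T3 — acrocentric (short p, long q; q queried with the acrocentric window)
    #  T4 — moderate arms just above the window
    mb = 1_000_000
    chroms = [
        ChromSpec("T1", p_end=60 * mb, q_start=61 * mb + 1, length=141 * mb),
        ChromSpec("T2", p_end=40 * mb, q_start=41 * mb + 1, length=61 * mb),
        ChromSpec("T3", p_end=5 * mb, q_start=6 * mb + 1, length=56 * mb, acrocentric=True),
        ChromSpec("T4", p_end=35 * mb, q_start=36 * mb + 1, length=81 * mb),
    ]
    return Genome(chroms, mode="toy")


def make_genome_spec(mode: str) -> Genome:
    """Build the arm table for the requested genome.

    Parameters
    ----------
    mode:
        ``"grch37-arms"`` for the 22 GRCh37 autosomes, ``"toy"`` for a small
        four-chromosome genome used in tests and examples.
    """
    if mode == "grch37-arms":
        return _grch37_genome()
    if mode == "toy":
        return _toy_genome()
    raise ValueError(f"unknown genome mode: {mode!r} (expected 'toy' or 'grch37-arms')")
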