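"""ABBA/BABA site-pattern classification for the two reciprocal quartets.

The reciprocal construction arranges four of the five taxa as
(P1, P2, P3, O) and *excludes the donor subgenome* so that gene flow
from the donor into the tested subgenome surfaces as an excess of ABBA
sites:

* ``MAT`` direction (maternal subgenome overwrites paternal):
  (P1, P2, P3, O) = (C_DIP, C_SUB, E_DIP, OUT). HGF makes the C
  subgenome look "maternal-like", i.e. C_SUB shares derived alleles
  with E_DIP -> ABBA.
* ``PAT`` direction (paternal overwrites maternal):
  (P1, P2, P3, O) = (E_DIP, E_SUB, C_DIP, OUT).

The outgroup state is taken as the ancestral allele A; the single
alternative state among the quartet is the derived allele B. A column is
usable only when all four quartet bases are unambiguous nucleotides and
at most two states are present. IUPAC ambiguity codes are treated as
missing rather than resolved probabilistically, giving a strict binary
site count. The excluded donor subgenome's state (even a gap) never
affects a column's usability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd

from .io_model import GeneAlignment

ABBA = "ABBA"
BABA = "BABA"
OTHER_BIALLELIC = "OTHER_BIALLELIC"
UNUSABLE = "UNUSABLE"

_UNAMBIG = frozenset(b"ACGT")
_VALID = frozenset(b"ACGTN-RYSWKMBDHV")


@dataclass(frozen=True)
class QuartetSpec:
    """Ordered quartet (P1, P2, P3, O) for one test direction."""

    direction: str  # "MAT" or "PAT"
    p1: str
    p2: str
    p3: str
    out: str = "OUT"

    @property
    def roles(self) -> Tuple[str, str, str, str]:
        return (self.p1, self.p2, self.p3, self.out)


#: Maternal-overwrites-paternal test: donor E_SUB excluded.
MAT_QUARTET = QuartetSpec(direction="MAT", p1="C_DIP", p2="C_SUB", p3="E_DIP")
#: Paternal-overwrites-maternal test: donor C_SUB excluded.
PAT_QUARTET = QuartetSpec(direction="PAT", p1="E_DIP", p2="E_SUB", p3="C_DIP")

QUARTETS: Dict[str, QuartetSpec] = {"MAT": MAT_QUARTET, "PAT": PAT_QUARTET}


@dataclass(frozen=True)
class SitePatternCounts:
    """Per-gene tallies for one quartet direction."""

    gene_id: str
    direction: str
    n_abba: int
    n_baba: int
    n_usable: int
    n_columns: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_abba + self.n_baba <= self.n_usable <= self.n_columns):
            raise ValueError(
                f"inconsistent counts for {self.gene_id}/{self.direction}"
            )


def classify_column(bases: Tuple[str, str, str, str]) -> str:
    """Classify one alignment column given quartet-ordered bases (P1,P2,P3,O).

    Returns one of ABBA / BABA / OTHER_BIALLELIC / UNUSABLE. Monomorphic,
    singleton-derived and BBAA columns are OTHER_BIALLELIC; gaps,
    ambiguity codes and >2-state columns are UNUSABLE.
    """
    ups = tuple(b.upper().replace("U", "T") for b in bases)
    for b in ups:
        if len(b) != 1 or ord(b) not in _VALID:
            raise ValueError(f"invalid base {b!r}")
    if any(ord(b) not in _UNAMBIG for b in ups):
        return UNUSABLE
    p1, p2, p3, o = ups
    states = set(ups)
    if len(states) > 2:
        return UNUSABLE
    if p1 == o and p2 == p3 != o:
        return ABBA
    if p2 == o and p1 == p3 != o:
        return BABA
    return OTHER_BIALLELIC


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def count_patterns(gene: GeneAlignment, quartet: QuartetSpec) -> SitePatternCounts:
    """Tally ABBA/BABA/usable columns of one gene for one direction.

    Column-wise application of :func:`classify_column`, vectorized.
    """
    p1 = _seq_array(gene.sequences[quartet.p1])
    p2 = _seq_array(gene.sequences[quartet.p2])
    p3 = _seq_array(gene.sequences[quartet.p3])
    o = _seq_array(gene.sequences[quartet.out])

    unambig = np.ones(len(o), dtype=bool)
    for arr in (p1, p2, p3, o):
        ok = np.zeros(len(o), dtype=bool)
        for c in b"ACGT":
            ok |= arr == c
        unambig &= ok

    # <=2 distinct states: every base equals the outgroup state or a
    # single shared alternative.
    m1, m2, m3 = p1 != o, p2 != o, p3 != o
    alt = np.where(m1, p1, np.where(m2, p2, p3))
    biallelic = (
        (~m1 | (p1 == alt)) & (~m2 | (p2 == alt)) & (~m3 | (p3 == alt))
    )
    usable = unambig & biallelic

    abba = usable & ~m1 & m2 & m3 & (p2 == p3)
    baba = usable & ~m2 & m1 & m3 & (p1 == p3)
    return SitePatternCounts(
        gene_id=gene.gene_id,
        direction=quartet.direction,
        n_abba=int(abba.sum()),
        n_baba=int(baba.sum()),
        n_usable=int(usable.sum()),
        n_columns=len(o),
    )


def count_dataset(
    genes: Iterable[GeneAlignment], quartet: QuartetSpec
) -> List[SitePatternCounts]:
    return [count_patterns(g, quartet) for g in genes]


def counts_to_frame(counts: Iterable[SitePatternCounts]) -> pd.DataFrame:
    """Per-gene counts as a DataFrame (TSV-export layout)."""
    rows = [
        (c.gene_id, c.direction, c.n_abba, c.n_baba, c.n_usable, c.n_columns)
        for c in counts
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "direction", "n_abba", "n_baba", "n_usable", "n_columns"],
    )
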