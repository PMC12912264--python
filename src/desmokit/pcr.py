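"""In-silico PCR amplicon prediction for splice-isoform discrimination.

Alternative splicing that inserts or removes an exon between two primer
sites changes the predicted amplicon length by exactly the exon length, so
a primer pair flanking the variable exon discriminates isoforms by product
size on a gel.  :func:`splice` assembles isoform templates from ordered exon
fragments and :func:`find_amplicons` reports every exact-match product:
forward-primer sites on the plus strand paired with downstream sites whose
plus-strand sequence is the reverse complement of the reverse primer.

Matching is exact (no mismatch tolerance) and coordinates are 0-based
half-open, so ``length == end - start`` always.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = ["PrimerPair", "Amplicon", "find_amplicons", "splice",
           "read_templates_fasta", "read_primer_pairs"]

_ALPHABET = set("ACGT")


@dataclass(frozen=True)
class PrimerPair:
    """A named primer pair; both primers written 5'->3', ACGT only."""

    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if len(seq) < 10:
                raise ValueError(f"{label} primer must be >= 10 nt")
            if not set(seq) <= _ALPHABET:
                raise ValueError(f"{label} primer has non-ACGT characters")


@dataclass(frozen=True)
class Amplicon:
    """A predicted product: 0-based half-open template coordinates."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def find_amplicons(template: str, pair: PrimerPair,
                   max_len: int = 5000) -> list[Amplicon]:
    """All products of ``pair`` on ``template`` up to ``max_len`` bases.

    A product runs from the 5' end of a forward-primer match to the 3' end
    of a reverse-primer binding site (whose plus-strand sequence is the
    reverse complement of the reverse primer), sorted by start coordinate.
    No match yields an empty list.
    """
    if not template:
        raise ValueError("template must be non-empty")
    template = template.upper()
    rev_site = str(Seq(pair.reverse).reverse_complement())
    fwd_starts = _find_all(template, pair.forward)
    rev_ends = [i + len(rev_site) for i in _find_all(template, rev_site)]
    out = []
    for s in fwd_starts:
        for e in rev_ends:
            if e > s and (e - s) <= max_len and e - s >= len(pair.forward):
                out.append(Amplicon(s, e))
    return sorted(out, key=lambda a: (a.start, a.end))


def splice(exons: Sequence[str], inclusion_flags: Sequence[int | bool]) -> str:
    """Concatenate the included exon fragments, in order."""
    if len(exons) != len(inclusion_flags):
        raise ValueError("one inclusion flag per exon required")
    included = [e for e, f in zip(exons, inclusion_flags) if f]
    if not included:
        raise ValueError("at least one exon must be included")
    return "".join(included)


def read_templates_fasta(path: str | Path) -> dict[str, str]:
    """Read templates from FASTA as {record id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def read_primer_pairs(path: str | Path) -> list[PrimerPair]:
    """Read primer pairs from TSV columns (name, forward, reverse)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("name", "forward", "reverse"):
        if col not in df.columns:
            raise ValueError(f"primer TSV lacks column {col!r}")
    return [PrimerPair(r["name"], r["forward"].upper(), r["reverse"].upper())
            for _, r in df.iterrows()]
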