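"""Codon alphabet, genetic-code classification, SHM motifs and region masks.

Everything downstream (rate matrices, likelihoods, simulators) works on the
61 sense codons of the standard genetic code, ordered lexicographically with
A < C < G < T and the three stop codons (TAA, TAG, TGA) removed.  That
ordering is fixed so that serialized matrices are reproducible.

SHM hot- and cold-spot motifs are short IUPAC patterns in which a single
target base experiences an altered substitution rate: WRC/GYW (AID hot
spots), WA/TW (polymerase-eta hot spots) and SYC/GRS (cold spots).  The
three pairs are reverse complements of each other, acting on opposite
strands.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
NT_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA

#: IUPAC nucleotide codes used in motif patterns.
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide (or IUPAC pattern) string."""
    return seq.translate(_COMPLEMENT)[::-1]


class CodonSpace:
    """The 61 sense codons of the standard genetic code.

    Attributes
    ----------
    codons : tuple of str
        Lexicographic (A<C<G<T) ordering of the sense codons.
    index_of : dict
        codon string -> integer in 0..60.
    amino_acid_of : dict
        codon string -> one-letter amino acid.
    """

    def __init__(self) -> None:
        self.codons: tuple[str, ...] = tuple(
            "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)
            if "".join(c) not in STOP_CODONS
        )
        self.index_of = {c: i for i, c in enumerate(self.codons)}
        self.amino_acid_of = {c: standard_dna_table.forward_table[c] for c in self.codons}
        # codon index -> (3,) array of nucleotide indices
        self.codon_nt = np.array(
            [[NT_INDEX[b] for b in c] for c in self.codons], dtype=np.int8
        )

    @property
    def n(self) -> int:
        return len(self.codons)

    def __len__(self) -> int:
        return len(self.codons)


#: Module-level singleton; the codon space is immutable.
CODON_SPACE = CodonSpace()


def is_transition_pair(a: str, b: str) -> bool:
    """True if the single-base change a->b is a transition (purine<->purine
    or pyrimidine<->pyrimidine)."""
    return (a in "AG") == (b in "AG") and a != b


@dataclass(frozen=True)
class MotifSpec:
    """An SHM targeting motif.

    ``pattern`` is an IUPAC string; ``target_offset`` is the 0-based index
    within the pattern of the base whose substitution rate is modified.
    """

    name: str
    pattern: str
    target_offset: int

    def __post_init__(self) -> None:
        if not (0 <= self.target_offset < len(self.pattern)):
            raise ValueError(f"target_offset out of bounds for motif {self.name}")

    def allowed(self, k: int) -> frozenset:
        """Set of bases allowed at pattern position k."""
        return IUPAC[self.pattern[k]]

    def reverse_complement(self) -> "MotifSpec":
        return MotifSpec(
            name=f"rc({self.name})",
            pattern=revcomp(self.pattern),
            target_offset=len(self.pattern) - 1 - self.target_offset,
        )


#: Canonical motif set; order fixed (it defines the layout of h vectors).
MOTIFS: dict[str, MotifSpec] = {
    "WRC": MotifSpec("WRC", "WRC", 2),
    "GYW": MotifSpec("GYW", "GYW", 0),
    "WA": MotifSpec("WA", "WA", 1),
    "TW": MotifSpec("TW", "TW", 0),
    "SYC": MotifSpec("SYC", "SYC", 2),
    "GRS": MotifSpec("GRS", "GRS", 0),
}
MOTIF_NAMES: tuple[str, ...] = tuple(MOTIFS)

#: Reverse-complement partners (each motif acts on the opposite strand of
#: its partner).
MOTIF_PARTNERS = {"WRC": "GYW", "GYW": "WRC", "WA": "TW", "TW": "WA",
                  "SYC": "GRS", "GRS": "SYC"}

FWR = "FWR"
CDR = "CDR"
IGNORED = "IGNORED"
_REGION_LABELS = (FWR, CDR, IGNORED)


@dataclass
class RegionMask:
    """Per-codon-site region labels (FWR / CDR / IGNORED).

    IGNORED marks sites excluded from the likelihood, e.g. the CDR3 which
    cannot be aligned against a reliable germline junction.
    """

    labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        bad = [l for l in self.labels if l not in _REGION_LABELS]
        if bad:
            raise ValueError(f"unknown region labels: {sorted(set(bad))}")
        if len(self.labels) == 0 or all(l == IGNORED for l in self.labels):
            raise ValueError("mask must contain at least one non-IGNORED site")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def is_cdr(self) -> np.ndarray:
        return np.array([l == CDR for l in self.labels])

    @property
    def is_scored(self) -> np.ndarray:
        return np.array([l != IGNORED for l in self.labels])

    @classmethod
    def uniform(cls, n_codons: int, label: str = FWR) -> "RegionMask":
        return cls((label,) * n_codons)


def _check_sense(codon: str) -> None:
    if codon not in CODON_SPACE.index_of:
        if codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon!r} is not part of the 61-codon state space")
        raise ValueError(f"{codon!r} is not a sense codon over ACGT")


def classify_substitution(codon_a: str, codon_b: str) -> dict:
    """Classify the change between two sense codons.

    Returns a dict with ``positions_differing`` (0-based nucleotide
    positions), ``is_transition`` (defined only for single-base changes,
    else None) and ``is_synonymous`` (amino acids equal).
    """
    _check_sense(codon_a)
    _check_sense(codon_b)
    diff = [p for p in range(3) if codon_a[p] != codon_b[p]]
    is_ts = None
    if len(diff) == 1:
        p = diff[0]
        is_ts = is_transition_pair(codon_a[p], codon_b[p])
    return {
        "positions_differing": diff,
        "is_transition": is_ts,
        "is_synonymous": CODON_SPACE.amino_acid_of[codon_a] == CODON_SPACE.amino_acid_of[codon_b],
    }


def motif_hits(sequence: str, motif: MotifSpec) -> list[int]:
    """0-based positions of the *target* base of every occurrence of
    ``motif`` in ``sequence``.  Overlapping occurrences all count.

    Windows containing ambiguous characters are skipped (logged once per
    call).
    """
    m = len(motif.pattern)
    hits: list[int] = []
    skipped = 0
    for start in range(len(sequence) - m + 1):
        window = sequence[start:start + m]
        if any(b not in NUCLEOTIDES for b in window):
            skipped += 1
            continue
        if all(window[k] in motif.allowed(k) for k in range(m)):
            hits.append(start + motif.target_offset)
    if skipped:
        logger.debug("motif_hits: skipped %d windows with ambiguous bases", skipped)
    return hits


def seq_to_codon_indices(seq: str) -> np.ndarray:
    """Encode a nucleotide string as codon indices; codons containing gaps,
    ambiguity characters or stops are flagged missing (-1), never dropped."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for i in range(len(out)):
        out[i] = CODON_SPACE.index_of.get(seq[3 * i:3 * i + 3].upper(), -1)
    return out


def codon_indices_to_seq(idx: Iterable[int]) -> str:
    return "".join(CODON_SPACE.codons[i] if i >= 0 else "NNN" for i in idx)


def empirical_codon_frequencies(seqs: Sequence[str], pseudocount: float = 0.5) -> np.ndarray:
    """Codon frequencies across sequences, with a small pseudocount so that
    no sense codon has frequency exactly zero."""
    counts = np.full(CODON_SPACE.n, pseudocount)
    for s in seqs:
        idx = seq_to_codon_indices(s)
        for i in idx[idx >= 0]:
            counts[i] += 1
    return counts / counts.sum()
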