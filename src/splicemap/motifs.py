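"""Motif representation and scanning.

Two motif kinds are supported: gapped dimers — two short words separated
by a bounded spacer, e.g. the tandem CAC N(1–12) CAC element bound by an
RBPMS dimer — and literal IUPAC words such as the RBFOX element GCAYG
(covering GCACG/GCATG).  Single-nucleotide mutated controls of IUPAC
words provide specificity baselines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifSpec:
    """A scannable motif: gapped dimer or IUPAC word, plus control lineage."""

    name: str
    kind: str  # "gapped_dimer" | "iupac_word"
    left: str = "CAC"
    right: str = "CAC"
    gap_min: int = 1
    gap_max: int = 12
    word: str = ""
    control_of: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gapped_dimer", "iupac_word"):
            raise ValueError(f"unknown motif kind {self.kind!r}")
        if self.kind == "gapped_dimer":
            if not self.left or not self.right:
                raise ValueError("gapped dimer needs non-empty left/right words")
            for w in (self.left, self.right):
                if any(c not in IUPAC for c in w):
                    raise ValueError(f"invalid IUPAC character in {w!r}")
            if self.gap_min < 1 or self.gap_max < self.gap_min:
                raise ValueError("require 1 <= gap_min <= gap_max")
        else:
            if not self.word:
                raise ValueError("iupac_word needs a non-empty word")
            if any(c not in IUPAC for c in self.word):
                raise ValueError(f"invalid IUPAC character in {self.word!r}")


#: RBPMS-type tandem element: CAC pairs 1–12 nt apart.
RBPMS_DIMER = MotifSpec(name="RBPMS_CAC_dimer", kind="gapped_dimer")

#: RBFOX-family element GCAYG (= GCACG or GCATG).
RBFOX_WORD = MotifSpec(name="RBFOX_GCAYG", kind="iupac_word", word="GCAYG")


@dataclass(frozen=True, order=True)
class MotifHit:
    """Half-open hit interval on a scanned transcript-sense sequence."""

    start: int
    end: int
    sequence_id: str = ""
    motif_name: str = ""


def _check_alphabet(seq: str) -> None:
    if re.search(r"[^ACGTN]", seq):
        bad = sorted(set(re.findall(r"[^ACGTN]", seq)))
        raise ValueError(f"sequence contains invalid characters: {bad}")


def _word_regex(word: str) -> re.Pattern:
    # concrete character classes only, so N in the sequence never matches
    parts = []
    for c in word:
        opts = IUPAC[c] if c != "N" else "ACGT"
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile(f"(?=({''.join(parts)}))")


def _word_starts(seq: str, word: str) -> list[int]:
    return [m.start() for m in _word_regex(word).finditer(seq)]


def scan(seq: str, motif: MotifSpec, sequence_id: str = "") -> list[MotifHit]:
    """All (possibly overlapping) motif occurrences, sorted by (start, end).

    For a gapped dimer every (left, right) occurrence pair whose spacer
    length lies in [gap_min, gap_max] yields one hit spanning from the
    left word's start to the right word's end.
    """
    _check_alphabet(seq)
    hits: list[MotifHit] = []
    if motif.kind == "iupac_word":
        for s in _word_starts(seq, motif.word):
            hits.append(MotifHit(s, s + len(motif.word), sequence_id, motif.name))
        return hits
    lefts = _word_starts(seq, motif.left)
    rights = np.array(_word_starts(seq, motif.right), dtype=int)
    llen, rlen = len(motif.left), len(motif.right)
    for ls in lefts:
        lo = ls + llen + motif.gap_min
        hi = ls + llen + motif.gap_max
        i0, i1 = np.searchsorted(rights, [lo, hi + 1])
        for rs in rights[i0:i1]:
            hits.append(MotifHit(ls, int(rs) + rlen, sequence_id, motif.name))
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def coverage_mask(seq_len: int, hits: list[MotifHit]) -> np.ndarray:
    """Boolean per-base vector: True where covered by the union of hits."""
    mask = np.zeros(seq_len, dtype=bool)
    for h in hits:
        if not 0 <= h.start < h.end <= seq_len:
            raise ValueError(f"hit [{h.start},{h.end}) outside sequence of "
                             f"length {seq_len}")
        mask[h.start:h.end] = True
    return mask


def mutate_control(motif: MotifSpec, position: int, base: str) -> MotifSpec:
    """Single-nucleotide mutated control word for an IUPAC-word motif.

    ``base`` must be a concrete nucleotide not matched by the parent
    word at ``position``.
    """
    if motif.kind != "iupac_word":
        raise ValueError("mutated controls are defined for iupac_word motifs")
    if not 0 <= position < len(motif.word):
        raise ValueError(f"position {position} outside word {motif.word!r}")
    if base not in "ACGT":
        raise ValueError(f"control base must be a concrete nucleotide, got {base!r}")
    if base in IUPAC[motif.word[position]]:
        raise ValueError(
            f"base {base} is already matched by {motif.word!r} at {position}")
    word = motif.word[:position] + base + motif.word[position + 1:]
    return replace(motif, name=f"{motif.name}_mut{position}{base}",
                   word=word, control_of=motif.name)


def default_rbfox_control() -> MotifSpec:
    """GCAAG: the RBFOX word with its central pyrimidine position mutated."""
    return mutate_control(RBFOX_WORD, 3, "A")
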