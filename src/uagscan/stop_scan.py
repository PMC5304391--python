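"""In-frame stop detection, termination-codon inference and codon usage.

A transcriptome harbouring a stop-to-sense reassignment shows a telltale
pattern: one particular stop codon (here UAG) appears in-frame inside
otherwise conserved coding regions, while the bona fide termination codons
— the stops actually ending each coding sequence, located from
homology-defined 3' boundaries — are drawn only from the remaining stops
(UAA/UGA).  This module detects internal stops, infers each transcript's
termination codon, and computes relative codon frequencies: the percentage
of a codon among all occurrences of codons with the same meaning.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .genetic_codes import GeneticCode, get_code, to_rna
from .seqio import CodingSequence

TRUNCATED = "TRUNCATED"
STANDARD_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class StopReport:
    """Internal stop codons and the inferred termination codon of one transcript."""

    seq_id: str
    internal_stops: list[tuple[int, str]] = field(default_factory=list)
    termination_codon: str | None = None  # UAA/UGA/UAG (RNA letters) or TRUNCATED
    termination_index: int | None = None

    def __post_init__(self) -> None:
        if self.termination_index is not None:
            for idx, _ in self.internal_stops:
                if idx >= self.termination_index:
                    raise ValueError(
                        f"{self.seq_id}: internal stop at codon {idx} not before "
                        f"termination codon {self.termination_index}"
                    )

    def stop_counts(self) -> dict[str, int]:
        counts = Counter(codon for _, codon in self.internal_stops)
        return {to_rna(c): counts.get(c, 0) for c in STANDARD_STOPS}


def find_internal_stops(
    cds: CodingSequence,
    cds_3prime_boundary: int,
    code: GeneticCode | None = None,
) -> StopReport:
    """Report every stop codon strictly before a codon-index boundary.

    The boundary is typically the inferred termination codon or, when
    alignment coordinates are available, the end of the aligned region.
    The stop set is taken from ``code`` (default: the standard code), so a
    code with UAG reassigned never reports UAG.
    """
    code = code or get_code("standard")
    if cds.frame_offset + 3 * cds_3prime_boundary > len(cds.seq):
        raise ValueError(f"{cds.id}: boundary beyond sequence end")
    stops = [
        (i, codon)
        for i, codon in enumerate(cds.codons(end=len(cds.seq))[:cds_3prime_boundary])
        if code.is_stop(codon)
    ]
    return StopReport(seq_id=cds.id, internal_stops=stops)


def infer_termination_codon(
    cds: CodingSequence,
    aligned_region_end: int,
    uag_is_sense: bool = False,
) -> StopReport:
    """Find the bona fide termination codon downstream of the aligned region.

    Scans codons at or after ``aligned_region_end`` for the first standard
    stop.  With ``uag_is_sense`` set, UAG is skipped — it is presumed to be a
    sense codon — and scanning continues to the first UAA/UGA.  Transcripts
    with no stop before the sequence end are reported as TRUNCATED.
    """
    if aligned_region_end > cds.n_codons:
        raise ValueError(f"{cds.id}: aligned region end beyond sequence")
    codons = cds.codons(end=len(cds.seq))
    for i in range(aligned_region_end, len(codons)):
        codon = codons[i]
        if codon in STANDARD_STOPS:
            if uag_is_sense and codon == "TAG":
                continue
            return StopReport(
                seq_id=cds.id, termination_codon=to_rna(codon), termination_index=i
            )
    return StopReport(seq_id=cds.id, termination_codon=TRUNCATED)


@dataclass
class CodonFrequencyTable:
    """Relative codon frequencies per meaning class (amino acid or STOP).

    For each class the table lists ``(codon, percent, count)`` where percent
    is 100 x count(codon) / count(all codons with that meaning).
    """

    classes: dict[str, list[tuple[str, float, int]]]

    def percent(self, meaning: str, codon: str) -> float:
        codon = codon.upper().replace("U", "T")
        for c, pct, _ in self.classes.get(meaning, []):
            if c == codon:
                return pct
        return 0.0

    def class_total(self, meaning: str) -> int:
        return sum(n for _, _, n in self.classes.get(meaning, []))


def relative_codon_frequencies(
    cds_set: list[CodingSequence],
    code: GeneticCode,
    boundaries: dict[str, int] | None = None,
) -> CodonFrequencyTable:
    """Relative codon frequencies over a set of coding sequences.

    Codons are classified under ``code`` (possibly non-canonical, e.g. with
    UAG meaning leucine).  Coding codons are counted from the frame offset up
    to each transcript's termination codon; the termination codon itself is
    counted once per transcript in the STOP class.  The 3' boundary comes
    from ``boundaries`` (codon index of the termination codon), falling back
    to the transcript's declared CDS end, then to the first in-frame stop of
    ``code``.
    """
    if not cds_set:
        raise ValueError("no coding sequences supplied")
    counts: dict[str, Counter] = {}
    for cds in cds_set:
        if boundaries and cds.id in boundaries:
            term_idx = boundaries[cds.id]
        elif cds.declared_cds_end is not None:
            term_idx = (cds.declared_cds_end - cds.frame_offset) // 3
        else:
            term_idx = next(
                (i for i, c in enumerate(cds.codons(end=len(cds.seq))) if code.is_stop(c)),
                None,
            )
            if term_idx is None:
                raise ValueError(
                    f"{cds.id}: no termination codon found and no boundary declared"
                )
        all_codons = cds.codons(end=len(cds.seq))
        for codon in all_codons[:term_idx]:
            meaning = code.translate_codon(codon)
            if meaning == "X":
                continue  # ambiguous codons are not attributable to a class
            counts.setdefault(meaning, Counter())[codon] += 1
        if term_idx < len(all_codons):
            term_codon = all_codons[term_idx]
            if code.is_stop(term_codon):
                counts.setdefault("*", Counter())[term_codon] += 1
    classes = {}
    for meaning, ctr in counts.items():
        total = sum(ctr.values())
        classes[meaning] = sorted(
            (codon, 100.0 * n / total, n) for codon, n in ctr.items()
        )
    return CodonFrequencyTable(classes=classes)
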