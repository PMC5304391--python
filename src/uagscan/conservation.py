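"""Hyperconserved-position voting for the meaning of a reassigned codon.

If a focal taxon translates UAG as some amino acid, its UAG-backed alignment
columns should tend to sit at positions where the orthologues of other
species carry that amino acid.  The method locates the focal taxon's
UAG-backed columns (optionally requiring well-conserved 5-residue flanks),
classifies each column by its dominant residue at an identity threshold
(0.9 for hyperconserved, 0.5 for the permissive variant), and tallies which
residue the sites vote for.  Running the same tally on columns backed by
canonical codons of a candidate amino acid (e.g. CAA/CAG for glutamine)
gives a matched control distribution.

The focal sequence's own cell is excluded from the identity denominator:
it is X (or the codon under test) by construction, so including it would
make the threshold depend on alignment depth rather than conservation.
Gaps and X in non-focal rows are likewise excluded; a minimum-depth guard
keeps shallow columns from classifying.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .genetic_codes import AMINO_ACIDS
from .seqio import GAP, CodonAlignment, ProteinAlignment

FLANK_WIDTH = 5
NONE_LABEL = "NONE"


@dataclass(frozen=True)
class UagSite:
    """One focal-sequence alignment column backed by a codon of interest."""

    focal_seq_id: str
    column: int
    flank_ok: bool
    source_codon: str


@dataclass
class ColumnProfile:
    """Residue composition of one alignment column over non-focal sequences."""

    counts: dict[str, int]
    n_effective: int

    @property
    def identity_fraction(self) -> float:
        if self.n_effective == 0:
            return 0.0
        return max(self.counts.values()) / self.n_effective

    @property
    def most_frequent(self) -> str | None:
        if not self.counts:
            return None
        return max(self.counts, key=lambda r: (self.counts[r], r))


def column_profile(
    aln: ProteinAlignment, column: int, exclude: str | None = None
) -> ColumnProfile:
    """Count residues in a column, skipping gaps, X and the excluded row."""
    counts: Counter = Counter()
    for name, row in zip(aln.names, aln.rows):
        if name == exclude:
            continue
        cell = row[column]
        if cell == GAP or cell not in AMINO_ACIDS:
            continue
        counts[cell] += 1
    return ColumnProfile(counts=dict(counts), n_effective=sum(counts.values()))


class ConservationProfile:
    """Per-column conservation profiles of an alignment, focal row excluded."""

    def __init__(self, aln: ProteinAlignment, focal: str | None = None):
        if focal is not None and focal not in aln.names:
            raise KeyError(f"focal sequence {focal!r} not in alignment")
        self.alignment = aln
        self.focal = focal
        self._profiles: dict[int, ColumnProfile] = {}

    def __getitem__(self, column: int) -> ColumnProfile:
        if column not in self._profiles:
            self._profiles[column] = column_profile(
                self.alignment, column, exclude=self.focal
            )
        return self._profiles[column]


def find_candidate_sites(
    caln: CodonAlignment,
    focal: str,
    codon_class: set[str] = frozenset({"TAG"}),
    flank_threshold: float = 0.7,
    flank_width: int = FLANK_WIDTH,
) -> list[UagSite]:
    """Locate focal columns backed by a codon class and score their flanks.

    A site's ``flank_ok`` is true iff each of the ``flank_width`` columns on
    both sides exists, contains no focal gap, and reaches the flank identity
    threshold among non-focal sequences.  Sites near the alignment edge are
    still reported, with ``flank_ok=False``.
    """
    aln = caln.alignment
    if focal not in aln.names:
        raise KeyError(f"focal sequence {focal!r} not in alignment")
    profile = ConservationProfile(aln, focal=focal)
    focal_row = aln.row(focal)
    sites = []
    for col in caln.codon_columns(focal, codon_class):
        lo, hi = col - flank_width, col + flank_width
        if lo < 0 or hi >= aln.n_columns:
            ok = False
        else:
            flank_cols = list(range(lo, col)) + list(range(col + 1, hi + 1))
            ok = all(
                focal_row[j] != GAP and profile[j].identity_fraction >= flank_threshold
                for j in flank_cols
            )
        sites.append(
            UagSite(
                focal_seq_id=focal,
                column=col,
                flank_ok=ok,
                source_codon=caln.codon_map[focal][col],
            )
        )
    return sites


def classify_column(
    profile: ColumnProfile, threshold: float, min_depth: int = 10
) -> str:
    """Dominant residue of a column at an identity threshold, or NONE.

    The most frequent residue classifies iff its identity fraction reaches
    the threshold; a tied maximum (e.g. two residues at exactly a 0.5
    threshold) is conservative: NONE.  Columns shallower than ``min_depth``
    never classify.  Lowering the threshold can only add classified columns.
    """
    if profile.n_effective < min_depth or not profile.counts:
        return NONE_LABEL
    top = max(profile.counts.values())
    if top / profile.n_effective < threshold:
        return NONE_LABEL
    leaders = [r for r, n in profile.counts.items() if n == top]
    if len(leaders) > 1:
        return NONE_LABEL
    return leaders[0]


@dataclass
class VoteTally:
    """Histogram of dominant residues over candidate sites."""

    counts: dict[str, int]
    n_sites: int
    n_unclassified: int

    @property
    def n_classified(self) -> int:
        return self.n_sites - self.n_unclassified

    def percent_of_classified(self, residue: str) -> float:
        if self.n_classified == 0:
            return 0.0
        return 100.0 * self.counts.get(residue, 0) / self.n_classified


def tally_votes(
    sites: list[UagSite],
    profiles: ConservationProfile,
    threshold: float,
    min_depth: int = 10,
    require_flank: bool = True,
) -> VoteTally:
    """Tally the dominant residues at candidate-site columns.

    Sites failing the flank requirement (when enforced) and columns that do
    not classify at the threshold are reported as unclassified rather than
    dropped, so the tally always accounts for every input site.
    """
    if not sites:
        raise ValueError("no candidate sites to tally")
    counts: Counter = Counter()
    unclassified = 0
    for site in sites:
        if require_flank and not site.flank_ok:
            unclassified += 1
            continue
        residue = classify_column(profiles[site.column], threshold, min_depth=min_depth)
        if residue == NONE_LABEL:
            unclassified += 1
        else:
            counts[residue] += 1
    return VoteTally(
        counts=dict(counts), n_sites=len(sites), n_unclassified=unclassified
    )
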