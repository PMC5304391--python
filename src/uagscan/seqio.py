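"""Sequence, alignment and tree containers plus FASTA/Newick I/O.

Coordinates are 0-based half-open throughout; codon index ``i`` covers
nucleotides ``frame_offset + 3*i`` to ``frame_offset + 3*i + 3``.  DNA and
RNA input are both accepted; T is used internally and stop codons are
rendered as UAA/UAG/UGA only in user-facing reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_codes import GeneticCode

GAP = "-"


@dataclass
class CodingSequence:
    """A transcript (mRNA-sense) nucleotide sequence with reading-frame info."""

    id: str
    seq: str
    frame_offset: int = 0
    declared_cds_end: int | None = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        if not 0 <= self.frame_offset < 3:
            raise ValueError(f"{self.id}: frame_offset must be 0, 1 or 2")
        if self.declared_cds_end is not None:
            if self.declared_cds_end > len(self.seq):
                raise ValueError(f"{self.id}: declared_cds_end beyond sequence end")
            if (self.declared_cds_end - self.frame_offset) % 3:
                raise ValueError(f"{self.id}: declared_cds_end not in frame")

    def codons(self, end: int | None = None) -> list[str]:
        """Complete codons from the frame offset; trailing partial codon dropped."""
        stop = self.declared_cds_end if end is None else end
        if stop is None:
            stop = len(self.seq)
        usable = self.frame_offset + 3 * ((stop - self.frame_offset) // 3)
        return [self.seq[i : i + 3] for i in range(self.frame_offset, usable, 3)]

    def codon(self, index: int) -> str:
        start = self.frame_offset + 3 * index
        return self.seq[start : start + 3]

    @property
    def n_codons(self) -> int:
        return max(0, (len(self.seq) - self.frame_offset) // 3)


@dataclass
class ProteinAlignment:
    """A gapped amino-acid alignment: unique names, equal-length rows."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in count")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence identifiers in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("unequal lengths: alignment rows must all match")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def column(self, j: int) -> list[str]:
        return [r[j] for r in self.rows]

    def replaced(self, name: str, columns: list[int], letter: str) -> "ProteinAlignment":
        """Copy with ``letter`` written into the given columns of one row."""
        idx = self.names.index(name)
        chars = list(self.rows[idx])
        for j in columns:
            chars[j] = letter
        rows = list(self.rows)
        rows[idx] = "".join(chars)
        return ProteinAlignment(list(self.names), rows)


@dataclass
class CodonAlignment:
    """A protein alignment whose non-gap cells carry their source codons."""

    alignment: ProteinAlignment
    codon_map: dict[str, list[str | None]] = field(repr=False)
    code: GeneticCode

    def __post_init__(self) -> None:
        ncol = self.alignment.n_columns
        for name, codons in self.codon_map.items():
            if len(codons) != ncol:
                raise ValueError(f"{name}: codon map length != alignment length")

    def validate(self) -> None:
        """Check translate/map consistency for every non-gap cell."""
        for name, codons in self.codon_map.items():
            row = self.alignment.row(name)
            for j, codon in enumerate(codons):
                cell = row[j]
                if codon is None:
                    if cell != GAP:
                        raise ValueError(f"{name} column {j}: gap codon under residue {cell}")
                    continue
                aa = self.code.translate_codon(codon)
                if not _residues_compatible(cell, aa):
                    raise ValueError(
                        f"{name} column {j}: codon {codon} translates to {aa}, "
                        f"alignment has {cell}"
                    )

    def codon_columns(self, name: str, codon_class: set[str]) -> list[int]:
        """Columns of a row whose underlying codon is in ``codon_class``."""
        wanted = {c.upper().replace("U", "T") for c in codon_class}
        return [j for j, c in enumerate(self.codon_map[name]) if c in wanted]

    def uag_columns(self, name: str) -> list[int]:
        return self.codon_columns(name, {"TAG"})


class Tree:
    """A phylogeny with branch lengths, backed by dendropy."""

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        names = [leaf.taxon.label for leaf in dtree.leaf_node_iter()]
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf names in tree")
        self.leaf_names = names
        n_missing = 0
        for edge in dtree.preorder_edge_iter():
            if edge.head_node is dtree.seed_node:
                continue
            if edge.length is None:
                edge.length = 0.0
                n_missing += 1
            elif edge.length < 0:
                raise ValueError("negative branch length")
        if n_missing:
            warnings.warn(f"{n_missing} branch length(s) missing; set to 0", stacklevel=3)

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except dendropy.utility.error.DataParseError as exc:
            raise ValueError(f"invalid Newick: {exc}") from exc
        return cls(dtree)

    @property
    def total_length(self) -> float:
        return sum(
            e.length or 0.0
            for e in self._tree.preorder_edge_iter()
            if e.head_node is not self._tree.seed_node
        )

    @property
    def n_edges(self) -> int:
        return sum(
            1
            for e in self._tree.preorder_edge_iter()
            if e.head_node is not self._tree.seed_node
        )

    def bipartitions(self) -> set[frozenset[str]]:
        """Unordered leaf bipartitions (smaller side), for topology comparison."""
        all_leaves = frozenset(self.leaf_names)
        out = set()
        for node in self._tree.postorder_node_iter():
            if node is self._tree.seed_node or node.is_leaf():
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            out.add(min(below, all_leaves - below, key=lambda s: (len(s), sorted(s))))
        return out

    def postorder_edges(self):
        """Yield (node, parent, branch_length) in postorder, root last with parent None."""
        for node in self._tree.postorder_node_iter():
            if node is self._tree.seed_node:
                yield node, None, 0.0
            else:
                yield node, node.parent_node, float(node.edge.length)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


def _residues_compatible(a: str, b: str) -> bool:
    return a == b or a == "X" or b == "X"


def read_fasta(path: str | Path, alignment: bool = False):
    """Read a FASTA file as CDS records or, with ``alignment=True``, an alignment.

    Sequences are case-normalised to upper; duplicate identifiers and (in
    alignment mode) ragged rows are rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty FASTA file: {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate identifiers in {path}")
    if alignment:
        return ProteinAlignment(ids, [str(r.seq).upper() for r in records])
    return [CodingSequence(id=r.id, seq=str(r.seq)) for r in records]


def write_fasta(path: str | Path, entries) -> None:
    """Write CodingSequence objects or a ProteinAlignment to FASTA."""
    if isinstance(entries, ProteinAlignment):
        pairs = zip(entries.names, entries.rows)
    else:
        pairs = ((e.id, e.seq) for e in entries)
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in pairs]
    SeqIO.write(records, str(path), "fasta")


def read_newick(path: str | Path) -> Tree:
    """Read a Newick tree with branch lengths."""
    with open(path) as fh:
        return Tree.from_newick(fh.read())


def translate_cds(
    cds: CodingSequence, code: GeneticCode
) -> tuple[str, list[tuple[int, str]]]:
    """Conceptually translate a CDS under a genetic code.

    Translation halts at the first stop codon of the supplied code, which is
    reported as ``(codon_index, codon)``.  Codons containing N or other
    ambiguity translate to X and never count as stops.  A trailing incomplete
    codon is ignored; degenerate inputs give an empty protein.
    """
    protein = []
    stops: list[tuple[int, str]] = []
    for i, codon in enumerate(cds.codons()):
        aa = code.translate_codon(codon)
        if aa == "*":
            stops.append((i, codon))
            break
        protein.append(aa)
    return "".join(protein), stops


def map_alignment_to_codons(
    aln: ProteinAlignment,
    cds_set: list[CodingSequence],
    code: GeneticCode,
) -> CodonAlignment:
    """Link protein-alignment cells back to the codons of the underlying CDS.

    Each aligned row with gaps removed must equal the conceptual translation
    of its CDS (X-compatible: X on either side matches anything), which pins
    every non-gap cell to a unique source codon — in particular the cells
    backed by in-frame UAG codons.
    """
    by_id = {c.id: c for c in cds_set}
    codon_map: dict[str, list[str | None]] = {}
    for name, row in zip(aln.names, aln.rows):
        if name not in by_id:
            raise KeyError(f"no CDS provided for alignment row {name!r}")
        cds = by_id[name]
        protein, _ = translate_cds(cds, code)
        ungapped = row.replace(GAP, "")
        if len(ungapped) != len(protein):
            raise ValueError(
                f"{name}: aligned row has {len(ungapped)} residues but the CDS "
                f"translates to {len(protein)}"
            )
        codons = cds.codons()
        mapped: list[str | None] = []
        k = 0
        for j, cell in enumerate(row):
            if cell == GAP:
                mapped.append(None)
                continue
            if not _residues_compatible(cell, protein[k]):
                raise ValueError(
                    f"{name} column {j}: residue {cell} does not match "
                    f"translated {protein[k]}"
                )
            mapped.append(codons[k])
            k += 1
        codon_map[name] = mapped
    return CodonAlignment(alignment=aln, codon_map=codon_map, code=code)


def concatenate_alignments(
    alns: list[ProteinAlignment],
) -> tuple[ProteinAlignment, list[tuple[int, int]]]:
    """Concatenate alignments over a shared taxon namespace.

    Taxa missing from an alignment are padded with gaps over that partition.
    Returns the concatenated alignment and the 0-based half-open source
    ranges of each input.
    """
    if not alns:
        raise ValueError("no alignments to concatenate")
    taxa: list[str] = []
    for a in alns:
        for n in a.names:
            if n not in taxa:
                taxa.append(n)
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: list[tuple[int, int]] = []
    offset = 0
    for a in alns:
        ncol = a.n_columns
        partitions.append((offset, offset + ncol))
        offset += ncol
        for t in taxa:
            parts[t].append(a.row(t) if t in a.names else GAP * ncol)
    return ProteinAlignment(taxa, ["".join(parts[t]) for t in taxa]), partitions
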