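"""Transcriptome-wide screening filters over precomputed homology-search hits.

The screen consumes BLAST-style tabular hit files (no live database
searches): it keeps queries whose best hits are all eukaryotic and
frame-consistent, whose homolog support is deep enough for conservation
analysis, deduplicates alternative transcripts of the same gene, and hands
single-hsp survivors to the termination-codon survey.  Taxonomic division
of each subject is expected as a precomputed column; resolving it from
subject identifiers is the caller's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import stop_scan
from .genetic_codes import to_rna
from .seqio import CodingSequence

EUKARYOTE = "eukaryote"
CONTAMINANT_DIVISIONS = {"bacteria", "archaea", "virus"}

# common 12-column tabular layout plus frame and taxon-division extensions
DEFAULT_COLUMNS = [
    "query_id", "subject_id", "pident", "length", "mismatch", "gapopen",
    "query_start", "query_end", "subject_start", "subject_end",
    "evalue", "bitscore", "query_frame", "subject_taxon_division",
]


@dataclass(frozen=True)
class HitRecord:
    """One hsp of a database hit; coordinates 1-based inclusive as in the format."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    query_frame: int
    query_start: int
    query_end: int
    subject_taxon_division: str = "unknown"

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("negative e-value")
        if self.query_frame == 0 or abs(self.query_frame) > 3:
            raise ValueError("query frame must be in {-3..-1, 1..3}")


@dataclass
class ScreenDecision:
    query_id: str
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.reasons


def read_hits(path: str | Path, colmap: str | Path | dict | None = None) -> list[HitRecord]:
    """Read a tabular hit file; ``colmap`` maps field names to column indices."""
    if colmap is None:
        mapping = {name: i for i, name in enumerate(DEFAULT_COLUMNS)}
    elif isinstance(colmap, dict):
        mapping = colmap
    else:
        with open(colmap) as fh:
            mapping = yaml.safe_load(fh)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            HitRecord(
                query_id=str(row[mapping["query_id"]]),
                subject_id=str(row[mapping["subject_id"]]),
                evalue=float(row[mapping["evalue"]]),
                bitscore=float(row[mapping["bitscore"]]),
                query_frame=int(row[mapping["query_frame"]]),
                query_start=int(row[mapping["query_start"]]),
                query_end=int(row[mapping["query_end"]]),
                subject_taxon_division=str(row[mapping["subject_taxon_division"]]),
            )
        )
    return records


def group_by_query(hits: list[HitRecord]) -> dict[str, list[HitRecord]]:
    grouped: dict[str, list[HitRecord]] = {}
    for h in hits:
        grouped.setdefault(h.query_id, []).append(h)
    return grouped


def _ranked_subjects(hits: list[HitRecord]) -> list[tuple[str, list[HitRecord]]]:
    """Subjects ranked by their best hsp: e-value ascending, bitscore tiebreak."""
    by_subject: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_subject.setdefault(h.subject_id, []).append(h)
    def key(item):
        best = min(item[1], key=lambda h: (h.evalue, -h.bitscore))
        return (best.evalue, -best.bitscore, item[0])
    return sorted(by_subject.items(), key=key)


def filter_taxon_and_frame(hits: list[HitRecord], n_top: int = 5) -> ScreenDecision:
    """Taxon- and frame-consistency filter for one query.

    Passes iff the ``n_top`` best hits (distinct subjects) are all of
    eukaryotic origin and all hsps of the single best hit share one reading
    frame.  Queries whose top hits are all archaeal/eubacterial/viral get the
    separate ``contamination`` label.
    """
    if not hits:
        return ScreenDecision(query_id="", reasons=["no_hits"])
    query_id = hits[0].query_id
    ranked = _ranked_subjects(hits)
    reasons = []
    top = ranked[:n_top]
    divisions = [
        min(hsps, key=lambda h: (h.evalue, -h.bitscore)).subject_taxon_division
        for _, hsps in top
    ]
    if any(d != EUKARYOTE for d in divisions):
        if all(d in CONTAMINANT_DIVISIONS for d in divisions):
            reasons.append("contamination")
        else:
            reasons.append("non_eukaryotic_hit")
    best_hsps = ranked[0][1]
    if len({h.query_frame for h in best_hsps}) > 1:
        reasons.append("frame_conflict")
    return ScreenDecision(query_id=query_id, reasons=reasons)


def filter_min_informative(
    hits: list[HitRecord], min_hits: int = 50, evalue_max: float = 1e-30
) -> ScreenDecision:
    """Require enough close homologs: at least ``min_hits`` hits with
    e-value strictly below ``evalue_max``."""
    if not hits:
        return ScreenDecision(query_id="", reasons=["no_hits"])
    query_id = hits[0].query_id
    n_good = sum(1 for _, hsps in _ranked_subjects(hits)
                 if min(h.evalue for h in hsps) < evalue_max)
    reasons = [] if n_good >= min_hits else ["too_few_informative_hits"]
    return ScreenDecision(query_id=query_id, reasons=reasons)


def screen_queries(
    hits: list[HitRecord],
    n_top: int = 5,
    min_hits: int = 50,
    evalue_max: float = 1e-30,
) -> dict[str, ScreenDecision]:
    """Apply both filters to every query; filter order does not matter."""
    decisions = {}
    for query_id, qhits in group_by_query(hits).items():
        d1 = filter_taxon_and_frame(qhits, n_top=n_top)
        d2 = filter_min_informative(qhits, min_hits=min_hits, evalue_max=evalue_max)
        decisions[query_id] = ScreenDecision(
            query_id=query_id, reasons=d1.reasons + d2.reasons
        )
    return decisions


def dedupe_transcripts(
    groups: dict[str, str], hits: list[HitRecord]
) -> set[str]:
    """Keep one representative query per gene group.

    ``groups`` maps query id to a gene-grouping label (e.g. assembler gene
    ids).  Within each group the query whose best hit has the lowest e-value
    wins; ties break by highest bitscore, then lexicographic query id.
    """
    grouped_hits = group_by_query(hits)
    best_key = {}
    for query_id, qhits in grouped_hits.items():
        best = min(qhits, key=lambda h: (h.evalue, -h.bitscore))
        best_key[query_id] = (best.evalue, -best.bitscore, query_id)
    winners: dict[str, str] = {}
    for query_id, gene in sorted(groups.items()):
        if query_id not in best_key:
            continue
        if gene not in winners or best_key[query_id] < best_key[winners[gene]]:
            winners[gene] = query_id
    return set(winners.values())


@dataclass
class TerminationSurveyRow:
    query_id: str
    termination_codon: str
    termination_index: int | None
    uag_flagged: bool  # first downstream stop was UAG; re-checked as sense
    recheck_codon: str | None = None
    recheck_index: int | None = None


def survey_termination(
    queries: list[str],
    cds_by_id: dict[str, CodingSequence],
    hits: list[HitRecord],
) -> list[TerminationSurveyRow]:
    """Termination-codon survey downstream of each query's best-hit hsp.

    Only single-hsp queries are surveyed (multi-hsp queries are skipped to
    keep the aligned-region end unambiguous).  The first in-frame stop
    downstream of the hsp is reported; when it is UAG, the query is flagged
    and re-checked with UAG treated as a sense codon, mirroring the manual
    inspection step that finds the true UAA/UGA terminator further
    downstream.
    """
    grouped = group_by_query(hits)
    rows = []
    for query_id in queries:
        qhits = grouped.get(query_id, [])
        if not qhits:
            continue
        ranked = _ranked_subjects(qhits)
        best_hsps = ranked[0][1]
        if len(best_hsps) != 1:
            continue
        hsp = best_hsps[0]
        cds = cds_by_id[query_id]
        # 1-based inclusive nucleotide end -> 0-based half-open -> codon index
        end_nt = hsp.query_end
        if end_nt > len(cds.seq):
            raise ValueError(f"{query_id}: hsp end beyond sequence")
        end_codon = -(-(end_nt - cds.frame_offset) // 3)  # ceil: first codon after hsp
        report = stop_scan.infer_termination_codon(cds, end_codon, uag_is_sense=False)
        flagged = report.termination_codon == to_rna("TAG")
        recheck_codon = recheck_index = None
        if flagged:
            recheck = stop_scan.infer_termination_codon(cds, end_codon, uag_is_sense=True)
            recheck_codon = recheck.termination_codon
            recheck_index = recheck.termination_index
        rows.append(
            TerminationSurveyRow(
                query_id=query_id,
                termination_codon=report.termination_codon,
                termination_index=report.termination_index,
                uag_flagged=flagged,
                recheck_codon=recheck_codon,
                recheck_index=recheck_index,
            )
        )
    return rows
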