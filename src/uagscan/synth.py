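"""Synthetic fixtures: alignments evolved on a tree with a reassignment injected.

The generator emulates the data structure the inference modules assume:
conserved orthologue protein alignments in which one focal taxon's UAG-backed
columns all carry a single true residue.  Background columns evolve under the
substitution model (LG + discrete gamma by default) along a fixed tree;
reassigned columns evolve the same way except that the focal leaf's state is
forced to the true residue, representing a site whose focal codon is UAG.
Matched CDS fixtures are produced by weighted reverse translation, writing
TAG at the focal reassigned columns and appending a UAA/UGA terminator.

What this does not emulate: alignment error, compositional heterogeneity
across lineages, indels (off by default), or expression-linked codon bias
beyond a simple skew preset — conclusions from these fixtures are about the
algorithms, not about any real transcriptome.

All randomness flows from explicit integer seeds (default 1337).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._lg import AA_ORDER
from .genetic_codes import GeneticCode, get_code
from .phylo_ml import SubstitutionModel, build_model
from .screen import DEFAULT_COLUMNS, EUKARYOTE
from .seqio import CodingSequence, ProteinAlignment, Tree

DEFAULT_SEED = 1337

# terminator odds follow the observed survey pattern: UAA much more common
DEFAULT_TERMINATOR_ODDS = {"TAA": 56, "TGA": 15}


@dataclass
class SimSpec:
    """Parameters of one simulated alignment with an injected reassignment."""

    tree: Tree
    model: SubstitutionModel
    n_background_sites: int
    n_reassigned_sites: int
    focal: str
    true_residue: str
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.focal not in self.tree.leaf_names:
            raise ValueError(f"focal taxon {self.focal!r} not a tree leaf")
        if self.n_background_sites < 0 or self.n_reassigned_sites < 0:
            raise ValueError("site counts must be non-negative")
        if self.true_residue not in AA_ORDER:
            raise ValueError(f"invalid residue {self.true_residue!r}")


def random_tree(
    n_taxa: int,
    seed: int = DEFAULT_SEED,
    branch_length_range: tuple[float, float] = (0.02, 0.3),
    prefix: str = "t",
) -> Tree:
    """A random binary tree over ``t1..tN`` with uniform branch lengths."""
    rng = np.random.default_rng(seed)
    lo, hi = branch_length_range
    nodes = [f"{prefix}{i + 1}:{rng.uniform(lo, hi):.6f}" for i in range(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(lo, hi):.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return Tree.from_newick(f"({','.join(nodes)});")


def _focal_rooted_order(tree: Tree, focal: str):
    """Edges (parent, child, length) in preorder from the focal leaf.

    The substitution process is reversible and at stationarity, so evolving
    outward from any node — here the focal leaf — samples the same joint
    leaf distribution as evolving from the original root.
    """
    adjacency: dict[int, list[tuple[object, float]]] = {}
    for node in tree._tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        t = float(node.edge.length)
        adjacency.setdefault(id(parent), []).append((node, t))
        adjacency.setdefault(id(node), []).append((parent, t))
    start = next(
        leaf for leaf in tree._tree.leaf_node_iter() if leaf.taxon.label == focal
    )
    edges = []
    seen = {id(start)}
    stack = [start]
    while stack:
        node = stack.pop()
        for neighbor, t in adjacency.get(id(node), []):
            if id(neighbor) in seen:
                continue
            seen.add(id(neighbor))
            edges.append((node, neighbor, t))
            stack.append(neighbor)
    return start, edges


def simulate_alignment(spec: SimSpec) -> tuple[ProteinAlignment, list[int]]:
    """Evolve an alignment along the tree with a reassignment in the focal taxon.

    Each site gets a discrete-gamma category and evolves edge-wise under
    P(rate * t).  The traversal starts at the focal leaf (valid by model
    reversibility): background columns start from a draw from the stationary
    frequencies, while reassigned columns start from the true residue.  A
    reassigned column therefore represents a site whose focal codon is UAG
    and is homologous to the true residue — the rest of the column shows the
    conservation pattern the inference modules exploit.  Returns the
    alignment and the sorted ground-truth list of reassigned columns.
    """
    rng = np.random.default_rng(spec.seed)
    model, tree = spec.model, spec.tree
    n_sites = spec.n_background_sites + spec.n_reassigned_sites
    reassigned = sorted(
        rng.choice(n_sites, size=spec.n_reassigned_sites, replace=False).tolist()
    ) if n_sites else []
    pi = model.frequencies
    categories = rng.integers(0, model.ncat, size=n_sites)
    start, edges = _focal_rooted_order(tree, spec.focal)
    root_states = rng.choice(20, size=n_sites, p=pi)
    if reassigned:
        root_states[np.array(reassigned)] = AA_ORDER.index(spec.true_residue)
    states: dict[int, np.ndarray] = {id(start): root_states}
    leaf_states: dict[str, np.ndarray] = {spec.focal: root_states}
    for parent, child, t in edges:
        source = states[id(parent)]
        dest = np.empty(n_sites, dtype=np.int64)
        for c in range(model.ncat):
            mask = categories == c
            if not mask.any():
                continue
            P = model.transition_matrix(model.category_rates[c] * t)
            cum = P.cumsum(axis=1)
            u = rng.random(mask.sum())
            dest[mask] = (cum[source[mask]] > u[:, None]).argmax(axis=1)
        states[id(child)] = dest
        if child.is_leaf():
            leaf_states[child.taxon.label] = dest
    names = tree.leaf_names
    rows = ["".join(AA_ORDER[i] for i in leaf_states[name]) for name in names]
    return ProteinAlignment(list(names), rows), reassigned


def synonym_families(code: GeneticCode) -> dict[str, list[str]]:
    """Codons grouped by meaning under a code (amino acids only)."""
    fams: dict[str, list[str]] = {}
    for codon, aa in sorted(code.table.items()):
        if aa in AA_ORDER:
            fams.setdefault(aa, []).append(codon)
    return fams


def emit_cds_fixture(
    aln: ProteinAlignment,
    reassigned_columns: list[int],
    focal: str,
    codon_usage_weights: dict[str, float] | None = None,
    seed: int = DEFAULT_SEED,
    terminator_odds: dict[str, int] = DEFAULT_TERMINATOR_ODDS,
) -> tuple[list[CodingSequence], dict[str, int]]:
    """Reverse-translate a gap-free alignment into matched CDS fixtures.

    Synonymous codons are chosen with the given per-codon weights (uniform
    within each synonym family by default).  The focal row's reassigned
    columns are written as TAG; every sequence gets a terminal UAA/UGA stop
    drawn with the configured odds.  Returns the CDS records and a
    per-sequence boundary map giving the codon index of the terminator.
    """
    if any("-" in r for r in aln.rows):
        raise ValueError("CDS fixtures require a gap-free alignment")
    rng = np.random.default_rng(seed)
    fams = synonym_families(get_code("standard"))
    weights = {}
    for aa, codons in fams.items():
        w = np.array([codon_usage_weights.get(c, 1.0) if codon_usage_weights else 1.0
                      for c in codons])
        weights[aa] = w / w.sum()
    stops = list(terminator_odds)
    stop_p = np.array([terminator_odds[s] for s in stops], dtype=float)
    stop_p /= stop_p.sum()
    reassigned = set(reassigned_columns)
    out = []
    boundaries = {}
    for name, row in zip(aln.names, aln.rows):
        codons = []
        for j, aa in enumerate(row):
            if name == focal and j in reassigned:
                codons.append("TAG")
            else:
                codons.append(rng.choice(fams[aa], p=weights[aa]))
        codons.append(rng.choice(stops, p=stop_p))
        out.append(CodingSequence(id=name, seq="".join(codons)))
        boundaries[name] = len(row)
    return out, boundaries


UAG_SKEW_PRESET = {"TAG": 0.08}
"""Skew preset: give TAG ~8% of its synonym family, mimicking the observed
rarity of a freshly reassigned codon among its synonyms."""


@dataclass
class PlantedQuery:
    """A query with a planted screening outcome (empty reasons = pass)."""

    query_id: str
    reasons: list[str] = field(default_factory=list)


def emit_hit_fixture(
    patterns: list[PlantedQuery],
    seed: int = DEFAULT_SEED,
    n_top: int = 5,
    min_hits: int = 50,
    evalue_max: float = 1e-30,
    query_length: int = 600,
) -> list[list]:
    """Build hit-table rows whose screening decisions equal the planted patterns.

    Each query starts from a passing layout (``min_hits`` eukaryotic
    subjects below the e-value cutoff, single-frame best hit) and is then
    perturbed per planted reason:

    - ``frame_conflict``: a second hsp of the best hit in a different frame
    - ``non_eukaryotic_hit``: one of the top subjects set to bacteria
    - ``contamination``: all top subjects set to contaminant divisions
    - ``too_few_informative_hits``: informative hits capped at ``min_hits - 1``

    Rows follow the default column layout and can be written with
    ``write_hit_table``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for pat in patterns:
        reasons = set(pat.reasons)
        unknown = reasons - {
            "frame_conflict", "non_eukaryotic_hit", "contamination",
            "too_few_informative_hits",
        }
        if unknown:
            raise ValueError(f"{pat.query_id}: unplantable reasons {sorted(unknown)}")
        n_informative = min_hits if "too_few_informative_hits" not in reasons else min_hits - 1
        n_subjects = max(n_informative, n_top)
        # strictly decreasing significance so the ranking is unambiguous
        exponents = np.sort(rng.uniform(35, 80, size=n_subjects))[::-1]
        divisions = [EUKARYOTE] * n_subjects
        if "contamination" in reasons:
            for i in range(n_top):
                divisions[i] = rng.choice(["bacteria", "archaea", "virus"])
        elif "non_eukaryotic_hit" in reasons:
            divisions[rng.integers(1, n_top)] = "bacteria"
        for i in range(n_subjects):
            evalue = 10.0 ** -exponents[i]
            if i >= n_informative:
                evalue = float(evalue_max)  # exactly at the cutoff: not informative
            bitscore = round(100.0 + exponents[i], 1)
            end = query_length - 3 * int(rng.integers(5, 30))
            rows.append(_hit_row(pat.query_id, f"subj{i+1}", evalue, bitscore,
                                 1, 1, end, divisions[i]))
            if i == 0 and "frame_conflict" in reasons:
                rows.append(_hit_row(pat.query_id, "subj1", evalue * 10, bitscore - 5,
                                     2, 1, end, divisions[i]))
    return rows


def _hit_row(query_id, subject_id, evalue, bitscore, frame, qstart, qend, division):
    row = [None] * len(DEFAULT_COLUMNS)
    values = {
        "query_id": query_id, "subject_id": subject_id, "pident": 80.0,
        "length": (qend - qstart + 1) // 3, "mismatch": 10, "gapopen": 0,
        "query_start": qstart, "query_end": qend,
        "subject_start": 1, "subject_end": (qend - qstart + 1) // 3,
        "evalue": evalue, "bitscore": bitscore,
        "query_frame": frame, "subject_taxon_division": division,
    }
    for i, name in enumerate(DEFAULT_COLUMNS):
        row[i] = values[name]
    return row


def write_hit_table(path: str | Path, rows: list[list]) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_boundaries(path: str | Path, boundaries: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\ttermination_index\n")
        for name, idx in boundaries.items():
            fh.write(f"{name}\t{idx}\n")


def read_boundaries(path: str | Path) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            name, idx = line.rstrip("\n").split("\t")
            out[name] = int(idx)
    return out
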