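"""Genetic code tables with configurable UAG policy.

Nuclear stop-codon reassignments of the kind handled by this package leave
UAA/UGA as termination codons and give UAG a new meaning: either a concrete
amino acid (leucine in the rhizarian exLh lineage, glutamine in *Iotanema
spirale*) or, during screening, the non-committal placeholder X.  Codes are
stored as plain codon->letter tables over the 64 DNA triplets; RNA input
(U for T) is accepted everywhere and normalised internally.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Data import CodonTable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"
BASES = "TCAG"
ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]


def normalize_codon(codon: str) -> str:
    """Uppercase and convert RNA (U) to the internal DNA (T) alphabet."""
    return codon.upper().replace("U", "T")


def to_rna(codon: str) -> str:
    """Render a codon in RNA letters for user-facing output (TAG -> UAG)."""
    return codon.upper().replace("T", "U")


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon translation table plus the policy applied to UAG.

    Parameters
    ----------
    name:
        Short label ("standard", "uag_x", "uag_leu", ...).
    table:
        Mapping of each DNA codon to a one-letter amino acid, ``*`` (stop)
        or ``X`` (unknown; only TAG under the ``X`` policy).
    uag_policy:
        ``"STOP"``, ``"X"``, or the one-letter amino acid TAG is
        reassigned to.
    """

    name: str
    table: dict[str, str] = field(repr=False)
    uag_policy: str = "STOP"

    def __post_init__(self) -> None:
        missing = set(ALL_CODONS) - set(self.table)
        if missing:
            raise ValueError(f"genetic code {self.name!r} is missing codons: {sorted(missing)}")
        if self.uag_policy == "STOP":
            expected = STOP
        elif self.uag_policy == "X":
            expected = "X"
        elif self.uag_policy in AMINO_ACIDS:
            expected = self.uag_policy
        else:
            raise ValueError(f"invalid uag_policy {self.uag_policy!r}")
        if self.table["TAG"] != expected:
            raise ValueError(
                f"TAG maps to {self.table['TAG']!r}, inconsistent with "
                f"uag_policy={self.uag_policy!r}"
            )
        bad = self.stop_codons - {"TAA", "TAG", "TGA"}
        if bad:
            raise ValueError(f"unexpected stop codons {sorted(bad)}")

    @property
    def stop_codons(self) -> set[str]:
        return {c for c, aa in self.table.items() if aa == STOP}

    def translate_codon(self, codon: str) -> str:
        """Translate one codon; any non-ACGT base yields X (never a stop)."""
        codon = normalize_codon(codon)
        if len(codon) != 3:
            raise ValueError(f"not a codon: {codon!r}")
        if any(b not in "ACGT" for b in codon):
            return "X"
        return self.table[codon]

    def is_stop(self, codon: str) -> bool:
        codon = normalize_codon(codon)
        return codon in self.stop_codons


def _standard_table() -> dict[str, str]:
    ncbi = CodonTable.unambiguous_dna_by_id[1]
    table = dict(ncbi.forward_table)
    for stop in ncbi.stop_codons:
        table[stop] = STOP
    return table


def _variant(name: str, uag_policy: str, extra: dict[str, str] | None = None) -> GeneticCode:
    table = _standard_table()
    if uag_policy == "X":
        table["TAG"] = "X"
    elif uag_policy != "STOP":
        table["TAG"] = uag_policy
    if extra:
        table.update(extra)
    return GeneticCode(name=name, table=table, uag_policy=uag_policy)


BUILTIN_CODES: dict[str, GeneticCode] = {
    "standard": _variant("standard", "STOP"),
    # screening mode: UAG conceptually translated as an unknown amino acid
    "uag_x": _variant("uag_x", "X"),
    # UAG reassigned to leucine (rhizarian exLh pattern)
    "uag_leu": _variant("uag_leu", "L"),
    # UAG reassigned to glutamine (I. spirale pattern)
    "uag_gln": _variant("uag_gln", "Q"),
    # UAR -> glutamine (hexamitine diplomonad pattern): both UAG and UAA sense
    "uar_gln": _variant("uar_gln", "Q", extra={"TAA": "Q"}),
}


def get_code(name: str) -> GeneticCode:
    """Look up a built-in genetic code by name."""
    try:
        return BUILTIN_CODES[name]
    except KeyError:
        raise KeyError(
            f"unknown genetic code {name!r}; built-ins: {sorted(BUILTIN_CODES)}"
        ) from None


def load_codes(path: str | Path) -> dict[str, GeneticCode]:
    """Load user-defined codes from a JSON config.

    The file maps code names to ``{"uag_policy": ..., "overrides": {codon: letter}}``;
    each code starts from the standard table, applies the UAG policy, then any
    codon overrides.
    """
    with open(path) as fh:
        spec = json.load(fh)
    codes = {}
    for name, entry in spec.items():
        policy = entry.get("uag_policy", "STOP")
        overrides = {normalize_codon(c): aa for c, aa in entry.get("overrides", {}).items()}
        codes[name] = _variant(name, policy, extra=overrides or None)
    return codes
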