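"""Worked example: published 20-hypothesis scan scores for two organisms.

Two independent nuclear UAG reassignments have been characterised with the
phylogeny-informed scan implemented in :mod:`uagscan.phylo_ml`: a rhizarian
amoeba lineage ("exLh") where UAG encodes leucine, and the fornicate
flagellate *Iotanema spirale* where UAG encodes glutamine.  The dictionaries
below hold the reported log-likelihood scores of the 20 candidate alignments
(each with one amino acid written at all UAG-backed positions, scored on a
fixed reference tree under LG + gamma).  They serve as ready-made input for
:func:`uagscan.phylo_ml.conditional_probabilities`: the original alignments
are not needed to reproduce the conditional-probability arithmetic.
"""

RHIZARIAN_EXLH_LOGLIK: dict[str, float] = {
    "L": -362314.715,
    "I": -362502.554,
    "V": -362543.823,
    "M": -362553.384,
    "F": -362585.699,
    "A": -362632.167,
    "T": -362657.807,
    "Q": -362673.900,
    "R": -362687.179,
    "S": -362701.797,
    "K": -362710.573,
    "Y": -362713.231,
    "P": -362724.093,
    "H": -362741.154,
    "C": -362745.196,
    "E": -362745.729,
    "W": -362766.438,
    "N": -362774.796,
    "G": -362797.379,
    "D": -362848.162,
}
"""Rhizarian exLh: eight-protein concatenation, 71 in-frame UAG positions."""

IOTANEMA_SPIRALE_LOGLIK: dict[str, float] = {
    "Q": -55505.075,
    "E": -55582.654,
    "K": -55584.470,
    "R": -55632.340,
    "S": -55657.799,
    "A": -55659.005,
    "N": -55672.232,
    "T": -55677.733,
    "D": -55688.053,
    "H": -55708.978,
    "L": -55710.215,
    "P": -55750.281,
    "G": -55753.721,
    "V": -55757.545,
    "M": -55785.355,
    "I": -55808.382,
    "Y": -55825.982,
    "F": -55883.499,
    "C": -55936.549,
    "W": -55966.189,
}
"""*I. spirale*: 11-block concatenation, 96 in-frame UAG positions."""
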