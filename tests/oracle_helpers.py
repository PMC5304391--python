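"""Independent oracles shared by the unit and acceptance tests.

These deliberately avoid the package's pruning recursion and
eigendecomposition: transition matrices come from scipy's expm and the
likelihood is an exhaustive sum over all internal-node state assignments.
"""

import math

import numpy as np
from scipy.linalg import expm


def poisson_p_same(t):
    """P(identical end states) for the 20-state equal-rates model."""
    return 1 / 20 + (19 / 20) * math.exp(-20 * t / 19)


def enumeration_loglik(aln, tree, model):
    """Brute-force marginalisation over internal states (complete data only)."""
    nodes = [n for n, _, _ in tree.postorder_edges()]
    internal = [n for n in nodes if not n.is_leaf()]
    root = nodes[-1]
    edges = [(p, n, b) for n, p, b in tree.postorder_edges() if p is not None]
    from uagscan._lg import AA_ORDER

    leaf_rows = {
        name: [AA_ORDER.index(ch) for ch in aln.row(name)] for name in tree.leaf_names
    }
    internal_col = {id(n): j for j, n in enumerate(internal)}
    m = len(internal)
    combos = np.indices((20,) * m).reshape(m, -1).T  # (20^m, m)
    pi = model.frequencies
    lnL = 0.0
    for site in range(aln.n_columns):
        site_lik = 0.0
        for rate in model.category_rates:
            P = {id(n): expm(model.rate_matrix * rate * b) for _, n, b in edges}
            term = pi[combos[:, internal_col[id(root)]]].copy()
            for p, n, _ in edges:
                parent_states = combos[:, internal_col[id(p)]]
                if n.is_leaf():
                    child_states = leaf_rows[n.taxon.label][site]
                    term *= P[id(n)][parent_states, child_states]
                else:
                    term *= P[id(n)][parent_states, combos[:, internal_col[id(n)]]]
            site_lik += term.sum() / model.ncat
        lnL += math.log(site_lik)
    return lnL
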