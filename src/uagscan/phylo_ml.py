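"""Phylogeny-informed maximum-likelihood scan of candidate UAG meanings.

The engine computes the likelihood of a protein alignment on a fixed tree
with fixed branch lengths under LG + discrete gamma, by Felsenstein's
pruning algorithm.  The scan itself follows a simple conditional design:
assuming UAG codes for one single amino acid at all of the focal taxon's
UAG-backed columns, the alignment is modified 20 times — writing each
candidate amino acid into those cells — and each variant's log-likelihood
lnL_a is computed with the tree, branch lengths, and gamma shape alpha all
held fixed (alpha is pre-estimated on the alignment with UAG encoded as X).
The conditional probability of candidate a is then

    p_a = L_a / sum_b L_b = exp(lnL_a - m) / sum_b exp(lnL_b - m),

the ratio of its likelihood to the sum over all 20 hypotheses (evaluated
with the log-sum-exp shift m = max_b lnL_b for numerical safety).

Only the focal cells differ between the 20 evaluations, so the scan splits
the log-likelihood into a background part (computed once) and a focal-column
part (recomputed per hypothesis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ._lg import AA_ORDER, lg_exchangeabilities, lg_frequencies
from .seqio import CodonAlignment, ProteinAlignment, Tree

N_STATES = 20
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
MISSING = -1  # gap / X / ambiguity: all-ones partial likelihood

ALPHA_MIN, ALPHA_MAX = 0.02, 100.0


def discrete_gamma(alpha: float, k: int) -> np.ndarray:
    """Rates of k equal-probability discrete-gamma categories (category means).

    The continuous distribution is Gamma(alpha, alpha), mean 1.  Each
    category's rate is its conditional mean, so the discrete rates are
    non-decreasing and average exactly 1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if k < 1:
        raise ValueError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    bounds = gamma_dist.ppf(np.arange(k + 1) / k, a=alpha, scale=1.0 / alpha)
    # mean over [b_i, b_{i+1}) of Gamma(a, a) is the regularized incomplete
    # gamma with shape a+1 evaluated at a*b, times k for the 1/k mass
    upper = gammainc(alpha + 1.0, alpha * bounds[1:])
    lower = gammainc(alpha + 1.0, alpha * bounds[:-1])
    return k * (upper - lower)


@dataclass
class SubstitutionModel:
    """A reversible amino-acid model: exchangeabilities, frequencies, gamma rates.

    The rate matrix is Q_ij = R_ij * pi_j (i != j) with the diagonal set to
    minus the row sum, normalised so the expected rate at stationarity,
    -sum_i pi_i Q_ii, is 1; branch lengths are then expected substitutions
    per site.  Transition matrices are computed by symmetric
    eigendecomposition of the pi^(1/2)-similarity transform of Q.
    """

    exchangeabilities: np.ndarray = field(repr=False)
    frequencies: np.ndarray
    alpha: float = 1.0
    ncat: int = 4

    def __post_init__(self) -> None:
        R = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if R.shape != (N_STATES, N_STATES) or not np.allclose(R, R.T):
            raise ValueError("exchangeabilities must be a symmetric 20x20 matrix")
        if pi.shape != (N_STATES,) or np.any(pi <= 0):
            raise ValueError("frequencies must be 20 positive values")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        pi = pi / pi.sum()
        Q = R * pi[np.newaxis, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -np.sum(pi * np.diag(Q))
        Q /= scale
        self.frequencies = pi
        self.rate_matrix = Q
        self.category_rates = discrete_gamma(self.alpha, self.ncat)
        # symmetric form B = D^{1/2} Q D^{-1/2}; eigh gives orthonormal U
        sqrt_pi = np.sqrt(pi)
        B = Q * (sqrt_pi[:, np.newaxis] / sqrt_pi[np.newaxis, :])
        eigvals, U = np.linalg.eigh((B + B.T) / 2.0)
        self._eigvals = eigvals
        self._left = U / sqrt_pi[:, np.newaxis]  # D^{-1/2} U
        self._right = U.T * sqrt_pi[np.newaxis, :]  # U^T D^{1/2}

    def with_alpha(self, alpha: float) -> "SubstitutionModel":
        return SubstitutionModel(
            exchangeabilities=self.exchangeabilities,
            frequencies=self.frequencies,
            alpha=alpha,
            ncat=self.ncat,
        )

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, entries clipped at 0."""
        if t < 0:
            raise ValueError("negative evolutionary time")
        P = (self._left * np.exp(self._eigvals * t)[np.newaxis, :]) @ self._right
        return np.clip(P, 0.0, None)


def empirical_frequencies(aln: ProteinAlignment) -> np.ndarray:
    """Observed residue frequencies with add-one smoothing; gaps/X excluded."""
    counts = np.ones(N_STATES)
    for row in aln.rows:
        for ch in row:
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
    return counts / counts.sum()


def build_model(
    frequencies_mode: str = "lg_default",
    alpha: float = 1.0,
    ncat: int = 4,
    alignment: ProteinAlignment | None = None,
    exchangeabilities: np.ndarray | None = None,
) -> SubstitutionModel:
    """Construct an LG(+F) + discrete-gamma substitution model.

    ``frequencies_mode`` is ``"lg_default"`` (the LG stationary frequencies)
    or ``"empirical_from_alignment"`` (+F: counted from ``alignment`` with
    add-one smoothing).
    """
    R = lg_exchangeabilities() if exchangeabilities is None else exchangeabilities
    if frequencies_mode == "lg_default":
        pi = lg_frequencies()
    elif frequencies_mode == "empirical_from_alignment":
        if alignment is None:
            raise ValueError("empirical frequencies need an alignment")
        pi = empirical_frequencies(alignment)
    else:
        raise ValueError(f"unknown frequencies_mode {frequencies_mode!r}")
    return SubstitutionModel(
        exchangeabilities=R, frequencies=pi, alpha=alpha, ncat=ncat
    )


def encode_alignment(aln: ProteinAlignment, names: list[str]) -> np.ndarray:
    """Integer state matrix (len(names) x n_columns); missing data is -1."""
    mat = np.full((len(names), aln.n_columns), MISSING, dtype=np.int8)
    for i, name in enumerate(names):
        row = aln.row(name)
        for j, ch in enumerate(row):
            mat[i, j] = AA_INDEX.get(ch, MISSING)
    return mat


def _compress_patterns(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return patterns, counts


def _site_logliks(
    patterns: np.ndarray, tree: Tree, model: SubstitutionModel, leaf_order: list[str]
) -> np.ndarray:
    """Per-pattern log-likelihoods via pruning, gamma-averaged over categories."""
    n_pat = patterns.shape[1]
    leaf_row = {name: i for i, name in enumerate(leaf_order)}
    pi = model.frequencies
    k = model.ncat
    per_cat = np.empty((k, n_pat))
    for c, rate in enumerate(model.category_rates):
        partials: dict[int, np.ndarray] = {}
        scaler = np.zeros(n_pat)
        root_partial = None
        for node, parent, blen in tree.postorder_edges():
            if node.is_leaf():
                states = patterns[leaf_row[node.taxon.label]]
                L = np.zeros((n_pat, N_STATES))
                observed = states >= 0
                L[observed, states[observed]] = 1.0
                L[~observed, :] = 1.0
            else:
                L = np.ones((n_pat, N_STATES))
                for child in node.child_nodes():
                    L *= partials.pop(id(child))
                # rescale to avoid underflow on deep trees
                m = L.max(axis=1)
                m[m == 0.0] = 1.0
                L /= m[:, np.newaxis]
                scaler += np.log(m)
            if parent is None:
                root_partial = L
            else:
                P = model.transition_matrix(rate * blen)
                partials[id(node)] = L @ P.T
        per_cat[c] = np.log(root_partial @ pi) + scaler
    # average likelihood over equal-probability categories, in log space
    m = per_cat.max(axis=0)
    return m + np.log(np.mean(np.exp(per_cat - m), axis=0))


def tree_loglik(
    aln: ProteinAlignment, tree: Tree, model: SubstitutionModel
) -> float:
    """Log-likelihood of an alignment on a fixed tree under the model.

    Gaps, X and any non-standard residue contribute all-ones partial
    likelihoods (missing data).  Identical site patterns are compressed
    before pruning, which leaves the result unchanged.
    """
    missing = set(tree.leaf_names) - set(aln.names)
    if missing:
        raise ValueError(f"tree leaves without sequences: {sorted(missing)}")
    mat = encode_alignment(aln, tree.leaf_names)
    patterns, counts = _compress_patterns(mat)
    site_ll = _site_logliks(patterns, tree, model, tree.leaf_names)
    lnL = float(site_ll @ counts)
    if not np.isfinite(lnL):
        raise ValueError("non-finite log-likelihood")
    return lnL


@dataclass
class AlphaEstimate:
    alpha: float
    loglik: float
    at_bound: bool


def estimate_alpha(
    aln: ProteinAlignment,
    tree: Tree,
    model: SubstitutionModel | None = None,
    bounds: tuple[float, float] = (ALPHA_MIN, ALPHA_MAX),
) -> AlphaEstimate:
    """Maximum-likelihood gamma shape on a fixed tree.

    One-dimensional bounded maximisation of the tree log-likelihood over
    log(alpha), to a relative tolerance of 1e-4.  Intended for the alignment
    with UAG sites masked as X; the estimate is then held fixed during the
    hypothesis scan.  Rate-homogeneous data drive the estimate to the upper
    bound, which is flagged via ``at_bound``.
    """
    base = model or build_model()
    missing = set(tree.leaf_names) - set(aln.names)
    if missing:
        raise ValueError(f"tree leaves without sequences: {sorted(missing)}")
    mat = encode_alignment(aln, tree.leaf_names)
    patterns, counts = _compress_patterns(mat)

    def neg_loglik(log_alpha: float) -> float:
        m = base.with_alpha(float(np.exp(log_alpha)))
        return -float(_site_logliks(patterns, tree, m, tree.leaf_names) @ counts)

    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    res = minimize_scalar(
        neg_loglik, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4}
    )
    if not res.success:
        raise RuntimeError(f"alpha optimisation failed: {res.message}")
    alpha = float(np.exp(res.x))
    at_bound = alpha <= bounds[0] * 1.01 or alpha >= bounds[1] * 0.99
    if at_bound:
        warnings.warn(
            f"alpha estimate {alpha:.4g} at optimisation bound; "
            "data may be rate-homogeneous",
            stacklevel=2,
        )
    return AlphaEstimate(alpha=alpha, loglik=-float(res.fun), at_bound=at_bound)


def conditional_probabilities(loglik: dict[str, float]) -> dict[str, float]:
    """Conditional probability of each hypothesis from its log-likelihood.

    p_a = exp(lnL_a - m) / sum_b exp(lnL_b - m) with m = max lnL; the
    probabilities sum to 1 and preserve the lnL ordering.
    """
    if len(loglik) < 2:
        raise ValueError("need at least two hypotheses")
    values = np.array(list(loglik.values()), dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite log-likelihood input")
    shifted = np.exp(values - values.max())
    probs = shifted / shifted.sum()
    return dict(zip(loglik.keys(), probs))


@dataclass
class HypothesisScan:
    """Result of the 20-hypothesis scan for the meaning of a reassigned codon."""

    loglik: dict[str, float]
    alpha_used: float
    cond_prob: dict[str, float]
    best: str
    n_sites: int  # number of focal reassigned columns

    def ranked(self) -> list[tuple[str, float, float]]:
        """(amino acid, lnL, conditional probability), best first."""
        return sorted(
            (
                (a, self.loglik[a], self.cond_prob[a])
                for a in self.loglik
            ),
            key=lambda t: -t[1],
        )


def _column_subset(aln: ProteinAlignment, columns: list[int]) -> ProteinAlignment:
    cols = set(columns)
    rows = ["".join(r[j] for j in range(aln.n_columns) if j in cols) for r in aln.rows]
    return ProteinAlignment(list(aln.names), rows)


def hypothesis_scan(
    caln: CodonAlignment,
    tree: Tree,
    focal: str,
    model: SubstitutionModel | None = None,
    alpha: float | None = None,
) -> HypothesisScan:
    """Score all 20 candidate meanings of the focal taxon's UAG codons.

    The focal row's UAG-backed cells are first masked as X; alpha is
    estimated on that masked alignment unless supplied.  Each candidate
    amino acid is then written into those cells and the alignment's
    log-likelihood computed with everything else fixed.  With no UAG-backed
    columns the scan is degenerate: all lnL equal, p_a = 0.05 each.
    """
    base = model or build_model()
    uag_cols = caln.uag_columns(focal)
    masked = caln.alignment.replaced(focal, uag_cols, "X")
    if alpha is None:
        alpha = estimate_alpha(masked, tree, base).alpha
    fitted = base.with_alpha(alpha)

    background_cols = [j for j in range(masked.n_columns) if j not in set(uag_cols)]
    lnL_bg = (
        tree_loglik(_column_subset(masked, background_cols), tree, fitted)
        if background_cols
        else 0.0
    )
    focal_aln = _column_subset(masked, uag_cols) if uag_cols else None
    loglik: dict[str, float] = {}
    for aa in AA_ORDER:
        if focal_aln is None:
            loglik[aa] = lnL_bg
            continue
        variant = focal_aln.replaced(focal, list(range(len(uag_cols))), aa)
        loglik[aa] = lnL_bg + tree_loglik(variant, tree, fitted)
    cond = conditional_probabilities(loglik)
    best = max(loglik, key=lambda a: (loglik[a], a))
    return HypothesisScan(
        loglik=loglik,
        alpha_used=alpha,
        cond_prob=cond,
        best=best,
        n_sites=len(uag_cols),
    )
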