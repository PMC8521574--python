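"""Standard genetic code tables over the 61 sense codons, and the GY94 codon
rate matrix.

All codon-state arithmetic in the package runs over integer indices into
:data:`CODONS`, the alphabetically sorted list of sense codons of the standard
nuclear code (stop codons excluded, so simulated sequences can never contain
an internal stop by construction). Index ``-1`` is the gap/missing sentinel.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

NUCS = "ACGT"
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))

#: the 61 sense codons of the standard code, alphabetical
CODONS: tuple[str, ...] = tuple(
    sorted(c for c in _TABLE.forward_table if set(c) <= set(NUCS))
)
N_CODONS = len(CODONS)
assert N_CODONS == 61

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
#: amino acid (one-letter) per sense codon, aligned with CODONS
CODON_AA: tuple[str, ...] = tuple(_TABLE.forward_table[c] for c in CODONS)
CODON_AA_ARRAY = np.array(CODON_AA)

AMINO_ACIDS = tuple(sorted(set(CODON_AA)))
GAP = "-"
UNKNOWN = "X"

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _single_step_pairs():
    ii, jj, ts, syn = [], [], [], []
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i >= j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            ii.append(i)
            jj.append(j)
            ts.append(diffs[0] in _TRANSITIONS)
            syn.append(CODON_AA[i] == CODON_AA[j])
    return (
        np.asarray(ii, dtype=np.intp),
        np.asarray(jj, dtype=np.intp),
        np.asarray(ts, dtype=bool),
        np.asarray(syn, dtype=bool),
    )


#: index arrays over unordered single-nucleotide-step codon pairs
PAIR_I, PAIR_J, PAIR_IS_TRANSITION, PAIR_IS_SYNONYMOUS = _single_step_pairs()


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon; raises on stop/invalid."""
    try:
        return _TABLE.forward_table[codon]
    except KeyError:
        raise ValueError(f"not a sense codon: {codon!r}") from None


def uniform_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_frequencies(pos_nuc_freqs: np.ndarray) -> np.ndarray:
    """Codon frequencies from a 3x4 matrix of per-position nucleotide
    frequencies (rows = codon positions in ACGT order), renormalised over the
    61 sense codons."""
    f = np.asarray(pos_nuc_freqs, dtype=float)
    if f.shape != (3, 4):
        raise ValueError("expected a 3x4 nucleotide frequency matrix")
    nuc_idx = {n: k for k, n in enumerate(NUCS)}
    pi = np.array(
        [f[0, nuc_idx[c[0]]] * f[1, nuc_idx[c[1]]] * f[2, nuc_idx[c[2]]] for c in CODONS]
    )
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate nucleotide frequencies")
    return pi / total


def validate_frequencies(pi: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,):
        raise ValueError(f"codon frequency vector must have length {N_CODONS}")
    if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-12:
        raise ValueError("codon frequencies must be nonnegative and sum to 1")
    return pi


def codon_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """GY94-style 61x61 instantaneous rate matrix.

    Off-diagonal ``q_ij`` is nonzero only for single-nucleotide changes:
    ``pi_j``, multiplied by ``kappa`` for transitions and ``omega`` for
    nonsynonymous changes. The matrix is rescaled so the mean rate at
    stationarity, ``-sum_i pi_i q_ii``, equals 1: branch lengths are then
    expected substitutions per codon site.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    pi = validate_frequencies(pi)
    factor = np.ones(PAIR_I.shape[0])
    factor[PAIR_IS_TRANSITION] *= kappa
    factor[~PAIR_IS_SYNONYMOUS] *= omega
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[PAIR_I, PAIR_J] = factor * pi[PAIR_J]
    Q[PAIR_J, PAIR_I] = factor * pi[PAIR_I]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -np.dot(pi, np.diag(Q))
    if mean_rate <= 0:
        raise ValueError("degenerate rate matrix (zero mean rate)")
    return Q / mean_rate


def relative_rate(kappa: float, omega: float, pi: np.ndarray) -> float:
    """Total substitution rate of an omega-class site relative to a neutral
    (omega = 1) site, at stationarity under GY94.

    The unscaled GY94 mean rate is linear in omega, ``A(kappa) + omega *
    B(kappa)`` with A the synonymous and B the nonsynonymous flow, so the
    ratio is ``(A + omega B) / (A + B)``. Branch lengths throughout the
    package are expected substitutions per codon site *for a neutral site*;
    class generators act for time stretched by this factor — purifying
    classes accumulate proportionally fewer substitutions, positively
    selected foreground sites proportionally more (the convention codeml's
    common scaling implies, up to the unit choice).
    """
    pi = validate_frequencies(pi)
    flow = pi[PAIR_I] * pi[PAIR_J] * np.where(PAIR_IS_TRANSITION, kappa, 1.0)
    syn = 2.0 * flow[PAIR_IS_SYNONYMOUS].sum()
    nonsyn = 2.0 * flow[~PAIR_IS_SYNONYMOUS].sum()
    return (syn + omega * nonsyn) / (syn + nonsyn)


class CodonEigen:
    """Spectral decomposition of a reversible codon rate matrix.

    Exploits reversibility: ``diag(pi)^(1/2) Q diag(pi)^(-1/2)`` is symmetric,
    so transition matrices ``P(t) = exp(Qt)`` come from one `eigh` per Q.
    """

    __slots__ = ("eigvals", "_right", "_left")

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        sqrt_pi = np.sqrt(np.maximum(pi, 1e-300))
        S = Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        S = 0.5 * (S + S.T)  # symmetrise away rounding noise
        w, U = np.linalg.eigh(S)
        self.eigvals = w
        self._right = U / sqrt_pi[:, None]
        self._left = U.T * sqrt_pi[None, :]

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be >= 0")
        P = (self._right * np.exp(self.eigvals * t)) @ self._left
        np.clip(P, 0.0, None, out=P)
        # renormalise rows (rounding can leave sums ~1e-15 off 1)
        P /= P.sum(axis=1, keepdims=True)
        return P
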