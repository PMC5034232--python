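"""Codon substitution machinery: the standard genetic code, the
Goldman-Yang (GY94) rate matrix, beta site-class discretization, and
codon-frequency estimators.

The GY94 model assigns instantaneous rate ``q_ij = pi_j * kappa^[transition]
* omega^[nonsynonymous]`` to every pair of sense codons differing at exactly
one nucleotide position, and zero to all other pairs.  ``kappa`` is the
transition/transversion rate ratio, ``omega = dN/dS`` the
nonsynonymous/synonymous rate ratio, and ``pi`` the stationary codon
frequencies.  The chain is time-reversible with stationary distribution
``pi``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.special import betainc, betaincinv

NUCLEOTIDES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")

#: The 61 sense codons of the standard genetic code, alphabetical order.
SENSE_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in product(NUCLEOTIDES, repeat=3) if "".join(c) not in STOP_CODONS
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_codon(codon: str) -> str:
    """Amino acid (one-letter) for a codon; '*' for a stop codon."""
    return _CODON_TABLE[codon.upper().replace("U", "T")]


def is_stop(codon: str) -> bool:
    return codon.upper().replace("U", "T") in STOP_CODONS


def _build_pair_tables():
    """Index arrays over all ordered sense-codon pairs one nucleotide apart."""
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    src, dst, is_ts, is_nonsyn = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            src.append(i)
            dst.append(j)
            is_ts.append(diffs[0] in transitions)
            is_nonsyn.append(_CODON_TABLE[ci] != _CODON_TABLE[cj])
    return (
        np.asarray(src, dtype=np.intp),
        np.asarray(dst, dtype=np.intp),
        np.asarray(is_ts, dtype=bool),
        np.asarray(is_nonsyn, dtype=bool),
    )


_PAIR_SRC, _PAIR_DST, _PAIR_TS, _PAIR_NONSYN = _build_pair_tables()


def codon_differences(codon_a: str, codon_b: str) -> tuple[int, bool]:
    """(number of differing positions, any-difference-is-nonsynonymous).

    The nonsynonymy flag is only meaningful for single-difference pairs; for
    multi-step pairs it reports whether the two codons encode different
    amino acids.
    """
    ndiff = sum(a != b for a, b in zip(codon_a, codon_b))
    return ndiff, _CODON_TABLE[codon_a] != _CODON_TABLE[codon_b]


@dataclass(frozen=True)
class CodonRateModel:
    """A normalized GY94 rate matrix together with its parameters."""

    kappa: float
    omega: float
    pi: np.ndarray  # (61,)
    Q: np.ndarray  # (61, 61), rows sum to zero, mean rate 1

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")


def validate_codon_frequencies(pi: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,):
        raise ValueError(f"codon frequency vector must have length {N_CODONS}")
    if np.any(pi < 0):
        raise ValueError("codon frequencies must be non-negative")
    if abs(pi.sum() - 1.0) > 1e-12:
        raise ValueError("codon frequencies must sum to 1 within 1e-12")
    return pi


def build_unnormalized_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """GY94 rate matrix before mean-rate scaling (diagonal filled)."""
    rates = np.where(_PAIR_TS, kappa, 1.0) * np.where(_PAIR_NONSYN, omega, 1.0)
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[_PAIR_SRC, _PAIR_DST] = rates * pi[_PAIR_DST]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def build_codon_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> CodonRateModel:
    """Build a GY94 model scaled to one expected substitution per unit time.

    Scaling: ``-sum_i pi_i Q_ii = 1``, so branch lengths below the matrix are
    in expected codon substitutions per codon site at this omega.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    pi = validate_codon_frequencies(pi)
    Q = build_unnormalized_rate_matrix(kappa, omega, pi)
    rate = -float(pi @ np.diag(Q))
    if rate <= 0:
        raise ValueError("degenerate model: zero mean substitution rate")
    return CodonRateModel(kappa=kappa, omega=omega, pi=pi, Q=Q / rate)


def spectral_decomposition(Q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of a reversible rate matrix.

    Returns ``(A, lam, B)`` with ``expm(Q t) = A @ diag(exp(lam t)) @ B``.
    Uses the similarity transform ``diag(sqrt(pi)) Q diag(1/sqrt(pi))``,
    which is symmetric for reversible Q, so a stable symmetric
    eigendecomposition applies.
    """
    sqrt_pi = np.sqrt(np.maximum(pi, 1e-300))
    S = Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
    S = 0.5 * (S + S.T)  # symmetrize away rounding noise
    lam, U = np.linalg.eigh(S)
    A = U / sqrt_pi[:, None]
    B = U.T * sqrt_pi[None, :]
    return A, lam, B


def transition_matrix(A: np.ndarray, lam: np.ndarray, B: np.ndarray, t: float) -> np.ndarray:
    """``expm(Q t)`` from a spectral decomposition; tiny negatives clipped."""
    P = (A * np.exp(lam * t)) @ B
    np.clip(P, 0.0, None, out=P)
    return P


def discretize_beta(p: float, q: float, ncat: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Discretize Beta(p, q) into ``ncat`` equal-probability classes.

    Each class gets weight ``1/ncat`` and its value is the conditional mean
    of the beta distribution over the corresponding quantile bin, computed
    with regularized incomplete-beta ratios:

        value_k = ncat * p/(p+q) * [I(x_{k+1}; p+1, q) - I(x_k; p+1, q)]

    where x_k is the k/ncat quantile of Beta(p, q).
    """
    if p <= 0 or q <= 0:
        raise ValueError("beta shape parameters must be > 0")
    if ncat < 2:
        raise ValueError("ncat must be >= 2")
    edges = np.empty(ncat + 1)
    edges[0], edges[-1] = 0.0, 1.0
    edges[1:-1] = betaincinv(p, q, np.arange(1, ncat) / ncat)
    inc = betainc(p + 1.0, q, edges)
    values = ncat * (p / (p + q)) * np.diff(inc)
    values = np.clip(values, 1e-12, 1.0 - 1e-12)
    weights = np.full(ncat, 1.0 / ncat)
    return values, weights


def site_class_distribution(
    model: str,
    p: float | None = None,
    q: float | None = None,
    p0: float | None = None,
    omega_s: float | None = None,
    omega: float | None = None,
    ncat: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Class values and weights for the M0, M7, or M8 site-class model.

    M7: omega ~ Beta(p, q) discretized into ncat classes.
    M8: the M7 classes with total weight p0 plus one class at omega_s >= 1
    with weight 1 - p0.  M0: a single class at omega.
    """
    model = model.upper()
    if model == "M0":
        if omega is None:
            raise ValueError("M0 requires omega")
        return np.array([float(omega)]), np.array([1.0])
    if p is None or q is None:
        raise ValueError(f"{model} requires beta shapes p and q")
    values, weights = discretize_beta(p, q, ncat=ncat)
    if model == "M7":
        return values, weights
    if model == "M8":
        if p0 is None or omega_s is None:
            raise ValueError("M8 requires p0 and omega_s")
        if not 0.0 <= p0 <= 1.0:
            raise ValueError("p0 must be in [0, 1]")
        if omega_s < 1.0:
            raise ValueError("M8 selected-class omega_s must be >= 1")
        return (
            np.concatenate([values, [float(omega_s)]]),
            np.concatenate([weights * p0, [1.0 - p0]]),
        )
    raise ValueError(f"unknown site model {model!r}")


def uniform_codon_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


_NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}
_FREQ_FLOOR = 1e-6  # keeps F3x4 frequencies strictly positive on short genes


def f3x4_frequencies(sequences: list[str]) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts.

    Counts A/C/G/T separately at the three codon positions over all
    sequences (gaps and ambiguous bases ignored), forms the product
    frequency for each sense codon, and renormalizes over the 61 sense
    codons.  Frequencies are floored at a small positive value so that
    likelihood computations on sparse alignments stay well conditioned.
    """
    counts = np.zeros((3, 4))
    for seq in sequences:
        s = seq.upper().replace("U", "T")
        for i in range(0, len(s) - len(s) % 3, 3):
            for k in range(3):
                idx = _NUC_INDEX.get(s[i + k])
                if idx is not None:
                    counts[k, idx] += 1
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        return uniform_codon_frequencies()
    nuc_freq = counts / totals
    pi = np.array(
        [
            nuc_freq[0, _NUC_INDEX[c[0]]]
            * nuc_freq[1, _NUC_INDEX[c[1]]]
            * nuc_freq[2, _NUC_INDEX[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    pi = np.maximum(pi, _FREQ_FLOOR)
    return pi / pi.sum()


def f61_frequencies(sequences: list[str]) -> np.ndarray:
    """Empirical sense-codon frequencies (codeml CodonFreq=3 style)."""
    counts = np.zeros(N_CODONS)
    for seq in sequences:
        s = seq.upper().replace("U", "T")
        for i in range(0, len(s) - len(s) % 3, 3):
            idx = CODON_INDEX.get(s[i : i + 3])
            if idx is not None:
                counts[idx] += 1
    if counts.sum() == 0:
        return uniform_codon_frequencies()
    pi = np.maximum(counts / counts.sum(), _FREQ_FLOOR)
    return pi / pi.sum()
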