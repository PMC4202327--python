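"""Codon substitution models (Goldman–Yang style).

State space: the 61 sense codons of the standard genetic code.  Off-diagonal
rates are nonzero only between codons differing at a single nucleotide
position::

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

scaled so one unit of branch length is one expected substitution per codon.
Reversibility with respect to ``pi`` gives stable spectral transition
matrices.  The same machinery serves the pairwise dN/dS estimator, the
branch-specific asymmetry tests, the branch-site mixture model, and the
codon simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NUCS = "TCAG"
NUC_INDEX = {n: i for i, n in enumerate(NUCS)}

#: Sense codons in TCAG-major order (the conventional codon-model ordering).
SENSE_CODONS: list[str] = [
    a + b + c
    for a in NUCS
    for b in NUCS
    for c in NUCS
    if a + b + c not in standard_dna_table.stop_codons
]
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)  # 61
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
CODON_AA = [standard_dna_table.forward_table[c] for c in SENSE_CODONS]

_PURINES = {"A", "G"}


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


def _pair_structure() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Index arrays (i, j, ts_flag, nonsyn_flag) for single-nt codon pairs."""
    ii, jj, ts, ns = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            ii.append(i)
            jj.append(j)
            ts.append(_is_transition(ci[k], cj[k]))
            ns.append(CODON_AA[i] != CODON_AA[j])
    return (np.array(ii), np.array(jj),
            np.array(ts, dtype=bool), np.array(ns, dtype=bool))


_PAIR_I, _PAIR_J, _PAIR_TS, _PAIR_NS = _pair_structure()


def uniform_codon_freqs() -> np.ndarray:
    return np.full(N_SENSE, 1.0 / N_SENSE)


def f3x4_freqs(codon_columns: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies from observed codon-state columns.

    Parameters
    ----------
    codon_columns
        Integer array of sense-codon indices (any shape); all sequences and
        sites of the alignment pooled by the caller.
    """
    counts = np.zeros((3, 4))
    flat = np.asarray(codon_columns).ravel()
    for idx in flat:
        codon = SENSE_CODONS[int(idx)]
        for pos in range(3):
            counts[pos, NUC_INDEX[codon[pos]]] += 1
    if counts.sum() == 0:
        raise ValueError("no codons supplied for F3x4 estimation")
    # guard: a nucleotide absent from a position would zero out codons
    counts += 0.5
    pos_freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array([
        pos_freqs[0, NUC_INDEX[c[0]]]
        * pos_freqs[1, NUC_INDEX[c[1]]]
        * pos_freqs[2, NUC_INDEX[c[2]]]
        for c in SENSE_CODONS
    ])
    return pi / pi.sum()


@dataclass(frozen=True)
class CodonQ:
    """A single (kappa, omega, pi) codon rate matrix with spectral P(t)."""

    kappa: float
    omega: float
    freqs: tuple  # hashable 61-tuple

    def __post_init__(self):
        if self.kappa <= 0 or self.omega < 0:
            raise ValueError("kappa must be > 0 and omega >= 0")
        if len(self.freqs) != N_SENSE:
            raise ValueError("codon frequency vector must cover the 61 sense codons")

    @property
    def pi(self) -> np.ndarray:
        return np.asarray(self.freqs)

    def _build(self):
        pi = self.pi
        q = np.zeros((N_SENSE, N_SENSE))
        rate = pi[_PAIR_J].copy()
        rate[_PAIR_TS] *= self.kappa
        rate[_PAIR_NS] *= self.omega
        q[_PAIR_I, _PAIR_J] = rate
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(pi * np.diag(q)).sum()
        if scale <= 0:  # omega=0 with no synonymous moves cannot happen for 61 codons
            scale = 1.0
        q /= scale
        return q, scale

    @property
    def rate_matrix(self) -> np.ndarray:
        return self._spectral()[3]

    @lru_cache(maxsize=None)
    def _spectral(self):
        q, _ = self._build()
        pi = self.pi
        mask = pi > 0
        d = np.sqrt(np.where(mask, pi, 1.0))
        b = (q * d[:, None]) / d[None, :]
        evals, u = np.linalg.eigh((b + b.T) / 2.0)
        right = u / d[:, None]
        left = u * d[:, None]
        return evals, right, left, q

    def transition_matrix(self, t: float) -> np.ndarray:
        if not np.isfinite(t) or t < 0:
            raise ValueError(f"branch length must be finite and >= 0, got {t}")
        evals, right, left, _ = self._spectral()
        p = (right * np.exp(evals * t)) @ left.T
        return np.clip(p, 0.0, None)

    def flux_fractions(self) -> tuple[float, float]:
        """(synonymous, nonsynonymous) share of substitution flux under this Q."""
        pi = self.pi
        rate = pi[_PAIR_J] * pi[_PAIR_I]
        rate[_PAIR_TS] *= self.kappa
        rate[_PAIR_NS] *= self.omega
        syn = rate[~_PAIR_NS].sum()
        non = rate[_PAIR_NS].sum()
        tot = syn + non
        return syn / tot, non / tot


@lru_cache(maxsize=256)
def syn_nonsyn_flux(kappa: float, freqs: tuple) -> tuple[float, float]:
    """Unnormalized (synonymous, nonsynonymous) substitution flux of the
    omega-free part of the model: the mean rate at omega ``w`` is
    ``A + w * B``.  Used to give site classes their correct relative rates
    in mixture models (a class under weaker constraint evolves faster)."""
    pi = np.asarray(freqs)
    rate = pi[_PAIR_J] * pi[_PAIR_I]
    rate[_PAIR_TS] *= kappa
    return float(rate[~_PAIR_NS].sum()), float(rate[_PAIR_NS].sum())


def class_relative_rates(kappa: float, freqs: tuple, props: np.ndarray,
                         omegas: np.ndarray) -> np.ndarray:
    """Relative substitution rates of site classes on one branch.

    ``omegas`` holds each class's omega on this branch.  Rates are scaled
    so the class-proportion-weighted mean is 1: a branch length t then
    means t expected substitutions per codon averaged over classes, while
    class c experiences ``t * rates[c]``.
    """
    a, b = syn_nonsyn_flux(kappa, freqs)
    mu = a + np.asarray(omegas, float) * b
    return mu / float(np.asarray(props, float) @ mu)


@lru_cache(maxsize=256)
def codon_q(kappa: float, omega: float, freqs: tuple) -> CodonQ:
    """Memoized CodonQ factory.

    Optimizers with coordinate-wise finite differences re-request the same
    (kappa, omega) many times per iteration; caching skips the repeated
    61x61 eigendecompositions.
    """
    return CodonQ(kappa, omega, freqs)


def site_fractions(kappa: float, freqs: np.ndarray) -> tuple[float, float]:
    """Fractions of synonymous / nonsynonymous sites, i.e. mutational flux
    shares under the neutral (omega = 1) version of the model."""
    return CodonQ(kappa, 1.0, tuple(np.asarray(freqs, float))).flux_fractions()


def dn_ds_from_t(t: float, kappa: float, omega: float,
                 freqs: np.ndarray) -> tuple[float, float]:
    """Decompose a codon-branch length into (dN, dS).

    ``t`` is expected substitutions per codon under the fitted model; the
    flux through nonsynonymous (synonymous) changes divided by 3x the
    corresponding site fraction gives per-site rates, so dN/dS recovers
    omega exactly.
    """
    pi = tuple(np.asarray(freqs, float))
    rho_s, rho_n = CodonQ(kappa, omega, pi).flux_fractions()
    p_s, p_n = site_fractions(kappa, np.asarray(freqs, float))
    ds = t * rho_s / (3.0 * p_s)
    dn = t * rho_n / (3.0 * p_n)
    return dn, ds


def codons_to_indices(seq: str) -> np.ndarray:
    """Split an ungapped CDS into sense-codon indices; stops are an error."""
    if len(seq) % 3:
        raise ValueError("coding sequence length is not a multiple of 3")
    out = []
    for k in range(0, len(seq), 3):
        codon = seq[k:k + 3].upper().replace("U", "T")
        if codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon} at nucleotide position {k}")
        if codon not in CODON_INDEX:
            raise ValueError(f"unrecognized codon {codon!r} at nucleotide position {k}")
        out.append(CODON_INDEX[codon])
    return np.array(out, dtype=int)


def indices_to_codons(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[int(i)] for i in idx)
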