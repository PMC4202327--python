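"""Empirical amino-acid substitution models.

The workhorse here is the Jones–Taylor–Thornton (JTT) model, the classical
empirical replacement matrix estimated from pairwise-aligned protein
superfamilies.  A model is a reversible continuous-time Markov chain on the
20 amino acids defined by a symmetric exchangeability matrix ``S`` and a
stationary frequency vector ``pi``; the rate matrix is ``Q[i, j] =
S[i, j] * pi[j]`` (off-diagonal), with rows summing to zero and the whole
matrix scaled so that one unit of branch length equals one expected
substitution per site at stationarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Amino-acid ordering used throughout (the conventional matrix-file order).
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

# Published JTT exchangeabilities: lower triangle, rows R..V against the
# columns preceding them in AA_ORDER (the integer parameterization of the
# original publication, identical to the copy every ML phylogenetics
# package ships).
_JTT_LOWER = [
    [58],
    [54, 45],
    [81, 16, 528],
    [56, 113, 34, 10],
    [57, 310, 86, 49, 9],
    [105, 29, 58, 767, 5, 323],
    [179, 137, 81, 130, 59, 26, 119],
    [27, 328, 391, 112, 69, 597, 26, 23],
    [36, 22, 47, 11, 17, 9, 12, 6, 16],
    [30, 38, 12, 7, 23, 72, 9, 6, 56, 229],
    [35, 646, 263, 26, 7, 292, 181, 27, 45, 21, 14],
    [54, 44, 30, 15, 31, 43, 18, 14, 33, 479, 388, 65],
    [15, 5, 10, 4, 78, 4, 5, 5, 40, 89, 248, 4, 43],
    [194, 74, 15, 15, 14, 164, 18, 24, 115, 10, 102, 21, 16, 17],
    [378, 101, 503, 59, 223, 53, 30, 201, 73, 40, 59, 47, 29, 92, 285],
    [475, 64, 232, 38, 42, 51, 32, 33, 46, 245, 25, 103, 226, 12, 118, 477],
    [9, 126, 8, 4, 115, 18, 10, 55, 8, 9, 52, 10, 24, 53, 6, 35, 63],
    [11, 20, 70, 46, 209, 24, 7, 8, 573, 32, 24, 8, 18, 536, 10, 63, 38, 21],
    [298, 17, 16, 31, 62, 20, 45, 47, 11, 961, 180, 14, 323, 62, 23, 38, 112, 25, 16],
]

#: Published JTT equilibrium frequencies (order AA_ORDER).
JTT_FREQS = np.array([
    0.0767479232520768, 0.0516909483090517, 0.0426449573550427,
    0.0515439484560515, 0.0198029801970198, 0.0407519592480408,
    0.0618299381700618, 0.0731519268480732, 0.0229439770560229,
    0.0537609462390538, 0.0919039080960919, 0.0586759413240587,
    0.0238259761740238, 0.0401259598740401, 0.0509009490990509,
    0.0687649312350688, 0.0585649414350586, 0.0142609857390143,
    0.0321019678980321, 0.0660049339950660,
])


def _jtt_exchangeabilities() -> np.ndarray:
    s = np.zeros((20, 20))
    for i, row in enumerate(_JTT_LOWER, start=1):
        s[i, : len(row)] = row
    return s + s.T


@dataclass
class AminoAcidModel:
    """Reversible amino-acid substitution model with spectral transition matrices.

    Parameters
    ----------
    exchangeabilities
        Symmetric non-negative 20x20 matrix (diagonal ignored).
    freqs
        Stationary frequencies, summing to 1.
    """

    exchangeabilities: np.ndarray
    freqs: np.ndarray
    name: str = "custom"
    _evals: np.ndarray = field(init=False, repr=False)
    _evecs_left: np.ndarray = field(init=False, repr=False)
    _evecs_right: np.ndarray = field(init=False, repr=False)
    rate_matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.freqs, dtype=float)
        if s.shape != (20, 20) or not np.allclose(s, s.T):
            raise ValueError("exchangeability matrix must be symmetric 20x20")
        if np.any(s < 0) or np.any(pi <= 0):
            raise ValueError("exchangeabilities must be >= 0 and frequencies > 0")
        pi = pi / pi.sum()
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        # scale: one expected substitution per site per unit branch length
        q /= -(pi * np.diag(q)).sum()
        self.freqs = pi
        self.rate_matrix = q
        # reversibility makes D^{1/2} Q D^{-1/2} symmetric -> stable eigh
        d = np.sqrt(pi)
        b = (q * d[:, None]) / d[None, :]
        evals, u = np.linalg.eigh((b + b.T) / 2.0)
        self._evals = evals
        self._evecs_right = u / d[:, None]
        self._evecs_left = u * d[:, None]

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows are conditional distributions after time t."""
        if not np.isfinite(t) or t < 0:
            raise ValueError(f"branch length must be finite and >= 0, got {t}")
        p = (self._evecs_right * np.exp(self._evals * t)) @ self._evecs_left.T
        return np.clip(p, 0.0, None)


def jtt_model() -> AminoAcidModel:
    """The JTT model with its published frequencies."""
    return AminoAcidModel(_jtt_exchangeabilities(), JTT_FREQS.copy(), name="JTT")


def jtt_model_f(freqs: np.ndarray) -> AminoAcidModel:
    """JTT exchangeabilities with empirical (+F) frequencies."""
    return AminoAcidModel(_jtt_exchangeabilities(), np.asarray(freqs, float), name="JTT+F")
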