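"""Pairwise and branch-specific dN/dS estimation.

Two routes are provided for pairwise divergence:

* ``pairwise_dnds_ml`` — maximum likelihood under the codon model
  (parameters t, kappa, omega; F3x4 frequencies), with dN and dS derived
  from the fitted branch length by the standard decomposition of
  substitution flux into nonsynonymous and synonymous parts.
* ``ng86_dnds`` — the Nei–Gojobori (1986) counting method with
  Jukes–Cantor correction, used as an independent cross-check of the ML
  route (the two converge at low divergence).

``branch_asymmetry_test`` fits per-branch omegas on a duplicate triplet and
tests equality of dN (or omega) across the two duplicate branches by LRT.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .codonmodels import (
    CODON_AA,
    CODON_INDEX,
    N_SENSE,
    SENSE_CODONS,
    STOP_CODONS,
    codon_q,
    dn_ds_from_t,
    f3x4_freqs,
)
from .likelihood import LrtResult, lrt
from .simulate import TripletAlignment

T_BOUNDS = (1e-6, 50.0)
KAPPA_BOUNDS = (0.01, 100.0)
OMEGA_BOUNDS = (1e-6, 50.0)


@dataclass
class PairwiseDnDs:
    dn: float
    ds: float
    omega: float
    t: float
    kappa: float
    method: str
    saturated: bool = False


# ---------------------------------------------------------------------------
# alignment plumbing


def back_translate_alignment(protein_alignment: dict[str, str],
                             cds_by_id: dict[str, str]) -> dict[str, str]:
    """Thread coding sequences onto a gapped protein alignment.

    Each aligned protein column becomes a codon triplet; protein gaps
    become ``---``.  A terminal stop codon on the CDS is stripped.  Any
    translation mismatch is reported with its position.
    """
    from Bio.Seq import Seq

    out = {}
    for seq_id, prot in protein_alignment.items():
        if seq_id not in cds_by_id:
            raise KeyError(f"no CDS supplied for {seq_id!r}")
        cds = cds_by_id[seq_id].upper().replace("U", "T")
        if len(cds) % 3:
            raise ValueError(f"{seq_id}: CDS length {len(cds)} is not a multiple of 3")
        if cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        ungapped = prot.replace("-", "")
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"{seq_id}: CDS has {len(cds) // 3} codons for {len(ungapped)} residues")
        translated = str(Seq(cds).translate())
        if "*" in translated:
            raise ValueError(
                f"{seq_id}: internal stop codon at residue {translated.index('*') + 1}")
        for pos, (a, b) in enumerate(zip(translated, ungapped), start=1):
            if a != b.upper():
                raise ValueError(
                    f"{seq_id}: CDS translates to {a!r} but protein has {b!r}"
                    f" at ungapped residue {pos}")
        codons = iter([cds[k:k + 3] for k in range(0, len(cds), 3)])
        out[seq_id] = "".join("---" if ch == "-" else next(codons) for ch in prot)
    return out


def gap_free_codon_columns(*codon_seqs: str) -> list[np.ndarray]:
    """Complete deletion: keep codon columns where every sequence has an
    unambiguous sense codon; returns per-sequence index arrays."""
    n = len(codon_seqs[0])
    if any(len(s) != n for s in codon_seqs) or n % 3:
        raise ValueError("codon sequences must share a length divisible by 3")
    cols = [[] for _ in codon_seqs]
    for k in range(0, n, 3):
        codons = [s[k:k + 3].upper().replace("U", "T") for s in codon_seqs]
        if all(c in CODON_INDEX for c in codons):
            for lst, c in zip(cols, codons):
                lst.append(CODON_INDEX[c])
    if not cols[0]:
        raise ValueError("no usable gap-free codon columns")
    return [np.array(c, dtype=int) for c in cols]


# ---------------------------------------------------------------------------
# ML pairwise estimator


def _pair_pattern_counts(x: np.ndarray, y: np.ndarray):
    pair = x * N_SENSE + y
    uniq, counts = np.unique(pair, return_counts=True)
    return uniq // N_SENSE, uniq % N_SENSE, counts.astype(float)


def pairwise_dnds_ml(seq1: str, seq2: str,
                     freqs: np.ndarray | None = None) -> PairwiseDnDs:
    """ML estimates of (t, kappa, omega) and derived (dN, dS) for two CDSs.

    Input sequences may be gapped codon-aligned strings; gapped or
    ambiguous codon columns are dropped (complete deletion).  Frequencies
    default to F3x4 estimated from the two sequences.
    """
    x, y = gap_free_codon_columns(seq1, seq2)
    if freqs is None:
        freqs = f3x4_freqs(np.concatenate([x, y]))
    pi = tuple(np.asarray(freqs, float))
    xi, yi, counts = _pair_pattern_counts(x, y)
    log_pi = np.log(np.asarray(pi)[xi])

    if np.all(xi == yi):
        return PairwiseDnDs(dn=0.0, ds=0.0, omega=0.0, t=0.0, kappa=1.0, method="ML")

    def neg_lnl(params):
        t, kappa, omega = params
        pmat = codon_q(kappa, omega, pi).transition_matrix(t)
        vals = pmat[xi, yi]
        if np.any(vals <= 0):
            return 1e300
        return -float((log_pi + np.log(vals)) @ counts)

    bounds = [T_BOUNDS, KAPPA_BOUNDS, OMEGA_BOUNDS]
    best = None
    for t0, w0 in [(0.2, 0.2), (0.5, 1.0), (1.0, 0.05), (0.05, 0.5), (2.0, 0.3)]:
        res = optimize.minimize(neg_lnl, np.array([t0, 2.0, w0]),
                                method="L-BFGS-B", bounds=bounds,
                                options={"ftol": 1e-12, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    t, kappa, omega = best.x
    dn, ds = dn_ds_from_t(t, kappa, omega, np.asarray(pi))
    saturated = bool(t >= T_BOUNDS[1] * 0.99)
    return PairwiseDnDs(dn=dn, ds=ds, omega=omega, t=t, kappa=kappa,
                        method="ML", saturated=saturated)


# ---------------------------------------------------------------------------
# NG86 counting oracle


def _ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site count of one codon, normalized to 3.

    Changes to stop codons count as nonsynonymous, the field's usual
    counting convention.
    """
    aa = CODON_AA[CODON_INDEX[codon]]
    syn = non = 0
    for pos in range(3):
        for nt in "TCAG":
            if nt == codon[pos]:
                continue
            neighbor = codon[:pos] + nt + codon[pos + 1:]
            if neighbor in STOP_CODONS or CODON_AA[CODON_INDEX[neighbor]] != aa:
                non += 1
            else:
                syn += 1
    total = syn + non
    return 3.0 * syn / total, 3.0 * non / total


def _step_is_syn(c1: str, c2: str) -> bool:
    a1 = None if c1 in STOP_CODONS else CODON_AA[CODON_INDEX[c1]]
    a2 = None if c2 in STOP_CODONS else CODON_AA[CODON_INDEX[c2]]
    return a1 is not None and a1 == a2


def _ng86_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts, averaged over all
    mutational pathways with equal weight."""
    diff = [k for k in range(3) if c1[k] != c2[k]]
    if not diff:
        return 0.0, 0.0
    sd = nd = 0.0
    paths = list(itertools.permutations(diff))
    for path in paths:
        cur = c1
        for pos in path:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _step_is_syn(cur, nxt):
                sd += 1.0 / len(paths)
            else:
                nd += 1.0 / len(paths)
            cur = nxt
    return sd, nd


def ng86_dnds(seq1: str, seq2: str) -> PairwiseDnDs:
    """Nei–Gojobori (1986) dN/dS with Jukes–Cantor correction."""
    for seq in (seq1, seq2):
        s = seq.upper().replace("U", "T")
        for k in range(0, len(s), 3):
            if s[k:k + 3] in STOP_CODONS:
                raise ValueError(f"stop codon {s[k:k + 3]} at nucleotide position {k}")
    x, y = gap_free_codon_columns(seq1, seq2)
    s_sites = n_sites = 0.0
    for seq in (x, y):
        for idx in seq:
            s, n = _ng86_sites(SENSE_CODONS[int(idx)])
            s_sites += s / 2.0
            n_sites += n / 2.0
    sd = nd = 0.0
    for i, j in zip(x, y):
        s, n = _ng86_diffs(SENSE_CODONS[int(i)], SENSE_CODONS[int(j)])
        sd += s
        nd += n
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0

    def jc(p):
        if p >= 0.75:
            return np.inf
        return -0.75 * np.log(1.0 - 4.0 * p / 3.0)

    ds, dn = jc(ps), jc(pn)
    saturated = not (np.isfinite(ds) and np.isfinite(dn))
    omega = dn / ds if (ds > 0 and np.isfinite(ds) and np.isfinite(dn)) else np.nan
    return PairwiseDnDs(dn=dn, ds=ds, omega=omega, t=np.nan, kappa=np.nan,
                        method="NG86", saturated=saturated)


# ---------------------------------------------------------------------------
# branch-specific asymmetry LRT on triplets


def _triplet_patterns(alignment: TripletAlignment):
    x1, x2, x3 = gap_free_codon_columns(*alignment.seqs)
    key = (x1 * N_SENSE + x2) * N_SENSE + x3
    uniq, counts = np.unique(key, return_counts=True)
    return (uniq // (N_SENSE * N_SENSE), (uniq // N_SENSE) % N_SENSE,
            uniq % N_SENSE, counts.astype(float), np.concatenate([x1, x2, x3]))


def _triplet_lnl(xs, counts, pi, kappa, branch_params):
    """branch_params: list of (length, omega) for (dup1, dup2, outgroup)."""
    pi_arr = np.asarray(pi)
    prod = np.ones((N_SENSE, counts.shape[0]))
    for (b, w), x in zip(branch_params, xs):
        pmat = codon_q(kappa, w, pi).transition_matrix(b)
        prod *= pmat[:, x]
    site_l = pi_arr @ prod
    if np.any(site_l <= 0):
        return -np.inf
    return float(np.log(site_l) @ counts)


def branch_asymmetry_test(alignment: TripletAlignment, which: str = "omega",
                          freqs: np.ndarray | None = None) -> LrtResult:
    """LRT of equal dN (or equal omega) on the two duplicate branches.

    The alternative gives every branch its own length and omega; the null
    constrains omega1 = omega2 (``which='omega'``) or dN1 = dN2
    (``which='dn'``, implemented by tying b2 to b1 through the
    nonsynonymous flux so the two duplicate branches carry equal dN).
    """
    if which not in ("omega", "dn"):
        raise ValueError("which must be 'omega' or 'dn'")
    x1, x2, x3, counts, pooled = _triplet_patterns(alignment)
    if freqs is None:
        freqs = f3x4_freqs(pooled)
    pi = tuple(np.asarray(freqs, float))
    xs = (x1, x2, x3)
    lo_t, hi_t = T_BOUNDS

    def fit(neg, x0s, bounds):
        best = None
        for x0 in x0s:
            res = optimize.minimize(neg, np.asarray(x0), method="L-BFGS-B",
                                    bounds=bounds,
                                    options={"ftol": 1e-10, "maxiter": 500})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("branch-asymmetry optimization failed to converge")
        return -float(best.fun)

    tb, kb, wb = (lo_t, hi_t), KAPPA_BOUNDS, OMEGA_BOUNDS

    def neg_alt(v):
        b1, b2, b3, kappa, w1, w2, w3 = v
        return -_triplet_lnl(xs, counts, pi, kappa, [(b1, w1), (b2, w2), (b3, w3)])

    def neg_null_omega(v):
        b1, b2, b3, kappa, w12, w3 = v
        return -_triplet_lnl(xs, counts, pi, kappa, [(b1, w12), (b2, w12), (b3, w3)])

    def neg_null_dn(v):
        b1, b3, kappa, w1, w2, w3 = v
        # equal dN: b2 * rhoN(w2) = b1 * rhoN(w1)
        rho1 = codon_q(kappa, w1, pi).flux_fractions()[1]
        rho2 = codon_q(kappa, w2, pi).flux_fractions()[1]
        b2 = float(np.clip(b1 * rho1 / rho2, lo_t, hi_t))
        return -_triplet_lnl(xs, counts, pi, kappa, [(b1, w1), (b2, w2), (b3, w3)])

    starts_alt = [[0.1, 0.1, 0.3, 2.0, 0.3, 0.3, 0.3],
                  [0.3, 0.3, 0.9, 2.0, 0.8, 0.2, 0.5]]
    ln_alt = fit(neg_alt, starts_alt, [tb, tb, tb, kb, wb, wb, wb])
    if which == "omega":
        starts = [[0.1, 0.1, 0.3, 2.0, 0.3, 0.3], [0.3, 0.3, 0.9, 2.0, 0.6, 0.5]]
        ln_null = fit(neg_null_omega, starts, [tb, tb, tb, kb, wb, wb])
    else:
        starts = [[0.1, 0.3, 2.0, 0.3, 0.3, 0.3], [0.3, 0.9, 2.0, 0.6, 0.4, 0.5]]
        ln_null = fit(neg_null_dn, starts, [tb, tb, kb, wb, wb, wb])
    return lrt(ln_alt, ln_null, df=1)
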