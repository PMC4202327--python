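"""Synthetic data: sequence triplets and duplicate-pair cohorts.

The downstream analyses all operate on (duplicate 1, duplicate 2, outgroup)
triplets related by an unrooted star tree, and on cohorts of duplicate
pairs labelled with relocalization and asymmetric-evolution flags.  This
module generates both under the exact probabilistic assumptions the tests
and calibrations rely on: reversible substitution along each branch from a
stationary root, i.i.d. sites (with discrete site classes in the codon
case), and Bernoulli or exact-count flag assignment in cohorts.

Every operation takes an explicit seed; per-pair substreams are derived
from (seed, counter) so that cohort ordering never changes the draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aamodels import AA_ORDER, AminoAcidModel
from .codonmodels import (
    N_SENSE,
    CodonQ,
    class_relative_rates,
    indices_to_codons,
    uniform_codon_freqs,
)

DEFAULT_SEED = 0


@dataclass
class TripletTree:
    """Star tree joining duplicate 1, duplicate 2 and the outgroup.

    Branch lengths are expected substitutions per site (amino-acid models)
    or per codon (codon models).  The molecular-clock null is ``b1 == b2``.
    """

    b1: float
    b2: float
    b3: float

    def __post_init__(self) -> None:
        for name in ("b1", "b2", "b3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"branch length {name}={v!r} must be finite and >= 0")

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.b1, self.b2, self.b3)


@dataclass
class TripletAlignment:
    """Ungapped alignment of (dup1, dup2, outgroup)."""

    ids: tuple[str, str, str]
    seqs: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len({len(s) for s in self.seqs}) != 1:
            raise ValueError("triplet sequences must have equal length")

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0])


@dataclass
class CodonTripletAlignment(TripletAlignment):
    """Codon triplet alignment; also records the simulated site classes."""

    site_classes: np.ndarray | None = None

    @property
    def n_codons(self) -> int:
        return self.n_sites // 3


@dataclass
class CohortSpec:
    """Study-design parameters for a duplicate-pair cohort.

    Defaults reproduce the observed cohort this analysis is built around:
    128 pairs with localization data for both copies, 19 of them
    relocalized, asymmetric-rate frequencies 8/19 in the relocalized and
    13/109 in the non-relocalized group.
    """

    n_pairs: int = 128
    n_relocalized: int = 19
    p_asym_reloc: float = 8 / 19
    p_asym_same: float = 13 / 109
    seed: int = DEFAULT_SEED
    deterministic_counts: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.n_relocalized <= self.n_pairs):
            raise ValueError("need 0 <= n_relocalized <= n_pairs")
        for p in (self.p_asym_reloc, self.p_asym_same):
            if not (0.0 <= p <= 1.0):
                raise ValueError("asymmetry probabilities must lie in [0, 1]")

    @classmethod
    def from_json(cls, path) -> "CohortSpec":
        """Load a cohort specification from a JSON file; unknown keys are
        an error so typos do not silently fall back to defaults."""
        import json

        with open(path) as fh:
            payload = json.load(fh)
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - valid
        if unknown:
            raise ValueError(f"unknown cohort spec keys: {sorted(unknown)}")
        return cls(**payload)


def _draw_children(parent_states: np.ndarray, pmat: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Sample child states site-by-site given parent states and P(t)."""
    child = np.empty_like(parent_states)
    for s in np.unique(parent_states):
        sel = parent_states == s
        child[sel] = rng.choice(pmat.shape[1], size=int(sel.sum()), p=pmat[s] / pmat[s].sum())
    return child


def simulate_aa_triplet(tree: TripletTree, model: AminoAcidModel, n_sites: int,
                        seed: int = DEFAULT_SEED,
                        ids: tuple[str, str, str] = ("dup1", "dup2", "outgroup"),
                        ) -> TripletAlignment:
    """Evolve an amino-acid triplet along the star tree.

    The internal-node state is drawn from the model's stationary
    distribution; each leaf state evolves by the transition matrix at its
    branch length.  Zero branch lengths therefore yield identical
    sequences, and the same seed yields a byte-identical alignment.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    root = rng.choice(20, size=n_sites, p=model.freqs)
    seqs = []
    for b in tree.lengths:
        states = _draw_children(root, model.transition_matrix(b), rng)
        seqs.append("".join(AA_ORDER[s] for s in states))
    return TripletAlignment(ids=ids, seqs=tuple(seqs))


def simulate_codon_triplet(tree: TripletTree, kappa: float,
                           site_classes: list[tuple[float, tuple[float, float, float]]],
                           codon_freqs: np.ndarray | None = None,
                           n_codons: int = 300, seed: int = DEFAULT_SEED,
                           ids: tuple[str, str, str] = ("dup1", "dup2", "outgroup"),
                           ) -> CodonTripletAlignment:
    """Evolve a codon triplet with discrete site classes.

    ``site_classes`` is a list of ``(proportion, (omega_b1, omega_b2,
    omega_b3))``: sites are assigned to classes i.i.d. by proportion, and
    within a class each branch evolves under its own omega.  A class with
    omega > 1 on one duplicate branch only is the positive-selection
    scenario the branch-site test is meant to recover.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    props = np.array([p for p, _ in site_classes], dtype=float)
    if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-8:
        raise ValueError("site-class proportions must be >= 0 and sum to 1")
    for _, omegas in site_classes:
        if len(omegas) != 3 or any(w < 0 for w in omegas):
            raise ValueError("each class needs three omegas >= 0")
    if codon_freqs is None:
        pi = uniform_codon_freqs()
    else:
        pi = np.asarray(codon_freqs, dtype=float)
        if pi.shape != (N_SENSE,) or np.any(pi < 0):
            raise ValueError("codon_freqs must be a non-negative 61-vector")
        if abs(pi.sum() - 1.0) > 1e-6:
            raise ValueError("codon_freqs must sum to 1 over the sense codons")
        pi = pi / pi.sum()

    rng = np.random.default_rng(seed)
    classes = rng.choice(len(site_classes), size=n_codons, p=props)
    root = rng.choice(N_SENSE, size=n_codons, p=pi)
    leaf_states = [np.empty(n_codons, dtype=int) for _ in range(3)]
    pi_t = tuple(pi)
    # classes share one mutation process: a class with higher omega evolves
    # proportionally faster; branch length = class-averaged rate.
    omega_table = np.array([w for _, w in site_classes], dtype=float)  # (C, 3)
    rel = np.stack([class_relative_rates(kappa, pi_t, props, omega_table[:, leaf])
                    for leaf in range(3)], axis=1)                     # (C, 3)
    for c, (_, omegas) in enumerate(site_classes):
        sel = classes == c
        if not sel.any():
            continue
        for leaf, (b, w) in enumerate(zip(tree.lengths, omegas)):
            pmat = CodonQ(kappa, float(w), pi_t).transition_matrix(b * rel[c, leaf])
            leaf_states[leaf][sel] = _draw_children(root[sel], pmat, rng)
    seqs = tuple(indices_to_codons(states) for states in leaf_states)
    return CodonTripletAlignment(ids=ids, seqs=seqs, site_classes=classes)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a duplicate-pair roster with relocalization/asymmetry flags.

    Returns a DataFrame with columns ``pair_id, gene1, gene2, reloc_flag,
    asym_flag``.  In ``deterministic_counts`` mode the first
    ``round(p * n)`` pairs of each group carry the asymmetry flag, which
    reproduces an exact target contingency table; otherwise each pair's
    flag is an independent Bernoulli draw from its group probability, with
    the per-pair stream derived from ``(seed, pair index)``.
    """
    rows = []
    n_reloc = spec.n_relocalized
    n_same = spec.n_pairs - n_reloc
    k_reloc = int(round(spec.p_asym_reloc * n_reloc))
    k_same = int(round(spec.p_asym_same * n_same))
    reloc_seen = same_seen = 0
    for i in range(spec.n_pairs):
        reloc = i < n_reloc
        if spec.deterministic_counts:
            if reloc:
                asym = reloc_seen < k_reloc
                reloc_seen += 1
            else:
                asym = same_seen < k_same
                same_seen += 1
        else:
            rng = np.random.default_rng([spec.seed, i])
            p = spec.p_asym_reloc if reloc else spec.p_asym_same
            asym = bool(rng.random() < p)
        rows.append({
            "pair_id": f"pair{i + 1:04d}",
            "gene1": f"g{i + 1:04d}a",
            "gene2": f"g{i + 1:04d}b",
            "reloc_flag": bool(reloc),
            "asym_flag": bool(asym),
        })
    return pd.DataFrame(rows)


def write_roster(roster: pd.DataFrame, path) -> None:
    roster.to_csv(path, sep="\t", index=False)


def read_roster(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"pair_id", "gene1", "gene2", "reloc_flag", "asym_flag"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"roster is missing columns: {sorted(missing)}")
    df["reloc_flag"] = df["reloc_flag"].astype(bool)
    df["asym_flag"] = df["asym_flag"].astype(bool)
    return df
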