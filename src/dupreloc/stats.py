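"""Localization-divergence classification and group-level statistics.

A duplicate pair's two compartment sets are compared as sets: identical
sets mean no relocalization, disjoint sets a complete change, and partial
overlap an expansion/contraction.  Relocalized vs non-relocalized groups
are then tested for enrichment of asymmetric sequence evolution with a
one-tailed Fisher exact test and a Monte Carlo randomization of the DIF
statistic (absolute difference in asymmetry frequency between groups).
The module also computes protein isoelectric points (EMBOSS pK set) and
the Welch t-test on within-pair pI differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

N_SIM_DEFAULT = 10_000

#: EMBOSS pK values: ionizable groups and their dissociation constants.
EMBOSS_PK = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
    "K": 10.8, "R": 12.5, "Y": 10.1,
}
_BASIC = ("Nterm", "H", "K", "R")
_ACIDIC = ("Cterm", "C", "D", "E", "Y")


def load_relocalized_pairs() -> pd.DataFrame:
    """The 19 relocalized duplicate pairs with their compartment sets."""
    with resources.files("dupreloc.data").joinpath("relocalized_pairs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# localization comparison


def classify_localization_pair(set_a: frozenset[str] | set[str],
                               set_b: frozenset[str] | set[str]) -> str:
    """Classify a pair of compartment sets.

    Returns ``same`` (equal sets), ``complete_change`` (disjoint), or
    ``partial_change`` (any other overlap pattern — expansion, contraction
    or partial overlap).  Token comparison is case-insensitive.
    """
    a = frozenset(t.lower() for t in set_a)
    b = frozenset(t.lower() for t in set_b)
    if not a or not b:
        raise ValueError("compartment sets must be non-empty")
    if a == b:
        return "same"
    if not (a & b):
        return "complete_change"
    return "partial_change"


def classify_table(pairs: pd.DataFrame) -> pd.DataFrame:
    """Classify a gene1/scl1/gene2/scl2 table; adds a ``call`` column."""
    calls = []
    for _, row in pairs.iterrows():
        a = {t.strip() for t in str(row["scl1"]).split(";")}
        b = {t.strip() for t in str(row["scl2"]).split(";")}
        calls.append(classify_localization_pair(a, b))
    out = pairs.copy()
    out["call"] = calls
    return out


def build_contingency(calls: list[str], asym_flags: list[bool]) -> np.ndarray:
    """2x2 counts [[a, b], [c, d]]: rows relocalized / same-localized,
    columns asymmetric / symmetric.  Relocalized = complete or partial."""
    if len(calls) != len(asym_flags) or not calls:
        raise ValueError("calls and asymmetry flags must align and be non-empty")
    table = np.zeros((2, 2), dtype=int)
    for call, asym in zip(calls, asym_flags):
        if call in ("complete_change", "partial_change"):
            row = 0
        elif call == "same":
            row = 1
        else:
            raise ValueError(f"unclassified pair (call={call!r})")
        table[row, 0 if asym else 1] += 1
    return table


# ---------------------------------------------------------------------------
# enrichment statistics


def fisher_one_tailed(table: np.ndarray) -> float:
    """One-tailed (enrichment) Fisher exact P for a 2x2 table."""
    table = np.asarray(table)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a non-negative 2x2 table")
    if not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)):
            raise ValueError("counts must be integers")
        table = np.round(table).astype(int)
    return float(sps.fisher_exact(table, alternative="greater")[1])


@dataclass
class DifResult:
    dif_obs: float
    mc_p: float
    n_sim: int
    seed: int
    scheme: str


def dif_randomization(group_sizes: tuple[int, int], asym_counts: tuple[int, int],
                      n_sim: int = N_SIM_DEFAULT, seed: int = 0,
                      scheme: str = "resample",
                      plus_one: bool = False) -> DifResult:
    """Monte Carlo test of the DIF statistic.

    DIF = |a/n_reloc - c/n_same|, the absolute difference in asymmetry
    frequency between the relocalized and non-relocalized groups.  Under
    ``resample`` every pair's flag is redrawn at the pooled frequency with
    group sizes fixed; under ``permute`` the observed flags are shuffled
    across pairs.  mc_p is the fraction of simulated DIF values at least
    as large as the observed one (``plus_one`` switches to the
    (k+1)/(n+1) estimator).
    """
    n_reloc, n_same = group_sizes
    a, c = asym_counts
    if not (0 <= a <= n_reloc and 0 <= c <= n_same):
        raise ValueError("asymmetry counts cannot exceed group sizes")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if scheme not in ("resample", "permute"):
        raise ValueError("scheme must be 'resample' or 'permute'")
    dif_obs = abs(a / n_reloc - c / n_same)
    rng = np.random.default_rng(seed)
    if scheme == "resample":
        pooled = (a + c) / (n_reloc + n_same)
        sim_a = rng.binomial(n_reloc, pooled, size=n_sim)
        sim_c = rng.binomial(n_same, pooled, size=n_sim)
    else:
        flags = np.zeros(n_reloc + n_same, dtype=bool)
        flags[:a + c] = True
        sim_a = np.empty(n_sim, dtype=int)
        for i in range(n_sim):
            rng.shuffle(flags)
            sim_a[i] = flags[:n_reloc].sum()
        sim_c = (a + c) - sim_a
    dif_sim = np.abs(sim_a / n_reloc - sim_c / n_same)
    k = int((dif_sim >= dif_obs - 1e-12).sum())
    mc_p = (k + 1) / (n_sim + 1) if plus_one else k / n_sim
    return DifResult(dif_obs=dif_obs, mc_p=float(mc_p), n_sim=n_sim,
                     seed=seed, scheme=scheme)


# ---------------------------------------------------------------------------
# isoelectric points


def net_charge(sequence: str, ph: float, pk: dict[str, float] = EMBOSS_PK) -> float:
    """Henderson–Hasselbalch net charge of a peptide at a given pH."""
    seq = sequence.upper()
    counts = {res: seq.count(res) for res in "CDEHKRY"}
    charge = 0.0
    for group in _BASIC:
        n = 1 if group == "Nterm" else counts.get(group, 0)
        charge += n / (1.0 + 10.0 ** (ph - pk[group]))
    for group in _ACIDIC:
        n = 1 if group == "Cterm" else counts.get(group, 0)
        charge -= n / (1.0 + 10.0 ** (pk[group] - ph))
    return charge


def isoelectric_point(sequence: str, tol: float = 1e-4,
                      pk: dict[str, float] = EMBOSS_PK) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    Only the twenty standard residues contribute charge; ambiguity codes
    are ignored.  The net-charge function is strictly decreasing in pH, so
    bisection is exact to the requested tolerance.
    """
    if not sequence or not sequence.strip("-"):
        raise ValueError("empty protein sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(sequence, mid, pk) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


@dataclass
class IsoelectricResult:
    mean_reloc: float
    mean_same: float
    t_statistic: float
    df: float
    p_value: float


def delta_pi_ttest(dpi_relocalized: list[float],
                   dpi_same: list[float]) -> IsoelectricResult:
    """Welch two-sample t-test on within-pair |pI1 - pI2| differences."""
    x = np.asarray(dpi_relocalized, float)
    y = np.asarray(dpi_same, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two values")
    res = sps.ttest_ind(x, y, equal_var=False)
    # Welch–Satterthwaite df
    vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    if vx + vy == 0:
        df, t, p = float(x.size + y.size - 2), 0.0, 1.0
    else:
        df = (vx + vy) ** 2 / (vx ** 2 / (x.size - 1) + vy ** 2 / (y.size - 1))
        t, p = float(res.statistic), float(res.pvalue)
    return IsoelectricResult(mean_reloc=float(x.mean()), mean_same=float(y.mean()),
                             t_statistic=t, df=df, p_value=p)
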