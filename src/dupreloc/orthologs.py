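"""Outgroup-ortholog assignment for duplicate pairs.

Candidate orthologs come from all-vs-all protein similarity hits filtered
on e-value (<= 1e-5) and coverage (alignment length >= 60% of the shorter
protein), combined by reciprocal best hit with an optional one-way
fallback.  A candidate triplet is then validated by dS triangulation: the
duplicates must be younger than the speciation, i.e. dS(dup1, ortholog)
and dS(dup2, ortholog) must both strictly exceed dS(dup1, dup2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import HitRecord

EVALUE_MAX = 1e-5
COVERAGE_MIN = 0.60

#: Outgroup species in default priority order (closest first).
DEFAULT_SPECIES_PRIORITY = (
    "Carica papaya", "Fragaria vesca", "Glycine max", "Lotus japonica",
    "Malus domestica", "Manihot esculenta", "Medicago truncatula",
    "Populus trichocarpa", "Ricinus communis", "Theobroma cacao",
    "Vitis vinifera",
)


@dataclass
class OrthologTriplet:
    dup1: str
    dup2: str
    ortholog: str
    species: str = ""
    ds1: float = np.nan  # dS(dup1, dup2)
    ds2: float = np.nan  # dS(dup1, ortholog)
    ds3: float = np.nan  # dS(dup2, ortholog)
    provenance: str = "reciprocal"  # reciprocal | one-way


def filter_hits(hits: list[HitRecord], query_len: dict[str, int],
                subject_len: dict[str, int], evalue_max: float = EVALUE_MAX,
                coverage_min: float = COVERAGE_MIN) -> list[HitRecord]:
    """Retain hits with e-value <= threshold and alignment covering at
    least ``coverage_min`` of the shorter protein."""
    kept = []
    for hit in hits:
        if hit.query not in query_len:
            raise KeyError(f"no length for query {hit.query!r}")
        if hit.subject not in subject_len:
            raise KeyError(f"no length for subject {hit.subject!r}")
        shorter = min(query_len[hit.query], subject_len[hit.subject])
        if hit.evalue <= evalue_max and hit.aln_length / shorter >= coverage_min:
            kept.append(hit)
    return kept


def _best_by_query(hits: list[HitRecord]) -> dict[str, HitRecord]:
    """Best hit per query: highest bit score, ties by lowest e-value, then
    lexicographically smallest subject id (deterministic)."""
    best: dict[str, HitRecord] = {}
    for hit in hits:
        cur = best.get(hit.query)
        if cur is None or (
            (-hit.bitscore, hit.evalue, hit.subject)
            < (-cur.bitscore, cur.evalue, cur.subject)
        ):
            best[hit.query] = hit
    return best


def reciprocal_best_hits(hits_ab: list[HitRecord], hits_ba: list[HitRecord],
                         allow_one_way: bool = True) -> list[tuple[str, str, str]]:
    """(query, subject, provenance) candidate ortholog pairs.

    Reciprocal when each is the other's best hit; otherwise, with the
    fallback enabled, the query's one-way best hit.  Both tables are
    assumed pre-filtered by :func:`filter_hits`.
    """
    best_ab = _best_by_query(hits_ab)
    best_ba = _best_by_query(hits_ba)
    out = []
    for query, hit in sorted(best_ab.items()):
        back = best_ba.get(hit.subject)
        if back is not None and back.subject == query:
            out.append((query, hit.subject, "reciprocal"))
        elif allow_one_way:
            out.append((query, hit.subject, "one-way"))
    return out


def triangulation_filter(triplet: OrthologTriplet) -> tuple[bool, str]:
    """Accept iff dS2 > dS1 and dS3 > dS1 (strict).

    Returns (accepted, reason); non-finite dS estimates (saturation) are
    rejected as unestimable.
    """
    ds = (triplet.ds1, triplet.ds2, triplet.ds3)
    if any(not np.isfinite(d) or d < 0 for d in ds):
        return False, "unestimable"
    if triplet.ds2 > triplet.ds1 and triplet.ds3 > triplet.ds1:
        return True, "ok"
    return False, "duplication-older-than-speciation"


def choose_ortholog(candidates: list[OrthologTriplet],
                    species_priority: tuple[str, ...] = DEFAULT_SPECIES_PRIORITY,
                    ) -> OrthologTriplet | None:
    """Pick one ortholog per pair when several outgroup species qualify:
    first by the species priority list, then reciprocal before one-way,
    then lexicographic ortholog id."""
    accepted = [c for c in candidates if triangulation_filter(c)[0]]
    if not accepted:
        return None

    def rank(c: OrthologTriplet):
        try:
            sp = species_priority.index(c.species)
        except ValueError:
            sp = len(species_priority)
        return (sp, 0 if c.provenance == "reciprocal" else 1, c.ortholog)

    return min(accepted, key=rank)
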