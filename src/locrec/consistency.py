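"""Internal consistency of fluorescent-protein localization evidence.

A protein localized by FP tagging in at least two independent
publications can be checked against itself: do the publications point to
the same place? Each publication contributes the set of compartments it
reported for the protein. Two publications *agree* when those sets
intersect and *disagree* when they are disjoint; a publication reporting
a superset (e.g. {plastid, mitochondrion} vs {plastid}) is compatible
dual-target discovery, not conflict. A protein with three or more
publications can carry both labels at once — one pair agreeing, another
pair disjoint — and then counts toward both groups, which is why the
agree and disagree percentages may sum to more than 100.

"Independent" means distinct publication identifiers; two papers from
the same lab count as independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

from .evidence import ClaimSet
from .utils import pct_or_none


@dataclass(frozen=True)
class ConsistencyLabel:
    """Agreement/disagreement flags for one multiply-localized protein."""

    protein_id: str
    agree: bool
    disagree: bool
    n_publications: int

    def __post_init__(self) -> None:
        if not (self.agree or self.disagree):
            raise ValueError(
                f"{self.protein_id}: a protein with >=2 publications must "
                "agree or disagree with itself"
            )


@dataclass(frozen=True)
class ConsistencySummary:
    """Corpus-level internal-consistency counts and percentages.

    ``pct_agree``/``pct_disagree`` are each computed over ``n_multi``
    independently, so they may sum past 100 (the overlap is ``n_both``).
    Undefined percentages (``n_multi == 0``) are None, never 0.
    """

    n_multi: int
    n_agree: int
    n_disagree: int
    n_both: int
    pct_agree: int | None
    pct_disagree: int | None

    @classmethod
    def from_counts(
        cls, n_multi: int, n_agree: int, n_disagree: int, n_both: int = 0
    ) -> "ConsistencySummary":
        if not (0 <= n_both <= min(n_agree, n_disagree) or n_both == 0):
            raise ValueError("n_both cannot exceed min(n_agree, n_disagree)")
        if max(n_agree, n_disagree) > n_multi:
            raise ValueError("class counts cannot exceed n_multi")
        return cls(
            n_multi=n_multi,
            n_agree=n_agree,
            n_disagree=n_disagree,
            n_both=n_both,
            pct_agree=pct_or_none(n_agree, n_multi),
            pct_disagree=pct_or_none(n_disagree, n_multi),
        )


def publication_compartments(
    fp_claims: ClaimSet, protein_id: str
) -> dict[str, set[str]]:
    """Per-publication compartment sets for one protein.

    Maps each publication id to the set of compartments that publication
    reported the protein in (derived from claim-level publication sets;
    the raw records are not needed after deduplication).
    """
    out: dict[str, set[str]] = {}
    for claim in fp_claims.for_protein(protein_id):
        for pub in claim.publications:
            out.setdefault(pub, set()).add(claim.compartment)
    return out


def multiply_localized(fp_claims: ClaimSet) -> set[str]:
    """Proteins localized at least twice independently by FP, i.e. whose
    publications pooled over all FP claims number >= 2."""
    pubs: dict[str, set[str]] = {}
    for claim in fp_claims:
        pubs.setdefault(claim.protein_id, set()).update(claim.publications)
    return {pid for pid, ps in pubs.items() if len(ps) >= 2}


def classify_consistency(
    protein_id: str, fp_claims: ClaimSet
) -> ConsistencyLabel:
    """Label one multiply-localized protein as agreeing and/or
    disagreeing with itself across publications.

    Raises
    ------
    ValueError
        If the protein has fewer than two FP publications.
    """
    by_pub = publication_compartments(fp_claims, protein_id)
    if len(by_pub) < 2:
        raise ValueError(
            f"{protein_id} has {len(by_pub)} FP publication(s); "
            "consistency classification needs at least 2"
        )
    agree = False
    disagree = False
    for a, b in combinations(by_pub.values(), 2):
        if a & b:
            agree = True
        else:
            disagree = True
        if agree and disagree:
            break
    return ConsistencyLabel(protein_id, agree, disagree, len(by_pub))


def classify_all(fp_claims: ClaimSet) -> list[ConsistencyLabel]:
    """Labels for every multiply-localized protein, sorted by id."""
    return [
        classify_consistency(pid, fp_claims)
        for pid in sorted(multiply_localized(fp_claims))
    ]


def consistency_summary(
    labels: Iterable[ConsistencyLabel],
) -> ConsistencySummary:
    """Aggregate labels into corpus-level counts and percentages."""
    labels = list(labels)
    n_agree = sum(1 for l in labels if l.agree)
    n_disagree = sum(1 for l in labels if l.disagree)
    n_both = sum(1 for l in labels if l.agree and l.disagree)
    return ConsistencySummary.from_counts(
        n_multi=len(labels),
        n_agree=n_agree,
        n_disagree=n_disagree,
        n_both=n_both,
    )
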