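"""Dual-localization analysis of FP claims.

A protein with FP claims in two different compartments is a *dual
claim* for that unordered compartment pair; a protein claimed in k
compartments contributes all C(k, 2) pairs. The pairwise matrix collects
these at corpus level: the diagonal holds the number of distinct
proteins with an FP claim in each compartment, and each off-diagonal
cell the number of distinct proteins claimed in both compartments of the
pair. The matrix is symmetric, every cell is bounded by the smaller of
its two diagonals, and the lower-triangle off-diagonal sum equals the
total number of dual claims.

Directional overlap percentages — what fraction of compartment a's FP
proteome is shared with b, and vice versa — quantify how much any two
subcellular proteomes overlap.

Each dual claim is then partitioned by publication structure: if some
single publication reported the protein in *both* compartments, the dual
location was observed together and is presumed genuine multi-targeting
(``same_publication``); if every supporting publication saw only one of
the two compartments, the pair is a conflict between literature reports
(``cross_publication_only``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, NamedTuple

import pandas as pd

from .errors import FormatError
from .evidence import ClaimSet
from .utils import pct_or_none
from .vocab import COMPARTMENTS, canonicalize_compartment


@dataclass(frozen=True)
class DualClaim:
    """One (protein, unordered compartment pair) dual-localization claim."""

    protein_id: str
    compartment_a: str
    compartment_b: str

    def __post_init__(self) -> None:
        if self.compartment_a == self.compartment_b:
            raise ValueError("a dual claim needs two distinct compartments")
        # normalize pair order to fixed vocabulary order
        ia = COMPARTMENTS.index(self.compartment_a)
        ib = COMPARTMENTS.index(self.compartment_b)
        if ia > ib:
            object.__setattr__(self, "compartment_a", COMPARTMENTS[ib])
            object.__setattr__(self, "compartment_b", COMPARTMENTS[ia])

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.compartment_a, self.compartment_b))


class DualClaimStats(NamedTuple):
    n_claims: int
    n_distinct_proteins: int


def pairwise_matrix(fp_claims: ClaimSet) -> pd.DataFrame:
    """Symmetric compartment-by-compartment co-claim matrix.

    ``diag(c)`` = distinct proteins with an FP claim in c;
    ``cell(a, b)`` = distinct proteins with FP claims in both a and b.
    """
    fp = fp_claims.restrict("FP")
    comps_by_protein: dict[str, set[str]] = {}
    for claim in fp:
        comps_by_protein.setdefault(claim.protein_id, set()).add(
            claim.compartment
        )
    mat = pd.DataFrame(0, index=list(COMPARTMENTS), columns=list(COMPARTMENTS),
                       dtype=int)
    for comps in comps_by_protein.values():
        for c in comps:
            mat.loc[c, c] += 1
        for a, b in combinations(sorted(comps, key=COMPARTMENTS.index), 2):
            mat.loc[a, b] += 1
            mat.loc[b, a] += 1
    return mat


def enumerate_dual_claims(
    fp_claims: ClaimSet,
) -> tuple[list[DualClaim], DualClaimStats]:
    """All dual claims plus (n_claims, n_distinct_proteins).

    ``n_claims`` sums C(k, 2) over proteins claimed in k compartments;
    ``n_distinct_proteins`` counts proteins with k >= 2.
    """
    fp = fp_claims.restrict("FP")
    comps_by_protein: dict[str, set[str]] = {}
    for claim in fp:
        comps_by_protein.setdefault(claim.protein_id, set()).add(
            claim.compartment
        )
    claims: list[DualClaim] = []
    n_proteins = 0
    for pid in sorted(comps_by_protein):
        comps = sorted(comps_by_protein[pid], key=COMPARTMENTS.index)
        if len(comps) >= 2:
            n_proteins += 1
            for a, b in combinations(comps, 2):
                claims.append(DualClaim(pid, a, b))
    return claims, DualClaimStats(len(claims), n_proteins)


def overlap_percent(
    matrix: pd.DataFrame, a: str, b: str
) -> tuple[int | None, int | None]:
    """Directional overlap percentages for a compartment pair.

    Returns ``(pct_of_a, pct_of_b)``: the shared-protein count as a
    percentage of each compartment's own FP proteome. None where a
    diagonal is zero (undefined, not 0).
    """
    if a == b:
        raise ValueError("overlap needs two distinct compartments")
    shared = int(matrix.loc[a, b])
    return (
        pct_or_none(shared, int(matrix.loc[a, a])),
        pct_or_none(shared, int(matrix.loc[b, b])),
    )


def overlap_report(matrix: pd.DataFrame) -> pd.DataFrame:
    """Directional overlap percentages for all 55 compartment pairs."""
    rows = []
    for i, a in enumerate(COMPARTMENTS):
        for b in COMPARTMENTS[i + 1:]:
            pct_a, pct_b = overlap_percent(matrix, a, b)
            rows.append(
                {
                    "compartment_a": a,
                    "compartment_b": b,
                    "n_shared": int(matrix.loc[a, b]),
                    "n_a": int(matrix.loc[a, a]),
                    "n_b": int(matrix.loc[b, b]),
                    "pct_of_a": pct_a,
                    "pct_of_b": pct_b,
                }
            )
    df = pd.DataFrame(rows)
    df["pct_of_a"] = df["pct_of_a"].astype("Int64")
    df["pct_of_b"] = df["pct_of_b"].astype("Int64")
    return df


def off_diagonal_sum(matrix: pd.DataFrame) -> int:
    """Lower-triangle off-diagonal sum = total number of dual claims."""
    total = 0
    for i, a in enumerate(COMPARTMENTS):
        for b in COMPARTMENTS[:i]:
            total += int(matrix.loc[a, b])
    return total


def partition_by_publication(
    dual_claims: Iterable[DualClaim], fp_claims: ClaimSet
) -> tuple[dict[str, int], list[tuple[DualClaim, bool]]]:
    """Split dual claims into same-publication vs cross-publication-only.

    A dual claim is ``same_publication`` iff some publication id appears
    in the publication sets of the protein's FP claims for *both*
    compartments of the pair.
    """
    fp = fp_claims.restrict("FP")
    flagged: list[tuple[DualClaim, bool]] = []
    counts = {"same_publication": 0, "cross_publication_only": 0}
    same_pub_proteins: set[str] = set()
    cross_only_proteins: set[str] = set()
    for dc in dual_claims:
        pubs_a = fp.publications_of(dc.protein_id, dc.compartment_a)
        pubs_b = fp.publications_of(dc.protein_id, dc.compartment_b)
        same = bool(pubs_a & pubs_b)
        flagged.append((dc, same))
        if same:
            counts["same_publication"] += 1
            same_pub_proteins.add(dc.protein_id)
        else:
            counts["cross_publication_only"] += 1
            cross_only_proteins.add(dc.protein_id)
    counts["same_publication_proteins"] = len(same_pub_proteins)
    counts["cross_publication_only_proteins"] = len(cross_only_proteins)
    return counts, flagged


def matrix_to_lower_tsv(matrix: pd.DataFrame, path) -> None:
    """Write the matrix in lower-triangular layout (diagonal included,
    upper cells blank)."""
    out = matrix.astype(object).copy()
    for i, a in enumerate(COMPARTMENTS):
        for b in COMPARTMENTS[i + 1:]:
            out.loc[a, b] = ""
    out.index.name = "compartment"
    out.to_csv(path, sep="\t")


def read_lower_tsv(source) -> pd.DataFrame:
    """Read a lower-triangular matrix TSV and reconstruct the full
    symmetric matrix."""
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", index_col=0)
    idx = [canonicalize_compartment(str(c)) for c in df.index]
    cols = [canonicalize_compartment(str(c)) for c in df.columns]
    if set(idx) != set(COMPARTMENTS) or set(cols) != set(COMPARTMENTS):
        raise FormatError(
            "matrix file must have all 11 compartments as rows and columns"
        )
    df.index = idx
    df.columns = cols
    df = df.reindex(index=list(COMPARTMENTS), columns=list(COMPARTMENTS))
    mat = pd.DataFrame(0, index=list(COMPARTMENTS), columns=list(COMPARTMENTS),
                       dtype=int)
    for i, a in enumerate(COMPARTMENTS):
        for j, b in enumerate(COMPARTMENTS):
            v = df.iloc[i, j]
            if pd.isna(v) or v == "":
                continue
            v = int(v)
            if i == j:
                mat.loc[a, a] = v
            else:
                if mat.loc[a, b] and mat.loc[a, b] != v:
                    raise FormatError(
                        f"asymmetric duplicate cell ({a}, {b}) in matrix file"
                    )
                mat.loc[a, b] = v
                mat.loc[b, a] = v
    return mat
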