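"""Evidence data model: records, claims, and corpus counting semantics.

Localization evidence comes in at three granularities, and keeping them
distinct is the whole point of the reconciliation analysis:

* an **entry** is one published observation — a (protein, compartment,
  method, publication) tuple;
* a **claim** is a deduplicated (protein, compartment, method) assertion
  supported by one or more publications — a protein is counted once per
  location no matter how many groups reported it there;
* a **unique protein** is counted once regardless of how many
  compartments it has been claimed in.

On any corpus ``n_entries >= n_claims >= n_unique_proteins``.

Input is a tab-delimited table with columns ``protein_id``,
``compartment``, ``method``, ``publication_id`` and optional
``tag_position`` and ``assay``. Compartments are canonicalized against
the controlled vocabulary at parse time; exact duplicate rows are
collapsed with a logged warning.
"""

from __future__ import annotations

import io
import logging
import os
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError
from .vocab import COMPARTMENTS, canonicalize_compartment

logger = logging.getLogger(__name__)

METHODS = ("FP", "MS")
TAG_POSITIONS = ("N", "C", "internal", "NA")
ASSAYS = ("transient", "stable", "NA")

#: Default protein-identifier pattern: AGI locus codes (e.g. AT4G16160).
#: A mismatch is a warning, not an error, so non-Arabidopsis identifiers
#: pass through untouched.
AGI_PATTERN = re.compile(r"^AT[1-5CM]G\d{5}$", re.IGNORECASE)

REQUIRED_COLUMNS = ("protein_id", "compartment", "method", "publication_id")
OPTIONAL_COLUMNS = ("tag_position", "assay")


@dataclass(frozen=True, order=True)
class EvidenceRecord:
    """One per-publication localization observation (one input row)."""

    protein_id: str
    compartment: str
    method: str
    publication_id: str
    tag_position: str = "NA"
    assay: str = "NA"

    def entry_key(self) -> tuple[str, str, str, str]:
        """The identity of the observation for entry-level counting."""
        return (self.protein_id, self.compartment, self.method,
                self.publication_id)


@dataclass(frozen=True)
class Claim:
    """A deduplicated (protein, compartment, method) assertion.

    ``publications`` is the set of publications that independently
    support it; it is never empty.
    """

    protein_id: str
    compartment: str
    method: str
    publications: frozenset[str]

    def __post_init__(self) -> None:
        if not self.publications:
            raise ValueError(
                f"claim ({self.protein_id}, {self.compartment}, "
                f"{self.method}) has no supporting publications"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.protein_id, self.compartment, self.method)


@dataclass
class ClaimSet:
    """A collection of claims, unique per (protein, compartment, method)."""

    _claims: dict[tuple[str, str, str], Claim] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def claims(self) -> tuple[Claim, ...]:
        """Claims in deterministic (protein, compartment, method) order."""
        return tuple(self._claims[k] for k in sorted(self._claims))

    def __len__(self) -> int:
        return len(self._claims)

    def __iter__(self):
        return iter(self.claims)

    def __contains__(self, key: tuple[str, str, str]) -> bool:
        return key in self._claims

    def get(self, protein_id: str, compartment: str, method: str) -> Claim | None:
        return self._claims.get((protein_id, compartment, method))

    def add(self, claim: Claim) -> None:
        """Insert a claim, merging publication sets on key collision."""
        existing = self._claims.get(claim.key)
        if existing is not None:
            claim = replace(
                existing,
                publications=existing.publications | claim.publications,
            )
        self._claims[claim.key] = claim

    def restrict(self, method: str) -> "ClaimSet":
        """The sub-ClaimSet for one method (``FP`` or ``MS``)."""
        _check_method(method)
        sub = ClaimSet(provenance=dict(self.provenance))
        for key, claim in self._claims.items():
            if claim.method == method:
                sub._claims[key] = claim
        return sub

    def for_protein(self, protein_id: str) -> tuple[Claim, ...]:
        return tuple(c for c in self.claims if c.protein_id == protein_id)

    def proteins(self) -> set[str]:
        return {c.protein_id for c in self._claims.values()}

    def compartments_of(self, protein_id: str) -> set[str]:
        return {c.compartment for c in self._claims.values()
                if c.protein_id == protein_id}

    def publications_of(self, protein_id: str, compartment: str) -> frozenset[str]:
        """Union of supporting publications over methods for one
        (protein, compartment); empty frozenset if unclaimed."""
        pubs: set[str] = set()
        for method in METHODS:
            claim = self._claims.get((protein_id, compartment, method))
            if claim is not None:
                pubs |= claim.publications
        return frozenset(pubs)

    def by_protein(self) -> dict[str, tuple[Claim, ...]]:
        out: dict[str, list[Claim]] = {}
        for claim in self.claims:
            out.setdefault(claim.protein_id, []).append(claim)
        return {p: tuple(cs) for p, cs in out.items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClaimSet):
            return NotImplemented
        return self._claims == other._claims


@dataclass(frozen=True)
class CorpusSummary:
    """Corpus-level counts for one method.

    Invariant: ``n_entries >= n_claims >= n_unique_proteins``.
    """

    method: str
    n_entries: int
    n_publications: int
    n_unique_proteins: int
    n_claims: int


def _check_method(method: str) -> None:
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")


def parse_evidence(
    source,
    *,
    protein_pattern: re.Pattern | str | None = AGI_PATTERN,
    extra_synonyms: Mapping[str, str] | None = None,
) -> list[EvidenceRecord]:
    """Parse a tab-delimited evidence table into validated records.

    ``source`` may be a path, a file-like object, or a string containing
    TSV text. Compartment labels are canonicalized; exact duplicate rows
    are collapsed with a logged warning; protein identifiers are
    upper-cased and checked against ``protein_pattern`` (warning only).

    Raises
    ------
    FormatError
        If a required column is missing.
    ValueError
        For an invalid method token, empty protein or publication id, or
        an invalid optional-field token.
    """
    if isinstance(source, str) and "\t" in source:
        buf = io.StringIO(source)
    elif isinstance(source, (str, os.PathLike)):
        buf = source
    else:
        buf = source
    try:
        df = pd.read_csv(buf, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError("evidence file is empty (no header row)") from None

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"missing required column(s) {missing}; "
            f"expected at least {list(REQUIRED_COLUMNS)}"
        )

    if isinstance(protein_pattern, str):
        protein_pattern = re.compile(protein_pattern, re.IGNORECASE)

    records: list[EvidenceRecord] = []
    seen: set[EvidenceRecord] = set()
    n_duplicates = 0
    n_pattern_misses = 0
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        pid = str(getattr(row, "protein_id")).strip()
        if not pid:
            raise ValueError(f"empty protein_id (row {idx})")
        pid = pid.upper()
        if protein_pattern is not None and not protein_pattern.match(pid):
            n_pattern_misses += 1
        method = str(getattr(row, "method")).strip()
        if method not in METHODS:
            raise ValueError(
                f"invalid method {method!r} (row {idx}); only "
                f"{'/'.join(METHODS)} are allowed"
            )
        pub = str(getattr(row, "publication_id")).strip()
        if not pub:
            raise ValueError(f"empty publication_id (row {idx})")
        compartment = canonicalize_compartment(
            str(getattr(row, "compartment")),
            row=idx,
            extra_synonyms=dict(extra_synonyms) if extra_synonyms else None,
        )
        tag = str(getattr(row, "tag_position", "NA")).strip() or "NA"
        if tag not in TAG_POSITIONS:
            raise ValueError(
                f"invalid tag_position {tag!r} (row {idx}); "
                f"expected one of {TAG_POSITIONS}"
            )
        assay = str(getattr(row, "assay", "NA")).strip() or "NA"
        if assay not in ASSAYS:
            raise ValueError(
                f"invalid assay {assay!r} (row {idx}); "
                f"expected one of {ASSAYS}"
            )
        rec = EvidenceRecord(pid, compartment, method, pub, tag, assay)
        if rec in seen:
            n_duplicates += 1
            continue
        seen.add(rec)
        records.append(rec)

    if n_duplicates:
        logger.warning("collapsed %d exact duplicate row(s)", n_duplicates)
    if n_pattern_misses:
        logger.warning(
            "%d protein id(s) do not match the expected identifier "
            "pattern (kept as-is)", n_pattern_misses,
        )
    return records


def build_claims(
    records: Iterable[EvidenceRecord],
    *,
    provenance: dict | None = None,
) -> ClaimSet:
    """Deduplicate records into claims keyed by (protein, compartment,
    method), pooling supporting publications."""
    pubs: dict[tuple[str, str, str], set[str]] = {}
    for rec in records:
        key = (rec.protein_id, rec.compartment, rec.method)
        pubs.setdefault(key, set()).add(rec.publication_id)
    cs = ClaimSet(provenance=provenance or {})
    for (pid, comp, method), pubset in pubs.items():
        cs.add(Claim(pid, comp, method, frozenset(pubset)))
    return cs


def summarize_corpus(
    records: Iterable[EvidenceRecord],
    claims: ClaimSet | None = None,
    method: str = "FP",
) -> CorpusSummary:
    """Entry/claim/unique-protein counts for one method.

    ``n_entries`` counts distinct (protein, compartment, method,
    publication) tuples; ``n_claims`` distinct (protein, compartment)
    pairs; ``n_unique_proteins`` distinct proteins; ``n_publications``
    distinct publications contributing at least one entry.
    """
    _check_method(method)
    recs = [r for r in records if r.method == method]
    entries = {r.entry_key() for r in recs}
    if claims is not None:
        claim_keys = {(c.protein_id, c.compartment)
                      for c in claims.restrict(method)}
    else:
        claim_keys = {(r.protein_id, r.compartment) for r in recs}
    return CorpusSummary(
        method=method,
        n_entries=len(entries),
        n_publications=len({r.publication_id for r in recs}),
        n_unique_proteins=len({r.protein_id for r in recs}),
        n_claims=len(claim_keys),
    )


def write_claims(claims: ClaimSet, path) -> None:
    """Write a ClaimSet as TSV: protein_id, compartment, method,
    publications (semicolon-joined, sorted). Round-trips through
    :func:`read_claims`."""
    rows = [
        {
            "protein_id": c.protein_id,
            "compartment": c.compartment,
            "method": c.method,
            "publications": ";".join(sorted(c.publications)),
        }
        for c in claims
    ]
    df = pd.DataFrame(rows, columns=["protein_id", "compartment", "method",
                                     "publications"])
    df.to_csv(path, sep="\t", index=False)


def read_claims(source) -> ClaimSet:
    """Inverse of :func:`write_claims`."""
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    try:
        df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError("claims file is empty (no header row)") from None
    required = ("protein_id", "compartment", "method", "publications")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing} in claims file")
    cs = ClaimSet()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        comp = canonicalize_compartment(str(row.compartment), row=idx)
        method = str(row.method).strip()
        _check_method(method)
        pubs = frozenset(p for p in str(row.publications).split(";") if p)
        cs.add(Claim(str(row.protein_id).strip().upper(), comp, method, pubs))
    return cs


def records_to_frame(records: Iterable[EvidenceRecord]) -> pd.DataFrame:
    """Records as a DataFrame in the input-column layout."""
    return pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "compartment": r.compartment,
                "method": r.method,
                "publication_id": r.publication_id,
                "tag_position": r.tag_position,
                "assay": r.assay,
            }
            for r in records
        ],
        columns=list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS),
    )


def write_records(records: Iterable[EvidenceRecord], path) -> None:
    """Write records as an evidence TSV (parseable by
    :func:`parse_evidence`)."""
    records_to_frame(records).to_csv(path, sep="\t", index=False)
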