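"""Cross-method reconciliation: FP claims checked against MS evidence.

Each FP claim gets exactly one status:

* **confirmed** — some MS claim places the same protein in the same
  compartment (match takes precedence when a protein has MS claims both
  in and out of the compartment);
* **contradicted** — the protein has MS evidence, but none of it in the
  claimed compartment;
* **unvalidated** — the protein has no MS evidence at all.

The three statuses partition the FP claims, so per compartment
``n_fp = n_confirmed + n_contradicted + n_unvalidated``. Agreement and
disagreement percentages use only validated claims (confirmed +
contradicted) as denominator — the proteins with both FP and MS data.

Contradicted claims are then triaged: a conflict is *rescued* when the
same protein has a different FP claim that does match an MS location
(the overall FP evidence does not strictly disagree with proteomics),
*explained* when the protein is on a curated dual-targeted/dynamic list,
and otherwise left *unresolved*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .evidence import Claim, ClaimSet
from .utils import pct_or_none
from .vocab import COMPARTMENTS

STATUSES = ("confirmed", "contradicted", "unvalidated")
TRIAGE_CATEGORIES = ("other_fp_agrees", "curated_dual_targeted", "unresolved")

TOTAL_LABEL = "total"


@dataclass(frozen=True)
class ClaimStatus:
    """Reconciliation status of one FP claim."""

    protein_id: str
    compartment: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


@dataclass(frozen=True)
class TriageLabel:
    """Triage category for one contradicted FP claim."""

    protein_id: str
    compartment: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in TRIAGE_CATEGORIES:
            raise ValueError(f"unknown triage category {self.category!r}")


def reconcile_claim(fp_claim: Claim, ms_claims: ClaimSet) -> ClaimStatus:
    """Status of one FP claim against the MS claim set."""
    if fp_claim.method != "FP":
        raise ValueError(
            f"expected an FP claim, got method {fp_claim.method!r}"
        )
    ms_compartments = {
        c.compartment for c in ms_claims
        if c.protein_id == fp_claim.protein_id and c.method == "MS"
    }
    if not ms_compartments:
        status = "unvalidated"
    elif fp_claim.compartment in ms_compartments:
        status = "confirmed"
    else:
        status = "contradicted"
    return ClaimStatus(fp_claim.protein_id, fp_claim.compartment, status)


def reconcile_all(fp_claims: ClaimSet, ms_claims: ClaimSet) -> list[ClaimStatus]:
    """One status per FP claim, in deterministic claim order."""
    ms = ms_claims.restrict("MS")
    ms_by_protein: dict[str, set[str]] = {}
    for c in ms:
        ms_by_protein.setdefault(c.protein_id, set()).add(c.compartment)
    out: list[ClaimStatus] = []
    for claim in fp_claims.restrict("FP"):
        comps = ms_by_protein.get(claim.protein_id)
        if not comps:
            status = "unvalidated"
        elif claim.compartment in comps:
            status = "confirmed"
        else:
            status = "contradicted"
        out.append(ClaimStatus(claim.protein_id, claim.compartment, status))
    return out


def reconciliation_table(statuses: Iterable[ClaimStatus]) -> pd.DataFrame:
    """Per-compartment reconciliation counts and percentages.

    Returns a DataFrame indexed by compartment (fixed vocabulary order)
    plus a ``total`` row, with columns ``n_fp``, ``n_confirmed``,
    ``n_contradicted``, ``n_unvalidated``, ``pct_agree``,
    ``pct_disagree``. Percentages are over validated claims only and are
    pandas NA where a compartment has none.
    """
    counts = {c: {"confirmed": 0, "contradicted": 0, "unvalidated": 0}
              for c in COMPARTMENTS}
    for s in statuses:
        counts[s.compartment][s.status] += 1
    rows = []
    for comp in COMPARTMENTS + (TOTAL_LABEL,):
        if comp == TOTAL_LABEL:
            conf = sum(counts[c]["confirmed"] for c in COMPARTMENTS)
            contra = sum(counts[c]["contradicted"] for c in COMPARTMENTS)
            unval = sum(counts[c]["unvalidated"] for c in COMPARTMENTS)
        else:
            conf = counts[comp]["confirmed"]
            contra = counts[comp]["contradicted"]
            unval = counts[comp]["unvalidated"]
        validated = conf + contra
        rows.append(
            {
                "compartment": comp,
                "n_fp": conf + contra + unval,
                "n_confirmed": conf,
                "n_contradicted": contra,
                "n_unvalidated": unval,
                "pct_agree": pct_or_none(conf, validated),
                "pct_disagree": pct_or_none(contra, validated),
            }
        )
    df = pd.DataFrame(rows).set_index("compartment")
    for col in ("pct_agree", "pct_disagree"):
        df[col] = df[col].astype("Int64")
    return df


def recompute_percentages(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute ``pct_agree``/``pct_disagree`` from the count columns of
    a reconciliation-style table (e.g. a transcribed published table),
    over validated claims."""
    out = table.copy()
    out["pct_agree"] = [
        pct_or_none(conf, conf + contra)
        for conf, contra in zip(out["n_confirmed"], out["n_contradicted"])
    ]
    out["pct_disagree"] = [
        pct_or_none(contra, conf + contra)
        for conf, contra in zip(out["n_confirmed"], out["n_contradicted"])
    ]
    out["pct_agree"] = out["pct_agree"].astype("Int64")
    out["pct_disagree"] = out["pct_disagree"].astype("Int64")
    return out


def triage_contradictions(
    statuses: Iterable[ClaimStatus],
    fp_claims: ClaimSet,
    ms_claims: ClaimSet,
    curated_dual: set[str] | frozenset[str] = frozenset(),
) -> list[TriageLabel]:
    """Triage every contradicted FP claim.

    Precedence: ``other_fp_agrees`` (another FP claim for the protein
    matches some MS location) > ``curated_dual_targeted`` (protein on the
    curated dual-targeted list) > ``unresolved``.
    """
    fp = fp_claims.restrict("FP")
    ms = ms_claims.restrict("MS")
    ms_by_protein: dict[str, set[str]] = {}
    for c in ms:
        ms_by_protein.setdefault(c.protein_id, set()).add(c.compartment)
    curated = {p.upper() for p in curated_dual}
    out: list[TriageLabel] = []
    for s in statuses:
        if s.status != "contradicted":
            continue
        ms_comps = ms_by_protein.get(s.protein_id, set())
        other_fp = fp.compartments_of(s.protein_id) - {s.compartment}
        if other_fp & ms_comps:
            category = "other_fp_agrees"
        elif s.protein_id.upper() in curated:
            category = "curated_dual_targeted"
        else:
            category = "unresolved"
        out.append(TriageLabel(s.protein_id, s.compartment, category))
    return out
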