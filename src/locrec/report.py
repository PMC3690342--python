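"""Output rendering and run orchestration.

Every pipeline stage writes diff-stable TSV tables (compartments in
fixed vocabulary order, undefined percentages as ``NA``) and JSON
summaries, plus a run manifest recording input checksums, tool version,
seeds, stages and outputs, so identical inputs reproduce identical
output trees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .consistency import ConsistencyLabel, ConsistencySummary, classify_all, consistency_summary
from .dualloc import (
    DualClaim,
    enumerate_dual_claims,
    matrix_to_lower_tsv,
    overlap_report,
    pairwise_matrix,
    partition_by_publication,
)
from .evidence import build_claims, parse_evidence, summarize_corpus, write_claims
from .reconcile import (
    TriageLabel,
    reconcile_all,
    reconciliation_table,
    triage_contradictions,
)
from .utils import fmt_pct

MANIFEST_NAME = "manifest.json"


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: Path,
    inputs: dict[str, str | None],
    outputs: Sequence[str],
    stages: Sequence[str],
    seed: int | None = None,
) -> Path:
    manifest = {
        "tool": "locrec",
        "version": __version__,
        "seed": seed,
        "stages": list(stages),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in inputs.items()
            if p is not None
        },
        "outputs": sorted(str(o) for o in outputs),
    }
    path = Path(out_dir) / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_summary_json(summaries: dict, path) -> None:
    _write_json(
        {m: dataclasses.asdict(s) for m, s in summaries.items()}, Path(path)
    )


def write_consistency_outputs(
    labels: Iterable[ConsistencyLabel],
    summary: ConsistencySummary,
    out_dir,
) -> list[Path]:
    out_dir = Path(out_dir)
    labels_path = out_dir / "consistency_labels.tsv"
    pd.DataFrame(
        [
            {
                "protein_id": l.protein_id,
                "n_publications": l.n_publications,
                "agree": l.agree,
                "disagree": l.disagree,
            }
            for l in labels
        ],
        columns=["protein_id", "n_publications", "agree", "disagree"],
    ).to_csv(labels_path, sep="\t", index=False)
    summary_path = out_dir / "consistency_summary.json"
    _write_json(dataclasses.asdict(summary), summary_path)
    return [labels_path, summary_path]


def render_reconciliation_tsv(table: pd.DataFrame, path) -> None:
    """Reconciliation table in the published column layout, with the
    percentage pair rendered as ``agree/disagree``."""
    out = table.copy()
    out["pct_agree_disagree"] = [
        f"{fmt_pct(None if pd.isna(a) else int(a))}/"
        f"{fmt_pct(None if pd.isna(d) else int(d))}"
        for a, d in zip(out["pct_agree"], out["pct_disagree"])
    ]
    out = out[["n_fp", "n_confirmed", "n_contradicted", "pct_agree_disagree",
               "n_unvalidated"]]
    out.to_csv(path, sep="\t")


def write_reconcile_outputs(
    statuses,
    table: pd.DataFrame,
    triage: Iterable[TriageLabel],
    out_dir,
) -> list[Path]:
    out_dir = Path(out_dir)
    triage_by_key = {
        (t.protein_id, t.compartment): t.category for t in triage
    }
    statuses_path = out_dir / "claim_statuses.tsv"
    pd.DataFrame(
        [
            {
                "protein_id": s.protein_id,
                "compartment": s.compartment,
                "status": s.status,
                "triage_category": triage_by_key.get(
                    (s.protein_id, s.compartment), "NA"
                ),
            }
            for s in statuses
        ],
        columns=["protein_id", "compartment", "status", "triage_category"],
    ).to_csv(statuses_path, sep="\t", index=False)

    table_path = out_dir / "reconciliation_table.tsv"
    render_reconciliation_tsv(table, table_path)

    totals = table.loc["total"]
    totals_path = out_dir / "reconciliation_totals.json"
    _write_json(
        {
            "n_fp": int(totals["n_fp"]),
            "n_confirmed": int(totals["n_confirmed"]),
            "n_contradicted": int(totals["n_contradicted"]),
            "n_unvalidated": int(totals["n_unvalidated"]),
            "pct_agree": None if pd.isna(totals["pct_agree"])
            else int(totals["pct_agree"]),
            "pct_disagree": None if pd.isna(totals["pct_disagree"])
            else int(totals["pct_disagree"]),
        },
        totals_path,
    )
    return [statuses_path, table_path, totals_path]


def write_dualloc_outputs(
    matrix: pd.DataFrame,
    flagged: Sequence[tuple[DualClaim, bool]],
    counts: dict[str, int],
    out_dir,
) -> list[Path]:
    out_dir = Path(out_dir)
    matrix_path = out_dir / "dual_matrix.tsv"
    matrix_to_lower_tsv(matrix, matrix_path)

    claims_path = out_dir / "dual_claims.tsv"
    pd.DataFrame(
        [
            {
                "protein_id": dc.protein_id,
                "compartment_a": dc.compartment_a,
                "compartment_b": dc.compartment_b,
                "same_publication": same,
            }
            for dc, same in flagged
        ],
        columns=["protein_id", "compartment_a", "compartment_b",
                 "same_publication"],
    ).to_csv(claims_path, sep="\t", index=False)

    overlap_path = out_dir / "overlap_report.tsv"
    df = overlap_report(matrix)
    df["pct_of_a"] = [fmt_pct(None if pd.isna(v) else int(v))
                      for v in df["pct_of_a"]]
    df["pct_of_b"] = [fmt_pct(None if pd.isna(v) else int(v))
                      for v in df["pct_of_b"]]
    df.to_csv(overlap_path, sep="\t", index=False)

    counts_path = out_dir / "dual_summary.json"
    _write_json(dict(counts), counts_path)
    return [matrix_path, claims_path, overlap_path, counts_path]


def run_all(
    fp_path,
    ms_path,
    out_dir,
    curated_dual: set[str] | None = None,
) -> dict[str, Path]:
    """Run the full pipeline: validate -> summarize -> consistency ->
    reconcile -> dualloc, writing all outputs plus a manifest.

    Returns a mapping of output names to paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fp_records = parse_evidence(fp_path)
    ms_records = parse_evidence(ms_path)
    records = fp_records + ms_records
    claims = build_claims(records)
    fp = claims.restrict("FP")
    ms = claims.restrict("MS")

    outputs: list[Path] = []

    claims_path = out_dir / "claims.tsv"
    write_claims(claims, claims_path)
    outputs.append(claims_path)

    summary_path = out_dir / "corpus_summary.json"
    write_summary_json(
        {
            "FP": summarize_corpus(records, claims, "FP"),
            "MS": summarize_corpus(records, claims, "MS"),
        },
        summary_path,
    )
    outputs.append(summary_path)

    labels = classify_all(fp)
    outputs += write_consistency_outputs(
        labels, consistency_summary(labels), out_dir
    )

    statuses = reconcile_all(fp, ms)
    table = reconciliation_table(statuses)
    triage = triage_contradictions(statuses, fp, ms, curated_dual or set())
    outputs += write_reconcile_outputs(statuses, table, triage, out_dir)

    matrix = pairwise_matrix(fp)
    dual_claims, _ = enumerate_dual_claims(fp)
    counts, flagged = partition_by_publication(dual_claims, fp)
    outputs += write_dualloc_outputs(matrix, flagged, counts, out_dir)

    write_manifest(
        out_dir,
        inputs={"fp": fp_path, "ms": ms_path},
        outputs=[p.name for p in outputs],
        stages=["validate", "summarize", "consistency", "reconcile",
                "dualloc"],
    )
    return {p.name: p for p in outputs}
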