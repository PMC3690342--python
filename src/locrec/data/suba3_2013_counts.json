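{
  "description": "Corpus-level counts from the 2013 snapshot of the SUBA3 Arabidopsis subcellular-localization database. Entries are (protein, compartment, method, publication) observations; claims are deduplicated (protein, compartment) assertions per method. Values under 'printed' reproduce the published table totals verbatim, including their known internal inconsistencies (the contradicted total 554 differs from the column sum 553).",
  "fp": {
    "n_entries": 3788,
    "n_publications": 1074,
    "n_unique_proteins": 2477,
    "n_claims": 2996
  },
  "ms": {
    "n_entries": 22191,
    "n_publications": 122,
    "n_unique_proteins": 7685
  },
  "fp_consistency": {
    "n_multi": 443,
    "n_agree": 375,
    "n_disagree": 123
  },
  "dual": {
    "n_claims": 739,
    "n_distinct_proteins": 545,
    "same_publication_claims": 595,
    "same_publication_proteins": 491,
    "cross_publication_proteins_printed": 105
  },
  "printed": {
    "total_fp": 2996,
    "total_confirmed": 849,
    "total_contradicted": 554,
    "total_unvalidated": 1593,
    "total_pct_agree": 61,
    "total_pct_disagree": 39
  }
}
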