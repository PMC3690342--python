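# Methods

## Evidence model and counting semantics

The unit of input is an *entry*: one published observation, a
(protein, compartment, method, publication) tuple with method ∈
{FP, MS}. Parsing canonicalizes compartment labels against a closed
11-term vocabulary with a shipped, user-extensible synonym table;
an unresolvable label is a hard error naming the value and row, never a
silent drop, so vocabulary drift in an input corpus cannot quietly bias
the counts. Exact duplicate rows collapse with a logged warning.
Protein identifiers are upper-cased and checked against an AGI-style
pattern (`AT[1-5CM]G\d{5}`), but a mismatch is only a warning so the
pipeline works unchanged on non-Arabidopsis identifiers.

Entries deduplicate into *claims* keyed by (protein, compartment,
method), each carrying the union of supporting publication ids. A
publication reporting the same protein/compartment twice counts once.
"Independent" localizations means distinct publication ids; two papers
from the same lab are treated as independent, since lab identity is not
recoverable from a claims table. Corpus summaries report entry, claim,
publication and unique-protein counts per method; the conservation
`n_entries ≥ n_claims ≥ n_unique_proteins` holds by construction and is
property-tested.

## Internal FP consistency

For each protein whose FP claims pool ≥ 2 publications, every
publication contributes the set of compartments it reported for that
protein. A pair of publications *agrees* when the sets intersect and
*disagrees* when they are disjoint; the protein is labelled with
whichever relations any pair exhibits, possibly both. Pairwise
disjointness — rather than set inequality — is deliberate: a
publication seeing {plastid} and another seeing {plastid, mitochondrion}
is a compatible dual-target discovery, not a conflict. This choice is
what makes the "both" class reachable exactly as observed in real
corpora (agree with one paper, disagree with another). The agree and
disagree percentages are each computed over all multiply-localized
proteins, so their sum can exceed 100; the overlap (`n_both`) is
reported as a raw count rather than a derived percentage, since
rounding makes percentage arithmetic on the two classes inconsistent.

## FP-vs-MS reconciliation

Each FP claim receives exactly one status. Confirmed takes precedence:
if the protein has MS claims both in and out of the FP compartment, the
match wins. This mutual exclusivity is forced by the requirement that
the three status columns partition `n_fp` per compartment — the
conservation law `n_fp = confirmed + contradicted + unvalidated` is
asserted on every corpus. Agreement/disagreement percentages use only
validated claims (confirmed + contradicted) as denominator: the
proteins for which both methods have spoken.

Contradicted claims are triaged with a fixed precedence:
`other_fp_agrees` (some different FP claim for the protein matches an
MS location, so the FP evidence as a whole does not strictly disagree
with proteomics) > `curated_dual_targeted` (the protein appears on a
user-supplied curated list of known dual-targeted or dynamic proteins)
> `unresolved`. The curated list is an input, not package logic: the
verdicts that require reading the primary literature (method-technical
issues on the MS or FP side) are out of computational reach, and the
shipped `curated_dual_examples.txt` documents the file format only.

## Dual-localization analysis

Dual claims are counted at the protein × unordered-compartment-pair
level: a protein claimed in k compartments contributes C(k,2) pairs, so
the claim count can exceed the count of multiply-localized proteins.
The pairwise matrix aggregates these (diagonal: distinct proteins per
compartment; off-diagonal: distinct proteins shared by the pair); it is
symmetric, every cell is bounded by the smaller diagonal, and its
lower-triangle off-diagonal sum equals the enumerated dual-claim total —
all property-tested against brute-force pair enumeration. Directional
overlap percentages divide each shared count by either diagonal.

A dual claim is `same_publication` when the publication sets of the two
claims intersect — some single study saw both compartments, which is
read as presumptive genuine dual targeting; otherwise it is a
`cross_publication_only` literature conflict. Publication-set
intersection at claim level is sufficient; the raw records add nothing
after deduplication.

## Rounding

Every emitted percentage passes through a single rounding function:
round half away from zero to integer percent. This convention
reproduces the reference corpus's printed percentages (85, 28, 61, 63,
88, 46, 32) from its raw counts; banker's rounding would not (62.5 must
print as 63).

## Reference fixtures and their known print inconsistencies

The package ships transcriptions of the fully printed summary tables of
the 2013 SUBA3 Arabidopsis corpus snapshot: the per-compartment
FP/MS reconciliation table (`table1.tsv`), the pairwise
dual-localization matrix (`table2.tsv`), and the corpus-level headline
counts (`suba3_2013_counts.json`). Four internal inconsistencies of the
printed source are documented and excluded from assertions rather than
"corrected":

1. the printed contradicted-column total (554) disagrees with its own
   column sum (553); the conservation law, not the printed total, is
   asserted (the overall 61% agreement is insensitive to the choice);
2. the vacuole disagree percentage prints 34 although 18/52 rounds to
   35 under any half-rounding convention;
3. the mitochondrion disagree percentage prints 37 although 54/144 =
   37.5 rounds to 38 under the package's convention (the agree cell of
   the same row, 62.5 → 63, is itself what pins that convention);
4. the plasma-membrane diagonal of the pairwise matrix prints 145 while
   the reconciliation table counts 245 plasma-membrane FP claims; every
   other diagonal matches, so 145 is treated as a typographical error
   and no assertion ties the PM diagonal to the reconciliation table.

The fixture-reproduction test asserts exact agreement on every other
cell. Likewise, the printed "105 proteins" for the cross-publication
conflict class cannot be derived from the printed data (739 − 595 = 144
claims); both claim- and protein-level counts are reported and neither
is asserted. Whether the printed publication total counts publications
per entry or per claim is ambiguous, so the corpus summary exposes the
computed count without asserting the printed one.

## Synthetic corpus generator

The generator emulates a curated localization corpus with known ground
truth. Per protein: a true compartment set (size 2 with probability
`dual_fraction`, else 1), `fp_pubs_per_protein` FP publications, and an
MS survey covering the protein with probability `ms_coverage`. Each
study reports each true compartment correctly with probability
`1 − e` (e = `e_fp` or `e_ms`) and otherwise reports one of the 10
other compartments uniformly at random. Every simulated study has its
own publication id. Generation is a single pass over proteins driven by
one `numpy` generator seeded from the config, so identical config ⇒
byte-identical corpus.

Defaults sketch the reference corpus at reduced scale: 500 proteins;
compartment frequencies proportional to the corpus's per-compartment FP
claim counts; `dual_fraction` 0.20 (≈ 545 dual proteins / 2477);
2 FP publications per protein (≈ 3788 entries / 2477 proteins, rounded
up to make internal-consistency checks non-trivial); `ms_coverage` 0.5
(≈ 1402 validated / 2996 claims); `e_fp` 0.15 and `e_ms` 0.10, in the
range suggested by per-compartment disagreement rates of 12–64% once
genuine dual targeting is discounted. Pair weights for dual-targeted
proteins default to uniform over the 55 pairs; the strong
nucleus/cytosol and plastid/mitochondrion enrichment of real corpora
is reachable through the config but is not the default, which keeps
the closed-form expectations simple.

Uniform wrong-compartment draws give the confirmed fraction among
validated claims a closed form in the single-target, one-FP-publication
setting:

    P(confirmed) = (1 − e_fp)(1 − e_ms) + e_fp · e_ms / 10

(both studies correct, or both wrong and colliding among the 10 wrong
compartments). The test suite cross-checks this formula against
exhaustive enumeration over the 11 × 11 outcome grid, then checks the
full simulate→parse→deduplicate→reconcile pipeline against it within 3
Monte-Carlo standard errors at 2000 proteins, plus a 20-seed mean at
500 proteins; those problem sizes give standard errors of ~0.010 and
~0.005, small enough to detect any systematic defect in the pipeline's
counting. With noise off, recovery is exact: 100% confirmed, zero
internal conflicts, dual-claim count equal to the number of true dual
proteins. `e_fp` is recoverable as one minus the per-record truth-match
rate (exact for single-target corpora, where a wrong draw can never hit
another true compartment).

What the simulator does *not* emulate: publications spanning many
proteins (each simulated study covers one), compartment-biased
confusion (e.g. plastid/mitochondrion cross-talk), tag-position
artifacts (N-terminal tags masking transit peptides — `tag_position`
is carried as inert metadata), triple-targeted proteins (true sets are
capped at 2 to keep `dual_fraction` interpretable; k ≥ 3 behaviour is
exercised by hand-built fixtures in the tests), and correlated FP/MS
errors. Passing simulation-based tests therefore demonstrates that the
pipeline's counting and classification are correct under the stated
generative model, not that real FP or MS evidence satisfies that model.

## Numerical and degenerate-input choices

Undefined percentages (zero denominator: no validated claims in a
compartment, no multiply-localized proteins, an empty compartment
diagonal) are reported as a sentinel (`None` in memory, `NA` in TSV,
`null` in JSON), never as 0 — an empty denominator is absence of
evidence, not perfect disagreement. Tables always contain all 11
compartments in fixed vocabulary order plus a total row, so outputs are
diff-stable and column order never depends on the input. Nothing
depends on iteration order: claims sort by key, dual-claim pairs
normalize to vocabulary order, and a reversed input corpus produces
byte-identical outputs (property-tested). Every run directory gets a
manifest with input SHA-256 checksums, tool version, seed and stage
list.

## Known limitations

The reconciliation is claim-level and treats MS evidence as a flat
claim set: survey quality, peptide counts and fractionation purity are
out of scope, as is mapping the 11-term vocabulary onto GO cellular
components or suborganellar locations. Triage cannot distinguish
"technical issue with FP" from "technical issue with MS" — that
requires reading the underlying papers, which is exactly what the
curated-list input encodes.
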