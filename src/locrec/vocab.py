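"""Controlled vocabulary of subcellular compartments.

Localization evidence is reconciled over a closed set of 11 compartment
terms covering the major compartments of a plant cell. Free-text labels
from input tables are resolved against a shipped synonym table
(case-insensitive, punctuation-insensitive); anything that does not
resolve is a hard error rather than a silent drop, so vocabulary drift in
an input corpus surfaces immediately.

The fixed ordering of :data:`COMPARTMENTS` (alphabetical by display
label) is used for every emitted table so that outputs are diff-stable.
"""

from __future__ import annotations

import re

from .errors import VocabularyError

#: Canonical compartment tokens, in fixed report order.
COMPARTMENTS: tuple[str, ...] = (
    "cytoskeleton",
    "cytosol",
    "endoplasmic_reticulum",
    "extracellular",
    "golgi",
    "mitochondrion",
    "nucleus",
    "peroxisome",
    "plasma_membrane",
    "plastid",
    "vacuole",
)

#: Short display labels used in rendered tables.
DISPLAY_LABELS: dict[str, str] = {
    "cytoskeleton": "Cytoskeleton",
    "cytosol": "Cytosol",
    "endoplasmic_reticulum": "ER",
    "extracellular": "Extracellular",
    "golgi": "Golgi",
    "mitochondrion": "Mitochondrion",
    "nucleus": "Nucleus",
    "peroxisome": "Peroxisome",
    "plasma_membrane": "PM",
    "plastid": "Plastid",
    "vacuole": "Vacuole",
}

# Synonym table: normalized free-text label -> canonical token.
# Users may extend it at parse time; these shipped entries cover the
# labels commonly seen in plant localization literature and databases.
_SYNONYMS: dict[str, str] = {
    # endoplasmic reticulum
    "er": "endoplasmic_reticulum",
    "e_r": "endoplasmic_reticulum",
    "endoplasmic_reticulum": "endoplasmic_reticulum",
    # plasma membrane
    "pm": "plasma_membrane",
    "plasma_membrane": "plasma_membrane",
    "plasmalemma": "plasma_membrane",
    # plastid family
    "chloroplast": "plastid",
    "chloroplasts": "plastid",
    "plastids": "plastid",
    "amyloplast": "plastid",
    "etioplast": "plastid",
    "chromoplast": "plastid",
    # golgi
    "golgi_apparatus": "golgi",
    "golgi_body": "golgi",
    "golgi_bodies": "golgi",
    "golgi_stack": "golgi",
    # extracellular / secreted
    "cell_wall": "extracellular",
    "apoplast": "extracellular",
    "extracellular_space": "extracellular",
    "extracellular_region": "extracellular",
    "secreted": "extracellular",
    # mitochondrion
    "mitochondria": "mitochondrion",
    "mito": "mitochondrion",
    # cytosol
    "cytoplasm": "cytosol",
    # vacuole
    "vacuoles": "vacuole",
    "tonoplast": "vacuole",
    "vacuolar_membrane": "vacuole",
    # plurals of remaining canonical terms
    "nuclei": "nucleus",
    "peroxisomes": "peroxisome",
    "microbody": "peroxisome",
}
_SYNONYMS.update({c: c for c in COMPARTMENTS})

_NORM_RE = re.compile(r"[^a-z0-9]+")


def _normalize(label: str) -> str:
    """Lower-case and collapse runs of punctuation/whitespace to ``_``."""
    return _NORM_RE.sub("_", label.strip().lower()).strip("_")


def canonicalize_compartment(
    label: str,
    *,
    row: int | None = None,
    extra_synonyms: dict[str, str] | None = None,
) -> str:
    """Resolve a free-text compartment label to its canonical token.

    Parameters
    ----------
    label
        Free-text compartment name, e.g. ``"ER"``, ``"Chloroplast"``,
        ``"Golgi apparatus"``. Matching is case-insensitive and ignores
        punctuation.
    row
        Optional 1-based input row number, included in the error message
        so malformed files can be fixed by line.
    extra_synonyms
        User-supplied additions to the shipped synonym table, mapping
        free-text labels to canonical tokens. Values must themselves be
        canonical.

    Raises
    ------
    VocabularyError
        If the label is empty, resolves to nothing, or an extra synonym
        maps to a non-canonical token.
    """
    if not label or not label.strip():
        where = f" (row {row})" if row is not None else ""
        raise VocabularyError(f"empty compartment label{where}")
    key = _normalize(label)
    if extra_synonyms:
        for raw, target in extra_synonyms.items():
            if target not in COMPARTMENTS:
                raise VocabularyError(
                    f"synonym target {target!r} is not one of the 11 "
                    f"canonical compartments"
                )
            if _normalize(raw) == key:
                return target
    try:
        return _SYNONYMS[key]
    except KeyError:
        where = f" (row {row})" if row is not None else ""
        raise VocabularyError(
            f"unknown compartment label {label!r}{where}; expected one of "
            f"the 11 canonical terms or a listed synonym"
        ) from None


def compartment_pairs() -> list[tuple[str, str]]:
    """All 55 unordered compartment pairs, in report order."""
    return [
        (COMPARTMENTS[i], COMPARTMENTS[j])
        for i in range(len(COMPARTMENTS))
        for j in range(i + 1, len(COMPARTMENTS))
    ]
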