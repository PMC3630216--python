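"""Seven-way somatic mutation-signature classification.

Each GIST subject carries (at most) one primary somatic mutation record in
KIT or PDGFRA.  The case-only analysis contrasts subjects whose tumor shows a
particular mutation signature against all other genotyped cases, for seven
mutually exclusive signature categories:

1. ``kit_ex11_557_558_del`` — KIT exon 11 deletion whose codon span covers
   both codons 557 and 558 (the canonical 557-8 deletion),
2. ``kit_ex11_other_del`` — any other KIT exon 11 deletion,
3. ``kit_ex11_ins`` — KIT exon 11 insertion,
4. ``kit_ex11_point`` — KIT exon 11 point mutation,
5. ``kit_other_exon`` — KIT exon 9, 13, 14 or 17 mutation of any type
   (too rare individually to analyse separately),
6. ``pdgfra`` — PDGFRA exon 12 or 18 mutation,
7. ``wild_type`` — no KIT or PDGFRA mutation detected.

A deletion spanning 557-558 plus further codons still counts as category 1
(span-covers rule).  Classification is total on the validated mutation-record
grammar; anything else raises :class:`ClassificationError`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["CATEGORIES", "ClassificationError", "classify_mutation", "build_outcome_matrix"]

CATEGORIES = (
    "kit_ex11_557_558_del",
    "kit_ex11_other_del",
    "kit_ex11_ins",
    "kit_ex11_point",
    "kit_other_exon",
    "pdgfra",
    "wild_type",
)

_KIT_OTHER_EXONS = {9, 13, 14, 17}
_PDGFRA_EXONS = {12, 18}


class ClassificationError(ValueError):
    """Mutation record falls outside the recognized gene/exon grammar."""


def classify_mutation(record: pd.Series | dict | None) -> str:
    """Map one somatic mutation record to its signature category.

    Parameters
    ----------
    record
        A validated mutation-table row (``gene, exon, mutation_type,
        codon_start, codon_end``), or ``None`` / a gene == "none" row for a
        wild-type tumor.

    Returns
    -------
    str
        One of :data:`CATEGORIES`.
    """
    if record is None:
        return "wild_type"
    gene = record.get("gene") if isinstance(record, dict) else record["gene"]
    if gene in (None, "", "none") or (isinstance(gene, float) and np.isnan(gene)):
        return "wild_type"

    def _get(key):
        v = record.get(key) if isinstance(record, dict) else record[key]
        return None if v is None or pd.isna(v) else v

    exon = _get("exon")
    mtype = _get("mutation_type")
    if gene == "KIT":
        if exon == 11:
            if mtype == "deletion":
                start, end = _get("codon_start"), _get("codon_end")
                covers = start is not None and end is not None and start <= 557 and end >= 558
                return "kit_ex11_557_558_del" if covers else "kit_ex11_other_del"
            if mtype == "insertion":
                return "kit_ex11_ins"
            if mtype == "point":
                return "kit_ex11_point"
            raise ClassificationError(f"KIT exon 11 record with unrecognized type {mtype!r}")
        if exon in _KIT_OTHER_EXONS:
            return "kit_other_exon"
        raise ClassificationError(f"KIT record with unrecognized exon {exon!r}")
    if gene == "PDGFRA":
        if exon in _PDGFRA_EXONS:
            return "pdgfra"
        raise ClassificationError(f"PDGFRA record with unrecognized exon {exon!r}")
    raise ClassificationError(f"unrecognized gene {gene!r}")


def build_outcome_matrix(mutations: pd.DataFrame) -> pd.DataFrame:
    """Classify every subject and emit the seven case-only dichotomies.

    Returns a frame indexed by subject id with a ``category`` column and one
    0/1 indicator column per signature category; for dichotomy *k* the cases
    are the subjects in category *k* and the referents are every other
    genotyped case.  Indicator rows sum to exactly 1.
    """
    categories = [classify_mutation(row) for _, row in mutations.iterrows()]
    out = pd.DataFrame({"category": categories}, index=pd.Index(mutations["subject_id"], name="subject_id"))
    for cat in CATEGORIES:
        out[cat] = (out["category"] == cat).astype(int)
    return out
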