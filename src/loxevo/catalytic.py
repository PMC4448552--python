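"""Catalytic-competence assessment of LOX domains.

Two structural requirements proxy for enzymatic activity: the copper-binding
"copper-talon" histidine core (InterPro IPR019828 conserved site;
``WEWHSCHQHYHSMD`` in human LOX, with histidines at motif offsets 4, 7, 9
and 11), and the lysine/tyrosine pair that forms the lysyl-tyrosyl-quinone
(LTQ) cofactor (K320 and Y355 in the human reference). Mutagenesis showed
the first (N-terminal-most) histidine to be dispensable for copper binding,
so competence requires the three core histidines plus K and Y; the first
histidine is recorded but not required.

A located column containing a gap counts as residue-absent (conservative).
A row that is entirely gaps across the motif span is reported unalignable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .msa import GAP, MultipleAlignment

HUMAN_MOTIF = "WEWHSCHQHYHSMD"
# 1-based offsets of the histidines within the motif: first is dispensable
H_OFFSETS = (4, 7, 9, 11)


@dataclass
class CatalyticRule:
    motif_pattern: str = r"W.WH..H.H.H"
    h_offsets: tuple[int, int, int, int] = H_OFFSETS  # 1-based within motif
    dispensable_index: int = 0  # index into h_offsets of the dispensable H
    reference_id: str = "Hsap_ENSP00000231004"
    ltq_k_position: int = 320  # 1-based in the ungapped reference
    ltq_y_position: int = 355
    min_core_histidines: int = 3

    def __post_init__(self):
        if len(self.h_offsets) != 4:
            raise ValueError("exactly 4 histidine slots must be defined")
        if self.min_core_histidines != 3:
            raise ValueError("the core requires exactly 3 histidines")

    @property
    def core_offsets(self) -> tuple[int, ...]:
        return tuple(
            o for i, o in enumerate(self.h_offsets) if i != self.dispensable_index
        )


@dataclass
class CatalyticAssessment:
    protein_id: str
    h_flags: tuple[bool, bool, bool, bool]
    k_present: bool
    y_present: bool
    verdict: str  # competent | non_competent | unalignable
    reasons: list[str] = field(default_factory=list)


def _ungapped_to_columns(row: str) -> list[int]:
    """Map 0-based ungapped positions of a row to alignment columns."""
    return [j for j, c in enumerate(row) if c != GAP]


def locate_copper_talon(
    msa: MultipleAlignment, reference_id: str, rule: CatalyticRule | None = None
) -> tuple[int, int, int, int]:
    """Alignment columns (0-based) of the four motif histidines, mapped from
    the reference row. Gap characters in the reference are transparent."""
    rule = rule or CatalyticRule()
    try:
        row = msa.row(reference_id)
    except ValueError:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    ungapped = row.replace(GAP, "")
    m = re.search(rule.motif_pattern, ungapped)
    if m is None:
        raise ValueError(
            f"reference {reference_id!r} does not contain the copper-talon motif"
        )
    colmap = _ungapped_to_columns(row)
    return tuple(colmap[m.start() + off - 1] for off in rule.h_offsets)


def locate_ltq_columns(
    msa: MultipleAlignment, reference_id: str, rule: CatalyticRule | None = None
) -> tuple[int, int, list[str]]:
    """Columns of the LTQ lysine and tyrosine, by the reference positions
    projected through the alignment. If the reference residue at a stated
    position is not K (resp. Y), the nearest matching residue within +/-3
    ungapped positions is used and the fallback is flagged."""
    rule = rule or CatalyticRule()
    row = msa.row(reference_id)
    ungapped = row.replace(GAP, "")
    colmap = _ungapped_to_columns(row)
    notes: list[str] = []

    def locate(pos1: int, residue: str, label: str) -> int:
        idx = pos1 - 1
        if 0 <= idx < len(ungapped) and ungapped[idx] == residue:
            return colmap[idx]
        for d in (1, -1, 2, -2, 3, -3):
            k = idx + d
            if 0 <= k < len(ungapped) and ungapped[k] == residue:
                notes.append(f"ltq_{label}_fallback_scan(offset {d:+d})")
                return colmap[k]
        raise ValueError(
            f"reference {reference_id!r} lacks {residue} near position {pos1}"
        )

    kcol = locate(rule.ltq_k_position, "K", "k")
    ycol = locate(rule.ltq_y_position, "Y", "y")
    return kcol, ycol, notes


def assess_sequence(
    protein_id: str,
    row: str,
    h_columns: tuple[int, int, int, int],
    k_column: int,
    y_column: int,
    rule: CatalyticRule | None = None,
) -> CatalyticAssessment:
    """Classify one aligned row. Competent iff the three core histidines and
    both LTQ residues are present; the dispensable histidine is reported only."""
    rule = rule or CatalyticRule()
    h_flags = tuple(row[c] == "H" for c in h_columns)
    k_present = row[k_column] == "K"
    y_present = row[y_column] == "Y"
    motif_span_cols = range(min(h_columns), max(h_columns) + 1)
    if all(row[c] == GAP for c in motif_span_cols):
        return CatalyticAssessment(
            protein_id, h_flags, k_present, y_present, "unalignable",
            ["motif region entirely gapped"],
        )
    core_ok = all(
        f for i, f in enumerate(h_flags) if i != rule.dispensable_index
    )
    reasons = []
    if not core_ok:
        reasons.append("lacks the histidine core")
    if not k_present:
        reasons.append("lacks the LTQ lysine")
    if not y_present:
        reasons.append("lacks the LTQ tyrosine")
    if not h_flags[rule.dispensable_index]:
        reasons.append("first (dispensable) histidine absent")
    verdict = "competent" if (core_ok and k_present and y_present) else "non_competent"
    return CatalyticAssessment(protein_id, h_flags, k_present, y_present, verdict, reasons)


def assess_alignment(
    msa: MultipleAlignment, reference_id: str, rule: CatalyticRule | None = None
) -> pd.DataFrame:
    """Assess every row of the alignment; returns a table with one row per
    sequence plus verdict counts in ``df.attrs['summary']``."""
    rule = rule or CatalyticRule()
    hcols = locate_copper_talon(msa, reference_id, rule)
    kcol, ycol, notes = locate_ltq_columns(msa, reference_id, rule)
    rows = []
    for rid, row in zip(msa.ids, msa.rows):
        a = assess_sequence(rid, row, hcols, kcol, ycol, rule)
        rows.append(
            {
                "protein": a.protein_id,
                "h1": a.h_flags[0], "h2": a.h_flags[1],
                "h3": a.h_flags[2], "h4": a.h_flags[3],
                "K": a.k_present, "Y": a.y_present,
                "verdict": a.verdict,
                "reasons": ";".join(a.reasons + notes),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["summary"] = df["verdict"].value_counts().to_dict()
    df.attrs["core_histidine_count"] = rule.min_core_histidines
    return df
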