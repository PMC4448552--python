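"""Sequence-feature heuristics and domain-architecture assembly.

Signal peptides, transmembrane helices and proline-rich stretches are
detected with documented rule-based stand-ins for the dedicated predictors a
production analysis would use (hydropathy windows and simple motifs). The
thresholds are conventions, exposed as keyword arguments with the defaults
below, and every output table carries the method name so nobody mistakes
them for SignalP/TMHMM probabilities.

Coordinates in FeatureRegion are 1-based inclusive (user-facing convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .profile_hmm import DomainHit

# Kyte & Doolittle (1982) hydropathy scale; X counts as neutral (0).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2, "X": 0.0,
}

TOKEN_MAP = {
    "signal_peptide": "SP",
    "tm_region": "TM",
    "proline_rich": "PRR",
    "propeptide": "PROPEP",
}


@dataclass
class FeatureRegion:
    kind: str  # signal_peptide | tm_region | proline_rich | propeptide
    start: int  # 1-based inclusive
    end: int
    score: float = 0.0

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad feature coordinates {self.start}-{self.end}")

    def overlap(self, other) -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DomainArchitecture:
    protein_id: str
    tokens: list[str]  # ordered N->C

    @property
    def canonical(self) -> str:
        return canonical_string(self.tokens)


def canonical_string(tokens: list[str]) -> str:
    """Join tokens N->C, collapsing runs of identical adjacent tokens to
    ``kxTOKEN`` (k >= 2)."""
    out = []
    i = 0
    while i < len(tokens):
        j = i
        while j < len(tokens) and tokens[j] == tokens[i]:
            j += 1
        k = j - i
        out.append(tokens[i] if k == 1 else f"{k}x{tokens[i]}")
        i = j
    return "+".join(out)


def _hydropathy(seq: str) -> np.ndarray:
    return np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in seq.upper()])


def _window_means(h: np.ndarray, w: int) -> np.ndarray:
    if len(h) < w:
        return np.empty(0)
    c = np.concatenate([[0.0], np.cumsum(h)])
    return (c[w:] - c[:-w]) / w


def detect_tm_helices(
    seq: str, window: int = 19, threshold: float = 1.6, min_length: int = 15
) -> list[FeatureRegion]:
    """Kyte-Doolittle window scan for transmembrane helices.

    Windows with mean hydropathy >= threshold are merged; a merged region is
    kept if it spans at least ``min_length`` residues. Score is the maximum
    window mean inside the region.
    """
    if len(seq) < window:
        return []
    means = _window_means(_hydropathy(seq), window)
    flagged = np.where(means >= threshold)[0]  # 0-based window starts
    regions: list[FeatureRegion] = []
    if flagged.size == 0:
        return regions
    runs = np.split(flagged, np.where(np.diff(flagged) > 1)[0] + 1)
    for run in runs:
        start = int(run[0]) + 1
        end = int(run[-1]) + window  # last window's final residue, 1-based
        if end - start + 1 >= min_length:
            regions.append(
                FeatureRegion("tm_region", start, end, float(means[run].max()))
            )
    return regions


# lookahead so overlapping motif occurrences are all considered
_CLEAVAGE = re.compile(r"(?=[AGSV].[AGS])")


def detect_signal_peptide(
    seq: str,
    h_window: int = 8,
    h_threshold: float = 2.0,
    h_start_max: int = 12,
    cleave_min: int = 15,
    cleave_max: int = 35,
) -> FeatureRegion | None:
    """Signal-peptide rule: an N-terminal hydrophobic window plus an
    A-x-A-type cleavage motif.

    Reports a signal peptide iff (a) some ``h_window``-residue window with
    mean KD >= ``h_threshold`` starts within residues 1..``h_start_max`` and
    (b) an [AGSV]-x-[AGS] motif ends within ``cleave_min``..``cleave_max``.
    The region runs from residue 1 to the motif's last residue.
    """
    if len(seq) < 25:
        return None
    means = _window_means(_hydropathy(seq), h_window)
    n_starts = min(h_start_max, len(means))
    if n_starts <= 0 or means[:n_starts].max() < h_threshold:
        return None
    for m in _CLEAVAGE.finditer(seq.upper()):
        last = m.start() + 3  # 1-based position of the motif's last residue
        if cleave_min <= last <= cleave_max:
            return FeatureRegion(
                "signal_peptide", 1, last, float(means[:n_starts].max())
            )
        if last > cleave_max:
            break
    return None


def detect_proline_rich(
    seq: str,
    excluded: list[FeatureRegion] | None = None,
    window: int = 25,
    min_fraction: float = 0.25,
) -> list[FeatureRegion]:
    """Sliding-window proline-fraction scan; overlapping flagged windows are
    merged and regions fully inside an excluded region are dropped."""
    s = seq.upper()
    if len(s) < window:
        return []
    is_p = np.array([1.0 if c == "P" else 0.0 for c in s])
    frac = _window_means(is_p, window)
    flagged = np.where(frac >= min_fraction)[0]
    if flagged.size == 0:
        return []
    regions = []
    runs = np.split(flagged, np.where(np.diff(flagged) > 1)[0] + 1)
    for run in runs:
        start = int(run[0]) + 1
        end = int(run[-1]) + window
        reg = FeatureRegion("proline_rich", start, end, float(frac[run].max()))
        contained = any(
            reg.start >= e.start and reg.end <= e.end for e in (excluded or [])
        )
        if not contained:
            regions.append(reg)
    return regions


def annotate_features(seq: str, hits: list[DomainHit] | None = None) -> list[FeatureRegion]:
    """Run all detectors on one protein; domain hits (if given) exclude
    proline-rich calls inside domains."""
    feats: list[FeatureRegion] = []
    sp = detect_signal_peptide(seq)
    if sp:
        feats.append(sp)
    # an N-terminal hydrophobic helix coinciding with the predicted signal
    # peptide is the signal peptide, not a membrane anchor
    feats.extend(
        t for t in detect_tm_helices(seq) if sp is None or t.overlap(sp) == 0
    )
    excluded = list(feats)
    for h in hits or []:
        excluded.append(FeatureRegion("proline_rich", h.start, h.end))
    excluded = [FeatureRegion(e.kind, e.start, e.end) for e in excluded]
    feats.extend(detect_proline_rich(seq, excluded))
    return sorted(feats, key=lambda f: (f.start, f.end))


def assemble_architecture(
    protein_id: str,
    seq_length: int,
    hits: list[DomainHit],
    features: list[FeatureRegion],
    propeptide_min_length: int = 50,
) -> DomainArchitecture:
    """Assemble the canonical N->C architecture string.

    The unannotated stretch between the last N-terminal feature (signal
    peptide or proline-rich region; residue 1 if neither) and the first
    domain hit is labeled propeptide iff it is at least
    ``propeptide_min_length`` residues and not proline-rich. A tm_region may
    overlap a domain hit; its token is placed after the overlapped token.
    """
    hits = sorted(hits, key=lambda h: (h.start, h.end))
    for a, b in zip(hits, hits[1:]):
        if a.overlap(b) > 10:
            raise ValueError(
                f"{protein_id}: overlapping domain hits {a.profile_id}/{b.profile_id} "
                "(scan_proteome contract violated)"
            )
    items: list[tuple[int, int, str]] = []  # (start, order, token)
    for h in hits:
        items.append((h.start, 1, h.profile_id.upper()))
    tm_overlapping = []
    for f in features:
        tok = TOKEN_MAP[f.kind]
        if f.kind == "tm_region" and any(
            f.overlap(FeatureRegion("x", h.start, h.end)) > 0 for h in hits
        ):
            # place after the overlapped domain token
            host = next(h for h in hits if f.overlap(FeatureRegion("x", h.start, h.end)) > 0)
            items.append((host.start, 2, tok))
            tm_overlapping.append(f)
        else:
            items.append((f.start, 1, tok))

    # propeptide rule
    if hits:
        first_domain_start = hits[0].start
        nterm_feats = [
            f
            for f in features
            if f.kind in ("signal_peptide", "proline_rich")
            and f.end < first_domain_start
        ]
        region_start = max((f.end for f in nterm_feats), default=0) + 1
        gap_len = first_domain_start - region_start
        if gap_len >= propeptide_min_length:
            gap = FeatureRegion("propeptide", region_start, first_domain_start - 1)
            prolinerich = any(
                f.kind == "proline_rich" and f.overlap(gap) > 0 for f in features
            )
            if not prolinerich:
                items.append((region_start, 1, "PROPEP"))
    items.sort(key=lambda t: (t[0], t[1]))
    return DomainArchitecture(protein_id=protein_id, tokens=[t[2] for t in items])


def annotate_proteome(records, hits: list[DomainHit]):
    """Annotate every protein; returns (features table, architectures table)."""
    import pandas as pd

    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    feat_rows, arch_rows = [], []
    for rec in records:
        phits = by_protein.get(rec.id, [])
        feats = annotate_features(rec.sequence, phits)
        for f in feats:
            feat_rows.append(
                {"protein": rec.id, "kind": f.kind, "start": f.start, "end": f.end,
                 "score": f.score}
            )
        arch = assemble_architecture(rec.id, len(rec.sequence), phits, feats)
        arch_rows.append({"protein": rec.id, "architecture": arch.canonical})
    return (
        pd.DataFrame(feat_rows, columns=["protein", "kind", "start", "end", "score"]),
        pd.DataFrame(arch_rows, columns=["protein", "architecture"]),
    )
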