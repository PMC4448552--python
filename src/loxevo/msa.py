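"""Progressive multiple alignment of protein domains.

A deliberately simple stand-in for a production aligner: Needleman-Wunsch
pairwise alignment with affine gaps, Kimura-corrected distances, a UPGMA
guide tree and profile-profile merging, with an optional round of
tree-bisection refinement. Output metadata states the divergence from
consistency-based aligners so downstream users are not misled.

Gap cost convention: a gap of length L costs ``gap_open + L * gap_extend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

_BLOSUM62 = None


def blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def score_pair(a: str, b: str, matrix=None) -> float:
    """Substitution score; unknown residues (X etc.) score 0 against anything."""
    m = matrix if matrix is not None else blosum62()
    if a not in m.alphabet or b not in m.alphabet or a == "X" or b == "X":
        return 0.0
    return float(m[a, b])


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows keyed by unique ids."""

    ids: list[str]
    rows: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate row ids: {dupes}")
        if self.rows:
            L = len(self.rows[0])
            for rid, row in zip(self.ids, self.rows):
                if len(row) != L:
                    raise ValueError(
                        f"ragged alignment: row {rid!r} has length {len(row)}, expected {L}"
                    )
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]

    def degapped(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def to_fasta(self) -> str:
        return "".join(f">{i}\n{r}\n" for i, r in zip(self.ids, self.rows))

    def subset(self, ids: list[str]) -> "MultipleAlignment":
        keep = [self.ids.index(i) for i in ids]
        return MultipleAlignment(ids=list(ids), rows=[self.rows[k] for k in keep])


# ---------------------------------------------------------------------------
# pairwise global alignment (affine gaps, Gotoh)
# ---------------------------------------------------------------------------


def pairwise_global(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[tuple[str, str], float]:
    """Optimal global alignment of two sequences.

    Returns ``((aligned_a, aligned_b), score)``. Ties in the traceback are
    broken match > delete (gap in b) > insert (gap in a).
    """
    if not a or not b:
        raise ValueError("pairwise_global requires nonempty sequences")
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    D = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    I = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        D[i, 0] = -gap_open - gap_extend * i
    for j in range(1, m + 1):
        I[0, j] = -gap_open - gap_extend * j
    sub = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            sub[i, j] = score_pair(a[i], b[j], matrix)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best_prev = max(M[i - 1, j - 1], D[i - 1, j - 1], I[i - 1, j - 1])
            M[i, j] = best_prev + sub[i - 1, j - 1]
            D[i, j] = max(M[i - 1, j] - gap_open - gap_extend, D[i - 1, j] - gap_extend)
            I[i, j] = max(M[i, j - 1] - gap_open - gap_extend, I[i, j - 1] - gap_extend)
    score = max(M[n, m], D[n, m], I[n, m])
    # traceback, tie preference M > D > I
    out_a, out_b = [], []
    i, j = n, m
    state = max(
        (("M", M[n, m]), ("D", D[n, m]), ("I", I[n, m])), key=lambda t: (t[1], -"MDI".index(t[0]))
    )[0]
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            best = max(M[i, j], D[i, j], I[i, j])
            for s in "MDI":
                if {"M": M, "D": D, "I": I}[s][i, j] >= best - 1e-9:
                    state = s
                    break
        elif state == "D":
            out_a.append(a[i - 1])
            out_b.append(GAP)
            from_m = M[i - 1, j] - gap_open - gap_extend
            from_d = D[i - 1, j] - gap_extend
            i -= 1
            state = "M" if from_m >= from_d - 1e-9 else "D"
        else:  # I
            out_a.append(GAP)
            out_b.append(b[j - 1])
            from_m = M[i, j - 1] - gap_open - gap_extend
            from_i = I[i, j - 1] - gap_extend
            j -= 1
            state = "M" if from_m >= from_i - 1e-9 else "I"
        if i == 0 and j == 0:
            break
        if i == 0 and state != "I":
            state = "I"
        if j == 0 and state != "D":
            state = "D"
    return (("".join(reversed(out_a)), "".join(reversed(out_b))), float(score))


# ---------------------------------------------------------------------------
# distances & guide tree
# ---------------------------------------------------------------------------


def fractional_difference(row_a: str, row_b: str) -> float:
    """Proportion of differing residues over columns where both rows have residues."""
    same = diff = 0
    for x, y in zip(row_a, row_b):
        if x == GAP or y == GAP:
            continue
        if x == y:
            same += 1
        else:
            diff += 1
    total = same + diff
    return diff / total if total else 0.0


def kimura_distance(p: float, cap: float = 0.85) -> float:
    """Kimura's (1983) correction for protein distances, capped for saturation."""
    p = min(p, cap)
    return -math.log(1.0 - p - p * p / 5.0)


# ---------------------------------------------------------------------------
# profile-profile alignment
# ---------------------------------------------------------------------------


def _profile_column_score(cols_a: list[str], cols_b: list[str], matrix) -> float:
    """Mean pairwise substitution score between two alignment columns.

    Residue-vs-gap pairs contribute 0; the mean is over all cross pairs so
    gappy columns are softly down-weighted.
    """
    total = 0.0
    n = 0
    for x in cols_a:
        for y in cols_b:
            n += 1
            if x == GAP or y == GAP:
                continue
            total += score_pair(x, y, matrix)
    return total / n if n else 0.0


def _align_profiles(
    A: MultipleAlignment,
    B: MultipleAlignment,
    matrix,
    gap_open: float,
    gap_extend: float,
) -> MultipleAlignment:
    na, nb = A.n_cols, B.n_cols
    colsA = [A.column(j) for j in range(na)]
    colsB = [B.column(j) for j in range(nb)]
    NEG = -1e30
    M = np.full((na + 1, nb + 1), NEG)
    D = np.full((na + 1, nb + 1), NEG)
    I = np.full((na + 1, nb + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, na + 1):
        D[i, 0] = -gap_open - gap_extend * i
    for j in range(1, nb + 1):
        I[0, j] = -gap_open - gap_extend * j
    S = np.zeros((na, nb))
    for i in range(na):
        for j in range(nb):
            S[i, j] = _profile_column_score(colsA[i], colsB[j], matrix)
    ptrM = np.zeros((na + 1, nb + 1), dtype=np.int8)
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            cands = (M[i - 1, j - 1], D[i - 1, j - 1], I[i - 1, j - 1])
            k = int(np.argmax(cands))
            M[i, j] = cands[k] + S[i - 1, j - 1]
            ptrM[i, j] = k
            D[i, j] = max(M[i - 1, j] - gap_open - gap_extend, D[i - 1, j] - gap_extend)
            I[i, j] = max(M[i, j - 1] - gap_open - gap_extend, I[i, j - 1] - gap_extend)
    i, j = na, nb
    state = ["M", "D", "I"][int(np.argmax((M[i, j], D[i, j], I[i, j])))]
    colpairs = []  # (idx_a or None, idx_b or None)
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            colpairs.append((i - 1, j - 1))
            k = ptrM[i, j]
            i, j = i - 1, j - 1
            state = ["M", "D", "I"][k]
        elif state == "D" and i > 0:
            colpairs.append((i - 1, None))
            from_m = M[i - 1, j] - gap_open - gap_extend
            from_d = D[i - 1, j] - gap_extend
            i -= 1
            state = "M" if from_m >= from_d else "D"
        elif state == "I" and j > 0:
            colpairs.append((None, j - 1))
            from_m = M[i, j - 1] - gap_open - gap_extend
            from_i = I[i, j - 1] - gap_extend
            j -= 1
            state = "M" if from_m >= from_i else "I"
        elif i > 0:
            state = "D"
        else:
            state = "I"
    colpairs.reverse()
    new_rows_a = ["" for _ in A.rows]
    new_rows_b = ["" for _ in B.rows]
    for ia, ib in colpairs:
        ca = colsA[ia] if ia is not None else GAP * A.n_rows
        cb = colsB[ib] if ib is not None else GAP * B.n_rows
        for r in range(A.n_rows):
            new_rows_a[r] += ca[r]
        for r in range(B.n_rows):
            new_rows_b[r] += cb[r]
    return MultipleAlignment(ids=A.ids + B.ids, rows=new_rows_a + new_rows_b)


def sum_of_pairs_score(
    msa: MultipleAlignment, matrix=None, gap_open: float = 10.0, gap_extend: float = 0.5
) -> float:
    """Affine sum-of-pairs score of an alignment (used by the refiner)."""
    total = 0.0
    m = matrix if matrix is not None else blosum62()
    for i in range(msa.n_rows):
        for j in range(i + 1, msa.n_rows):
            a, b = msa.rows[i], msa.rows[j]
            in_gap = None
            for x, y in zip(a, b):
                if x == GAP and y == GAP:
                    continue
                if x == GAP or y == GAP:
                    which = "a" if x == GAP else "b"
                    if in_gap == which:
                        total -= gap_extend
                    else:
                        total -= gap_open + gap_extend
                    in_gap = which
                else:
                    total += score_pair(x, y, m)
                    in_gap = None
    return total


# ---------------------------------------------------------------------------
# progressive alignment
# ---------------------------------------------------------------------------


def progressive_align(
    sequences: dict[str, str] | list[tuple[str, str]],
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    refine: bool = False,
) -> MultipleAlignment:
    """Progressive alignment: NW distances -> UPGMA guide tree -> profile merge.

    Input order is canonicalized (sorted by id) so the result does not depend
    on the order sequences are supplied in.
    """
    if isinstance(sequences, dict):
        items = sorted(sequences.items())
    else:
        items = sorted(sequences)
    ids = [i for i, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if len(items) < 2:
        raise ValueError("progressive_align requires >= 2 sequences")
    seqs = {i: s.upper() for i, s in items}
    n = len(ids)
    m = matrix if matrix is not None else blosum62()

    # pairwise Kimura-corrected distances
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            (ra, rb), _ = pairwise_global(seqs[ids[i]], seqs[ids[j]], m, gap_open, gap_extend)
            D[i, j] = D[j, i] = kimura_distance(fractional_difference(ra, rb))

    # UPGMA guide tree via scipy average linkage
    profiles: dict[int, MultipleAlignment] = {
        k: MultipleAlignment(ids=[ids[k]], rows=[seqs[ids[k]]]) for k in range(n)
    }
    if n == 2:
        msa = _align_profiles(profiles[0], profiles[1], m, gap_open, gap_extend)
    else:
        Z = linkage(squareform(D, checks=False), method="average")
        for step, (a, b, _, _) in enumerate(Z):
            merged = _align_profiles(
                profiles.pop(int(a)), profiles.pop(int(b)), m, gap_open, gap_extend
            )
            profiles[n + step] = merged
        msa = profiles[max(profiles)]
    # restore canonical row order
    order = sorted(range(msa.n_rows), key=lambda k: msa.ids[k])
    msa = MultipleAlignment(ids=[msa.ids[k] for k in order], rows=[msa.rows[k] for k in order])

    if refine:
        msa = _refine_once(msa, m, gap_open, gap_extend)
    msa.meta["aligner"] = (
        "loxevo progressive (UPGMA guide, profile NW, affine gaps); "
        "not a consistency-based aligner"
    )
    # de-gapping invariance guard
    for rid in msa.ids:
        if msa.degapped(rid) != seqs[rid]:
            raise AssertionError(f"aligner corrupted sequence {rid}")
    return msa


def _strip_all_gap_columns(msa: MultipleAlignment) -> MultipleAlignment:
    keep = [j for j in range(msa.n_cols) if any(r[j] != GAP for r in msa.rows)]
    return MultipleAlignment(
        ids=list(msa.ids), rows=["".join(r[j] for j in keep) for r in msa.rows]
    )


def _refine_once(msa, matrix, gap_open, gap_extend) -> MultipleAlignment:
    """One leave-one-out refinement pass: realign each row to the rest,
    keeping changes that improve the sum-of-pairs score."""
    best = msa
    best_sp = sum_of_pairs_score(msa, matrix, gap_open, gap_extend)
    for rid in list(msa.ids):
        rest_ids = [i for i in best.ids if i != rid]
        rest = _strip_all_gap_columns(best.subset(rest_ids))
        single = MultipleAlignment(ids=[rid], rows=[best.degapped(rid)])
        cand = _align_profiles(rest, single, matrix, gap_open, gap_extend)
        order = sorted(range(cand.n_rows), key=lambda k: cand.ids[k])
        cand = MultipleAlignment(
            ids=[cand.ids[k] for k in order], rows=[cand.rows[k] for k in order]
        )
        sp = sum_of_pairs_score(cand, matrix, gap_open, gap_extend)
        if sp > best_sp + 1e-9:
            best, best_sp = cand, sp
    return best


def alignment_stats(msa: MultipleAlignment) -> tuple[int, int, float]:
    """(n_sequences, n_columns, mean pairwise identity ignoring gapped pairs)."""
    idents = []
    for i in range(msa.n_rows):
        for j in range(i + 1, msa.n_rows):
            idents.append(1.0 - fractional_difference(msa.rows[i], msa.rows[j]))
    mean_id = float(np.mean(idents)) if idents else 1.0
    return (msa.n_rows, msa.n_cols, mean_id)
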