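"""Reciprocal-hit similarity network for horizontal-gene-transfer screening.

All-vs-all Smith-Waterman local alignment with affine gaps stands in for a
BLAST search; Karlin-Altschul statistics turn raw scores into bit scores and
E-values. Two proteins are connected when each hits the other below the
E-value threshold (any-hit reciprocity by default; a best-hit mode is
available for sensitivity analysis). Connected components that mix
top-level clades (e.g. Bacteria and Archaea) are the HGT signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .msa import blosum62, score_pair

# gapped BLOSUM62 (open 11 / extend 1) convention
LAMBDA_DEFAULT = 0.267
K_DEFAULT = 0.041


@dataclass
class LocalHit:
    query_id: str
    subject_id: str
    raw_score: float
    bits: float = math.nan
    evalue: float = math.nan
    query_span: tuple[int, int] = (0, 0)  # 1-based inclusive; (0,0) = empty
    subject_span: tuple[int, int] = (0, 0)

    def __post_init__(self):
        if self.raw_score < 0:
            raise ValueError("local score cannot be negative")


def smith_waterman(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> LocalHit:
    """Optimal local alignment score with affine gaps (gap of length L costs
    open + L*extend). Traceback starts from the highest-scoring cell
    (leftmost in row-major order on ties)."""
    if not a or not b:
        raise ValueError("smith_waterman requires nonempty sequences")
    a, b = a.upper(), b.upper()
    m = matrix if matrix is not None else blosum62()
    n1, n2 = len(a), len(b)
    sub = np.zeros((n1, n2))
    for i in range(n1):
        for j in range(n2):
            sub[i, j] = score_pair(a[i], b[j], m)
    H = np.zeros((n1 + 1, n2 + 1))
    E = np.full((n1 + 1, n2 + 1), -1e30)  # gap in a (consumes b)
    F = np.full((n1 + 1, n2 + 1), -1e30)  # gap in b (consumes a)
    for i in range(1, n1 + 1):
        F[i] = np.maximum(H[i - 1] - gap_open - gap_extend, F[i - 1] - gap_extend)
        # E within-row: E[i,j] = max(H[i,j-1]-open-ext, E[i,j-1]-ext)
        row_h = np.empty(n2 + 1)
        row_h[0] = 0.0
        e = -1e30
        for j in range(1, n2 + 1):
            e = max(row_h[j - 1] - gap_open - gap_extend, e - gap_extend)
            E[i, j] = e
            h = max(0.0, H[i - 1, j - 1] + sub[i - 1, j - 1], e, F[i, j])
            row_h[j] = h
        H[i, 1:] = row_h[1:]
    best = float(H.max())
    if best <= 0:
        return LocalHit(query_id="", subject_id="", raw_score=0.0)
    flat = int(np.argmax(H))  # row-major: smallest i then j on ties
    bi, bj = divmod(flat, n2 + 1)
    # traceback
    qi, qj = bi, bj
    state = "H"
    i, j = bi, bj
    while i > 0 and j > 0 and H[i, j] > 0:
        if abs(H[i, j] - (H[i - 1, j - 1] + sub[i - 1, j - 1])) < 1e-9:
            i, j = i - 1, j - 1
        elif abs(H[i, j] - E[i, j]) < 1e-9:
            while j > 0 and abs(E[i, j] - (E[i, j - 1] - gap_extend)) < 1e-9 and not (
                abs(E[i, j] - (H[i, j - 1] - gap_open - gap_extend)) < 1e-9
            ):
                j -= 1
            j -= 1
        elif abs(H[i, j] - F[i, j]) < 1e-9:
            while i > 0 and abs(F[i, j] - (F[i - 1, j] - gap_extend)) < 1e-9 and not (
                abs(F[i, j] - (H[i - 1, j] - gap_open - gap_extend)) < 1e-9
            ):
                i -= 1
            i -= 1
        else:
            break
    return LocalHit(
        query_id="",
        subject_id="",
        raw_score=best,
        query_span=(i + 1, bi),
        subject_span=(j + 1, bj),
    )


def evalue_ka(
    raw_score: float,
    m: int,
    n: int,
    lam: float = LAMBDA_DEFAULT,
    K: float = K_DEFAULT,
) -> tuple[float, float]:
    """Karlin-Altschul statistics: bits = (lambda*S - ln K)/ln 2,
    E = m*n*2^(-bits)."""
    if lam <= 0 or K <= 0:
        raise ValueError("lambda and K must be positive")
    bits = (lam * raw_score - math.log(K)) / math.log(2.0)
    evalue = m * n * 2.0 ** (-bits)
    return bits, evalue


def reciprocal_network(
    proteins,
    evalue_threshold: float = 1e-10,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    lam: float = LAMBDA_DEFAULT,
    K: float = K_DEFAULT,
    best_hit: bool = False,
    database_size: int | None = None,
) -> nx.Graph:
    """All-vs-all reciprocal-hit graph.

    A directional hit query->subject uses m = len(query) and n = total
    residue count of the database searched (all proteins, unless
    ``database_size`` overrides it), the usual database-search semantics —
    so the two directions of a pair differ when the two query lengths
    differ. An undirected edge requires both directions to pass; with
    ``best_hit=True`` each endpoint must additionally be the other's
    best-scoring partner. Edge attribute ``evalue`` is the worse (max) of
    the two directional E-values.
    """
    proteins = sorted(proteins, key=lambda r: r.id)  # order-independence
    if len(proteins) < 2:
        raise ValueError("need >= 2 proteins")
    if evalue_threshold <= 0:
        raise ValueError("E-value threshold must be > 0")
    G = nx.Graph(
        mode="best-hit" if best_hit else "any-hit",
        evalue_threshold=evalue_threshold,
    )
    for rec in proteins:
        G.add_node(rec.id, taxon=rec.taxon, clade=rec.clade)
    n_rec = len(proteins)
    n_db = database_size or sum(len(r.sequence) for r in proteins)
    escore: dict[tuple[str, str], float] = {}
    raw: dict[tuple[str, str], float] = {}
    for i in range(n_rec):
        for j in range(i + 1, n_rec):
            a, b = proteins[i], proteins[j]
            hit = smith_waterman(a.sequence, b.sequence, matrix, gap_open, gap_extend)
            raw[(a.id, b.id)] = hit.raw_score
            _, e_ab = evalue_ka(hit.raw_score, len(a.sequence), n_db, lam, K)
            _, e_ba = evalue_ka(hit.raw_score, len(b.sequence), n_db, lam, K)
            escore[(a.id, b.id)] = e_ab
            escore[(b.id, a.id)] = e_ba
    best_partner: dict[str, str] = {}
    if best_hit:
        for rec in proteins:
            partners = [
                (raw[tuple(sorted((rec.id, o.id)))], o.id)
                for o in proteins
                if o.id != rec.id
            ]
            best_partner[rec.id] = max(partners)[1]
    for i in range(n_rec):
        for j in range(i + 1, n_rec):
            a, b = proteins[i].id, proteins[j].id
            if escore[(a, b)] <= evalue_threshold and escore[(b, a)] <= evalue_threshold:
                if best_hit and not (
                    best_partner[a] == b and best_partner[b] == a
                ):
                    continue
                G.add_edge(a, b, evalue=max(escore[(a, b)], escore[(b, a)]))
    return G


def components_and_clusters(G: nx.Graph) -> pd.DataFrame:
    """Connected components with per-component clade composition and a
    mixed-clade flag (>1 top-level clade: the HGT signal)."""
    rows = []
    for k, comp in enumerate(sorted(nx.connected_components(G), key=lambda c: sorted(c))):
        clades = sorted({G.nodes[n].get("clade", "") for n in comp} - {""})
        rows.append(
            {
                "component": k,
                "n_members": len(comp),
                "members": ",".join(sorted(comp)),
                "clades": ",".join(clades),
                "mixed_clades": len(clades) > 1,
            }
        )
    return pd.DataFrame(
        rows, columns=["component", "n_members", "members", "clades", "mixed_clades"]
    )


def write_graphml(G: nx.Graph, path) -> None:
    nx.write_graphml(G, path)
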