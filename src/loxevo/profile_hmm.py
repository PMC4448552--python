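"""Profile hidden Markov models for protein-domain retrieval.

A small Plan7-flavoured profile HMM: match/insert/delete core states built
from a seed alignment (Henikoff position-based weights, Laplace pseudocounts
mixed with background), local alignment with uniform entry/exit over match
columns, Viterbi for locating hits and the forward algorithm for total
log-odds. Multi-domain proteins are handled by recursive best-hit extraction
followed by a greedy non-overlapping decomposition, not by a multi-hit state
loop.

Scores are bits: log2 odds of the aligned subsequence under the profile
versus an i.i.d. background; unaligned flanking residues cancel. ``X``
residues emit at background (log-odds 0) everywhere, i.e. missing data.

E-values come from an empirical Gumbel null (seeded, method of moments on
forward scores of background-sampled sequences), not Karlin-Altschul
constants, because profiles here are user-supplied toys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .msa import GAP, MultipleAlignment

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA20)}
# Robinson & Robinson (1991) amino-acid background frequencies
BACKGROUND = np.array(
    [
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199, 0.05142,
        0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264, 0.05129, 0.07120,
        0.05841, 0.06441, 0.01330, 0.03216,
    ]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()

NEG = -1e30
EULER_GAMMA = 0.5772156649015329


def encode(seq: str) -> np.ndarray:
    """Residues to indices; X (or anything unknown) -> -1 (missing)."""
    return np.array([AA_INDEX.get(c, -1) for c in seq.upper()], dtype=np.int64)


@dataclass
class DomainHit:
    """A located domain match (envelope coordinates 1-based inclusive)."""

    protein_id: str
    profile_id: str
    start: int
    end: int
    bits: float
    evalue: float = math.nan
    alignment_map: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("hit start > end")
        if not math.isfinite(self.bits):
            raise ValueError("non-finite bit score")

    def overlap(self, other: "DomainHit") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class ProfileHMM:
    profile_id: str
    match_em: np.ndarray  # (L, 20) probabilities
    background: np.ndarray  # (20,)
    t: dict  # keys MM, MI, MD, IM, II, DM, DD -> (L,) arrays

    def __post_init__(self):
        L = self.match_em.shape[0]
        if L < 2:
            raise ValueError("profile needs >= 2 match columns")
        if not np.allclose(self.match_em.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emissions must sum to 1")
        if not np.allclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        for src, keys in (("M", ("MM", "MI", "MD")), ("I", ("IM", "II")), ("D", ("DM", "DD"))):
            total = sum(self.t[k] for k in keys)
            if not np.allclose(total, 1.0, atol=1e-9):
                raise ValueError(f"outgoing transitions from {src} must sum to 1")

    @property
    def L(self) -> int:
        return self.match_em.shape[0]

    def log_odds(self) -> np.ndarray:
        """(L, 20) log2(match emission / background)."""
        return np.log2(self.match_em / self.background[None, :])

    def consensus(self) -> str:
        return "".join(AA20[k] for k in np.argmax(self.match_em, axis=1))

    # -- serialization (documented TSV-based text format) ------------------
    def to_text(self) -> str:
        lines = [
            "# loxevo profile HMM v1",
            f"profile_id\t{self.profile_id}",
            f"L\t{self.L}",
            "alphabet\t" + AA20,
            "background\t" + "\t".join(f"{x:.10g}" for x in self.background),
            "match_emissions",
        ]
        for j in range(self.L):
            lines.append("\t".join(f"{x:.10g}" for x in self.match_em[j]))
        lines.append("transitions\t" + "\t".join(sorted(self.t)))
        for j in range(self.L):
            lines.append("\t".join(f"{self.t[k][j]:.10g}" for k in sorted(self.t)))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ProfileHMM":
        lines = [l for l in text.splitlines() if l and not l.startswith("#")]
        meta = {}
        i = 0
        while not lines[i].startswith("match_emissions"):
            k, _, v = lines[i].partition("\t")
            meta[k] = v
            i += 1
        L = int(meta["L"])
        bg = np.array([float(x) for x in meta["background"].split("\t")])
        i += 1
        em = np.array([[float(x) for x in lines[i + j].split("\t")] for j in range(L)])
        i += L
        keys = lines[i].split("\t")[1:]
        i += 1
        tmat = np.array([[float(x) for x in lines[i + j].split("\t")] for j in range(L)])
        t = {k: tmat[:, c].copy() for c, k in enumerate(keys)}
        return cls(profile_id=meta["profile_id"], match_em=em, background=bg, t=t)


# ---------------------------------------------------------------------------
# building
# ---------------------------------------------------------------------------


def henikoff_weights(msa: MultipleAlignment) -> np.ndarray:
    """Henikoff & Henikoff (1994) position-based sequence weights, mean 1."""
    n = msa.n_rows
    w = np.zeros(n)
    for j in range(msa.n_cols):
        col = msa.column(j)
        counts: dict[str, int] = {}
        for c in col:
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        r = len(counts)
        if r == 0:
            continue
        for i, c in enumerate(col):
            if c != GAP:
                w[i] += 1.0 / (r * counts[c])
    if w.sum() == 0:
        return np.ones(n)
    return w * n / w.sum()


def build_profile(
    seed: MultipleAlignment,
    pseudocount_weight: float = 1.0,
    profile_id: str = "profile",
    background: np.ndarray | None = None,
    max_gap_fraction: float = 0.5,
) -> ProfileHMM:
    """Build a profile HMM from a seed alignment.

    Columns with gap fraction < ``max_gap_fraction`` become match columns.
    Weighted residue counts are mixed with ``pseudocount_weight * background``
    and normalized; transitions get a flat pseudocount of
    ``pseudocount_weight`` split uniformly over the allowed targets.
    """
    if seed.n_rows < 2:
        raise ValueError("seed alignment needs >= 2 sequences")
    bg = BACKGROUND if background is None else np.asarray(background, dtype=float)
    n, C = seed.n_rows, seed.n_cols
    gapfrac = np.array(
        [sum(1 for c in seed.column(j) if c == GAP) / n for j in range(C)]
    )
    match_cols = [j for j in range(C) if gapfrac[j] < max_gap_fraction]
    L = len(match_cols)
    if L < 2:
        raise ValueError("no match columns: seed alignment is too gappy")
    w = henikoff_weights(seed)

    em = np.zeros((L, 20))
    for mj, j in enumerate(match_cols):
        for i, c in enumerate(seed.column(j)):
            k = AA_INDEX.get(c)
            if k is not None:  # gaps and X carry no emission count
                em[mj, k] += w[i]
    em = em + pseudocount_weight * bg[None, :]
    em = em / em.sum(axis=1, keepdims=True)

    # transition counts from each sequence's match/insert/delete path
    is_match = np.zeros(C, dtype=bool)
    is_match[match_cols] = True
    keys = ("MM", "MI", "MD", "IM", "II", "DM", "DD")
    counts = {k: np.zeros(L) for k in keys}
    for i, row in enumerate(seed.rows):
        # state sequence between consecutive match columns
        prev_state, prev_col = "M", -1  # begin treated as match column -1
        for j in range(C):
            if is_match[j]:
                mj = match_cols.index(j)
                state = "M" if row[j] != GAP else "D"
                if prev_col >= 0:
                    counts[prev_state + state][prev_col] += w[i]
                prev_state, prev_col = state, mj
            elif row[j] != GAP:
                if prev_col >= 0:
                    counts[prev_state + "I"][prev_col] += w[i]
                prev_state = "I"
                # insert loops stay at prev_col
    t = {}
    groups = {"M": ("MM", "MI", "MD"), "I": ("IM", "II"), "D": ("DM", "DD")}
    for src, ks in groups.items():
        tot = sum(counts[k] for k in ks) + pseudocount_weight
        for k in ks:
            t[k] = (counts[k] + pseudocount_weight / len(ks)) / tot
    return ProfileHMM(profile_id=profile_id, match_em=em, background=bg, t=t)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _log2_safe(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(x > 0, np.log2(np.maximum(x, 1e-300)), NEG)


def _dp_tables(profile: ProfileHMM, seq: str, mode: str):
    """Fill local-alignment DP tables (Viterbi max or forward logsumexp).

    Returns (VM, VI, VD) with shape (n, L), scores in bits for paths whose
    last emission is sequence position i (0-based) in the given state at
    profile column j.
    """
    x = encode(seq)
    n, L = len(x), profile.L
    lo = profile.log_odds()
    # per-position emission log-odds row (X -> 0)
    lt = {k: _log2_safe(v) for k, v in profile.t.items()}
    entry = -math.log2(L)
    lMM, lIM, lDM = lt["MM"], lt["IM"], lt["DM"]
    lMI, lII = lt["MI"], lt["II"]
    lMD, lDD = lt["MD"], lt["DD"]
    VM = np.full((n, L), NEG)
    VI = np.full((n, L), NEG)
    VD = np.full((n, L), NEG)
    if mode == "max":
        combine = lambda *arrs: np.maximum.reduce(arrs)
        accum = np.maximum.accumulate
    else:
        def combine(*arrs):
            out = arrs[0]
            for a in arrs[1:]:
                out = np.logaddexp2(out, a)
            return out

        accum = np.logaddexp2.accumulate
    # prefix sums of lDD for the within-row delete chain
    cDD = np.concatenate([[0.0], np.cumsum(lDD[:-1])])  # cDD[j] = sum lDD[:j] over cols < j
    for i in range(n):
        erow = lo[:, x[i]] if x[i] >= 0 else np.zeros(L)
        if i == 0:
            VM[i] = erow + entry
        else:
            shift = lambda a: np.concatenate([[NEG], a[:-1]])
            prev = combine(
                np.full(L, entry),
                shift(VM[i - 1] + lMM),
                shift(VI[i - 1] + lIM),
                shift(VD[i - 1] + lDM),
            )
            VM[i] = erow + prev
            VI[i] = combine(VM[i - 1] + lMI, VI[i - 1] + lII)
        # within-row deletes: VD[i,j] = combine over k<j of VM[i,k]+lMD[k]+sum(lDD[k+1..j-1])
        g = VM[i] + lMD - np.concatenate([cDD[1:], [cDD[-1] + lDD[-1]]])
        run = accum(g)
        VD[i, 1:] = run[:-1] + cDD[1:]
        VD[i, 0] = NEG
    return VM, VI, VD, x


def forward_score(profile: ProfileHMM, seq: str) -> float:
    """Total local log-odds in bits, summed over all paths, starts and ends."""
    if not seq:
        raise ValueError("empty sequence")
    VM, VI, VD, _ = _dp_tables(profile, seq, mode="sum")
    exit_ = -math.log2(profile.L)
    total = float(np.logaddexp2.reduce((VM + exit_).ravel()))
    return total


def viterbi_scan(profile: ProfileHMM, seq: str) -> DomainHit | None:
    """Best-scoring local hit (or None if nothing scores above 0 bits).

    Tie-break: among equal-scoring end cells the smallest sequence position,
    then the smallest profile column; the traceback prefers continuing the
    match (leftmost, i.e. longest leftward, envelope) over re-entry.
    """
    if not seq:
        raise ValueError("empty sequence")
    VM, VI, VD, x = _dp_tables(profile, seq, mode="max")
    L = profile.L
    exit_ = -math.log2(L)
    entry = -math.log2(L)
    score_mat = VM + exit_
    best = float(score_mat.max())
    if best <= 0.0:
        return None
    # end-cell tie-break: smallest i then smallest j
    flat = np.argwhere(score_mat >= best - 1e-12)
    i, j = int(flat[0][0]), int(flat[0][1])
    lo = profile.log_odds()
    lt = {k: _log2_safe(v) for k, v in profile.t.items()}
    amap = []
    state = "M"
    start_i = i
    tol = 1e-9
    while True:
        if state == "M":
            amap.append((i + 1, j + 1))
            start_i = i
            erow = lo[j, x[i]] if x[i] >= 0 else 0.0
            target = VM[i, j] - erow
            if i == 0 or j == 0:
                break  # must be entry
            if abs(target - entry) < tol and not (
                abs(VM[i - 1, j - 1] + lt["MM"][j - 1] - target) < tol
                or abs(VI[i - 1, j - 1] + lt["IM"][j - 1] - target) < tol
                or abs(VD[i - 1, j - 1] + lt["DM"][j - 1] - target) < tol
            ):
                break
            if abs(VM[i - 1, j - 1] + lt["MM"][j - 1] - target) < tol:
                i, j, state = i - 1, j - 1, "M"
            elif abs(VD[i - 1, j - 1] + lt["DM"][j - 1] - target) < tol:
                i, j, state = i - 1, j - 1, "D"
            elif abs(VI[i - 1, j - 1] + lt["IM"][j - 1] - target) < tol:
                i, j, state = i - 1, j - 1, "I"
            else:
                break  # entry
        elif state == "D":
            target = VD[i, j]
            if abs(VM[i, j - 1] + lt["MD"][j - 1] - target) < tol:
                j, state = j - 1, "M"
            else:
                j, state = j - 1, "D"
        else:  # I
            target = VI[i, j]
            start_i = i
            if i == 0:
                break
            if abs(VM[i - 1, j] + lt["MI"][j] - target) < tol:
                i, state = i - 1, "M"
            else:
                i, state = i - 1, "I"
    amap.reverse()
    env_start = amap[0][0]
    env_end = amap[-1][0]
    return DomainHit(
        protein_id="",
        profile_id=profile.profile_id,
        start=env_start,
        end=env_end,
        bits=best,
        alignment_map=amap,
    )


# ---------------------------------------------------------------------------
# E-values
# ---------------------------------------------------------------------------


@dataclass
class GumbelNull:
    mu: float
    beta: float
    length: int

    def exceedance(self, s: float) -> float:
        z = (s - self.mu) / self.beta
        # survival of the Gumbel law, numerically safe
        return -math.expm1(-math.exp(-z)) if z > -30 else 1.0


def calibrate_null(
    profile: ProfileHMM,
    null_sample_size: int = 200,
    length: int = 150,
    seed: int = 0,
) -> GumbelNull:
    """Fit a Gumbel law (method of moments) to forward scores of i.i.d.
    background sequences of the given length."""
    if null_sample_size < 100:
        raise ValueError("null_sample_size must be >= 100")
    rng = np.random.default_rng(seed)
    scores = np.empty(null_sample_size)
    for k in range(null_sample_size):
        idx = rng.choice(20, size=length, p=profile.background)
        s = "".join(AA20[i] for i in idx)
        scores[k] = forward_score(profile, s)
    var = float(np.var(scores))
    if var <= 0:
        raise ValueError("degenerate null distribution (zero variance)")
    beta = math.sqrt(6.0 * var) / math.pi
    mu = float(np.mean(scores)) - EULER_GAMMA * beta
    return GumbelNull(mu=mu, beta=beta, length=length)


def estimate_evalue(
    profile: ProfileHMM,
    score_bits: float,
    database_size: int,
    null_sample_size: int = 200,
    seed: int = 0,
    null_length: int = 150,
    null: GumbelNull | None = None,
) -> float:
    """E = database_size x P(S > score) under the fitted Gumbel null."""
    if null is None:
        null = calibrate_null(profile, null_sample_size, null_length, seed)
    return database_size * null.exceedance(score_bits)


# ---------------------------------------------------------------------------
# proteome scanning
# ---------------------------------------------------------------------------


def _extract_hits(profile, seq, offset, min_bits, depth=0) -> list[DomainHit]:
    """Recursive best-hit extraction: find the Viterbi hit, then recurse into
    the flanks left and right of its envelope."""
    if len(seq) < 5 or depth > 12:
        return []
    hit = viterbi_scan(profile, seq)
    if hit is None or hit.bits < min_bits:
        return []
    shifted = DomainHit(
        protein_id=hit.protein_id,
        profile_id=hit.profile_id,
        start=hit.start + offset,
        end=hit.end + offset,
        bits=hit.bits,
        alignment_map=[(p + offset, c) for p, c in hit.alignment_map],
    )
    out = [shifted]
    out += _extract_hits(profile, seq[: hit.start - 1], offset, min_bits, depth + 1)
    out += _extract_hits(profile, seq[hit.end :], offset + hit.end, min_bits, depth + 1)
    return out


def scan_proteome(
    profiles: list[ProfileHMM],
    proteins,
    inclusion_evalue: float = 1e-5,
    seed: int = 0,
    null_sample_size: int = 200,
    max_overlap: int = 10,
    nulls: dict[str, GumbelNull] | None = None,
) -> list[DomainHit]:
    """Scan proteins with all profiles; greedy non-overlapping decomposition.

    Hits are accepted in decreasing bit-score order; a hit overlapping an
    accepted one by more than ``max_overlap`` residues is dropped. All
    accepted hits satisfy E <= inclusion_evalue, where the search space of
    the Gumbel null is rescaled to each protein's length.
    """
    if inclusion_evalue <= 0:
        raise ValueError("inclusion_evalue must be > 0")
    proteins = list(proteins)
    db_size = len(proteins)
    if nulls is None:
        nulls = {}
    for k, prof in enumerate(profiles):
        if prof.profile_id not in nulls:
            nulls[prof.profile_id] = calibrate_null(
                prof, null_sample_size=null_sample_size, seed=seed + 7919 * k
            )
    results: list[DomainHit] = []
    for rec in proteins:
        candidates: list[DomainHit] = []
        for prof in profiles:
            null = nulls[prof.profile_id]
            raw = _extract_hits(prof, rec.sequence, 0, min_bits=1.0)
            for h in raw:
                scale = max(len(rec.sequence), 1) / null.length
                ev = db_size * scale * null.exceedance(h.bits)
                if ev <= inclusion_evalue:
                    h.protein_id = rec.id
                    h.evalue = ev
                    candidates.append(h)
        candidates.sort(key=lambda h: (-h.bits, h.start, h.end - h.start))
        accepted: list[DomainHit] = []
        for h in candidates:
            if all(h.overlap(a) <= max_overlap for a in accepted):
                accepted.append(h)
        accepted.sort(key=lambda h: h.start)
        results.extend(accepted)
    return results


def hits_to_frame(hits: list[DomainHit]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "protein": h.protein_id,
                "profile": h.profile_id,
                "start": h.start,
                "end": h.end,
                "bits": h.bits,
                "evalue": h.evalue,
            }
            for h in hits
        ],
        columns=["protein", "profile", "start", "end", "bits", "evalue"],
    )
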