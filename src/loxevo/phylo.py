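"""Maximum-likelihood protein phylogenetics.

Implements the standard machinery: empirical rate matrices (WAG, LG, JTT;
Poisson for testing), discrete-gamma among-site rate variation (4 categories,
mean-of-quantile discretization), a proportion of invariable sites, +F
empirical frequencies, Felsenstein pruning, neighbor joining, per-branch
length optimization, NNI hill-climbing with optional multi-start, AIC model
selection on a fixed topology, and nonparametric bootstrap supports.

Likelihoods are for the unrooted tree (reversible models); trees are stored
arbitrarily rooted. Gaps and X are missing data (unit partial likelihoods).
"""

from __future__ import annotations

import importlib.resources as resources
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .msa import GAP, MultipleAlignment, fractional_difference, kimura_distance
from .tree import PhyloTree, TreeNode

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA20)}
_DATA_ORDER = "ARNDCQEGHILKMFPSTWYV"  # residue order of the bundled matrix files

_matrix_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}


def _load_matrix(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Load bundled exchangeabilities (20x20 symmetric) and frequencies,
    reordered to the package's alphabetical residue order."""
    if name in _matrix_cache:
        return _matrix_cache[name]
    if name == "POISSON":
        S = np.ones((20, 20)) - np.eye(20)
        freqs = np.full(20, 0.05)
        _matrix_cache[name] = (S, freqs)
        return S, freqs
    text = (
        resources.files("loxevo").joinpath(f"data/{name.lower()}.tsv").read_text()
    )
    ex = fr = None
    for line in text.splitlines():
        if line.startswith("exchangeabilities"):
            ex = np.array([float(x) for x in line.split("\t")[1:]])
        elif line.startswith("frequencies"):
            fr = np.array([float(x) for x in line.split("\t")[1:]])
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = ex[k]
            k += 1
    # reorder from the file's residue order to alphabetical
    perm = [_DATA_ORDER.index(a) for a in AA20]
    S = S[np.ix_(perm, perm)]
    fr = fr[perm]
    fr = fr / fr.sum()
    _matrix_cache[name] = (S, fr)
    return S, fr


def discrete_gamma_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean-of-quantile discretization (Yang 1994); rates have mean exactly 1."""
    if alpha <= 0:
        raise ValueError("gamma shape must be > 0")
    cuts = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], cuts, [np.inf]])
    rates = np.empty(k)
    for i in range(k):
        lo, hi = bounds[i], bounds[i + 1]
        # E[X; X in (lo,hi]] / P(X in bin) with P = 1/k
        upper = gammainc(alpha + 1, hi * alpha) if np.isfinite(hi) else 1.0
        lower = gammainc(alpha + 1, lo * alpha)
        rates[i] = (upper - lower) * k
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """Reversible amino-acid model: matrix name (+F / +G / +I variants)."""

    name: str = "WAG"
    alpha: float | None = None  # gamma shape, 4 categories; None = no gamma
    p_inv: float | None = None
    empirical_freqs: np.ndarray | None = None  # +F (already normalized)
    n_categories: int = 4
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.p_inv is not None and not (0 <= self.p_inv < 1):
            raise ValueError("p_inv must be in [0, 1)")

    @property
    def freqs(self) -> np.ndarray:
        if self.empirical_freqs is not None:
            return self.empirical_freqs
        return _load_matrix(self.name)[1]

    def describe(self) -> str:
        s = self.name
        if self.alpha is not None:
            s += "+G"
        if self.p_inv is not None:
            s += "+I"
        if self.empirical_freqs is not None:
            s += "+F"
        return s

    def rate_matrix(self) -> np.ndarray:
        """Q = S * diag(pi), rows summing to 0, mean rate 1 (at p_inv = 0)."""
        S, _ = _load_matrix(self.name)
        pi = self.freqs
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -np.sum(pi * np.diag(Q))
        return Q / mean_rate

    def _eigen(self):
        if self._eig is None:
            pi = self.freqs
            Q = self.rate_matrix()
            d = np.sqrt(pi)
            B = (Q * d[:, None]) / d[None, :]
            B = (B + B.T) / 2  # enforce symmetry
            lam, U = np.linalg.eigh(B)
            self._eig = (lam, U, d)
        return self._eig

    def pmatrix(self, t: float) -> np.ndarray:
        """Transition probabilities P(t) = exp(Qt)."""
        lam, U, d = self._eigen()
        E = U * np.exp(lam * t)[None, :]
        P = (E @ U.T) / d[:, None] * d[None, :]
        return np.clip(P, 0.0, None)

    def site_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(category rates, category weights), excluding the invariant class."""
        if self.alpha is None:
            return np.array([1.0]), np.array([1.0])
        r = discrete_gamma_rates(self.alpha, self.n_categories)
        w = np.full(self.n_categories, 1.0 / self.n_categories)
        return r, w

    def with_updates(self, **kw) -> "SubstitutionModel":
        return SubstitutionModel(
            name=kw.get("name", self.name),
            alpha=kw.get("alpha", self.alpha),
            p_inv=kw.get("p_inv", self.p_inv),
            empirical_freqs=kw.get("empirical_freqs", self.empirical_freqs),
            n_categories=self.n_categories,
        )


def empirical_frequencies(msa: MultipleAlignment) -> np.ndarray:
    """Observed residue frequencies with a Laplace 1-pseudocount per residue."""
    counts = np.ones(20)
    for row in msa.rows:
        for c in row:
            k = AA_INDEX.get(c)
            if k is not None:
                counts[k] += 1
    return counts / counts.sum()


@dataclass
class ModelFit:
    model: SubstitutionModel
    loglik: float
    n_params: int

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


class CompiledAlignment:
    """Unique site patterns with weights; residue codes, -1 = missing."""

    def __init__(self, msa: MultipleAlignment):
        codes = np.array(
            [[AA_INDEX.get(c, -1) for c in row] for row in msa.rows], dtype=np.int64
        )
        patterns, weights = np.unique(codes, axis=1, return_counts=True)
        self.ids = list(msa.ids)
        self.patterns = patterns  # (n_rows, n_pat)
        self.weights = weights.astype(float)

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]


def tree_loglik(
    tree: PhyloTree,
    msa: MultipleAlignment,
    model: SubstitutionModel,
    compiled: CompiledAlignment | None = None,
) -> float:
    """Felsenstein pruning log-likelihood over sites."""
    data = compiled if compiled is not None else CompiledAlignment(msa)
    tips = set(tree.tip_names())
    rows = set(data.ids)
    if tips != rows:
        raise ValueError(
            f"tree tips and alignment rows differ: only-tree={sorted(tips - rows)}, "
            f"only-alignment={sorted(rows - tips)}"
        )
    n_pat = data.n_patterns
    pi = model.freqs
    rates, cat_w = model.site_rates()
    p_inv = model.p_inv or 0.0
    row_of = {rid: k for k, rid in enumerate(data.ids)}

    tip_partial: dict[str, np.ndarray] = {}

    def tip_like(name: str) -> np.ndarray:
        if name not in tip_partial:
            codes = data.patterns[row_of[name]]
            L = np.zeros((20, n_pat))
            miss = codes < 0
            L[:, miss] = 1.0
            ok = ~miss
            L[codes[ok], np.where(ok)[0]] = 1.0
            tip_partial[name] = L
        return tip_partial[name]

    site_lik = np.zeros(n_pat)
    for rate, w in zip(rates, cat_w):
        partials: dict[int, np.ndarray] = {}
        for node in tree.root.postorder():
            if node.is_leaf:
                partials[id(node)] = tip_like(node.name)
            else:
                L = np.ones((20, n_pat))
                for c in node.children:
                    t_eff = rate * (c.length or 0.0)
                    P = model.pmatrix(t_eff)
                    L = L * (P @ partials.pop(id(c)))
                partials[id(node)] = L
        site_lik += w * (pi @ partials[id(tree.root)])
    if p_inv > 0:
        inv = np.zeros(n_pat)
        for p in range(n_pat):
            col = data.patterns[:, p]
            present = col[col >= 0]
            if present.size == 0:
                inv[p] = 1.0
            elif np.all(present == present[0]):
                inv[p] = pi[present[0]]
        site_lik = (1.0 - p_inv) * site_lik + p_inv * inv
    return float(np.sum(data.weights * np.log(np.maximum(site_lik, 1e-300))))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def alignment_distances(msa: MultipleAlignment) -> np.ndarray:
    n = msa.n_rows
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = kimura_distance(
                fractional_difference(msa.rows[i], msa.rows[j])
            )
    return D


def nj_tree(D: np.ndarray, labels: list[str]) -> PhyloTree:
    """Saitou & Nei neighbor joining. Deterministic: ties pick the lowest
    index pair; negative branch estimates are clamped to 0. The returned
    tree has a trifurcating root (unrooted convention) for n >= 3."""
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(D) != 0) or not np.all(np.isfinite(D)):
        raise ValueError("distance matrix must be finite with zero diagonal")
    n = len(labels)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    nodes = [TreeNode(name=l) for l in labels]
    D = D.copy()
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Qm = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Qm, np.inf)
        best = np.unravel_index(np.argmin(Qm), Qm.shape)  # lowest flat index on ties
        i_, j_ = sorted(best)
        ai, aj = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        nodes[ai].length = li
        nodes[aj].length = lj
        parent.add_child(nodes[ai])
        parent.add_child(nodes[aj])
        # distances to the new node
        D = np.pad(D, ((0, 1), (0, 1)))
        knew = D.shape[0] - 1
        for k_ in active:
            if k_ in (ai, aj):
                continue
            D[knew, k_] = D[k_, knew] = 0.5 * (D[ai, k_] + D[aj, k_] - dij)
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [knew]
    if len(active) == 2:
        a, b = active
        d = max(D[a, b], 0.0)
        if nodes[a].children and not nodes[b].children:
            a, b = b, a
        if nodes[b].children:  # attach remaining leaf/cherry to the internal node
            nodes[a].length = d
            nodes[b].add_child(nodes[a])
            root = nodes[b]
        else:
            root = TreeNode()
            nodes[a].length = d / 2
            nodes[b].length = d / 2
            root.add_child(nodes[a])
            root.add_child(nodes[b])
    tree = PhyloTree(root)
    return tree


# ---------------------------------------------------------------------------
# branch-length optimization & NNI search
# ---------------------------------------------------------------------------


def optimize_branch_lengths(
    tree: PhyloTree,
    msa: MultipleAlignment,
    model: SubstitutionModel,
    tol_lnl: float = 1e-4,
    tol_len: float = 1e-6,
    max_rounds: int = 20,
    compiled: CompiledAlignment | None = None,
) -> tuple[PhyloTree, float]:
    """Cycle bracketed per-branch optimizations until the log-likelihood gain
    in a full pass drops below ``tol_lnl``. Never decreases lnL."""
    data = compiled if compiled is not None else CompiledAlignment(msa)
    tree = tree.copy()
    branches = [n for n in tree.root.preorder() if n.parent is not None]
    for b in branches:
        if b.length is None:
            b.length = 0.1
    current = tree_loglik(tree, msa, model, data)
    for _ in range(max_rounds):
        start = current
        for b in branches:
            orig = b.length

            def neg(t):
                b.length = t
                return -tree_loglik(tree, msa, model, data)

            res = minimize_scalar(
                neg, bounds=(0.0, 20.0), method="bounded",
                options={"xatol": tol_len},
            )
            if -res.fun >= current:
                b.length = float(res.x)
                current = -res.fun
            else:
                b.length = orig
        if current - start < tol_lnl:
            break
    return tree, current


def nni_search(
    tree: PhyloTree,
    msa: MultipleAlignment,
    model: SubstitutionModel,
    max_iter: int = 50,
) -> tuple[PhyloTree, float]:
    """Hill-climb over nearest-neighbor interchanges with per-candidate
    branch re-optimization; stops at an NNI-local optimum."""
    data = CompiledAlignment(msa)
    best, best_lnl = optimize_branch_lengths(tree, msa, model, compiled=data)
    for _ in range(max_iter):
        improved = False
        for cand in nni_rearrangements(best):
            cand_opt, lnl = optimize_branch_lengths(cand, msa, model, compiled=data)
            if lnl > best_lnl + 1e-6:
                best, best_lnl = cand_opt, lnl
                improved = True
                break  # greedy: restart scan from the new tree
        if not improved:
            break
    return best, best_lnl


def nni_rearrangements(tree: PhyloTree) -> list[PhyloTree]:
    """Both NNI alternatives for every internal edge."""
    out = []
    nodes = list(tree.root.preorder())
    for k, n in enumerate(nodes):
        if n.parent is None or n.is_leaf:
            continue
        parent = n.parent
        for si, s in enumerate(parent.children):
            if s is n:
                continue
            for ci in range(len(n.children)):
                t2 = tree.copy()
                nodes2 = list(t2.root.preorder())
                n2 = nodes2[k]
                p2 = n2.parent
                s2 = p2.children[si]
                c2 = n2.children[ci]
                # swap c2 and s2
                n2.children[ci] = s2
                p2.children[si] = c2
                s2.parent = n2
                c2.parent = p2
                out.append(t2)
            break  # one sibling suffices: swapping with each child covers both NNIs
    return out


def random_topology(labels: list[str], rng: np.random.Generator) -> PhyloTree:
    """Random bifurcating topology (sequential random attachment), branch
    lengths 0.1."""
    labels = list(labels)
    rng.shuffle(labels)
    nodes = [TreeNode(name=l, length=0.1) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        p = TreeNode(length=0.1)
        p.add_child(nodes[i])
        p.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [p]
    root = TreeNode()
    for n in nodes:
        root.add_child(n)
    return PhyloTree(root)


def ml_tree(
    msa: MultipleAlignment,
    model: SubstitutionModel,
    n_starts: int = 1,
    seed: int = 0,
) -> tuple[PhyloTree, float]:
    """NJ (+ random multi-start) followed by NNI hill-climbing."""
    D = alignment_distances(msa)
    starts = [nj_tree(D, msa.ids)]
    rng = np.random.default_rng(seed)
    for _ in range(n_starts - 1):
        starts.append(random_topology(msa.ids, rng))
    best, best_lnl = None, -math.inf
    for s in starts:
        t, lnl = nni_search(s, msa, model)
        if lnl > best_lnl:
            best, best_lnl = t, lnl
    return best, best_lnl


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


def _optimize_rate_params(tree, msa, model, data, use_gamma, use_inv):
    """Alternate scalar optimizations of alpha and p_inv on fixed topology."""
    alpha = 1.0 if use_gamma else None
    p_inv = 0.1 if use_inv else None
    m = model.with_updates(alpha=alpha, p_inv=p_inv)
    tree, lnl = optimize_branch_lengths(tree, msa, m, compiled=data)
    for _ in range(2):
        if use_gamma:
            def neg_a(log_a):
                mm = m.with_updates(alpha=math.exp(log_a))
                return -tree_loglik(tree, msa, mm, data)

            # upper bound far beyond any real alpha so +G properly nests the
            # equal-rates model (alpha -> inf)
            res = minimize_scalar(neg_a, bounds=(math.log(0.05), math.log(1e6)),
                                  method="bounded", options={"xatol": 1e-3})
            m = m.with_updates(alpha=math.exp(float(res.x)))
        if use_inv:
            def neg_p(p):
                mm = m.with_updates(p_inv=p)
                return -tree_loglik(tree, msa, mm, data)

            res = minimize_scalar(neg_p, bounds=(0.0, 0.9), method="bounded",
                                  options={"xatol": 1e-3})
            m = m.with_updates(p_inv=float(res.x))
        tree, lnl = optimize_branch_lengths(tree, msa, m, compiled=data)
    return m, tree, lnl


def select_model(
    msa: MultipleAlignment,
    candidates: list[dict] | None = None,
    topology: PhyloTree | None = None,
) -> list[ModelFit]:
    """Rank candidate models by AIC on a fixed (NJ) topology.

    Each candidate is a dict with keys name, gamma, inv, plus_f. Parameter
    count = #branches + (gamma ? 1 : 0) + (inv ? 1 : 0) + (+F ? 19 : 0).
    """
    if candidates is None:
        candidates = [
            {"name": n, "gamma": g, "inv": i, "plus_f": f}
            for n in ("WAG", "LG", "JTT")
            for g in (True, False)
            for i in (True, False)
            for f in (True, False)
        ]
    if not candidates:
        raise ValueError("no candidate models")
    if topology is None:
        topology = nj_tree(alignment_distances(msa), msa.ids)
    data = CompiledAlignment(msa)
    n_branches = sum(1 for n in topology.root.preorder() if n.parent is not None)
    fits = []
    for cand in candidates:
        ef = empirical_frequencies(msa) if cand["plus_f"] else None
        base = SubstitutionModel(name=cand["name"], empirical_freqs=ef)
        m, tree, lnl = _optimize_rate_params(
            topology, msa, base, data, cand["gamma"], cand["inv"]
        )
        k = n_branches + int(cand["gamma"]) + int(cand["inv"]) + (19 if cand["plus_f"] else 0)
        fits.append(ModelFit(model=m, loglik=lnl, n_params=k))
    fits.sort(key=lambda f: f.aic)
    return fits


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(
    msa: MultipleAlignment,
    best_tree: PhyloTree,
    n_replicates: int = 100,
    seed: int = 0,
    model: SubstitutionModel | None = None,
    use_nni: bool = False,
) -> tuple[PhyloTree, list[PhyloTree]]:
    """Nonparametric bootstrap: resample columns with replacement, NJ
    (+ optional NNI) per replicate, map split frequencies onto the best tree
    as percentage supports. Returns (annotated tree copy, replicate trees)."""
    from .tree_support import bipartition_set

    if n_replicates < 1:
        raise ValueError("need >= 1 replicate")
    rng = np.random.default_rng(seed)
    sample: list[PhyloTree] = []
    for _ in range(n_replicates):
        cols = rng.integers(0, msa.n_cols, size=msa.n_cols)
        rows = ["".join(r[j] for j in cols) for r in msa.rows]
        rep = MultipleAlignment(ids=list(msa.ids), rows=rows)
        t = nj_tree(alignment_distances(rep), rep.ids)
        if use_nni and model is not None:
            t, _ = nni_search(t, rep, model)
        sample.append(t)
    counts: dict[frozenset, int] = {}
    for t in sample:
        for split in bipartition_set(t):
            counts[split] = counts.get(split, 0) + 1
    annotated = best_tree.copy()
    ref = sorted(annotated.tip_names())[0]
    all_tips = frozenset(annotated.tip_names())
    for node in annotated.root.preorder():
        if node.parent is None or node.is_leaf:
            continue
        tipset = annotated.tipset(node)
        side = tipset if ref not in tipset else all_tips - tipset
        if 1 < len(side) < len(all_tips) - 1:
            node.support = 100.0 * counts.get(frozenset(side), 0) / n_replicates
    return annotated, sample
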