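"""Bipartition bookkeeping across tree samples.

Split frequencies, the bpcomp-style maxdiff statistic between two samples,
a burn-in scan for convergence assessment, and majority-rule consensus.
Splits are canonicalized as the side not containing a fixed reference tip
(the lexicographically smallest label); trivial splits are excluded.

maxdiff is taken over the union of splits observed in either sample, which
matches the usual bpcomp semantics: a split absent from a sample has
frequency 0 there. The burn-in grid is scanned at 1% steps up to 50% on the
fixed ingested samples (the generation dimension of an on-line scan
collapses once the chains are finished).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .tree import PhyloTree, TreeNode


def bipartition_set(tree: PhyloTree) -> set[frozenset]:
    """Non-trivial splits of the tree, each as the tip-side not containing
    the reference (lexicographically smallest) tip."""
    tips = sorted(tree.tip_names())
    ref = tips[0]
    all_tips = frozenset(tips)
    out: set[frozenset] = set()
    for node in tree.root.postorder():
        if node.parent is None or node.is_leaf:
            continue
        side = tree.tipset(node)
        if ref in side:
            side = all_tips - side
        if 1 < len(side) < len(all_tips) - 1:
            out.add(frozenset(side))
    return out


def _retained(sample: list[PhyloTree], burn_in: float, stride: int) -> list[PhyloTree]:
    if not (0 <= burn_in < 1):
        raise ValueError("burn_in fraction must be in [0, 1)")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    start = int(len(sample) * burn_in)
    kept = sample[start::stride]
    if not kept:
        raise ValueError("no trees retained after burn-in and striding")
    return kept


def _check_tipsets(samples: list[list[PhyloTree]]) -> None:
    tipsets = {frozenset(t.tip_names()) for s in samples for t in s}
    if len(tipsets) > 1:
        raise ValueError("trees are not all on the same tip set")


def bipartition_frequencies(
    sample: list[PhyloTree], burn_in: float = 0.0, stride: int = 1
) -> dict[frozenset, float]:
    """Fraction of retained trees containing each observed split."""
    _check_tipsets([sample])
    kept = _retained(sample, burn_in, stride)
    counts: dict[frozenset, int] = {}
    for t in kept:
        for split in bipartition_set(t):
            counts[split] = counts.get(split, 0) + 1
    return {s: c / len(kept) for s, c in counts.items()}


def maxdiff(
    sample_a: list[PhyloTree],
    sample_b: list[PhyloTree],
    burn_in: float = 0.0,
    stride: int = 1,
) -> float:
    """Maximum absolute split-frequency difference over the union of splits."""
    _check_tipsets([sample_a, sample_b])
    fa = bipartition_frequencies(sample_a, burn_in, stride)
    fb = bipartition_frequencies(sample_b, burn_in, stride)
    union = set(fa) | set(fb)
    if not union:
        return 0.0
    return max(abs(fa.get(s, 0.0) - fb.get(s, 0.0)) for s in union)


@dataclass
class ConvergenceReport:
    table: pd.DataFrame  # columns burn_in, maxdiff
    burn_in: float
    n_trees: int
    maxdiff: float
    threshold: float
    stride: int

    @property
    def converged(self) -> bool:
        return self.maxdiff <= self.threshold


def convergence_scan(
    sample_a: list[PhyloTree],
    sample_b: list[PhyloTree],
    threshold: float = 0.1,
    stride: int = 10,
    grid_step: float = 0.01,
    max_burn_in: float = 0.5,
) -> ConvergenceReport:
    """Evaluate maxdiff over the burn-in grid 1%..50%; the chosen burn-in
    minimizes maxdiff (smallest burn-in on ties)."""
    if min(len(sample_a), len(sample_b)) < 20:
        raise ValueError("convergence scan needs >= 20 trees per sample")
    rows = []
    grid = [round(grid_step * k, 10) for k in range(1, int(max_burn_in / grid_step) + 1)]
    for b in grid:
        rows.append({"burn_in": b, "maxdiff": maxdiff(sample_a, sample_b, b, stride)})
    table = pd.DataFrame(rows)
    best = table.loc[table["maxdiff"].idxmin()]  # idxmin takes first (smallest) on ties
    return ConvergenceReport(
        table=table,
        burn_in=float(best["burn_in"]),
        n_trees=len(sample_a),
        maxdiff=float(best["maxdiff"]),
        threshold=threshold,
        stride=stride,
    )


def majority_consensus(
    sample: list[PhyloTree], burn_in: float = 0.0, stride: int = 1
) -> PhyloTree:
    """Majority-rule (>50%) consensus; supports are 100 x split frequency.

    Splits above one half are pairwise compatible, so the greedy insertion
    below cannot conflict. The result may be multifurcating.
    """
    freqs = bipartition_frequencies(sample, burn_in, stride)
    tips = sorted(sample[0].tip_names())
    ref = tips[0]
    majority = sorted(
        [(s, f) for s, f in freqs.items() if f > 0.5],
        key=lambda t: (-len(t[0]), sorted(t[0])),
    )
    # ref-rooted representation: each split (side without ref) is a clade.
    # Splits are inserted largest first, so every split's host (the smallest
    # strict superset clade) already exists when it is inserted.
    root = TreeNode()
    containers: dict[frozenset, TreeNode] = {frozenset(tips) - {ref}: root}
    for split, f in majority:
        host_set = min(
            (s for s in containers if split < s), key=len
        )
        node = TreeNode(support=100.0 * f)
        containers[host_set].add_child(node)
        containers[split] = node
    # each non-ref tip attaches to the smallest clade containing it
    for t in tips[1:]:
        host_set = min((s for s in containers if t in s), key=len)
        containers[host_set].add_child(TreeNode(name=t))
    root.add_child(TreeNode(name=ref))
    return PhyloTree(root)
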