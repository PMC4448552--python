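"""Dollo-parsimony gain/loss reconstruction on a fixed species tree.

Each binary character (presence of a gene family or of a domain feature) is
gained exactly once — at the most recent common ancestor of the taxa that
have it, unless a deeper gain node is imposed — and lost any number of
times. Losses are the roots of the maximal all-absent subtrees inside the
gain clade, which is the unique minimum-cardinality loss set given the gain
node. Unsampled states are encoded "?" and excluded from both the presence
and absence sets.

Gains can be placed by gene-tree/species-tree reconciliation: after a
duplication, the daughter families' gains belong on the branch where the
duplication happened, which pure tip-state parsimony would place too
shallowly (e.g. a family lost in one early lineage). The reconciliation
rule used here is the species LCA of the family's own species together with
the species of its sister family clade in the gene tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .tree import PhyloTree, TreeNode


@dataclass
class CharacterEvents:
    character: str
    gain_branch: str
    loss_branches: list[str] = field(default_factory=list)


def _branch_label(node: TreeNode) -> str:
    if node.name:
        return node.name
    tips = sorted(n.name for n in node.postorder() if n.is_leaf)
    return "mrca(" + ",".join(tips) + ")"


def dollo_reconstruct(
    tree: PhyloTree,
    states: dict[str, str],
    character: str = "char",
    constrained_gain: str | None = None,
) -> CharacterEvents:
    """Single-character Dollo reconstruction.

    ``states`` maps tip name -> "1" | "0" | "?". The gain is at the MRCA of
    the 1-tips unless ``constrained_gain`` names a (necessarily ancestral)
    node; losses are roots of maximal subtrees of the gain clade whose
    non-"?" tips are all 0 (subtrees with only "?" tips require no loss).
    """
    present = {t for t, s in states.items() if s == "1"}
    absent = {t for t, s in states.items() if s == "0"}
    if not present:
        raise ValueError(f"character {character!r} has no presence tip")
    missing = (present | absent) - set(tree.tip_names())
    if missing:
        raise KeyError(f"tips not in species tree: {sorted(missing)}")
    gain = tree.mrca(present)
    if constrained_gain is not None:
        node = tree.find(constrained_gain)
        anc_tips = tree.tipset(node)
        if not present <= anc_tips:
            raise ValueError(
                f"constrained gain node {constrained_gain!r} is not ancestral to "
                f"all presence tips of {character!r}"
            )
        gain = node
    losses: list[TreeNode] = []

    def scan(node: TreeNode) -> str:
        """Returns subtree status: 'present', 'absent', or 'unknown'."""
        if node.is_leaf:
            s = states.get(node.name, "?")
            return {"1": "present", "0": "absent"}.get(s, "unknown")
        child_status = [scan(c) for c in node.children]
        if any(s == "present" for s in child_status):
            # losses are the absent children subtrees (maximal all-0)
            for c, s in zip(node.children, child_status):
                if s == "absent":
                    losses.append(c)
            return "present"
        if all(s == "unknown" for s in child_status):
            return "unknown"
        return "absent"

    status = scan(gain)
    if status == "absent":  # cannot happen: gain is MRCA of >= 1 presence tip
        raise AssertionError("gain clade without presence tips")
    return CharacterEvents(
        character=character,
        gain_branch=_branch_label(gain),
        loss_branches=[_branch_label(n) for n in losses],
    )


def reconcile_gain_nodes(
    gene_tree: PhyloTree,
    species_tree: PhyloTree,
    family_assignments: dict[str, str],
    species_of: dict[str, str],
) -> dict[str, str]:
    """Duplication-aware gain placement.

    ``family_assignments`` maps gene-tree tip -> family name; ``species_of``
    maps gene-tree tip -> species-tree tip. Each family must be monophyletic
    in the gene tree. The gain node of a family is the species-tree LCA of
    its own species together with the species of its sister clade's
    families (the duplication context); a family whose sister clade is empty
    (single family) gets the LCA of its own species.
    """
    families = sorted(set(family_assignments.values()))
    out: dict[str, str] = {}
    for fam in families:
        members = [g for g, f in family_assignments.items() if f == fam]
        mrca = gene_tree.mrca(members)
        clade_tips = set(gene_tree.tipset(mrca))
        intruders = sorted(
            t for t in clade_tips if family_assignments.get(t) != fam
        )
        if intruders:
            raise ValueError(
                f"family {fam!r} is not monophyletic in the gene tree; "
                f"intruders: {intruders}"
            )
        own_species = {species_of[g] for g in members}
        sister_species: set[str] = set()
        if mrca.parent is not None:
            for sib in mrca.parent.children:
                if sib is mrca:
                    continue
                sister_species |= {
                    species_of[t] for t in gene_tree.tipset(sib) if t in species_of
                }
        target = own_species | sister_species
        if len(target) == 1:
            node = species_tree.find(next(iter(target)))
        else:
            node = species_tree.mrca(target)
        out[fam] = _branch_label(node)
    return out


def event_report(
    tree: PhyloTree,
    matrix: pd.DataFrame,
    constrained_gains: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reconstruct every character column of a taxa x characters matrix
    (entries "1"/"0"/"?"; taxa in the index).

    Returns (events table, per-branch summary). The events table has one
    row per gain/loss; the summary aggregates counts per branch.
    """
    constrained_gains = constrained_gains or {}
    ev_rows = []
    for char in matrix.columns:
        states = {t: str(matrix.at[t, char]) for t in matrix.index}
        ev = dollo_reconstruct(tree, states, char, constrained_gains.get(char))
        ev_rows.append({"character": char, "branch": ev.gain_branch, "type": "gain"})
        for b in ev.loss_branches:
            ev_rows.append({"character": char, "branch": b, "type": "loss"})
    events = pd.DataFrame(ev_rows, columns=["character", "branch", "type"])
    summary = (
        events.groupby(["branch", "type"]).size().unstack(fill_value=0).reset_index()
    )
    return events, summary
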