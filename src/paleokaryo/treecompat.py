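"""1R/2R compatibility classification of gene-family trees.

A gene tree is judged against the expected gnathostome backbone
``((A,B),(C,D))``, where A-D are the four post-2R chromosome groups of the
reference species and (A,B) / (C,D) are the two post-1R lineages.  A test
gene (e.g. a cyclostome gene) supports 2R when it branches inside, or as
sister to, exactly one of A-D; it supports 1R (without 2R) when it
branches as sister to a whole 1R pair or inside a pair but outside both of
its 2R clades; anything attaching outside the gnathostome ingroup
supports neither.  Trees are treated as topologies: branch lengths and
support values are ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import pandas as pd

__all__ = [
    "LabeledGeneTree",
    "CompatibilityCall",
    "parse_leaf_label",
    "label_backbone",
    "classify_test_genes",
    "tally_support",
]

LEAF_PATTERN = re.compile(
    r"^(?P<species>[^|]+)\|(?P<gene>[^|]+)\|(?P<chrom>.+)$"
)

PAIRS = (("A", "B"), ("C", "D"))


def parse_leaf_label(label: str, pattern: re.Pattern = LEAF_PATTERN):
    """Split a ``species|gene|chromosome`` leaf label."""
    m = pattern.match(label)
    if not m:
        raise ValueError(f"leaf label {label!r} does not match the convention")
    return m.group("species"), m.group("gene"), m.group("chrom")


@dataclass
class LabeledGeneTree:
    """A rooted gene tree with its gnathostome backbone labelled."""

    tree: dendropy.Tree
    group_of: dict  # leaf node -> "A"/"B"/"C"/"D"
    outgroup_leaves: list
    excluded_leaves: list
    usable: bool
    reason: str = ""
    tree_id: str = ""


@dataclass(frozen=True)
class CompatibilityCall:
    tree_id: str
    test_species: str
    supports_1R: bool
    supports_2R: bool
    attachment: str
    flags: str = ""


def _leaf_fields(leaf) -> tuple[str, str, str]:
    return parse_leaf_label(leaf.taxon.label)


def label_backbone(
    tree: dendropy.Tree | str,
    pairing: dict[str, set[str]],
    ref_species: Iterable[str],
    outgroup_species: Iterable[str],
    tree_id: str = "",
) -> LabeledGeneTree:
    """Root a gene tree on its outgroup and label the 2R backbone clades.

    ``pairing`` maps the group letters A-D to the chromosome names of the
    reference (gnathostome) species expected in each post-2R clade.
    Reference-species leaves on chromosomes absent from the pairing are
    excluded (flagged); trees whose backbone is not topologically
    compatible with ``((A,B),(C,D))`` after pruning test leaves are marked
    unusable rather than partially scored.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(
            data=tree, schema="newick", preserve_underscores=True
        )
    tree.is_rooted = True
    ref_species = set(ref_species)
    outgroup_species = set(outgroup_species)
    chrom_group = {
        chrom: letter for letter, chroms in pairing.items() for chrom in chroms
    }
    leaves = tree.leaf_node_iter()
    out_leaves, group_of, excluded = [], {}, []
    for leaf in leaves:
        sp, _gene, chrom = _leaf_fields(leaf)
        if sp in outgroup_species:
            out_leaves.append(leaf)
        elif sp in ref_species:
            letter = chrom_group.get(chrom)
            if letter is None:
                excluded.append(leaf)
            else:
                group_of[leaf] = letter
    if not out_leaves:
        raise ValueError("tree has no outgroup leaf; cannot root")
    # root on the outgroup edge
    og_taxa = [l.taxon for l in out_leaves]
    if len(og_taxa) == 1:
        node = out_leaves[0]
    else:
        node = tree.mrca(taxa=og_taxa)
    if node is not tree.seed_node:
        tree.reroot_at_edge(node.edge, update_bipartitions=False)
    # rebuild leaf references after rerooting
    group_of = {}
    out_leaves = []
    excluded = []
    for leaf in tree.leaf_node_iter():
        sp, _gene, chrom = _leaf_fields(leaf)
        if sp in outgroup_species:
            out_leaves.append(leaf)
        elif sp in ref_species:
            letter = chrom_group.get(chrom)
            if letter is None:
                excluded.append(leaf)
            else:
                group_of[leaf] = letter
    present = {g for g in group_of.values()}
    if len(present) < 2:
        return LabeledGeneTree(
            tree, group_of, out_leaves, excluded, False,
            "fewer than 2 backbone groups present", tree_id,
        )
    usable, reason = _verify_backbone(tree, group_of)
    return LabeledGeneTree(
        tree, group_of, out_leaves, excluded, usable, reason, tree_id
    )


def _backbone_leaves_under(node, group_of) -> set:
    return {l for l in node.leaf_iter() if l in group_of}


def _verify_backbone(tree: dendropy.Tree, group_of: dict) -> tuple[bool, str]:
    """Check that backbone leaves are compatible with ((A,B),(C,D)).

    Each present group must be monophyletic with respect to the other
    backbone leaves, and each 1R pair must likewise exclude the other
    pair's leaves (test and outgroup leaves are ignored throughout).
    """
    by_group: dict[str, list] = {}
    for leaf, letter in group_of.items():
        by_group.setdefault(letter, []).append(leaf)
    sets = {letter: set(ls) for letter, ls in by_group.items()}
    all_backbone = set(group_of)

    def clean(leafset: set, label: str) -> bool:
        if len(leafset) == len(all_backbone):
            return True
        mrca = tree.mrca(taxa=[l.taxon for l in leafset])
        inside = _backbone_leaves_under(mrca, group_of)
        return inside <= leafset

    for letter, leafset in sorted(sets.items()):
        if len(leafset) > 1 and not clean(leafset, letter):
            return False, f"group {letter} not monophyletic"
    for pair in PAIRS:
        leafset = set().union(*(sets.get(l, set()) for l in pair))
        if leafset and len({l for l in pair if sets.get(l)}) == 2:
            if not clean(leafset, "".join(pair)):
                return False, f"pair {'+'.join(pair)} not monophyletic"
    return True, ""


def _maximal_test_clades(tree: dendropy.Tree, test_leaves: set) -> list:
    """Maximal nodes whose entire leaf set consists of test-species leaves."""
    clades = []

    def walk(node) -> bool:
        if node.is_leaf():
            return node in test_leaves
        child_pure = [walk(c) for c in node.child_nodes()]
        if all(child_pure) and child_pure:
            return True
        for c, pure in zip(node.child_nodes(), child_pure):
            if pure:
                clades.append(c)
        return False

    if walk(tree.seed_node):
        clades.append(tree.seed_node)
    return clades


def classify_test_genes(
    t: LabeledGeneTree, test_species: Iterable[str]
) -> list[CompatibilityCall]:
    """Classify each maximal test-species clade for 1R/2R support."""
    if not t.usable:
        raise ValueError(f"tree {t.tree_id or '<anon>'} flagged unusable: {t.reason}")
    test_species = set(test_species)
    test_leaves = set()
    for leaf in t.tree.leaf_node_iter():
        sp, _g, _c = _leaf_fields(leaf)
        if sp in test_species:
            test_leaves.add(leaf)
    calls: list[CompatibilityCall] = []
    pair_sets = [set(p) for p in PAIRS]
    for clade in _maximal_test_clades(t.tree, test_leaves):
        species = sorted({_leaf_fields(l)[0] for l in clade.leaf_iter()})
        label = "+".join(species)
        node = clade.parent_node
        flags = ""
        # climb to the smallest ancestor with backbone context; note any
        # outgroup leaves passed on the way (a test clade nested among
        # outgroup leaves branches before the ingroup radiation)
        prev = clade
        outgroup_on_path = False
        context: set = set()
        out_set = set(t.outgroup_leaves)
        while node is not None:
            sibling_leaves = {
                l
                for child in node.child_nodes()
                if child is not prev
                for l in child.leaf_iter()
            }
            context = sibling_leaves & set(t.group_of)
            if context:
                break
            if sibling_leaves & out_set:
                outgroup_on_path = True
            prev = node
            node = node.parent_node
        if node is None or not context:
            calls.append(
                CompatibilityCall(t.tree_id, label, False, False, "no-context")
            )
            continue
        groups = {t.group_of[l] for l in context}
        whole_backbone = context == set(t.group_of)
        if outgroup_on_path or whole_backbone:
            # branches with the pre-WGD outgroup, or as sister to the whole
            # gnathostome ingroup: a pre-1R position
            calls.append(
                CompatibilityCall(
                    t.tree_id, label, False, False, "pre-ingroup",
                    "outgroup-path" if outgroup_on_path else "",
                )
            )
            continue
        s2 = len(groups) == 1
        s1 = s2 or any(groups <= p for p in pair_sets)
        attachment = "|".join(sorted(groups))
        if not s2 and len(node.child_nodes()) > 2:
            # permissive polytomy reading: a clean 2R (or 1R-pair) clade
            # sitting beside the test clade in the same polytomy counts as
            # its sister
            for child in node.child_nodes():
                if child is prev:
                    continue
                sub = {t.group_of[l] for l in _backbone_leaves_under(child, t.group_of)}
                if len(sub) == 1:
                    s2 = s1 = True
                    flags = "polytomy"
                    attachment = f"polytomy-sister:{next(iter(sub))}"
                    break
                if sub and any(sub <= p for p in pair_sets) and not s1:
                    s1 = True
                    flags = "polytomy"
                    attachment = f"polytomy-sister:{'|'.join(sorted(sub))}"
        calls.append(
            CompatibilityCall(t.tree_id, label, bool(s1), bool(s2), attachment, flags)
        )
    return calls


def tally_support(
    calls: Sequence[CompatibilityCall], per_tree: bool = False
) -> pd.DataFrame:
    """Fractions of calls supporting 1R and 2R per test species.

    With ``per_tree=True`` calls are first collapsed to one conservative
    call per (tree, species): a tree supports a hypothesis only if every
    one of its test clades does.
    """
    if not calls:
        return pd.DataFrame(columns=["test_species", "n", "frac_1R", "frac_2R"])
    df = pd.DataFrame(
        [
            (c.tree_id, c.test_species, c.supports_1R, c.supports_2R)
            for c in calls
        ],
        columns=["tree_id", "test_species", "supports_1R", "supports_2R"],
    )
    if per_tree:
        df = (
            df.groupby(["tree_id", "test_species"], as_index=False)
            .agg(supports_1R=("supports_1R", "all"), supports_2R=("supports_2R", "all"))
        )
    out = (
        df.groupby("test_species")
        .agg(n=("supports_1R", "size"), frac_1R=("supports_1R", "mean"),
             frac_2R=("supports_2R", "mean"))
        .reset_index()
        .sort_values("test_species")
        .reset_index(drop=True)
    )
    return out
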