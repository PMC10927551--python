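"""Ancestral-chromosome (AC) reconstruction from cross-genome homology.

The reconstruction follows the classic content-based macrosynteny recipe:
reciprocal best hits between two slow-evolving ingroup genomes (plus
unidirectional best hits from an unduplicated outgroup used as reference),
chi-squared enrichment of shared homologues per chromosome pair with
Benjamini-Hochberg FDR control, a homology graph over chromosomes, and
grouping of ingroup chromosomes into AC groups anchored by the outgroup's
linkage groups.  Finally, outgroup genes are anchored to ACs to define
each AC's reference gene content.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .genome import GenomeMap

__all__ = [
    "ChromosomePairStats",
    "AncestralChromosomeSet",
    "reciprocal_best_hits",
    "pair_enrichment",
    "homologous_chromosome_graph",
    "group_ancestral_chromosomes",
    "anchor_outgroup_genes",
    "best_hits",
    "outgroup_linkage_from_stats",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChromosomePairStats:
    """Shared-homologue enrichment for one chromosome pair.

    The 2x2 table tested is ``[[n_ab, n_a - n_ab], [n_b - n_ab,
    N - n_a - n_b + n_ab]]`` where margins count homologue *pairs*
    involving each chromosome and N is the grand total of pairs.
    """

    chrom_a: tuple[str, str]  # (species, chromosome)
    chrom_b: tuple[str, str]
    n_ab: int
    n_a: int
    n_b: int
    n_total: int
    chi2: float
    p: float
    q: float = float("nan")
    enriched: bool = False

    @property
    def expected(self) -> float:
        return self.n_a * self.n_b / self.n_total


@dataclass
class AncestralChromosomeSet:
    """Recovered AC groups with anchored outgroup gene content.

    ``groups`` maps AC id -> set of (species, chromosome) members; a fusion
    product carrying material of several ACs appears in each matching group
    and is listed in ``multi_members``.  ``anchored_genes`` maps AC id ->
    ordered outgroup gene ids; ``provenance`` records which anchoring rule
    fired per gene.
    """

    groups: dict[str, set[tuple[str, str]]]
    anchored_genes: dict[str, list[str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    multi_members: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    unanchored: dict[str, str] = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def _strip_species(qualified: str) -> tuple[str, str]:
    species, _, gid = qualified.partition(":")
    if not gid:
        raise ValueError(f"gene id {qualified!r} is not species-qualified")
    return species, gid


# ---------------------------------------------------------------------------
# best hits
# ---------------------------------------------------------------------------


def _dedup_best(hits: pd.DataFrame) -> pd.DataFrame:
    """Keep the best-scoring row per (query, subject)."""
    h = hits.sort_values(
        ["qseqid", "sseqid", "bitscore", "evalue"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return h.drop_duplicates(["qseqid", "sseqid"], keep="first")


def best_hits(hits: pd.DataFrame, evalue_max: float = 1e-6) -> pd.DataFrame:
    """Unidirectional best hit per query (highest bit-score).

    Ties are broken by lower e-value, then lexicographic subject id, so the
    result is deterministic regardless of input row order.
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be > 0")
    h = _dedup_best(hits)
    h = h[h["evalue"] <= evalue_max]
    if h.empty:
        return h
    h = h.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return h.drop_duplicates("qseqid", keep="first")


def reciprocal_best_hits(
    hits: pd.DataFrame, evalue_max: float = 1e-6
) -> set[tuple[str, str]]:
    """Mutual best-hit gene pairs at an e-value ceiling.

    ``(a, b)`` is returned iff b is a's best-scoring subject and a is b's,
    with both supporting rows at ``evalue <= evalue_max``.  The hit table
    is expected to cover one genome pair (both directions); pairs are
    returned with the lexicographically smaller member first.
    """
    fwd = best_hits(hits, evalue_max)
    if fwd.empty:
        return set()
    best = dict(zip(fwd["qseqid"], fwd["sseqid"]))
    pairs = set()
    for q, s in best.items():
        if best.get(s) == q:
            pairs.add((q, s) if q <= s else (s, q))
    return pairs


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def pair_enrichment(
    pairs: set[tuple[str, str]] | list[tuple[str, str]],
    maps: dict[str, GenomeMap],
    q_max: float = 0.05,
) -> list[ChromosomePairStats]:
    """Chi-squared enrichment of shared homologues per chromosome pair.

    Every chromosome pair with at least one homologue pair is tested with
    a Pearson chi-squared test (no continuity correction) on the 2x2 table
    of pair counts; cells with expected count < 5 fall back to Fisher's
    exact test.  P-values are Benjamini-Hochberg corrected across all
    tested pairs (one family per call).  A pair is ``enriched`` when the
    observed count exceeds expectation and q < ``q_max``.
    """
    gene_loc: dict[str, tuple[str, str]] = {}
    for sp, g in maps.items():
        for gene in g:
            gene_loc[f"{sp}:{gene.gene_id}"] = (sp, gene.chromosome)
    counts: dict[tuple[tuple[str, str], tuple[str, str]], int] = {}
    margins: dict[tuple[str, str], int] = {}
    n_total = 0
    for a, b in pairs:
        if a not in gene_loc:
            raise KeyError(f"gene {a!r} absent from maps")
        if b not in gene_loc:
            raise KeyError(f"gene {b!r} absent from maps")
        ca, cb = gene_loc[a], gene_loc[b]
        key = (ca, cb) if ca <= cb else (cb, ca)
        counts[key] = counts.get(key, 0) + 1
        margins[ca] = margins.get(ca, 0) + 1
        if cb != ca:
            margins[cb] = margins.get(cb, 0) + 1
        n_total += 1
    out: list[ChromosomePairStats] = []
    for (ca, cb), n_ab in sorted(counts.items()):
        n_a, n_b = margins[ca], margins[cb]
        table = np.array(
            [
                [n_ab, n_a - n_ab],
                [n_b - n_ab, n_total - n_a - n_b + n_ab],
            ],
            dtype=float,
        )
        if table.min() < 0:  # degenerate margins (ca == cb self-pairs)
            continue
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        if (expected < 5).any():
            _odds, p = sps.fisher_exact(table.astype(int), alternative="two-sided")
            with np.errstate(divide="ignore", invalid="ignore"):
                contrib = np.where(
                    expected > 0, (table - expected) ** 2 / expected, 0.0
                )
            chi2 = float(contrib.sum())
        else:
            chi2, p, _dof, _exp = sps.chi2_contingency(table, correction=False)
        out.append(
            ChromosomePairStats(
                ca, cb, n_ab, n_a, n_b, n_total, float(chi2), float(p)
            )
        )
    if not out:
        return out
    pvals = np.array([s.p for s in out])
    _rej, qvals, _a, _b = multipletests(pvals, method="fdr_bh")
    final = []
    for s, q in zip(out, qvals):
        q = float(max(q, s.p))
        enriched = bool(s.n_ab > s.expected and q < q_max)
        final.append(
            ChromosomePairStats(
                s.chrom_a, s.chrom_b, s.n_ab, s.n_a, s.n_b, s.n_total,
                s.chi2, s.p, q, enriched,
            )
        )
    return final


def homologous_chromosome_graph(
    stats: list[ChromosomePairStats], q_max: float = 0.05
) -> nx.Graph:
    """Undirected chromosome homology graph: edges are enriched pairs."""
    g = nx.Graph()
    for s in stats:
        g.add_node(s.chrom_a, species=s.chrom_a[0])
        g.add_node(s.chrom_b, species=s.chrom_b[0])
        if s.enriched and s.q < q_max:
            g.add_edge(s.chrom_a, s.chrom_b, q=s.q, n_ab=s.n_ab)
    return g


def outgroup_linkage_from_stats(
    stats: list[ChromosomePairStats], outgroup_species: str, q_max: float = 0.05
) -> dict[tuple[str, str], set[str]]:
    """Ingroup chromosome -> set of enriched outgroup linkage groups."""
    linkage: dict[tuple[str, str], set[str]] = {}
    for s in stats:
        if not (s.enriched and s.q < q_max):
            continue
        a_out = s.chrom_a[0] == outgroup_species
        b_out = s.chrom_b[0] == outgroup_species
        if a_out == b_out:
            continue
        ingroup = s.chrom_b if a_out else s.chrom_a
        lg = s.chrom_a[1] if a_out else s.chrom_b[1]
        linkage.setdefault(ingroup, set()).add(lg)
    return linkage


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------


def group_ancestral_chromosomes(
    graph: nx.Graph,
    outgroup_linkage: dict[tuple[str, str], set[str] | str] | None = None,
) -> AncestralChromosomeSet:
    """Group ingroup chromosomes into AC groups.

    Without outgroup evidence, AC groups are the connected components of
    the homology graph.  With an ``outgroup_linkage`` map (ingroup
    chromosome -> outgroup linkage group(s)), each outgroup linkage group
    seeds one AC: components are split along linkage-group boundaries, so
    chained components whose members map to disjoint linkage groups
    separate cleanly, and a fusion product linked to several linkage
    groups is listed under each of its ACs (recorded in ``multi_members``)
    instead of collapsing them into one group.  Chromosomes lacking
    outgroup signal inherit the AC of their best-connected neighbours.
    AC ids are assigned deterministically by sorted member order.
    """
    components = [set(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: sorted(c))
    if not outgroup_linkage:
        groups = {
            f"ACG{k + 1:02d}": comp for k, comp in enumerate(components)
        }
        return AncestralChromosomeSet(groups=groups)
    norm: dict[tuple[str, str], frozenset[str]] = {}
    for chrom, lgs in outgroup_linkage.items():
        norm[chrom] = frozenset([lgs] if isinstance(lgs, str) else lgs)
    by_lg: dict[str, set[tuple[str, str]]] = {}
    orphans: list[tuple[set, list]] = []
    for comp in components:
        lg_here: set[str] = set()
        unlinked = []
        for chrom in sorted(comp):
            lgs = norm.get(chrom, frozenset())
            if lgs:
                lg_here.update(lgs)
                for lg in lgs:
                    by_lg.setdefault(lg, set()).add(chrom)
            else:
                unlinked.append(chrom)
        if lg_here:
            for chrom in unlinked:
                # inherit the linkage group best supported among neighbours
                votes: dict[str, int] = {}
                for nb in graph.neighbors(chrom):
                    for lg in norm.get(nb, frozenset()):
                        votes[lg] = votes.get(lg, 0) + 1
                if votes:
                    best = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
                    by_lg.setdefault(best, set()).add(chrom)
                else:
                    logger.info("chromosome %s left ungrouped (no outgroup signal)", chrom)
        else:
            orphans.append((comp, sorted(comp)))
    groups: dict[str, set[tuple[str, str]]] = {}
    lg_to_ac: dict[str, str] = {}
    for k, lg in enumerate(sorted(by_lg)):
        ac = f"ACG{k + 1:02d}"
        groups[ac] = by_lg[lg]
        lg_to_ac[lg] = ac
    for comp, members in orphans:
        ac = f"ACG{len(groups) + 1:02d}"
        groups[ac] = set(members)
    multi: dict[tuple[str, str], list[str]] = {}
    member_of: dict[tuple[str, str], list[str]] = {}
    for ac, members in groups.items():
        for chrom in members:
            member_of.setdefault(chrom, []).append(ac)
    for chrom, acs in member_of.items():
        if len(acs) > 1:
            multi[chrom] = sorted(acs)
            logger.info(
                "chromosome %s spans %d AC groups (putative fusion product)",
                chrom, len(acs),
            )
    out = AncestralChromosomeSet(groups=groups, multi_members=multi)
    out.lg_to_ac = lg_to_ac  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# outgroup gene anchoring
# ---------------------------------------------------------------------------


def anchor_outgroup_genes(
    acs: AncestralChromosomeSet,
    outgroup_map: GenomeMap,
    hits: pd.DataFrame,
    ingroup_maps: dict[str, GenomeMap],
    min_multi: int = 5,
    evalue_max: float = 1e-6,
) -> AncestralChromosomeSet:
    """Anchor outgroup genes to AC groups, defining AC gene content.

    Rule 1: the gene's own chromosome is a linkage group tied to AC X and
    the gene has at least one ingroup homologue on X's chromosomes.
    Rule 2: the gene is homologous to at least ``min_multi`` distinct
    ingroup genes, all located on chromosomes of X.  Genes satisfying
    neither rule, or whose rules point to different ACs, stay unanchored
    (with the reason recorded).  The hit table is read with the outgroup
    as query (unidirectional, outgroup as reference).
    """
    if min_multi < 1:
        raise ValueError("min_multi must be >= 1")
    lg_to_ac: dict[str, str] = getattr(acs, "lg_to_ac", {})
    chrom_to_acs: dict[tuple[str, str], list[str]] = {}
    for ac, members in acs.groups.items():
        for chrom in members:
            chrom_to_acs.setdefault(chrom, []).append(ac)
    gene_loc: dict[str, tuple[str, str]] = {}
    for sp, g in ingroup_maps.items():
        for gene in g:
            gene_loc[f"{sp}:{gene.gene_id}"] = (sp, gene.chromosome)
    h = _dedup_best(hits)
    h = h[h["evalue"] <= evalue_max]
    og = outgroup_map.species
    h = h[h["qseqid"].str.startswith(og + ":")]
    subj_by_query: dict[str, list[str]] = {}
    for q, s in zip(h["qseqid"], h["sseqid"]):
        if s in gene_loc:
            subj_by_query.setdefault(q, []).append(s)
    anchored: dict[str, list[str]] = {ac: [] for ac in acs.groups}
    provenance: dict[str, str] = {}
    unanchored: dict[str, str] = {}
    for gene in outgroup_map:
        qid = f"{og}:{gene.gene_id}"
        subjects = subj_by_query.get(qid, [])
        hit_acs: dict[str, int] = {}
        for s in subjects:
            for ac in chrom_to_acs.get(gene_loc[s], []):
                hit_acs[ac] = hit_acs.get(ac, 0) + 1
        # rule 1: own linkage group names an AC, confirmed by >=1 ingroup hit
        rule1 = None
        own_ac = lg_to_ac.get(gene.chromosome)
        if own_ac is not None and hit_acs.get(own_ac, 0) >= 1:
            rule1 = own_ac
        # rule 2: >= min_multi distinct ingroup homologues all on one AC
        rule2 = None
        if len(subjects) >= min_multi and len(hit_acs) >= 1:
            top_ac, top_n = sorted(
                hit_acs.items(), key=lambda kv: (-kv[1], kv[0])
            )[0]
            if top_n == len(set(subjects)) and top_n >= min_multi:
                rule2 = top_ac
        if rule1 and rule2 and rule1 != rule2:
            unanchored[gene.gene_id] = f"conflict:{rule1}!={rule2}"
            continue
        target = rule1 or rule2
        if target is None:
            unanchored[gene.gene_id] = "no-rule"
            continue
        anchored[target].append(gene.gene_id)
        provenance[gene.gene_id] = (
            "rule1+rule2" if rule1 and rule2 else ("rule1" if rule1 else "rule2")
        )
    return AncestralChromosomeSet(
        groups=acs.groups,
        anchored_genes=anchored,
        provenance=provenance,
        multi_members=acs.multi_members,
        unanchored=unanchored,
    )
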