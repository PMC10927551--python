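"""Gene-retention profiles, overlapping ratios and ohnolog calling.

The overlapping ratio (OR) between two chromosomes, both putative
descendants of the same ancestral chromosome (AC), is

    OR = |shared retained AC genes| / min(retained_a, retained_b)

where a retention profile is the binary vector recording, per gene
anchored to the AC, whether at least one homologue survives on the query
chromosome.  OR lies in [0, 1], is symmetric, ignores gene order and is
insensitive to chromosome size differences.  Chromosome pairs descending
from a WGD share far more retained genes than pairs produced by fission
plus translocation, so a threshold on OR separates ohnologous from
fission-derived chromosomes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import Gene

__all__ = [
    "RetentionProfile",
    "ORMatrix",
    "AnalysisThresholds",
    "retention_profile",
    "overlapping_ratio",
    "or_matrix",
    "call_ohnologues",
    "multiplicity_per_ac",
    "ward_cluster",
    "assign_orthologs",
    "retention_asymmetry",
    "detect_fusions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisThresholds:
    """The analysis constants, bundled so they are echoed everywhere."""

    or_ohnolog_min: float = 0.15
    min_retained: int = 20
    q_max: float = 0.05
    rbh_evalue_max: float = 1e-6
    anchor_min_multi: int = 5
    tpm_min: float = 5.0
    strong_spec_frac: float = 0.40

    def __post_init__(self) -> None:
        if not 0.0 < self.or_ohnolog_min < 1.0:
            raise ValueError("or_ohnolog_min must be in (0, 1)")
        for name in (
            "min_retained", "q_max", "rbh_evalue_max", "anchor_min_multi",
            "tpm_min", "strong_spec_frac",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class RetentionProfile:
    """Binary retention vector of one query chromosome against an AC gene list."""

    ac_id: str
    species: str
    chromosome: str
    vector: tuple[int, ...]

    @property
    def n_retained(self) -> int:
        return int(sum(self.vector))


@dataclass
class ORMatrix:
    """Symmetric pairwise OR values among an AC's qualifying descendants."""

    ac_id: str
    chromosomes: list[tuple[str, str]]
    values: np.ndarray
    n_retained: dict[tuple[str, str], int]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return len(self.chromosomes) < 2

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{sp}:{c}" for sp, c in self.chromosomes]
        return pd.DataFrame(self.values, index=labels, columns=labels)


def retention_profile(
    ac_genes: Sequence[str],
    chromosome: Iterable[Gene] | Iterable[str],
    family_map: Mapping[str, str] | None = None,
    ac_id: str = "AC",
    species: str = "",
    chrom_name: str = "",
) -> RetentionProfile:
    """Binary retention vector of a chromosome against an ordered AC gene list.

    Position i is 1 iff at least one gene on the chromosome belongs to the
    family of AC gene i; multiplicity is ignored (binary mode).  The
    chromosome may be given as Gene records (families read directly) or as
    gene ids resolved through ``family_map``.
    """
    if not ac_genes:
        raise ValueError("ac_genes must be non-empty")
    fams: set[str] = set()
    for item in chromosome:
        if isinstance(item, Gene):
            fams.add(item.family_id)
            if not species:
                species = item.species
            if not chrom_name:
                chrom_name = item.chromosome
        else:
            if family_map is None:
                raise ValueError("family_map required when passing gene ids")
            fams.add(family_map[item])
    vector = tuple(1 if fam in fams else 0 for fam in ac_genes)
    return RetentionProfile(ac_id, species, chrom_name, vector)


def overlapping_ratio(a: RetentionProfile, b: RetentionProfile) -> float:
    """Shared retained genes over the smaller retained count."""
    if a.ac_id != b.ac_id or len(a.vector) != len(b.vector):
        raise ValueError("profiles must reference the same AC gene list")
    na, nb = a.n_retained, b.n_retained
    if min(na, nb) == 0:
        raise ZeroDivisionError(
            "OR undefined: a profile retains zero genes"
        )
    shared = sum(x & y for x, y in zip(a.vector, b.vector))
    return shared / min(na, nb)


def or_matrix(
    profiles: Sequence[RetentionProfile], min_retained: int = 20
) -> ORMatrix:
    """All pairwise ORs among profiles retaining at least ``min_retained`` genes.

    Chromosomes below the retention floor are excluded (and listed); with
    fewer than two survivors an empty, flagged matrix is returned rather
    than an error.
    """
    if not profiles:
        raise ValueError("no profiles given")
    ac_ids = {p.ac_id for p in profiles}
    if len(ac_ids) != 1:
        raise ValueError(f"profiles span multiple ACs: {sorted(ac_ids)}")
    ac_id = profiles[0].ac_id
    kept = [p for p in profiles if p.n_retained >= min_retained]
    excluded = [
        (p.species, p.chromosome) for p in profiles if p.n_retained < min_retained
    ]
    for sp, c in excluded:
        logger.info("%s: %s:%s excluded (<%d genes retained)", ac_id, sp, c,
                    min_retained)
    chroms = [(p.species, p.chromosome) for p in kept]
    n = len(kept)
    values = np.zeros((n, n))
    vecs = np.array([p.vector for p in kept]) if n else np.zeros((0, 0))
    for i in range(n):
        values[i, i] = 1.0
        for j in range(i + 1, n):
            shared = int(np.sum(vecs[i] & vecs[j]))
            values[i, j] = values[j, i] = shared / min(
                kept[i].n_retained, kept[j].n_retained
            )
    return ORMatrix(
        ac_id,
        chroms,
        values,
        {c: p.n_retained for c, p in zip(chroms, kept)},
        excluded,
    )


def call_ohnologues(
    m: ORMatrix, or_min: float = 0.15
) -> tuple[nx.Graph, list[set], list[set]]:
    """Ohnolog graph (edge iff OR strictly above ``or_min``) and mutual sets.

    Mutually ohnologous sets are reported two ways: connected components
    (the headline, robust to a single stochastically missing edge) and
    maximal cliques; disagreements between the two views are logged.
    """
    g = nx.Graph()
    for c in m.chromosomes:
        g.add_node(c)
    for i, j in itertools.combinations(range(len(m.chromosomes)), 2):
        if m.values[i, j] > or_min:
            g.add_edge(m.chromosomes[i], m.chromosomes[j], OR=float(m.values[i, j]))
    components = sorted(
        (set(c) for c in nx.connected_components(g)), key=lambda s: sorted(s)
    )
    cliques = sorted((set(c) for c in nx.find_cliques(g)), key=lambda s: sorted(s))
    comp_sizes = sorted(map(len, components))
    cliq_sizes = sorted(map(len, cliques))
    if comp_sizes != cliq_sizes:
        logger.info(
            "%s: component sizes %s differ from clique sizes %s",
            m.ac_id, comp_sizes, cliq_sizes,
        )
    return g, components, cliques


def multiplicity_per_ac(
    calls: Mapping[str, tuple[nx.Graph, list[set], list[set]]]
) -> dict[str, int]:
    """Size of the largest mutually ohnologous set per AC.

    Uses the connected-component view; an AC whose qualifying descendants
    form no edges still counts 1 (a lone descendant).
    """
    out: dict[str, int] = {}
    for ac, (g, components, _cliques) in calls.items():
        if components:
            out[ac] = max(len(c) for c in components)
        else:
            out[ac] = 1 if g.number_of_nodes() else 0
    return out


# ---------------------------------------------------------------------------
# Ward clustering (Lance-Williams on raw dissimilarities, 'Ward.D' flavour)
# ---------------------------------------------------------------------------


def ward_cluster(
    m: ORMatrix | np.ndarray,
    labels: Sequence[str] | None = None,
) -> dict:
    """Agglomerative Ward clustering of 1 - OR dissimilarities.

    Implements the Lance-Williams Ward update applied to the *raw*
    dissimilarities (the 'Ward.D' flavour: no squaring), with
    deterministic tie-breaking by label order.  Merge heights are reported
    as computed; with non-Euclidean input, inversions (a merge lower than
    an earlier one) are possible and flagged, never silently repaired.

    Returns a dict with ``merges`` (list of (i, j, height, size) in scipy
    linkage convention), ``labels``, ``newick``, ``inversions`` and a
    ``cut(k)`` callable giving flat cluster labels.
    """
    if isinstance(m, ORMatrix):
        d = 1.0 - m.values
        labels = [f"{sp}:{c}" for sp, c in m.chromosomes]
    else:
        d = np.asarray(m, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(d.shape[0])]
    n = d.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least 2 items")
    d = d.copy()
    np.fill_diagonal(d, np.inf)
    active = {i: (i, 1) for i in range(n)}  # pos -> (cluster id, size)
    order = {i: (labels[i],) for i in range(n)}  # tie-break key per position
    merges: list[tuple[int, int, float, int]] = []
    subtrees = {i: labels[i] for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    next_id = n
    inversions = []
    dm = d
    pos_alive = list(range(n))
    for _step in range(n - 1):
        best = None
        for ii in range(len(pos_alive)):
            for jj in range(ii + 1, len(pos_alive)):
                a, b = pos_alive[ii], pos_alive[jj]
                key = (dm[a, b], min(order[a], order[b]), max(order[a], order[b]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _key, a, b = best
        h = float(dm[a, b])
        ida, sa = active[a]
        idb, sb = active[b]
        if merges and h < merges[-1][2] - 1e-12:
            inversions.append((next_id, h, merges[-1][2]))
        merges.append((min(ida, idb), max(ida, idb), h, sa + sb))
        # Lance-Williams Ward update on the raw dissimilarities
        for c in pos_alive:
            if c in (a, b):
                continue
            sc = active[c][1]
            tot = sa + sb + sc
            dm[a, c] = dm[c, a] = (
                (sa + sc) / tot * dm[a, c]
                + (sb + sc) / tot * dm[b, c]
                - sc / tot * h
            )
        la, lb = subtrees[a], subtrees[b]
        ba = max(h - heights[a], 0.0)
        bb = max(h - heights[b], 0.0)
        subtrees[a] = f"({la}:{ba:.6g},{lb}:{bb:.6g})"
        heights[a] = h
        active[a] = (next_id, sa + sb)
        order[a] = min(order[a], order[b])
        next_id += 1
        pos_alive.remove(b)
    newick = subtrees[pos_alive[0]] + ";"
    for mid, h, prev in inversions:
        logger.info("merge %d height %.4f below previous %.4f (inversion)",
                    mid, h, prev)

    def cut(k: int) -> dict[str, int]:
        """Flat clusters from the last k-1 merges undone."""
        if not 1 <= k <= n:
            raise ValueError("k out of range")
        parent = list(range(2 * n - 1))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for idx, (i, j, _h, _s) in enumerate(merges[: n - k]):
            parent[find(i)] = parent[find(j)] = n + idx
        roots: dict[int, int] = {}
        out = {}
        for leaf in range(n):
            r = find(leaf)
            out[labels[leaf]] = roots.setdefault(r, len(roots))
        return out

    return {
        "labels": list(labels),
        "merges": merges,
        "newick": newick,
        "inversions": inversions,
        "cut": cut,
    }


# ---------------------------------------------------------------------------
# ortholog assignment, asymmetry, fusion detection
# ---------------------------------------------------------------------------


def assign_orthologs(
    inter: pd.DataFrame,
    or_min: float = 0.15,
    ambiguity_rel_tol: float = 0.10,
) -> pd.DataFrame:
    """Classify cross-species chromosome pairings from an OR table.

    ``inter`` is a rectangular frame of OR values (rows: species-A
    chromosomes, columns: species-B chromosomes).  Mutual best pairs above
    ``or_min`` become 1:1 orthologues.  A chromosome whose top two
    partners lie within ``ambiguity_rel_tol`` of each other (both above
    ``or_min``) is flagged as an ambiguous 1:2 (row side) or 2:1 (column
    side) relationship; everything else is unassigned.
    """
    rows = list(inter.index)
    cols = list(inter.columns)
    v = inter.values
    records = []
    best_col = {r: cols[int(np.argmax(v[i]))] for i, r in enumerate(rows)}
    best_row = {c: rows[int(np.argmax(v[:, j]))] for j, c in enumerate(cols)}

    def top_two(vals: np.ndarray) -> tuple[float, float]:
        s = np.sort(vals)[::-1]
        return float(s[0]), float(s[1]) if len(s) > 1 else 0.0

    for i, r in enumerate(rows):
        b = best_col[r]
        top, second = top_two(v[i])
        if top <= or_min:
            records.append((r, None, top, "unassigned"))
        elif (
            second > or_min
            and top > 0
            and (top - second) / top <= ambiguity_rel_tol
        ):
            js = np.argsort(v[i])[::-1][:2]
            partners = ";".join(cols[j] for j in sorted(js))
            records.append((r, partners, top, "1:2"))
        elif best_row[b] == r:
            records.append((r, b, top, "1:1"))
        else:
            records.append((r, b, top, "unassigned"))
    for j, c in enumerate(cols):
        b = best_row[c]
        top, second = top_two(v[:, j])
        if (
            top > or_min
            and second > or_min
            and (top - second) / top <= ambiguity_rel_tol
        ):
            is_ = np.argsort(v[:, j])[::-1][:2]
            partners = ";".join(rows[i] for i in sorted(is_))
            records.append((c, partners, top, "2:1"))
    return pd.DataFrame(
        records, columns=["chromosome", "partner", "best_or", "klass"]
    )


def retention_asymmetry(
    pairs: Sequence[tuple[int, int]],
    groups: Sequence[str] | None = None,
) -> dict:
    """Per-pair retention ratios and a rank-sum comparison between groups.

    The ratio is ``max(nA, nB) / min(nA, nB)`` per ohnologous pair (1.0 =
    perfectly symmetric retention).  With a two-level ``groups`` labelling
    (e.g. post-1R vs post-2R pairs), a two-sided Wilcoxon rank-sum test
    compares the two ratio sets.  Pairs with a zero count are excluded and
    logged.
    """
    ratios, kept_groups = [], []
    for idx, (na, nb) in enumerate(pairs):
        if min(na, nb) == 0:
            logger.info("pair %d excluded (zero retained genes)", idx)
            continue
        ratios.append(max(na, nb) / min(na, nb))
        if groups is not None:
            kept_groups.append(groups[idx])
    out: dict = {"ratios": ratios, "median": float(np.median(ratios)) if ratios else float("nan")}
    if groups is not None and ratios:
        levels = sorted(set(kept_groups))
        out["group_medians"] = {
            lv: float(np.median([r for r, g in zip(ratios, kept_groups) if g == lv]))
            for lv in levels
        }
        if len(levels) == 2:
            x = [r for r, g in zip(ratios, kept_groups) if g == levels[0]]
            y = [r for r, g in zip(ratios, kept_groups) if g == levels[1]]
            stat, p = sps.ranksums(x, y)
            out["ranksum_stat"], out["ranksum_p"] = float(stat), float(p)
    return out


def detect_fusions(
    ac_composition: Mapping[str, Mapping[str, int]],
    min_frag: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Count fusion events from per-chromosome AC gene composition.

    A chromosome carrying at least ``min_frag`` anchored genes from each of
    k >= 2 ACs is a fusion product contributing k - 1 events; the genome
    total is the sum.  Returns (count, per-chromosome detail).
    """
    rows = []
    total = 0
    for chrom in sorted(ac_composition):
        counts = ac_composition[chrom]
        acs = sorted(ac for ac, n in counts.items() if n >= min_frag)
        k = len(acs)
        contribution = max(k - 1, 0)
        total += contribution
        rows.append((chrom, k, ";".join(acs), contribution))
    detail = pd.DataFrame(
        rows, columns=["chromosome", "n_acs", "acs", "fusions"]
    )
    return total, detail
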