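"""Ground-truthed simulation of karyotype evolution under polyploidy.

The generator evolves a proto-karyotype of ancestral chromosomes (ACs)
through whole-genome duplication/triplication (WGD), chromosome fusion and
fission, speciation, and per-gene attrition (loss, translocation,
small-scale duplication).  Every product carries enough bookkeeping to
recover the full truth afterwards:

* chromosome descent — which AC(s) and which WGD copy each extant
  chromosome derives from — is tracked as ordered "zones" of genes;
* gene ancestry is encoded in gene identifiers (one suffix token per WGD
  copy or small-scale duplication), so true gene-family trees can be
  transcribed directly from the identifiers plus the lineage log.

Besides genomes, the module emits the auxiliary inputs the downstream
stages consume: noisy reciprocal similarity tables (BLAST outfmt-6
dialect), true gene-family trees (newick), tissue-expression matrices for
ohnologue pairs with planted fates, and synthetic gene models with
accessible-chromatin intervals planted in known genomic contexts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import Gene, GenomeMap

__all__ = [
    "EvolutionScenario",
    "SimulationResult",
    "make_ancestral_genome",
    "apply_wgd",
    "apply_fusion",
    "apply_fission",
    "apply_attrition",
    "speciate",
    "artificial_split",
    "emit_hit_table",
    "simulate_gene_trees",
    "simulate_expression",
    "simulate_regulatory_landscape",
    "simulate_post1R_fusion_null",
    "run_scenario",
    "ancestral_family_lists",
    "descent_of",
    "empty_chromosomes",
    "backbone_pairing",
    "HIT_COLUMNS",
    "FATES",
]

_COPY_LETTERS = "abc"

HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

FATES = ("redundancy", "subfunctionalization", "strong_spec", "mild_spec")


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# descent bookkeeping
#
# Each chromosome carries a list of "zones" [tag, n]: tag is (ac_id,
# copy_suffix) for a block of genes descending from one AC through a
# specific chain of WGD copies, or None for genes that arrived by
# translocation / small-scale duplication (strays, appended at the end).
# Zones survive fusion (concatenation), fission (split by cumulative gene
# count) and attrition (in-place decrements), so the descent record of any
# extant chromosome is exact.
# ---------------------------------------------------------------------------


def _zones_of(g: GenomeMap) -> dict[str, list[list]]:
    return getattr(g, "zones", None) or {
        c: [[(c, ""), len(genes)]] for c, genes in g.chromosomes.items()
    }


def _set_zones(g: GenomeMap, zones: dict[str, list[list]]) -> GenomeMap:
    g.zones = zones  # type: ignore[attr-defined]
    return g


def descent_of(g: GenomeMap, chrom: str) -> tuple[tuple[str, str], ...]:
    """Ordered, deduplicated (AC id, WGD copy chain) record for a chromosome."""
    out: list[tuple[str, str]] = []
    for tag, n in _zones_of(g)[chrom]:
        if tag is not None and n > 0 and tag not in out:
            out.append(tag)
    return tuple(out)


# ---------------------------------------------------------------------------
# karyotype operators
# ---------------------------------------------------------------------------


def make_ancestral_genome(
    n_chr: int, genes_per_chr: int, seed: int = 0, species: str = "ancestor"
) -> GenomeMap:
    """Build the pre-duplication proto-karyotype.

    Chromosomes are named ``AC01..ACn``; every gene founds its own singleton
    family (``family_id == gene_id``).
    """
    if n_chr < 1 or genes_per_chr < 1:
        raise ValueError("n_chr and genes_per_chr must be positive")
    chroms: dict[str, list[Gene]] = {}
    for k in range(1, n_chr + 1):
        name = f"AC{k:02d}"
        chroms[name] = [
            Gene(f"{name}g{i:04d}", f"{name}g{i:04d}", species, name, i)
            for i in range(genes_per_chr)
        ]
    g = GenomeMap(species, chroms)
    return _set_zones(g, {c: [[(c, ""), genes_per_chr]] for c in chroms})


def ancestral_family_lists(n_chr: int, genes_per_chr: int) -> dict[str, list[str]]:
    """Family identifiers per AC, in ancestral gene order."""
    return {
        f"AC{k:02d}": [f"AC{k:02d}g{i:04d}" for i in range(genes_per_chr)]
        for k in range(1, n_chr + 1)
    }


def apply_wgd(
    g: GenomeMap,
    multiplicity: int = 2,
    mode: str = "auto",
    seed: int = 0,
    allo_extra_loss: float = 0.15,
) -> GenomeMap:
    """Whole-genome duplication (x2) or triplication (x3).

    Every chromosome and every gene copy is replicated ``multiplicity``
    times; copies are tagged with a subgenome letter appended to the
    chromosome name (``~a``, ``~b`` ...) and to the gene identifier.
    ``mode="allo"`` models allopolyploidy phenomenologically: subgenome
    ``b`` (and ``c``) immediately suffers an extra round of gene loss at
    ``allo_extra_loss``, producing the retention asymmetry that
    distinguishes allo- from autopolyploid descendants.
    """
    if multiplicity not in (2, 3):
        raise ValueError("multiplicity must be 2 or 3")
    if mode not in ("auto", "allo"):
        raise ValueError("mode must be 'auto' or 'allo'")
    if len(g) == 0:
        raise ValueError("cannot duplicate an empty genome")
    zones = _zones_of(g)
    new_chroms: dict[str, list[Gene]] = {}
    new_zones: dict[str, list[list]] = {}
    for chrom, genes in g.chromosomes.items():
        for letter in _COPY_LETTERS[:multiplicity]:
            cname = f"{chrom}~{letter}"
            new_chroms[cname] = [
                Gene(f"{x.gene_id}.{letter}", x.family_id, g.species, cname, i)
                for i, x in enumerate(genes)
            ]
            new_zones[cname] = [
                [(tag[0], tag[1] + letter) if tag is not None else None, n]
                for tag, n in zones[chrom]
            ]
    out = _set_zones(GenomeMap(g.species, new_chroms), new_zones)
    if mode == "allo" and allo_extra_loss > 0:
        rng = _rng(seed)
        kept: dict[str, list[Gene]] = {}
        for chrom, genes in out.chromosomes.items():
            letter = chrom.rsplit("~", 1)[1]
            if letter == "a":
                kept[chrom] = genes
                continue
            keep_mask = rng.random(len(genes)) >= allo_extra_loss
            zlist = out.zones[chrom]
            kept[chrom] = _drop_by_mask(genes, keep_mask, zlist)
        out = _set_zones(GenomeMap(g.species, kept), out.zones)
    return out


def _zone_bounds(zlist: list[list]) -> np.ndarray:
    """Cumulative right bounds of the zones, frozen before any decrement."""
    return np.cumsum([n for _tag, n in zlist]) if zlist else np.array([], dtype=int)


def _decrement_zone(zlist: list[list], bounds: np.ndarray, pos: int) -> None:
    """Decrement the zone that held original position ``pos`` (if tracked)."""
    zi = int(np.searchsorted(bounds, pos, side="right"))
    if zi < len(zlist):
        zlist[zi][1] -= 1


def _drop_by_mask(genes: list[Gene], keep: np.ndarray, zlist: list[list]) -> list[Gene]:
    """Drop genes where ``keep`` is False, decrementing their zones in place."""
    bounds = _zone_bounds(zlist)
    out = []
    for pos, (gene, k) in enumerate(zip(genes, keep)):
        if k:
            out.append(gene)
        else:
            _decrement_zone(zlist, bounds, pos)
    return out


def apply_fusion(g: GenomeMap, chr_a: str, chr_b: str) -> GenomeMap:
    """Fuse two chromosomes end-to-end (gene order: A then B)."""
    if chr_a == chr_b:
        raise ValueError("cannot fuse a chromosome with itself")
    if chr_a not in g.chromosomes or chr_b not in g.chromosomes:
        raise KeyError(f"unknown chromosome in fusion: {chr_a!r}, {chr_b!r}")
    zones = _zones_of(g)
    fused = f"{chr_a}+{chr_b}"
    new_chroms: dict[str, list[Gene]] = {}
    new_zones: dict[str, list[list]] = {}
    for chrom, genes in g.chromosomes.items():
        if chrom == chr_a:
            new_chroms[fused] = list(genes) + list(g.chromosomes[chr_b])
            new_zones[fused] = [list(z) for z in zones[chr_a]] + [
                list(z) for z in zones[chr_b]
            ]
        elif chrom == chr_b:
            continue
        else:
            new_chroms[chrom] = genes
            new_zones[chrom] = [list(z) for z in zones[chrom]]
    return _set_zones(GenomeMap(g.species, new_chroms), new_zones)


def apply_fission(g: GenomeMap, chrom: str, breakpoint: int) -> GenomeMap:
    """Split a chromosome into two at ``breakpoint`` genes, preserving order."""
    if chrom not in g.chromosomes:
        raise KeyError(f"unknown chromosome {chrom!r}")
    n = len(g.chromosomes[chrom])
    if not 0 < breakpoint < n:
        raise ValueError(f"breakpoint must be in (0, {n}), got {breakpoint}")
    zones = _zones_of(g)
    new_chroms: dict[str, list[Gene]] = {}
    new_zones: dict[str, list[list]] = {}
    for c, genes in g.chromosomes.items():
        if c != chrom:
            new_chroms[c] = genes
            new_zones[c] = [list(z) for z in zones[c]]
            continue
        left, right = f"{c}:1", f"{c}:2"
        new_chroms[left] = genes[:breakpoint]
        new_chroms[right] = genes[breakpoint:]
        zl, zr, cum = [], [], 0
        for tag, zn in zones[c]:
            lo, hi = cum, cum + zn
            cum = hi
            take_l = max(0, min(hi, breakpoint) - lo)
            take_r = zn - take_l
            if take_l:
                zl.append([tag, take_l])
            if take_r:
                zr.append([tag, take_r])
        new_zones[left], new_zones[right] = zl, zr
    return _set_zones(GenomeMap(g.species, new_chroms), new_zones)


def apply_attrition(
    g: GenomeMap,
    loss_rate: float = 0.0,
    transloc_rate: float = 0.0,
    ssd_rate: float = 0.0,
    seed: int = 0,
    era: int = 0,
) -> GenomeMap:
    """Per-gene stochastic degradation of a genome.

    Each gene is independently deleted with probability ``loss_rate``;
    each survivor independently moves to a uniformly chosen *other*
    chromosome with probability ``transloc_rate`` and, independently, a
    small-scale duplicate (new gene_id, same family) is created with
    probability ``ssd_rate`` — landing 50% of the time on the same
    chromosome and 50% uniformly elsewhere, mirroring the mix of tandem
    and dispersed duplication.  Arriving genes are appended at the end of
    the target chromosome; gene order is irrelevant to every downstream
    statistic.  Chromosomes emptied by loss are retained (flagged via
    :func:`empty_chromosomes`).

    ``era`` stamps small-scale duplicates so that their position in the
    event history (and hence in true gene trees) stays recoverable.
    """
    for name, r in (
        ("loss_rate", loss_rate),
        ("transloc_rate", transloc_rate),
        ("ssd_rate", ssd_rate),
    ):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {r}")
    rng = _rng(seed)
    zones = {c: [list(z) for z in _zones_of(g)[c]] for c in g.chromosomes}
    chrom_names = list(g.chromosomes)
    surviving: dict[str, list[Gene]] = {c: [] for c in chrom_names}
    arrivals: dict[str, list[Gene]] = {c: [] for c in chrom_names}
    ssd_counter = 0
    for chrom in chrom_names:
        genes = g.chromosomes[chrom]
        n = len(genes)
        if n == 0:
            continue
        u_loss = rng.random(n)
        u_move = rng.random(n)
        u_ssd = rng.random(n)
        bounds = _zone_bounds(zones[chrom])
        for pos, gene in enumerate(genes):
            if u_loss[pos] < loss_rate:
                _decrement_zone(zones[chrom], bounds, pos)
                continue
            moved = u_move[pos] < transloc_rate and len(chrom_names) > 1
            if moved:
                others = [c for c in chrom_names if c != chrom]
                dest = others[rng.integers(len(others))]
                arrivals[dest].append(gene)
                _decrement_zone(zones[chrom], bounds, pos)
            else:
                surviving[chrom].append(gene)
            if u_ssd[pos] < ssd_rate:
                if rng.random() < 0.5 or len(chrom_names) == 1:
                    dest = chrom
                else:
                    others = [c for c in chrom_names if c != chrom]
                    dest = others[rng.integers(len(others))]
                new_id = f"{gene.gene_id}.d{era}n{ssd_counter}"
                ssd_counter += 1
                arrivals[dest].append(
                    Gene(new_id, gene.family_id, g.species, dest, 0)
                )
    new_chroms = {c: surviving[c] + arrivals[c] for c in chrom_names}
    # zone decrements above used positions in the original layout, which is
    # exactly how _zone_index interprets them; arrivals fall past the zones
    return _set_zones(GenomeMap(g.species, new_chroms), zones)


def empty_chromosomes(g: GenomeMap) -> list[str]:
    """Chromosomes retained with zero surviving genes."""
    return [c for c, genes in g.chromosomes.items() if not genes]


def speciate(
    g: GenomeMap,
    names: Sequence[str],
    loss_rate: float = 0.0,
    transloc_rate: float = 0.0,
    ssd_rate: float = 0.0,
    seed: int = 0,
    era: int = 0,
) -> list[GenomeMap]:
    """Split one lineage into independently evolving species.

    Each descendant starts as an exact copy of ``g`` and then undergoes its
    own independent round of :func:`apply_attrition`.  Chromosome names are
    preserved, so orthologous chromosomes across the descendants are simply
    the identically named ones.
    """
    if len(names) < 2:
        raise ValueError("speciation needs at least 2 descendant names")
    if len(set(names)) != len(names):
        raise ValueError("species names must be unique")
    master = _rng(seed)
    out = []
    for name in names:
        child = _set_zones(
            g.copy(species=name),
            {c: [list(z) for z in _zones_of(g)[c]] for c in g.chromosomes},
        )
        child = apply_attrition(
            child,
            loss_rate=loss_rate,
            transloc_rate=transloc_rate,
            ssd_rate=ssd_rate,
            seed=int(master.integers(2**31)),
            era=era,
        )
        out.append(child)
    return out


def artificial_split(
    g: GenomeMap, chrom: str, seed: int = 0
) -> tuple[list[Gene], list[Gene]]:
    """Midpoint split of a chromosome into two query halves (floor/ceil).

    This is the fission control: the halves emulate chromosomes produced by
    an ancestral fission rather than by WGD, and their overlapping ratio
    sets the empirical ceiling below which WGD cannot be claimed.  The
    parent genome is not mutated.  ``seed`` is accepted for interface
    symmetry with the stochastic operators; the split point is the
    deterministic midpoint.
    """
    genes = g.chromosomes[chrom]
    if len(genes) < 2:
        raise ValueError("artificial_split needs a chromosome with >= 2 genes")
    mid = len(genes) // 2
    return list(genes[:mid]), list(genes[mid:])


# ---------------------------------------------------------------------------
# similarity hit tables
# ---------------------------------------------------------------------------


def _evalue_from_score(score: np.ndarray) -> np.ndarray:
    return np.minimum(1.0, np.exp(-score / 2.0))


def emit_hit_table(
    genomes: Sequence[GenomeMap],
    score_mu: float = 200.0,
    score_noise_sd: float = 10.0,
    offtarget_rate: float = 0.0,
    seed: int = 0,
    include_within: bool = False,
) -> pd.DataFrame:
    """Simulate an all-vs-all protein-similarity hit table.

    For every cross-genome gene pair sharing a family, two reciprocal rows
    are emitted with a common bit-score drawn from
    Normal(``score_mu``, ``score_noise_sd``); the e-value is the
    deterministic monotone map ``min(1, exp(-score/2))`` (only the ordering
    matters for reciprocal-best-hit detection).  Spurious off-target rows
    join random non-family pairs at ``offtarget_rate`` per true row, with
    scores from a clearly lower distribution.  Gene identifiers are
    qualified as ``species:gene_id``.  Columns follow the 12-column tabular
    (outfmt-6) dialect.
    """
    if len(genomes) < 2 and not include_within:
        raise ValueError("need at least 2 genomes")
    if score_noise_sd < 0:
        raise ValueError("score_noise_sd must be >= 0")
    if not 0.0 <= offtarget_rate <= 1.0:
        raise ValueError("offtarget_rate must be in [0, 1]")
    rng = _rng(seed)
    frames = []
    for g in genomes:
        df = g.to_frame()
        df["qualified"] = g.species + ":" + df["gene_id"]
        frames.append(df[["qualified", "family_id", "species"]])
    pair_rows = []
    n_genomes = len(genomes)
    combos = list(itertools.combinations(range(n_genomes), 2))
    if include_within:
        combos += [(i, i) for i in range(n_genomes)]
    for i, j in combos:
        merged = frames[i].merge(frames[j], on="family_id", suffixes=("_q", "_s"))
        if i == j:
            merged = merged[merged["qualified_q"] < merged["qualified_s"]]
        if len(merged):
            pair_rows.append(merged[["qualified_q", "qualified_s"]])
    if pair_rows:
        pairs = pd.concat(pair_rows, ignore_index=True)
    else:
        pairs = pd.DataFrame(columns=["qualified_q", "qualified_s"])
    scores = rng.normal(score_mu, score_noise_sd, size=len(pairs))
    scores = np.maximum(scores, 1.0)
    rows = pd.concat(
        [
            pd.DataFrame(
                {"qseqid": pairs["qualified_q"], "sseqid": pairs["qualified_s"],
                 "bitscore": scores}
            ),
            pd.DataFrame(
                {"qseqid": pairs["qualified_s"], "sseqid": pairs["qualified_q"],
                 "bitscore": scores}
            ),
        ],
        ignore_index=True,
    )
    # spurious off-target hits between random non-family cross-genome genes
    n_spurious = int(rng.binomial(len(pairs), offtarget_rate)) if len(pairs) else 0
    if n_spurious:
        all_genes = pd.concat(frames, ignore_index=True)
        qi = rng.integers(len(all_genes), size=3 * n_spurious)
        si = rng.integers(len(all_genes), size=3 * n_spurious)
        q = all_genes.iloc[qi].reset_index(drop=True)
        s = all_genes.iloc[si].reset_index(drop=True)
        ok = (q["family_id"].values != s["family_id"].values) & (
            q["species"].values != s["species"].values
        )
        q, s = q[ok][:n_spurious], s[ok][:n_spurious]
        sp_scores = np.maximum(
            rng.normal(score_mu / 3.0, score_noise_sd, size=len(q)), 1.0
        )
        rows = pd.concat(
            [
                rows,
                pd.DataFrame(
                    {"qseqid": q["qualified"].values,
                     "sseqid": s["qualified"].values,
                     "bitscore": sp_scores}
                ),
            ],
            ignore_index=True,
        )
    n = len(rows)
    rows["pident"] = np.clip(rows["bitscore"] / score_mu * 90.0, 10.0, 100.0).round(2)
    rows["length"] = 200
    rows["mismatch"] = (200 * (1 - rows["pident"] / 100)).astype(int)
    rows["gapopen"] = 0
    rows["qstart"] = 1
    rows["qend"] = 200
    rows["sstart"] = 1
    rows["send"] = 200
    rows["evalue"] = _evalue_from_score(rows["bitscore"].values)
    rows["bitscore"] = rows["bitscore"].round(1)
    return rows[HIT_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# scenario driver
# ---------------------------------------------------------------------------


@dataclass
class EvolutionScenario:
    """A declarative karyotype-evolution history.

    ``events`` is an ordered list of dicts applied to the main lineage:

    - ``{"type": "wgd", "multiplicity": 2|3, "mode": "auto"|"allo"}``
    - ``{"type": "fusion", "a": chrom, "b": chrom}``
    - ``{"type": "fusions", "n": int}`` — n random disjoint fusions
    - ``{"type": "fission", "chromosome": chrom, "breakpoint": int}``
    - ``{"type": "attrition", "loss_rate": p, "transloc_rate": p, "ssd_rate": p}``
    - ``{"type": "branch", "name": str, ...rates}`` — a side lineage splits
      off (receives its own attrition); the main lineage continues
    - ``{"type": "speciate", "names": [...], ...rates}`` — terminal split of
      the main lineage into named species
    """

    n_ancestral_chromosomes: int
    genes_per_chromosome: int
    events: list[dict] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ancestral_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValueError("karyotype dimensions must be positive")
        for ev in self.events:
            t = ev.get("type")
            if t not in {
                "wgd", "fusion", "fusions", "fission", "attrition", "branch",
                "speciate",
            }:
                raise ValueError(f"unknown event type {t!r}")
            if t == "wgd" and ev.get("multiplicity", 2) not in (2, 3):
                raise ValueError("wgd multiplicity must be 2 or 3")
            for key in ("loss_rate", "transloc_rate", "ssd_rate"):
                if key in ev and not 0.0 <= ev[key] <= 1.0:
                    raise ValueError(f"{key} must be in [0, 1]")


@dataclass
class SimulationResult:
    """Genomes plus the truth needed to verify downstream inference.

    ``lineages`` maps each species to its chronological event history: a
    tuple of tokens ``("W", era, multiplicity)`` for WGDs the lineage lived
    through and ``("S", era, species_or_branch)`` for splits, used to
    transcribe true gene trees.
    """

    scenario: EvolutionScenario
    genomes: dict[str, GenomeMap]
    lineages: dict[str, tuple]
    event_log: list[str] = field(default_factory=list)

    def descent(self, species: str, chrom: str) -> tuple[tuple[str, str], ...]:
        return descent_of(self.genomes[species], chrom)

    def ac_families(self) -> dict[str, list[str]]:
        return ancestral_family_lists(
            self.scenario.n_ancestral_chromosomes,
            self.scenario.genes_per_chromosome,
        )

    def true_ohnolog_pairs(self, species: str) -> list[tuple[str, str]]:
        """Within-species chromosome pairs sharing an AC via different WGD copies."""
        g = self.genomes[species]
        by_ac: dict[str, list[tuple[str, str]]] = {}
        for chrom in g.chromosomes:
            for ac, copies in descent_of(g, chrom):
                by_ac.setdefault(ac, []).append((chrom, copies))
        pairs = set()
        for ac, members in by_ac.items():
            for (c1, k1), (c2, k2) in itertools.combinations(members, 2):
                if c1 != c2 and k1 != k2:
                    pairs.add(tuple(sorted((c1, c2))))
        return sorted(pairs)

    def backbone_pairing(self, species: str, ac: str) -> dict[str, set[str]]:
        return backbone_pairing(self, species, ac)

    def true_ortholog_pairs(self, sp_a: str, sp_b: str) -> list[tuple[str, str]]:
        """Cross-species chromosome pairs descending from the same parent chromosome."""
        a = set(self.genomes[sp_a].chromosomes)
        b = set(self.genomes[sp_b].chromosomes)
        return sorted((c, c) for c in a & b)


def run_scenario(scenario: EvolutionScenario) -> SimulationResult:
    """Execute an :class:`EvolutionScenario` and collect ground truth."""
    master = _rng(scenario.seed)
    g = make_ancestral_genome(
        scenario.n_ancestral_chromosomes, scenario.genes_per_chromosome
    )
    genomes: dict[str, GenomeMap] = {}
    lineages: dict[str, tuple] = {}
    main_lineage: list[tuple] = []
    log: list[str] = []
    for era, ev in enumerate(scenario.events):
        t = ev["type"]
        seed = int(master.integers(2**31))
        if t == "wgd":
            mult = ev.get("multiplicity", 2)
            g = apply_wgd(g, mult, ev.get("mode", "auto"), seed=seed)
            main_lineage.append(("W", era, mult))
            log.append(f"era {era}: wgd x{mult} ({ev.get('mode', 'auto')})")
        elif t == "fusion":
            g = apply_fusion(g, ev["a"], ev["b"])
            log.append(f"era {era}: fusion {ev['a']}+{ev['b']}")
        elif t == "fusions":
            rng = _rng(seed)
            n = ev["n"]
            # random disjoint fusions between chromosomes of distinct AC
            # origin (fusing two copies of the same AC would mimic
            # rediploidization, not an inter-chromosomal fusion)
            for k in range(n):
                chroms = [c for c in g.chromosomes if g.chromosomes[c]]
                acs_of = {c: {ac for ac, _ in descent_of(g, c)} for c in chroms}
                candidates = [
                    (a, b)
                    for i, a in enumerate(chroms)
                    for b in chroms[i + 1:]
                    if not (acs_of[a] & acs_of[b])
                ]
                if not candidates:
                    raise ValueError("no distinct-AC chromosome pair left to fuse")
                a, b = candidates[rng.integers(len(candidates))]
                g = apply_fusion(g, a, b)
                log.append(f"era {era}: fusion {a}+{b}")
        elif t == "fission":
            g = apply_fission(g, ev["chromosome"], ev["breakpoint"])
            log.append(f"era {era}: fission {ev['chromosome']}@{ev['breakpoint']}")
        elif t == "attrition":
            g = apply_attrition(
                g,
                ev.get("loss_rate", 0.0),
                ev.get("transloc_rate", 0.0),
                ev.get("ssd_rate", 0.0),
                seed=seed,
                era=era,
            )
            log.append(f"era {era}: attrition on main lineage")
        elif t == "branch":
            name = ev["name"]
            side = _set_zones(
                g.copy(species=name),
                {c: [list(z) for z in _zones_of(g)[c]] for c in g.chromosomes},
            )
            side = apply_attrition(
                side,
                ev.get("loss_rate", 0.0),
                ev.get("transloc_rate", 0.0),
                ev.get("ssd_rate", 0.0),
                seed=seed,
                era=era,
            )
            genomes[name] = side
            lineages[name] = tuple(main_lineage + [("S", era, name)])
            main_lineage.append(("S", era, "__main__"))
            log.append(f"era {era}: branch {name}")
        elif t == "speciate":
            names = ev["names"]
            children = speciate(
                g,
                names,
                ev.get("loss_rate", 0.0),
                ev.get("transloc_rate", 0.0),
                ev.get("ssd_rate", 0.0),
                seed=seed,
                era=era,
            )
            for name, child in zip(names, children):
                genomes[name] = child
                lineages[name] = tuple(main_lineage + [("S", era, name)])
            log.append(f"era {era}: speciation into {', '.join(names)}")
            g = None  # type: ignore[assignment]
            break
    if g is not None:
        genomes["__main__"] = g
        lineages["__main__"] = tuple(main_lineage)
    return SimulationResult(scenario, genomes, lineages, log)


_GROUP_OF_COPY = {"aa": "A", "ab": "B", "ba": "C", "bb": "D"}


def backbone_pairing(
    result: "SimulationResult", species: str, ac: str
) -> dict[str, set[str]]:
    """Expected post-2R chromosome groups A-D of one AC for a reference species.

    Assumes the lineage of ``species`` passed through two x2 WGDs: groups
    A/B are the two second-WGD copies of the first WGD's 'a' subgenome,
    C/D of the 'b' subgenome, so the expected backbone is ((A,B),(C,D)).
    Fusion products appear in the group of each AC segment they carry.
    """
    pairing: dict[str, set[str]] = {"A": set(), "B": set(), "C": set(), "D": set()}
    g = result.genomes[species]
    for chrom in g.chromosomes:
        for seg_ac, copies in descent_of(g, chrom):
            if seg_ac == ac and len(copies) >= 2:
                letter = _GROUP_OF_COPY.get(copies[:2])
                if letter:
                    pairing[letter].add(chrom)
    return pairing


# ---------------------------------------------------------------------------
# true gene trees
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("children", "leaves")

    def __init__(self) -> None:
        self.children: dict = {}
        self.leaves: list[str] = []


def _gene_tokens(gene_id: str, lineage: tuple) -> list[tuple]:
    """Chronological divergence tokens for one extant gene copy.

    WGD copy letters in the gene identifier are consumed in the order of the
    lineage's WGD events; small-scale-duplication suffixes carry their own
    era stamp; speciation tokens come from the lineage itself.
    """
    suffix = gene_id.split(".")[1:]
    wgd_letters = [s for s in suffix if len(s) == 1]
    ssd_tokens = []
    for s in suffix:
        if s.startswith("d"):
            era_s, _, k = s[1:].partition("n")
            ssd_tokens.append((int(era_s), ("D", int(era_s), int(k))))
    events = []
    wi = 0
    for token in lineage:
        if token[0] == "W":
            events.append((token[1], ("W", token[1], wgd_letters[wi])))
            wi += 1
        else:
            events.append((token[1], token))
    events.extend(ssd_tokens)
    events.sort(key=lambda x: x[0])
    return [tok for _era, tok in events]


def simulate_gene_trees(
    truth: SimulationResult,
    families: Iterable[str] | None = None,
    seed: int = 0,
    error_rate: float = 0.0,
) -> dict[str, str]:
    """Transcribe true gene-family topologies into rooted newick strings.

    For each family, extant copies across all simulated genomes are grouped
    by their recorded divergence history (speciations, WGD copies,
    small-scale duplications), yielding the true rooted topology with
    leaves labelled ``species|gene_id|chromosome``.  With probability
    ``error_rate`` a single random NNI (nearest-neighbour interchange) is
    applied to a tree, emulating gene-tree estimation error.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    rng = _rng(seed)
    wanted = set(families) if families is not None else None
    leaves_by_family: dict[str, list[tuple[list[tuple], str]]] = {}
    for species, g in truth.genomes.items():
        lineage = truth.lineages[species]
        for gene in g:
            if wanted is not None and gene.family_id not in wanted:
                continue
            label = f"{species}|{gene.gene_id}|{gene.chromosome}"
            leaves_by_family.setdefault(gene.family_id, []).append(
                (_gene_tokens(gene.gene_id, lineage), label)
            )
    if wanted is not None:
        missing = wanted - set(leaves_by_family)
        if missing:
            raise KeyError(f"families absent from simulation: {sorted(missing)}")
    trees: dict[str, str] = {}
    for fam in sorted(leaves_by_family):
        root = _Node()
        for tokens, label in leaves_by_family[fam]:
            node = root
            for tok in tokens:
                node = node.children.setdefault(tok, _Node())
            node.leaves.append(label)
        nested = _to_nested(root)
        if nested is None:
            continue
        if error_rate > 0 and rng.random() < error_rate:
            nested = _random_nni(nested, rng)
        trees[fam] = _to_newick(nested) + ";"
    return trees


def _to_nested(node: _Node):
    """Collapse the token trie into nested lists (leaf = str), dropping unary nodes."""
    parts = list(node.leaves)
    for child in node.children.values():
        sub = _to_nested(child)
        if sub is not None:
            parts.append(sub)
    if not parts:
        return None
    if len(parts) == 1:
        return parts[0]
    return parts


def _to_newick(nested) -> str:
    if isinstance(nested, str):
        return nested
    return "(" + ",".join(_to_newick(p) for p in nested) + ")"


def _random_nni(nested, rng: np.random.Generator):
    """One random nearest-neighbour interchange on a nested-list topology."""
    internal_edges = []

    def walk(node, path):
        if isinstance(node, str):
            return
        for i, child in enumerate(node):
            if not isinstance(child, str) and len(path) + 1 > 1:
                internal_edges.append(path + (i,))
            walk(child, path + (i,))

    walk(nested, ())
    internal_edges = [p for p in internal_edges if len(p) >= 1]
    if not internal_edges:
        return nested
    target = internal_edges[rng.integers(len(internal_edges))]

    def get(node, path):
        for i in path:
            node = node[i]
        return node

    parent = get(nested, target[:-1])
    child = parent[target[-1]]
    siblings = [i for i in range(len(parent)) if i != target[-1]]
    if not siblings or isinstance(child, str) or len(child) < 2:
        return nested
    si = siblings[rng.integers(len(siblings))]
    ci = rng.integers(len(child))
    # swap one grandchild with one sibling of its parent
    parent[si], child[ci] = child[ci], parent[si]
    return nested


# ---------------------------------------------------------------------------
# expression fates
# ---------------------------------------------------------------------------


def simulate_expression(
    n_pairs: int,
    fate_mix: dict[str, float],
    tissues: Sequence[str],
    tpm_hi: float = 50.0,
    tpm_lo: float = 0.5,
    tpm_threshold: float = 5.0,
    noise_sd: float = 0.0,
    strong_frac: float = 0.40,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a TPM matrix for ohnologue pairs with planted expression fates.

    Each pair draws a fate from ``fate_mix`` (over ``redundancy``,
    ``subfunctionalization``, ``strong_spec``, ``mild_spec``); tissue
    domain sets realizing that fate exactly are constructed, then TPM
    values are ``tpm_hi`` in-domain and ``tpm_lo`` elsewhere, with a
    multiplicative noise factor bounded so it can never cross
    ``tpm_threshold``.  Returns (matrix genes x tissues, truth table).
    """
    tissues = list(tissues)
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    if n_pairs < 1:
        raise ValueError("n_pairs must be positive")
    if set(fate_mix) - set(FATES):
        raise ValueError(f"unknown fates in mix: {set(fate_mix) - set(FATES)}")
    total = sum(fate_mix.values())
    if not np.isclose(total, 1.0):
        raise ValueError("fate_mix proportions must sum to 1")
    if not tpm_lo < tpm_threshold < tpm_hi:
        raise ValueError("need tpm_lo < tpm_threshold < tpm_hi")
    f_lo, f_hi = 0.5, 2.0  # noise factor bounds
    if tpm_lo * f_hi >= tpm_threshold or tpm_hi * f_lo <= tpm_threshold:
        raise ValueError("noise bounds would let TPM cross the threshold")
    rng = _rng(seed)
    T = len(tissues)
    fates = list(fate_mix)
    probs = np.array([fate_mix[f] for f in fates])
    draw = rng.choice(len(fates), size=n_pairs, p=probs)

    def pick(k: int) -> set[int]:
        return set(rng.choice(T, size=k, replace=False).tolist())

    rows, truth_rows = [], []
    for i in range(n_pairs):
        fate = fates[draw[i]]
        if fate == "redundancy":
            dom_a = dom_b = pick(int(rng.integers(1, T + 1)))
        elif fate == "subfunctionalization":
            sh = int(rng.integers(0, T - 1))
            rem = T - sh
            ea = int(rng.integers(1, rem))
            eb = int(rng.integers(1, rem - ea + 1))
            chosen = list(rng.choice(T, size=sh + ea + eb, replace=False))
            shared = set(chosen[:sh])
            dom_a = shared | set(chosen[sh:sh + ea])
            dom_b = shared | set(chosen[sh + ea:])
        else:
            if fate == "strong_spec":
                sizes = [
                    (a, b)
                    for b in range(2, T + 1)
                    for a in range(1, b)
                    if a / b < strong_frac
                ]
            else:
                sizes = [
                    (a, b)
                    for b in range(2, T + 1)
                    for a in range(1, b)
                    if a / b >= strong_frac
                ]
            if not sizes:
                raise ValueError(
                    f"no valid domain sizes for fate {fate!r} with {T} tissues"
                )
            a, b = sizes[rng.integers(len(sizes))]
            broad = pick(b)
            narrow = set(
                rng.choice(sorted(broad), size=a, replace=False).tolist()
            )
            if rng.random() < 0.5:
                dom_a, dom_b = narrow, broad
            else:
                dom_a, dom_b = broad, narrow
        pid = f"pair{i:04d}"
        for suffix, dom in (("a", dom_a), ("b", dom_b)):
            tpm = np.full(T, tpm_lo)
            tpm[sorted(dom)] = tpm_hi
            if noise_sd > 0:
                factor = np.clip(
                    np.exp(rng.normal(0.0, noise_sd, size=T)), f_lo, f_hi
                )
                tpm = tpm * factor
            rows.append(pd.Series(tpm, index=tissues, name=f"{pid}_{suffix}"))
        truth_rows.append(
            {
                "pair_id": pid,
                "gene_a": f"{pid}_a",
                "gene_b": f"{pid}_b",
                "fate": fate,
                "domains_a": ";".join(tissues[t] for t in sorted(dom_a)),
                "domains_b": ";".join(tissues[t] for t in sorted(dom_b)),
            }
        )
    matrix = pd.DataFrame(rows)
    matrix.columns.name = "tissue"
    return matrix, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# regulatory landscape
# ---------------------------------------------------------------------------


def simulate_regulatory_landscape(
    genes_per_chr: int,
    acr_rate_per_gene: float = 3.0,
    distal_fraction: float = 0.25,
    seed: int = 0,
    chrom: str = "chrS1",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic gene models plus ACR intervals planted in known contexts.

    Genes are laid out every 50 kb (10-kb bodies, three exons, random
    strand) on one synthetic chromosome; each gene receives
    Poisson(``acr_rate_per_gene``) accessible-chromatin regions, each
    planted unambiguously in one category: ``distal`` with probability
    ``distal_fraction``, otherwise uniformly promoter / proximal / exonic.
    Returns ``(acrs, gene_models)``: ACRs as 0-based half-open intervals
    with truth columns, gene models as a tidy frame (gene and exon
    features, 0-based half-open).
    """
    if genes_per_chr < 1:
        raise ValueError("genes_per_chr must be positive")
    if acr_rate_per_gene < 0:
        raise ValueError("acr_rate_per_gene must be non-negative")
    if not 0.0 <= distal_fraction <= 1.0:
        raise ValueError("distal_fraction must be in [0, 1]")
    rng = _rng(seed)
    spacing, body = 50_000, 10_000
    gene_rows, acr_rows = [], []
    width = 200
    acr_idx = 0
    for i in range(genes_per_chr):
        start = i * spacing + 20_000
        end = start + body
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"sg{i:04d}"
        tss = start if strand == "+" else end - 1
        sgn = 1 if strand == "+" else -1
        gene_rows.append((gid, chrom, start, end, strand, "gene"))
        # exons at gene-local offsets 0-1k, 6-7k, 9-10k from the TSS
        for off_lo, off_hi in ((0, 1000), (6000, 7000), (9000, 10000)):
            if strand == "+":
                ex = (start + off_lo, start + off_hi)
            else:
                ex = (end - off_hi, end - off_lo)
            gene_rows.append((gid, chrom, ex[0], ex[1], strand, "exon"))
        n_acr = int(rng.poisson(acr_rate_per_gene))
        for _ in range(n_acr):
            if rng.random() < distal_fraction:
                category = "distal"
                center = i * spacing + 40_000 + int(rng.integers(-3000, 3001))
            else:
                category = ("promoter", "proximal", "exonic")[int(rng.integers(3))]
                if category == "promoter":
                    off = int(rng.integers(-800, 301))
                elif category == "proximal":
                    off = -int(rng.integers(1200, 4801))
                else:  # middle exon, outside the proximal window
                    off = int(rng.integers(6200, 6801))
                center = tss + sgn * off
            acr_rows.append(
                {
                    "chrom": chrom,
                    "start": center - width // 2,
                    "end": center + width // 2,
                    "name": f"acr{acr_idx:05d}",
                    "truth_category": category,
                    "truth_gene": gid,
                }
            )
            acr_idx += 1
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "feature"]
    )
    acrs = pd.DataFrame(
        acr_rows,
        columns=["chrom", "start", "end", "name", "truth_category", "truth_gene"],
    )
    return acrs, genes


# ---------------------------------------------------------------------------
# post-1R pairwise-fusion null
# ---------------------------------------------------------------------------


def simulate_post1R_fusion_null(
    n_ac: int, n_fusions: int, reps: int = 10_000, seed: int = 0
) -> float:
    """Monte-Carlo null for "mirror" post-1R fusion pairs.

    After a single WGD, each of ``n_ac`` pre-duplication chromosomes exists
    in two copies.  Each replicate draws ``n_fusions`` random disjoint
    fusions (a random partial matching of the ``2*n_ac`` chromosomes; fused
    products do not fuse again).  A replicate succeeds if at least one
    *mirror pair* occurs: two fusions that join the two WGD copies of the
    same two pre-duplication chromosomes — the configuration that would
    mimic a single pre-WGD fusion.  Returns the success fraction.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if n_fusions < 0 or n_fusions > n_ac:
        raise ValueError("need 0 <= n_fusions <= n_ac")
    if n_fusions == 0:
        return 0.0
    rng = _rng(seed)
    n_chr = 2 * n_ac
    hits = 0
    acs = np.arange(n_chr) // 2
    for _ in range(reps):
        chosen = rng.permutation(n_chr)[: 2 * n_fusions]
        keys: dict[tuple[int, int], int] = {}
        success = False
        for k in range(n_fusions):
            i, j = acs[chosen[2 * k]], acs[chosen[2 * k + 1]]
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            keys[key] = keys.get(key, 0) + 1
            if keys[key] == 2:
                success = True
                break
        hits += success
    return hits / reps
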