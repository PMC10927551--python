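"""End-to-end orchestration: simulate -> reconstruct ACs -> OR analysis.

The pipeline ties the stages together through declared artifacts (TSV
tables on disk) and a machine-readable JSON summary.  Reruns with the
same configuration and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .genome import GenomeMap
from .homology import (
    AncestralChromosomeSet,
    anchor_outgroup_genes,
    best_hits,
    group_ancestral_chromosomes,
    homologous_chromosome_graph,
    outgroup_linkage_from_stats,
    pair_enrichment,
    reciprocal_best_hits,
)
from .retention import (
    AnalysisThresholds,
    call_ohnologues,
    multiplicity_per_ac,
    or_matrix,
    overlapping_ratio,
    retention_profile,
    ward_cluster,
)
from .simulate import (
    EvolutionScenario,
    artificial_split,
    backbone_pairing,
    emit_hit_table,
    run_scenario,
    simulate_expression,
    simulate_gene_trees,
)
from .treecompat import classify_test_genes, label_backbone, tally_support
from .fates import classify_pairs

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]

_KNOWN_KEYS = {
    "scenario", "ingroup", "outgroup", "outdir", "seed", "log_level",
    "thresholds", "with_trees", "with_fates", "n_tree_families",
    "test_species", "tree_outgroup", "n_expression_pairs", "tissues",
    "fate_mix",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``scenario`` is an :class:`EvolutionScenario` dict; ``ingroup`` names
    the two genomes used for reconstruction and ``outgroup`` the
    unduplicated genome anchoring the AC groups.  Unknown keys in a YAML
    config are rejected.
    """

    scenario: dict
    ingroup: list[str]
    outgroup: str
    outdir: str
    seed: int = 0
    log_level: str = "INFO"
    thresholds: AnalysisThresholds = field(default_factory=AnalysisThresholds)
    with_trees: bool = False
    with_fates: bool = False
    n_tree_families: int = 40
    test_species: list[str] = field(default_factory=list)
    tree_outgroup: str = ""
    n_expression_pairs: int = 200
    tissues: list[str] = field(
        default_factory=lambda: [
            "brain", "gill", "heart", "gut", "liver", "muscle", "skin",
            "gonad", "kidney",
        ]
    )
    fate_mix: dict = field(
        default_factory=lambda: {
            "redundancy": 0.30, "subfunctionalization": 0.35,
            "strong_spec": 0.20, "mild_spec": 0.15,
        }
    )

    def __post_init__(self) -> None:
        if len(self.ingroup) != 2:
            raise ValueError("ingroup must name exactly two genomes")
        if isinstance(self.thresholds, dict):
            self.thresholds = AnalysisThresholds(**self.thresholds)
        EvolutionScenario(**self.scenario)  # validates

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)


def demo_config(outdir, seed: int = 0) -> PipelineConfig:
    """A small, fast two-WGD demo history with an unduplicated outgroup."""
    scenario = {
        "n_ancestral_chromosomes": 6,
        "genes_per_chromosome": 80,
        "seed": seed,
        "events": [
            {"type": "branch", "name": "echino", "loss_rate": 0.05},
            {"type": "branch", "name": "basal", "loss_rate": 0.1},
            {"type": "wgd", "multiplicity": 2, "mode": "auto"},
            {"type": "attrition", "loss_rate": 0.15},
            {"type": "branch", "name": "cyclo", "loss_rate": 0.25},
            {"type": "fusions", "n": 2},
            {"type": "wgd", "multiplicity": 2, "mode": "auto"},
            # rediploidization precedes speciation: ohnologues diverge in the
            # common ancestor, orthologues only after the split
            {"type": "attrition", "loss_rate": 0.25},
            {"type": "speciate", "names": ["gar", "chicken"],
             "loss_rate": 0.08, "transloc_rate": 0.01, "ssd_rate": 0.01},
        ],
    }
    return PipelineConfig(
        scenario=scenario,
        ingroup=["gar", "chicken"],
        outgroup="echino",
        outdir=str(outdir),
        seed=seed,
        with_trees=True,
        with_fates=True,
        test_species=["cyclo"],
        tree_outgroup="basal",
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def reconstruct_acs(
    maps: dict[str, GenomeMap],
    hits: pd.DataFrame,
    ingroup: list[str],
    outgroup: str,
    thresholds: AnalysisThresholds,
) -> tuple[AncestralChromosomeSet, list]:
    """Reciprocal-best-hit homology -> enrichment -> AC groups -> anchoring."""
    sp_a, sp_b = ingroup
    pref = {sp: f"{sp}:" for sp in maps}

    def between(df, x, y):
        return df[
            df["qseqid"].str.startswith(pref[x]) & df["sseqid"].str.startswith(pref[y])
        ]

    ingroup_hits = pd.concat(
        [between(hits, sp_a, sp_b), between(hits, sp_b, sp_a)], ignore_index=True
    )
    rbh = reciprocal_best_hits(ingroup_hits, thresholds.rbh_evalue_max)
    # outgroup as reference: unidirectional best hit per outgroup gene
    pairs = set(rbh)
    for sp in ingroup:
        og_hits = between(hits, outgroup, sp)
        bh = best_hits(og_hits, thresholds.rbh_evalue_max)
        pairs |= {
            (q, s) if q <= s else (s, q) for q, s in zip(bh["qseqid"], bh["sseqid"])
        }
    stats = pair_enrichment(pairs, maps, thresholds.q_max)
    graph = homologous_chromosome_graph(stats, thresholds.q_max)
    ingroup_graph = graph.subgraph(
        [n for n in graph if n[0] in ingroup]
    ).copy()
    linkage = outgroup_linkage_from_stats(stats, outgroup, thresholds.q_max)
    acs = group_ancestral_chromosomes(ingroup_graph, linkage)
    acs = anchor_outgroup_genes(
        acs,
        maps[outgroup],
        hits,
        {sp: maps[sp] for sp in ingroup},
        min_multi=thresholds.anchor_min_multi,
        evalue_max=thresholds.rbh_evalue_max,
    )
    return acs, stats


def or_analysis(
    maps: dict[str, GenomeMap],
    acs: AncestralChromosomeSet,
    outgroup_map: GenomeMap,
    thresholds: AnalysisThresholds,
    species: list[str],
) -> dict:
    """Retention profiles, OR matrices, ohnolog calls and ortholog map."""
    fam_of = {g.gene_id: g.family_id for g in outgroup_map}
    ac_fams = {
        ac: [fam_of[gid] for gid in gids]
        for ac, gids in acs.anchored_genes.items()
        if gids
    }
    member_chroms: dict[str, dict[str, list[str]]] = {}
    for ac, members in acs.groups.items():
        for sp, chrom in members:
            member_chroms.setdefault(ac, {}).setdefault(sp, []).append(chrom)
    results: dict = {
        "per_ac": {}, "ohnolog_or": {sp: [] for sp in species},
        "ortholog_or": [], "orthology_classes": {},
        "multiplicity": {sp: {} for sp in species},
    }
    class_counts: dict[str, int] = {}
    for ac in sorted(ac_fams):
        fams = ac_fams[ac]
        profiles_by_sp = {}
        for sp in species:
            profs = []
            for chrom in sorted(member_chroms.get(ac, {}).get(sp, [])):
                profs.append(
                    retention_profile(
                        fams, maps[sp].genes_on(chrom), ac_id=ac,
                        species=sp, chrom_name=chrom,
                    )
                )
            profiles_by_sp[sp] = profs
        per_sp = {}
        for sp in species:
            if not profiles_by_sp[sp]:
                continue
            m = or_matrix(profiles_by_sp[sp], thresholds.min_retained)
            graph, components, cliques = call_ohnologues(
                m, thresholds.or_ohnolog_min
            )
            for _u, _v, data in graph.edges(data=True):
                results["ohnolog_or"][sp].append(data["OR"])
            mult = multiplicity_per_ac({ac: (graph, components, cliques)})[ac]
            results["multiplicity"][sp][ac] = mult
            per_sp[sp] = {
                "matrix": m,
                "dendrogram": ward_cluster(m) if len(m.chromosomes) >= 2 else None,
            }
        # cross-species OR for orthology
        sp_a, sp_b = species[0], species[-1]
        pa = [p for p in profiles_by_sp.get(sp_a, [])
              if p.n_retained >= thresholds.min_retained]
        pb = [p for p in profiles_by_sp.get(sp_b, [])
              if p.n_retained >= thresholds.min_retained]
        if pa and pb and sp_a != sp_b:
            inter = pd.DataFrame(
                [[overlapping_ratio(x, y) for y in pb] for x in pa],
                index=[x.chromosome for x in pa],
                columns=[y.chromosome for y in pb],
            )
            from .retention import assign_orthologs

            omap = assign_orthologs(inter, thresholds.or_ohnolog_min)
            for row in omap.itertuples(index=False):
                class_counts[row.klass] = class_counts.get(row.klass, 0) + 1
                if row.klass == "1:1":
                    results["ortholog_or"].append(row.best_or)
            per_sp["ortholog_map"] = omap
        results["per_ac"][ac] = per_sp
    results["orthology_classes"] = class_counts
    return results


def fission_control(
    maps: dict[str, GenomeMap],
    acs: AncestralChromosomeSet,
    outgroup_map: GenomeMap,
    thresholds: AnalysisThresholds,
    species: list[str],
    seed: int = 0,
) -> float:
    """Max OR between artificial midpoint halves across chromosomes."""
    fam_of = {g.gene_id: g.family_id for g in outgroup_map}
    chrom_acs: dict[tuple[str, str], list[str]] = {}
    for ac, members in acs.groups.items():
        for m in members:
            chrom_acs.setdefault(m, []).append(ac)
    best = 0.0
    for sp in species:
        g = maps[sp]
        for chrom in sorted(g.chromosomes):
            if len(g.chromosomes[chrom]) < 2 * thresholds.min_retained:
                continue
            for ac in chrom_acs.get((sp, chrom), []):
                fams = [fam_of[gid] for gid in acs.anchored_genes.get(ac, [])]
                if not fams:
                    continue
                left, right = artificial_split(g, chrom, seed)
                p1 = retention_profile(fams, left, ac_id=ac)
                p2 = retention_profile(fams, right, ac_id=ac)
                if (
                    min(p1.n_retained, p2.n_retained) >= thresholds.min_retained
                ):
                    best = max(best, overlapping_ratio(p1, p2))
    return best


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def _quantiles(values: list[float]) -> dict:
    if not values:
        return {"n": 0, "median": None, "iqr": None}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "n": len(values),
        "median": round(float(med), 4),
        "iqr": [round(float(q1), 4), round(float(q3), 4)],
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all configured stages and write artifacts plus a summary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    thresholds = cfg.thresholds
    log_lines = [
        f"seed={cfg.seed}",
        "thresholds="
        + ",".join(
            f"{k}={v}" for k, v in dataclasses.asdict(thresholds).items()
        ),
    ]
    # stage: simulate
    scenario = EvolutionScenario(**{**cfg.scenario, "seed": cfg.scenario.get("seed", cfg.seed)})
    result = run_scenario(scenario)
    for sp, g in result.genomes.items():
        pio.write_gene_map(g, outdir / f"genes_{sp}.tsv", comments=log_lines)
    needed = set(cfg.ingroup) | {cfg.outgroup}
    missing = needed - set(result.genomes)
    if missing:
        raise ValueError(f"scenario does not produce genomes: {sorted(missing)}")
    maps = {sp: result.genomes[sp] for sp in needed}
    hits = emit_hit_table(
        [maps[sp] for sp in sorted(needed)],
        offtarget_rate=0.005,
        seed=cfg.seed + 1,
    )
    pio.write_hit_table(hits, outdir / "hits.tsv")
    # stage: reconstruct
    acs, stats = reconstruct_acs(maps, hits, cfg.ingroup, cfg.outgroup, thresholds)
    stats_df = pd.DataFrame(
        [
            {
                "species_a": s.chrom_a[0], "chrom_a": s.chrom_a[1],
                "species_b": s.chrom_b[0], "chrom_b": s.chrom_b[1],
                "n_ab": s.n_ab, "n_a": s.n_a, "n_b": s.n_b, "N": s.n_total,
                "chi2": round(s.chi2, 4), "p": s.p, "q": s.q,
                "enriched": s.enriched,
            }
            for s in stats
        ]
    )
    stats_df.to_csv(outdir / "pair_stats.tsv", sep="\t", index=False)
    members_df = pd.DataFrame(
        [
            {"ac": ac, "species": sp, "chromosome": chrom}
            for ac, members in sorted(acs.groups.items())
            for sp, chrom in sorted(members)
        ]
    )
    members_df.to_csv(outdir / "ac_members.tsv", sep="\t", index=False)
    anchored_df = pd.DataFrame(
        [
            {"ac": ac, "gene_id": gid, "rule": acs.provenance.get(gid, "")}
            for ac, gids in sorted(acs.anchored_genes.items())
            for gid in gids
        ]
    )
    anchored_df.to_csv(outdir / "anchored_genes.tsv", sep="\t", index=False)
    # stage: OR analysis
    orres = or_analysis(maps, acs, maps[cfg.outgroup], thresholds, cfg.ingroup)
    fiss_max = fission_control(
        maps, acs, maps[cfg.outgroup], thresholds, cfg.ingroup, cfg.seed
    )
    summary: dict = {
        "seed": cfg.seed,
        "thresholds": dataclasses.asdict(thresholds),
        "ac_count": acs.n_groups,
        "n_anchored_genes": int(sum(len(v) for v in acs.anchored_genes.values())),
        "multiplicity": orres["multiplicity"],
        "or_ohnolog": {
            sp: _quantiles(v) for sp, v in orres["ohnolog_or"].items()
        },
        "or_ortholog": _quantiles(orres["ortholog_or"]),
        "orthology_classes": orres["orthology_classes"],
        "fission_or_max": round(float(fiss_max), 4),
        "tree_support": None,
        "fate_proportions": None,
    }
    # stage: gene-tree compatibility (optional)
    if cfg.with_trees:
        summary["tree_support"] = _tree_stage(cfg, result, outdir)
    # stage: expression fates (optional)
    if cfg.with_fates:
        summary["fate_proportions"] = _fate_stage(cfg, outdir)
    pio.write_json_summary(summary, outdir / "summary.json")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


def _tree_stage(cfg: PipelineConfig, result, outdir: Path) -> dict | None:
    rng = np.random.default_rng(cfg.seed + 7)
    fams_by_ac = result.ac_families()
    ref_sp = cfg.ingroup
    chosen: list[str] = []
    for ac, fams in sorted(fams_by_ac.items()):
        take = max(1, cfg.n_tree_families // len(fams_by_ac))
        idx = rng.choice(len(fams), size=min(take, len(fams)), replace=False)
        chosen.extend(fams[i] for i in sorted(idx))
    trees = simulate_gene_trees(result, seed=cfg.seed + 8)
    trees = {f: t for f, t in trees.items() if f in set(chosen)}
    pio.write_trees(trees, outdir / "trees")
    calls = []
    for fam, newick in sorted(trees.items()):
        ac = fam.split("g")[0]
        pairing = backbone_pairing(result, ref_sp[0], ac)
        if sum(bool(v) for v in pairing.values()) < 2:
            continue
        try:
            labeled = label_backbone(
                newick, pairing, set(ref_sp),
                {cfg.tree_outgroup}, tree_id=fam,
            )
        except ValueError:
            continue
        if not labeled.usable:
            continue
        calls.extend(classify_test_genes(labeled, set(cfg.test_species)))
    table = tally_support(calls, per_tree=True)
    table.to_csv(outdir / "tree_support.tsv", sep="\t", index=False)
    return {
        row.test_species: {
            "n": int(row.n),
            "frac_1R": round(float(row.frac_1R), 4),
            "frac_2R": round(float(row.frac_2R), 4),
        }
        for row in table.itertuples(index=False)
    }


def _fate_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    matrix, truth = simulate_expression(
        cfg.n_expression_pairs, cfg.fate_mix, cfg.tissues,
        noise_sd=0.1, seed=cfg.seed + 9,
    )
    pio.write_expression(matrix, outdir / "expression.tsv")
    calls, _excluded = classify_pairs(
        matrix, truth[["pair_id", "gene_a", "gene_b"]],
        tpm_min=cfg.thresholds.tpm_min,
        strong_frac=cfg.thresholds.strong_spec_frac,
    )
    n = len(calls)
    frac = lambda f: round(sum(c.fate == f for c in calls) / n, 4) if n else None
    calls_df = pd.DataFrame(
        [
            {"pair_id": c.pair_id, "fate": c.fate, "grade": c.spec_grade}
            for c in calls
        ]
    )
    calls_df.to_csv(outdir / "fate_calls.tsv", sep="\t", index=False)
    return {
        "n": n,
        "redundancy": frac("redundancy"),
        "subfunctionalization": frac("subfunctionalization"),
        "specialization": frac("specialization"),
        "strong_specialization": round(
            sum(c.spec_grade == "strong" for c in calls) / n, 4
        ) if n else None,
    }
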