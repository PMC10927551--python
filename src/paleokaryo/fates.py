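"""Post-WGD ohnologue expression fates and regulatory-context annotation.

Expression fates follow the domain-set logic: after quantile
normalization, a gene is "expressed" in a tissue when TPM > 5 (strict);
an ohnologue pair is *redundant* when both copies share the same tissue
set, *subfunctionalized* when each copy keeps at least one exclusive
tissue, and *specialized* when one copy's domains are a strict subset of
the other's — graded *strong* when the narrow copy covers < 40% of the
broad copy's domains, else *mild*.

Accessible chromatin regions (ACRs) are annotated by genomic context with
the precedence promoter > proximal > exonic > distal, using strand-aware
windows around transcription start sites (promoter: 1 kb upstream to
0.5 kb downstream; proximal: 5 kb upstream to 1 kb downstream, minus
promoters), and assigned to the gene with the nearest TSS.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FateCall",
    "ACRAnnotation",
    "quantile_normalize",
    "expression_domains",
    "classify_fate",
    "classify_pairs",
    "specialization_tissue_profile",
    "classify_acr_context",
    "acr_counts_per_gene",
    "tss_distance_cdf",
]

logger = logging.getLogger(__name__)

PROMOTER_UP, PROMOTER_DOWN = 1000, 500
PROXIMAL_UP, PROXIMAL_DOWN = 5000, 1000
ACR_CATEGORIES = ("promoter", "proximal", "exonic", "distal")


@dataclass(frozen=True)
class FateCall:
    pair_id: str
    fate: str  # redundancy | subfunctionalization | specialization
    spec_grade: str  # strong | mild | n/a
    domains_a: frozenset
    domains_b: frozenset


@dataclass(frozen=True)
class ACRAnnotation:
    chrom: str
    start: int  # 0-based half-open
    end: int
    name: str
    category: str
    gene: str
    tss_distance: int  # signed, strand-aware (positive = downstream of TSS)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize tissue columns to the mean-of-sorted reference.

    Every column is replaced by the across-column mean of sorted values at
    its ranks; ties within a column receive the average of the reference
    values they span.
    """
    if m.shape[1] < 2:
        warnings.warn("single tissue column: quantile normalization is a no-op")
        return m.copy()
    ref = np.sort(m.values, axis=0).mean(axis=1)
    cum = np.concatenate([[0.0], np.cumsum(ref)])
    out = {}
    for col in m.columns:
        # a tie spanning ranks [lo, hi) receives the mean reference value
        # over that span
        lo = m[col].rank(method="min").values.astype(int) - 1
        hi = m[col].rank(method="max").values.astype(int)
        out[col] = (cum[hi] - cum[lo]) / (hi - lo)
    return pd.DataFrame(out, index=m.index)


def expression_domains(m: pd.DataFrame, tpm_min: float = 5.0) -> dict[str, set]:
    """Tissue domain set per gene: tissues with TPM strictly above ``tpm_min``."""
    mask = m.values > tpm_min
    tissues = np.array(m.columns)
    return {
        gene: set(tissues[mask[i]]) for i, gene in enumerate(m.index)
    }


def classify_fate(
    dom_a: set, dom_b: set, strong_frac: float = 0.40, pair_id: str = ""
) -> FateCall:
    """Classify one ohnologue pair from its two tissue domain sets.

    Both sets must be non-empty (pairs with a silent copy are excluded
    upstream).  Equal sets -> redundancy; mutual exclusive tissues ->
    subfunctionalization; strict containment -> specialization, strong
    when narrow/broad < ``strong_frac``.
    """
    if not dom_a or not dom_b:
        raise ValueError("both ohnologues must be expressed in >=1 tissue")
    a, b = frozenset(dom_a), frozenset(dom_b)
    if a == b:
        return FateCall(pair_id, "redundancy", "n/a", a, b)
    if (a - b) and (b - a):
        return FateCall(pair_id, "subfunctionalization", "n/a", a, b)
    narrow, broad = (a, b) if a < b else (b, a)
    grade = "strong" if len(narrow) / len(broad) < strong_frac else "mild"
    return FateCall(pair_id, "specialization", grade, a, b)


def classify_pairs(
    m: pd.DataFrame,
    pairs: pd.DataFrame,
    tpm_min: float = 5.0,
    strong_frac: float = 0.40,
) -> tuple[list[FateCall], pd.DataFrame]:
    """Classify ohnologue pairs from an expression matrix.

    ``pairs`` needs columns ``pair_id``, ``gene_a``, ``gene_b``.  Pairs in
    which either copy is expressed nowhere are excluded with a reason.
    Returns (calls, excluded-pairs table).
    """
    domains = expression_domains(m, tpm_min)
    calls, excluded = [], []
    for row in pairs.itertuples(index=False):
        da = domains.get(row.gene_a, set())
        db = domains.get(row.gene_b, set())
        if not da or not db:
            which = row.gene_a if not da else row.gene_b
            excluded.append((row.pair_id, f"{which} expressed in no tissue"))
            continue
        calls.append(classify_fate(da, db, strong_frac, row.pair_id))
    return calls, pd.DataFrame(excluded, columns=["pair_id", "reason"])


def specialization_tissue_profile(
    calls: list[FateCall], strong_max_domains: int = 2
) -> pd.Series:
    """Tissue counts of strongly specialized narrow copies.

    Counts, per tissue, the strongly specialized ohnologues whose narrow
    copy retains at most ``strong_max_domains`` expression domains (the
    "one or two ancestral domains" reading); multi-domain genes count once
    per tissue.
    """
    counter: dict[str, int] = {}
    for c in calls:
        if c.fate != "specialization" or c.spec_grade != "strong":
            continue
        narrow = c.domains_a if len(c.domains_a) < len(c.domains_b) else c.domains_b
        if len(narrow) > strong_max_domains:
            continue
        for tissue in narrow:
            counter[tissue] = counter.get(tissue, 0) + 1
    return pd.Series(counter, dtype=int).sort_index()


# ---------------------------------------------------------------------------
# ACR genomic context
# ---------------------------------------------------------------------------


def _tss_of(gene_row) -> int:
    # 0-based: for '-' strand genes the TSS is the last base of the interval
    return gene_row.start if gene_row.strand == "+" else gene_row.end - 1


def classify_acr_context(
    acrs: pd.DataFrame, gene_models: pd.DataFrame
) -> list[ACRAnnotation]:
    """Annotate ACR intervals by genomic context with fixed precedence.

    ``acrs``: 0-based half-open intervals (columns chrom, start, end and
    optionally name).  ``gene_models``: tidy frame with columns gene_id,
    chrom, start, end, strand, feature ('gene' rows define TSSs, 'exon'
    rows the exonic space), 0-based half-open.  Precedence: promoter >
    proximal > exonic > distal; windows are strand-aware and an overlap of
    one base suffices.  Every ACR is also assigned the gene with the
    nearest TSS and the signed strand-aware distance (positive =
    downstream of that TSS).
    """
    for col in ("chrom", "start", "end"):
        if col not in acrs.columns:
            raise ValueError(f"ACR table missing column {col!r}")
    genes = gene_models[gene_models["feature"] == "gene"]
    if genes.empty:
        raise ValueError("no gene features in gene models")
    exons = gene_models[gene_models["feature"] == "exon"]
    windows = {}
    for chrom, sub in genes.groupby("chrom"):
        tss = np.array([_tss_of(r) for r in sub.itertuples(index=False)])
        strand = (sub["strand"] == "+").values
        # promoter: [TSS-1000, TSS+500]; proximal: [TSS-5000, TSS+1000]
        prom_lo = np.where(strand, tss - PROMOTER_UP, tss - PROMOTER_DOWN)
        prom_hi = np.where(strand, tss + PROMOTER_DOWN, tss + PROMOTER_UP)
        prox_lo = np.where(strand, tss - PROXIMAL_UP, tss - PROXIMAL_DOWN)
        prox_hi = np.where(strand, tss + PROXIMAL_DOWN, tss + PROXIMAL_UP)
        windows[chrom] = {
            "tss": tss,
            "strand": strand,
            "gene_id": sub["gene_id"].values,
            "prom": (np.maximum(prom_lo, 0), prom_hi + 1),  # half-open
            "prox": (np.maximum(prox_lo, 0), prox_hi + 1),
            "exon_start": exons[exons["chrom"] == chrom]["start"].values
            if len(exons)
            else np.array([]),
            "exon_end": exons[exons["chrom"] == chrom]["end"].values
            if len(exons)
            else np.array([]),
        }
    out: list[ACRAnnotation] = []
    for i, row in enumerate(acrs.itertuples(index=False)):
        name = getattr(row, "name", None) or f"acr{i:05d}"
        w = windows.get(row.chrom)
        if w is None:
            raise KeyError(f"ACR chromosome {row.chrom!r} has no gene models")
        a_lo, a_hi = int(row.start), int(row.end)
        if a_hi <= a_lo:
            raise ValueError(f"ACR {name}: empty interval [{a_lo}, {a_hi})")

        def overlaps(lo: np.ndarray, hi: np.ndarray) -> bool:
            return bool(np.any((lo < a_hi) & (a_lo < hi)))

        if overlaps(*w["prom"]):
            category = "promoter"
        elif overlaps(*w["prox"]):
            category = "proximal"
        elif len(w["exon_start"]) and overlaps(w["exon_start"], w["exon_end"]):
            category = "exonic"
        else:
            category = "distal"
        mid = (a_lo + a_hi - 1) // 2
        d_abs = np.abs(w["tss"] - mid)
        j = int(np.argmin(d_abs))
        signed = mid - w["tss"][j]
        if not w["strand"][j]:
            signed = -signed
        out.append(
            ACRAnnotation(
                row.chrom, a_lo, a_hi, str(name), category,
                str(w["gene_id"][j]), int(signed),
            )
        )
    return out


def acr_counts_per_gene(
    annots: list[ACRAnnotation],
    all_genes: list[str] | None = None,
    gene_classes: dict[str, str] | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-gene ACR counts with optional between-class rank-sum tests.

    Counts ACRs assigned (nearest TSS, all categories) to each gene; genes
    without any ACR count 0 when listed in ``all_genes``.  With
    ``gene_classes``, all pairwise two-sided Wilcoxon rank-sum tests
    between classes are reported with Bonferroni-adjusted p-values.
    """
    counts: dict[str, int] = {}
    for a in annots:
        counts[a.gene] = counts.get(a.gene, 0) + 1
    if all_genes is not None:
        for g in all_genes:
            counts.setdefault(g, 0)
    series = pd.Series(counts, dtype=int).sort_index()
    tests = pd.DataFrame(
        columns=["class_a", "class_b", "stat", "p", "p_bonferroni"]
    )
    if gene_classes:
        by_class: dict[str, list[int]] = {}
        for g, n in series.items():
            cls = gene_classes.get(g)
            if cls is not None:
                by_class.setdefault(cls, []).append(n)
        combos = list(itertools.combinations(sorted(by_class), 2))
        rows = []
        for ca, cb in combos:
            stat, p = sps.ranksums(by_class[ca], by_class[cb])
            rows.append((ca, cb, float(stat), float(p)))
        if rows:
            m = len(rows)
            tests = pd.DataFrame(rows, columns=["class_a", "class_b", "stat", "p"])
            tests["p_bonferroni"] = np.minimum(tests["p"] * m, 1.0)
    return series, tests


def tss_distance_cdf(
    annots: list[ACRAnnotation],
    scale_by: float | None = None,
) -> pd.DataFrame:
    """Empirical CDF of |distance to nearest TSS| across ACRs.

    ``scale_by`` divides distances by a genome-level scale (typically the
    mean intergenic length) to make species with different genome sizes
    comparable.
    """
    d = np.sort(np.abs([a.tss_distance for a in annots]).astype(float))
    if scale_by is not None:
        if scale_by <= 0:
            raise ValueError("scale_by must be positive")
        d = d / scale_by
    n = len(d)
    return pd.DataFrame(
        {"distance": d, "cumulative": np.arange(1, n + 1) / n if n else []}
    )
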