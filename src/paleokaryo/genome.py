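"""Core containers for gene-level karyotype maps.

A :class:`GenomeMap` is an ordered collection of chromosomes, each an ordered
list of :class:`Gene` records.  Genes carry a ``family_id`` naming the
ancestral gene they descend from; all homology bookkeeping downstream
(retention profiles, hit tables, gene trees) is keyed on families, never on
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import pandas as pd

__all__ = ["Gene", "GenomeMap"]


@dataclass(frozen=True)
class Gene:
    """A gene occurrence on a chromosome.

    ``family_id`` is shared by every descendant (ohnologue, orthologue or
    small-scale duplicate) of one ancestral gene; ``gene_id`` is unique within
    a :class:`GenomeMap`.
    """

    gene_id: str
    family_id: str
    species: str
    chromosome: str
    index: int


class GenomeMap:
    """Ordered map chromosome -> list of genes for one species.

    Invariants enforced on construction: gene indices within a chromosome are
    ``0..len-1``, every ``gene_id`` is unique, and no gene sits on a
    chromosome other than the one it is filed under.
    """

    def __init__(self, species: str, chromosomes: dict[str, list[Gene]]):
        self.species = species
        self.chromosomes: dict[str, list[Gene]] = {}
        seen: set[str] = set()
        for chrom, genes in chromosomes.items():
            fixed = []
            for i, g in enumerate(genes):
                if g.gene_id in seen:
                    raise ValueError(f"duplicate gene_id {g.gene_id!r}")
                seen.add(g.gene_id)
                if g.chromosome != chrom or g.index != i or g.species != species:
                    g = replace(g, species=species, chromosome=chrom, index=i)
                fixed.append(g)
            self.chromosomes[chrom] = fixed

    # -- basic queries -----------------------------------------------------

    def __len__(self) -> int:
        return sum(len(v) for v in self.chromosomes.values())

    def __iter__(self) -> Iterator[Gene]:
        for genes in self.chromosomes.values():
            yield from genes

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def genes_on(self, chrom: str) -> list[Gene]:
        return self.chromosomes[chrom]

    def families_on(self, chrom: str) -> set[str]:
        return {g.family_id for g in self.chromosomes[chrom]}

    def family_multiset(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in self:
            counts[g.family_id] = counts.get(g.family_id, 0) + 1
        return counts

    def copy(self, species: str | None = None) -> "GenomeMap":
        return GenomeMap(
            species if species is not None else self.species,
            {c: list(v) for c, v in self.chromosomes.items()},
        )

    # -- tabular views -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g.species, g.chromosome, g.gene_id, g.family_id, g.index) for g in self
        ]
        return pd.DataFrame(
            rows, columns=["species", "chromosome", "gene_id", "family_id", "index"]
        )

    @classmethod
    def from_records(
        cls, species: str, records: Iterable[tuple[str, str, str]]
    ) -> "GenomeMap":
        """Build from (chromosome, gene_id, family_id) triples, in order."""
        chroms: dict[str, list[Gene]] = {}
        for chrom, gid, fam in records:
            chroms.setdefault(chrom, []).append(
                Gene(gid, fam, species, chrom, len(chroms.get(chrom, [])))
            )
        return cls(species, chroms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeMap):
            return NotImplemented
        return self.species == other.species and self.chromosomes == other.chromosomes

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"GenomeMap(species={self.species!r}, n_chromosomes="
            f"{self.n_chromosomes}, n_genes={len(self)})"
        )
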