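"""Genome shortlisting and within-family pair-set construction.

The evaluation design compares genomes only within the same family (pairs
across families are uninformative for genus delineation and blow up the
comparison count), bans self-comparisons, and labels each unordered pair by
whether its two genomes share a genus — the positive class of the
classifier evaluation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from pocpu.proteome_io import TaxonomyTable

DEFAULT_MIN_GENERA_PER_FAMILY = 2
DEFAULT_MIN_GENOMES_PER_GENUS = 10


@dataclass(frozen=True, order=True)
class GenomePair:
    """One unordered within-family genome pair, canonically ordered."""

    genome_a: str
    genome_b: str
    family: str
    same_genus: bool

    def __post_init__(self) -> None:
        if self.genome_a == self.genome_b:
            raise ValueError(f"self-pair: {self.genome_a!r}")
        if self.genome_a > self.genome_b:
            raise ValueError(
                f"pair not canonically ordered: {self.genome_a!r} > {self.genome_b!r}"
            )


def select_genomes(
    taxonomy: TaxonomyTable,
    min_genera_per_family: int = DEFAULT_MIN_GENERA_PER_FAMILY,
    min_genomes_per_genus: int = DEFAULT_MIN_GENOMES_PER_GENUS,
) -> TaxonomyTable:
    """Apply the genus-size then family-diversity shortlisting criteria.

    First drops genera with fewer than ``min_genomes_per_genus`` genomes,
    then drops families left with fewer than ``min_genera_per_family``
    genera. May return an empty table.
    """
    df = taxonomy.frame
    genus_sizes = df.groupby(["family", "genus"])["genome_id"].transform("size")
    df = df[genus_sizes >= min_genomes_per_genus]
    genera_per_family = df.groupby("family")["genus"].transform("nunique")
    df = df[genera_per_family >= min_genera_per_family]
    return TaxonomyTable(frame=df.reset_index(drop=True))


def build_pair_set(taxonomy: TaxonomyTable) -> list[GenomePair]:
    """Enumerate all unordered within-family pairs of distinct genomes.

    A family of n genomes yields n(n-1)/2 pairs; the alignment layer later
    expands each into two directional comparisons. ``same_genus`` labels the
    pair for downstream confusion-matrix evaluation. Output is sorted by
    (family, genome_a, genome_b) and independent of input row order.
    """
    df = taxonomy.frame
    pairs: list[GenomePair] = []
    for family, group in df.groupby("family", sort=True):
        genus_of = dict(zip(group["genome_id"], group["genus"]))
        for a, b in itertools.combinations(sorted(genus_of), 2):
            pairs.append(
                GenomePair(
                    genome_a=a,
                    genome_b=b,
                    family=str(family),
                    same_genus=genus_of[a] == genus_of[b],
                )
            )
    return pairs


def write_pair_manifest(pairs: list[GenomePair], path) -> None:
    """Write the pair manifest TSV: genome_a, genome_b, family, same_genus."""
    with open(path, "wt") as fh:
        fh.write("genome_a\tgenome_b\tfamily\tsame_genus\n")
        for p in pairs:
            fh.write(f"{p.genome_a}\t{p.genome_b}\t{p.family}\t{str(p.same_genus).lower()}\n")
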