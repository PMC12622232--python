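"""Synthetic proteome pairs and labeled family datasets with known truth.

The generator emulates the features that drive POCP/POCPu behaviour:

* a shared ortholog core between the two genomes of a pair, optionally
  diverged by per-site substitutions on one side;
* per-genome accessory proteins — i.i.d. random sequences whose expected
  identity to anything (~5%) sits far below the 40% conservation filter;
* within-genome paralog duplications of core proteins, the mechanism that
  makes POCP exceed 100% while POCPu stays bounded.

For the evaluation layer, :func:`generate_family_dataset` skips sequences
entirely and draws labeled POCPu-like values from controlled within-genus /
between-genera ranges, emulating families whose distributions are neatly
distinct, overlapping, or anything in between.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from pocpu.delineation import LabeledValue
from pocpu.pairs import build_pair_set
from pocpu.proteome_io import ProteinRecord, Proteome, TaxonomyTable
import pandas as pd

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

DEFAULT_LENGTH_RANGE = (80, 120)


@dataclass(frozen=True)
class PairSpec:
    """Recipe for one synthetic proteome pair.

    ``n_core`` orthologs are shared; genome b's core copies are mutated at
    per-site probability ``sub_rate``. ``dup_a``/``dup_b`` core proteins are
    duplicated (exact copies of their within-genome template), and
    ``n_acc_a``/``n_acc_b`` random accessory proteins are added per genome.
    Protein lengths are drawn uniformly from ``length_range`` (residues).
    """

    n_core: int = 10
    n_acc_a: int = 0
    n_acc_b: int = 0
    dup_a: int = 0
    dup_b: int = 0
    sub_rate: float = 0.0
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE
    seed: int = 0
    genome_a: str = "genomeA"
    genome_b: str = "genomeB"

    def __post_init__(self) -> None:
        if self.n_core < 0 or self.n_acc_a < 0 or self.n_acc_b < 0:
            raise ValueError("protein counts must be non-negative")
        if not 0 <= self.dup_a <= self.n_core or not 0 <= self.dup_b <= self.n_core:
            raise ValueError("duplication counts must be on [0, n_core]")
        if not 0 <= self.sub_rate < 1:
            raise ValueError("sub_rate must be on [0, 1)")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("length_range must be a positive interval")
        if self.n_core + self.n_acc_a == 0 or self.n_core + self.n_acc_b == 0:
            raise ValueError("each genome needs at least one protein")

    @property
    def t_a(self) -> int:
        return self.n_core + self.dup_a + self.n_acc_a

    @property
    def t_b(self) -> int:
        return self.n_core + self.dup_b + self.n_acc_b

    @property
    def expected_pocpu_no_mutation(self) -> float:
        """Closed-form POCPu when sub_rate = 0.

        Every core and duplicate protein is a query with a passing unique
        match in the other genome; accessory proteins match nothing.
        """
        conserved = (self.n_core + self.dup_a) + (self.n_core + self.dup_b)
        return 100.0 * conserved / (self.t_a + self.t_b)


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for one family's labeled values.

    Within-genus pair values are drawn uniformly from
    ``within_value_range`` and between-genera values from
    ``between_value_range``; disjoint ranges give a perfectly separable
    family, overlapping ranges a hard one.
    """

    family: str
    genera: tuple[tuple[str, int], ...]
    within_value_range: tuple[float, float] = (70.0, 90.0)
    between_value_range: tuple[float, float] = (10.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.within_value_range, self.between_value_range):
            if not (0 <= lo <= hi <= 100):
                raise ValueError("value ranges must be ordered intervals within [0, 100]")
        for _, count in self.genera:
            if count < 1:
                raise ValueError("genome count per genus must be >= 1")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _mutate(rng: np.random.Generator, sequence: str, sub_rate: float) -> str:
    """Substitute each site with probability sub_rate, always to a different residue."""
    if sub_rate == 0:
        return sequence
    residues = np.array(list(sequence))
    hit = rng.random(len(residues)) < sub_rate
    for i in np.flatnonzero(hit):
        choices = AMINO_ACIDS[AMINO_ACIDS != residues[i]]
        residues[i] = rng.choice(choices)
    return "".join(residues)


def generate_pair(spec: PairSpec) -> tuple[Proteome, Proteome, float]:
    """Generate a proteome pair per ``spec``; returns (a, b, closed-form POCPu).

    Deterministic under ``spec.seed``. The third element is the expected
    POCPu for sub_rate = 0 (with mutation the realized value falls as
    divergence crosses the identity filter).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    core = [
        _random_protein(rng, int(rng.integers(lo, hi + 1)))
        for _ in range(spec.n_core)
    ]
    records_a = [
        ProteinRecord(f"{spec.genome_a}_core{i}", seq) for i, seq in enumerate(core)
    ]
    records_a += [
        ProteinRecord(f"{spec.genome_a}_dup{i}", core[i]) for i in range(spec.dup_a)
    ]
    records_a += [
        ProteinRecord(
            f"{spec.genome_a}_acc{i}", _random_protein(rng, int(rng.integers(lo, hi + 1)))
        )
        for i in range(spec.n_acc_a)
    ]
    core_b = [_mutate(rng, seq, spec.sub_rate) for seq in core]
    records_b = [
        ProteinRecord(f"{spec.genome_b}_core{i}", seq) for i, seq in enumerate(core_b)
    ]
    records_b += [
        ProteinRecord(f"{spec.genome_b}_dup{i}", core_b[i]) for i in range(spec.dup_b)
    ]
    records_b += [
        ProteinRecord(
            f"{spec.genome_b}_acc{i}", _random_protein(rng, int(rng.integers(lo, hi + 1)))
        )
        for i in range(spec.n_acc_b)
    ]
    proteome_a = Proteome(genome_id=spec.genome_a, records=tuple(records_a))
    proteome_b = Proteome(genome_id=spec.genome_b, records=tuple(records_b))
    return proteome_a, proteome_b, spec.expected_pocpu_no_mutation


def family_taxonomy(specs: Sequence[FamilySpec]) -> TaxonomyTable:
    """Taxonomy table covering every genome the family specs imply."""
    rows = []
    for spec in specs:
        for genus, count in spec.genera:
            for i in range(count):
                genome = f"{spec.family}_{genus}_{i:03d}"
                rows.append((genome, spec.family, genus, f"{genus} sp{i:03d}"))
    return TaxonomyTable(
        frame=pd.DataFrame(rows, columns=["genome_id", "family", "genus", "species"])
    )


def generate_family_dataset(specs: Sequence[FamilySpec]) -> list[LabeledValue]:
    """Draw labeled values for every within-family pair of every spec.

    Pairs come from :func:`pocpu.pairs.build_pair_set` on the implied
    taxonomy; each pair's value is uniform on its class's range.
    Deterministic under the specs' seeds; an empty spec list yields an
    empty dataset.
    """
    values: list[LabeledValue] = []
    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        taxonomy = family_taxonomy([spec])
        for pair in build_pair_set(taxonomy):
            lo, hi = (
                spec.within_value_range if pair.same_genus else spec.between_value_range
            )
            values.append(LabeledValue(pair=pair, value=float(rng.uniform(lo, hi))))
    return values
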