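"""Conservation filtering and the POCP / POCPu metrics.

A protein is conserved when its best match in the other genome has an
e-value < 1e-5, a sequence identity > 40%, and an aligned region > 50% of
the query protein length — all three comparisons strict. POCP is the number
of conserved hit rows in both directions over the total protein count of
the pair:

    POCP  = (C_QS  + C_SQ ) / (T_Q + T_S) x 100
    POCPu = (CuQS + CuSQ) / (T_Q + T_S) x 100

POCP counts hit rows, so one query matching k paralogous subjects
contributes k and POCP can exceed 100%. POCPu counts each query at most
once (unique matches) and is bounded by 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from pocpu.alignment import AlignmentHit, HitTable
from pocpu.proteome_io import Proteome, query_lengths

DEFAULT_MAX_EVALUE = 1e-5
DEFAULT_MIN_IDENTITY_PCT = 40.0
DEFAULT_MIN_QUERY_COVERAGE = 0.5


@dataclass(frozen=True)
class FilterThresholds:
    """Conservation-filter cutoffs; defaults locked to the published values.

    All three filters are strict: a hit at evalue exactly ``max_evalue``,
    identity exactly ``min_identity_pct`` or coverage exactly
    ``min_query_coverage`` is excluded.
    """

    max_evalue: float = DEFAULT_MAX_EVALUE
    min_identity_pct: float = DEFAULT_MIN_IDENTITY_PCT
    min_query_coverage: float = DEFAULT_MIN_QUERY_COVERAGE

    def __post_init__(self) -> None:
        if not self.max_evalue > 0:
            raise ValueError("max_evalue must be > 0")
        if not 0 <= self.min_identity_pct <= 100:
            raise ValueError("min_identity_pct must be on [0, 100]")
        if not 0 < self.min_query_coverage <= 1:
            raise ValueError("min_query_coverage must be on (0, 1]")

    @property
    def is_default(self) -> bool:
        return (
            self.max_evalue == DEFAULT_MAX_EVALUE
            and self.min_identity_pct == DEFAULT_MIN_IDENTITY_PCT
            and self.min_query_coverage == DEFAULT_MIN_QUERY_COVERAGE
        )


@dataclass(frozen=True)
class ConservedCounts:
    """Conserved matches in one direction: hit rows (C) and distinct queries (Cu)."""

    total_matches: int
    unique_matches: int

    def __post_init__(self) -> None:
        if self.total_matches < 0 or self.unique_matches < 0:
            raise ValueError("counts must be non-negative")
        if self.unique_matches > self.total_matches:
            raise ValueError("unique_matches cannot exceed total_matches")


@dataclass(frozen=True)
class PairResult:
    """POCP and POCPu of one unordered genome pair, with its raw counts."""

    genome_a: str
    genome_b: str
    t_a: int
    t_b: int
    counts_ab: ConservedCounts
    counts_ba: ConservedCounts
    pocp: float
    pocpu: float
    default_thresholds: bool = True

    def __post_init__(self) -> None:
        if self.pocpu > self.pocp + 1e-9:
            raise ValueError("pocpu cannot exceed pocp")
        if not 0 <= self.pocpu <= 100 + 1e-9:
            raise ValueError("pocpu must be on [0, 100]")


def filter_conserved(
    hits: HitTable,
    qlen: Mapping[str, int],
    thresholds: FilterThresholds = FilterThresholds(),
) -> HitTable:
    """Keep hits passing the three strict conservation cutoffs.

    Retains exactly the hits with ``evalue < max_evalue`` and
    ``pct_identity > min_identity_pct`` and
    ``aln_length > min_query_coverage * qlen[query_id]``, preserving row
    order. A query id missing from ``qlen`` is an error — silent dropping
    would corrupt the counts.
    """
    kept = []
    for hit in hits:
        if hit.query_id not in qlen:
            raise KeyError(
                f"query id {hit.query_id!r} has a hit but no length entry; "
                f"hit table and proteome are inconsistent"
            )
        if (
            hit.evalue < thresholds.max_evalue
            and hit.pct_identity > thresholds.min_identity_pct
            and hit.aln_length > thresholds.min_query_coverage * qlen[hit.query_id]
        ):
            kept.append(hit)
    return HitTable(hits.query_genome, hits.subject_genome, tuple(kept))


def count_conserved(filtered: HitTable) -> ConservedCounts:
    """Count conserved hit rows (C_QS) and distinct matched queries (CuQS)."""
    return ConservedCounts(
        total_matches=len(filtered.hits),
        unique_matches=len({h.query_id for h in filtered.hits}),
    )


def compute_pair(
    proteome_a: Proteome,
    proteome_b: Proteome,
    hits_ab: HitTable,
    hits_ba: HitTable,
    thresholds: FilterThresholds = FilterThresholds(),
) -> PairResult:
    """Filter both directional hit tables and compute POCP and POCPu.

    ``hits_ab`` must be the a→b comparison and ``hits_ba`` the b→a
    comparison; each is filtered with its own query-length map. Percentages
    carry full floating precision — rounding is presentation-only.
    """
    if hits_ab.query_genome != proteome_a.genome_id or hits_ab.subject_genome != proteome_b.genome_id:
        raise ValueError(
            f"hits_ab is {hits_ab.query_genome}->{hits_ab.subject_genome}, "
            f"expected {proteome_a.genome_id}->{proteome_b.genome_id}"
        )
    if hits_ba.query_genome != proteome_b.genome_id or hits_ba.subject_genome != proteome_a.genome_id:
        raise ValueError(
            f"hits_ba is {hits_ba.query_genome}->{hits_ba.subject_genome}, "
            f"expected {proteome_b.genome_id}->{proteome_a.genome_id}"
        )
    counts_ab = count_conserved(filter_conserved(hits_ab, query_lengths(proteome_a), thresholds))
    counts_ba = count_conserved(filter_conserved(hits_ba, query_lengths(proteome_b), thresholds))
    denom = proteome_a.total_proteins + proteome_b.total_proteins
    pocp = 100.0 * (counts_ab.total_matches + counts_ba.total_matches) / denom
    pocpu = 100.0 * (counts_ab.unique_matches + counts_ba.unique_matches) / denom
    return PairResult(
        genome_a=proteome_a.genome_id,
        genome_b=proteome_b.genome_id,
        t_a=proteome_a.total_proteins,
        t_b=proteome_b.total_proteins,
        counts_ab=counts_ab,
        counts_ba=counts_ba,
        pocp=pocp,
        pocpu=pocpu,
        default_thresholds=thresholds.is_default,
    )


def format_pair_row(result: PairResult) -> str:
    """One TSV row of the pair output interface (POCP/POCPu to 4 decimals)."""
    return (
        f"{result.genome_a}\t{result.genome_b}\t{result.t_a}\t{result.t_b}"
        f"\t{result.counts_ab.total_matches}\t{result.counts_ba.total_matches}"
        f"\t{result.counts_ab.unique_matches}\t{result.counts_ba.unique_matches}"
        f"\t{result.pocp:.4f}\t{result.pocpu:.4f}"
    )


PAIR_TSV_HEADER = "genome_a\tgenome_b\tt_a\tt_b\tc_ab\tc_ba\tcu_ab\tcu_ba\tpocp\tpocpu"
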