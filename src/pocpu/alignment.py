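"""Protein hit tables: parsing, external aligner wrappers, built-in aligner.

Hit tables are directional (query genome → subject genome); the metric layer
consumes one table per direction, mirroring the C_QS + C_SQ structure of the
POCP formula. Three sources are supported:

* :func:`parse_hits` — BLAST-tabular (outfmt 6) TSV in the BLAST, DIAMOND or
  MMseqs2 dialect. MMseqs2 reports identity on [0, 1] and is rescaled to the
  shared percent scale on ingest.
* :func:`run_external` — named tool profiles (blastp, diamond_*, mmseqs2_*)
  that shell out to the corresponding binary and parse its tabular output.
* :func:`builtin_align` — an exhaustive Smith–Waterman aligner (BLOSUM62,
  gap open 11 / extend 1) so the metric layer is exercisable with no
  external binary. Its Karlin–Altschul e-value is an acknowledged
  approximation used only for reportability; the conservation filter
  re-applies the exact 1e-5 cutoff downstream.
"""

from __future__ import annotations

import json
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from pocpu.proteome_io import Proteome

PathLike = Union[str, Path]

OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

DIALECTS = ("blast", "diamond", "mmseqs2")

# Karlin-Altschul constants for gapped BLOSUM62 (open 11 / extend 1) and the
# reportability cutoff of the built-in aligner.
_KA_LAMBDA = 0.267
_KA_K = 0.041
_BUILTIN_EVALUE_CUTOFF = 10.0


@dataclass(frozen=True)
class AlignmentHit:
    """One query→subject protein match.

    ``pct_identity`` is always on the percent scale [0, 100] regardless of
    the producing tool; ``aln_length`` counts alignment columns including
    gaps (the outfmt-6 ``length`` column).
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    evalue: float
    bitscore: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(
                f"pct_identity {self.pct_identity} outside [0, 100] "
                f"for {self.query_id}->{self.subject_id}"
            )
        if self.aln_length < 1:
            raise ValueError(f"aln_length must be >= 1, got {self.aln_length}")
        if self.evalue < 0:
            raise ValueError(f"evalue must be >= 0, got {self.evalue}")


@dataclass(frozen=True)
class HitTable:
    """Ordered hits of one directional comparison (query genome → subject genome)."""

    query_genome: str
    subject_genome: str
    hits: tuple[AlignmentHit, ...]

    def __post_init__(self) -> None:
        if self.query_genome == self.subject_genome:
            raise ValueError(
                f"self-comparison banned: query and subject genome are both "
                f"{self.query_genome!r}"
            )

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def to_frame(self) -> pd.DataFrame:
        """Hits as a DataFrame (percent-scale identity)."""
        return pd.DataFrame(
            {
                "qseqid": [h.query_id for h in self.hits],
                "sseqid": [h.subject_id for h in self.hits],
                "pident": [h.pct_identity for h in self.hits],
                "length": [h.aln_length for h in self.hits],
                "evalue": [h.evalue for h in self.hits],
                "bitscore": [h.bitscore for h in self.hits],
            }
        )


def parse_hits(
    path: PathLike,
    dialect: str,
    query_genome: str,
    subject_genome: str,
) -> HitTable:
    """Parse a 12-column BLAST-tabular TSV (no header, gzip accepted).

    ``dialect`` is one of ``blast``, ``diamond``, ``mmseqs2``. MMseqs2
    reports identity as a fraction on [0, 1]; those values are multiplied by
    100 so every stored hit shares the percent scale. Identities outside the
    dialect's admissible range are an error, as are malformed rows. Row
    order is preserved, duplicates included.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=OUTFMT6_COLUMNS,
            dtype={"qseqid": str, "sseqid": str},
            comment="#",
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed hit table {path}: {exc}") from exc
    if df.shape[1] != len(OUTFMT6_COLUMNS):
        raise ValueError(
            f"expected {len(OUTFMT6_COLUMNS)} columns in {path}, got {df.shape[1]}"
        )
    for col in ("pident", "evalue", "bitscore"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"non-numeric values in column {col!r} of {path}")
    numeric = ["pident", "length", "mismatch", "gapopen", "evalue", "bitscore"]
    if df[numeric].isna().any().any():
        raise ValueError(f"malformed hit table {path}: missing or non-numeric fields")

    upper = 1.0 if dialect == "mmseqs2" else 100.0
    bad = df[(df["pident"] < 0) | (df["pident"] > upper)]
    if not bad.empty:
        raise ValueError(
            f"{dialect} identity outside [0, {upper:g}] in {path}: "
            f"{bad['pident'].iloc[0]}"
        )
    pident = df["pident"] * 100.0 if dialect == "mmseqs2" else df["pident"]

    hits = tuple(
        AlignmentHit(
            query_id=row.qseqid,
            subject_id=row.sseqid,
            pct_identity=float(p),
            aln_length=int(row.length),
            evalue=float(row.evalue),
            bitscore=float(row.bitscore),
        )
        for row, p in zip(df.itertuples(index=False), pident)
    )
    return HitTable(query_genome=query_genome, subject_genome=subject_genome, hits=hits)


def write_hits(table: HitTable, path: PathLike) -> None:
    """Serialize a HitTable back to 12-column outfmt-6 TSV (blast dialect).

    Positional columns not tracked by :class:`AlignmentHit` (mismatch,
    gapopen, coordinates) are written as 0 placeholders; the numeric fields
    the metrics consume (pident, length, evalue, bitscore) round-trip.
    """
    with open(path, "wt") as fh:
        for h in table.hits:
            bits = 0.0 if h.bitscore is None else h.bitscore
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:g}\t{h.aln_length}"
                f"\t0\t0\t0\t0\t0\t0\t{h.evalue:g}\t{bits:g}\n"
            )


# ---------------------------------------------------------------------------
# External tools


def load_profiles() -> dict:
    """Load the shipped profile → command-template mapping."""
    with resources.files("pocpu").joinpath("profiles.json").open() as fh:
        return json.load(fh)


def _log_run(log_path: Optional[PathLike], profile: str, argv: Sequence[str], status: int) -> None:
    if log_path is None:
        return
    stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
    with open(log_path, "at") as fh:
        fh.write(f"{stamp}\t{profile}\t{' '.join(argv)}\texit={status}\n")


def run_external(
    query_fasta: PathLike,
    subject_fasta: PathLike,
    tool_profile: str,
    query_genome: str,
    subject_genome: str,
    run_log: Optional[PathLike] = None,
) -> HitTable:
    """Run a named external aligner profile and parse its tabular output.

    Profiles are defined in the shipped ``profiles.json`` (blastp, blastpdb,
    diamond_fast/sensitive/verysensitive/ultrasensitive, mmseqs2_s*); each
    carries the tool's sensitivity flags and a 1e-5 e-value reporting
    cutoff. Every invocation is appended to ``run_log`` (timestamp, profile,
    command line, exit status) when given.
    """
    if query_genome == subject_genome:
        raise ValueError(f"self-comparison banned: {query_genome!r}")
    profiles = load_profiles()
    if tool_profile not in profiles:
        raise ValueError(
            f"unknown profile {tool_profile!r}; available: {sorted(profiles)}"
        )
    prof = profiles[tool_profile]
    if shutil.which(prof["tool"]) is None:
        raise RuntimeError(
            f"profile {tool_profile!r} needs the {prof['tool']!r} binary, "
            f"which was not found on PATH"
        )
    with tempfile.TemporaryDirectory(prefix="pocpu_aln_") as tmp:
        tmpdir = Path(tmp)
        subst = {
            "query": str(query_fasta),
            "subject": str(subject_fasta),
            "db": str(tmpdir / "subject_db"),
            "out": str(tmpdir / "hits.tsv"),
            "tmpdir": str(tmpdir / "work"),
        }
        for template in list(prof["prepare"]) + [prof["command"]]:
            argv = [arg.format(**subst) for arg in template]
            proc = subprocess.run(argv, capture_output=True, text=True)
            _log_run(run_log, tool_profile, argv, proc.returncode)
            if proc.returncode != 0:
                raise RuntimeError(
                    f"{argv[0]} exited with {proc.returncode}: {proc.stderr.strip()}"
                )
        out = Path(subst["out"])
        if not out.exists() or out.stat().st_size == 0:
            return HitTable(query_genome, subject_genome, hits=())
        return parse_hits(out, prof["dialect"], query_genome, subject_genome)


# ---------------------------------------------------------------------------
# Built-in aligner


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def builtin_align(query: Proteome, subject: Proteome) -> HitTable:
    """All-vs-all Smith–Waterman of two proteomes (BLOSUM62, gap 11/1).

    Emits at most one hit — the best local alignment — per query–subject
    protein pair. A pair is reported when its approximate Karlin–Altschul
    e-value (lambda = 0.267, K = 0.041, search space = query length × total
    subject residues) is below 10. Identity is identical aligned columns
    over alignment columns including gaps. Deterministic given its inputs.
    """
    if query.genome_id == subject.genome_id:
        raise ValueError(f"self-comparison banned: {query.genome_id!r}")
    aligner = _make_aligner()
    subject_residues = sum(rec.length for rec in subject.records)
    hits = []
    for q in query.records:
        for s in subject.records:
            score = aligner.score(q.sequence, s.sequence)
            if score <= 0:
                continue
            evalue = _KA_K * q.length * subject_residues * math.exp(-_KA_LAMBDA * score)
            if evalue >= _BUILTIN_EVALUE_CUTOFF:
                continue
            best = aligner.align(q.sequence, s.sequence)[0]
            counts = best.counts()
            aln_length = counts.identities + counts.mismatches + counts.gaps
            if aln_length == 0:
                continue
            hits.append(
                AlignmentHit(
                    query_id=q.protein_id,
                    subject_id=s.protein_id,
                    pct_identity=100.0 * counts.identities / aln_length,
                    aln_length=aln_length,
                    evalue=evalue,
                    bitscore=(_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2.0),
                )
            )
    return HitTable(query_genome=query.genome_id, subject_genome=subject.genome_id, hits=tuple(hits))
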