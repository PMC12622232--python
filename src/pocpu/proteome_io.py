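"""Proteome (protein FASTA) and taxonomy input.

A proteome is one genome's set of predicted protein sequences; its record
count is the T_Q / T_S denominator term of the POCP formulas, and per-protein
lengths feed the alignment-coverage filter. Taxonomy tables carry the
family/genus labels used as classification ground truth.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PathLike = Union[str, Path]

_GTDB_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence. ``length`` counts residues after '*' stripping."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Proteome:
    """A genome's proteins, in file order. ``total_proteins`` is T_Q (or T_S)."""

    genome_id: str
    records: tuple[ProteinRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"empty proteome for genome {self.genome_id!r}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.protein_id in seen:
                raise ValueError(
                    f"duplicate protein id {rec.protein_id!r} in genome {self.genome_id!r}"
                )
            seen.add(rec.protein_id)

    @property
    def total_proteins(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)


@dataclass(frozen=True, eq=False)
class TaxonomyTable:
    """Genome → (family, genus, species) labels, one row per genome."""

    frame: pd.DataFrame

    REQUIRED = ("genome_id", "family", "genus", "species")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"taxonomy table missing columns: {missing}")
        dup = df["genome_id"][df["genome_id"].duplicated()]
        if not dup.empty:
            raise ValueError(f"duplicate genome_id(s): {sorted(dup.unique())}")
        for col in ("family", "genus"):
            bad = df.loc[df[col].isna() | (df[col].astype(str).str.len() == 0), "genome_id"]
            if not bad.empty:
                raise ValueError(f"empty {col} for genome(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)


def _open_text(path: PathLike):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_proteome(path: PathLike, genome_id: str) -> Proteome:
    """Read a protein FASTA (optionally gzipped) into a :class:`Proteome`.

    The protein id is the first whitespace-delimited token of each header,
    matching how alignment tools report query/subject ids. Sequences are
    uppercased and stop characters ('*') are stripped so that trailing stops
    emitted by gene callers do not inflate query length in the coverage
    filter. Empty files and duplicate ids are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"proteome file not found: {path}")
    records = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper().replace("*", "")
            records.append(ProteinRecord(protein_id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"empty proteome: {path}")
    return Proteome(genome_id=genome_id, records=tuple(records))


def write_proteome(proteome: Proteome, path: PathLike) -> None:
    """Write a proteome back to FASTA (round-trip partner of read_proteome)."""
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.protein_id, description="")
        for rec in proteome.records
    ]
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as handle:
            SeqIO.write(seq_records, handle, "fasta")
    else:
        SeqIO.write(seq_records, str(path), "fasta")


def query_lengths(proteome: Proteome) -> Mapping[str, int]:
    """Map protein_id → residue length, for the aligned-region coverage filter."""
    return {rec.protein_id: rec.length for rec in proteome.records}


def _split_gtdb_taxonomy(tax_string: str) -> dict:
    """Split 'd__...;p__...;...;s__...' into rank fields, prefixes stripped."""
    parts = [p.strip() for p in tax_string.split(";")]
    ranks = {}
    for part in parts:
        for prefix in _GTDB_RANK_PREFIXES:
            if part.startswith(prefix):
                ranks[prefix[0]] = part[len(prefix):]
                break
    return ranks


def read_taxonomy(path: PathLike) -> TaxonomyTable:
    """Read a taxonomy TSV into a validated :class:`TaxonomyTable`.

    Accepts either explicit ``genome_id/family/genus/species`` columns or a
    ``genome_id/gtdb_taxonomy`` pair where the second column is a GTDB-style
    'd__;p__;c__;o__;f__;g__;s__' string, split on ';' with rank prefixes
    stripped. An optional boolean ``valid_name`` column is carried through
    for upstream name-validity curation.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gtdb_taxonomy" in df.columns:
        ranks = df["gtdb_taxonomy"].map(_split_gtdb_taxonomy)
        df = df.assign(
            family=ranks.map(lambda r: r.get("f", "")),
            genus=ranks.map(lambda r: r.get("g", "")),
            species=ranks.map(lambda r: r.get("s", "")),
        ).drop(columns=["gtdb_taxonomy"])
    if "species" not in df.columns:
        df["species"] = ""
    df["species"] = df["species"].fillna("")
    return TaxonomyTable(frame=df.reset_index(drop=True))
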