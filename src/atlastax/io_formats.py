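"""Readers and writers for the external formats the pipeline touches.

Formats handled here: FASTA (queries and reference), taxonomy maps
(two-column TSV, semicolon-delimited ranked lineages), the 14-field BLAST
tabular dialect that carries the aligned strings
(``qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore qseq sseq``), OTU count tables, and the assignment /
partition output tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

NUCLEOTIDES = frozenset("ACGTN")
#: IUPAC nucleotide one-letter codes (ambiguity codes are collapsed to N).
IUPAC_CODES = frozenset("ACGTUNRYSWKMBDHV")

CANONICAL_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Greengenes-style rank prefixes tolerated (and stripped) in lineage strings.
_RANK_PREFIXES = ("k__", "d__", "p__", "c__", "o__", "f__", "g__", "s__")

BLAST_FIELDS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend "
    "sstart send evalue bitscore qseq sseq"
).split()


class FormatError(ValueError):
    """Raised on malformed input files or inconsistent records."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A, C, G, T, N}, upper-cased."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise FormatError(f"invalid sequence id {self.id!r}")
        if len(self.seq) == 0:
            raise FormatError(f"empty sequence for id {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TaxonomyLineage:
    """A ranked lineage, outermost rank first.

    ``names`` holds taxon names aligned to the canonical seven ranks
    (domain, phylum, class, order, family, genus, species); an empty string
    is an explicit missing placeholder. Lineages deeper than seven ranks
    keep their extra levels, named ``level8``, ``level9``, ...
    """

    names: tuple[str, ...] = ()

    @property
    def rank_names(self) -> tuple[str, ...]:
        extra = tuple(f"level{i + 1}" for i in range(len(CANONICAL_RANKS), len(self.names)))
        return CANONICAL_RANKS[: len(self.names)] + extra

    @property
    def depth(self) -> int:
        """Number of leading non-empty ranks."""
        d = 0
        for name in self.names:
            if not name:
                break
            d += 1
        return d

    @property
    def deepest_rank(self) -> str:
        """Rank name of the deepest resolved level, or ``"root"``."""
        d = self.depth
        return self.rank_names[d - 1] if d else "root"

    @property
    def species(self) -> str | None:
        if len(self.names) >= 7 and self.names[6]:
            return self.names[6]
        return None

    def __str__(self) -> str:
        return ";".join(self.names[: self.depth]) if self.depth else ""

    def __bool__(self) -> bool:
        return self.depth > 0


@dataclass(frozen=True)
class BlastHit:
    """One pairwise match in the 14-field tabular dialect.

    ``qseq``/``sseq`` are the gapped aligned strings; coordinates are
    1-based inclusive, ``pident`` on the printed 0-100 scale.
    """

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qseq: str
    sseq: str

    def __post_init__(self) -> None:
        if len(self.qseq) != len(self.sseq):
            raise FormatError(
                f"aligned strings differ in length for ({self.qseqid}, {self.sseqid})"
            )
        if len(self.qseq) != self.length:
            raise FormatError(
                f"alignment length field {self.length} != |qseq| {len(self.qseq)} "
                f"for ({self.qseqid}, {self.sseqid})"
            )
        if any(q == "-" and s == "-" for q, s in zip(self.qseq, self.sseq)):
            raise FormatError(
                f"all-gap column in alignment ({self.qseqid}, {self.sseqid})"
            )

    def to_line(self) -> str:
        vals = [
            self.qseqid, self.sseqid, f"{self.pident:.3f}", str(self.length),
            str(self.mismatch), str(self.gapopen), str(self.qstart), str(self.qend),
            str(self.sstart), str(self.send), f"{self.evalue:g}",
            f"{self.bitscore:g}", self.qseq, self.sseq,
        ]
        return "\t".join(vals)


@dataclass
class CountTable:
    """A features x samples table of non-negative integer counts.

    ``counts`` is a pandas DataFrame indexed by feature id with sample ids
    as columns; ``groups`` optionally maps sample id to a group label
    (e.g. case / control) for prevalence filtering.
    """

    counts: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any() or self.counts.columns.duplicated().any():
            raise FormatError("duplicate feature or sample ids in count table")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative counts in count table")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into upper-cased :class:`SequenceRecord` objects.

    Wrapped sequence lines are concatenated and record order is preserved.
    Characters outside {A,C,G,T,N} are replaced with ``N`` (with a warning);
    a duplicate id or an empty sequence is a hard error.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for id {rec.id}")
        if not NUCLEOTIDES.issuperset(seq):
            bad = sorted(set(seq) - NUCLEOTIDES)
            warnings.warn(
                f"record {rec.id}: characters {bad} replaced with N", stacklevel=2
            )
            seq = "".join(ch if ch in NUCLEOTIDES else "N" for ch in seq)
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records to FASTA with fixed line wrapping (deterministic bytes)."""
    bio = (
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_taxonomy_map(path: str | Path) -> dict[str, TaxonomyLineage]:
    """Read a two-column TSV mapping sequence id -> ranked lineage.

    The lineage column is split on ``;`` with surrounding whitespace
    trimmed; Greengenes-style rank prefixes (``g__`` etc.) are stripped.
    Trailing empty ranks are recorded as missing. A line with a column
    count other than two is a hard error naming the line number.
    """
    out: dict[str, TaxonomyLineage] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            seq_id, lineage_str = parts[0].strip(), parts[1]
            names = []
            for token in lineage_str.split(";"):
                token = token.strip()
                for prefix in _RANK_PREFIXES:
                    if token.lower().startswith(prefix):
                        token = token[len(prefix):].strip()
                        break
                names.append(token)
            while names and not names[-1]:
                names.pop()
            out[seq_id] = TaxonomyLineage(tuple(names))
    return out


def _parse_hit_line(line: str, lineno: int, path: str) -> BlastHit:
    cols = line.split("\t")
    if len(cols) != 14:
        raise FormatError(
            f"{path}: line {lineno}: expected 14 columns, got {len(cols)}"
        )
    try:
        return BlastHit(
            qseqid=cols[0], sseqid=cols[1], pident=float(cols[2]),
            length=int(cols[3]), mismatch=int(cols[4]), gapopen=int(cols[5]),
            qstart=int(cols[6]), qend=int(cols[7]), sstart=int(cols[8]),
            send=int(cols[9]), evalue=float(cols[10]), bitscore=float(cols[11]),
            qseq=cols[12].upper(), sseq=cols[13].upper(),
        )
    except ValueError as exc:
        raise FormatError(f"{path}: line {lineno}: {exc}") from exc


def parse_blast_tabular(path: str | Path) -> dict[str, list[BlastHit]]:
    """Parse the 14-field tabular search output, grouped by query.

    Within each query group only the highest-bitscore HSP per subject is
    retained, and hits are sorted by descending bitscore with ties broken
    by ascending subject id — a total order, so downstream split searches
    are deterministic across runs and platforms. Group order follows first
    appearance in the file.
    """
    best: dict[str, dict[str, BlastHit]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            hit = _parse_hit_line(line, lineno, str(path))
            per_query = best.setdefault(hit.qseqid, {})
            prev = per_query.get(hit.sseqid)
            if prev is None or hit.bitscore > prev.bitscore:
                per_query[hit.sseqid] = hit
    return {
        qid: sorted(hits.values(), key=lambda h: (-h.bitscore, h.sseqid))
        for qid, hits in best.items()
    }


def write_blast_tabular(
    hits_by_query: Mapping[str, Sequence[BlastHit]], path: str | Path
) -> None:
    """Write hits back out in the same 14-field dialect (round-trip safe)."""
    with open(path, "w") as fh:
        for qid in hits_by_query:
            for hit in hits_by_query[qid]:
                fh.write(hit.to_line() + "\n")


def read_count_table(
    path: str | Path, groups: Mapping[str, str] | None = None
) -> CountTable:
    """Read a features x samples TSV whose first header cell is ``feature_id``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "feature_id"
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountTable(df.astype(int), dict(groups or {}))


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def write_outputs(assignments, partition_summaries, prefix: str | Path) -> tuple[Path, Path]:
    """Write the assignment and partition report tables.

    ``<prefix>.assignments.tsv`` has one row per query, in input order:
    query id, partition id (or ``unclassified``), membership fraction, MRCA
    lineage, and the semicolon-joined species list; unclassified rows carry
    ``NA`` sentinels. ``<prefix>.partitions.tsv`` has one row per partition
    in ascending id order: id, comma-joined member ids, MRCA lineage, MRCA
    rank, and size. Output bytes are stable across reruns.
    """
    prefix = Path(prefix)
    by_id = {s.partition_id: s for s in partition_summaries}
    for a in assignments:
        if a.partition_id is not None and a.partition_id not in by_id:
            raise FormatError(
                f"assignment for {a.query_id} references unknown partition "
                f"{a.partition_id}"
            )
    assign_path = prefix.with_name(prefix.name + ".assignments.tsv")
    part_path = prefix.with_name(prefix.name + ".partitions.tsv")
    with open(assign_path, "w") as fh:
        fh.write("query_id\tpartition\tfraction\tmrca\tspecies\n")
        for a in assignments:
            if a.partition_id is None:
                fh.write(f"{a.query_id}\tunclassified\tNA\tNA\tNA\n")
            else:
                summ = by_id[a.partition_id]
                species = ";".join(summ.species) if summ.species else "NA"
                lineage = str(summ.lineage) if summ.lineage else "NA"
                fh.write(
                    f"{a.query_id}\t{a.partition_id}\t{a.fraction:.4f}\t"
                    f"{lineage}\t{species}\n"
                )
    with open(part_path, "w") as fh:
        fh.write("partition_id\tmembers\tmrca\tmrca_rank\tsize\n")
        for summ in sorted(partition_summaries, key=lambda s: s.partition_id):
            lineage = str(summ.lineage) if summ.lineage else "NA"
            fh.write(
                f"{summ.partition_id}\t{','.join(sorted(summ.members))}\t"
                f"{lineage}\t{summ.mrca_rank}\t{len(summ.members)}\n"
            )
    return assign_path, part_path
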