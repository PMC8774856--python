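"""Sequence, feature-table and alignment I/O.

Everything downstream assumes the conventions enforced here:

* coordinates are 1-based inclusive on the heavy (H) strand, the convention
  used by GenBank feature tables;
* light-strand (L) features are stored by their H-strand coordinates plus a
  strand flag and are reverse-complemented on extraction;
* sequences are uppercase DNA over ``{A, C, G, T, N}`` (RNA input is accepted,
  U is mapped to T);
* wrap-around (origin-spanning) features are not supported — they must be
  split before ingestion.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import AlphabetError, AlignmentError, FastaError, FeatureError

DNA_ALPHABET = frozenset("ACGTN")
GAPPED_ALPHABET = frozenset("ACGTN-")

FEATURE_KINDS = ("PCG", "tRNA", "rRNA", "origin", "control_region", "other")

#: mapping of common GFF3 feature types onto the kinds used here
_GFF_TYPE_TO_KIND = {
    "CDS": "PCG",
    "gene": "other",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "rep_origin": "origin",
    "D_loop": "control_region",
    "D-loop": "control_region",
    "misc_feature": "other",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N, gaps preserved)."""
    return str(Seq(seq).reverse_complement())


def _clean_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"record {record_id!r} contains non-IUPAC characters: {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` in file order.

    Sequences are uppercased, U is mapped to T. Raises :class:`FastaError`
    for empty files or duplicate ids and :class:`AlphabetError` for
    characters outside ``{A,C,G,T,N}``.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, _clean_sequence(str(rec.seq), rec.id)))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated feature: a 1-based inclusive H-strand span with strand flag."""

    name: str
    kind: str
    start: int
    end: int
    strand: str
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise FeatureError(f"{self.name}: unknown feature kind {self.kind!r}")
        if self.start < 1:
            raise FeatureError(f"{self.name}: start {self.start} violates 1-based convention")
        if self.start > self.end:
            raise FeatureError(
                f"{self.name}: start > end ({self.start} > {self.end}); "
                "wrap-around features must be split before ingestion"
            )
        if self.strand not in ("H", "L"):
            raise FeatureError(f"{self.name}: strand must be 'H' or 'L', got {self.strand!r}")
        if self.anticodon is not None and len(self.anticodon) != 3:
            raise FeatureError(f"{self.name}: anticodon must be a 3-mer")

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    def validate_against(self, genome_length: int) -> None:
        if self.end > genome_length:
            raise FeatureError(
                f"{self.name}: end {self.end} outside [1, {genome_length}]"
            )


@dataclass
class AnnotatedMitogenome:
    """A circular mitogenome sequence with its ordered feature table."""

    id: str
    sequence: str
    circular: bool = True
    features: list[FeatureRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AlphabetError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise AlphabetError(f"{self.id}: non-IUPAC characters {sorted(bad)}")
        for f in self.features:
            f.validate_against(len(self.sequence))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def extract(self, feature: FeatureRecord) -> str:
        """Feature sequence in reading orientation (revcomp for L-strand)."""
        sub = self.sequence[feature.start - 1 : feature.end]
        return revcomp(sub) if feature.strand == "L" else sub

    def slice_h(self, start: int, end: int) -> str:
        """H-strand slice by 1-based inclusive coordinates."""
        return self.sequence[start - 1 : end]


@dataclass
class MultipleAlignment:
    """Aligned haplotypes over ``{A,C,G,T,N,-}`` with a designated reference."""

    ids: list[str]
    rows: list[str]
    reference_id: str

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate row ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError(f"rows are not equal length: {sorted(lengths)}")
        if self.reference_id not in self.ids:
            raise AlignmentError(f"reference id {self.reference_id!r} not among rows")
        for rid, row in zip(self.ids, self.rows):
            bad = set(row) - GAPPED_ALPHABET
            if bad:
                raise AlphabetError(f"row {rid!r}: characters {sorted(bad)} not allowed")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]


def read_alignment(path: str | Path, reference_id: str | None = None) -> MultipleAlignment:
    """Read an aligned FASTA file; gaps ('-') are preserved."""
    ids, rows, seen = [], [], set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        ids.append(rec.id)
        rows.append(seq)
    if not ids:
        raise FastaError(f"no FASTA records found in {path}")
    return MultipleAlignment(ids, rows, reference_id or ids[0])


def write_alignment(path: str | Path, aln: MultipleAlignment) -> None:
    write_fasta(path, zip(aln.ids, aln.rows))


def _parse_tsv_features(path: str | Path) -> list[FeatureRecord]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FeatureError(f"{path}:{lineno}: expected 6 tab-separated columns")
            name, kind, start, end, strand, anticodon = parts[:6]
            feats.append(
                FeatureRecord(
                    name=name,
                    kind=kind,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    anticodon=None if anticodon in (".", "") else anticodon,
                )
            )
    return feats


def _parse_gff3_features(path: str | Path) -> list[FeatureRecord]:
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FeatureError(f"malformed GFF3 line: {line[:60]}...")
            _, _, ftype, start, end, _, strand, _, attrs = cols
            if ftype == "gene":  # gene lines duplicate their CDS/tRNA/rRNA children
                continue
            kind = _GFF_TYPE_TO_KIND.get(ftype)
            if kind is None:
                raise FeatureError(f"unknown GFF3 feature type {ftype!r}")
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            name = attr.get("Name") or attr.get("gene") or attr.get("ID") or ftype
            feats.append(
                FeatureRecord(
                    name=name,
                    kind=kind,
                    start=int(start),
                    end=int(end),
                    strand="L" if strand == "-" else "H",
                    anticodon=attr.get("anticodon"),
                )
            )
    return feats


def read_features(path: str | Path, genome_length: int) -> list[FeatureRecord]:
    """Read a feature table (GFF3 by extension, else the 6-column TSV dialect).

    Every record is validated against the 1-based coordinate conventions and
    the genome length.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        feats = _parse_gff3_features(path)
    else:
        feats = _parse_tsv_features(path)
    for f in feats:
        f.validate_against(genome_length)
    return feats


def write_features(path: str | Path, features: Sequence[FeatureRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("# name\tkind\tstart\tend\tstrand\tanticodon\n")
        for f in features:
            fh.write(
                f"{f.name}\t{f.kind}\t{f.start}\t{f.end}\t{f.strand}\t"
                f"{f.anticodon or '.'}\n"
            )


def load_feature_template() -> list[FeatureRecord]:
    """The bundled mink gene-layout template (a 16,504 bp circular genome)."""
    ref = resources.files("mitoprofile.data").joinpath("mink_features.tsv")
    with resources.as_file(ref) as p:
        return _parse_tsv_features(p)


TEMPLATE_GENOME_LENGTH = 16_504


def intergenic_and_overlaps(
    features: Sequence[FeatureRecord],
    genome_length: int,
    circular: bool = True,
) -> list[tuple[tuple[str, str], int]]:
    """Spacing between consecutive features: ``next.start - prev.end - 1``.

    Negative values are overlaps, 0 means abutting. When ``circular`` the
    closure pair (last, first) is included, measured across the origin.
    """
    feats = sorted(features, key=lambda f: (f.start, f.end))
    out = []
    for prev, nxt in zip(feats, feats[1:]):
        out.append(((prev.name, nxt.name), nxt.start - prev.end - 1))
    if circular and len(feats) > 1:
        first, last = feats[0], feats[-1]
        out.append(((last.name, first.name), first.start + genome_length - last.end - 1))
    return out


def read_genome(
    fasta_path: str | Path,
    features_path: str | Path | None = None,
    circular: bool = True,
) -> AnnotatedMitogenome:
    """Read a single-record FASTA (plus optional feature table) into a genome."""
    records = read_fasta(fasta_path)
    if len(records) != 1:
        raise FastaError(f"expected a single record in {fasta_path}, found {len(records)}")
    gid, seq = records[0]
    feats = read_features(features_path, len(seq)) if features_path else []
    return AnnotatedMitogenome(id=gid, sequence=seq, circular=circular, features=feats)


def write_genome(
    genome: AnnotatedMitogenome,
    fasta_path: str | Path,
    features_path: str | Path | None = None,
) -> None:
    write_fasta(fasta_path, [(genome.id, genome.sequence)])
    if features_path is not None:
        write_features(features_path, genome.features)


def log(msg: str, quiet: bool = False) -> None:
    if not quiet:
        print(msg, file=sys.stderr)
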