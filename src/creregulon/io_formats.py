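"""Readers and writers for the external formats the pipeline touches.

Internal coordinates are 0-based half-open throughout the package.  GFF3 is
1-based inclusive and is converted on read; BED output converts back on write,
so composing the two conversions is the identity.

The DNA alphabet is {A, C, G, T, N}; lowercase is folded to uppercase on read.
IUPAC ambiguity codes other than N are rejected by default — motif scoring is
defined over the four bases, and N scores as background (log-odds 0) — but can
be mapped to N via ``map_ambiguous_to_n``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from creregulon.cre_scan import CreHit
    from creregulon.expression import ExpressionMatrix

DNA_ALPHABET = frozenset("ACGTN")
_AMBIGUITY = frozenset("RYSWKMBDHV")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (one FASTA record), uppercase over {A,C,G,T,N}."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FeatureRecord:
    """One annotated feature (gene/CDS).

    ``start0``/``end0`` are 0-based half-open genomic coordinates; the 1-based
    inclusive GFF3 view is available via :attr:`start1`/:attr:`end1`.
    """

    contig: str
    start0: int
    end0: int
    strand: str
    feature_id: str
    feature_type: str = "gene"
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"feature {self.feature_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (0 <= self.start0 < self.end0):
            raise ValueError(
                f"feature {self.feature_id!r}: invalid interval [{self.start0}, {self.end0})"
            )

    @property
    def start1(self) -> int:
        return self.start0 + 1

    @property
    def end1(self) -> int:
        return self.end0

    def __len__(self) -> int:
        return self.end0 - self.start0


def normalize_sequence(seq: str, *, map_ambiguous_to_n: bool = False, origin: str = "") -> str:
    """Uppercase ``seq`` and validate it against the {A,C,G,T,N} alphabet.

    Ambiguity codes (R, Y, S, W, ...) are rejected with the offending position
    unless ``map_ambiguous_to_n`` is set, in which case they become N.  Any
    other character is always an error.
    """
    folded = seq.upper()
    out = []
    for i, ch in enumerate(folded):
        if ch in DNA_ALPHABET:
            out.append(ch)
        elif ch in _AMBIGUITY and map_ambiguous_to_n:
            out.append("N")
        else:
            where = f" in {origin}" if origin else ""
            raise ValueError(f"illegal residue {ch!r} at position {i}{where}")
    return "".join(out)


def read_fasta(path: str | Path, *, map_ambiguous_to_n: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, in file order."""
    records = [
        SequenceRecord(
            id=rec.id,
            sequence=normalize_sequence(
                str(rec.seq), map_ambiguous_to_n=map_ambiguous_to_n, origin=rec.id
            ),
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


_SURFACED_ATTRS = ("cog", "operon")


def read_gff(path: str | Path, *, feature_types: tuple[str, ...] = ("gene", "CDS")) -> list[FeatureRecord]:
    """Read gene/CDS features from a GFF3 file.

    Coordinates are converted to the internal 0-based half-open convention.
    The attribute keys ``cog`` (COG category letter) and ``operon`` (operon id)
    are surfaced into :attr:`FeatureRecord.attributes` when present, alongside
    all other key=value attributes.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[FeatureRecord] = []
    for ft in feature_types:
        for f in db.features_of_type(ft, order_by="start"):
            if f.end < f.start:
                raise ValueError(f"feature {f.id!r}: end ({f.end}) < start ({f.start})")
            if f.strand not in ("+", "-"):
                raise ValueError(
                    f"feature {f.id!r}: strand must be '+' or '-', got {f.strand!r}"
                )
            attrs = {k: ";".join(v) for k, v in f.attributes.items() if k != "ID"}
            features.append(
                FeatureRecord(
                    contig=f.seqid,
                    start0=f.start - 1,
                    end0=f.end,
                    strand=f.strand,
                    feature_id=f.id,
                    feature_type=ft,
                    attributes=attrs,
                )
            )
    features.sort(key=lambda f: (f.contig, f.start0))
    return features


def write_gff(features: Iterable[FeatureRecord], path: str | Path) -> None:
    """Write features as GFF3, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(
                [f"ID={f.feature_id}"] + [f"{k}={v}" for k, v in f.attributes.items()]
            )
            fh.write(
                "\t".join(
                    [
                        f.contig,
                        "creregulon",
                        f.feature_type,
                        str(f.start1),
                        str(f.end1),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_expression(path: str | Path, *, delimiter: str = "|") -> "ExpressionMatrix":
    """Read a genes × samples TSV into an :class:`~creregulon.expression.ExpressionMatrix`.

    The first column holds gene ids; each remaining column header encodes a
    sample as ``strain<delimiter>phase<delimiter>replicate`` (e.g.
    ``824WT|M|1``).  Missing values and duplicate gene ids are errors.
    """
    import pandas as pd

    from creregulon.expression import ExpressionMatrix, SampleKey

    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id(s): {dupes}")
    samples = []
    for col in df.columns:
        parts = str(col).split(delimiter)
        if len(parts) != 3:
            raise ValueError(
                f"unparseable sample header {col!r}: expected "
                f"'strain{delimiter}phase{delimiter}replicate'"
            )
        try:
            rep = int(parts[2])
        except ValueError as exc:
            raise ValueError(f"unparseable replicate in header {col!r}") from exc
        samples.append(SampleKey(strain=parts[0], phase=parts[1], replicate=rep))
    if df.isna().any().any():
        row, col = next(
            (r, c) for r in df.index for c in df.columns if pd.isna(df.at[r, c])
        )
        raise ValueError(f"missing value at gene {row!r}, sample {col!r}")
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        samples=samples,
        values=df.to_numpy(dtype=float),
    )


def write_expression(matrix: "ExpressionMatrix", path: str | Path, *, delimiter: str = "|") -> None:
    matrix.to_frame(delimiter=delimiter).to_csv(path, sep="\t", float_format="%.10g")


_SITE_FIELDS = (
    "contig",
    "start0",
    "end0",
    "strand",
    "score",
    "context",
    "associated_gene",
    "inclusion",
    "status",
    "removal_reason",
)


def write_sites(hits: "Iterable[CreHit]", bed_path: str | Path, tsv_path: str | Path | None = None) -> None:
    """Write candidate CRE sites as BED6 plus a full-field TSV sidecar.

    BED is 0-based half-open; the score column is the bit score × 100, rounded.
    The BED name field is ``gene@context``; the TSV carries every field
    including kept/removed status and the removal reason.
    """
    bed_path = Path(bed_path)
    if tsv_path is None:
        tsv_path = bed_path.with_suffix(".tsv")
    hits = list(hits)
    with open(bed_path, "w") as bed:
        for h in hits:
            name = f"{h.associated_gene or 'NA'}@{h.context}"
            bed.write(
                f"{h.contig}\t{h.start0}\t{h.end0}\t{name}\t{round(h.score * 100)}\t{h.strand}\n"
            )
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_SITE_FIELDS)
        for h in hits:
            writer.writerow(
                [
                    h.contig,
                    h.start0,
                    h.end0,
                    h.strand,
                    repr(h.score),
                    h.context,
                    h.associated_gene or "",
                    h.inclusion,
                    h.status,
                    h.removal_reason or "",
                ]
            )


def read_sites(tsv_path: str | Path) -> "list[CreHit]":
    """Read back the TSV sidecar written by :func:`write_sites`."""
    from creregulon.cre_scan import CreHit

    hits = []
    with open(tsv_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            hits.append(
                CreHit(
                    contig=row["contig"],
                    start0=int(row["start0"]),
                    end0=int(row["end0"]),
                    strand=row["strand"],
                    score=float(row["score"]),
                    context=row["context"],
                    associated_gene=row["associated_gene"] or None,
                    inclusion=row["inclusion"],
                    status=row["status"],
                    removal_reason=row["removal_reason"] or None,
                )
            )
    return hits
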