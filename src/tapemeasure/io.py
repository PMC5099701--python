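"""FASTA and GFF3 input/output plus the shared feature-annotation container.

Coordinates are 1-based inclusive at every interface, matching both the
GFF3 convention and the residue numbering used throughout the package
(e.g. the first hydrophobic region I390-Y460).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Feature",
    "SequenceAnnotation",
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_gff3",
]

GFF_SOURCE = "tapemeasure"


@dataclass(frozen=True)
class Feature:
    """One annotated interval (1-based inclusive)."""

    type: str
    start: int
    end: int
    feature_id: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid feature span {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SequenceAnnotation:
    """All features annotated on one sequence."""

    sequence_id: str
    length: int
    features: list[Feature] = field(default_factory=list)

    def of_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.type == ftype]

    def get(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)


def write_fasta(sequence: str, path, sequence_id: str = "synthetic_tmp",
                description: str = "") -> None:
    try:
        record = SeqRecord(Seq(sequence), id=sequence_id, description=description)
        SeqIO.write([record], str(path), "fasta")
    except OSError as exc:
        raise OSError(f"cannot write FASTA to {path}: {exc}") from exc


def read_fasta(path) -> tuple[str, str]:
    """Read the first record of a FASTA file as ``(id, sequence)``."""
    try:
        record = next(SeqIO.parse(str(path), "fasta"))
    except OSError as exc:
        raise OSError(f"cannot read FASTA from {path}: {exc}") from exc
    except StopIteration:
        raise ValueError(f"no FASTA records in {path}") from None
    return record.id, str(record.seq)


def _escape(value: str) -> str:
    return str(value).replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def _unescape(value: str) -> str:
    return value.replace("%2C", ",").replace("%3D", "=").replace("%3B", ";")


def write_gff3(annotation: SequenceAnnotation, path) -> None:
    """Write the annotation as GFF3; an empty annotation yields a valid
    header-only file."""
    lines = ["##gff-version 3",
             f"##sequence-region {annotation.sequence_id} 1 {annotation.length}"]
    for f in annotation.features:
        attrs = {"ID": f.feature_id, **f.attributes}
        attr_text = ";".join(f"{k}={_escape(v)}" for k, v in attrs.items())
        lines.append("\t".join([
            annotation.sequence_id, GFF_SOURCE, f.type,
            str(f.start), str(f.end), ".", ".", ".", attr_text,
        ]))
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write GFF3 to {path}: {exc}") from exc


def read_gff3(path) -> SequenceAnnotation:
    """Inverse of :func:`write_gff3` (round-trips exactly)."""
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise OSError(f"cannot read GFF3 from {path}: {exc}") from exc
    sequence_id, length = "", 0
    features: list[Feature] = []
    for line in text.splitlines():
        if line.startswith("##sequence-region"):
            _, sequence_id, _, length = line.split()
            length = int(length)
            continue
        if not line or line.startswith("#"):
            continue
        seqid, _source, ftype, start, end, *_rest, attr_text = line.split("\t")
        attrs = {}
        for item in attr_text.split(";"):
            k, _, v = item.partition("=")
            attrs[k] = _unescape(v)
        fid = attrs.pop("ID", "")
        features.append(Feature(ftype, int(start), int(end), fid, attrs))
        sequence_id = sequence_id or seqid
    return SequenceAnnotation(sequence_id, length, features)
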