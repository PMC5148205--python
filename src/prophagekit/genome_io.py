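"""Annotated genome I/O and coordinate conventions.

All user-facing coordinates in this package are 1-based inclusive (the GenBank
convention). BED export converts to 0-based half-open. ``N`` bases are legal in
sequences but never participate in repeat matches or motif hits elsewhere in
the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FeatureKind = Literal["CDS", "tmRNA", "gene", "other"]


class GenomeFormatError(ValueError):
    """Malformed or unsupported genome input."""


class BoundsError(IndexError):
    """Coordinates outside [1, len(seq)]."""


@dataclass(frozen=True)
class Feature:
    """An annotated interval on the host genome (1-based inclusive)."""

    locus_tag: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    partial: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"feature {self.locus_tag}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.locus_tag}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """A single replicon with features.

    ``seq`` is stored uppercase over {A, C, G, T, N}.
    """

    id: str
    seq: str
    topology: str = "linear"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise GenomeFormatError(f"record {self.id}: invalid bases {sorted(bad)}")
        if self.topology not in ("linear", "circular"):
            raise GenomeFormatError(f"record {self.id}: bad topology {self.topology}")
        seen: set[str] = set()
        for f in self.features:
            if not (1 <= f.start <= f.end <= len(self.seq)):
                raise BoundsError(
                    f"feature {f.locus_tag} [{f.start},{f.end}] outside "
                    f"[1,{len(self.seq)}]"
                )
            if f.locus_tag in seen:
                raise GenomeFormatError(f"duplicate locus_tag {f.locus_tag}")
            seen.add(f.locus_tag)

    def __len__(self) -> int:
        return len(self.seq)

    def feature(self, locus_tag: str) -> Feature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(locus_tag)

    def features_overlapping(self, start: int, end: int) -> list[Feature]:
        """Features whose interval intersects [start, end] (1-based inclusive)."""
        return [f for f in self.features if f.start <= end and f.end >= start]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_region(g: GenomeRecord | str, start: int, end: int, strand: str = "+") -> str:
    """Extract [start, end] (1-based inclusive); minus strand reverse-complements."""
    seq = g.seq if isinstance(g, GenomeRecord) else g
    if not (1 <= start <= end <= len(seq)):
        raise BoundsError(f"region [{start},{end}] outside [1,{len(seq)}]")
    sub = seq[start - 1 : end]
    return reverse_complement(sub) if strand == "-" else sub


def gene_sequence(g: GenomeRecord, feature: Feature) -> str:
    """Coding-strand sequence of a feature."""
    return extract_region(g, feature.start, feature.end, feature.strand)


_KIND_MAP = {"CDS": "CDS", "tmRNA": "tmRNA", "gene": "gene"}


def _feature_from_seqfeature(sf: SeqFeature, idx: int) -> Feature | None:
    if sf.type == "source":
        return None
    kind = _KIND_MAP.get(sf.type, "other")
    quals = sf.qualifiers
    tag = (quals.get("locus_tag") or quals.get("gene") or [f"feature_{idx}"])[0]
    start = int(sf.location.start) + 1  # Biopython is 0-based half-open
    end = int(sf.location.end)
    strand = "-" if sf.location.strand == -1 else "+"
    partial = "<" in str(sf.location) or ">" in str(sf.location)
    return Feature(locus_tag=tag, kind=kind, start=start, end=end,
                   strand=strand, partial=partial)


def read_genome(path: str | Path, format: str = "fasta") -> GenomeRecord:
    """Read one replicon from a FASTA or GenBank flat file.

    FASTA yields an empty feature list. Multi-record files are rejected
    (one replicon per run).
    """
    if format not in ("fasta", "genbank"):
        raise GenomeFormatError(f"unknown format {format!r}")
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), format))
    except ValueError as exc:
        raise GenomeFormatError(f"{path}: {exc}") from exc
    if not records:
        raise GenomeFormatError(f"{path}: no records parsed as {format}")
    if len(records) > 1:
        raise GenomeFormatError(f"{path}: {len(records)} records; expected one replicon")
    rec = records[0]
    topology = "linear"
    if format == "genbank":
        topology = rec.annotations.get("topology", "linear")
        if topology not in ("linear", "circular"):
            topology = "linear"
    features: list[Feature] = []
    seen: set[str] = set()
    if format == "genbank":
        for i, sf in enumerate(rec.features):
            f = _feature_from_seqfeature(sf, i)
            if f is None or f.locus_tag in seen:
                continue
            seen.add(f.locus_tag)
            features.append(f)
    return GenomeRecord(id=rec.id, seq=str(rec.seq), topology=topology,
                        features=features)


def write_genome(g: GenomeRecord, path: str | Path, format: str = "fasta") -> None:
    """Write FASTA (always) or GenBank (with features)."""
    path = Path(path)
    rec = SeqRecord(Seq(g.seq), id=g.id, description="")
    if format == "fasta":
        SeqIO.write([rec], str(path), "fasta")
        return
    if format != "genbank":
        raise GenomeFormatError(f"unknown format {format!r}")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = g.topology
    for f in g.features:
        loc = SimpleLocation(f.start - 1, f.end, strand=(-1 if f.strand == "-" else 1))
        rec.features.append(
            SeqFeature(loc, type=f.kind if f.kind != "other" else "misc_feature",
                       qualifiers={"locus_tag": [f.locus_tag]})
        )
    SeqIO.write([rec], str(path), "genbank")


def features_to_bed(g: GenomeRecord) -> str:
    """Feature table as 6-column BED text (0-based half-open)."""
    lines = []
    for f in g.features:
        lines.append(
            f"{g.id}\t{f.start - 1}\t{f.end}\t{f.locus_tag}\t0\t{f.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def with_features(g: GenomeRecord, features: Iterable[Feature]) -> GenomeRecord:
    return replace(g, features=list(features))
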