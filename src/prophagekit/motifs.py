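"""Exact motif scanning in promoter windows.

H-NS, the xenogeneic silencer of horizontally acquired DNA, binds AT-rich
sites; a reported binding motif is 5'-GATAATG-3'. Scanning a promoter window
upstream of an excisionase gene for this motif distinguishes H-NS-silenced
from non-silenced prophage excision modules. The scan is exact (no ambiguity
codes, no PWM); overlapping occurrences are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import GenomeRecord, extract_region, reverse_complement

HNS_MOTIF = "GATAATG"
DEFAULT_WINDOW = 300


@dataclass(frozen=True)
class MotifHit:
    promoter: str
    offset: int      # 1-based within the scanned window
    strand: str      # "+" = as given, "-" = reverse complement
    matched_seq: str


def scan_promoter(
    window_seq: str,
    motif: str = HNS_MOTIF,
    strands: str = "given",
    promoter: str = "window",
) -> list[MotifHit]:
    """All exact occurrences of the motif, overlapping allowed, ordered by offset.

    ``strands`` is "given" (scan the window as supplied, 5'->3') or "both"
    (additionally scan for the motif's reverse complement). ``N`` never
    matches.
    """
    motif = motif.upper()
    if len(motif) < 4 or set(motif) - set("ACGT"):
        raise ValueError("motif must be >= 4 nt over A/C/G/T (exact scan only)")
    if strands not in ("given", "both"):
        raise ValueError(f"strands must be 'given' or 'both', got {strands!r}")
    window_seq = window_seq.upper()

    def occurrences(pattern: str, strand: str) -> list[MotifHit]:
        hits = []
        start = window_seq.find(pattern)
        while start >= 0:
            hits.append(MotifHit(promoter=promoter, offset=start + 1,
                                 strand=strand, matched_seq=pattern))
            start = window_seq.find(pattern, start + 1)
        return hits

    hits = occurrences(motif, "+")
    if strands == "both":
        rc = reverse_complement(motif)
        hits += occurrences(rc, "-")
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def promoter_window(g: GenomeRecord, locus_tag: str,
                    upstream: int = DEFAULT_WINDOW) -> str:
    """Coding-strand sequence upstream of a gene's start codon (clamped at the
    replicon edge)."""
    feat = g.feature(locus_tag)
    if feat.strand == "+":
        start = max(1, feat.start - upstream)
        end = feat.start - 1
        if end < start:
            return ""
        return extract_region(g, start, end, "+")
    start = feat.end + 1
    end = min(len(g.seq), feat.end + upstream)
    if end < start:
        return ""
    return extract_region(g, start, end, "-")


def scan_gene_promoter(g: GenomeRecord, locus_tag: str,
                       motif: str = HNS_MOTIF, upstream: int = DEFAULT_WINDOW,
                       strands: str = "given") -> list[MotifHit]:
    window = promoter_window(g, locus_tag, upstream)
    if not window:
        return []
    return scan_promoter(window, motif=motif, strands=strands,
                         promoter=locus_tag)


def hits_to_tsv(hits: list[MotifHit]) -> str:
    lines = ["promoter\toffset\tstrand\tmatched_seq"]
    lines += [f"{h.promoter}\t{h.offset}\t{h.strand}\t{h.matched_seq}"
              for h in hits]
    return "\n".join(lines) + "\n"
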