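"""In-silico site-specific recombination between attL and attR.

Excision of an integrated element by a tyrosine recombinase crosses over
within the exact shared core, leaving one core copy on the chromosome (the
regenerated attB) and one on the excised circle (attP). When the sequence
context flanking the two copies differs inside the anchor gene, excision
mutates the gene: the classic case is a one-nucleotide deletion at the 3' end
of a tmRNA whose final bases are templated by the attR flank after excision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

from Bio import Align

from .att_finder import AttSitePair, DEFAULT_FLANK_WIDTH
from .genome_io import Feature, GenomeRecord, extract_region, reverse_complement


class CrossoverPolicy(str, Enum):
    """Which core copy is written at each junction.

    With an exact shared core (the AttSitePair invariant) every crossover
    point yields the same products, so the policy only matters for hypothetical
    degenerate cores; it is kept explicit for reproducibility.
    """

    KEEP_ATTL_COPY = "keep_attL_copy"
    KEEP_ATTR_COPY = "keep_attR_copy"
    MIDPOINT_CROSSOVER = "midpoint_crossover"


class GeneRemoved(Exception):
    """The queried gene lies entirely within the excised interval."""


class NoCoreMatch(Exception):
    """Integration site core absent from one of the molecules."""


@dataclass(frozen=True)
class GeneVariant:
    """A single edit to a gene, on its coding strand, 1-based.

    ``ref``/``alt`` use "" (epsilon) for the absent side of an indel.
    """

    gene: str
    position: int
    ref: str
    alt: str
    kind: str  # substitution | deletion | insertion

    def __post_init__(self) -> None:
        if self.kind == "substitution" and (not self.ref or not self.alt):
            raise ValueError("substitution requires ref and alt bases")
        if self.kind == "deletion" and (not self.ref or self.alt):
            raise ValueError("deletion requires ref and empty alt")
        if self.kind == "insertion" and (self.ref or not self.alt):
            raise ValueError("insertion requires empty ref and alt")


@dataclass
class ExcisionProducts:
    chromosome_after: str
    circle: str
    attB_window: str
    attP_window: str
    variants: list[GeneVariant]
    policy_used: CrossoverPolicy
    unique_outcome: bool
    att: AttSitePair = field(repr=False, default=None)  # type: ignore[assignment]


def _junction_core(g: GenomeRecord, att: AttSitePair, policy: CrossoverPolicy) -> str:
    left_copy = extract_region(g, att.attL[0], att.attL[1])
    right_copy = extract_region(g, att.attR[0], att.attR[1])
    if left_copy != right_copy or left_copy != att.core_seq:
        raise ValueError("attL/attR cores unequal: AttSitePair invariant violated")
    if policy is CrossoverPolicy.KEEP_ATTL_COPY:
        return left_copy
    if policy is CrossoverPolicy.KEEP_ATTR_COPY:
        return right_copy
    mid = len(left_copy) // 2
    return left_copy[:mid] + right_copy[mid:]


def excise(
    g: GenomeRecord,
    att: AttSitePair,
    policy: CrossoverPolicy = CrossoverPolicy.MIDPOINT_CROSSOVER,
    flank_width: int = DEFAULT_FLANK_WIDTH,
) -> ExcisionProducts:
    """Recombine attL x attR: excised chromosome, circle, junctions, variants.

    chromosome_after = sequence up to attL, one core copy, sequence after attR.
    circle = the removed interval closed with the complementary core copy, with
    its origin set at the attP core start.
    """
    seq = g.seq
    core = _junction_core(g, att, policy)
    ls, le = att.attL
    rs, re = att.attR
    chromosome_after = seq[: ls - 1] + core + seq[re:]
    # circle: attR core copy followed by the inter-core segment
    circle = seq[rs - 1 : re] + seq[le : rs - 1]

    w = flank_width
    b_start = max(0, ls - 1 - w)
    attB_window = chromosome_after[b_start : ls - 1 + len(core) + w]
    # circular: wrap the left flank around the origin
    attP_window = circle[-w:] + circle[: len(core)] + circle[len(core) : len(core) + w]
    if len(circle) < len(core) + 2 * w:
        # small circles: just report the full circle rotated to core start
        attP_window = circle

    variants: list[GeneVariant] = []
    for feat in g.features_overlapping(ls, le):
        try:
            variants.extend(diff_gene(g, chromosome_after, feat))
        except GeneRemoved:
            continue

    # with exact equal cores every crossover point gives the same sequence
    unique_outcome = True
    return ExcisionProducts(
        chromosome_after=chromosome_after,
        circle=circle,
        attB_window=attB_window,
        attP_window=attP_window,
        variants=variants,
        policy_used=policy,
        unique_outcome=unique_outcome,
        att=att,
    )


def integrate(
    chromosome_after: str,
    circle: str,
    attB: tuple[int, int],
    policy: CrossoverPolicy = CrossoverPolicy.MIDPOINT_CROSSOVER,
) -> str:
    """Insert the circle at attB, reconstituting two core copies (inverse of excise)."""
    bs, be = attB
    core = chromosome_after[bs - 1 : be]
    if not core:
        raise NoCoreMatch(f"attB interval [{bs},{be}] empty on chromosome")
    pos = circle.find(core)
    if pos < 0:
        # the core may wrap the circle origin; search the doubled sequence
        pos = (circle + circle).find(core)
        if pos < 0 or pos >= len(circle):
            raise NoCoreMatch("attB core not found on the circle")
    rotated = circle[pos:] + circle[:pos]  # core now at circle origin
    return (
        chromosome_after[: be]          # left flank + first core copy
        + rotated[len(core):]           # phage interior
        + core                          # second core copy
        + chromosome_after[be:]         # right flank
    )


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -6   # gaps cost more than a mismatch
    aligner.extend_gap_score = -4
    # free end gaps on the post-excision window so only intra-gene edits are
    # reported (insertions relative to the gene at either end cost nothing)
    aligner.end_insertion_score = 0.0
    return aligner


def diff_gene(
    original: GenomeRecord,
    chromosome_after: str,
    gene: Feature,
    pad: int = 10,
) -> list[GeneVariant]:
    """Minimal edit script between a gene and its post-excision counterpart.

    The post-excision window starts at the gene's original start coordinate and
    extends ``pad`` nt past its original end to absorb length changes; end gaps
    on that window are free. Positions are 1-based on the coding strand.
    """
    ref = extract_region(original, gene.start, gene.end, gene.strand)
    n = gene.length
    if gene.strand == "+":
        lo = gene.start - 1
        if lo >= len(chromosome_after):
            raise GeneRemoved(gene.locus_tag)
        post = chromosome_after[lo : min(len(chromosome_after), lo + n + pad)]
    else:
        hi = gene.end
        lo = max(0, hi - n - pad)
        if hi > len(chromosome_after):
            hi = len(chromosome_after)
        if lo >= hi:
            raise GeneRemoved(gene.locus_tag)
        post = reverse_complement(chromosome_after[lo:hi])
    if not post:
        raise GeneRemoved(gene.locus_tag)
    if post[:n] == ref:
        return []

    aln = _aligner().align(ref, post)[0]
    ra, pa = str(aln[0]), str(aln[1])
    variants: list[GeneVariant] = _script_from_alignment(ra, pa, gene, n)
    return _right_normalise(variants, ref)


def _script_from_alignment(ra: str, pa: str, gene: Feature, n: int
                           ) -> list[GeneVariant]:
    variants: list[GeneVariant] = []
    pos = 0  # 1-based position of the last consumed ref base
    for a, b in zip(ra, pa):
        if a == "-" and b == "-":
            continue
        if a == "-":
            if 0 < pos < n:  # ignore free end-gap insertions outside the gene
                variants.append(GeneVariant(gene=gene.locus_tag, position=pos + 1,
                                            ref="", alt=b, kind="insertion"))
            continue
        pos += 1
        if b == "-":
            variants.append(GeneVariant(gene=gene.locus_tag, position=pos,
                                        ref=a, alt="", kind="deletion"))
        elif a != b:
            variants.append(GeneVariant(gene=gene.locus_tag, position=pos,
                                        ref=a, alt=b, kind="substitution"))
    return variants


def _right_normalise(variants: list[GeneVariant], ref: str) -> list[GeneVariant]:
    """Shift indels 3'-ward within homopolymer runs (deleting any T of a TT run
    is the same edit; report the 3'-most position, as gene 3'-end deletions are
    conventionally given)."""
    occupied = {v.position for v in variants}
    out = []
    for v in variants:
        if v.kind == "deletion":
            pos = v.position
            while (pos < len(ref) and ref[pos] == v.ref
                   and pos + 1 not in occupied):
                pos += 1
            out.append(GeneVariant(gene=v.gene, position=pos, ref=v.ref,
                                   alt=v.alt, kind=v.kind) if pos != v.position
                       else v)
        else:
            out.append(v)
    return out


def products_report(products: ExcisionProducts) -> str:
    """JSON report of junction windows, policy, and variants."""
    return json.dumps(
        {
            "policy": products.policy_used.value,
            "unique_outcome": products.unique_outcome,
            "attB_window": products.attB_window,
            "attP_window": products.attP_window,
            "chromosome_len": len(products.chromosome_after),
            "circle_len": len(products.circle),
            "variants": [
                {"gene": v.gene, "position": v.position, "ref": v.ref,
                 "alt": v.alt, "kind": v.kind}
                for v in products.variants
            ],
        },
        indent=2,
    )


def variants_to_vcf(
    g: GenomeRecord,
    products: ExcisionProducts,
) -> str:
    """Variants as minimal VCF 4.2 text against the original genome.

    Indels are left-anchored on the reference base preceding the event, per VCF
    convention; the gene-relative position is carried in INFO.
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={g.id},length={len(g.seq)}>",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Locus tag">',
        '##INFO=<ID=GPOS,Number=1,Type=Integer,Description="1-based position within gene">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for v in products.variants:
        gene = g.feature(v.gene)
        if gene.strand == "+":
            gpos = gene.start + v.position - 1
        else:
            gpos = gene.end - v.position + 1
        info = f"GENE={v.gene};GPOS={v.position}"
        if v.kind == "substitution":
            ref, alt, pos = v.ref, v.alt, gpos
            if gene.strand == "-":
                ref, alt = reverse_complement(ref), reverse_complement(alt)
        elif v.kind == "deletion":
            pos = gpos - 1  # anchor on the base preceding the deleted one
            ref = g.seq[pos - 1 : pos + 1]
            alt = g.seq[pos - 1]
        else:  # insertion
            pos = gpos
            anchor = g.seq[pos - 1]
            ins = v.alt if gene.strand == "+" else reverse_complement(v.alt)
            ref, alt = anchor, anchor + ins
        lines.append(f"{g.id}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}")
    return "\n".join(lines) + "\n"
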