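"""Low-frequency population variants from per-site allele counts.

Deep sequencing of a bacterial population detects subpopulation mutations as
non-reference alleles at frequencies well above the sequencing error rate. For
each non-reference allele (single-base substitutions and single-base
deletions) with count k at depth n, a one-sided binomial tail
P(X >= k | n, error_rate) is computed, Benjamini-Hochberg corrected across all
tested alleles genome-wide, and calls are kept when the adjusted p-value,
frequency and depth clear the configured thresholds.

Coding effects are classified on the annotated genome: in-frame codon
translation for CDS substitutions (synonymous/nonsynonymous), any change in an
RNA gene (e.g. tmRNA) as rna_gene, otherwise intergenic.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq
from scipy import stats

from .genome_io import Feature, GenomeRecord, extract_region, reverse_complement

BASES = ("A", "C", "G", "T")
DELETION = "-"

DEFAULT_ERROR_RATE = 0.001
DEFAULT_MIN_FREQ = 0.01
DEFAULT_MIN_DEPTH = 100
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class PileupSite:
    pos: int
    ref: str
    counts: dict[str, int]  # keys A,C,G,T and "-" for deletion
    chrom: str = "genome"

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class MutationCall:
    pos: int
    ref: str
    alt: str                    # base, or "-" for a single-base deletion
    frequency: float
    p_adj: float
    effect: str = "unclassified"
    gene: str = ""
    protein_change: str = ""
    chrom: str = "genome"

    @property
    def kind(self) -> str:
        return "deletion" if self.alt == DELETION else "substitution"


class ClassificationError(ValueError):
    """CDS unusable for codon classification (e.g. length not divisible by 3)."""


def read_pileup_tsv(path) -> list[PileupSite]:
    """TSV columns: CHROM, POS, REF, A, C, G, T, DEL, DEPTH."""
    df = pd.read_csv(path, sep="\t")
    sites = []
    for _, r in df.iterrows():
        counts = {b: int(r[b]) for b in BASES}
        counts[DELETION] = int(r["DEL"])
        site = PileupSite(pos=int(r["POS"]), ref=str(r["REF"]).upper(),
                          counts=counts, chrom=str(r["CHROM"]))
        if site.depth != int(r["DEPTH"]):
            raise ValueError(f"POS {site.pos}: DEPTH column inconsistent with counts")
        sites.append(site)
    return sites


def write_pileup_tsv(sites: Sequence[PileupSite], path) -> None:
    rows = [
        {"CHROM": s.chrom, "POS": s.pos, "REF": s.ref,
         **{b: s.counts.get(b, 0) for b in BASES},
         "DEL": s.counts.get(DELETION, 0), "DEPTH": s.depth}
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def call_variants(
    sites: Iterable[PileupSite],
    error_rate: float = DEFAULT_ERROR_RATE,
    min_freq: float = DEFAULT_MIN_FREQ,
    min_depth: int = DEFAULT_MIN_DEPTH,
    alpha: float = DEFAULT_ALPHA,
) -> list[MutationCall]:
    """Binomial-tail calls with genome-wide BH correction.

    Every non-reference allele with count >= 1 is tested; the BH family is the
    set of all tested alleles, not per site.
    """
    if not (0 < error_rate <= 0.01):
        raise ValueError("error_rate must be in (0, 0.01]")
    if min_freq < error_rate:
        raise ValueError("min_freq must be >= error_rate")

    tested: list[tuple[PileupSite, str, int, int]] = []
    skipped = 0
    for site in sites:
        n = site.depth
        if n == 0:
            skipped += 1
            continue
        for allele in (*BASES, DELETION):
            if allele == site.ref:
                continue
            k = site.counts.get(allele, 0)
            if k >= 1:
                tested.append((site, allele, k, n))
    if skipped:
        warnings.warn(f"skipped {skipped} zero-depth sites", stacklevel=2)
    if not tested:
        return []

    k_arr = np.array([t[2] for t in tested])
    n_arr = np.array([t[3] for t in tested])
    # one-sided upper tail: P(X >= k) = sf(k - 1)
    pvals = stats.binom.sf(k_arr - 1, n_arr, error_rate)
    padj = stats.false_discovery_control(pvals, method="bh")

    calls = []
    for (site, allele, k, n), p in zip(tested, padj):
        freq = k / n
        if p < alpha and freq >= min_freq and n >= min_depth:
            calls.append(MutationCall(pos=site.pos, ref=site.ref, alt=allele,
                                      frequency=freq, p_adj=float(p),
                                      chrom=site.chrom))
    calls.sort(key=lambda c: (c.pos, c.alt))
    return calls


_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

RNA_KINDS = frozenset({"tmRNA"})


def classify_effect(call: MutationCall, g: GenomeRecord) -> MutationCall:
    """Fill in effect / gene / protein_change for a call.

    Substitutions inside a CDS are translated in-frame on the coding strand;
    any change inside an RNA feature is rna_gene; outside all features,
    intergenic.
    """
    hits = [f for f in g.features_overlapping(call.pos, call.pos)
            if f.kind in ("CDS", "tmRNA")]
    if not hits:
        return replace(call, effect="intergenic")
    feat = hits[0]
    gene_pos = (call.pos - feat.start + 1 if feat.strand == "+"
                else feat.end - call.pos + 1)
    if feat.kind in RNA_KINDS:
        change = (f"Deletion of U" if call.alt == DELETION
                  else f"{gene_pos} ({_rna(call, feat, 'ref')}"
                       f"→{_rna(call, feat, 'alt')})")
        return replace(call, effect="rna_gene", gene=feat.locus_tag,
                       protein_change=change)
    # CDS
    if feat.length % 3 != 0:
        raise ClassificationError(
            f"CDS {feat.locus_tag} length {feat.length} not divisible by 3")
    if call.alt == DELETION:
        # single-base deletion in a CDS: frameshift, amino-acid change certain
        return replace(call, effect="nonsynonymous", gene=feat.locus_tag,
                       protein_change=f"{(gene_pos - 1) // 3 + 1} (frameshift)")
    cds = extract_region(g, feat.start, feat.end, feat.strand)
    ref_base = call.ref if feat.strand == "+" else reverse_complement(call.ref)
    alt_base = call.alt if feat.strand == "+" else reverse_complement(call.alt)
    if cds[gene_pos - 1] != ref_base:
        raise ClassificationError(
            f"ref mismatch at {feat.locus_tag}:{gene_pos}: "
            f"annotation has {cds[gene_pos - 1]}, call has {ref_base}")
    codon_idx = (gene_pos - 1) // 3
    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    within = (gene_pos - 1) % 3
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate(table=_STANDARD_TABLE))
    aa_alt = str(Seq(alt_codon).translate(table=_STANDARD_TABLE))
    effect = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
    change = f"{codon_idx + 1} ({aa_ref}→{aa_alt})"
    return replace(call, effect=effect, gene=feat.locus_tag,
                   protein_change=change)


def _rna(call: MutationCall, feat: Feature, which: str) -> str:
    base = call.ref if which == "ref" else call.alt
    if feat.strand == "-":
        base = reverse_complement(base)
    return base.replace("T", "U")


@dataclass(frozen=True)
class CallSummary:
    total: int
    synonymous: int
    nonsynonymous: int
    rna_gene: int
    intergenic: int
    freq_min: float
    freq_max: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_calls(calls: Sequence[MutationCall]) -> CallSummary:
    if not calls:
        return CallSummary(0, 0, 0, 0, 0, float("nan"), float("nan"))
    freqs = [c.frequency for c in calls]
    counts = {e: sum(1 for c in calls if c.effect == e)
              for e in ("synonymous", "nonsynonymous", "rna_gene", "intergenic")}
    return CallSummary(total=len(calls), freq_min=min(freqs), freq_max=max(freqs),
                       **counts)


def calls_to_vcf(calls: Sequence[MutationCall], contig: str = "genome",
                 contig_len: int | None = None) -> str:
    """Calls as VCF 4.2 text with AF and ADJP in INFO.

    Single-base deletions are written as REF=<deleted base>, ALT=<DEL>
    (symbolic), since pileup input carries no anchor base context.
    """
    lines = ["##fileformat=VCFv4.2"]
    if contig_len:
        lines.append(f"##contig=<ID={contig},length={contig_len}>")
    lines += [
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">',
        '##INFO=<ID=ADJP,Number=1,Type=Float,Description="BH-adjusted p-value">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Locus tag">',
        '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect">',
        '##ALT=<ID=DEL,Description="Single-base deletion">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in calls:
        alt = "<DEL>" if c.alt == DELETION else c.alt
        info = f"AF={c.frequency:.6g};ADJP={c.p_adj:.6g}"
        if c.gene:
            info += f";GENE={c.gene}"
        if c.effect != "unclassified":
            info += f";EFFECT={c.effect}"
        lines.append(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{alt}\t.\tPASS\t{info}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Packaged survey of population mutations in cold-grown S. oneidensis MR-1
# (whole-genome deep-sequencing, 4 degC vs 30 degC), shipped as a TSV fixture.
# ---------------------------------------------------------------------------

def load_packaged_mutation_table() -> pd.DataFrame:
    """The published S. oneidensis cold-growth mutation survey as a DataFrame."""
    ref = importlib.resources.files("prophagekit.data") / "cold_shift_mutations.tsv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


def _effect_from_change(change: str) -> str:
    """Derive the coding effect from a 'change in protein or RNA' string.

    'N (X→Y)' with X == Y is synonymous, X != Y nonsynonymous; textual RNA
    changes (e.g. 'Deletion of U') are rna_gene.
    """
    change = change.strip()
    if "(" in change and "→" in change:
        inner = change[change.index("(") + 1 : change.rindex(")")]
        left, right = inner.split("→")
        return "synonymous" if left.strip() == right.strip() else "nonsynonymous"
    return "rna_gene"


def packaged_mutation_calls() -> list[MutationCall]:
    """MutationCalls from the packaged survey, effects classified from the
    reported residue changes."""
    df = load_packaged_mutation_table()
    calls = []
    for _, r in df.iterrows():
        effect = _effect_from_change(str(r["change_in_protein_or_rna"]))
        dna = str(r["change_in_dna"])
        ref = alt = ""
        if "→" in dna:
            inner = dna[dna.index("(") + 1 : dna.rindex(")")]
            ref, alt = (s.strip() for s in inner.split("→"))
        else:
            ref, alt = "T", DELETION  # single-base RNA deletion
        calls.append(MutationCall(
            pos=int(r["genome_position"]), ref=ref, alt=alt,
            frequency=float(r["frequency"]), p_adj=0.0, effect=effect,
            gene=str(r["locus_tag"]),
            protein_change=str(r["change_in_protein_or_rna"]),
        ))
    return calls
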