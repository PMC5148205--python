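"""Synthetic inputs with machine-readable ground truth.

Every input the pipeline consumes can be generated here: a host genome
carrying a tmRNA-anchored integrated element delimited by an imperfect direct
repeat (excision deletes exactly one nucleotide of the anchor gene), mixed
lysogen/excised populations of sequencing reads, qPCR mixing-series standard
curves with sample wells, per-site allele-count pileups with planted
subpopulation mutations, and colony screens.

Randomness: one pseudo-random stream per generator, derived from the master
seed by a fixed label, so adding a generator never perturbs the others.

Default geometry (a scaled-down analogue of a tmRNA-anchored P4-like locus):
50 kb genome, 5 kb element, 26 nt core, anchor gene 360 nt whose excision
deletes the T at gene position 349 and whose 3' acceptor stem ends in a G.U
wobble pair.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .excision import GeneVariant
from .genome_io import Feature, GenomeRecord
from .popseq import BASES, DELETION, PileupSite
from .quant import QpcrWell
from .tmrna_stem import StemSpec

_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A"}


def stream(seed: int, label: str) -> np.random.Generator:
    """Independent generator stream derived from (master seed, label)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


class SynthConfigError(ValueError):
    pass


@dataclass(frozen=True)
class FlankEdit:
    """How the attR-side copy of the anchor-gene tail differs from attL's.

    ``offset`` is 1-based within the tail (the gene segment 3' of the core).
    kind "deletion": the lysogen tail carries a base at that offset that the
    excised tail lacks; "substitution": the excised tail carries ``alt`` there.
    Tail bases before ``offset`` are shared between the two copies, so the
    maximal exact repeat (the att core as a repeat finder sees it) is
    core_len + offset - 1; the default offset of 1 puts the edit immediately
    after the core.
    """

    kind: str = "deletion"
    offset: int = 1
    alt: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "substitution"):
            raise SynthConfigError(f"bad flank_edit kind {self.kind!r}")
        if self.kind == "substitution" and self.alt not in BASES:
            raise SynthConfigError("substitution flank_edit needs alt base")


@dataclass(frozen=True)
class SynthConfig:
    seed: int
    genome_len: int = 50_000
    anchor_start: int = 10_001
    anchor_body_len: int = 322       # gene 5' of the core
    core_len: int = 26
    tail_len: int = 14               # gene 3' of the core (lysogen copy)
    flank_edit: FlankEdit | None = field(default_factory=FlankEdit)
    prophage_len: int = 5_000        # span attR.start - attL.start
    n_phage_genes: int = 3           # CDS inside the element, incl. integrase
    stem_pairs: int = 7
    excision_fraction: float = 0.03
    n_reads: int = 10_000
    read_len: int = 100
    base_error: float = 0.001
    qpcr_efficiency: float = 2.0
    qpcr_cq0: float = 15.0           # Cq at fraction 1
    qpcr_noise_sd: float = 0.1
    qpcr_replicates: int = 3
    standard_fractions: tuple[float, ...] = (
        1e-1, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6)
    mean_depth: float = 500.0
    mutations: tuple[tuple[int, str, str, float], ...] = ()
    colony_n: int = 200
    colony_p: float = 0.01

    def __post_init__(self) -> None:
        if not (self.core_len < self.prophage_len < self.genome_len):
            raise SynthConfigError("need core_len < prophage_len < genome_len")
        for p in (self.excision_fraction, self.base_error, self.colony_p):
            if not (0.0 <= p <= 1.0):
                raise SynthConfigError(f"probability {p} outside [0,1]")
        if not (1.0 < self.qpcr_efficiency <= 2.0):
            raise SynthConfigError("qpcr_efficiency must be in (1, 2]")
        if self.flank_edit and self.flank_edit.offset > self.tail_len - 1:
            raise SynthConfigError("flank_edit offset beyond tail")
        interior = self.prophage_len - self.core_len - self.tail_len
        if interior < 200:
            raise SynthConfigError("element too small for an interior")

    @property
    def anchor_len(self) -> int:
        return self.anchor_body_len + self.core_len + self.tail_len


@dataclass
class TruthRecord:
    """Ground truth emitted next to every synthetic dataset."""

    attL: tuple[int, int]
    attR: tuple[int, int]
    core_seq: str
    span: int
    anchor_locus: str
    planted_variant: GeneVariant | None
    stem_spec: StemSpec | None
    attB_junction: str = ""
    attL_junction: str = ""
    attP_junction: str = ""
    excision_fraction: float | None = None
    mutation_frequencies: tuple[tuple[int, str, str, float], ...] = ()

    def to_json(self) -> str:
        d = asdict(self)
        if self.stem_spec is not None:
            d["stem_spec"] = [list(p) for p in self.stem_spec.pairs]
        if self.planted_variant is not None:
            d["planted_variant"] = asdict(self.planted_variant)
        return json.dumps(d, indent=2)


def _build_stem_spec(cfg: SynthConfig) -> StemSpec:
    """Acceptor-stem layout: 5' arm inside the core, 3' arm at the gene end,
    outermost pair (first i, last j) is the G.U wobble."""
    g = cfg.anchor_len
    n = cfg.stem_pairs
    j_positions = list(range(g, g - n, -1))        # g, g-1, ...
    core_start_in_gene = cfg.anchor_body_len + 1
    i_start = core_start_in_gene + cfg.core_len - 2 * n  # inside the core
    i_positions = list(range(i_start, i_start + n))
    return StemSpec(pairs=tuple(zip(i_positions, j_positions)))


def build_host_with_prophage(cfg: SynthConfig
                             ) -> tuple[GenomeRecord, GenomeRecord, TruthRecord]:
    """Lysogen genome, its excision product, and the ground truth.

    Lysogen layout: background | gene body | CORE | tail_L | element interior
    | CORE | tail_R | background, where tail_R is tail_L with the flank edit
    applied, so excising the element rewrites the anchor gene's 3' end.
    """
    rng = stream(cfg.seed, "genome")
    interior_len = cfg.prophage_len - cfg.core_len - cfg.tail_len
    tail_R_len = cfg.tail_len - (1 if cfg.flank_edit
                                 and cfg.flank_edit.kind == "deletion" else 0)
    fixed_len = (cfg.anchor_start - 1 + cfg.anchor_body_len + cfg.core_len
                 + cfg.tail_len + interior_len + cfg.core_len + tail_R_len)
    right_bg_len = cfg.genome_len - fixed_len
    if right_bg_len < cfg.read_len + 100:
        raise SynthConfigError("genome_len too small for the configured element")

    for attempt in range(20):
        left_bg = _random_dna(rng, cfg.anchor_start - 1)
        body = _random_dna(rng, cfg.anchor_body_len)
        core = _random_dna(rng, cfg.core_len)
        tail = list(_random_dna(rng, cfg.tail_len))
        interior = _random_dna(rng, interior_len)
        right_bg = _random_dna(rng, right_bg_len)

        # force the acceptor stem into the gene (5' arm in core, 3' arm in tail)
        spec = _build_stem_spec(cfg)
        gene = list(body + core + "".join(tail))
        first = True
        for i, j in spec.pairs:
            if first:
                gene[i - 1], gene[j - 1] = "G", "T"  # the G.U wobble pair
                first = False
            else:
                gene[j - 1] = _COMPL[gene[i - 1]]
        # shared tail prefix extends the maximal repeat past the core; with no
        # flank edit the whole tail is shared by both copies
        ext = cfg.tail_len
        if cfg.flank_edit is not None:
            ext = cfg.flank_edit.offset - 1
            tpos = cfg.anchor_body_len + cfg.core_len + cfg.flank_edit.offset
            if cfg.flank_edit.kind == "deletion":
                gene[tpos - 1] = "T"
                # the copies must diverge right after the edit, else the
                # deleted base would extend the repeat instead
                if tpos < cfg.anchor_len and gene[tpos] == "T":
                    gene[tpos] = "A"
            elif gene[tpos - 1] == cfg.flank_edit.alt:
                gene[tpos - 1] = _COMPL[cfg.flank_edit.alt]
        gene_seq = "".join(gene)
        body = gene_seq[: cfg.anchor_body_len]
        core = gene_seq[cfg.anchor_body_len : cfg.anchor_body_len + cfg.core_len]
        tail_L = gene_seq[cfg.anchor_body_len + cfg.core_len :]

        if cfg.flank_edit is None:
            tail_R = tail_L
        elif cfg.flank_edit.kind == "deletion":
            o = cfg.flank_edit.offset
            tail_R = tail_L[: o - 1] + tail_L[o:]
        else:
            o = cfg.flank_edit.offset
            tail_R = tail_L[: o - 1] + cfg.flank_edit.alt + tail_L[o:]

        # the repeat must not extend left of the planted cores
        if interior[-1] == body[-1]:
            interior = interior[:-1] + _COMPL[body[-1]]
        # nor rightward past the shared tail when there is no flank edit
        if cfg.flank_edit is None and interior[0] == right_bg[0]:
            interior = _COMPL[right_bg[0]] + interior[1:]

        lys_seq = (left_bg + body + core + tail_L + interior + core + tail_R
                   + right_bg)
        attL_start = cfg.anchor_start + cfg.anchor_body_len
        rep_len = cfg.core_len + ext  # length of the maximal exact repeat
        attL = (attL_start, attL_start + rep_len - 1)
        attR_start = attL_start + cfg.prophage_len
        attR = (attR_start, attR_start + rep_len - 1)
        rep_seq = core + tail_L[:ext]
        assert lys_seq[attL[0] - 1 : attL[1]] == rep_seq
        assert lys_seq[attR[0] - 1 : attR[1]] == rep_seq

        if _core_is_unique_repeat(lys_seq, attL, attR, cfg, rep_len=rep_len):
            break
    else:  # pragma: no cover - vanishingly unlikely with random backgrounds
        raise SynthConfigError("could not place a collision-free core in 20 tries")

    features = [Feature(locus_tag="anchor_tmRNA", kind="tmRNA",
                        start=cfg.anchor_start,
                        end=cfg.anchor_start + cfg.anchor_len - 1, strand="+")]
    # integrase abuts the anchor's 3' end; remaining CDS tile the interior
    interior_start = attL[1] + cfg.tail_len + 1
    interior_end = attR[0] - 1
    gene_slots = max(1, cfg.n_phage_genes)
    slot = (interior_end - interior_start - 100) // gene_slots
    cds_len = max(300, min(900, (slot - 60) // 3 * 3))
    pos = interior_start + 50
    for idx in range(gene_slots):
        if pos + cds_len - 1 > interior_end:
            break
        tag = "integrase" if idx == 0 else f"phage_cds_{idx:02d}"
        features.append(Feature(locus_tag=tag, kind="CDS", start=pos,
                                end=pos + cds_len - 1, strand="+"))
        pos += slot
    # a couple of host CDS outside the element, for effect classification
    host_cds_len = 900
    features.append(Feature(locus_tag="host_cds_left", kind="CDS",
                            start=1001, end=1000 + host_cds_len, strand="+"))
    hs = attR[1] + tail_R_len + 501
    features.append(Feature(locus_tag="host_cds_right", kind="CDS",
                            start=hs, end=hs + host_cds_len - 1, strand="+"))

    lysogen = GenomeRecord(id="synthetic_lysogen", seq=lys_seq,
                           features=features)

    exc_seq = left_bg + body + core + tail_R + right_bg
    exc_features = [Feature(locus_tag="anchor_tmRNA", kind="tmRNA",
                            start=cfg.anchor_start,
                            end=cfg.anchor_start + cfg.anchor_body_len
                            + cfg.core_len + len(tail_R) - 1, strand="+"),
                    Feature(locus_tag="host_cds_left", kind="CDS",
                            start=1001, end=1000 + host_cds_len, strand="+")]
    excised = GenomeRecord(id="synthetic_excised", seq=exc_seq,
                           features=exc_features)

    variant: GeneVariant | None = None
    if cfg.flank_edit is not None:
        gpos = cfg.anchor_body_len + cfg.core_len + cfg.flank_edit.offset
        if cfg.flank_edit.kind == "deletion":
            variant = GeneVariant(gene="anchor_tmRNA", position=gpos,
                                  ref=tail_L[cfg.flank_edit.offset - 1],
                                  alt="", kind="deletion")
        else:
            variant = GeneVariant(gene="anchor_tmRNA", position=gpos,
                                  ref=tail_L[cfg.flank_edit.offset - 1],
                                  alt=cfg.flank_edit.alt, kind="substitution")

    w = 30
    attB_junction = exc_seq[attL[0] - 1 - w : attL[1] + w]
    attL_junction = lys_seq[attL[0] - 1 - w : attL[1] + w]
    circle = lys_seq[attR[0] - 1 : attR[1]] + lys_seq[attL[1] : attR[0] - 1]
    attP_junction = circle[-w:] + circle[: cfg.core_len + w]

    truth = TruthRecord(
        attL=attL, attR=attR, core_seq=rep_seq, span=cfg.prophage_len,
        anchor_locus="anchor_tmRNA", planted_variant=variant,
        stem_spec=_build_stem_spec(cfg),
        attB_junction=attB_junction, attL_junction=attL_junction,
        attP_junction=attP_junction,
        excision_fraction=cfg.excision_fraction,
    )
    return lysogen, excised, truth


def _core_is_unique_repeat(seq: str, attL: tuple[int, int],
                           attR: tuple[int, int], cfg: SynthConfig,
                           rep_len: int | None = None, k: int = 15) -> bool:
    """No shared k-mer between the anchor window and the downstream sequence
    other than within the planted repeat copies."""
    rep_len = rep_len or cfg.core_len
    left_lo = cfg.anchor_start - 1
    left_hi = attL[1] + cfg.tail_len + 200
    right_lo = left_hi
    right_hi = len(seq)

    left_km: set[str] = set()
    for i in range(left_lo, left_hi - k + 1):
        if attL[0] - 1 <= i <= attL[0] - 1 + rep_len - k:
            continue  # inside the planted repeat copy
        left_km.add(seq[i : i + k])
    for i in range(right_lo, right_hi - k + 1):
        if attR[0] - 1 <= i <= attR[0] - 1 + rep_len - k:
            continue
        if seq[i : i + k] in left_km:
            return False
    return True


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_population_reads(
    cfg: SynthConfig,
    lysogen: GenomeRecord,
    excised: GenomeRecord,
) -> tuple[list[str], TruthRecord]:
    """Single-end reads from a mixed population.

    Each read is drawn from the excised genome with probability
    ``excision_fraction``, otherwise from the lysogen; uniform start, either
    strand, i.i.d. per-base errors.
    """
    rng = stream(cfg.seed, "reads")
    p = cfg.excision_fraction
    L = cfg.read_len
    if L > min(len(lysogen.seq), len(excised.seq)):
        raise SynthConfigError("read_len exceeds genome length")
    sources = (lysogen.seq, excised.seq)
    pick = rng.random(cfg.n_reads) < p  # True -> excised
    strands = rng.random(cfg.n_reads) < 0.5
    reads: list[str] = []
    for i in range(cfg.n_reads):
        src = sources[1] if pick[i] else sources[0]
        start = int(rng.integers(0, len(src) - L + 1))
        read = src[start : start + L]
        if strands[i]:
            read = read.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
        n_err = rng.binomial(L, cfg.base_error)
        if n_err:
            arr = list(read)
            for pos in rng.choice(L, size=n_err, replace=False):
                choices = [b for b in "ACGT" if b != arr[pos]]
                arr[pos] = choices[int(rng.integers(0, 3))]
            read = "".join(arr)
        reads.append(read)
    truth = TruthRecord(attL=(0, 0), attR=(0, 0), core_seq="", span=0,
                        anchor_locus="", planted_variant=None, stem_spec=None,
                        excision_fraction=p)
    return reads, truth


def write_fasta(reads: Sequence[str], path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f">{prefix}_{i}\n{r}\n")


def read_fasta_seqs(path) -> list[str]:
    seqs, cur = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if cur:
                    seqs.append("".join(cur))
                    cur = []
            elif line:
                cur.append(line)
    if cur:
        seqs.append("".join(cur))
    return seqs


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(cfg: SynthConfig
                  ) -> tuple[list[tuple[float, float, float]], list[QpcrWell],
                             TruthRecord]:
    """Mixing-series standard curve plus sample wells at the true fraction.

    Cq_junction = Cq0 - log_E(fraction) + N(0, sd); Cq_reference = Cq0 + noise.
    Returns (standard rows (fraction, Cq_junction, Cq_reference), sample wells,
    truth).
    """
    rng = stream(cfg.seed, "qpcr")
    E = cfg.qpcr_efficiency
    if any(f <= 0 for f in cfg.standard_fractions):
        raise SynthConfigError("standard-series fractions must be positive")
    logE = np.log(E)

    def cq_junction(fraction: float) -> float:
        return (cfg.qpcr_cq0 - np.log(fraction) / logE
                + rng.normal(0.0, cfg.qpcr_noise_sd))

    def cq_reference() -> float:
        return cfg.qpcr_cq0 + rng.normal(0.0, cfg.qpcr_noise_sd)

    standard = [(f, float(cq_junction(f)), float(cq_reference()))
                for f in cfg.standard_fractions]

    wells: list[QpcrWell] = []
    for rep in range(1, cfg.qpcr_replicates + 1):
        wells.append(QpcrWell(sample="sample", target="junction",
                              Cq=float(cq_junction(cfg.excision_fraction)),
                              replicate=rep))
        wells.append(QpcrWell(sample="sample", target="reference",
                              Cq=float(cq_reference()), replicate=rep))
    truth = TruthRecord(attL=(0, 0), attR=(0, 0), core_seq="", span=0,
                        anchor_locus="", planted_variant=None, stem_spec=None,
                        excision_fraction=cfg.excision_fraction)
    return standard, wells, truth


def standard_rows_to_points(standard: Sequence[tuple[float, float, float]]
                            ) -> list[tuple[float, float]]:
    """(fraction, Cq_junction, Cq_reference) rows -> (fraction, dCq) points."""
    return [(f, cj - cr) for f, cj, cr in standard]


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------

def simulate_pileup(
    cfg: SynthConfig,
    genome: GenomeRecord,
    n_background_sites: int = 200,
) -> tuple[list[PileupSite], TruthRecord]:
    """Allele-count pileup at planted-mutation sites plus background sites.

    Depth ~ Poisson(mean_depth); alt count ~ Binomial(depth, true frequency);
    error reads ~ Binomial(remaining depth, base_error) spread uniformly over
    the non-reference bases.
    """
    rng = stream(cfg.seed, "pileup")
    positions = {pos for pos, *_ in cfg.mutations}
    if len(positions) != len(cfg.mutations):
        raise SynthConfigError("overlapping planted mutations at one site")
    sites: list[PileupSite] = []
    for pos, ref, alt, freq in cfg.mutations:
        g_ref = genome.seq[pos - 1]
        if ref != g_ref:
            raise SynthConfigError(f"mutation ref {ref} != genome {g_ref} at {pos}")
        sites.append(_one_site(rng, pos, ref, alt, freq, cfg))
    bg_positions = rng.choice(
        np.setdiff1d(np.arange(1, len(genome.seq) + 1), sorted(positions)),
        size=n_background_sites, replace=False)
    for pos in sorted(int(x) for x in bg_positions):
        ref = genome.seq[pos - 1]
        if ref == "N":
            continue
        sites.append(_one_site(rng, pos, ref, None, 0.0, cfg))
    sites.sort(key=lambda s: s.pos)
    truth = TruthRecord(attL=(0, 0), attR=(0, 0), core_seq="", span=0,
                        anchor_locus="", planted_variant=None, stem_spec=None,
                        mutation_frequencies=tuple(cfg.mutations))
    return sites, truth


def _one_site(rng: np.random.Generator, pos: int, ref: str, alt: str | None,
              freq: float, cfg: SynthConfig) -> PileupSite:
    depth = int(rng.poisson(cfg.mean_depth))
    counts = {b: 0 for b in (*BASES, DELETION)}
    n_alt = int(rng.binomial(depth, freq)) if alt is not None and freq > 0 else 0
    if alt is not None:
        counts[alt] += n_alt
    remaining = depth - n_alt
    n_err = int(rng.binomial(remaining, cfg.base_error))
    err_targets = [b for b in BASES if b != ref]
    for t in rng.integers(0, len(err_targets), size=n_err):
        counts[err_targets[int(t)]] += 1
    counts[ref] += remaining - n_err
    return PileupSite(pos=pos, ref=ref, counts=counts)


def simulate_error_pileup(n_sites: int, depth: float, error_rate: float,
                          seed: int) -> list[PileupSite]:
    """Pure-error pileup (no planted variants) for false-call-rate studies.

    Vectorised: depths Poisson(depth); error reads Binomial(depth, error_rate)
    split uniformly over the three non-reference bases.
    """
    rng = stream(seed, "error_pileup")
    refs = np.array(list("ACGT"))[rng.integers(0, 4, size=n_sites)]
    depths = rng.poisson(depth, size=n_sites)
    n_err = rng.binomial(depths, error_rate)
    sites = []
    for i in range(n_sites):
        ref = str(refs[i])
        counts = {b: 0 for b in (*BASES, DELETION)}
        err_targets = [b for b in BASES if b != ref]
        if n_err[i]:
            split = rng.multinomial(int(n_err[i]), [1 / 3] * 3)
            for b, c in zip(err_targets, split):
                counts[b] = int(c)
        counts[ref] = int(depths[i]) - int(n_err[i])
        sites.append(PileupSite(pos=i + 1, ref=ref, counts=counts))
    return sites


def survey_mutation_panel(genome: GenomeRecord, frequencies_syn: Sequence[float],
                          frequencies_nonsyn: Sequence[float],
                          rna_deletion_freq: float, seed: int
                          ) -> tuple[tuple[int, str, str, float], ...]:
    """Plant a published-style mutation panel on a synthetic genome.

    Picks CDS codon positions whose substitution is synonymous or
    nonsynonymous (verified by translation) and one single-base deletion in
    the tmRNA anchor gene.
    """
    from Bio.Seq import Seq

    rng = stream(seed, "panel")
    cds = [f for f in genome.features if f.kind == "CDS" and f.strand == "+"]
    tmrna = [f for f in genome.features if f.kind == "tmRNA"]
    if not cds or not tmrna:
        raise SynthConfigError("genome needs CDS and tmRNA features")
    panel: list[tuple[int, str, str, float]] = []
    used: set[int] = set()

    def plant_substitution(want_syn: bool, freq: float) -> None:
        for _ in range(5000):
            feat = cds[int(rng.integers(0, len(cds)))]
            n_codons = feat.length // 3
            ci = int(rng.integers(0, n_codons))
            within = int(rng.integers(0, 3))
            pos = feat.start + ci * 3 + within
            if pos in used:
                continue
            ref = genome.seq[pos - 1]
            codon = genome.seq[feat.start - 1 + ci * 3 : feat.start - 1 + ci * 3 + 3]
            for alt in rng.permutation([b for b in BASES if b != ref]):
                alt_codon = codon[:within] + alt + codon[within + 1 :]
                syn = str(Seq(codon).translate()) == str(Seq(alt_codon).translate())
                if syn == want_syn:
                    panel.append((pos, ref, str(alt), freq))
                    used.add(pos)
                    return
        raise SynthConfigError("could not plant requested substitution")

    for f in frequencies_syn:
        plant_substitution(True, float(f))
    for f in frequencies_nonsyn:
        plant_substitution(False, float(f))
    t = tmrna[0]
    for _ in range(100):
        pos = int(rng.integers(t.start, t.end + 1))
        if pos not in used:
            panel.append((pos, genome.seq[pos - 1], DELETION,
                          float(rna_deletion_freq)))
            break
    return tuple(sorted(panel))


# ---------------------------------------------------------------------------
# colony screen
# ---------------------------------------------------------------------------

def simulate_colony_screen(n: int, p: float, seed: int,
                           replicates: int = 1) -> int | np.ndarray:
    """Positive-colony count(s): Binomial(n, p) draws."""
    if n < 1:
        raise SynthConfigError("n must be >= 1")
    rng = stream(seed, "colony")
    draws = rng.binomial(n, p, size=replicates)
    return int(draws[0]) if replicates == 1 else draws
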