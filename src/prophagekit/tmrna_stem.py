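"""Acceptor-stem pairing check for tmRNA / tRNA-like 3' domains.

tmRNA carries a tRNA-like domain at its 3' end whose acceptor stem includes a
conserved G·U wobble pair; losing that pair inactivates the molecule. This
module does no structure prediction: the stem layout is supplied as a list of
expected (i, j) pairing positions, and each pair is classified against the
current sequence as Watson-Crick, wobble, or unpaired. Comparing a reference
and a variant sequence against the same positional layout shows which pairs an
edit (for example a one-nucleotide deletion that shifts the 3' arm) destroys.

DNA input is transcribed internally (T -> U); U and T are equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

WATSON_CRICK = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
WOBBLE = frozenset({("G", "U"), ("U", "G")})
DEFAULT_ALLOWED = WATSON_CRICK | WOBBLE


@dataclass(frozen=True)
class StemSpec:
    """Expected pairings (i, j), 1-based within the gene, i on the 5' arm."""

    pairs: tuple[tuple[int, int], ...]
    allowed_pairs: frozenset[tuple[str, str]] = DEFAULT_ALLOWED

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(tuple(p) for p in self.pairs))
        used: set[int] = set()
        prev_i, prev_j = 0, None
        for i, j in self.pairs:
            if i >= j:
                raise ValueError(f"pair ({i},{j}): need i < j")
            if i <= prev_i:
                raise ValueError("i positions must be strictly increasing")
            if prev_j is not None and j >= prev_j:
                raise ValueError("j positions must be strictly decreasing")
            if i in used or j in used:
                raise ValueError(f"position reused in pair ({i},{j})")
            used.update((i, j))
            prev_i, prev_j = i, j


@dataclass(frozen=True)
class PairStatus:
    i: int
    j: int
    base_i: str   # RNA alphabet; "" if beyond sequence end
    base_j: str
    status: str   # watson_crick | wobble | unpaired


@dataclass(frozen=True)
class StemCheckResult:
    per_pair: tuple[PairStatus, ...]
    wobble_count: int = field(init=False)
    intact: bool = field(init=False)
    truncated: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "wobble_count",
            sum(1 for p in self.per_pair if p.status == "wobble"))
        object.__setattr__(
            self, "intact",
            all(p.status != "unpaired" for p in self.per_pair))


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def check_stem(gene_seq: str, spec: StemSpec, *, allow_truncated: bool = False
               ) -> StemCheckResult:
    """Classify every expected pair of the stem against the sequence.

    Positions beyond the sequence end raise a bounds error unless
    ``allow_truncated`` is set, in which case they are reported unpaired and
    the result is flagged truncated (a variant shorter than the layout).
    """
    rna = _to_rna(gene_seq)
    n = len(rna)
    statuses: list[PairStatus] = []
    truncated = False
    for i, j in spec.pairs:
        if i < 1 or j < 1:
            raise IndexError(f"pair ({i},{j}) out of range")
        if i > n or j > n:
            if not allow_truncated:
                raise IndexError(f"pair ({i},{j}) beyond sequence length {n}")
            truncated = True
            bi = rna[i - 1] if i <= n else ""
            bj = rna[j - 1] if j <= n else ""
            statuses.append(PairStatus(i, j, bi, bj, "unpaired"))
            continue
        bi, bj = rna[i - 1], rna[j - 1]
        if (bi, bj) in WATSON_CRICK and (bi, bj) in spec.allowed_pairs:
            status = "watson_crick"
        elif (bi, bj) in WOBBLE and (bi, bj) in spec.allowed_pairs:
            status = "wobble"
        else:
            status = "unpaired"
        statuses.append(PairStatus(i, j, bi, bj, status))
    return StemCheckResult(per_pair=tuple(statuses), truncated=truncated)


@dataclass(frozen=True)
class StemComparison:
    ref: StemCheckResult
    var: StemCheckResult
    lost_pairs: tuple[tuple[int, int], ...]


def compare_stem(ref_seq: str, var_seq: str, spec: StemSpec) -> StemComparison:
    """Evaluate variant against the reference's positional layout.

    The variant is *not* re-annotated: the same (i, j) positions are read off
    the variant sequence, so an upstream deletion shifts every downstream base
    under the layout. ``lost_pairs`` are pairs intact (paired) in the reference
    but unpaired in the variant.
    """
    ref = check_stem(ref_seq, spec)
    var = check_stem(var_seq, spec, allow_truncated=True)
    lost = tuple(
        (r.i, r.j)
        for r, v in zip(ref.per_pair, var.per_pair)
        if r.status != "unpaired" and v.status == "unpaired"
    )
    return StemComparison(ref=ref, var=var, lost_pairs=lost)


def result_to_dict(res: StemCheckResult) -> dict:
    return {
        "per_pair": [
            {"i": p.i, "j": p.j, "base_i": p.base_i, "base_j": p.base_j,
             "status": p.status}
            for p in res.per_pair
        ],
        "wobble_count": res.wobble_count,
        "intact": res.intact,
        "truncated": res.truncated,
    }
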