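"""Anchored discovery of prophage attachment sites as direct repeats.

An integrated P4-like element is delimited by two same-strand copies of a core
sequence: attL (overlapping the 3' end of the anchor tmRNA/tRNA gene) and attR
(at the element's far boundary). Given a window around the anchor's 3' end and
a window downstream, this module reports every maximal exact direct repeat of
at least ``min_core_len`` nucleotides with one copy in each window.

Search is seed-and-extend with k = min_core_len exact seeds; matches are
restricted to, and maximal within, the two windows. ``N`` never matches,
including against another ``N``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from Bio import Align

from .genome_io import Feature, GenomeRecord

DEFAULT_MIN_CORE_LEN = 15
DEFAULT_FLANK_WIDTH = 30
DEFAULT_MAX_SPAN = 100_000


class NoAttSiteFound(Exception):
    """No direct repeat of the required length in the searched windows."""

    def __init__(self, windows: "SearchWindows"):
        self.windows = windows
        super().__init__(
            f"no direct repeat >= {windows.min_core_len} nt between "
            f"left window {windows.left} and right window {windows.right}"
        )


@dataclass(frozen=True)
class SearchWindows:
    """Two disjoint 1-based inclusive intervals to search for repeat copies."""

    left: tuple[int, int]
    right: tuple[int, int]
    min_core_len: int = DEFAULT_MIN_CORE_LEN
    max_span: int = DEFAULT_MAX_SPAN

    def __post_init__(self) -> None:
        ls, le = self.left
        rs, re = self.right
        if ls > le or rs > re:
            raise ValueError("window start > end")
        if not (le < rs or re < ls):
            raise ValueError("left and right windows must be disjoint")
        if self.min_core_len < 8:
            raise ValueError("min_core_len must be >= 8")


@dataclass(frozen=True)
class FlankDifference:
    """One difference between the aligned attL and attR contexts.

    ``offset`` is 0-based relative to the start of the aligned window
    (core start minus flank width).
    """

    offset: int
    type: str  # mismatch | insertion_L | insertion_R
    bases: str


@dataclass(frozen=True)
class AttSitePair:
    """attL/attR coordinates (1-based inclusive) with their exact shared core."""

    attL: tuple[int, int]
    attR: tuple[int, int]
    core_len: int
    core_seq: str
    flank_alignment: tuple[FlankDifference, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.attL[1] >= self.attR[0]:
            raise ValueError("attL must end before attR starts")
        if self.core_len != len(self.core_seq):
            raise ValueError("core_len inconsistent with core_seq")

    @property
    def span(self) -> int:
        """Distance attR.start - attL.start (the integrated element's extent)."""
        return self.attR[0] - self.attL[0]


def _window_seq(seq: str, window: tuple[int, int]) -> str:
    return seq[window[0] - 1 : window[1]]


def find_direct_repeats(seq: str, windows: SearchWindows) -> list[AttSitePair]:
    """All maximal exact same-strand repeats with one copy per window.

    Matches are maximal within the windows: extension stops at a mismatch, an
    ``N`` in either copy, or a window boundary. Output is sorted by core length
    descending, then leftmost attL start, then leftmost attR start.
    """
    seq = seq.upper()
    k = windows.min_core_len
    left = _window_seq(seq, windows.left)
    right = _window_seq(seq, windows.right)
    if len(left) < k or len(right) < k:
        return []

    # index left-window k-mers (seeds); skip any containing N
    seeds: dict[str, list[int]] = {}
    for i in range(len(left) - k + 1):
        kmer = left[i : i + k]
        if "N" in kmer:
            continue
        seeds.setdefault(kmer, []).append(i)

    found: set[tuple[int, int, int]] = set()  # (left_start, right_start, length), 0-based in windows
    for j in range(len(right) - k + 1):
        kmer = right[j : j + k]
        if "N" in kmer:
            continue
        for i in seeds.get(kmer, ()):
            # extend left
            li, rj = i, j
            while li > 0 and rj > 0 and left[li - 1] == right[rj - 1] != "N":
                li -= 1
                rj -= 1
            # extend right
            le, re_ = i + k, j + k
            while (le < len(left) and re_ < len(right)
                   and left[le] == right[re_] != "N"):
                le += 1
                re_ += 1
            found.add((li, rj, le - li))

    ls0 = windows.left[0]
    rs0 = windows.right[0]
    pairs = [
        AttSitePair(
            attL=(ls0 + li, ls0 + li + n - 1),
            attR=(rs0 + rj, rs0 + rj + n - 1),
            core_len=n,
            core_seq=left[li : li + n],
        )
        for (li, rj, n) in found
    ]
    pairs.sort(key=lambda p: (-p.core_len, p.attL[0], p.attR[0]))
    return pairs


def align_flanks(seq: str, pair: AttSitePair, w: int = DEFAULT_FLANK_WIDTH
                 ) -> tuple[FlankDifference, ...]:
    """Banded global alignment of core +/- w around each copy; returns the diffs.

    Gap cost exceeds mismatch cost so a single indel is preferred over a run of
    mismatches only when it truly shortens the edit script.
    """
    lw = seq[max(0, pair.attL[0] - 1 - w) : pair.attL[1] + w]
    rw = seq[max(0, pair.attR[0] - 1 - w) : pair.attR[1] + w]
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -2
    aln = aligner.align(lw, rw)[0]
    diffs: list[FlankDifference] = []
    la, ra = str(aln[0]), str(aln[1])
    off = 0  # offset in the left window coordinates
    for a, b in zip(la, ra):
        if a == "-":
            diffs.append(FlankDifference(offset=off, type="insertion_R", bases=b))
            continue  # left coordinate does not advance
        if b == "-":
            diffs.append(FlankDifference(offset=off, type="insertion_L", bases=a))
        elif a != b:
            diffs.append(FlankDifference(offset=off, type="mismatch", bases=a + b))
        off += 1
    return tuple(diffs)


def locate_prophage(
    g: GenomeRecord,
    anchor: Feature,
    integrase: Feature,
    windows: SearchWindows | None = None,
    flank_width: int = DEFAULT_FLANK_WIDTH,
    min_core_len: int = DEFAULT_MIN_CORE_LEN,
    max_span: int = DEFAULT_MAX_SPAN,
) -> AttSitePair:
    """Best att-site pair anchored at a tmRNA/tRNA gene.

    Default windows: [anchor.start, integrase.start] on the left, and from the
    integrase start to anchor.start + max_span (clamped) on the right.
    Candidates must have attL overlapping or abutting the anchor's 3' region
    and span <= max_span; ties break to (longer core, smaller attL start).
    """
    if windows is None:
        left = (anchor.start, integrase.start)
        right = (integrase.start + 1, min(len(g.seq), anchor.start + max_span))
        windows = SearchWindows(left=left, right=right,
                                min_core_len=min_core_len, max_span=max_span)
    candidates = find_direct_repeats(g.seq, windows)
    best: AttSitePair | None = None
    for pair in candidates:
        if pair.span > windows.max_span:
            continue
        # attL overlaps or abuts (within 1 nt of) the anchor interval
        if pair.attL[0] > anchor.end + 1 or pair.attL[1] < anchor.start - 1:
            continue
        best = pair
        break  # list is already sorted by the tie-break order
    if best is None:
        raise NoAttSiteFound(windows)
    return AttSitePair(
        attL=best.attL, attR=best.attR, core_len=best.core_len,
        core_seq=best.core_seq,
        flank_alignment=align_flanks(g.seq, best, w=flank_width),
    )


def att_pair_to_bed(g_id: str, pair: AttSitePair, name: str = "att") -> str:
    """attL and attR as two 6-column BED lines (0-based half-open)."""
    lines = [
        f"{g_id}\t{pair.attL[0] - 1}\t{pair.attL[1]}\t{name}L\t{pair.core_len}\t+",
        f"{g_id}\t{pair.attR[0] - 1}\t{pair.attR[1]}\t{name}R\t{pair.core_len}\t+",
    ]
    return "\n".join(lines) + "\n"


def att_pair_report(pair: AttSitePair) -> str:
    """JSON report with core sequence and flank differences."""
    return json.dumps(
        {
            "attL": list(pair.attL),
            "attR": list(pair.attR),
            "core_len": pair.core_len,
            "core_seq": pair.core_seq,
            "span": pair.span,
            "flank_alignment": [
                {"offset": d.offset, "type": d.type, "bases": d.bases}
                for d in pair.flank_alignment
            ],
        },
        indent=2,
    )
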