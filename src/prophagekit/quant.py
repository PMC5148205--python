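"""Excision-frequency estimation: qPCR standard curve and junction reads.

Two independent estimators of the fraction of prophage-free chromosomes in a
mixed population:

* qPCR — the excision-specific junction amplicon (product only exists once the
  element has left the chromosome) is quantified against a single-copy
  reference gene (e.g. gyrB). A mixing series of known prophage-free fractions
  (1/10 ... 1/10^6) calibrates a standard curve of dCq = Cq_junction -
  Cq_reference against log10(fraction); sample dCq values are inverted through
  the fit. For a perfectly efficient reaction (E = 2) the slope is
  -1/log10(2) = -3.3219 cycles per decade.

* junction-spanning reads — reads that cross the regenerated attB junction
  versus reads crossing the intact attL junction, with a Wilson 95% interval.

Plus fold-change arithmetic for condition series (e.g. temperature shifts) and
an efficiency-corrected ddCq relative-expression helper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import reverse_complement

DEFAULT_MIN_OVERHANG = 10


class FitError(ValueError):
    """Standard-curve fit impossible (too few points or degenerate design)."""


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class QpcrWell:
    sample: str
    target: str  # junction | reference
    Cq: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if not (self.Cq > 0 and math.isfinite(self.Cq)):
            raise ValueError(f"Cq must be finite and positive, got {self.Cq}")


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares fit of dCq against log10(known fraction)."""

    slope: float       # cycles per decade; negative for a working assay
    intercept: float   # dCq at fraction 1
    r2: float

    @property
    def efficiency(self) -> float:
        """Fold amplification per cycle, E = 10^(-1/slope)."""
        return 10.0 ** (-1.0 / self.slope)

    def summary(self) -> str:
        return (
            f"StandardCurve: dCq = {self.slope:.4f} * log10(f) + "
            f"{self.intercept:.4f}  (r2 = {self.r2:.4f}, "
            f"E = {self.efficiency:.3f})"
        )


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit (known fraction, dCq) calibration points.

    Requires >= 3 distinct fractions spanning at least two decades.
    """
    if len(points) < 3:
        raise FitError(f"need >= 3 calibration points, got {len(points)}")
    f = np.asarray([p[0] for p in points], dtype=float)
    d = np.asarray([p[1] for p in points], dtype=float)
    if np.any(f <= 0):
        raise FitError("fractions must be positive")
    x = np.log10(f)
    if len(np.unique(x)) < 3 or np.ptp(x) < 2.0 - 1e-9:
        raise FitError("calibration fractions must span >= 2 decades "
                       "with >= 3 distinct values")
    res = stats.linregress(x, d)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r2=float(res.rvalue) ** 2)


@dataclass(frozen=True)
class FrequencyEstimate:
    frequency: float
    clamped: bool = False


def qpcr_frequency(cq_junction: float, cq_reference: float,
                   curve: StandardCurve) -> FrequencyEstimate:
    """Invert a sample's dCq through the standard curve; clamp to [0, 1]."""
    dcq = cq_junction - cq_reference
    f = 10.0 ** ((dcq - curve.intercept) / curve.slope)
    if f > 1.0:
        return FrequencyEstimate(frequency=1.0, clamped=True)
    return FrequencyEstimate(frequency=f, clamped=False)


def summarise_wells(wells: Iterable[QpcrWell]) -> pd.DataFrame:
    """Mean Cq per (sample, target) — replicates are averaged before inversion."""
    df = pd.DataFrame([w.__dict__ for w in wells])
    return (df.groupby(["sample", "target"], as_index=False)["Cq"]
              .mean())


def frequencies_from_wells(wells: Iterable[QpcrWell],
                           curve: StandardCurve) -> pd.DataFrame:
    """Per-sample excision frequency table from junction+reference wells."""
    mean_cq = summarise_wells(wells).pivot(index="sample", columns="target",
                                           values="Cq")
    if not {"junction", "reference"} <= set(mean_cq.columns):
        raise ConfigurationError("each sample needs junction and reference wells")
    rows = []
    for sample, row in mean_cq.iterrows():
        est = qpcr_frequency(row["junction"], row["reference"], curve)
        rows.append({"sample": sample, "frequency": est.frequency,
                     "clamped": est.clamped})
    return pd.DataFrame(rows)


def wilson_interval(k: int, n: int, confidence: float = 0.95
                    ) -> tuple[float, float]:
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=confidence,
                                             method="wilson")
    return float(ci.low), float(ci.high)


@dataclass(frozen=True)
class JunctionCounts:
    n_attB: int
    n_attL: int
    n_ambiguous: int = 0

    @property
    def n_informative(self) -> int:
        return self.n_attB + self.n_attL

    @property
    def insufficient_data(self) -> bool:
        return self.n_informative == 0

    @property
    def freq(self) -> float:
        if self.insufficient_data:
            return float("nan")
        return self.n_attB / self.n_informative

    @property
    def ci(self) -> tuple[float, float]:
        if self.insufficient_data:
            return (float("nan"), float("nan"))
        return wilson_interval(self.n_attB, self.n_informative)


def count_junction_reads(
    reads: Iterable[str],
    attB_junction: str,
    attL_junction: str,
    core: str,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> JunctionCounts:
    """Count reads spanning the excised (attB) vs lysogen (attL) junction.

    A read counts for a junction iff it contains, exactly and on either strand,
    the window core +/- min_overhang of that junction string. Reads matching
    both windows are ambiguous and count for neither. Matching is exact — no
    mismatches tolerated.
    """
    attB_junction = attB_junction.upper()
    attL_junction = attL_junction.upper()
    core = core.upper()
    if attB_junction == attL_junction:
        raise ConfigurationError("attB and attL junction strings are identical")

    def window(junction: str, name: str) -> str:
        i = junction.find(core)
        if i < 0 or junction.find(core, i + 1) >= 0:
            raise ConfigurationError(
                f"core must occur exactly once in the {name} junction string")
        if i < min_overhang or len(junction) - (i + len(core)) < min_overhang:
            raise ConfigurationError(
                f"{name} junction needs >= {min_overhang} nt flank on each side")
        return junction[i - min_overhang : i + len(core) + min_overhang]

    wb = window(attB_junction, "attB")
    wl = window(attL_junction, "attL")
    if wb == wl:
        raise ConfigurationError("junction windows identical; raise min_overhang")

    n_b = n_l = n_amb = 0
    for read in reads:
        r = read.upper()
        hit_b = wb in r or wb in reverse_complement(r)
        hit_l = wl in r or wl in reverse_complement(r)
        if hit_b and hit_l:
            n_amb += 1
        elif hit_b:
            n_b += 1
        elif hit_l:
            n_l += 1
    return JunctionCounts(n_attB=n_b, n_attL=n_l, n_ambiguous=n_amb)


@dataclass(frozen=True)
class FoldChange:
    ratio: float
    infinite: bool = False


def fold_change(f_after: float, f_before: float) -> FoldChange:
    """Ratio of two excision frequencies (e.g. across a temperature shift)."""
    if f_before == 0:
        return FoldChange(ratio=float("inf"), infinite=True)
    return FoldChange(ratio=f_after / f_before)


def relative_expression(cq_gene_a: float, cq_ref_a: float,
                        cq_gene_b: float, cq_ref_b: float,
                        efficiency: float = 2.0) -> float:
    """Efficiency-corrected ddCq fold change of a gene between conditions a and b."""
    if not (1.0 < efficiency <= 2.0):
        raise ValueError(f"efficiency must be in (1, 2], got {efficiency}")
    ddcq = (cq_gene_a - cq_ref_a) - (cq_gene_b - cq_ref_b)
    return efficiency ** (-ddcq)


def temperature_series_report(conditions: Sequence[tuple[str, float]]
                              ) -> pd.DataFrame:
    """Condition -> frequency -> fold-change-vs-previous table.

    Mirrors the layout of a temperature-shift series: each row carries the
    measured excision frequency and the fold change relative to the preceding
    condition.
    """
    rows = []
    prev: float | None = None
    for name, freq in conditions:
        fc = float("nan") if prev is None else fold_change(freq, prev).ratio
        rows.append({"condition": name, "frequency": freq,
                     "fold_change_vs_previous": fc})
        prev = freq
    return pd.DataFrame(rows)


def read_qpcr_wells_tsv(path) -> list[QpcrWell]:
    """TSV columns: sample, target, replicate, Cq."""
    df = pd.read_csv(path, sep="\t")
    return [
        QpcrWell(sample=str(r["sample"]), target=str(r["target"]),
                 Cq=float(r["Cq"]), replicate=int(r.get("replicate", 1)))
        for _, r in df.iterrows()
    ]


def read_standard_curve_tsv(path) -> list[tuple[float, float]]:
    """TSV columns: fraction, Cq_junction, Cq_reference -> (fraction, dCq)."""
    df = pd.read_csv(path, sep="\t")
    return [
        (float(r["fraction"]), float(r["Cq_junction"]) - float(r["Cq_reference"]))
        for _, r in df.iterrows()
    ]
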