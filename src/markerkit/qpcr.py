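"""Absolute qPCR quantification of marker and 16S rRNA gene copies.

A standard curve (Ct against log10 gene copies over a serial dilution) is
fitted by least squares; amplification efficiency follows from the slope as
``E = 10**(-1/slope) - 1``.  Quality control uses the accepted bands for
trustworthy absolute quantification: efficiency within 85-125% and a
y-intercept (Ct of a single template copy) within 35-40 cycles.  Sample Cts
are inverted through the curve to copies/µL, averaged over technical
replicates, and the cellulolytic fraction of a community is reported as the
GH48/16S gene-copy ratio in percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "QuantResult",
    "RatioResult",
    "fit_standard_curve",
    "copies_from_mass",
    "quantify",
    "marker_ratio",
    "load_published_copy_numbers",
]

AVOGADRO = 6.02214076e23

#: Per-strand residue weights (g/mol) of the DNA molecular-weight calculator
#: convention used for the plasmid standards; the constant term removes one
#: phosphate (-HPO3, +H) per strand.
DNA_WEIGHTS = {"A": 313.21, "T": 304.2, "C": 289.18, "G": 329.21}
STRAND_OFFSET = -61.96

EFFICIENCY_BAND = (85.0, 125.0)
INTERCEPT_BAND = (35.0, 40.0)
DEFAULT_LOQ = 1e3  # copies/µL, lower end of the linear range


@dataclass
class StandardCurve:
    """Fitted qPCR calibration: Ct = slope * log10(copies) + intercept."""

    points: list[tuple[float, float]]  # (log10 copies, Ct)
    slope: float
    intercept: float
    r2: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency in percent (100% = perfect doubling)."""
        return (10.0 ** (-1.0 / self.slope) - 1.0) * 100.0

    @property
    def qc_efficiency(self) -> bool:
        return EFFICIENCY_BAND[0] <= self.efficiency <= EFFICIENCY_BAND[1]

    @property
    def qc_intercept(self) -> bool:
        return INTERCEPT_BAND[0] <= self.intercept <= INTERCEPT_BAND[1]

    @property
    def qc_pass(self) -> bool:
        return self.qc_efficiency and self.qc_intercept

    def ct_at(self, copies: float) -> float:
        return self.slope * math.log10(copies) + self.intercept

    def copies_at(self, ct: float) -> float:
        return 10.0 ** ((ct - self.intercept) / self.slope)

    def summary(self) -> str:
        return (
            f"standard curve over {len(self.points)} dilution points\n"
            f"  slope = {self.slope:.4f}  y-intercept = {self.intercept:.2f} Ct"
            f"  R2 = {self.r2:.4f}\n"
            f"  efficiency = {self.efficiency:.1f}% "
            f"[QC {EFFICIENCY_BAND[0]:.0f}-{EFFICIENCY_BAND[1]:.0f}%: "
            f"{'PASS' if self.qc_efficiency else 'FAIL'}]\n"
            f"  intercept QC [{INTERCEPT_BAND[0]:.0f}-{INTERCEPT_BAND[1]:.0f} Ct]: "
            f"{'PASS' if self.qc_intercept else 'FAIL'}"
        )


def fit_standard_curve(points: Iterable[tuple[float, float]]) -> StandardCurve:
    """Fit Ct against log10(copies) for a serial dilution.

    ``points`` are ``(copies_per_µl, Ct)`` pairs; at least 4 dilution points
    spanning at least 3 orders of magnitude are required, and the slope must
    be negative (Ct decreases with template amount).
    """
    pts = [(float(c), float(ct)) for c, ct in points]
    if len(pts) < 4:
        raise ValueError(f"need >= 4 dilution points, got {len(pts)}")
    logs = [math.log10(c) for c, _ in pts]
    if max(logs) - min(logs) < 3.0:
        raise ValueError("dilution series must span >= 3 log10 units")
    cts = [ct for _, ct in pts]
    fit = stats.linregress(logs, cts)
    if fit.slope >= 0:
        raise ValueError(f"invalid standard curve: non-negative slope {fit.slope:.3f}")
    return StandardCurve(
        points=list(zip(logs, cts)),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
    )


def copies_from_mass(conc: float, sequence: str, topology: str = "linear-ds") -> float:
    """Gene copies/µL of a linearized double-stranded DNA standard.

    ``conc`` is in g/µL.  The molecular weight sums per-base residue weights
    over both strands, minus one phosphate equivalent per strand.
    """
    if conc <= 0:
        raise ValueError(f"concentration must be positive, got {conc}")
    if topology != "linear-ds":
        raise ValueError(f"unsupported topology {topology!r}")
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    n_at = seq.count("A") + seq.count("T")
    n_cg = seq.count("C") + seq.count("G")
    mw = (
        n_at * (DNA_WEIGHTS["A"] + DNA_WEIGHTS["T"])
        + n_cg * (DNA_WEIGHTS["C"] + DNA_WEIGHTS["G"])
        + 2 * STRAND_OFFSET
    )
    return conc * AVOGADRO / mw


@dataclass
class QuantResult:
    """Mean absolute copy number of one target in one sample."""

    sample: str
    target: str
    copies_per_ul: float
    sd: float | None
    n_reps: int
    below_loq: bool

    def __str__(self) -> str:
        sd = f" ± {self.sd:.3g}" if self.sd is not None else ""
        flag = "  [below LOQ]" if self.below_loq else ""
        return (
            f"{self.sample} {self.target}: {self.copies_per_ul:.3g}{sd} "
            f"copies/µL (n={self.n_reps}){flag}"
        )


def quantify(
    cts: Sequence[float | None],
    curve: StandardCurve,
    sample: str = "",
    target: str = "GH48",
    loq: float = DEFAULT_LOQ,
) -> QuantResult:
    """Invert technical-replicate Cts through the standard curve.

    Missing replicates (``None``/NaN) are dropped; the mean and sample
    standard deviation are taken over the per-replicate copy numbers, and
    the result is flagged when the mean falls below the limit of
    quantification (default 10³ copies/µL).
    """
    values = [
        float(ct) for ct in cts if ct is not None and not (isinstance(ct, float) and math.isnan(ct))
    ]
    if not values:
        raise ValueError(f"sample {sample!r}: no valid Ct among replicates")
    copies = np.array([curve.copies_at(ct) for ct in values])
    mean = float(copies.mean())
    sd = float(copies.std(ddof=1)) if len(copies) > 1 else None
    return QuantResult(
        sample=sample,
        target=target,
        copies_per_ul=mean,
        sd=sd,
        n_reps=len(copies),
        below_loq=mean < loq,
    )


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RatioResult:
    """Marker/16S gene-copy ratio of one sample, in percent."""

    sample: str
    ratio_pct: float  # unrounded
    ratio_pct_rounded: float  # half-up, 1 decimal (presentation value)
    sd: float | None  # delta-method propagated, unrounded
    reliable: bool

    def __str__(self) -> str:
        note = "" if self.reliable else "  [unreliable: below LOQ]"
        return f"{self.sample}: GH48/16S = {self.ratio_pct_rounded}%{note}"


def marker_ratio(gh48: QuantResult, rrna: QuantResult) -> RatioResult:
    """GH48/16S gene-copy ratio, 100 × marker copies / 16S copies.

    The standard deviation is propagated to first order (relative variances
    add).  The ratio is flagged unreliable when either quantification sits
    below the limit of quantification.
    """
    if gh48.sample != rrna.sample:
        raise ValueError(f"sample mismatch: {gh48.sample!r} vs {rrna.sample!r}")
    if rrna.copies_per_ul == 0:
        raise ValueError(f"sample {rrna.sample!r}: zero 16S copies")
    ratio = 100.0 * gh48.copies_per_ul / rrna.copies_per_ul
    sd = None
    if gh48.sd is not None and rrna.sd is not None:
        rel = math.sqrt(
            (gh48.sd / gh48.copies_per_ul) ** 2 + (rrna.sd / rrna.copies_per_ul) ** 2
        )
        sd = ratio * rel
    return RatioResult(
        sample=gh48.sample,
        ratio_pct=ratio,
        ratio_pct_rounded=_round_half_up(ratio, 1),
        sd=sd,
        reliable=not (gh48.below_loq or rrna.below_loq),
    )


def ratio_from_copies(
    sample: str,
    gh48_copies: float,
    rrna_copies: float,
    gh48_sd: float | None = None,
    rrna_sd: float | None = None,
) -> RatioResult:
    """Ratio directly from reported copy numbers (e.g. a published table)."""
    g = QuantResult(sample, "GH48", gh48_copies, gh48_sd, 3, gh48_copies < DEFAULT_LOQ)
    r = QuantResult(sample, "16S", rrna_copies, rrna_sd, 3, rrna_copies < DEFAULT_LOQ)
    return marker_ratio(g, r)


def load_published_copy_numbers() -> pd.DataFrame:
    """Published GH48/16S copy-number table for the biogas fermenter samples
    (raw digestate and in sacco enrichments), with the printed ratios."""
    with resources.as_file(
        resources.files("markerkit.data") / "biogas_qpcr_copy_numbers.tsv"
    ) as path:
        return pd.read_csv(path, sep="\t")


def quantification_table(results: Iterable[RatioResult]) -> pd.DataFrame:
    rows = [
        {
            "sample": r.sample,
            "ratio_gh48_16s_pct": r.ratio_pct_rounded,
            "ratio_sd_pct": r.sd,
            "reliable": r.reliable,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
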