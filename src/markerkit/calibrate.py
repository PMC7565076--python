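"""Calibration of marker-gene OTU thresholds against 16S rRNA identity.

Two complementary calibrations for a fast-evolving functional marker such
as the GH48 cellulase gene:

1. **Identity correlation** — for every pair of reference organisms, the
   marker-amplicon identity is regressed on the 16S rRNA identity (linear
   or polynomial least squares).  Reading the fitted curve at conventional
   16S cut-offs (95/97/99%) converts them into marker cut-offs.  Fit quality
   is reported as adjusted R², RMSE, MAE and the leave-one-out PRESS
   statistic.

2. **Clustering agreement** — marker sequences are greedily clustered over
   a grid of identity thresholds and, at each threshold, the percentage of
   sequences sitting in a cluster that is pure with respect to their
   taxonomic label is recorded.  The calibrated threshold is the smallest
   one at which every sequence is placed consistently (100% agreement),
   optionally after excluding outlier sequences (e.g. horizontally
   transferred genes) that prevent perfect agreement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .align import pairwise_identity
from .cluster import Clustering, greedy_cluster

__all__ = [
    "IdentityPairSet",
    "FitResult",
    "AgreementCurve",
    "build_pairset",
    "pairset_from_db",
    "fit_model",
    "predict_threshold",
    "greedy_cluster",
    "clustering_agreement",
    "calibrate_threshold",
]


@dataclass
class IdentityPairSet:
    """Unordered organism pairs with marker and 16S percent identities."""

    pairs: list[tuple[str, str, float, float]]
    subset_tag: str = "custom"

    def __len__(self) -> int:
        return len(self.pairs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pairs, columns=["id_a", "id_b", "gh48_identity", "rrna_identity"]
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, subset_tag: str = "custom") -> "IdentityPairSet":
        df = pd.read_csv(path, sep="\t")
        pairs = [
            (str(r.id_a), str(r.id_b), float(r.gh48_identity), float(r.rrna_identity))
            for r in df.itertuples()
        ]
        return cls(pairs, subset_tag=subset_tag)


def build_pairset(
    entries: Mapping[str, tuple[str, str]],
    subset_tag: str = "custom",
    identity_fn: Callable[[str, str], float] = pairwise_identity,
) -> IdentityPairSet:
    """All unordered pairs of ``{organism_id: (marker_seq, rrna_seq)}``.

    Both identities of a pair are computed on the same two organisms.
    """
    ids = sorted(entries)
    if len(ids) < 3:
        raise ValueError(f"need at least 3 entries to build a pair set, got {len(ids)}")
    pairs = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            gi = identity_fn(entries[a][0], entries[b][0])
            ri = identity_fn(entries[a][1], entries[b][1])
            pairs.append((a, b, gi, ri))
    return IdentityPairSet(pairs, subset_tag=subset_tag)


def pairset_from_db(
    db,
    amplicons: Mapping[str, str],
    complete_only: bool = False,
    min_16s_length: int = 1200,
    **kwargs,
) -> IdentityPairSet:
    """Derive a calibration pair set from a combined reference database.

    Keeps records with an extracted amplicon and a full-length 16S gene,
    drops hypothetical proteins, and — for the all-assemblies subset —
    drops entries without a valid species epithet in the dominant genus
    *Streptomyces* (which would otherwise swamp the pair set).  With
    ``complete_only`` only complete genome assemblies are used
    (GH48-16S-C); otherwise any assembly qualifies (GH48-16S).
    """
    entries: dict[str, tuple[str, str]] = {}
    for rec in db.records:
        if rec.record_id not in amplicons:
            continue
        if not rec.rrna16s or len(rec.rrna16s) < min_16s_length:
            continue
        if "hypothetical" in rec.flags:
            continue
        if complete_only:
            if rec.assembly_level != "complete":
                continue
        else:
            if rec.organism.startswith("Streptomyces sp."):
                continue
        entries[rec.record_id] = (amplicons[rec.record_id], rec.rrna16s)
    tag = "GH48-16S-C" if complete_only else "GH48-16S"
    return build_pairset(entries, subset_tag=tag, **kwargs)


@dataclass
class FitResult:
    """A fitted marker-vs-16S identity model with its fit diagnostics.

    ``coefficients`` are in ascending power order (intercept first); the
    response is marker identity, the predictor 16S identity.  ``rmse`` uses
    denominator n; ``press`` is the exact leave-one-out residual sum of
    squares from the hat matrix.
    """

    model: str
    degree: int
    coefficients: np.ndarray
    r2_adj: float
    rmse: float
    mae: float
    press: float
    n: int
    x_range: tuple[float, float]

    def predict(self, x) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float), self.coefficients)

    def summary(self) -> str:
        coefs = ", ".join(f"b{i}={c:.6g}" for i, c in enumerate(self.coefficients))
        return (
            f"{self.model} fit (degree {self.degree}, n={self.n})\n"
            f"  coefficients: {coefs}\n"
            f"  adj. R2 = {self.r2_adj:.4f}   RMSE = {self.rmse:.4f}   "
            f"MAE = {self.mae:.4f}   PRESS = {self.press:.4f}\n"
            f"  16S identity range observed: "
            f"[{self.x_range[0]:.2f}, {self.x_range[1]:.2f}]"
        )


def fit_model(
    pairs: IdentityPairSet | Sequence[tuple],
    model: str = "linear",
    degree: int | None = None,
) -> FitResult:
    """Least-squares fit of marker identity on 16S identity.

    ``model`` is ``"linear"`` (degree 1) or ``"polynomial"`` (default
    degree 2).  Diagnostics: adjusted R², RMSE (denominator n), MAE and
    PRESS computed exactly via leave-one-out residuals e_i / (1 - h_ii).
    """
    if model == "linear":
        if degree not in (None, 1):
            raise ValueError("linear model has degree 1")
        degree = 1
    elif model == "polynomial":
        degree = 2 if degree is None else degree
        if degree < 2:
            raise ValueError("polynomial model needs degree >= 2")
    else:
        raise ValueError(f"model must be linear|polynomial, got {model!r}")

    if isinstance(pairs, IdentityPairSet):
        data = pairs.pairs
    else:
        data = list(pairs)
    x = np.array([p[3] for p in data], dtype=float)
    y = np.array([p[2] for p in data], dtype=float)
    n = len(x)
    if n <= degree + 1:
        raise ValueError(f"n={n} too small for degree {degree}")

    X = np.vander(x, degree + 1, increasing=True)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (too few distinct 16S identities)")
    res = sm.OLS(y, X).fit()
    resid = res.resid
    infl = res.get_influence()
    press = float(np.sum((resid / (1.0 - infl.hat_matrix_diag)) ** 2))
    return FitResult(
        model=model,
        degree=degree,
        coefficients=np.asarray(res.params, dtype=float),
        r2_adj=float(res.rsquared_adj),
        rmse=float(np.sqrt(np.sum(resid**2) / n)),
        mae=float(np.mean(np.abs(resid))),
        press=press,
        n=n,
        x_range=(float(x.min()), float(x.max())),
    )


def predict_threshold(fit: FitResult, rrna_identity: float) -> tuple[int, bool]:
    """Marker-identity threshold at a given 16S identity.

    Returns ``(threshold, extrapolated)``: the fitted value rounded half-up
    to the nearest integer percent, and a flag raised when the requested 16S
    identity lies outside the fitted range.
    """
    if not 0 <= rrna_identity <= 100:
        raise ValueError(f"rrna_identity must be in [0, 100], got {rrna_identity}")
    y = float(fit.predict(rrna_identity))
    extrapolated = not (fit.x_range[0] <= rrna_identity <= fit.x_range[1])
    if extrapolated:
        warnings.warn(
            f"16S identity {rrna_identity}% outside fitted range {fit.x_range}",
            stacklevel=2,
        )
    return int(math.floor(y + 0.5)), extrapolated


def clustering_agreement(
    clustering: Clustering,
    labels: Mapping[str, str],
    mode: str = "purity",
) -> float:
    """Agreement (%) between an OTU partition and taxonomic labels.

    ``purity`` (primary): percentage of sequences whose cluster contains no
    member of a different taxon.  ``pairwise``: percentage of same-taxon
    pairs that are co-clustered.
    """
    membership = clustering.membership()
    missing = [sid for sid in membership if sid not in labels]
    if missing:
        raise ValueError(f"unlabelled sequences: {missing[:5]}")
    if mode == "purity":
        n = 0
        pure = 0
        for members in clustering.clusters.values():
            taxa = {labels[m] for m in members}
            n += len(members)
            if len(taxa) == 1:
                pure += len(members)
        return 100.0 * pure / n if n else 100.0
    if mode == "pairwise":
        by_taxon: dict[str, list[str]] = {}
        for sid in membership:
            by_taxon.setdefault(labels[sid], []).append(sid)
        total = 0
        together = 0
        for members in by_taxon.values():
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    total += 1
                    if membership[a] == membership[b]:
                        together += 1
        return 100.0 * together / total if total else 100.0
    raise ValueError(f"mode must be purity|pairwise, got {mode!r}")


@dataclass
class AgreementCurve:
    """Clustering agreement across an identity-threshold grid."""

    thresholds: list[int]
    agreement: list[float]
    rank: str = "genus"
    mode: str = "purity"
    calibrated_threshold: int | None = None
    outliers: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "agreement": self.agreement})

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _curve(
    seqs: Mapping[str, str],
    labels: Mapping[str, str],
    grid: Sequence[int],
    mode: str,
    identity_fn,
) -> tuple[list[float], dict[int, Clustering]]:
    agreement = []
    clusterings = {}
    for t in grid:
        cl = greedy_cluster(seqs, float(t), identity_fn=identity_fn)
        clusterings[t] = cl
        agreement.append(clustering_agreement(cl, labels, mode=mode))
    return agreement, clusterings


def calibrate_threshold(
    seqs: Mapping[str, str],
    labels: Mapping[str, str],
    grid: Iterable[int] = range(60, 101),
    rank: str = "genus",
    mode: str = "purity",
    exclude_outliers: bool = False,
    identity_fn: Callable[[str, str], float] = pairwise_identity,
) -> AgreementCurve:
    """Scan an identity grid for the smallest threshold with 100% agreement.

    With ``exclude_outliers``, sequences sitting in impure clusters at the
    best grid point (candidate threshold) are reported and removed, and the
    curve recomputed — mirroring the exclusion of putatively misclassified
    or horizontally transferred reference sequences.  When no threshold
    reaches 100% even then, ``calibrated_threshold`` is ``None`` and the
    curve is still returned.
    """
    grid = sorted(set(int(t) for t in grid))
    if len(set(labels[s] for s in seqs)) < 2:
        # single taxon: trivially 100% everywhere
        return AgreementCurve(
            thresholds=list(grid),
            agreement=[100.0] * len(grid),
            rank=rank,
            mode=mode,
            calibrated_threshold=grid[0] if grid else None,
        )

    agreement, clusterings = _curve(seqs, labels, grid, mode, identity_fn)
    outliers: list[str] = []
    calibrated = _smallest_perfect(grid, agreement)
    if calibrated is None and exclude_outliers:
        # candidate = smallest threshold achieving the maximal agreement
        best = max(agreement)
        candidate = grid[agreement.index(best)]
        cl = clusterings[candidate]
        for members in cl.clusters.values():
            if len({labels[m] for m in members}) > 1:
                outliers.extend(members)
        outliers = sorted(set(outliers))
        kept = {sid: s for sid, s in seqs.items() if sid not in set(outliers)}
        agreement, _ = _curve(kept, labels, grid, mode, identity_fn)
        calibrated = _smallest_perfect(grid, agreement)
    return AgreementCurve(
        thresholds=list(grid),
        agreement=agreement,
        rank=rank,
        mode=mode,
        calibrated_threshold=calibrated,
        outliers=outliers,
    )


def _smallest_perfect(grid: Sequence[int], agreement: Sequence[float]) -> int | None:
    for t, a in zip(grid, agreement):
        if a >= 100.0 - 1e-9:
            return t
    return None


def plot_fit(pairs: IdentityPairSet, fits: Sequence[FitResult], path=None):
    """Scatter of marker vs 16S identity with fitted curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pairs.to_dataframe()
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(df.rrna_identity, df.gh48_identity, s=8, alpha=0.4, color="grey")
    xs = np.linspace(df.rrna_identity.min(), df.rrna_identity.max(), 200)
    for fit, color in zip(fits, ("tab:blue", "tab:red", "tab:green")):
        ax.plot(xs, fit.predict(xs), color=color, label=f"{fit.model} (deg {fit.degree})")
    ax.set_xlabel("16S rRNA identity (%)")
    ax.set_ylabel("marker amplicon identity (%)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
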