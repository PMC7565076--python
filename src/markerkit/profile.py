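"""Community profiling of marker-gene amplicon reads.

Merged, demultiplexed reads are end-trimmed, filtered on length and
expected-error rate, dereplicated, clustered into OTUs at the calibrated
94% identity threshold, and classified by best-hit comparison against a
combined reference database of amplicons with known taxonomy:

* best-hit identity ≥ genus threshold (94%) → the genus of the best hit;
* within [family threshold, genus threshold) → "unknown <Family>" of the
  best hit;
* below the family threshold → "unclassified".

Outputs are per-sample OTU tables, relative-abundance tables (percent of
kept reads) and basic alpha-diversity indices.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .align import pairwise_identity
from .cluster import Clustering, greedy_cluster

__all__ = [
    "ReadSet",
    "filter_reads",
    "dereplicate",
    "cluster_reads",
    "assign_taxonomy",
    "abundance_table",
    "alpha_diversity",
    "run_pipeline",
]

GENUS_THRESHOLD = 94.0
FAMILY_THRESHOLD = 80.0


@dataclass
class ReadSet:
    """Merged amplicon reads of one sample (sequence + Phred+33 quality)."""

    ids: list[str]
    seqs: list[str]
    quals: list[list[int]]  # Phred scores per base
    sample: str = ""

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.seqs) == len(self.quals)):
            raise ValueError("ids, seqs and quals must have equal length")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_fastq(cls, path: str | Path, sample: str | None = None) -> "ReadSet":
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        ids, seqs, quals = [], [], []
        with opener(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                ids.append(rec.id)
                seqs.append(str(rec.seq).upper())
                quals.append(list(rec.letter_annotations["phred_quality"]))
        name = sample if sample is not None else path.name.split(".")[0]
        return cls(ids=ids, seqs=seqs, quals=quals, sample=name)


def expected_errors(quals: Sequence[int]) -> float:
    """Sum of per-base error probabilities, EE = Σ 10^(−Q/10)."""
    return float(sum(10.0 ** (-q / 10.0) for q in quals))


def filter_reads(
    rs: ReadSet,
    min_len: int = 320,
    max_len: int = 500,
    max_ee_rate: float = 0.02,
    trim: int = 10,
    min_q_unpaired: int = 20,
) -> tuple[ReadSet, dict[str, int]]:
    """Trim and quality-filter merged reads.

    ``trim`` bases are removed from both ends first; a read is kept when its
    post-trim length lies in ``[min_len, max_len]`` and its expected-error
    *rate* EE/length does not exceed ``max_ee_rate``.  Returns the filtered
    read set and a log of counts per rejection reason.

    ``min_q_unpaired`` belongs to the upstream handling of unpaired reads
    during merging; it is accepted for configuration completeness but plays
    no role for already-merged input.
    """
    del min_q_unpaired
    log = {"input": len(rs), "kept": 0, "length": 0, "ee_rate": 0, "malformed": 0}
    ids, seqs, quals = [], [], []
    for rid, seq, qual in zip(rs.ids, rs.seqs, rs.quals):
        if len(seq) != len(qual):
            log["malformed"] += 1
            continue
        if trim:
            seq = seq[trim : len(seq) - trim] if len(seq) > 2 * trim else ""
            qual = qual[trim : len(qual) - trim] if len(qual) > 2 * trim else []
        if not (min_len <= len(seq) <= max_len):
            log["length"] += 1
            continue
        if expected_errors(qual) / len(seq) > max_ee_rate:
            log["ee_rate"] += 1
            continue
        ids.append(rid)
        seqs.append(seq)
        quals.append(qual)
    log["kept"] = len(ids)
    return ReadSet(ids=ids, seqs=seqs, quals=quals, sample=rs.sample), log


def dereplicate(rs: ReadSet) -> tuple[dict[str, str], dict[str, int]]:
    """Collapse identical sequences.

    Returns ``(uniques, counts)``: unique sequences keyed by the id of their
    first occurrence, and per-unique read counts.
    """
    seen: dict[str, str] = {}  # sequence -> representative id
    counts: dict[str, int] = {}
    for rid, seq in zip(rs.ids, rs.seqs):
        if seq in seen:
            counts[seen[seq]] += 1
        else:
            seen[seq] = rid
            counts[rid] = 1
    uniques = {rid: seq for seq, rid in seen.items()}
    return uniques, counts


def cluster_reads(
    rs: ReadSet,
    threshold: float = GENUS_THRESHOLD,
    identity_fn: Callable[[str, str], float] = pairwise_identity,
) -> Clustering:
    """Dereplicate and greedily cluster one sample's kept reads into OTUs.

    Dereplication counts are carried as cluster weights, so OTU sizes are
    read counts, not unique-sequence counts.
    """
    uniques, counts = dereplicate(rs)
    return greedy_cluster(uniques, threshold, identity_fn=identity_fn, weights=counts)


def assign_taxonomy(
    otu_centroids: Mapping[str, str],
    reference: Mapping[str, tuple[str, str, str]],
    genus_threshold: float = GENUS_THRESHOLD,
    family_threshold: float = FAMILY_THRESHOLD,
    identity_fn: Callable[[str, str], float] = pairwise_identity,
) -> dict[str, str]:
    """Label OTU centroids by best hit against reference amplicons.

    ``reference`` maps reference id → (amplicon sequence, genus, family).
    Ties on identity are broken towards the lexicographically smallest
    reference id.
    """
    if not reference:
        raise ValueError("empty reference database")
    if genus_threshold <= family_threshold:
        raise ValueError("genus_threshold must exceed family_threshold")
    labels: dict[str, str] = {}
    ref_ids = sorted(reference)
    for oid, centroid in otu_centroids.items():
        best_id = None
        best_identity = -1.0
        for rid in ref_ids:
            ident = identity_fn(reference[rid][0], centroid)
            if ident > best_identity:
                best_identity = ident
                best_id = rid
        _, genus, family = reference[best_id]
        if best_identity >= genus_threshold:
            labels[oid] = genus
        elif best_identity >= family_threshold:
            labels[oid] = f"unknown {family}" if family else "unclassified"
        else:
            labels[oid] = "unclassified"
    return labels


def abundance_table(
    clusterings: Mapping[str, Clustering],
    labels: Mapping[str, Mapping[str, str]],
) -> pd.DataFrame:
    """Relative-abundance table (taxon × sample, percent of kept reads).

    ``clusterings`` and ``labels`` are keyed by sample; OTUs sharing a
    label are aggregated.  Samples without kept reads are omitted with a
    warning.  Columns sum to 100.
    """
    import warnings

    columns: dict[str, pd.Series] = {}
    for sample, cl in clusterings.items():
        sizes = cl.sizes()
        total = sum(sizes.values())
        if total == 0:
            warnings.warn(f"sample {sample!r}: no kept reads, column omitted", stacklevel=2)
            continue
        agg: dict[str, float] = {}
        for oid, size in sizes.items():
            taxon = labels[sample][oid]
            agg[taxon] = agg.get(taxon, 0.0) + size
        columns[sample] = pd.Series({t: 100.0 * c / total for t, c in agg.items()})
    table = pd.DataFrame(columns).fillna(0.0)
    return table.sort_index()


def alpha_diversity(clustering: Clustering) -> dict[str, float]:
    """Richness, Shannon H (natural log) and Simpson (1 − Σp²) of one sample."""
    sizes = np.array(list(clustering.sizes().values()), dtype=float)
    if sizes.size == 0 or sizes.sum() == 0:
        raise ValueError("empty OTU size vector")
    p = sizes / sizes.sum()
    p = p[p > 0]
    return {
        "richness": int(sizes.size),
        "shannon": float(-np.sum(p * np.log(p))),
        "simpson": float(1.0 - np.sum(p**2)),
    }


@dataclass
class ProfileResult:
    """All outputs of the amplicon profiling pipeline."""

    otu_table: pd.DataFrame  # OTU × sample read counts
    taxonomy: pd.DataFrame  # OTU → label
    abundance: pd.DataFrame  # taxon × sample, percent
    alpha: pd.DataFrame  # sample × indices
    rejection_log: pd.DataFrame  # sample × rejection reasons

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.otu_table.to_csv(outdir / "otu_table.tsv", sep="\t")
        self.taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
        self.abundance.to_csv(outdir / "abundance.tsv", sep="\t")
        self.alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
        self.rejection_log.to_csv(outdir / "rejection_log.tsv", sep="\t")


def run_pipeline(
    readsets: Iterable[ReadSet],
    reference: Mapping[str, tuple[str, str, str]],
    threshold: float = GENUS_THRESHOLD,
    family_threshold: float = FAMILY_THRESHOLD,
    filter_kwargs: Mapping | None = None,
) -> ProfileResult:
    """Filter, cluster and classify several samples; deterministic for a
    fixed input."""
    filter_kwargs = dict(filter_kwargs or {})
    clusterings: dict[str, Clustering] = {}
    per_sample_labels: dict[str, dict[str, str]] = {}
    logs: dict[str, dict[str, int]] = {}
    otu_rows: list[dict] = []
    tax_rows: list[dict] = []
    alpha_rows: dict[str, dict[str, float]] = {}
    for rs in readsets:
        kept, log = filter_reads(rs, **filter_kwargs)
        logs[rs.sample] = log
        if len(kept) == 0:
            continue
        cl = cluster_reads(kept, threshold=threshold)
        centroids = {cid: kept.seqs[kept.ids.index(cid)] for cid in cl.clusters}
        labels = assign_taxonomy(
            centroids,
            reference,
            genus_threshold=threshold,
            family_threshold=family_threshold,
        )
        clusterings[rs.sample] = cl
        per_sample_labels[rs.sample] = labels
        for cid, size in cl.sizes().items():
            otu_rows.append({"otu": cid, "sample": rs.sample, "reads": size})
            tax_rows.append(
                {"otu": cid, "sample": rs.sample, "label": labels[cid], "centroid": centroids[cid]}
            )
        alpha_rows[rs.sample] = alpha_diversity(cl)
    otu_table = (
        pd.DataFrame(otu_rows)
        .pivot_table(index="otu", columns="sample", values="reads", fill_value=0)
        if otu_rows
        else pd.DataFrame()
    )
    return ProfileResult(
        otu_table=otu_table,
        taxonomy=pd.DataFrame(tax_rows),
        abundance=abundance_table(clusterings, per_sample_labels),
        alpha=pd.DataFrame(alpha_rows).T,
        rejection_log=pd.DataFrame(logs).T,
    )
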