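"""Synthetic fixtures: correlated marker/16S divergence, GenBank genomes
and amplicon read sets.

The generator emulates the statistical structure the calibration relies
on: a fast-evolving marker gene (GH48-like) that accumulates substitutions
``marker_rate_multiplier`` times faster than the 16S rRNA gene, with
genus-banded identity ranges.  Evolution is substitution-only on a star
phylogeny per genus, with every branch mutating a disjoint set of sites —
so pairwise divergences add exactly and identity arithmetic is closed
form: marker identity = 100 − m·(100 − 16S identity) up to optional
Gaussian jitter.

Everything is a pure function of the :class:`SynthConfig` seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .primers import PrimerMix, expand_variants, load_cel48_mix2
from .profile import ReadSet

__all__ = [
    "SynthConfig",
    "PairData",
    "GenbankFixture",
    "make_correlated_pairs",
    "make_genbank",
    "make_reads",
    "write_fastq",
]

GENUS_NAMES = (
    "Hungateiclostridium",
    "Herbinix",
    "Ruminiclostridium",
    "Paenibacillus",
    "Cellulomonas",
    "Caldicellulosiruptor",
    "Streptomyces",
    "Acetivibrio",
)

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for all three generators.

    Identity bands are percent ranges for *pairwise* 16S identities; the
    within-genus lower bound must exceed the between-genus upper bound so
    genera are separable.  ``marker_rate_multiplier`` is the number of
    marker substitutions per 16S substitution (site-fraction scale); the
    default of 6 reproduces the observed regime in which ~97% 16S identity
    corresponds to ~82% marker-amplicon identity and the genus threshold of
    94% marker identity falls at ~99% 16S identity.
    """

    seed: int = 0
    n_taxa: int = 3
    strains_per_taxon: int = 4
    marker_rate_multiplier: float = 6.0
    within_genus_16s_identity: tuple[float, float] = (99.0, 100.0)
    between_genus_16s_identity: tuple[float, float] = (94.0, 97.0)
    read_error_rate: float = 0.01
    reads_per_taxon: int = 500
    marker_len: int = 375
    rrna_len: int = 1500
    jitter_sd: float = 0.0  # marker identity jitter, percent

    def __post_init__(self) -> None:
        for lo, hi in (self.within_genus_16s_identity, self.between_genus_16s_identity):
            if not (0 <= lo < hi <= 100):
                raise ValueError(f"invalid identity band ({lo}, {hi})")
        if self.within_genus_16s_identity[0] <= self.between_genus_16s_identity[1]:
            raise ValueError("within-genus band must lie above the between-genus band")
        if self.marker_rate_multiplier <= 1:
            raise ValueError("marker must diverge faster than 16S (multiplier > 1)")
        if self.n_taxa < 1 or self.strains_per_taxon < 1:
            raise ValueError("need at least one taxon and one strain")

    def genus_names(self) -> list[str]:
        names = []
        for i in range(self.n_taxa):
            base = GENUS_NAMES[i % len(GENUS_NAMES)]
            names.append(base if i < len(GENUS_NAMES) else f"{base}{i // len(GENUS_NAMES) + 1}")
        return names


@dataclass
class SynthTip:
    """One synthetic strain: marker amplicon + 16S gene + labels."""

    tip_id: str
    genus: str
    organism: str
    txid: str
    marker: str
    rrna: str


@dataclass
class PairData:
    """Correlated-divergence fixture for the calibration machinery."""

    tips: list[SynthTip]
    expected_slope: float
    config: SynthConfig

    @property
    def labels(self) -> dict[str, str]:
        return {t.tip_id: t.genus for t in self.tips}

    @property
    def entries(self) -> dict[str, tuple[str, str]]:
        """``{tip_id: (marker_seq, rrna_seq)}``, the pair-set input."""
        return {t.tip_id: (t.marker, t.rrna) for t in self.tips}

    @property
    def markers(self) -> dict[str, str]:
        return {t.tip_id: t.marker for t in self.tips}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "marker.fasta", "w") as fm, open(outdir / "rrna16s.fasta", "w") as fr:
            for t in self.tips:
                fm.write(f">{t.tip_id}\n{t.marker}\n")
                fr.write(f">{t.tip_id}\n{t.rrna}\n")
        pd.DataFrame(
            [{"seq_id": t.tip_id, "genus": t.genus, "species": t.organism} for t in self.tips]
        ).to_csv(outdir / "labels.tsv", sep="\t", index=False)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _substitute(seq: list[str], sites: Sequence[int], rng: np.random.Generator) -> None:
    for site in sites:
        alternatives = [b for b in "ACGT" if b != seq[site]]
        seq[site] = alternatives[rng.integers(0, 3)]


class _SitePool:
    """Hands out disjoint site indices so branch divergences add exactly."""

    def __init__(self, length: int, rng: np.random.Generator):
        self._sites: Iterator[int] = iter(rng.permutation(length).tolist())
        self.length = length

    def take(self, k: int) -> list[int]:
        out = []
        try:
            for _ in range(k):
                out.append(next(self._sites))
        except StopIteration:
            raise ValueError(
                "identity bands require more substitutions than available sites; "
                "reduce taxa/strains or widen the sequences"
            ) from None
        return out


def _snap(k: int, lo: int, hi: int, step_ok) -> int:
    """Nearest value to k in [lo, hi] satisfying ``step_ok`` (exists: checked)."""
    for delta in range(hi - lo + 1):
        for cand in (k - delta, k + delta):
            if lo <= cand <= hi and step_ok(cand):
                return cand
    raise ValueError(f"no admissible substitution count in [{lo}, {hi}]")


def make_correlated_pairs(cfg: SynthConfig) -> PairData:
    """Simulate genus-banded, linearly correlated marker/16S divergence.

    Substitution counts are snapped so that the marker count is exactly
    ``multiplier × (16S site fraction) × marker length`` — with zero jitter
    every pair lies exactly on the line
    ``marker_identity = 100 − m·(100 − rrna_identity)``.
    """
    rng = np.random.default_rng(cfg.seed)
    L16, Lm = cfg.rrna_len, cfg.marker_len
    mult = Fraction(str(cfg.marker_rate_multiplier))
    scale = mult * Lm / L16  # marker substitutions per 16S substitution

    def integral(k: int) -> bool:
        return (scale * k).denominator == 1

    def km_of(k16: int) -> int:
        return int(scale * k16)

    w_lo, _ = cfg.within_genus_16s_identity
    b_lo, b_hi = cfg.between_genus_16s_identity
    kt_max = math.floor(L16 * (100 - w_lo) / 200)
    t_lo = math.ceil(L16 * (100 - b_hi) / 100)
    t_hi = math.floor(L16 * (100 - b_lo) / 100)
    kg_lo = math.ceil(t_lo / 2)
    kg_hi = math.floor((t_hi - 2 * kt_max) / 2)
    if kg_hi < kg_lo:
        raise ValueError(
            "identity bands incompatible: between-genus band too narrow for the "
            "within-genus spread"
        )

    root16 = list(_random_seq(rng, L16))
    rootm = list(_random_seq(rng, Lm))
    pool16 = _SitePool(L16, rng)
    poolm = _SitePool(Lm, rng)

    jitter_subs_sd = cfg.jitter_sd * Lm / 100.0
    tips: list[SynthTip] = []
    for gi, genus in enumerate(cfg.genus_names()):
        kg = _snap(int(rng.integers(kg_lo, kg_hi + 1)), kg_lo, kg_hi, integral)
        g16 = list(root16)
        gm = list(rootm)
        _substitute(g16, pool16.take(kg), rng)
        _substitute(gm, poolm.take(km_of(kg)), rng)
        for si in range(cfg.strains_per_taxon):
            kt = _snap(int(rng.integers(0, kt_max + 1)), 0, kt_max, integral)
            t16 = list(g16)
            tm = list(gm)
            _substitute(t16, pool16.take(kt), rng)
            km = km_of(kt)
            if jitter_subs_sd > 0:
                km = max(0, km + int(round(rng.normal(0.0, jitter_subs_sd))))
            _substitute(tm, poolm.take(km), rng)
            organism = f"{genus} fixturei str. S{si + 1}"
            tips.append(
                SynthTip(
                    tip_id=f"{genus}_s{si + 1}",
                    genus=genus,
                    organism=organism,
                    txid=str(1000 + gi * 100 + si),
                    marker="".join(tm),
                    rrna="".join(t16),
                )
            )
    return PairData(tips=tips, expected_slope=float(mult), config=cfg)


# ---------------------------------------------------------------------------
# GenBank fixture


GH48_PRODUCTS = (
    "glycoside hydrolase family 48 protein",
    "glycosyl hydrolase family 48",
    "cellulose 1,4-beta-cellobiosidase (GH48)",
)
DECOY_PRODUCTS = (
    "glycoside hydrolase family 9 protein",
    "MULTISPECIES: glycoside hydrolase family 48",
    "DNA polymerase III subunit alpha",
)


@dataclass
class GenbankFixture:
    """Synthetic genome records with full ground truth."""

    records: list[SeqRecord]
    truth: pd.DataFrame
    taxonomy: dict[str, dict[str, str]]
    allow_list: list[str]
    assembly_info: dict[str, tuple[str, str]]
    pairs: PairData

    def write(self, outdir: str | Path) -> Path:
        from Bio import SeqIO

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gb = outdir / "genomes.gbff"
        SeqIO.write(self.records, str(gb), "genbank")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        rows = [
            {"txid": txid, "lineage": ";".join(lineage.values())}
            for txid, lineage in self.taxonomy.items()
        ]
        pd.DataFrame(rows).to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
        pd.DataFrame({"protein_accession": self.allow_list}).to_csv(
            outdir / "allow_list.tsv", sep="\t", index=False
        )
        return gb


def _plant_mismatches(
    site: str, primer_positions, n_mismatch: int, rng: np.random.Generator
) -> str:
    """Substitute ``n_mismatch`` singleton positions of a primer site with a
    base outside the position set."""
    from .primers import INOSINE

    site = list(site)
    singles = [
        i
        for i, pos in enumerate(primer_positions)
        if pos is not INOSINE and len(pos) == 1
    ]
    chosen = rng.choice(len(singles), size=n_mismatch, replace=False) if n_mismatch else []
    for idx in np.atleast_1d(np.asarray(chosen, dtype=int)):
        i = singles[idx]
        outside = [b for b in "ACGT" if b not in primer_positions[i]]
        site[i] = outside[rng.integers(0, len(outside))]
    return "".join(site)


def _stopfree_codons(rng: np.random.Generator, n: int) -> str:
    codons = []
    while len(codons) < n:
        c = _random_seq(rng, 3)
        if c not in ("TAA", "TAG", "TGA"):
            codons.append(c)
    return "".join(codons)


def make_genbank(cfg: SynthConfig) -> GenbankFixture:
    """Generate one GenBank genome per strain (plus one duplicate assembly).

    Each genome carries a GH48-like CDS whose amplicon core is the strain's
    marker sequence from :func:`make_correlated_pairs`, flanked by cel48-Mix2
    primer sites with 0-2 planted mismatches; decoy CDS (wrong family,
    multispecies, hypothetical-but-allow-listed) and 0-2 16S rRNA copies
    exercise the database builder's selection rules.  Ground-truth feature
    coordinates, amplicon sequences and planted mismatch counts are returned
    alongside.
    """
    pairs = make_correlated_pairs(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    mix = load_cel48_mix2()
    fwd_variants = [(p, v) for p in mix.forward for v in expand_variants(p)]
    rev_variants = [(p, v) for p in mix.reverse for v in expand_variants(p)]

    records: list[SeqRecord] = []
    truth_rows: list[dict] = []
    taxonomy: dict[str, dict[str, str]] = {}
    allow_list: list[str] = []
    assembly_info: dict[str, tuple[str, str]] = {}
    levels = ("complete", "chromosome", "scaffold", "contig")

    def build_record(
        tip: SynthTip, idx: int, assembly_suffix: str, level: str
    ) -> SeqRecord:
        locus = f"SYN{idx:04d}{assembly_suffix}"
        assembly_id = f"GCF_SYN{idx:04d}{assembly_suffix}"
        # --- GH48 CDS with planted primer sites around the marker core
        fp, fseq = fwd_variants[rng.integers(0, len(fwd_variants))]
        rp, rseq = rev_variants[rng.integers(0, len(rev_variants))]
        fseq = fseq.replace("I", "A")  # inosine matches anything; pick A on template
        rseq = rseq.replace("I", "A")
        n_f = int(idx % 3)  # 0-2 planted mismatches, deterministic cycle
        n_r = int((idx + 1) % 3)
        fsite = _plant_mismatches(fseq, fp.positions, n_f, rng)
        rsite_plus = str(Seq(_plant_mismatches(rseq, rp.positions, n_r, rng)).reverse_complement())
        insert = fsite + tip.marker + rsite_plus
        pad = (3 - (3 + len(insert)) % 3) % 3
        cds = "ATG" + _stopfree_codons(rng, 170) + insert + _random_seq(rng, pad)
        cds += _stopfree_codons(rng, 170) + "TAA"
        protein_id = f"SYP{idx:04d}{assembly_suffix}.1"
        hypothetical = idx % 4 == 3
        product = "hypothetical protein" if hypothetical else GH48_PRODUCTS[idx % 3]
        if hypothetical:
            allow_list.append(protein_id)
        translation = str(Seq(cds).translate()).rstrip("*")

        # --- assemble genome
        strand = -1 if idx % 2 else 1
        joined = idx == 0
        segments: list[str] = [_random_seq(rng, 80)]
        features: list[SeqFeature] = []

        def append_segment(s: str) -> tuple[int, int]:
            start = sum(len(x) for x in segments)
            segments.append(s)
            return start, start + len(s)

        # decoy CDS (never a GH48 hit)
        d_seq = "ATG" + _stopfree_codons(rng, 40) + "TAA"
        ds, de = append_segment(d_seq)
        features.append(
            SeqFeature(
                SimpleLocation(ds, de, strand=1),
                type="CDS",
                qualifiers={
                    "product": [DECOY_PRODUCTS[idx % 3]],
                    "protein_id": [f"SYD{idx:04d}.1"],
                    "translation": [str(Seq(d_seq).translate()).rstrip("*")],
                },
            )
        )
        append_segment(_random_seq(rng, 60))

        # GH48 CDS (possibly complement strand, one joined case)
        placed = cds if strand == 1 else str(Seq(cds).reverse_complement())
        if joined:
            cut = 3 * (len(cds) // 6)
            exon1, exon2 = cds[:cut], cds[cut:]
            s1, e1 = append_segment(exon1)
            append_segment(_random_seq(rng, 50))  # intervening spacer
            s2, e2 = append_segment(exon2)
            location = CompoundLocation(
                [SimpleLocation(s1, e1, strand=1), SimpleLocation(s2, e2, strand=1)]
            )
        else:
            cs, ce = append_segment(placed)
            location = SimpleLocation(cs, ce, strand=strand)
        features.append(
            SeqFeature(
                location,
                type="CDS",
                qualifiers={
                    "product": [product],
                    "protein_id": [protein_id],
                    "translation": [translation],
                },
            )
        )
        append_segment(_random_seq(rng, 60))

        # 16S rRNA copies: most genomes one, every third two, on both strands
        n_16s = 2 if idx % 3 == 0 else 1
        for copy in range(n_16s):
            r_strand = -1 if (idx + copy) % 4 == 2 else 1
            r_seq = tip.rrna
            if copy == 1:  # second copy differs by one base; first must win
                r = list(r_seq)
                r[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[r[5]]
                r_seq = "".join(r)
            placed16 = r_seq if r_strand == 1 else str(Seq(r_seq).reverse_complement())
            rs, re = append_segment(placed16)
            features.append(
                SeqFeature(
                    SimpleLocation(rs, re, strand=r_strand),
                    type="rRNA",
                    qualifiers={"product": ["16S ribosomal RNA"]},
                )
            )
            append_segment(_random_seq(rng, 40))
            truth_rows.append(
                {
                    "locus": locus,
                    "feature": "rRNA",
                    "copy": copy,
                    "start": rs,
                    "end": re,
                    "strand": r_strand,
                    "product": "16S ribosomal RNA",
                    "protein_id": "",
                    "sequence": r_seq,
                    "fwd_mismatches": "",
                    "rev_mismatches": "",
                }
            )

        genome = "".join(segments)
        source = SeqFeature(
            SimpleLocation(0, len(genome), strand=1),
            type="source",
            qualifiers={
                "organism": [tip.organism],
                "db_xref": [f"taxon:{tip.txid}"],
                "note": [f"assembly:{assembly_id}; level:{level}"],
            },
        )
        rec = SeqRecord(
            Seq(genome),
            id=locus,
            name=locus,
            description=f"{tip.organism} synthetic genome",
            features=[source] + features,
            annotations={
                "molecule_type": "DNA",
                "topology": "linear",
                "data_file_division": "BCT",
                "date": "01-JAN-2020",
                "organism": tip.organism,
                "source": tip.organism,
                "taxonomy": ["Bacteria", f"{tip.genus}aceae", tip.genus],
            },
        )
        assembly_info[locus] = (assembly_id, level)
        truth_rows.append(
            {
                "locus": locus,
                "feature": "CDS",
                "copy": 0,
                "start": int(location.start),
                "end": int(location.end),
                "strand": strand if not joined else 1,
                "product": product,
                "protein_id": protein_id,
                "sequence": cds,
                "fwd_mismatches": n_f,
                "rev_mismatches": n_r,
            }
        )
        truth_rows.append(
            {
                "locus": locus,
                "feature": "amplicon",
                "copy": 0,
                "start": "",
                "end": "",
                "strand": 1,
                "product": f"{fp.id}+{rp.id}",
                "protein_id": protein_id,
                "sequence": tip.marker,
                "fwd_mismatches": n_f,
                "rev_mismatches": n_r,
            }
        )
        return rec

    for idx, tip in enumerate(pairs.tips):
        taxonomy[tip.txid] = {
            "domain": "Bacteria",
            "phylum": "Bacillota",
            "class": "Clostridia",
            "order": "Eubacteriales",
            "family": f"{tip.genus}aceae",
            "genus": tip.genus,
            "species": f"{tip.genus} fixturei",
        }
        records.append(build_record(tip, idx, "A", levels[idx % 2 * 3]))
        if idx == 0:  # duplicate assembly of the first strain, worse level
            records.append(build_record(tip, idx, "B", "contig"))

    return GenbankFixture(
        records=records,
        truth=pd.DataFrame(truth_rows),
        taxonomy=taxonomy,
        allow_list=allow_list,
        assembly_info=assembly_info,
        pairs=pairs,
    )


# ---------------------------------------------------------------------------
# Read simulation


def make_reads(
    cfg: SynthConfig,
    reference: Mapping[str, tuple[str, str]],
    proportions: Mapping[str, float] | None = None,
    sample: str = "S1",
    n_reads: int | None = None,
) -> tuple[ReadSet, dict[str, int]]:
    """Simulate merged amplicon reads from reference amplicons.

    ``reference`` maps reference id → (amplicon sequence, taxon); reads are
    drawn from taxa at ``proportions`` (uniform by default), each base
    substituted with probability ``cfg.read_error_rate``, and the quality
    string is constant at the Phred score matching that error rate.
    Returns the read set and the ground-truth per-taxon read counts.
    """
    if not reference:
        raise ValueError("no reference amplicons")
    rng = np.random.default_rng(cfg.seed + 2)
    taxa = sorted({taxon for _, taxon in reference.values()})
    if proportions is None:
        proportions = {t: 1.0 / len(taxa) for t in taxa}
    else:
        missing = set(proportions) - set(taxa)
        if missing:
            raise ValueError(f"proportions name unknown taxa: {sorted(missing)}")
        taxa = sorted(proportions)
    probs = np.array([proportions[t] for t in taxa], dtype=float)
    probs = probs / probs.sum()
    by_taxon: dict[str, list[str]] = {t: [] for t in taxa}
    for rid in sorted(reference):
        seq, taxon = reference[rid]
        if taxon in by_taxon:
            by_taxon[taxon].append(rid)

    total = n_reads if n_reads is not None else cfg.reads_per_taxon * len(taxa)
    p_err = cfg.read_error_rate
    q = 40 if p_err <= 0 else int(np.clip(round(-10.0 * math.log10(p_err)), 2, 40))
    ids, seqs, quals = [], [], []
    counts = {t: 0 for t in taxa}
    for i in range(total):
        taxon = taxa[rng.choice(len(taxa), p=probs)]
        counts[taxon] += 1
        rid = by_taxon[taxon][rng.integers(0, len(by_taxon[taxon]))]
        read = list(reference[rid][0])
        if p_err > 0:
            errors = np.flatnonzero(rng.random(len(read)) < p_err)
            _substitute(read, errors.tolist(), rng)
        ids.append(f"{sample}_r{i:06d}")
        seqs.append("".join(read))
        quals.append([q] * len(read))
    return ReadSet(ids=ids, seqs=seqs, quals=quals, sample=sample), counts


def write_fastq(rs: ReadSet, path: str | Path) -> None:
    """Write a read set as plain FASTQ (Phred+33)."""
    with open(path, "w") as fh:
        for rid, seq, qual in zip(rs.ids, rs.seqs, rs.quals):
            qstr = "".join(chr(q + 33) for q in qual)
            fh.write(f"@{rid}\n{seq}\n+\n{qstr}\n")
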