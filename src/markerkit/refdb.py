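"""Combined GH48/16S reference database built from GenBank flat files.

Each database entry links one GH48-family CDS (nucleotide and protein
sequence, product annotation, accessions) to the 16S rRNA gene of the same
assembly and to the organism's ranked taxonomy.  Species or strains with
several genome assemblies contribute only their best assembly; assemblies
with several GH48 CDS contribute one entry per CDS.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MarkerRecord",
    "CombinedDatabase",
    "parse_genbank",
    "find_gh48_cds",
    "find_16s",
    "read_taxonomy",
    "attach_taxonomy",
    "dedupe_assemblies",
    "find_identical",
    "summarize",
    "build_database",
]

#: Product-name patterns selecting GH48 CDS (case-insensitive substrings;
#: both annotation spellings occur in RefSeq).
DEFAULT_NAME_PATTERNS = (
    "glycosyl hydrolase family 48",
    "glycoside hydrolase family 48",
    "gh48",
)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

ASSEMBLY_LEVEL_ORDER = {"complete": 0, "chromosome": 1, "scaffold": 2, "contig": 3}


@dataclass
class MarkerRecord:
    """One GH48 CDS linked to its organism's 16S gene and taxonomy."""

    record_id: str
    txid: str
    organism: str
    nt_accession: str
    gh48_nt: str
    protein_accession: str
    gh48_aa: str
    product: str
    rrna16s: str | None = None
    lineage: dict[str, str] = field(default_factory=dict)
    assembly_id: str = ""
    assembly_level: str = "contig"
    flags: set[str] = field(default_factory=set)

    @property
    def genus(self) -> str:
        return self.lineage.get("genus") or self.organism.split()[0]

    @property
    def family(self) -> str:
        return self.lineage.get("family", "")

    @property
    def species_key(self) -> str:
        """Normalized organism name used as the species/strain dedupe key."""
        return " ".join(self.organism.split()).lower()


def parse_genbank(path: str | Path) -> list[SeqRecord]:
    """Parse a (possibly multi-record) GenBank flat file.

    Records must carry sequence data (an ORIGIN section); a record without
    one raises with the offending locus named.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ValueError(f"{path}: no GenBank records found")
    for rec in records:
        try:
            defined = len(rec.seq) > 0 and str(rec.seq[:1])
        except Exception:
            defined = False
        if not defined:
            raise ValueError(f"{path}: locus {rec.name}: missing ORIGIN sequence")
        rec.seq = rec.seq.upper()
    return records


def _product(feature: SeqFeature) -> str:
    return feature.qualifiers.get("product", [""])[0]


def find_gh48_cds(
    record: SeqRecord,
    name_patterns: Sequence[str] = DEFAULT_NAME_PATTERNS,
    allow_list: Iterable[str] = (),
) -> list[SeqFeature]:
    """CDS features whose product matches a GH48 name pattern or whose
    protein accession is explicitly allow-listed.

    "Multispecies" annotations are excluded; the allow-list rescues entries
    with uninformative products (e.g. "hypothetical protein").
    """
    allow = set(allow_list)
    patterns = tuple(p.lower() for p in name_patterns)
    hits = []
    for feat in record.features:
        if feat.type != "CDS":
            continue
        product = _product(feat).lower()
        protein_id = feat.qualifiers.get("protein_id", [""])[0]
        if "multispecies" in product:
            continue
        if any(p in product for p in patterns) or protein_id in allow:
            hits.append(feat)
    return hits


def find_16s(record: SeqRecord) -> str | None:
    """First (file order) rRNA feature annotated '16S ribosomal RNA'."""
    for feat in record.features:
        if feat.type != "rRNA":
            continue
        if "16s ribosomal rna" in _product(feat).lower():
            return str(feat.extract(record.seq))
    return None


def read_taxonomy(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a txid → ranked-lineage TSV.

    Expected columns: ``txid`` and ``lineage`` (semicolon-separated, domain
    to genus or species), or one column per rank.
    """
    taxmap: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if "txid" not in header:
            raise ValueError(f"{path}: line 1: taxonomy TSV needs a 'txid' column")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            row = dict(zip(header, fields))
            if "lineage" in row:
                names = [x.strip() for x in row["lineage"].split(";") if x.strip()]
                lineage = dict(zip(RANKS, names))
            else:
                lineage = {r: row[r] for r in RANKS if r in row and row[r]}
            if not lineage:
                raise ValueError(f"{path}: line {lineno}: empty lineage for txid {row['txid']}")
            taxmap[row["txid"]] = lineage
    return taxmap


def attach_taxonomy(
    records: Iterable[MarkerRecord], taxmap: Mapping[str, Mapping[str, str]]
) -> list[MarkerRecord]:
    """Fill ranked lineages from a txid map; unknown txids are flagged
    ``no-lineage`` but kept."""
    out = []
    for rec in records:
        if rec.txid in taxmap:
            rec.lineage = dict(taxmap[rec.txid])
            rec.flags.discard("no-lineage")
        else:
            rec.flags.add("no-lineage")
        out.append(rec)
    return out


def dedupe_assemblies(records: Sequence[MarkerRecord]) -> list[MarkerRecord]:
    """Keep one assembly per species/strain.

    Preference order complete > chromosome > scaffold > contig, ties broken
    by lexicographic assembly id; all GH48 CDS of the chosen assembly stay.
    Idempotent.
    """
    by_key: dict[str, list[MarkerRecord]] = {}
    for rec in records:
        by_key.setdefault(rec.species_key, []).append(rec)
    kept: list[MarkerRecord] = []
    for recs in by_key.values():
        best = min(
            {r.assembly_id for r in recs},
            key=lambda aid: (
                min(
                    ASSEMBLY_LEVEL_ORDER.get(r.assembly_level, 99)
                    for r in recs
                    if r.assembly_id == aid
                ),
                aid,
            ),
        )
        kept.extend(r for r in recs if r.assembly_id == best)
    kept.sort(key=lambda r: r.record_id)
    return kept


def _pair_relation(a: MarkerRecord, b: MarkerRecord) -> str:
    if a.species_key == b.species_key or (
        " ".join(a.organism.split()[:2]) == " ".join(b.organism.split()[:2])
    ):
        return "same-species"
    if a.genus == b.genus:
        return "same-genus"
    return "cross-genus"


def find_identical(
    records: Sequence[MarkerRecord],
    level: str = "module",
    amplicons: Mapping[str, str] | None = None,
) -> list[tuple[str, str, str]]:
    """All unordered pairs of records with byte-identical sequences.

    ``level`` is ``"module"`` (full GH48 CDS nucleotide) or ``"amplicon"``
    (pre-extracted amplicons passed via ``amplicons``).  Each pair is
    annotated same-species / same-genus / cross-genus.
    """
    if level == "module":
        seq_of = {r.record_id: r.gh48_nt for r in records}
    elif level == "amplicon":
        if amplicons is None:
            raise ValueError("level='amplicon' requires pre-extracted amplicons")
        seq_of = {r.record_id: amplicons[r.record_id] for r in records if r.record_id in amplicons}
    else:
        raise ValueError(f"level must be module|amplicon, got {level!r}")
    by_rec = {r.record_id: r for r in records}
    groups: dict[str, list[str]] = {}
    for rid in sorted(seq_of):
        groups.setdefault(seq_of[rid], []).append(rid)
    pairs = []
    for members in groups.values():
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                pairs.append((a, b, _pair_relation(by_rec[a], by_rec[b])))
    return pairs


@dataclass
class CombinedDatabase:
    """The combined GH48 ↔ 16S ↔ taxonomy reference table."""

    records: list[MarkerRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "record_id": r.record_id,
                "txid": r.txid,
                "organism": r.organism,
                "nt_accession": r.nt_accession,
                "gh48_nt": r.gh48_nt,
                "protein_accession": r.protein_accession,
                "gh48_aa": r.gh48_aa,
                "product": r.product,
                "rrna16s": r.rrna16s or "",
                "lineage": ";".join(r.lineage.get(k, "") for k in RANKS),
                "assembly_id": r.assembly_id,
                "assembly_level": r.assembly_level,
                "flags": ",".join(sorted(r.flags)),
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def export(self, prefix: str | Path) -> None:
        """Write the combined table (TSV) plus module/amplicon-ready/16S FASTAs."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(f"{prefix}.tsv", sep="\t", index=False)
        nt = [
            SeqRecord(Seq(r.gh48_nt), id=r.record_id, description=r.organism)
            for r in self.records
        ]
        SeqIO.write(nt, f"{prefix}.gh48_nt.fasta", "fasta")
        aa = [
            SeqRecord(Seq(r.gh48_aa), id=r.record_id, description=r.organism)
            for r in self.records
            if r.gh48_aa
        ]
        SeqIO.write(aa, f"{prefix}.gh48_aa.fasta", "fasta")
        rr = [
            SeqRecord(Seq(r.rrna16s), id=r.record_id, description=r.organism)
            for r in self.records
            if r.rrna16s
        ]
        SeqIO.write(rr, f"{prefix}.16s.fasta", "fasta")

    @classmethod
    def from_table(cls, path: str | Path) -> "CombinedDatabase":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        records = []
        for row in df.itertuples():
            names = row.lineage.split(";")
            lineage = {k: v for k, v in zip(RANKS, names) if v}
            records.append(
                MarkerRecord(
                    record_id=row.record_id,
                    txid=row.txid,
                    organism=row.organism,
                    nt_accession=row.nt_accession,
                    gh48_nt=row.gh48_nt,
                    protein_accession=row.protein_accession,
                    gh48_aa=row.gh48_aa,
                    product=row.product,
                    rrna16s=row.rrna16s or None,
                    lineage=lineage,
                    assembly_id=row.assembly_id,
                    assembly_level=row.assembly_level,
                    flags=set(x for x in row.flags.split(",") if x),
                )
            )
        return cls(records=records, provenance={"source": str(path)})


def translation_consistent(rec: MarkerRecord) -> bool:
    """Standard-table translation of the CDS equals the stored protein
    (terminal stop stripped); skipped (True) for partial CDS."""
    if "partial" in rec.flags or not rec.gh48_aa:
        return True
    if len(rec.gh48_nt) % 3 != 0:
        return False
    aa = str(Seq(rec.gh48_nt).translate())
    return aa.rstrip("*") == rec.gh48_aa.rstrip("*")


def _assembly_meta(record: SeqRecord, assembly_info: Mapping[str, tuple[str, str]] | None):
    if assembly_info and record.name in assembly_info:
        return assembly_info[record.name]
    # fall back to source-feature note tags "assembly:<id>" / "level:<level>"
    for feat in record.features:
        if feat.type == "source":
            meta = {}
            for note in feat.qualifiers.get("note", []):
                for part in note.split(";"):
                    if ":" in part:
                        k, v = part.split(":", 1)
                        meta[k.strip().lower()] = v.strip()
            if "assembly" in meta:
                return meta["assembly"], meta.get("level", "contig")
    return record.name, "contig"


def _taxon_id(record: SeqRecord) -> str:
    for feat in record.features:
        if feat.type == "source":
            for xref in feat.qualifiers.get("db_xref", []):
                if xref.startswith("taxon:"):
                    return xref.split(":", 1)[1]
    return ""


def build_database(
    genbank_paths: Iterable[str | Path],
    taxonomy: str | Path | Mapping[str, Mapping[str, str]] | None = None,
    allow_list: Iterable[str] = (),
    name_patterns: Sequence[str] = DEFAULT_NAME_PATTERNS,
    assembly_info: Mapping[str, tuple[str, str]] | None = None,
    dedupe: bool = True,
) -> CombinedDatabase:
    """Build the combined database from GenBank flat files.

    One entry is emitted per matching CDS; the 16S gene is taken from the
    same record (first 16S in file order).  ``taxonomy`` is a txid-lineage
    TSV path or mapping; ``assembly_info`` optionally maps locus names to
    ``(assembly_id, assembly_level)`` when that metadata is not embedded in
    the files.
    """
    paths = [Path(p) for p in genbank_paths]
    records: list[MarkerRecord] = []
    for path in paths:
        for gb in parse_genbank(path):
            assembly_id, level = _assembly_meta(gb, assembly_info)
            txid = _taxon_id(gb)
            organism = gb.annotations.get("organism", gb.description or gb.name)
            rrna = find_16s(gb)
            for i, feat in enumerate(find_gh48_cds(gb, name_patterns, allow_list)):
                nt = str(feat.extract(gb.seq))
                protein_id = feat.qualifiers.get("protein_id", [f"{gb.name}_p{i}"])[0]
                aa = feat.qualifiers.get("translation", [""])[0]
                product = _product(feat)
                flags: set[str] = set()
                if "hypothetical" in product.lower():
                    flags.add("hypothetical")
                partial = str(feat.location.start).startswith("<") or str(
                    feat.location.end
                ).startswith(">")
                if partial or len(nt) % 3 != 0:
                    flags.add("partial")
                records.append(
                    MarkerRecord(
                        record_id=protein_id,
                        txid=txid,
                        organism=organism,
                        nt_accession=gb.id or gb.name,
                        gh48_nt=nt,
                        protein_accession=protein_id,
                        gh48_aa=aa,
                        product=product,
                        rrna16s=rrna,
                        assembly_id=assembly_id,
                        assembly_level=level,
                        flags=flags,
                    )
                )
    if taxonomy is not None:
        taxmap = taxonomy if isinstance(taxonomy, Mapping) else read_taxonomy(taxonomy)
        attach_taxonomy(records, taxmap)
    else:
        for rec in records:
            rec.flags.add("no-lineage")
    if dedupe:
        records = dedupe_assemblies(records)
    return CombinedDatabase(
        records=records,
        provenance={"sources": [str(p) for p in paths], "build_date": date.today().isoformat()},
    )


def summarize(
    db: CombinedDatabase, amplicons: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Database parameter table: entry/genus/family counts, 16S coverage,
    multi-GH48 species, identical-sequence statistics and length ranges."""

    def _stats(lengths: list[int]) -> tuple:
        if not lengths:
            return (None, None, None)
        return (min(lengths), round(sum(lengths) / len(lengths)), max(lengths))

    recs = db.records
    n = len(recs)
    genera = {r.genus for r in recs if r.genus}
    families = {r.family for r in recs if r.family}
    with_16s = sum(1 for r in recs if r.rrna16s)
    per_species: dict[str, int] = {}
    for r in recs:
        per_species[r.species_key] = per_species.get(r.species_key, 0) + 1
    multi = sum(1 for v in per_species.values() if v > 1)

    mod_pairs = find_identical(recs, level="module")
    mod_entries = len({x for a, b, _ in mod_pairs for x in (a, b)})
    amp_pairs = amp_entries = None
    if amplicons is not None:
        ap = find_identical(recs, level="amplicon", amplicons=amplicons)
        amp_pairs = len(ap)
        amp_entries = len({x for a, b, _ in ap for x in (a, b)})

    rows = {
        "n_entries": n,
        "n_genera": len(genera),
        "n_families": len(families),
        "n_with_16s": with_16s,
        "pct_with_16s": round(100.0 * with_16s / n, 1) if n else None,
        "n_species_multi_gh48": multi,
        "n_identical_module_entries": mod_entries,
        "n_identical_module_pairs": len(mod_pairs),
        "n_identical_amplicon_entries": amp_entries,
        "n_identical_amplicon_pairs": amp_pairs,
    }
    for label, lengths in (
        ("module_nt", [len(r.gh48_nt) for r in recs]),
        ("module_aa", [len(r.gh48_aa) for r in recs if r.gh48_aa]),
        (
            "amplicon_nt",
            [len(s) for s in (amplicons or {}).values()],
        ),
        ("rrna16s_nt", [len(r.rrna16s) for r in recs if r.rrna16s]),
    ):
        mn, mean, mx = _stats(lengths)
        rows[f"{label}_min"] = mn
        rows[f"{label}_mean"] = mean
        rows[f"{label}_max"] = mx
    return pd.DataFrame([rows]).T.rename(columns={0: "value"})
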