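"""Degenerate primer parsing, mixing rules and in-silico PCR.

The cel48-Mix2 system amplifies a ~344 bp conserved stretch of bacterial GH48
(glycoside hydrolase family 48) cellulase genes with a cocktail of 16 forward
and 9 reverse partially degenerate primers.  A primer position is either a
single natural base, a set of 2-4 alternative bases (written inline as an
IUPAC code or as a bracket group like ``[AG]``), or the universal base
deoxy-inosine ``[I]`` which pairs with any template base.

Mixing follows the published rule: each primer's volume in the mix is
``V = 2**N`` microlitres, where ``N`` counts positions with more than one
natural base.  Inosine deliberately does not count towards ``N``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Primer",
    "PrimerMix",
    "AmpliconHit",
    "PrimerParseError",
    "parse_primer",
    "degeneracy_count",
    "mix_volume",
    "expand_variants",
    "match_site",
    "in_silico_pcr",
    "extract_amplicon_by_reference",
    "load_cel48_mix2",
    "read_primer_tsv",
]

#: IUPAC nucleotide degeneracy codes (natural-base sets only).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Sentinel position for deoxy-inosine: matches any base at zero penalty,
#: contributes nothing to the degeneracy count, and is kept as a literal
#: ``I`` when variants are expanded.
INOSINE: frozenset[str] = frozenset("I")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class PrimerParseError(ValueError):
    """Raised for malformed primer notation."""


@dataclass(frozen=True)
class Primer:
    """A (possibly degenerate) oligonucleotide.

    ``positions`` holds one base set per position, 5'→3'.  Inosine positions
    are the :data:`INOSINE` sentinel.
    """

    id: str
    positions: tuple[frozenset[str], ...]
    orientation: str = "forward"
    text: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward|reverse, got {self.orientation!r}")
        if len(self.positions) < 10:
            raise ValueError(f"primer {self.id!r}: length {len(self.positions)} < 10")
        for pos in self.positions:
            if not pos:
                raise ValueError(f"primer {self.id!r}: empty position set")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def length(self) -> int:
        return len(self.positions)

    def matches(self, base: str, position: int) -> bool:
        pos = self.positions[position]
        return pos is INOSINE or "I" in pos or base in pos


@dataclass(frozen=True)
class AmpliconHit:
    """One productive forward/reverse primer site pair on a template.

    Intervals are 0-based half-open in the frame of the reported strand
    (i.e. on the reverse complement of the template for ``strand == '-'``),
    so ``fwd_site`` always lies upstream of ``rev_site``.
    """

    template_id: str
    fwd_site: tuple[int, int]
    rev_site: tuple[int, int]
    strand: str
    amplicon_seq: str
    mismatches: tuple[int, int]
    fwd_primer: str = ""
    rev_primer: str = ""

    @property
    def inner_length(self) -> int:
        return self.rev_site[0] - self.fwd_site[1]


def parse_primer(text: str, id: str = "", orientation: str = "forward") -> Primer:
    """Parse primer notation with bracket groups and inline IUPAC codes.

    ``[XY]`` is a degenerate position allowing the listed natural bases;
    ``[I]`` (or an inline ``I``) is inosine; ``[AG]`` is equivalent to
    inline ``R``.
    """
    positions: list[frozenset[str]] = []
    i = 0
    raw = text.strip().upper()
    while i < len(raw):
        ch = raw[i]
        if ch == "[":
            j = raw.find("]", i)
            if j < 0:
                raise PrimerParseError(f"{id or raw}: unbalanced bracket at position {i}")
            members = raw[i + 1 : j]
            if not members:
                raise PrimerParseError(f"{id or raw}: empty bracket group at position {i}")
            if members == "I":
                positions.append(INOSINE)
            else:
                bases: set[str] = set()
                for m in members:
                    if m not in "ACGT":
                        raise PrimerParseError(
                            f"{id or raw}: bracket member {m!r} is not a natural base or I"
                        )
                    bases.add(m)
                positions.append(frozenset(bases))
            i = j + 1
        elif ch == "]":
            raise PrimerParseError(f"{id or raw}: unbalanced bracket at position {i}")
        elif ch == "I":
            positions.append(INOSINE)
            i += 1
        elif ch in IUPAC_SETS:
            positions.append(IUPAC_SETS[ch])
            i += 1
        else:
            raise PrimerParseError(f"{id or raw}: illegal character {ch!r} at position {i}")
    return Primer(id=id or raw, positions=tuple(positions), orientation=orientation, text=raw)


def degeneracy_count(p: Primer) -> int:
    """Number of degenerate positions N: natural-base sets of size >= 2.

    Inosine positions contribute 0 — the universal base was introduced
    precisely to avoid 3- and 4-fold degeneracies, and the published mixing
    rule does not count it.  Positions with 3-4 alternatives still count as
    one degeneration each (the rule is positional, not combinatorial).
    """
    return sum(1 for pos in p.positions if pos is not INOSINE and len(pos) >= 2)


def mix_volume(p: Primer) -> int:
    """Volume V = 2**N (µL) of this primer in the mix."""
    return 2 ** degeneracy_count(p)


def expand_variants(p: Primer, cap: int = 4096) -> list[str]:
    """All concrete oligos of a degenerate primer, lexicographically sorted.

    Inosine is kept as a literal ``I``.  Refuses to expand when the product
    of position-set sizes exceeds ``cap``.
    """
    n_variants = 1
    choice_sets: list[Sequence[str]] = []
    for pos in p.positions:
        if pos is INOSINE:
            choice_sets.append(("I",))
        else:
            choice_sets.append(tuple(sorted(pos)))
            n_variants *= len(pos)
    if n_variants > cap:
        raise ValueError(f"primer {p.id!r}: {n_variants} variants exceed cap {cap}")
    return sorted("".join(combo) for combo in itertools.product(*choice_sets))


def reverse_complement_positions(
    positions: Sequence[frozenset[str]],
) -> tuple[frozenset[str], ...]:
    out: list[frozenset[str]] = []
    for pos in reversed(positions):
        if pos is INOSINE:
            out.append(INOSINE)
        else:
            out.append(frozenset(_COMPLEMENT[b] for b in pos))
    return tuple(out)


def _count_window_mismatches(
    positions: Sequence[frozenset[str]],
    window: str,
    limit: int,
    ambiguity_intersection: bool = False,
) -> int:
    """Mismatches of a template window against a position-set pattern.

    Returns ``limit + 1`` as soon as the limit is exceeded (early exit).
    """
    mism = 0
    for pos, base in zip(positions, window):
        if pos is INOSINE:
            continue
        if base in pos:
            continue
        if ambiguity_intersection and base in IUPAC_SETS:
            if IUPAC_SETS[base] & pos:
                continue
        mism += 1
        if mism > limit:
            return mism
    return mism


def match_site(
    p: Primer,
    template: str,
    max_mismatch: int = 0,
    ambiguity_intersection: bool = False,
) -> list[tuple[int, str, int]]:
    """Find annealing sites of a primer on both strands of a template.

    A window matches when every template base lies in the primer's position
    set (inosine = any base), with at most ``max_mismatch`` violations.
    Returns ``(offset, strand, mismatches)`` tuples; offsets are 0-based on
    the + strand of the template for both orientations.  Template ambiguity
    codes count as mismatches unless ``ambiguity_intersection`` enables
    set-intersection matching.
    """
    template = template.upper()
    k = len(p)
    hits: list[tuple[int, str, int]] = []
    if len(template) < k:
        return hits
    patterns = (("+", p.positions), ("-", reverse_complement_positions(p.positions)))
    for strand, positions in patterns:
        for off in range(len(template) - k + 1):
            mism = _count_window_mismatches(
                positions, template[off : off + k], max_mismatch, ambiguity_intersection
            )
            if mism <= max_mismatch:
                hits.append((off, strand, mism))
    return hits


@dataclass
class PrimerMix:
    """A degenerate primer cocktail with its 2**N mixing recipe."""

    primers: list[Primer]
    name: str = "mix"

    def __post_init__(self) -> None:
        fwd = {p.id for p in self.forward}
        rev = {p.id for p in self.reverse}
        if fwd & rev:
            raise ValueError(f"forward/reverse sub-mixes share ids: {sorted(fwd & rev)}")

    @property
    def forward(self) -> list[Primer]:
        return [p for p in self.primers if p.orientation == "forward"]

    @property
    def reverse(self) -> list[Primer]:
        return [p for p in self.primers if p.orientation == "reverse"]

    @property
    def volumes(self) -> dict[str, int]:
        return {p.id: mix_volume(p) for p in self.primers}

    @property
    def degeneracy_counts(self) -> dict[str, int]:
        return {p.id: degeneracy_count(p) for p in self.primers}

    def recipe(self) -> pd.DataFrame:
        """Mixing recipe table: id, sequence, length, V_µL, N."""
        rows = [
            {
                "id": p.id,
                "sequence": p.text,
                "orientation": p.orientation,
                "length": p.length,
                "V_uL": mix_volume(p),
                "N": degeneracy_count(p),
            }
            for p in self.primers
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.recipe().to_csv(path, sep="\t", index=False)


def read_primer_tsv(path: str | Path, name: str | None = None) -> PrimerMix:
    """Read a primer mix from a TSV with columns id, sequence, orientation."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "sequence", "orientation"}
    if not required.issubset(df.columns):
        raise ValueError(f"primer TSV needs columns {sorted(required)}, got {list(df.columns)}")
    primers = [
        parse_primer(row.sequence, id=row.id, orientation=row.orientation)
        for row in df.itertuples()
    ]
    return PrimerMix(primers, name=name or Path(path).stem)


def load_cel48_mix2() -> PrimerMix:
    """The published cel48-Mix2 cocktail (16 forward + 9 reverse primers)."""
    with resources.as_file(resources.files("markerkit.data") / "cel48_mix2.tsv") as path:
        return read_primer_tsv(path, name="cel48-Mix2")


def in_silico_pcr(
    mix: PrimerMix,
    template: str | SeqRecord,
    max_mismatch: int = 2,
    min_len: int = 291,
    max_len: int = 379,
    include_primers: bool = False,
    template_id: str | None = None,
) -> list[AmpliconHit]:
    """Enumerate all productive amplicons of a primer mix on one template.

    A product is a forward site followed by a reverse site on the same
    strand with an inner (primer-free) length within ``[min_len, max_len]``.
    The default length bounds are the observed GH48 amplicon range.  Both
    strands are scanned; all site pairs in range are reported, sorted by
    template id then forward offset.
    """
    if min_len >= max_len:
        raise ValueError(f"min_len {min_len} must be < max_len {max_len}")
    if isinstance(template, SeqRecord):
        template_id = template_id or template.id
        seq = str(template.seq).upper()
    else:
        template_id = template_id or "template"
        seq = template.upper()

    hits: list[AmpliconHit] = []
    for strand, frame in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        fwd_sites: list[tuple[int, int, int, str]] = []
        rev_sites: list[tuple[int, int, int, str]] = []
        for p in mix.forward:
            k = len(p)
            for off in range(len(frame) - k + 1):
                m = _count_window_mismatches(p.positions, frame[off : off + k], max_mismatch)
                if m <= max_mismatch:
                    fwd_sites.append((off, off + k, m, p.id))
        for p in mix.reverse:
            rc = reverse_complement_positions(p.positions)
            k = len(p)
            for off in range(len(frame) - k + 1):
                m = _count_window_mismatches(rc, frame[off : off + k], max_mismatch)
                if m <= max_mismatch:
                    rev_sites.append((off, off + k, m, p.id))
        for fs, fe, fm, fid in fwd_sites:
            for rs, re, rm, rid in rev_sites:
                inner = rs - fe
                if min_len <= inner <= max_len:
                    amp = frame[fs:re] if include_primers else frame[fe:rs]
                    hits.append(
                        AmpliconHit(
                            template_id=template_id,
                            fwd_site=(fs, fe),
                            rev_site=(rs, re),
                            strand=strand,
                            amplicon_seq=amp,
                            mismatches=(fm, rm),
                            fwd_primer=fid,
                            rev_primer=rid,
                        )
                    )
    hits.sort(key=lambda h: (h.template_id, h.strand, h.fwd_site[0], h.rev_site[0]))
    return hits


def ispcr_fasta(
    mix: PrimerMix,
    templates: Iterable[SeqRecord],
    **kwargs,
) -> Iterator[tuple[AmpliconHit, SeqRecord]]:
    """Run :func:`in_silico_pcr` over FASTA records, yielding amplicon records
    with ``templateID|start-end|strand`` headers."""
    for rec in templates:
        for hit in in_silico_pcr(mix, rec, **kwargs):
            header = f"{hit.template_id}|{hit.fwd_site[1]}-{hit.rev_site[0]}|{hit.strand}"
            yield hit, SeqRecord(Seq(hit.amplicon_seq), id=header, description="")


def extract_amplicon_by_reference(
    ref_amplicon: str,
    full_gene: str,
    min_identity: float = 60.0,
) -> str | None:
    """Recover the amplicon region of a gene by local alignment to a
    reference amplicon; fallback for templates where primer matching fails.

    Returns the spanned gene region when the alignment identity (matches over
    aligned columns) reaches ``min_identity`` percent, else ``None``.
    """
    from Bio import Align

    if not ref_amplicon:
        raise ValueError("reference amplicon is empty")
    if not full_gene:
        return None
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=2,
        mismatch_score=-2,
        open_gap_score=-5,
        extend_gap_score=-2,
    )
    alignments = aligner.align(full_gene.upper(), ref_amplicon.upper())
    try:
        aln = alignments[0]
    except IndexError:
        return None
    matches = 0
    columns = 0
    a, b = aln[0], aln[1]
    for ca, cb in zip(a, b):
        columns += 1
        if ca == cb and ca != "-":
            matches += 1
    if columns == 0 or 100.0 * matches / columns < min_identity:
        return None
    start, end = aln.coordinates[0][0], aln.coordinates[0][-1]
    return full_gene[start:end]
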