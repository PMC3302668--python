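"""Read preprocessing, mismatch classification, grouping and annotation.

PAR-CLIP libraries carry the crosslink signature as T=>C transitions in
transcript orientation.  This module converts aligned short reads into the
unit the site caller operates on: strand-aware *read groups* (connected
components of reads overlapping by at least one nucleotide), with every
mismatch classified as either a conversion event or an ordinary mismatch,
and with each group assigned a genomic category by a fixed priority order
(3' UTR > CDS > 5' UTR > miRNA > intron > intergenic).

Coordinates are 0-based half-open throughout, matching BED.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: category priority used when an interval overlaps several annotations
ANNOTATION_PRIORITY = ("3'UTR", "CDS", "5'UTR", "miRNA", "intron")
INTERGENIC = "intergenic"

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# reference access
# ---------------------------------------------------------------------------

def fetch_reference(reference, chrom: str, start: int, end: int) -> str:
    """Fetch an uppercase plus-strand slice from any common FASTA accessor.

    Accepts a plain mapping of contig name to sequence, a pyfaidx.Fasta,
    or a pysam.FastaFile.
    """
    if hasattr(reference, "fetch"):  # pysam.FastaFile
        return reference.fetch(chrom, start, end).upper()
    seq = reference[chrom]
    if isinstance(seq, str):
        return seq[start:end].upper()
    # pyfaidx.FastaRecord supports slicing and returns a Sequence object
    return str(seq[start:end]).upper()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AlignedRead:
    """One ungapped genome alignment of a read.

    ``mismatches`` holds ``(ref_offset, ref_base, read_base)`` triples in
    plus-strand reference orientation, regardless of the alignment strand.
    """

    read_id: str
    chrom: str
    strand: str
    start: int
    end: int
    sequence: str  # read orientation (as sequenced)
    mismatches: tuple[tuple[int, str, str], ...] = ()
    n_candidate_locations: int = 1

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"{self.read_id}: span {self.end - self.start} != "
                f"sequence length {len(self.sequence)} (ungapped alignments only)"
            )
        for off, _, _ in self.mismatches:
            if not self.start <= off < self.end:
                raise ValueError(f"{self.read_id}: mismatch offset {off} outside alignment")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MismatchClassification:
    """T=>C conversion vs other-mismatch counts for one alignment."""

    n_conversion: int
    n_other: int
    conversion_offsets: tuple[int, ...]  # plus-strand reference coordinates


@dataclass
class ReadGroup:
    """Connected component of >=1-nt-overlapping reads on one strand."""

    chrom: str
    strand: str
    start: int
    end: int
    reads: list[AlignedRead]
    annotation: str = INTERGENIC
    in_repeat: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_reads(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# adapter stripping / read-level filters
# ---------------------------------------------------------------------------

def strip_adapter(read: str, adapter: str, min_prefix: int = 7) -> str:
    """Remove a 3' adapter from a read.

    The read is truncated at the leftmost occurrence of the longest adapter
    prefix found in it; prefixes shorter than ``min_prefix`` are only honored
    when they are the full adapter.  Reads with no adapter hit are returned
    unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    shortest = min(min_prefix, len(adapter))
    for k in range(len(adapter), shortest - 1, -1):
        idx = read.find(adapter[:k])
        if idx >= 0:
            return read[:idx]
    return read


def preprocess_reads(
    raw_reads: Iterable[str],
    adapter: str,
    min_len: int = 13,
    min_prefix: int = 7,
) -> tuple[list[str], dict[str, int]]:
    """Adapter-strip and length/ambiguity-filter raw read strings.

    Returns the retained inserts plus a counter of discard reasons
    (``too_short``, ``ambiguous``, ``invalid``).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept: list[str] = []
    stats = {"input": 0, "kept": 0, "too_short": 0, "ambiguous": 0, "invalid": 0}
    for read in raw_reads:
        stats["input"] += 1
        read = read.upper()
        if not set(read) <= VALID_BASES:
            stats["invalid"] += 1
            logger.warning("read rejected, non-ACGTN characters: %r", read)
            continue
        insert = strip_adapter(read, adapter.upper(), min_prefix=min_prefix)
        if len(insert) < min_len:
            stats["too_short"] += 1
            continue
        if "N" in insert:
            stats["ambiguous"] += 1
            continue
        kept.append(insert)
        stats["kept"] += 1
    return kept, stats


# ---------------------------------------------------------------------------
# mismatch classification
# ---------------------------------------------------------------------------

def classify_mismatches(read: AlignedRead, reference) -> MismatchClassification:
    """Split a read's mismatches into T=>C conversions and everything else.

    A mismatch is a conversion iff, in transcript orientation, the reference
    base is T and the read base is C.  For '-'-strand alignments this appears
    on the plus-strand reference as A=>G.
    """
    ref_seq = fetch_reference(reference, read.chrom, read.start, read.end)
    if read.strand == "+":
        conv_ref, conv_read = "T", "C"
    else:
        conv_ref, conv_read = "A", "G"
    conv_offsets: list[int] = []
    n_other = 0
    for off, ref_base, read_base in read.mismatches:
        actual = ref_seq[off - read.start]
        if actual != ref_base.upper():
            raise ValueError(
                f"{read.read_id}: mismatch at {read.chrom}:{off} states reference "
                f"{ref_base!r} but reference sequence has {actual!r}"
            )
        if ref_base.upper() == conv_ref and read_base.upper() == conv_read:
            conv_offsets.append(off)
        else:
            n_other += 1
    return MismatchClassification(
        n_conversion=len(conv_offsets),
        n_other=n_other,
        conversion_offsets=tuple(sorted(conv_offsets)),
    )


def select_unique(
    alignments: Sequence[tuple[AlignedRead, MismatchClassification]],
    max_locations: int = 10,
) -> AlignedRead | None:
    """Pick the single usable alignment for one read, or nothing.

    A read is retained iff exactly one reported location has zero
    non-conversion mismatches; reads with more reported candidate locations
    than ``max_locations`` are dropped outright.
    """
    if not alignments:
        return None
    ids = {r.read_id for r, _ in alignments}
    if len(ids) != 1:
        raise ValueError(f"alignments from multiple reads passed: {sorted(ids)}")
    if any(r.n_candidate_locations > max_locations for r, _ in alignments):
        return None
    clean = [r for r, c in alignments if c.n_other == 0]
    if len(clean) == 1:
        return clean[0]
    return None


# ---------------------------------------------------------------------------
# read grouping
# ---------------------------------------------------------------------------

def build_read_groups(reads: Iterable[AlignedRead]) -> list[ReadGroup]:
    """Group reads into connected components of the >=1-nt-overlap relation.

    Components are computed per (chrom, strand); because overlap of sorted
    intervals is transitive through a running maximum end, a single sweep
    suffices.  Abutting half-open intervals ([0,20) and [20,40)) do not
    overlap and land in separate groups.
    """
    by_key: dict[tuple[str, str], list[AlignedRead]] = defaultdict(list)
    for read in reads:
        by_key[(read.chrom, read.strand)].append(read)

    groups: list[ReadGroup] = []
    for (chrom, strand), members in sorted(by_key.items()):
        members.sort(key=lambda r: (r.start, r.end, r.read_id))
        current: list[AlignedRead] = []
        cur_end = -1
        for read in members:
            if current and read.start < cur_end:
                current.append(read)
                cur_end = max(cur_end, read.end)
            else:
                if current:
                    groups.append(_finish_group(chrom, strand, current))
                current = [read]
                cur_end = read.end
        if current:
            groups.append(_finish_group(chrom, strand, current))
    return groups


def _finish_group(chrom: str, strand: str, reads: list[AlignedRead]) -> ReadGroup:
    return ReadGroup(
        chrom=chrom,
        strand=strand,
        start=min(r.start for r in reads),
        end=max(r.end for r in reads),
        reads=list(reads),
    )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

# feature-name spellings accepted from GTF/GFF and BED inputs
_CATEGORY_ALIASES = {
    "three_prime_utr": "3'UTR",
    "3utr": "3'UTR",
    "3'utr": "3'UTR",
    "utr3": "3'UTR",
    "cds": "CDS",
    "coding": "CDS",
    "five_prime_utr": "5'UTR",
    "5utr": "5'UTR",
    "5'utr": "5'UTR",
    "utr5": "5'UTR",
    "mirna": "miRNA",
    "intron": "intron",
}


def normalize_category(label: str) -> str | None:
    return _CATEGORY_ALIASES.get(label.strip().lower())


@dataclass
class AnnotationModel:
    """Stranded interval collections per genomic category plus repeats."""

    trees: dict[tuple[str, str, str], IntervalTree] = field(default_factory=dict)
    repeat_trees: dict[tuple[str, str], IntervalTree] = field(default_factory=dict)
    _warned_chroms: set = field(default_factory=set, repr=False)

    def add(self, category: str, chrom: str, strand: str, start: int, end: int) -> None:
        if category not in ANNOTATION_PRIORITY:
            raise ValueError(f"unknown category {category!r}")
        if end <= start:
            return
        key = (category, chrom, strand)
        self.trees.setdefault(key, IntervalTree()).addi(start, end)

    def add_repeat(self, chrom: str, strand: str, start: int, end: int, family: str = "") -> None:
        if end <= start:
            return
        self.repeat_trees.setdefault((chrom, strand), IntervalTree()).addi(start, end, family)

    def known_chroms(self) -> set[str]:
        return {chrom for (_, chrom, _) in self.trees}

    def annotate(self, chrom: str, strand: str, start: int, end: int) -> tuple[str, bool]:
        """Highest-priority category overlapping the query, plus repeat flag."""
        if chrom not in self.known_chroms():
            if chrom not in self._warned_chroms:
                logger.warning("chromosome %r absent from annotation; calling intergenic", chrom)
                self._warned_chroms.add(chrom)
            return INTERGENIC, self._in_repeat(chrom, strand, start, end)
        category = INTERGENIC
        for cat in ANNOTATION_PRIORITY:
            tree = self.trees.get((cat, chrom, strand))
            if tree is not None and tree.overlap(start, end):
                category = cat
                break
        return category, self._in_repeat(chrom, strand, start, end)

    def _in_repeat(self, chrom: str, strand: str, start: int, end: int) -> bool:
        # repeat intervals are treated as strand-agnostic: check both strands
        for key in ((chrom, strand), (chrom, "+" if strand == "-" else "-")):
            tree = self.repeat_trees.get(key)
            if tree is not None and tree.overlap(start, end):
                return True
        return False


def annotate_interval(
    chrom: str, strand: str, start: int, end: int, model: AnnotationModel
) -> tuple[str, bool]:
    """Functional wrapper around :meth:`AnnotationModel.annotate`."""
    return model.annotate(chrom, strand, start, end)


def load_annotation_bed(path: str) -> AnnotationModel:
    """Load a 6-column category BED (name column = category label)."""
    model = AnnotationModel()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if len(fields) > 5 else "+"
            category = normalize_category(name)
            if category is None:
                logger.warning("skipping BED record with unknown category %r", name)
                continue
            model.add(category, chrom, strand, start, end)
    return model


def load_annotation_gtf(path: str, model: AnnotationModel | None = None) -> AnnotationModel:
    """Load category intervals from a GTF/GFF file's feature column."""
    model = model or AnnotationModel()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                continue
            chrom, _, feature, start, end, _, strand = fields[:7]
            category = normalize_category(feature)
            if category is None:
                continue
            model.add(category, chrom, strand, int(start) - 1, int(end))  # GTF is 1-based closed
    return model


def load_repeats_bed(path: str, model: AnnotationModel) -> AnnotationModel:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            family = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "+"
            model.add_repeat(chrom, strand, start, end, family)
    return model


# ---------------------------------------------------------------------------
# SAM ingestion
# ---------------------------------------------------------------------------

def iter_sam_alignments(path: str, reference=None) -> Iterator[AlignedRead]:
    """Yield :class:`AlignedRead` for every ungapped alignment in a SAM/BAM.

    Mismatches are derived from the MD tag when present, otherwise from the
    reference accessor.  Alignments with indels or clipping are skipped (the
    mapping mode this pipeline consumes is mismatch-only).
    """
    import pysam

    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            cigar = aln.cigartuples or []
            if any(op != 0 for op, _ in cigar):  # anything but pure M
                continue
            start, end = aln.reference_start, aln.reference_end
            seq_plus = aln.query_sequence.upper()
            strand = "-" if aln.is_reverse else "+"
            mismatches = _alignment_mismatches(aln, seq_plus, reference)
            if mismatches is None:
                continue
            n_loc = aln.get_tag("NH") if aln.has_tag("NH") else 1
            # SAM stores SEQ on the plus strand; restore read orientation
            read_seq = seq_plus if strand == "+" else reverse_complement(seq_plus)
            yield AlignedRead(
                read_id=aln.query_name,
                chrom=aln.reference_name,
                strand=strand,
                start=start,
                end=end,
                sequence=read_seq,
                mismatches=tuple(mismatches),
                n_candidate_locations=int(n_loc),
            )


def _alignment_mismatches(aln, seq_plus: str, reference):
    start = aln.reference_start
    if aln.has_tag("MD"):
        ref_seq = _reference_from_md(aln.get_tag("MD"), seq_plus)
    elif reference is not None:
        ref_seq = fetch_reference(reference, aln.reference_name, start, aln.reference_end)
    else:
        logger.warning("alignment %s lacks MD tag and no reference given; skipped", aln.query_name)
        return None
    out = []
    for i, (ref_base, read_base) in enumerate(zip(ref_seq, seq_plus)):
        if ref_base != read_base:
            out.append((start + i, ref_base, read_base))
    return out


def _reference_from_md(md: str, seq: str) -> str:
    """Reconstruct the plus-strand reference for an ungapped alignment from MD."""
    ref = []
    i = 0  # position in seq
    num = ""
    for ch in md:
        if ch.isdigit():
            num += ch
            continue
        if num:
            n = int(num)
            ref.append(seq[i : i + n])
            i += n
            num = ""
        if ch == "^":
            raise ValueError("deletion in MD tag of supposedly ungapped alignment")
        ref.append(ch.upper())
        i += 1
    if num:
        ref.append(seq[i : i + int(num)])
    return "".join(ref)


def ingest_alignments(
    alignments: Iterable[AlignedRead],
    reference,
    max_locations: int = 10,
    annotation: AnnotationModel | None = None,
) -> tuple[list[ReadGroup], dict[str, int]]:
    """Full ingest pipeline from classified alignments to annotated groups.

    Alignments are grouped per read id, uniquely-mapping conversion-only
    reads are retained, grouped into read groups, and annotated.
    """
    by_read: dict[str, list[tuple[AlignedRead, MismatchClassification]]] = defaultdict(list)
    for aln in alignments:
        by_read[aln.read_id].append((aln, classify_mismatches(aln, reference)))

    stats = {"reads": len(by_read), "retained": 0, "dropped": 0}
    retained: list[AlignedRead] = []
    for read_id, alns in by_read.items():
        chosen = select_unique(alns, max_locations=max_locations)
        if chosen is None:
            stats["dropped"] += 1
        else:
            retained.append(chosen)
            stats["retained"] += 1

    groups = build_read_groups(retained)
    if annotation is not None:
        for g in groups:
            g.annotation, g.in_repeat = annotation.annotate(g.chrom, g.strand, g.start, g.end)
    stats["groups"] = len(groups)
    return groups, stats
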