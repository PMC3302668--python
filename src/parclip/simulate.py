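"""Seeded synthetic PAR-CLIP libraries for offline pipeline testing.

The generator emulates the statistical structure the caller and the
enrichment models assume: transcripts with labeled 5' UTR / CDS / 3' UTR
segments, planted crosslink sites whose adjacent thymines convert with a
high per-read probability against a low background conversion rate, read
lengths and depths typical of PAR-CLIP libraries, and an Argonaute mode in
which conversions are forbidden inside a planted miRNA seed match and
concentrated one nucleotide upstream of it.  All randomness flows from a
single integer-seeded generator, so fixed seeds give byte-identical
output.

Sequencing base-call errors, PCR duplicates and multimapping reads are
outside the analytical model and are not simulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ingest import AlignedRead, AnnotationModel, ReadGroup, reverse_complement
from .motifmatch import IUPAC, seed_sites, to_dna
from .discover import EvidenceRegion, make_regions
from .sitecaller import InteractionSite, build_profile, call_sites

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))

CCR_WIDTH = 41


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for a synthetic library.

    Probabilities are per read at the relevant reference T.  The crosslink
    conversion probability must exceed the background probability, else the
    library carries no usable crosslink signal.
    """

    seed: int = 0
    n_transcripts: int = 50
    utr5_length: tuple[int, int] = (50, 120)
    cds_length: tuple[int, int] = (200, 400)
    utr3_length: tuple[int, int] = (150, 300)
    n_planted_sites: int = 30
    motif: str | None = None  # IUPAC motif planted at each site, e.g. UGUANAUA
    mirnas: tuple[tuple[str, str], ...] = ()  # (id, sequence); AGO mode when non-empty
    crosslink_conversion_prob: float = 0.5
    adjacent_conversion_prob: float = 0.25  # Ts within the crosslink window
    crosslink_window: int = 2  # nt either side of the crosslink
    background_conversion_prob: float = 0.001
    read_length: tuple[int, int] = (20, 35)
    depth: int = 20  # reads per planted site
    n_background_reads: int = 200
    seed_protection: bool = False  # forced on in AGO mode
    rnase_g_bias: bool = False
    au_enrichment: float = 0.0  # extra A/T weight in site flanks, in [0, 1)
    minus_strand_fraction: float = 0.3
    min_site_separation: int = 80

    def __post_init__(self) -> None:
        for p in (self.crosslink_conversion_prob, self.background_conversion_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.crosslink_conversion_prob <= self.background_conversion_prob:
            raise ValueError("crosslink conversion prob must exceed background")
        if self.adjacent_conversion_prob < self.background_conversion_prob:
            raise ValueError("adjacent conversion prob must be at least background")
        if self.read_length[0] < 13:
            raise ValueError("reads shorter than 13 nt are discarded upstream")


@dataclass
class PlantedSite:
    chrom: str
    strand: str
    crosslink_pos: int  # plus-strand genomic coordinate of the crosslink T
    site_start: int  # plus-strand genomic half-open span of the planted element
    site_end: int
    motif_id: str
    tx_crosslink: int  # transcript-sense coordinate
    tx_site_start: int
    tx_site_end: int


@dataclass
class GroundTruth:
    sites: list[PlantedSite] = field(default_factory=list)
    transcripts: dict[str, dict] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, at_weight: float = 0.0) -> str:
    p = np.full(4, 0.25)
    if at_weight > 0:
        p = np.array([0.25 + at_weight / 2, 0.25 - at_weight / 2,
                      0.25 - at_weight / 2, 0.25 + at_weight / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _resolve_iupac(rng: np.random.Generator, pattern: str) -> str:
    return "".join(rng.choice(sorted(IUPAC[sym])) for sym in to_dna(pattern))


def simulate_reference(config: SimConfig) -> tuple[dict[str, str], AnnotationModel, GroundTruth]:
    """Generate transcripts, their annotation, and planted crosslink sites.

    Each transcript occupies its own contig; minus-strand transcripts are
    stored reverse-complemented so reads align to the '-' strand of the
    reference, exercising both orientations downstream.  Planted elements
    go into 3' UTRs.  In AGO mode each site is an 8mer-m1 seed match of a
    configured miRNA with the crosslink T placed directly upstream of it;
    otherwise the planted element is the configured motif (crosslink at a
    T inside it, or directly upstream when it contains none) or, with no
    motif, a bare crosslink T.
    """
    rng = np.random.default_rng(config.seed)
    ago_mode = len(config.mirnas) > 0
    seed_protection = config.seed_protection or ago_mode

    reference: dict[str, str] = {}
    annotation = AnnotationModel()
    truth = GroundTruth()

    # draw transcript structures first, then distribute sites so that no
    # 3' UTR receives more sites than it can hold at the minimum separation
    structures = []
    for t in range(config.n_transcripts):
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        l5 = int(rng.integers(*config.utr5_length, endpoint=True))
        lc = int(rng.integers(*config.cds_length, endpoint=True))
        l3 = int(rng.integers(*config.utr3_length, endpoint=True))
        structures.append((strand, l5, lc, l3))
    capacity = [max(0, 1 + (l3 - 31) // config.min_site_separation)
                for _, _, _, l3 in structures]
    if sum(capacity) < config.n_planted_sites:
        raise ValueError("infeasible lengths: not enough 3' UTR space for planted sites")
    site_counts = np.zeros(config.n_transcripts, dtype=int)
    for _ in range(config.n_planted_sites):
        while True:
            t = int(rng.integers(config.n_transcripts))
            if site_counts[t] < capacity[t]:
                site_counts[t] += 1
                break

    for t in range(config.n_transcripts):
        chrom = f"tx{t:03d}"
        strand, l5, lc, l3 = structures[t]
        tx_len = l5 + lc + l3
        seq = list(_random_seq(rng, tx_len))

        n_here = int(site_counts[t])
        utr3_start = l5 + lc
        positions = _place_sites(rng, n_here, utr3_start + 10, tx_len - 20,
                                 config.min_site_separation)
        site_records = []
        for pos in positions:
            if ago_mode:
                idx = int(rng.integers(len(config.mirnas)))
                mirna_id, mirna_seq = config.mirnas[idx]
                element = seed_sites(mirna_id, mirna_seq)[0].site_pattern  # 8mer-m1
                motif_id = mirna_id
            elif config.motif is not None:
                element = _resolve_iupac(rng, config.motif)
                motif_id = config.motif
            else:
                element = ""
                motif_id = "crosslink"
            for k, base in enumerate(element):
                seq[pos + k] = base
            elem_end = pos + max(len(element), 1)
            if element and seed_protection:
                # crosslink directly upstream of the protected element, with a
                # second crosslink-window T so the site shows >=2 conversion
                # locations, as real multi-contact sites do
                crosslink = pos - 1
                seq[crosslink] = "T"
                seq[pos - 2] = "T"
            elif element:
                ts = [pos + k for k, b in enumerate(element) if b == "T"]
                if ts:
                    crosslink = int(rng.choice(ts))
                else:
                    crosslink = pos - 1
                    seq[crosslink] = "T"
                    seq[pos - 2] = "T"
            else:
                crosslink = pos
                seq[crosslink] = "T"
                seq[pos + 1] = "T"
            if config.au_enrichment > 0:
                for k in range(max(0, pos - 5), pos):
                    if k != crosslink:
                        seq[k] = _random_seq(rng, 1, at_weight=config.au_enrichment)
                for k in range(elem_end, min(tx_len, elem_end + 5)):
                    seq[k] = _random_seq(rng, 1, at_weight=config.au_enrichment)
            site_records.append((pos, elem_end, crosslink, motif_id, len(element)))

        tx_seq = "".join(seq)
        contig_seq = tx_seq if strand == "+" else reverse_complement(tx_seq)
        reference[chrom] = contig_seq

        def to_genomic(a: int, b: int) -> tuple[int, int]:
            if strand == "+":
                return a, b
            return tx_len - b, tx_len - a

        for (a, b), cat in (((0, l5), "5'UTR"), ((l5, l5 + lc), "CDS"),
                            ((l5 + lc, tx_len), "3'UTR")):
            ga, gb = to_genomic(a, b)
            annotation.add(cat, chrom, strand, ga, gb)

        truth.transcripts[chrom] = {
            "strand": strand, "length": tx_len,
            "utr5": (0, l5), "cds": (l5, l5 + lc), "utr3": (l5 + lc, tx_len),
        }
        for pos, elem_end, crosslink, motif_id, elem_len in site_records:
            gs, ge = to_genomic(pos, elem_end)
            gx = crosslink if strand == "+" else tx_len - 1 - crosslink
            truth.sites.append(PlantedSite(
                chrom=chrom, strand=strand, crosslink_pos=gx,
                site_start=gs, site_end=ge, motif_id=motif_id,
                tx_crosslink=crosslink, tx_site_start=pos, tx_site_end=elem_end,
            ))
    return reference, annotation, truth


def _place_sites(rng: np.random.Generator, n: int, lo: int, hi: int,
                 min_sep: int) -> list[int]:
    """Sample n positions in [lo, hi), pairwise at least min_sep apart.

    Uses the gap construction: draw n sorted offsets from the region with
    the mandatory separations removed, then add the separations back, so
    any feasible count always places.
    """
    if n == 0:
        return []
    slack = (hi - lo) - (n - 1) * min_sep
    if slack < n:
        raise ValueError("could not place planted sites with requested separation")
    offsets = np.sort(rng.choice(slack, size=n, replace=False))
    return [int(lo + off + i * min_sep) for i, off in enumerate(offsets)]


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    reference: dict[str, str],
    truth: GroundTruth,
    config: SimConfig,
) -> list[AlignedRead]:
    """Sample reads around planted sites plus uniform background reads.

    Conversions are drawn per read: the crosslink T converts with
    ``crosslink_conversion_prob``; every other transcript-sense T in the
    read converts with ``background_conversion_prob``, except inside a
    protected seed element where conversion probability is zero.
    """
    rng = np.random.default_rng(config.seed + 1)
    seed_protection = config.seed_protection or len(config.mirnas) > 0
    reads: list[AlignedRead] = []
    counter = 0

    protected: dict[str, list[tuple[int, int]]] = {c: [] for c in reference}
    crosslinks: dict[str, set[int]] = {c: set() for c in reference}
    elevated: dict[str, set[int]] = {c: set() for c in reference}
    for site in truth.sites:
        crosslinks[site.chrom].add(site.tx_crosslink)
        for d in range(-config.crosslink_window, config.crosslink_window + 1):
            elevated[site.chrom].add(site.tx_crosslink + d)
        if seed_protection:
            protected[site.chrom].append((site.tx_site_start, site.tx_site_end))
        else:
            # crosslinking can hit any T of the bound element itself
            elevated[site.chrom].update(range(site.tx_site_start, site.tx_site_end))

    tx_seq_cache = {
        chrom: (seq if truth.transcripts[chrom]["strand"] == "+"
                else reverse_complement(seq))
        for chrom, seq in reference.items()
    }

    def emit(chrom: str, tx_start: int, tx_end: int) -> None:
        nonlocal counter
        info = truth.transcripts[chrom]
        tx_seq = tx_seq_cache[chrom]
        strand = info["strand"]
        tx_len = info["length"]
        frag = list(tx_seq[tx_start:tx_end])
        conv_tx: list[int] = []
        for i in range(tx_start, tx_end):
            if tx_seq[i] != "T":
                continue
            if i in crosslinks[chrom]:
                p = config.crosslink_conversion_prob
            elif any(s <= i < e for s, e in protected[chrom]):
                p = 0.0
            elif i in elevated[chrom]:
                p = config.adjacent_conversion_prob
            else:
                p = config.background_conversion_prob
            if p > 0 and rng.random() < p:
                frag[i - tx_start] = "C"
                conv_tx.append(i)
        read_seq = "".join(frag)
        if strand == "+":
            g_start, g_end = tx_start, tx_end
            mismatches = tuple((pos, "T", "C") for pos in conv_tx)
        else:
            g_start, g_end = tx_len - tx_end, tx_len - tx_start
            mismatches = tuple(sorted((tx_len - 1 - pos, "A", "G") for pos in conv_tx))
        reads.append(AlignedRead(
            read_id=f"sim_{counter:06d}", chrom=chrom, strand=strand,
            start=g_start, end=g_end, sequence=read_seq,
            mismatches=mismatches, n_candidate_locations=1,
        ))
        counter += 1

    def draw_span(chrom: str, anchor: int | None) -> tuple[int, int]:
        info = truth.transcripts[chrom]
        tx_len = info["length"]
        length = int(rng.integers(*config.read_length, endpoint=True))
        if anchor is None:
            start = int(rng.integers(0, max(1, tx_len - length)))
        else:
            lo = max(0, anchor - length + 1)
            hi = min(anchor, tx_len - length)
            start = int(rng.integers(lo, hi + 1)) if hi >= lo else lo
        end = min(start + length, tx_len)
        if config.rnase_g_bias and rng.random() < 0.8:
            # RNase T1 cleaves after G: nudge the 3' fragment end just past a G
            tx_seq = tx_seq_cache[chrom]
            for shift in (0, -1, -2, 1, 2):
                j = end + shift
                if (anchor is None or j > anchor) and tx_len >= j > start + 13 \
                        and tx_seq[j - 1] == "G":
                    end = j
                    break
        return start, end

    for site in truth.sites:
        for _ in range(config.depth):
            emit(site.chrom, *draw_span(site.chrom, site.tx_crosslink))
    chroms = sorted(reference)
    for _ in range(config.n_background_reads):
        chrom = chroms[int(rng.integers(len(chroms)))]
        emit(chrom, *draw_span(chrom, None))
    return reads


# ---------------------------------------------------------------------------
# library output (SAM / FASTA)
# ---------------------------------------------------------------------------

def write_fasta(reference: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(reference):
            fh.write(f">{chrom}\n")
            seq = reference[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _md_tag(ref_len: int, start: int, mismatches) -> str:
    parts = []
    prev = start
    for off, ref_base, _ in mismatches:
        parts.append(str(off - prev))
        parts.append(ref_base)
        prev = off + 1
    parts.append(str(start + ref_len - prev))
    return "".join(parts)


def write_sam(reads: Sequence[AlignedRead], reference: dict[str, str], path: str) -> None:
    """Write already-mapped records with correct SEQ orientation and MD/NM."""
    import pysam

    chroms = sorted(reference)
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(reference[c])} for c in chroms],
    })
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for read in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = read.read_id
            a.reference_id = tid[read.chrom]
            a.reference_start = read.start
            a.mapping_quality = 255
            a.flag = 16 if read.strand == "-" else 0
            seq_plus = (read.sequence if read.strand == "+"
                        else reverse_complement(read.sequence))
            a.query_sequence = seq_plus
            a.cigarstring = f"{len(seq_plus)}M"
            a.set_tag("NM", len(read.mismatches))
            a.set_tag("MD", _md_tag(len(seq_plus), read.start, read.mismatches))
            a.set_tag("NH", read.n_candidate_locations)
            fh.write(a)


def truth_table(truth: GroundTruth) -> str:
    rows = ["chrom\tstrand\tcrosslink_pos\tsite_start\tsite_end\tmotif_id"]
    for s in truth.sites:
        rows.append(f"{s.chrom}\t{s.strand}\t{s.crosslink_pos}\t{s.site_start}\t"
                    f"{s.site_end}\t{s.motif_id}")
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# CCR baseline and benchmarking
# ---------------------------------------------------------------------------

def call_ccrs(groups: Sequence[ReadGroup], reference,
              min_conversions: int = 1) -> list[InteractionSite]:
    """41-nt crosslink-centered windows, the baseline comparison caller.

    Each read group with conversion evidence yields one window centered on
    the offset with the highest conversion fraction (conversions / depth,
    leftmost on ties).
    """
    import math

    sites = []
    for group in groups:
        profile = build_profile(group, reference)
        if profile.n_tc < min_conversions:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(profile.depth > 0, profile.x_tc / profile.depth, 0.0)
        center = group.start + int(np.argmax(frac))
        start = max(0, center - CCR_WIDTH // 2)
        end = start + CCR_WIDTH
        lo = max(0, start - group.start)
        hi = min(profile.length, end - group.start)
        n_conv = int(profile.x_tc[lo:hi].sum()) if hi > lo else 0
        sites.append(InteractionSite(
            chrom=group.chrom, strand=group.strand, start=start, end=end,
            group=group,
            n_conversion_locations=int(np.count_nonzero(profile.x_tc[lo:hi])) if hi > lo else 0,
            n_conversions=n_conv,
            n_reads=sum(1 for r in group.reads if r.start < end and r.end > start),
            evidence=math.log2(n_conv) if n_conv > 0 else 0.0,
            annotation=group.annotation, in_repeat=group.in_repeat,
            extension_mode="ccr41",
        ))
    return sites


def recovery_metrics(
    sites: Sequence[InteractionSite],
    truth: GroundTruth,
    midpoint_tolerance: int = 3,
    pad: int = 5,
) -> dict[str, float]:
    """Planted-site recall (midpoint near crosslink) and nucleotide precision."""
    recovered = 0
    for planted in truth.sites:
        for site in sites:
            if site.chrom == planted.chrom and site.strand == planted.strand \
                    and abs(site.midpoint - planted.crosslink_pos) <= midpoint_tolerance:
                recovered += 1
                break
    true_spans: dict[str, list[tuple[int, int]]] = {}
    for planted in truth.sites:
        lo = min(planted.site_start, planted.crosslink_pos) - pad
        hi = max(planted.site_end, planted.crosslink_pos + 1) + pad
        true_spans.setdefault(planted.chrom, []).append((lo, hi))
    overlap_nt = 0
    total_nt = 0
    for site in sites:
        total_nt += site.length
        for lo, hi in true_spans.get(site.chrom, []):
            overlap_nt += max(0, min(site.end, hi) - max(site.start, lo))
    return {
        "n_planted": len(truth.sites),
        "n_called": len(sites),
        "recall": recovered / len(truth.sites) if truth.sites else 0.0,
        "nucleotide_precision": overlap_nt / total_nt if total_nt else 0.0,
    }


def benchmark_callers(
    groups: Sequence[ReadGroup],
    reference,
    truth: GroundTruth,
    mode: str = "fixed5",
    midpoint_tolerance: int = 3,
    **caller_kwargs,
) -> dict[str, dict[str, float]]:
    """Planted-site recovery of the KDE caller against the CCR baseline."""
    kde_sites = call_sites(groups, reference, mode=mode, **caller_kwargs)
    ccr_sites = call_ccrs(groups, reference)
    return {
        "kde": recovery_metrics(kde_sites, truth, midpoint_tolerance),
        "ccr": recovery_metrics(ccr_sites, truth, midpoint_tolerance),
    }


def transcript_conversion_counts(
    reads: Sequence[AlignedRead],
    reference: dict[str, str],
    truth: GroundTruth,
) -> tuple[dict[str, str], dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Per-transcript conversion / non-conversion counts in transcript sense.

    Returns transcript-sense sequences and ``(x_tc, x_tt)`` arrays indexed
    by transcript coordinate, ready for
    :func:`parclip.motifmatch.conversion_likelihood_profile`.
    """
    seqs: dict[str, str] = {}
    counts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, seq in reference.items():
        strand = truth.transcripts[chrom]["strand"]
        tx_seq = seq if strand == "+" else reverse_complement(seq)
        seqs[chrom] = tx_seq
        counts[chrom] = (np.zeros(len(tx_seq), dtype=np.int64),
                         np.zeros(len(tx_seq), dtype=np.int64))
    for read in reads:
        tx_len = truth.transcripts[read.chrom]["length"]
        tx_seq = seqs[read.chrom]
        x_tc, x_tt = counts[read.chrom]
        conv_genomic = {off for off, _, _ in read.mismatches}
        for g in range(read.start, read.end):
            tx = g if read.strand == "+" else tx_len - 1 - g
            if tx_seq[tx] != "T":
                continue
            if g in conv_genomic:
                x_tc[tx] += 1
            else:
                x_tt[tx] += 1
    return seqs, counts


# ---------------------------------------------------------------------------
# evidence-region simulators for the discovery models
# ---------------------------------------------------------------------------

def simulate_motif_regions(
    n_regions: int = 500,
    motif: str = "TGTANATA",
    region_length: tuple[int, int] = (40, 60),
    planted_fraction: float = 1 / 3,
    seed: int = 0,
) -> tuple[list[EvidenceRegion], list[str]]:
    """Regions with a motif planted into the top-evidence fraction.

    Evidence is standard normal; the regions in the top ``planted_fraction``
    by evidence each receive one motif instance (degenerate symbols resolved
    randomly) at a random offset.  Returns the centered regions and the ids
    of the planted ones.
    """
    rng = np.random.default_rng(seed)
    evidence = rng.normal(size=n_regions)
    order = np.argsort(evidence)[::-1]
    planted = set(order[: int(round(planted_fraction * n_regions))])
    ids, seqs = [], []
    planted_ids = []
    for i in range(n_regions):
        length = int(rng.integers(*region_length, endpoint=True))
        seq = list(_random_seq(rng, length))
        rid = f"region_{i:04d}"
        if i in planted:
            instance = _resolve_iupac(rng, motif)
            off = int(rng.integers(0, length - len(instance) + 1))
            seq[off : off + len(instance)] = instance
            planted_ids.append(rid)
        ids.append(rid)
        seqs.append("".join(seq))
    return make_regions(ids, seqs, evidence), planted_ids


def simulate_mirna_regions(
    n_regions: int = 2000,
    planted_mirna: tuple[str, str] = ("mir-planted", "UAGCAGCACGUAAAUAUUGGCG"),
    decoy_mirnas: Sequence[tuple[str, str]] = (),
    effect: float = 1.0,
    target_fraction: float = 0.15,
    region_length: tuple[int, int] = (45, 60),
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[list[EvidenceRegion], list[tuple[str, str]]]:
    """Regions where one miRNA's 7mer-m8 seed matches carry extra evidence.

    A ``target_fraction`` of regions get the planted miRNA's 7mer-m8 site
    written in; evidence is ``effect`` times the (post-hoc) presence of
    that site plus Gaussian noise, so the regression coefficient of the
    indicator is ``effect`` by construction.  Decoy miRNAs are returned
    alongside the planted one for ranking experiments.
    """
    rng = np.random.default_rng(seed)
    site = seed_sites(*planted_mirna)
    pattern_7m8 = next(d.site_pattern for d in site if d.seed_type == "7mer-m8")
    ids, seqs = [], []
    for i in range(n_regions):
        length = int(rng.integers(*region_length, endpoint=True))
        seq = list(_random_seq(rng, length))
        if rng.random() < target_fraction:
            off = int(rng.integers(0, length - len(pattern_7m8) + 1))
            seq[off : off + len(pattern_7m8)] = pattern_7m8
        ids.append(f"region_{i:05d}")
        seqs.append("".join(seq))
    indicator = np.array([pattern_7m8 in s for s in seqs], dtype=float)
    evidence = effect * indicator + rng.normal(scale=noise_sd, size=n_regions)
    mirnas = [planted_mirna, *decoy_mirnas]
    return make_regions(ids, seqs, evidence), mirnas
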