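"""Kernel-density classification of crosslink signal and site delineation.

Within each read group two smoothed densities are estimated over group
offsets: one from T=>C conversion events (signal of crosslinking) and one
from non-conversion events at reference thymines (background).  Offsets
where the normalized conversion density exceeds the non-conversion density
at sufficient read depth form interaction-site cores, which are then
extended (by a fixed window or by the underlying conversion-bearing reads)
and merged.

For a group of length L with per-offset conversion counts x_TC(i) and
non-conversion counts x_TT(i), the class densities are

    f_c(j) = sum_i  x_c(i)/n_c * exp(-(i-j)^2 / (2 lambda^2)),
    k_c(j) = f_c(j) / sum_j f_c(j),

evaluated at integer offsets only.  Any constant kernel prefactor cancels
in the normalization and is omitted.  lambda (default 3 nt) acts as the
Gaussian bandwidth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .ingest import (
    AnnotationModel,
    AlignedRead,
    INTERGENIC,
    MismatchClassification,
    ReadGroup,
    classify_mismatches,
    fetch_reference,
    reverse_complement,
)

logger = logging.getLogger(__name__)

ExtensionMode = Literal["fixed5", "by_read"]

DEFAULT_LAMBDA = 3.0
DEFAULT_MIN_READS = 5
DEFAULT_MIN_CONVERSION_LOCATIONS = 2
DEFAULT_MIN_DEPTH = 5
FIXED_EXTENSION = 5


# ---------------------------------------------------------------------------
# conversion profiles
# ---------------------------------------------------------------------------

@dataclass
class ConversionProfile:
    """Per-offset conversion / non-conversion counts for one read group.

    Offsets are 0-based relative to the group start on the plus strand of
    the reference.  ``is_t`` marks transcript-sense thymines (plus-strand
    'T' for '+' groups, plus-strand 'A' for '-' groups).
    """

    group: ReadGroup
    x_tc: np.ndarray
    x_tt: np.ndarray
    depth: np.ndarray
    is_t: np.ndarray

    @property
    def length(self) -> int:
        return len(self.x_tc)

    @property
    def n_tc(self) -> int:
        return int(self.x_tc.sum())

    @property
    def n_tt(self) -> int:
        return int(self.x_tt.sum())

    @property
    def n_conversion_locations(self) -> int:
        return int(np.count_nonzero(self.x_tc))


@dataclass
class DensityEstimate:
    """Normalized smoothed conversion / non-conversion densities."""

    lam: float
    k_tc: np.ndarray
    k_tt: np.ndarray


def build_profile(
    group: ReadGroup,
    reference,
    classifications: Mapping[str, MismatchClassification] | None = None,
) -> ConversionProfile:
    """Tally conversion, non-conversion and depth counts over a group.

    ``classifications`` maps read_id to a precomputed classification; reads
    absent from it are classified on the fly.
    """
    if not group.reads:
        raise ValueError("cannot profile an empty read group")
    L = group.end - group.start
    x_tc = np.zeros(L, dtype=np.int64)
    x_tt = np.zeros(L, dtype=np.int64)
    depth = np.zeros(L, dtype=np.int64)

    ref_seq = fetch_reference(reference, group.chrom, group.start, group.end)
    t_base = "T" if group.strand == "+" else "A"
    is_t = np.frombuffer(ref_seq.encode(), dtype=np.uint8) == ord(t_base)

    for read in group.reads:
        cls = None
        if classifications is not None:
            cls = classifications.get(read.read_id)
        if cls is None:
            cls = classify_mismatches(read, reference)
        lo, hi = read.start - group.start, read.end - group.start
        depth[lo:hi] += 1
        conv = {off - group.start for off in cls.conversion_offsets}
        plus_seq = read.sequence if read.strand == "+" else reverse_complement(read.sequence)
        for i in range(lo, hi):
            if not is_t[i]:
                continue
            if i in conv:
                x_tc[i] += 1
            elif plus_seq[i - lo] == ref_seq[i]:
                x_tt[i] += 1
            # reference-T with a non-conversion mismatch counts as neither
    return ConversionProfile(group=group, x_tc=x_tc, x_tt=x_tt, depth=depth, is_t=is_t)


# ---------------------------------------------------------------------------
# density estimation and classification
# ---------------------------------------------------------------------------

def estimate_densities(profile: ConversionProfile, lam: float = DEFAULT_LAMBDA) -> DensityEstimate:
    """Gaussian-kernel density estimates of both event classes.

    Each class's per-offset counts are weighted by their total and smoothed
    with exp(-(i-j)^2/(2 lambda^2)); the result is renormalized to sum to 1
    over the group.  A class with zero events yields an all-zero density.
    """
    L = profile.length
    if L == 0:
        raise ValueError("zero-length profile")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    idx = np.arange(L, dtype=float)
    kernel = np.exp(-((idx[:, None] - idx[None, :]) ** 2) / (2.0 * lam * lam))

    def _density(x: np.ndarray) -> np.ndarray:
        n = x.sum()
        if n == 0:
            return np.zeros(L)
        f = (x / n) @ kernel
        return f / f.sum()

    return DensityEstimate(lam=lam, k_tc=_density(profile.x_tc), k_tt=_density(profile.x_tt))


def classify_positions(
    profile: ConversionProfile,
    densities: DensityEstimate,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> np.ndarray:
    """Offsets classified as crosslink signal.

    An offset is signal iff its depth reaches ``min_depth`` and the
    conversion density strictly exceeds the non-conversion density.  With no
    non-conversion events at all, k_TT is identically zero and every
    depth-qualified offset is signal (the k_TT -> 0 limit).
    """
    if profile.n_tc == 0:
        return np.array([], dtype=int)
    qualified = profile.depth >= min_depth
    if profile.n_tt == 0:
        logger.debug("group %s:%d-%d has no non-conversion events; all depth-qualified "
                     "offsets classified signal", profile.group.chrom,
                     profile.group.start, profile.group.end)
        mask = qualified
    else:
        mask = qualified & (densities.k_tc > densities.k_tt)
    return np.flatnonzero(mask)


def signal_runs(offsets: np.ndarray) -> list[tuple[int, int]]:
    """Split signal offsets into maximal contiguous runs (half-open spans)."""
    if len(offsets) == 0:
        return []
    runs = []
    start = prev = int(offsets[0])
    for off in offsets[1:]:
        off = int(off)
        if off == prev + 1:
            prev = off
        else:
            runs.append((start, prev + 1))
            start = prev = off
    runs.append((start, prev + 1))
    return runs


# ---------------------------------------------------------------------------
# extension and merging
# ---------------------------------------------------------------------------

def extend_site(
    core: tuple[int, int],
    profile: ConversionProfile,
    mode: ExtensionMode,
    min_depth: int = DEFAULT_MIN_DEPTH,
    classifications: Mapping[str, MismatchClassification] | None = None,
    reference=None,
) -> tuple[int, int]:
    """Extend a core signal run, returning a half-open offset span.

    ``fixed5`` grows up to five offsets per side, stopping where the depth
    drops below ``min_depth``.  ``by_read`` grows toward the most distal
    ends of conversion-bearing reads that overlap the core by >=1 nt, again
    truncated at the first depth failure scanning outward from the core.
    """
    lo, hi = core
    L = profile.length
    depth = profile.depth
    group = profile.group
    if mode == "fixed5":
        left_limit = max(0, lo - FIXED_EXTENSION)
        right_limit = min(L, hi + FIXED_EXTENSION)
    elif mode == "by_read":
        core_start = group.start + lo
        core_end = group.start + hi
        left_limit, right_limit = lo, hi
        for read in group.reads:
            if read.start >= core_end or read.end <= core_start:
                continue  # no overlap with the core
            cls = None
            if classifications is not None:
                cls = classifications.get(read.read_id)
            if cls is None:
                if reference is None:
                    raise ValueError("by_read extension needs classifications or a reference")
                cls = classify_mismatches(read, reference)
            if cls.n_conversion < 1:
                continue
            left_limit = min(left_limit, read.start - group.start)
            right_limit = max(right_limit, read.end - group.start)
    else:
        raise ValueError(f"unknown extension mode {mode!r}")

    while lo > left_limit and depth[lo - 1] >= min_depth:
        lo -= 1
    while hi < right_limit and depth[hi] >= min_depth:
        hi += 1
    return lo, hi


def merge_spans(spans: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open spans; spans overlapping by >=1 nt are combined."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if merged and s < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------
# interaction sites
# ---------------------------------------------------------------------------

@dataclass
class InteractionSite:
    """A called, extended crosslink region with its conversion evidence."""

    chrom: str
    strand: str
    start: int
    end: int
    group: ReadGroup
    n_conversion_locations: int
    n_conversions: int
    n_reads: int
    evidence: float  # log2(n_conversions) by default
    annotation: str = INTERGENIC
    in_repeat: bool = False
    extension_mode: str = "fixed5"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end - 1) / 2.0


def _site_from_span(
    span: tuple[int, int],
    profile: ConversionProfile,
    mode: str,
    evidence_kind: str,
) -> InteractionSite | None:
    lo, hi = span
    group = profile.group
    n_conv = int(profile.x_tc[lo:hi].sum())
    if n_conv < 1:
        logger.debug("dropping span without conversion events in %s:%d-%d",
                     group.chrom, group.start + lo, group.start + hi)
        return None
    start, end = group.start + lo, group.start + hi
    n_reads = sum(1 for r in group.reads if r.start < end and r.end > start)
    value = n_reads if evidence_kind == "reads" else n_conv
    return InteractionSite(
        chrom=group.chrom,
        strand=group.strand,
        start=start,
        end=end,
        group=group,
        n_conversion_locations=int(np.count_nonzero(profile.x_tc[lo:hi])),
        n_conversions=n_conv,
        n_reads=n_reads,
        evidence=math.log2(value),
        annotation=group.annotation,
        in_repeat=group.in_repeat,
        extension_mode=mode,
    )


def call_sites(
    groups: Iterable[ReadGroup],
    reference,
    mode: ExtensionMode = "fixed5",
    min_reads: int = DEFAULT_MIN_READS,
    min_conversion_locations: int = DEFAULT_MIN_CONVERSION_LOCATIONS,
    min_depth: int = DEFAULT_MIN_DEPTH,
    lam: float = DEFAULT_LAMBDA,
    per_position_depth: bool = True,
    evidence: str = "conversions",
    classifications: Mapping[str, MismatchClassification] | None = None,
    annotation: AnnotationModel | None = None,
) -> list[InteractionSite]:
    """Run the full caller over read groups.

    Groups with fewer than ``min_reads`` reads or fewer than
    ``min_conversion_locations`` distinct conversion offsets are skipped.
    ``per_position_depth=False`` selects the relaxed variant that keeps the
    per-group read floor but drops the per-position depth requirement.
    Multiple signal runs within one group yield multiple sites; extended
    spans that overlap are merged and their statistics recomputed.
    """
    if evidence not in ("conversions", "reads"):
        raise ValueError("evidence must be 'conversions' or 'reads'")
    eff_min_depth = min_depth if per_position_depth else 1
    sites: list[InteractionSite] = []
    for group in groups:
        if group.n_reads < min_reads:
            continue
        profile = build_profile(group, reference, classifications)
        if profile.n_conversion_locations < min_conversion_locations:
            continue
        densities = estimate_densities(profile, lam=lam)
        offsets = classify_positions(profile, densities, min_depth=eff_min_depth)
        if len(offsets) == 0:
            continue
        spans = [
            extend_site(run, profile, mode, min_depth=eff_min_depth,
                        classifications=classifications, reference=reference)
            for run in signal_runs(offsets)
        ]
        for span in merge_spans(spans):
            site = _site_from_span(span, profile, mode, evidence)
            if site is not None:
                if annotation is not None:
                    site.annotation, site.in_repeat = annotation.annotate(
                        site.chrom, site.strand, site.start, site.end
                    )
                sites.append(site)
    return sites


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def sites_to_bed(sites: Sequence[InteractionSite]) -> str:
    """BED6 text: name = site index, score = evidence scaled to [0, 1000]."""
    lines = []
    max_ev = max((s.evidence for s in sites), default=1.0) or 1.0
    for i, s in enumerate(sites, start=1):
        score = int(round(1000 * max(0.0, s.evidence) / max_ev)) if max_ev > 0 else 0
        lines.append(f"{s.chrom}\t{s.start}\t{s.end}\tsite_{i}\t{score}\t{s.strand}")
    return "\n".join(lines) + ("\n" if lines else "")


def sites_to_table(sites: Sequence[InteractionSite]) -> str:
    """Tab-separated per-site report (1-based closed coordinates)."""
    header = ("site_id\tchrom\tstart\tend\tstrand\tn_reads\tn_conversions\t"
              "n_conversion_locations\tevidence\tannotation\tin_repeat\textension_mode")
    rows = [header]
    for i, s in enumerate(sites, start=1):
        rows.append(
            f"site_{i}\t{s.chrom}\t{s.start + 1}\t{s.end}\t{s.strand}\t{s.n_reads}\t"
            f"{s.n_conversions}\t{s.n_conversion_locations}\t{s.evidence:.4f}\t"
            f"{s.annotation}\t{int(s.in_repeat)}\t{s.extension_mode}"
        )
    return "\n".join(rows) + "\n"
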