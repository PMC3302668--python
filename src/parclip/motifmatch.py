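"""IUPAC motif scanning, miRNA seed-match scanning, and match profiles.

All scanning happens on transcript-sense sequence; genome minus-strand
regions must be reverse-complemented before being handed in.  T and U are
equivalent (sequences are normalized to DNA letters internally).

miRNA target sites are represented by the seven canonical seed-match
types.  Counting miRNA positions 1..8 from the 5' end, the mRNA-sense site
patterns are reverse complements of the stated positions; the *-A1 types
replace pairing to miRNA position 1 with an adenine at the site's 3'-most
position:

    8mer-m1:  revcomp(positions 1-8)
    8mer-A1:  revcomp(positions 2-8) + A
    7mer-m1:  revcomp(positions 1-7)
    7mer-A1:  revcomp(positions 2-7) + A
    7mer-m8:  revcomp(positions 2-8)
    6mer2-7:  revcomp(positions 2-7)
    6mer3-8:  revcomp(positions 3-8)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ingest import reverse_complement

logger = logging.getLogger(__name__)

#: IUPAC degeneracy classes over DNA letters (U is folded into T)
IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "M": frozenset("AC"),
    "N": frozenset("ACGT"),
}

#: seed types in the match-preference order (longest to shortest)
SEED_TYPE_ORDER = ("8mer-m1", "8mer-A1", "7mer-m1", "7mer-A1", "7mer-m8", "6mer2-7", "6mer3-8")

#: built-in RBP motif presets (configuration defaults, overridable at call time)
MOTIF_PRESETS: dict[str, tuple[str, ...]] = {
    "PUM2": ("UGUANAUA",),
    "QKI": ("AUUAAY", "ACUAAY"),
    "IGF2BP1": ("CAUU", "CUUU"),
}


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# IUPAC scanning
# ---------------------------------------------------------------------------

def validate_motif(pattern: str) -> str:
    """Uppercase/DNA-normalize an IUPAC pattern, rejecting invalid symbols."""
    norm = to_dna(pattern)
    bad = set(norm) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC symbols in motif {pattern!r}: {sorted(bad)}")
    return norm


def iupac_scan(sequence: str, pattern: str) -> list[int]:
    """All (possibly overlapping) start offsets where the motif matches."""
    pat = validate_motif(pattern)
    seq = to_dna(sequence)
    classes = [IUPAC[sym] for sym in pat]
    k = len(classes)
    hits = []
    for i in range(len(seq) - k + 1):
        if all(seq[i + j] in classes[j] for j in range(k)):
            hits.append(i)
    return hits


# ---------------------------------------------------------------------------
# miRNA seed sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeedDefinition:
    mirna_id: str
    seed_type: str
    site_pattern: str  # mRNA-sense, DNA letters, 5'->3'


def seed_sites(mirna_id: str, mirna_sequence: str) -> list[SeedDefinition]:
    """The seven canonical seed-match site patterns for one miRNA."""
    seq = to_dna(mirna_sequence)
    if len(seq) < 8:
        raise ValueError(f"{mirna_id}: miRNA sequence shorter than 8 nt")
    rc = reverse_complement
    patterns = {
        "8mer-m1": rc(seq[0:8]),
        "8mer-A1": rc(seq[1:8]) + "A",
        "7mer-m1": rc(seq[0:7]),
        "7mer-A1": rc(seq[1:7]) + "A",
        "7mer-m8": rc(seq[1:8]),
        "6mer2-7": rc(seq[1:7]),
        "6mer3-8": rc(seq[2:8]),
    }
    return [SeedDefinition(mirna_id, st, patterns[st]) for st in SEED_TYPE_ORDER]


@dataclass(frozen=True)
class SeedMatch:
    region_id: str
    start: int
    end: int
    mirna_id: str
    seed_type: str
    expression_rank: int


def nonredundant_seed_scan(
    regions: Mapping[str, str],
    mirnas: Sequence[tuple[str, str, int]],
    top_n: int = 20,
) -> list[SeedMatch]:
    """Non-redundant seed matches for the top expressed miRNAs.

    ``mirnas`` are ``(mirna_id, sequence, expression_rank)`` with rank 1 the
    most expressed; only the ``top_n`` best ranks are scanned.  Matches are
    accepted greedily in seed-type preference order (longest first) and, at
    equal type, by expression rank, so an overlapping shorter/later match is
    suppressed and a site shared by several miRNAs is credited once, to the
    most highly expressed one.
    """
    chosen = sorted(mirnas, key=lambda m: m[2])[:top_n]
    accepted: list[SeedMatch] = []
    occupied: dict[str, list[tuple[int, int]]] = {rid: [] for rid in regions}

    for type_idx, seed_type in enumerate(SEED_TYPE_ORDER):
        for mirna_id, mirna_seq, rank in chosen:
            pattern = seed_sites(mirna_id, mirna_seq)[type_idx].site_pattern
            for region_id, seq in regions.items():
                for off in iupac_scan(seq, pattern):
                    span = (off, off + len(pattern))
                    if any(span[0] < e and span[1] > s for s, e in occupied[region_id]):
                        continue
                    occupied[region_id].append(span)
                    accepted.append(SeedMatch(region_id, span[0], span[1],
                                              mirna_id, seed_type, rank))
    accepted.sort(key=lambda m: (m.region_id, m.start))
    return accepted


# ---------------------------------------------------------------------------
# composition and conversion-likelihood profiles
# ---------------------------------------------------------------------------

@dataclass
class MatchProfile:
    """Aligned composition and conversion statistics around motif matches.

    ``offsets[k]`` is the position relative to the match start; offset 0 is
    the first matched base.  ``composition`` rows are A, C, G, T
    frequencies relative to the 0.25 uniform background (one count per
    match location regardless of read depth).  ``conversion_likelihood`` is
    P(T=>C | reference T) per offset, pooled over all reads covering the
    offset, NaN where no reference-T coverage exists.  ``background`` is
    the same likelihood over every reference T in the full regions.
    """

    offsets: np.ndarray
    composition: np.ndarray  # shape (4, W), order ACGT
    conversion_likelihood: np.ndarray  # shape (W,)
    background: float
    n_matches: int


BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def conversion_likelihood_profile(
    matches: Iterable[tuple[str, int, int]],
    regions: Mapping[str, str],
    conversion_counts: Mapping[str, tuple[np.ndarray, np.ndarray]],
    flank: int = 5,
) -> MatchProfile:
    """Profile composition and conversion likelihood around matches.

    ``matches`` are ``(region_id, start, end)`` in region coordinates;
    ``conversion_counts`` maps region_id to per-position ``(x_tc, x_tt)``
    arrays (conversion and non-conversion event counts from all reads).
    """
    matches = list(matches)
    if not matches:
        raise ValueError("no matches to profile")
    max_len = max(e - s for _, s, e in matches)
    width = flank + max_len + flank
    offsets = np.arange(-flank, max_len + flank)

    comp = np.zeros((4, width))
    comp_n = np.zeros(width)
    conv = np.zeros(width)
    nonconv = np.zeros(width)

    for region_id, start, end in matches:
        seq = to_dna(regions[region_id])
        x_tc, x_tt = conversion_counts[region_id]
        for k, rel in enumerate(offsets):
            pos = start + rel
            if pos < 0 or pos >= len(seq):
                continue
            base = seq[pos]
            if base in BASE_INDEX:
                comp[BASE_INDEX[base], k] += 1
                comp_n[k] += 1
            if base == "T":
                conv[k] += x_tc[pos]
                nonconv[k] += x_tt[pos]

    with np.errstate(invalid="ignore", divide="ignore"):
        composition = np.where(comp_n > 0, comp / comp_n, np.nan) / 0.25
        likelihood = np.where(conv + nonconv > 0, conv / (conv + nonconv), np.nan)

    bg_conv = bg_non = 0.0
    for region_id, seq in regions.items():
        seq = to_dna(seq)
        x_tc, x_tt = conversion_counts[region_id]
        for pos, base in enumerate(seq):
            if base == "T":
                bg_conv += x_tc[pos]
                bg_non += x_tt[pos]
    background = bg_conv / (bg_conv + bg_non) if bg_conv + bg_non > 0 else float("nan")

    return MatchProfile(
        offsets=offsets,
        composition=composition,
        conversion_likelihood=likelihood,
        background=background,
        n_matches=len(matches),
    )


def profile_to_tsv(profile: MatchProfile) -> str:
    """Serialize a MatchProfile as a plotting-ready TSV matrix."""
    rows = ["offset\tA\tC\tG\tT\tconversion_likelihood\tbackground"]
    for k, off in enumerate(profile.offsets):
        comp = "\t".join(f"{profile.composition[b, k]:.4f}" for b in range(4))
        rows.append(f"{off}\t{comp}\t{profile.conversion_likelihood[k]:.4f}\t"
                    f"{profile.background:.6f}")
    return "\n".join(rows) + "\n"
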