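"""Evidence-ranked motif discovery and miRNA seed-enrichment regression.

Interaction sites carry a quantitative binding evidence y* (log2 conversion
count, mean-centered over the region set).  Two scoring routes share this
evidence:

* cERMIT-style motif scoring: for a candidate IUPAC motif with target set
  of size n_j, the enrichment score is S = A_j * e_j / (sigma_hat/sqrt(n_j))
  where e_j is the mean centered evidence over targets, sigma_hat^2 the
  sample variance of all evidence, and A_j an adjustment factor that tends
  to 1 for small target sets (implemented as sqrt(1 - n_j/n), pluggable).
  The search enumerates all non-degenerate 7-mers passing a minimum target
  fraction and hill-climbs over single-symbol degeneracy substitutions and
  length changes (6-10 nt).

* Seed-enrichment regression for Argonaute libraries: per miRNA and per
  canonical seed type, evidence is regressed (no intercept) on a binary
  seed-match indicator plus 16 standardized overlapping dinucleotide
  counts, which absorb local composition confounding such as the AU
  richness around functional miRNA sites.  The per-type score is the
  indicator coefficient over its standard error; the miRNA score is the
  mean over positively scoring types.  Significance is judged against a
  Gaussian fitted to scores from permuted evidence (default 100
  permutations, 3 SD threshold).
"""

from __future__ import annotations

import itertools
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .motifmatch import IUPAC, SEED_TYPE_ORDER, iupac_scan, seed_sites, to_dna, validate_motif

logger = logging.getLogger(__name__)

DINUCLEOTIDES = ["".join(p) for p in itertools.product("ACGT", repeat=2)]


# ---------------------------------------------------------------------------
# evidence regions
# ---------------------------------------------------------------------------

@dataclass
class EvidenceRegion:
    region_id: str
    sequence: str  # transcript-sense
    y_star: float  # centered binding evidence


def make_regions(
    ids: Sequence[str], sequences: Sequence[str], evidence: Sequence[float]
) -> list[EvidenceRegion]:
    """Build a centered region set from raw evidence values."""
    y = np.asarray(evidence, dtype=float)
    y = y - y.mean()
    return [
        EvidenceRegion(rid, to_dna(seq), float(v))
        for rid, seq, v in zip(ids, sequences, y)
    ]


def _evidence_vector(regions: Sequence[EvidenceRegion]) -> np.ndarray:
    y = np.array([r.y_star for r in regions])
    if abs(y.mean()) > 1e-6 * max(1.0, np.abs(y).max()):
        logger.warning("evidence not centered (mean %.4g); centering now", y.mean())
        y = y - y.mean()
    return y


# ---------------------------------------------------------------------------
# cERMIT scoring
# ---------------------------------------------------------------------------

def default_adjustment(n_j: int, n: int) -> float:
    """Target-set-size adjustment A_j; tends to 1 as n_j/n -> 0."""
    return math.sqrt(max(0.0, 1.0 - n_j / n))


@dataclass
class MotifScore:
    pattern: str
    n_targets: int
    e_j: float
    sigma_hat_j: float
    a_j: float
    score: float


class RegionIndex:
    """Fast existence matching of IUPAC motifs across a region set.

    Regions are concatenated with a sentinel so a single compiled-regex
    pass yields the set of matched regions.
    """

    def __init__(self, regions: Sequence[EvidenceRegion]):
        self.regions = regions
        self.y = _evidence_vector(regions)
        seqs = [to_dna(r.sequence) for r in regions]
        self._starts = np.cumsum([0] + [len(s) + 1 for s in seqs[:-1]])
        self._blob = "#".join(seqs)
        self._cache: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.regions)

    def match_mask(self, pattern: str) -> np.ndarray:
        """Boolean indicator over regions: does the motif occur at all."""
        if pattern in self._cache:
            return self._cache[pattern]
        regex = re.compile("".join(
            "[" + "".join(sorted(IUPAC[sym])) + "]" for sym in validate_motif(pattern)
        ))
        mask = np.zeros(len(self.regions), dtype=bool)
        for m in regex.finditer(self._blob):
            mask[np.searchsorted(self._starts, m.start(), side="right") - 1] = True
        self._cache[pattern] = mask
        return mask


def cermit_score(
    regions: Sequence[EvidenceRegion],
    pattern: str,
    adjustment: Callable[[int, int], float] = default_adjustment,
    index: RegionIndex | None = None,
) -> MotifScore | None:
    """Enrichment score of one motif over the centered evidence.

    Returns None when the motif has no targets (undefined score).
    """
    index = index or RegionIndex(regions)
    mask = index.match_mask(pattern)
    n = len(index)
    n_j = int(mask.sum())
    if n_j == 0:
        return None
    y = index.y
    sigma2 = float(np.var(y, ddof=1))
    e_j = float(y[mask].mean())
    sigma_hat_j = math.sqrt(sigma2 / n_j)
    a_j = adjustment(n_j, n)
    score = a_j * e_j / sigma_hat_j if sigma_hat_j > 0 else 0.0
    return MotifScore(validate_motif(pattern), n_j, e_j, sigma_hat_j, a_j, score)


# ---------------------------------------------------------------------------
# cERMIT search
# ---------------------------------------------------------------------------

_DEGENERATE = set("WKRYSMN")


def _n_degenerate(pattern: str) -> int:
    return sum(1 for s in pattern if s in _DEGENERATE)


@dataclass
class SearchResult:
    motifs: list[MotifScore]
    pfm: np.ndarray  # (4, L) position frequency matrix of the top motif
    occurrences: list[tuple[str, int, float]]  # (region_id, offset, evidence), evidence-sorted


def cermit_search(
    regions: Sequence[EvidenceRegion],
    k_start: int = 7,
    min_target_frac: float = 0.05,
    max_degenerate: int = 3,
    min_len: int = 6,
    max_len: int = 10,
    n_seeds: int = 50,
    adjustment: Callable[[int, int], float] = default_adjustment,
) -> SearchResult:
    """Greedy evidence-ranked motif search.

    All 4^k non-degenerate k-mers with a target set of at least
    ``min_target_frac`` of the regions seed a best-first hill climb over
    single-symbol degeneracy substitutions and single-position extensions
    or contractions; only strict score improvements are accepted.  The top
    ``n_seeds`` seeds (by score) are expanded.
    """
    if len(regions) < 20:
        raise ValueError("motif search needs at least 20 regions")
    index = RegionIndex(regions)
    n = len(index)
    y = index.y
    min_targets = max(1, math.ceil(min_target_frac * n))
    sigma2 = float(np.var(y, ddof=1))

    # stage 1: enumerate k-mer occurrences by a single pass over the regions
    kmer_targets: dict[str, set[int]] = {}
    for ridx, region in enumerate(regions):
        seq = to_dna(region.sequence)
        for i in range(len(seq) - k_start + 1):
            kmer = seq[i : i + k_start]
            if set(kmer) <= set("ACGT"):
                kmer_targets.setdefault(kmer, set()).add(ridx)

    def quick_score(target_set: set[int]) -> float:
        n_j = len(target_set)
        e_j = y[list(target_set)].mean()
        return adjustment(n_j, n) * e_j / math.sqrt(sigma2 / n_j)

    seeds = sorted(
        (kmer for kmer, t in kmer_targets.items() if len(t) >= min_targets),
        key=lambda kmer: quick_score(kmer_targets[kmer]),
        reverse=True,
    )[:n_seeds]
    if not seeds:
        logger.warning("no %d-mer passes the minimum target fraction %.2f",
                       k_start, min_target_frac)
        return SearchResult([], np.zeros((4, 0)), [])

    scored: dict[str, MotifScore] = {}

    def evaluate(pattern: str) -> MotifScore | None:
        if pattern in scored:
            return scored[pattern]
        ms = cermit_score(regions, pattern, adjustment=adjustment, index=index)
        if ms is not None and ms.n_targets < min_targets:
            ms = None
        if ms is not None:
            scored[pattern] = ms
        return ms

    symbols = sorted(IUPAC.keys() - {"U"})
    finals: dict[str, MotifScore] = {}
    for seed in seeds:
        current = evaluate(seed)
        if current is None:
            continue
        while True:
            best = None
            for cand in _moves(current.pattern, symbols, min_len, max_len, max_degenerate):
                ms = evaluate(cand)
                if ms is not None and (best is None or ms.score > best.score):
                    best = ms
            if best is not None and best.score > current.score:
                current = best
            else:
                break
        finals[current.pattern] = current

    # ties (a degenerate symbol that adds no targets) resolve toward the
    # most specific, shortest pattern
    ranked = sorted(finals.values(),
                    key=lambda m: (-m.score, _n_degenerate(m.pattern), len(m.pattern),
                                   m.pattern))
    top = ranked[0]
    pfm, occurrences = _top_motif_occurrences(regions, top.pattern)
    return SearchResult(ranked, pfm, occurrences)


def _moves(pattern: str, symbols: Sequence[str], min_len: int, max_len: int,
           max_degenerate: int) -> Iterable[str]:
    for i, cur in enumerate(pattern):
        for sym in symbols:
            if sym == cur:
                continue
            cand = pattern[:i] + sym + pattern[i + 1:]
            if _n_degenerate(cand) <= max_degenerate:
                yield cand
    if len(pattern) < max_len:
        for sym in symbols:
            for cand in (sym + pattern, pattern + sym):
                if _n_degenerate(cand) <= max_degenerate:
                    yield cand
    if len(pattern) > min_len:
        yield pattern[1:]
        yield pattern[:-1]


def _top_motif_occurrences(
    regions: Sequence[EvidenceRegion], pattern: str
) -> tuple[np.ndarray, list[tuple[str, int, float]]]:
    L = len(pattern)
    pfm = np.zeros((4, L))
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    occurrences: list[tuple[str, int, float]] = []
    for region in regions:
        seq = to_dna(region.sequence)
        for off in iupac_scan(seq, pattern):
            occurrences.append((region.region_id, off, region.y_star))
            for j in range(L):
                b = seq[off + j]
                if b in base_idx:
                    pfm[base_idx[b], j] += 1
    occurrences.sort(key=lambda t: t[2], reverse=True)
    return pfm, occurrences


def pfm_to_text(pfm: np.ndarray, pattern: str) -> str:
    """MEME-minimal-style text block of a position frequency matrix."""
    total = pfm.sum(axis=0)
    total[total == 0] = 1.0
    probs = pfm / total
    lines = [f"MOTIF {pattern}", f"letter-probability matrix: alength= 4 w= {pfm.shape[1]}"]
    for j in range(pfm.shape[1]):
        lines.append("  " + "  ".join(f"{probs[b, j]:.6f}" for b in range(4)))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# seed-enrichment regression (per-miRNA scoring)
# ---------------------------------------------------------------------------

def dinucleotide_design(regions: Sequence[EvidenceRegion]) -> np.ndarray:
    """Standardized (n, 16) matrix of overlapping dinucleotide counts.

    Columns are mean-centered and scaled to unit sample SD; zero-variance
    columns are left at zero (and dropped from fits downstream).
    """
    n = len(regions)
    counts = np.zeros((n, 16))
    col = {d: k for k, d in enumerate(DINUCLEOTIDES)}
    for i, region in enumerate(regions):
        seq = to_dna(region.sequence)
        for j in range(len(seq) - 1):
            d = seq[j : j + 2]
            if d in col:
                counts[i, col[d]] += 1
    centered = counts - counts.mean(axis=0)
    sd = centered.std(axis=0, ddof=1)
    out = np.zeros_like(centered)
    nz = sd > 0
    out[:, nz] = centered[:, nz] / sd[nz]
    return out


class _SeedTypeFit:
    """Precomputed OLS machinery for one design matrix, reusable across
    evidence permutations (only Z'y changes)."""

    def __init__(self, Z: np.ndarray):
        self.Z = Z
        self.n, self.p = Z.shape
        ztz = Z.T @ Z
        try:
            self.ztz_inv = np.linalg.inv(ztz)
        except np.linalg.LinAlgError:
            logger.warning("singular design; using pseudo-inverse")
            self.ztz_inv = np.linalg.pinv(ztz)

    def score(self, y: np.ndarray) -> float:
        """Indicator coefficient divided by its estimated standard error."""
        zty = self.Z.T @ y
        beta = self.ztz_inv @ zty
        rss = float(y @ y - beta @ zty)
        dof = self.n - self.p
        sigma2 = max(rss / dof, 0.0) if dof > 0 else 0.0
        se = math.sqrt(max(sigma2 * self.ztz_inv[0, 0], 0.0))
        return beta[0] / se if se > 0 else 0.0

    def coefficient(self, y: np.ndarray) -> tuple[float, float]:
        zty = self.Z.T @ y
        beta = self.ztz_inv @ zty
        rss = float(y @ y - beta @ zty)
        dof = max(self.n - self.p, 1)
        se = math.sqrt(max(rss / dof * self.ztz_inv[0, 0], 0.0))
        return float(beta[0]), se


@dataclass
class MiRNAScore:
    mirna_id: str
    site_8mer: str  # 8mer-m1 pattern, DNA letters
    per_type_scores: dict[str, float | None]
    s_reg: float
    n_targets: int
    null_mean: float = float("nan")
    null_sd: float = float("nan")
    p_value: float = float("nan")
    significant: bool = False
    cluster_id: int | None = None


def _seed_indicators(
    regions: Sequence[EvidenceRegion], mirna_id: str, mirna_seq: str
) -> dict[str, np.ndarray]:
    defs = seed_sites(mirna_id, mirna_seq)
    seqs = [to_dna(r.sequence) for r in regions]
    return {
        d.seed_type: np.array([d.site_pattern in s for s in seqs], dtype=float)
        for d in defs
    }


def _mean_positive(scores: Iterable[float]) -> float:
    pos = [s for s in scores if s is not None and s > 0]
    return float(np.mean(pos)) if pos else 0.0


def seed_enrichment_score(
    regions: Sequence[EvidenceRegion],
    mirna_id: str,
    mirna_sequence: str,
    design: np.ndarray | None = None,
) -> tuple[MiRNAScore, dict[str, _SeedTypeFit]]:
    """Confounder-adjusted enrichment score of one miRNA's seed family.

    Fits one no-intercept OLS per canonical seed type (indicator plus the
    standardized dinucleotide design), scores each as t = beta/SE(beta),
    and averages the positively scoring types.  Seed types absent from all
    regions are excluded as undefined.  Returns the score together with
    the per-type fit objects (reused by the permutation null).
    """
    if design is None:
        design = dinucleotide_design(regions)
    keep = [k for k in range(design.shape[1]) if design[:, k].std() > 0]
    if len(keep) < design.shape[1]:
        logger.warning("dropping %d zero-variance dinucleotide covariates",
                       design.shape[1] - len(keep))
    C = design[:, keep]
    y = _evidence_vector(regions)

    indicators = _seed_indicators(regions, mirna_id, to_dna(mirna_sequence))
    fits: dict[str, _SeedTypeFit] = {}
    per_type: dict[str, float | None] = {}
    any_target = np.zeros(len(regions), dtype=bool)
    for seed_type, x in indicators.items():
        if x.sum() == 0 or x.sum() == len(x):
            per_type[seed_type] = None  # degenerate indicator: no contrast
            continue
        any_target |= x.astype(bool)
        # the indicator is mean-centered like every other column: with the
        # centered evidence this makes the no-intercept fit equivalent to a
        # with-intercept fit, so the coefficient estimates the effect without
        # attenuation by the target fraction
        fit = _SeedTypeFit(np.column_stack([x - x.mean(), C]))
        fits[seed_type] = fit
        per_type[seed_type] = fit.score(y)

    site_8mer = seed_sites(mirna_id, to_dna(mirna_sequence))[0].site_pattern
    score = MiRNAScore(
        mirna_id=mirna_id,
        site_8mer=site_8mer,
        per_type_scores=per_type,
        s_reg=_mean_positive(per_type.values()),
        n_targets=int(any_target.sum()),
    )
    return score, fits


def seed_enrichment_significance(
    score: MiRNAScore,
    fits: Mapping[str, _SeedTypeFit],
    regions: Sequence[EvidenceRegion],
    b_permutations: int = 100,
    sd_threshold: float = 3.0,
    rng: np.random.Generator | None = None,
) -> MiRNAScore:
    """Permutation-calibrated significance of a miRNA score.

    The evidence vector is permuted jointly for all seed types B times, the
    miRNA score recomputed, and a Gaussian fitted to the null scores; the
    observed score is significant when it exceeds mean + sd_threshold * SD,
    with the upper Gaussian tail as p-value.
    """
    if b_permutations < 10:
        raise ValueError("need at least 10 permutations")
    rng = rng or np.random.default_rng()
    y = _evidence_vector(regions)
    null_scores = np.empty(b_permutations)
    for b in range(b_permutations):
        y_perm = rng.permutation(y)
        null_scores[b] = _mean_positive(fit.score(y_perm) for fit in fits.values())
    mean, sd = float(null_scores.mean()), float(null_scores.std(ddof=1))
    if sd == 0:
        logger.warning("zero-variance permutation null for %s; p-value degenerate",
                       score.mirna_id)
        score.significant = score.s_reg > mean
        score.p_value = 0.0 if score.s_reg > mean else 1.0
    else:
        score.significant = score.s_reg > mean + sd_threshold * sd
        score.p_value = float(stats.norm.sf(score.s_reg, loc=mean, scale=sd))
    score.null_mean, score.null_sd = mean, sd
    return score


def rank_mirnas(
    regions: Sequence[EvidenceRegion],
    mirnas: Sequence[tuple[str, str]],
    b_permutations: int = 100,
    sd_threshold: float = 3.0,
    seed: int | None = None,
) -> list[MiRNAScore]:
    """Score, test and cluster a miRNA list; returns scores ranked by S."""
    rng = np.random.default_rng(seed)
    design = dinucleotide_design(regions)
    scores = []
    for mirna_id, mirna_seq in mirnas:
        score, fits = seed_enrichment_score(regions, mirna_id, mirna_seq, design=design)
        if fits:
            score = seed_enrichment_significance(
                score, fits, regions, b_permutations, sd_threshold, rng
            )
        scores.append(score)
    scores.sort(key=lambda s: s.s_reg, reverse=True)
    cluster_seeds(scores)
    return scores


# ---------------------------------------------------------------------------
# seed clustering
# ---------------------------------------------------------------------------

def _share_long_substring(a: str, b: str, min_len: int = 7) -> bool:
    for length in range(min(len(a), len(b)), min_len - 1, -1):
        subs = {a[i : i + length] for i in range(len(a) - length + 1)}
        if any(b[i : i + length] in subs for i in range(len(b) - length + 1)):
            return True
    return False


def cluster_seeds(ranked_scores: Sequence[MiRNAScore], min_shared: int = 7) -> list[int]:
    """Greedy clustering of ranked miRNAs by near-identical seeds.

    The highest-scoring miRNA founds cluster 1; each subsequent miRNA joins
    the first existing cluster whose center shares an identical canonical
    seed-site substring of at least ``min_shared`` nt, else founds a new
    cluster.  Assignments are written to ``cluster_id`` and returned.
    """
    centers: list[tuple[int, str]] = []  # (cluster_id, 8mer)
    assignments = []
    for score in ranked_scores:
        assigned = None
        for cid, center_8mer in centers:
            if _share_long_substring(score.site_8mer, center_8mer, min_shared):
                assigned = cid
                break
        if assigned is None:
            assigned = len(centers) + 1
            centers.append((assigned, score.site_8mer))
        score.cluster_id = assigned
        assignments.append(assigned)
    return assignments


def mirna_report(scores: Sequence[MiRNAScore]) -> str:
    """TSV report: cluster, miRNA, 8-mer, score, p-value, targets, cumulative."""
    rows = ["cluster\tmirna_id\tsite_8mer\tscore\tp_value\tn_targets\tcumulative_targets"]
    seen_clusters: dict[int, int] = {}
    cumulative = 0
    for s in scores:
        if s.cluster_id not in seen_clusters:
            cumulative += s.n_targets
            seen_clusters[s.cluster_id] = cumulative
        rows.append(
            f"{s.cluster_id}\t{s.mirna_id}\t{s.site_8mer}\t{s.s_reg:.2f}\t"
            f"{s.p_value:.2e}\t{s.n_targets}\t{seen_clusters[s.cluster_id]}"
        )
    return "\n".join(rows) + "\n"
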