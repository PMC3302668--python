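"""Expressed-gene backgrounds, signal-to-noise, and 3' UTR positional analysis.

The signal-to-noise statistic is the density of motif (or seed) matches in
a foreground set of called sites divided by the match density in a
background of expressed-gene sequence:

    S/N = (fg_matches / fg_nucleotides) / (bg_matches / bg_nucleotides)

Backgrounds are built from genes called expressed on a companion
microarray: a gene is expressed when its value (max over probes, probe
replicates averaged first) exceeds the 80th percentile of the
background-probe (no-gene) distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# expressed genes
# ---------------------------------------------------------------------------

def expressed_gene_set(
    table: pd.DataFrame,
    percentile: float = 80.0,
    value_columns: Sequence[str] | None = None,
) -> set[str]:
    """Genes whose expression exceeds the background-probe percentile.

    ``table`` needs columns ``gene_id``, ``probe_id``, ``is_background``
    plus one or more numeric value columns (biological replicates, averaged
    per probe before anything else).  Background probes (``is_background``
    true) define the threshold: the linearly-interpolated ``percentile`` of
    their averaged values.  Gene values are the maximum over the gene's
    probes; expression requires a strictly greater value.
    """
    if value_columns is None:
        reserved = {"gene_id", "probe_id", "is_background"}
        value_columns = [c for c in table.columns if c not in reserved]
    if not value_columns:
        raise ValueError("no value columns found")
    probe_values = table[list(value_columns)].mean(axis=1)

    bg = probe_values[table["is_background"].astype(bool)]
    if bg.empty:
        raise ValueError("no background probes; cannot set expression threshold")
    threshold = float(np.percentile(bg.to_numpy(), percentile))

    genes = table.loc[~table["is_background"].astype(bool), "gene_id"]
    gene_values = probe_values.loc[genes.index].groupby(genes).max()
    return set(gene_values.index[gene_values > threshold])


# ---------------------------------------------------------------------------
# signal-to-noise
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SNResult:
    fg_matches: int
    fg_nucleotides: int
    bg_matches: int
    bg_nucleotides: int

    @property
    def ratio(self) -> float:
        return (self.fg_matches / self.fg_nucleotides) / (
            self.bg_matches / self.bg_nucleotides
        )

    @property
    def ratio_2dp(self) -> float:
        """Display rounding at table precision (half-even, 2 dp)."""
        return round(self.ratio, 2)


def signal_to_noise(
    fg_matches: int, fg_nucleotides: int, bg_matches: int, bg_nucleotides: int
) -> SNResult:
    """Match density of a site set relative to its expressed background."""
    if min(fg_matches, fg_nucleotides, bg_nucleotides) <= 0:
        raise ValueError("all counts must be positive")
    if bg_matches <= 0:
        raise ValueError("zero background matches: ratio undefined")
    return SNResult(fg_matches, fg_nucleotides, bg_matches, bg_nucleotides)


# ---------------------------------------------------------------------------
# normalized 3' UTR positions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UTRPosition:
    utr_id: str
    n_polya_sites: int
    normalized_length: int  # 100 or 200 (percent)
    site_midpoint_fraction: float  # in [0, normalized_length]


def normalized_utr_position(
    utr_id: str,
    site_start: int,
    site_end: int,
    utr_start: int,
    utr_end: int,
    strand: str,
    n_polya_sites: int,
) -> UTRPosition:
    """Site midpoint as a percentage position along a normalized 3' UTR.

    UTRs of genes with a single annotated poly-adenylation site span 100%;
    genes with two or more span 200%.  The fraction is measured from the
    UTR's 5' end (strand-aware).
    """
    if n_polya_sites < 1:
        raise ValueError("n_polya_sites must be >= 1")
    if utr_end <= utr_start:
        raise ValueError("empty UTR span")
    midpoint = (site_start + site_end - 1) / 2.0
    if not utr_start <= midpoint < utr_end:
        raise ValueError(
            f"site midpoint {midpoint} outside UTR [{utr_start}, {utr_end})"
        )
    span = utr_end - utr_start
    frac = (midpoint - utr_start) / span
    if strand == "-":
        frac = 1.0 - frac
    scale = 100 if n_polya_sites == 1 else 200
    return UTRPosition(utr_id, n_polya_sites, scale, frac * scale)


# ---------------------------------------------------------------------------
# sliding signal-to-noise over miRNA expression rank
# ---------------------------------------------------------------------------

def sliding_expression_sn(ratios: Sequence[float], window: int = 21) -> np.ndarray:
    """Centered moving average of log2 signal-to-noise over expression rank.

    ``ratios`` must be ordered by miRNA expression rank (most expressed
    first).  Edges use the positions available within the centered window;
    a window wider than the list collapses to the single global mean.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    log_ratios = np.log2(np.asarray(ratios, dtype=float))
    n = len(log_ratios)
    if n == 0:
        return log_ratios
    if window > n:
        return np.full(n, log_ratios.mean())
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = log_ratios[lo:hi].mean()
    return out
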