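# parclip

Interaction-site calling and motif/seed enrichment analysis for PAR-CLIP
short-read data.

PAR-CLIP (photoactivatable-ribonucleoside-enhanced crosslinking and
immunoprecipitation) marks the contact points between an RNA-binding
protein (RBP) and its target transcripts with a diagnostic mutation:
4-thiouridine incorporated at the crosslink misreads during cDNA synthesis,
so reference thymines appear as cytosines (T=>C) in the sequenced reads.
`parclip` turns aligned PAR-CLIP reads into a high-resolution map of
RBP–RNA interaction sites by exploiting exactly this signal, and then
quantifies what those sites contain — known RBP motifs, microRNA seed
matches, or de-novo motifs ranked by crosslink evidence. It is intended
for computational biologists analysing CLIP-style libraries, and comes
with a fully synthetic library generator so the entire pipeline can be
exercised and validated without any external data.

## The model

Reads overlapping by ≥1 nt (per strand) form **read groups**. Within a
group of length *L*, let x<sub>T→C</sub>(i) and x<sub>T→T</sub>(i) count
conversion and non-conversion events at offset *i*. Each class is smoothed
with a Gaussian kernel of bandwidth λ (default 3 nt) and normalized:

    f_c(j) = Σ_i  x_c(i)/n_c · exp(−(i−j)² / 2λ²),      k_c(j) = f_c(j) / Σ_j f_c(j)

Offsets where k<sub>T→C</sub>(j) > k<sub>T→T</sub>(j) at read depth ≥ 5
are crosslink signal; contiguous runs are extended (±5 nt, or to the ends
of conversion-bearing reads, depth permitting), merged, and reported as
**interaction sites** carrying evidence y\* = log₂(#T=>C conversions).
Only groups with ≥5 reads and ≥2 distinct conversion locations are
considered.

Downstream, sites are scored by:

* **signal-to-noise** — (matches per site nucleotide) / (matches per
  nucleotide of expressed-gene background);
* **evidence-ranked motif search** — S = A·e<sub>j</sub>/(σ̂/√n<sub>j</sub>)
  over IUPAC motifs, hill-climbed from all qualifying 7-mers;
* **miRNA seed-enrichment regression** — per canonical seed type
  (8mer-m1 … 6mer3-8), evidence is regressed on a seed-match indicator
  plus 16 standardized dinucleotide counts; significance comes from a
  Gaussian fit to permuted-evidence scores (3 SD default), and
  near-identical seeds are clustered greedily.

## Worked example

Simulate a library (50 transcripts, 30 planted crosslink sites, 20 reads
per site, 50% crosslink conversion probability vs 0.1% background), call
sites, and benchmark against the 41-nt fixed-window baseline:

```python
from parclip import (SimConfig, simulate_reference, simulate_reads,
                     build_read_groups, call_sites, benchmark_callers,
                     signal_to_noise)

config = SimConfig(seed=1)
reference, annotation, truth = simulate_reference(config)
reads = simulate_reads(reference, truth, config)
groups = build_read_groups(reads)
sites = call_sites(groups, reference, mode="fixed5", annotation=annotation)
print(f"{len(groups)} read groups, {len(sites)} interaction sites")
```

```
174 read groups, 30 interaction sites
```

The first site shows the per-site statistics the caller reports:

```
first site: tx002:551-571(+) reads=20 conversions=17 evidence=4.09 annotation=3'UTR
```

i.e. a 20-nt site on the plus strand of transcript 2, supported by 20
reads with 17 conversion events (evidence log₂17 ≈ 4.09), inside a 3' UTR.
Benchmarking both callers against the planted truth:

```python
for name, m in benchmark_callers(groups, reference, truth).items():
    print(name, m)
```

```
kde: recall=1.00 precision=0.51 called=30
ccr: recall=1.00 precision=0.25 called=32
```

Both callers find every planted site (midpoint within ±3 nt of the
crosslink), but the density classifier's sites waste half as many
nucleotides as the fixed 41-nt windows — the resolution gain the method
exists for. Signal-to-noise works directly from match/nucleotide counts;
for example, 1,262 motif matches over 127,168 site nucleotides against a
background of 113,478 matches over 689,309,457 nt:

```python
print(signal_to_noise(1262, 127168, 113478, 689309457).ratio_2dp)  # 60.28
```

A shell interface mirrors the library (`parclip simulate`, `parclip call`,
`parclip scan`, `parclip sn`, `parclip discover cermit|seeds`); see
`parclip --help`.

## Documentation

`docs/methods.md` describes the model assumptions, parameter defaults,
numerical choices, what the simulator does and does not emulate, and known
limitations.
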