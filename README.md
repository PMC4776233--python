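# bbcscreen

Tools for **bead-based cleavage (BBC) protease-substrate screening**, an
in vitro degradomics strategy: a whole cell proteome is covalently
immobilized on beads through its primary amines, incubated with an active
protease (the model case is caspase-3), and only cleaved proteins shed
fragments into solution. Released fragments are trypsin-digested,
isotope-labeled against a no-protease control, and every peptide is
quantified as a heavy/light ratio H/L = treated/untreated. Substrates then
stand out as proteins with many strongly up-regulated peptides.

The package is aimed at proteomics researchers who want to analyse such
screens — or stress-test their filtering criteria — without rerunning the
wet lab. It provides:

- **`bbcscreen.simulate`** — an end-to-end synthetic experiment: random
  proteome, planted caspase substrates with DXXD-family cleavage motifs,
  bead attachment, specific and background cleavage, fragment release,
  tryptic digestion (KR/P rule, missed cleavages), and ratio quantification
  with log-normal noise, plus the ground truth for benchmarking.
- **`bbcscreen.quantio`** — FASTA and quantified-peptide TSV I/O, peptide
  location on the proteome, flanking-residue annotation.
- **`bbcscreen.calling`** — the dual-threshold substrate caller and the
  cutoff-optimization curves that justify it.
- **`bbcscreen.sites`** — cleavage sites read off semi-tryptic peptide
  termini, enzyme classification (tryptic / aspartate / other), DXXD motif
  families, and position frequency matrices for sequence logos.
- **`bbcscreen.overlap`** — set-overlap statistics against reference
  substrate databases and in vivo degradome lists.

A thin `bbc` command line (`bbc simulate / call / sites / overlap`) wraps
the library; the `examples/` scripts are the quickest tour.

## The statistics at the core

For each quantified peptide *i* the screen records log₂(H/L)ᵢ. Background
peptides (released by trace endogenous proteases, identical in both arms)
have log₂ ratios centred at 0; protease-released peptides are shifted
strongly positive. A protein is called a **substrate** when

> at least 2 distinct peptide sequences reach log₂(H/L) ≥ 1.8,

and the call is tiered **hot** (≥ 5 up-regulated peptides) or **warm**
(2–4). Each non-terminal peptide terminus reads out one cleavage site with
P1 the residue before the scissile bond: tryptic if P1 ∈ {K, R} and P1′ ≠ P,
aspartate (the caspase signature) if P1 = D. Aspartate sites are screened
for the caspase-3 motif D-X-X-D (P4 = P1 = D) with sub-families DEXD, DLXD
and DDXD fixed by P3. Substrate sets A, B are compared by recovery
(|A∩B|/|A|) and by the overlap ratio (Jaccard, |A∩B|/|A∪B|).

## Worked example

```bash
python examples/call_substrates.py
```

prints (default study conditions, seed 42):

```
substrate calls:  36 (33 hot, 3 warm)
precision:        1.000
recall:           0.857 of 42 planted substrates

at log2 >= 1.0, peptide-count minimum vs % of qualifying proteins
that are true substrates:
  >= 1 peptides:  84.1%
  >= 2 peptides:  97.3%
  >= 3 peptides: 100.0%
  ...
```

Of the 42 planted substrates, 36 are recovered by the dual-threshold
criteria with no false positives; the rising curve shows why a
peptide-count minimum is imposed on top of the ratio cutoff — proteins
supported by a single up-regulated peptide are the least trustworthy.
`examples/cleavage_sites.py` continues the analysis: 545 unique cleavage
sites, 76.7% tryptic and 21.5% aspartate, with the aspartate sites
recovering the planted DXXD motifs at precision 1.000 (modal P4 = D,
P1 = D in the position frequency matrix).

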