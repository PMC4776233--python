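# Methods

## The experiment being modelled

A bead-based cleavage (BBC) screen separates proteolyzed proteins from the
cellular background physically rather than statistically. The proteome is
coupled to CNBr-activated beads through its primary amines; when an added
protease cuts an immobilized protein, any piece that no longer carries an
attachment diffuses into solution. The released material — plus whatever
trace endogenous proteases shed from both arms — is trypsin-digested,
dimethyl-labeled heavy (protease-treated) and light (control), pooled and
quantified by LC-MS/MS. Downstream analysis therefore sees one table:
peptides with H/L ratios, located on a protein library.

`bbcscreen.simulate` reproduces exactly this data-generating process at the
event level; everything upstream of the quantified table that is pure
chemistry (labeling kinetics, isotope envelopes, retention, spectra,
search-engine FDR) is out of scope and not modelled.

## Simulation model

Per protein, in order:

1. **Attachment.** Primary amines are the N-terminus plus every lysine;
   each couples independently with probability `coupling_prob` (default
   0.2). No kinetics, no steric effects.
2. **Background cleavage.** Every peptide bond is cut with probability
   `background_rate` (default 0.001) — positionally uniform, since the
   endogenous proteases responsible have no characterized specificity. The
   *same* background cuts apply to both arms (one bead batch split into
   two aliquots), which is what centres background log₂ ratios at 0
   rather than adding independent sampling variance.
3. **Specific cleavage (treated arm only).** Each planted site is cut with
   probability `cleavage_efficiency` (default 0.9).
4. **Release.** The chain is partitioned at all cuts; a fragment is
   released iff it contains no attachment.
5. **Digestion.** Released fragments are digested with the KR/P rule and
   up to `max_missed_cleavages` (default 2) missed cleavages; peptides
   outside the 7–35 residue detectability window are discarded.
6. **Quantification.** Occurrences are tallied per (sequence, position) in
   each arm. Peptides present in both arms get ratio
   (treated count / control count) × 2^N(0, `log2_bg_sd`). Peptides present
   only in the treated arm are the caspase-released population: their log₂
   ratio is drawn from N(`log2_sub_mean`, `log2_sub_sd`), capped at +10.
   This reflects that the "absent" control channel in real MS data is a
   noise floor, not a true zero — the ratio is finite, large and
   stochastic, and the ±10 cap (ratio 2¹⁰) keeps the table finite while
   preserving strong up-regulation under any cutoff ≤ 10. Control-only
   peptides (they span a cut executed only in the treated arm) get the
   mirrored treatment capped at −10.

Substrates are a Bernoulli(`substrate_fraction`) subset of the proteome.
Each receives 1 + Poisson(`sites_per_substrate_mean` − 1) cleavage sites at
uniform internal positions with non-overlapping P4–P1 windows; the window
is overwritten with a motif drawn from `motif_weights`, so every planted P1
is D. Randomness flows from a single `SeedSequence(seed)`; identical
parameters give byte-identical output tables.

## Default parameters and why

| parameter | default | rationale |
|---|---|---|
| `n_proteins` | 300 | thousands of peptides in well under a second |
| `length_mean` / `length_sd` | 350 / 100 aa (min 50) | human-like protein length distribution |
| `substrate_fraction` | 0.15 | a broad-specificity executioner protease |
| `sites_per_substrate_mean` | 4 | prolonged in vitro digestion at high enzyme dose cleaves several accessible D sites per substrate; multi-peptide ("hot") substrates are common in such screens |
| `motif_weights` | DEVD 0.4, DELD 0.2, DDXD 0.2, DQXD 0.2 | canonical caspase-3 P4–P1 preferences, DEVD foremost |
| `coupling_prob` | 0.2 | partial amine coupling; immobilization density is not experimentally known and is a free parameter |
| `background_rate` | 0.001 /bond | likewise free: trace endogenous activity |
| `cleavage_efficiency` | 0.9 | near-complete cutting of accessible sites |
| `log2_bg_sd` | 0.4 | background ratio spread of dimethyl quantification |
| `log2_sub_mean` / `log2_sub_sd` | 3.0 / 0.8 | released peptides up ~8-fold with biological scatter |
| `max_missed_cleavages` | 2, window 7–35 aa | standard search-engine settings |

Under these conditions the default run (seed 42) yields ~1 750 quantified
peptides, ~48% up-regulated at log₂ > 1 — the regime reported for real
caspase-3 screens, where roughly 43% clear that bar — and a tryptic
majority among derived cleavage sites.

## What the simulator does and does not emulate

It reproduces the *statistical structure* the analysis depends on: a
background population centred at log₂ = 0, a strongly shifted
substrate-derived population, semi-tryptic termini exactly at true
protease cleavage positions, fully tryptic termini elsewhere, shared
peptides across missed-cleavage variants, and release governed by
attachment topology. It does **not** emulate protein abundance dynamic
range, ionization/detectability bias, chimeric or mis-assigned spectra,
shared peptides between homologous proteins, or post-translational
modifications. Passing parameter-recovery tests therefore shows the
pipeline's logic is sound under the stated noise model — not that real
data will reach the same precision/recall, since real screens add
identification noise the simulator deliberately leaves out.

## Analysis conventions

- Coordinates are 1-based inclusive; a cleavage site is named by its P1
  position (cut between P1 and P1′), matching site names like D148.
- The substrate-calling ratio cutoff is **inclusive** (log₂ ≥ 1.8); the
  up-regulated-peptide fraction is **strict** (log₂ > 1). Both follow the
  screen's published usage and are kept verbatim to avoid off-by-one
  ambiguity.
- Peptides are counted as distinct sequences per protein; charge and
  modification variants collapse.
- "Terminal peptides" contribute no site on their flush side only: a
  peptide starting at residue 1 still yields its C-side site, and vice
  versa.
- A site whose P1 is K/R (not before P) is classified tryptic even when it
  could equally be a protease product; the ambiguity is inherent to
  re-digestion and is the reason tryptic sites dominate the site table.
- Sites are unique per (protein, P1 position), not per peptide occurrence.
- DXXD sub-families are fixed by P3 alone (E → DEXD, L → DLXD, D → DDXD)
  and are mutually exclusive; DQXD is plantable in the simulator but is
  reported under generic DXXD, matching the families conventionally
  enumerated in results.
- Empty denominators (a cutoff no peptide reaches, an empty tier) yield
  NaN with a logged warning, never a silent 0 — 0% is a real observation.
- Overlap percentages keep full double precision internally and are
  rounded to one decimal only for presentation. The "overlap ratio" is
  Jaccard (intersection over union) and is labelled `jaccard_pct`
  explicitly. Accession matching is exact string equality after
  whitespace stripping; identifier mapping between namespaces (UniProt vs
  gene symbol) is a curation step to perform before calling `overlap`.
- In the quantified-table reader, `accession` is a mandatory column, so a
  peptide's protein assignment always comes from the row; `map_peptide`
  resolves only the position, taking the smallest start (with a warning)
  when a sequence occurs more than once in its protein.

## Numerical and degenerate-input behaviour

Ratios are validated positive and finite; `log2_ratio` must agree with
`log2(ratio_hl)` to 1e−9. The TSV writer serialises ratios with `repr` and
the reader parses with round-trip float precision, so write→read is exact
and seeded runs are byte-identical on disk. Empty tables, zero-site PFMs
and non-positive fold changes raise `ValueError` rather than returning
sentinels; row-level defects in input files (unlocatable peptide,
non-positive ratio) drop the row with a logged count. A protein too short
to host a motif window is skipped by the substrate planter after bounded
retries and never enters the ground truth.

## Problem sizes

The shipped defaults (300 proteins, mean length 350) were chosen so a full
simulated screen, substrate calling and site analysis complete in well
under a second, and the multi-seed trend analyses in the test suite in a
few seconds, while still yielding 10³–10⁴ peptides — enough for the
fraction-level checks to be statistically meaningful.

## Known limitations

- The intensity model is occurrence counting (one abundance unit per
  released occurrence); no dynamic range across proteins.
- Background cleavage shares cuts across arms by design; fully independent
  background digestion (bead-batch effects) is not modelled.
- The caveat count of K/R sites located at caspase fragment edges
  (tryptic-looking sites that are actually protease products) is not
  separately reported; such sites are classified tryptic.
- No protein-level FDR or per-call statistical test: the calling criteria
  are deterministic thresholds, as in the screen being modelled.
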