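"""Read cleavage sites off up-regulated peptide termini and classify them.

Each non-terminal peptide terminus marks one cleavage event.  Most are
tryptic (the released fragments are re-digested with trypsin before MS);
aspartate-P1 sites are the caspase signature, and their P4-P1 windows are
screened for the DXXD motif families.
"""

from bbcscreen import (
    SimulationParams,
    build_pfm,
    extract_sites,
    generate_proteome,
    plant_substrates,
    simulate_experiment,
    summarize_sites,
)

params = SimulationParams(seed=42)
table, truth = simulate_experiment(params)
proteome = {p.accession: p for p in plant_substrates(generate_proteome(params), params)[0]}

passing = [r for r in table if r.log2_ratio >= 1.8]
sites = extract_sites(passing, proteome)
summary = summarize_sites(sites)

print(f"peptides at log2 >= 1.8:  {len(passing)}")
print(f"unique cleavage sites:    {summary.n_sites}")
print(f"  tryptic (K/R, not -P):  {summary.n_tryptic} ({summary.tryptic_fraction:.1%})")
print(f"  aspartate (P1 = D):     {summary.n_aspartate} ({summary.aspartate_fraction:.1%})")
print(f"  other:                  {summary.n_other} ({summary.other_fraction:.1%})")
print(f"DXXD motifs among D sites: {summary.n_dxxd} ({summary.dxxd_pct_of_aspartate:.1f}%)"
      f" -- DEXD {summary.n_dexd}, DLXD {summary.n_dlxd}, DDXD {summary.n_ddxd}")

aspartate = [s for s in sites if s.enzyme_class == "aspartate"]
tp = sum(1 for s in aspartate if (s.accession, s.position) in truth.true_sites)
print(f"planted-site precision of D sites: {tp / len(aspartate):.3f}")

pfm = build_pfm(aspartate)
p1_top = pfm.frequencies["P1"].idxmax()
p4_top = pfm.frequencies["P4"].idxmax()
print(f"\nPFM over {pfm.n_sites} D-site windows: modal P4 = {p4_top}, modal P1 = {p1_top}")
print("(export with pfm.write_tsv(...) for a sequence-logo renderer)")
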