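# hccnet

Network genomics for small hepatocellular-carcinoma (HCC) cohorts.
`hccnet` is for computational biologists who have per-patient annotated
variant tables (somatic and germline), a STRING-like weighted
protein–protein interaction (PPI) network, and a drug-response grouping,
and who want to go from raw variant calls to per-patient network modules
and a drug-resistance burden test — reproducibly, with every stage
testable against planted synthetic truth.

## What it computes

1. **Rare non-synonymous filtering** — keep variants with gnomAD AF < 0.01
   (missing AF counts as rare) and a protein-altering consequence
   (stop gained, frameshift, splice acceptor/donor, start lost, missense);
   summarize zygosity (homozygotes, unphased compound heterozygotes) and
   match a cancer-predisposition variant catalog.
2. **Per-patient PCST modules** — on the confidence-filtered PPI network
   (combined score ≥ 700; edge cost `c(e) = 1 − score/1000`), each gene
   gets prize `p(v) = (#filtered variants)/(gene length)`, and a
   prize-collecting Steiner tree minimizes

   `o(F) = β · Σ_{v∉F} p(v) + Σ_{e∈F} c(e)`

   — the patient's most economical connected module. Modules are
   aggregated into cohort-level gene frequencies.
3. **RWR guilt-by-association** — random walk with restart
   `p_{t+1} = (1−γ) W p_t + γ p₀` from a bait panel (sorafenib
   pharmacogenes), `W` column-stochastic; the top-k genes form the
   candidate panel.
4. **Resistance comparison** — gene × patient mutation-count matrices on
   the panels, carrier status (≥ 1 qualifying variant) per patient, and a
   two-sided Fisher exact test (point-probability method, exact rational
   arithmetic) between sensitive and resistant groups.

A fully seeded synthetic generator emulates every input (network with a
planted high-prize module, cohort with planted resistant-only enrichment,
DE table, panels, catalog) so the whole pipeline runs and is tested
without any external data. See `docs/methods.md` for the model details
and assumptions.

## Worked example

The package ships the mutation-count tables of a reference cohort of 13
sorafenib-treated HCC patients (3 sensitive, 10 resistant):

```sh
$ hccnet compare --packaged-cohort -o report.json
somatic: 4/10 resistant vs 0/3 sensitive carriers, p = 0.50
germline: 7/10 resistant vs 0/3 sensitive carriers, p = 0.07
```

Reading: 4 of 10 resistant patients carry a somatic non-synonymous
variant in a sorafenib pharmacogene while 0 of 3 sensitive patients do
(two-sided Fisher exact p = 0.50 — no evidence at this size); 7 of 10
resistant vs 0 of 3 sensitive carry rare germline variants in the
sorafenib-associated candidate genes (p = 0.07 — suggestive, limited by
the three-patient sensitive group). `report.json` carries the raw
p-values (0.4965…, 0.06993…), the 2×2 tables, per-patient totals and
carrier lists.

End-to-end on generated data:

```sh
$ hccnet run-all --synthetic --seed 1 -o demo/
pipeline complete; manifest at demo/run_manifest.json
  synthesize: 0.02s
  filter: 0.00s
  network: 0.03s
  pcst: 0.03s
  rwr: 0.01s
  compare: 0.01s
```

`demo/` then contains the filtered variants, one PCST tree per patient
(`pcst_solutions.json`), cohort module-gene frequencies, RWR scores, both
count matrices, the comparison report, and a run manifest with input
checksums — re-running with the same seed reproduces every file
byte-identically. Per-stage CLIs (`hccnet synth|filter|network|pcst|rwr|
compare`) expose the same steps on your own files; β, γ, thresholds and
cutoffs are flags.

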