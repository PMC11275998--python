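# prmkit

Build scheduled parallel-reaction-monitoring (PRM) assays from global
DDA/DIA peptide libraries for nominal-mass quadrupole–linear-ion-trap
instruments, and assess them with matrix-matched calibration curves.

The workflow:

1. **library_io** — read DDA spectrum / DIA chromatogram libraries (flat
   TSV dialects), FASTA databases, target/inclusion/exclusion lists and
   observed-RT tables; write the method-editor inclusion list CSV and a
   scheduling report.
2. **ranking** — score peptides by library signal (DDA: precursor
   intensity; DIA: intensity of the third-largest fragment surviving the
   transition filters) and select diagnostic transitions (b/y series,
   product m/z 200–1500, precursor-window exclusion, terminal trim).
3. **rt_alignment** — robust affine map (median of pairwise slopes) from
   library RTs onto current column conditions using anchors from a recent
   single-injection DIA run.
4. **scheduler** — greedy density-constrained scheduling: most abundant
   peptides first, per-protein caps (typically 3–5), and a hard cap on
   concurrent targets at every instant, checked exactly at interval
   endpoints with half-open windows. Cycle-time arithmetic (per-scan
   maxIIT budgets, points across peak) included.
5. **dimethyl** — mass arithmetic validating the matched-matrix design:
   labeled background precursors (worst case: one single methyl,
   +14.01565 Da) must fall outside every foreground isolation window.
6. **calibration** — per-peptide LoD/LoQ from dilution series: bilinear
   (hockey-stick) fit by log-grid search, LoD at the 2-sigma blank
   crossing, LoQ as the smallest level with bootstrap CV ≤ 20%.
7. **synthetic** — seeded generators for libraries, observed-RT tables and
   calibration curves with ground truth, so everything is testable offline.

## CLI

```sh
# generate synthetic inputs with ground truth
prmkit simulate library --seed 1 --proteins 20 --peptides 6 --out demo/
prmkit simulate rt --library demo/library.tsv --slope 1.05 --intercept 1 --out demo/
prmkit simulate curve --seed 1 --peptides 10 --out demo/

# schedule a PRM assay (10 targets/cycle, 5-minute windows)
prmkit schedule --library demo/library.tsv --dialect dia \
    --fasta demo/proteins.fasta --observed-rt demo/observed_rt.tsv \
    --density 10 --window-min 5 --cycle-s 2 --cap 3 \
    --gradient-min 0 --gradient-max 50 \
    --validate-dimethyl --max-charge 3 \
    --out demo/assay.csv --report demo/report.tsv

# estimate LoD/LoQ figures of merit from a quant table
prmkit calibrate --quant demo/areas.csv --cv 0.20 --boot 100 --seed 17 \
    --out demo/fom.csv
```

`--targets` takes a text file of accessions (one per line; lines starting
with `keyword:` match FASTA descriptions case-insensitively; `#` comments).
All flags can also come from a TOML file via `--config run.toml`. Every run
writes a JSON manifest next to its outputs recording inputs, configuration,
and stage counts.

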