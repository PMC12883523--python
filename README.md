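# nativems

Inference of protein-complex stoichiometry from native mass spectra, built
around the workflow used to characterise phycobiliprotein complexes:

1. **mass_model** — PTM-adjusted average masses of subunits from sequence
   or fixed mass, and combinatorial enumeration of candidate complex
   compositions (oligomer states, variant-subunit substitution, linker
   attachment, cross-source/cross-family protomer mixing).
2. **spectrum_io** — mzML / two-column-text spectrum reading, robust
   MAD-based noise estimation, and peak picking with a 3:1 S/N cut.
3. **deconvolution** — grouping of picked peaks into charge-state series
   via adjacent-peak charge inference, and neutral-mass estimation from
   multiple charge states.
4. **assignment** — matching of experimental masses to enumerated
   compositions under a strict <0.1% mass-error threshold, abundance
   classification (<5% of base peak = low-abundant), presence/absence
   verdicts for queried heterogeneous compositions, and the end-to-end
   pipeline.
5. **sequence_identity** — affine-gap global pairwise alignment
   (BLOSUM62, gap open 10 / extend 0.5) and percent-identity matrices.
6. **synthetic** — seeded generation of subunit inventories and realistic
   charge-envelope spectra with ground truth, including a library of
   canned scenarios mirroring typical experiments.

## CLI

```bash
# simulate a canned scenario (spectrum + subunit FASTA + ground truth)
nativems simulate --scenario fig1b --seed 0 --out-dir sim/

# subunit masses and candidate compositions
nativems masses sim/fig1b_subunits.fasta
nativems enumerate sim/fig1b_subunits.fasta --out compositions.tsv

# peak picking and charge-state deconvolution
nativems peaks sim/fig1b.txt --sn 3.0 --out peaks.tsv
nativems deconv sim/fig1b.txt --z-min 5 --z-max 40 --min-series 3 --out series.tsv

# full pipeline from a YAML config (flags override the file)
nativems assign config.yaml --error-pct 0.1 --sn 3.0 --low-abund 0.05
```

A pipeline config names the inputs and thresholds:

```yaml
fasta: subunits.fasta        # headers: id|species|role[|family]
ptms: ptms.tsv               # subunit_id  ptm_name  delta_mass  count
rules: rules.cfg             # flat key = value assembly rules
spectrum: spectrum.txt       # mzML or two-column text
queries: ["2a11.a21.2b11.b21"]
out_dir: out/
```

Outputs are TSV tables (`compositions`, `peaks`, `series`, `assignments`,
`verdicts`) plus a threshold log on stderr. A `not_detected` verdict means
no charge-state series matched within threshold; it does not assert
absence below the noise level.

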