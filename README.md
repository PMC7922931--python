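# pgpmkit

Tools for two recurring tasks in the design of plant-growth-promoting
microbial (PGPM) inoculants:

1. **Metagenome fragment recruitment** — estimating how well candidate PGPM
   reference genomes are represented in soil, root and rhizosphere shotgun
   metagenomes. Reads are aligned ungapped to each reference with a q-gram
   candidate filter and kept only above a strict identity threshold
   (default > 97 %); reads piling up on abnormally covered loci (conserved
   repeats such as 16S rRNA operons) are removed by a single-pass
   mean + 2·SD coverage rule; surviving counts are normalized to a
   per-billion-read scale, N = R × 10⁹ / T, pooled per environment, and
   presented as average-linkage (UPGMA, Euclidean) clustered heatmaps with
   optional unit-variance row scaling.
2. **Synthetic consortium design** — building multi-strain inoculants from
   pairwise agar-diffusion compatibility tables. Strain pairs score
   `+` (compatible), `-` (inhibition halo) or `nc` (not clear); candidate
   consortia are maximal cliques of the compatibility graph under a strict
   (`+` only) or lenient (`+`/`nc`) policy, filtered to cover a required set
   of plant-beneficial functions (nitrogen fixation, P solubilization,
   biocontrol, amylolytic activity, auxin production, ...). A companion
   table of qualitative prebiotic responses scores four bioactive compounds
   (BS1–BS4) per consortium.

The package ships machine-readable transcriptions of the published strain,
compatibility, biostimulant and consortium tables (with an alias map
reconciling the names each strain goes by across tables), and a synthetic
data generator producing reference genomes, divergence-controlled read sets
with planted coverage peaks, and compatibility matrices with planted cliques
— so the whole pipeline runs and is tested without any external download.

## Worked example

Simulate a two-genome reference panel and three single-sample environments,
run the full recruitment pipeline, and validate a packaged consortium:

```bash
pgpmkit simulate --out sim --seed 7 --n-genomes 2 --genome-length 8000 \
    --n-reads 500 --repeat-copies 2
pgpmkit run-all --refs sim/refs.fasta --metadata sim/samples.tsv \
    --fastq-dir sim --out run --seed 7
cat run/matrix.environments.tsv
```

```
        rhizosphere    root         soil
genome_00  592000000.0  140000000.0  594000000.0
genome_01  162000000.0  574000000.0  144000000.0
```

Each cell is N = R × 10⁹ / T for the environment's pooled samples: soil and
rhizosphere reads were simulated from `genome_00`, root reads from
`genome_01`, and the off-diagonal signal comes from the shared repeat
element plus off-target reads. The run manifest records the per-stage
counts, e.g. for the soil sample: 389 reads recruited, 20 removed by the
coverage-peak filter, 369 qualified.

```bash
pgpmkit validate --consortium MC_A
```

reports all 15 member-pair verdicts of the six-strain consortium MC_A: no
pair is incompatible, exactly one pair — *Paraburkholderia tropica*
MDIIIAzo225 with *Trichoderma harzianum* TH01 — is `nc`, so MC_A passes the
lenient policy and fails the strict one (`"passes_lenient": true,
"passes_strict": false`). The five-strain consortia MC_B and MC_C pass
strict. `pgpmkit score-bs --consortium MC_C` ranks the bioactive compounds:
BS2 supports every member (fraction 1.0) and BS4, unclear for every strain,
ranks last.

Other subcommands (`recruit`, `filter-peaks`, `abundance`, `heatmap`,
`design-consortia`) expose the individual stages; the same functionality is
available as a library (`import pgpmkit`).

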