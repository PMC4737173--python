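# shapeseq

Analysis toolkit for **targeted in-cell chemical probing** (SHAPE-Seq-style)
experiments that measure RNA secondary structure and gene expression from the
same bacterial culture.

In these experiments a cell-permeable reagent (e.g. 1M7, or DMS) acylates the
2′-OH of flexible RNA nucleotides in vivo. Reverse transcription from a
target-specific primer halts one nucleotide before each modification, so
sequencing the resulting cDNA fragments reveals where the RNA was unpaired.
A matched solvent-only (−) channel measures natural polymerase drop-off.
`shapeseq` takes such an experiment from raw paired-end FASTQ all the way to
per-nucleotide reactivities, reactivity-constrained structure models, and
statistics linking ribosome-binding-site (RBS) accessibility to fluorescent
reporter output — and ships a generative read simulator so the entire pipeline
is testable without any external data.

Intended users: RNA synthetic biologists and structural bioinformaticians
analysing small panels of probed RNAs (riboregulators, sRNAs, riboswitches,
endogenous ncRNAs) rather than transcriptome-wide data.

## The model

For each target and channel the experiment reduces to RT-stop counts
`X_1..X_n` (1-based, position 1 = transcription start) plus a full-length
count `X_full`. RT proceeds 3′→5′, so the transcripts *arriving* at site *k*
are those that did not stop at any site > *k*, and the maximum-likelihood
per-encounter stop probability is

```
beta_k = X_k / (sum_{i<=k} X_i + X_full)        (+) channel
gamma_k = Y_k / (sum_{i<=k} Y_i + Y_full)       (−) channel
```

Since a (+)-channel stop is drop-off *or* modification,
`1 − beta_k = (1 − gamma_k)(1 − m_k)`, the modification-attributable signal is

```
raw_k = ln(1 − gamma_k) − ln(1 − beta_k),   truncated at 0,
theta_k = raw_k / sum(raw),                 rho_k = n * theta_k
```

`theta` is the probability distribution of modification across the probed
region; `rho` is the length-normalised reactivity (mean 1), classified as
high (> 1.25), moderate (0.5–1.25) or weak (< 0.5). Reactivities constrain
thermodynamic folding through the standard pseudo-free-energy term
`dG_i = m·ln(rho_i + 1) + b` (defaults m = 1.1, b = −0.3 kcal/mol), applied
through the ViennaRNA Turner nearest-neighbour engine. Structure–function
coupling uses a six-nucleotide sliding-window scan that locates the
Shine-Dalgarno hexamer with the largest ON−OFF reactivity change, paired with
blank-corrected, autofluorescence-subtracted FL/OD expression fold changes.

## Worked example

```python
import numpy as np
from shapeseq import (TargetRNA, RunConfig, random_truth, simulate_stop_counts,
                      simulate_reads, process_read_pairs, ReactivityModel, fold_mfe)

target = TargetRNA(
    "demo",
    "GGACUGCUGAAGGGCAAUCCGCUGAAGCGGAUACGGCGUUCACGCUUAUGGCUAAGGAGGACAGCUAUGAGC"
    "GAUCGUAGCUAGGCUAAGC",
    probed_end=72, rt_primer_start=73, rt_primer_end=91,
)
truth = random_truth(target, seed=1, depth=20_000)
plus, minus = simulate_stop_counts(truth)
reads = simulate_reads(plus, minus, target, seed=2, dimer_rate=0.1)
counts, qc = process_read_pairs(reads, RunConfig(targets=[target]))
print(f"aligned {qc['aligned']}/{qc['total_reads']} reads, "
      f"dimer fraction {qc['dimer_fraction']:.3f}")

result = ReactivityModel(counts["demo"]["plus"], counts["demo"]["minus"], target).fit()
print(result.summary().head(6).to_string(index=False))

fold = fold_mfe(target.probed_sequence, result.rho_profile())
print(fold.dotbracket)
print(f"dG = {fold.free_energy:.2f} kcal/mol ({fold.engine})")
```

prints

```
aligned 40000/44444 reads, dimer fraction 0.100
 position base     beta    gamma    theta      rho    class  observed
        1    G 0.030053 0.009268 0.010855 0.781564 moderate      True
        2    G 0.053670 0.003498 0.026447 1.904190     high      True
        3    A 0.015801 0.005843 0.005154 0.371102     weak      True
        4    C 0.049764 0.000139 0.026061 1.876418     high      True
        5    U 0.019352 0.006083 0.006881 0.495422     weak      True
        6    G 0.025820 0.008702 0.008917 0.642058 moderate      True
........(((.(.(.((((((....))))))..).).)))...............................
dG = -6.70 kcal/mol (ViennaRNA 2.7.2)
```

Every one of the 44,444 simulated reads is accounted for: 10% are flagged as
RT-primer/adapter ligation dimers (exactly the contamination rate that was
simulated) and the remaining 40,000 align and reproduce the simulated stop
counts exactly. `beta`/`gamma` are the per-site stop frequencies of the two
channels; `rho` is the mean-1 reactivity whose class drives the colouring in
reactivity plots (`result.plot()`) and the pairing penalties in the
constrained fold on the last two lines.

A `shapeseq` console script exposes the same workflow from the shell
(`shapeseq simulate | count | reactivity | fold | spikes`).

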