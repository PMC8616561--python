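# ncx — native channel complexome explorer

`ncx` is a Python package for identifying the protein composition of native
membrane-protein complexes from **multi-epitope affinity-purification mass
spectrometry (ME-AP MS)** and for sizing those complexes by **blue-native gel
complexome profiling (csBN-MS)**. It is aimed at interaction-proteomics
practitioners who pull down a low-abundance bait (e.g. an ion channel) with
several independent antibodies, run stringent negative controls
(target-unrelated control antibodies and knock-out material), and need a
reproducible, scriptable route from peptide-level MS1 feature tables to a
table of high-confidence interaction partners and apparent complex masses.

## What it computes

**Label-free MS1 quantification.** Each run's identified peptide features
(peak volumes, PVs) are first mass-recalibrated by the median ppm offset of
peptides matched within a wide 50 ppm window; retention times are pairwise
aligned onto a dynamically recomputed reference (median peptide elution time
over all aligned runs) by robust LOESS regression with an isotonic repair
that preserves elution order; PVs are then assigned to peptides within
±1 min and 3 ppm (configurable 2–3 ppm).

**Protein abundance.** Assigned peptide PVs are summed per protein
(single-peptide identifications are discarded) and normalised by the number
of MS-accessible tryptic peptides (in-silico digest, ≤1 missed cleavage,
700–3500 Da) to give the *abundance norm*, a molar-abundance estimate:

    abundance_norm(p, run) = Σ_peptides PV / #{accessible peptides of p}

**Interactor calling.** A prey is *specific* in a pull-down when its
abundance norm exceeds the worst-case (maximum) negative-control value
≥ 10-fold, or when it was never detected in any control; it is *consistent*
— and called a high-confidence partner — when specifically co-purified by
at least two different antibodies under the same solubilisation condition
(CL-47 or CL-91). Partner abundance relative to the bait is reported per
detergent with the symbols `=` (0.33–3.3×), `<` (0.033–0.33×),
`<<` (0.0033–0.033×), `<<<` (<0.0033×).

**Complexome profiling.** Protein × gel-slice PV matrices (192 slices by
default) are smoothed with a 5-slice sliding average; slice number is
converted to apparent molecular mass by fitting
`log10(M) = d + (a − d) / (1 + exp((s − s0)/b))` through marker complexes of
known mass; each profile peak is reported with its apparent mass and a
half-maximum mass range, next to the sequence-computed mass of an
n-mer (`oligomer_mass`).

Because real studies of this kind start from unpublished in-house feature
tables, the package includes seeded **synthetic-study generators**
(`ncx.simulate`) that plant known partners, abundances, RT drifts, m/z
offsets and complex masses, so the entire pipeline is testable end to end
with no external data.

## Worked example

```python
from ncx import simulate_apms_study, paper_like_apms_config
from ncx.pipeline import run_apms_pipeline

bundle, truth = simulate_apms_study(paper_like_apms_config(seed=1))
result = run_apms_pipeline(bundle, bait_id=truth.bait_id)
print(result.interactors.calls.head(6)[
    ["protein_id", "n_specific_aps", "high_confidence",
     "ratio_to_bait_CL-47", "class_CL-47", "class_CL-91"]
].to_string(index=False))
```

prints

```
protein_id  n_specific_aps  high_confidence  ratio_to_bait_CL-47 class_CL-47 class_CL-91
 PARTNER01              10             True             1.053472           =           <
 PARTNER02              10             True             0.100111           <          <<
 PARTNER03              10             True             0.104549           <          <<
 PARTNER04              10             True             0.117248           <          <<
 PARTNER05              10             True             0.012241          <<         <<<
   BAIT001              10            False             1.000000           =           =
```

All five planted partners — and nothing else — pass both criteria in all
10 target pull-downs; their recovered bait-relative abundances land in the
planted classes, one class lower under the more stringent CL-91 detergent.
The bait itself is kept as the `=` reference row and is not counted as its
own partner.

The same pipeline is available from the shell:

```bash
ncx simulate --preset paper_like_apms --seed 1 --out study/
ncx align --in study/ --out aligned/
ncx quantify --in aligned/ --out quant.tsv
ncx call-interactors --quant quant.tsv --bait BAIT001 --out interactors.tsv
ncx simulate --preset paper_like_complexome --seed 1 --out bn/
ncx complexome --matrix bn/slice_matrix.tsv --markers bn/markers.tsv --out peaks.tsv
```

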