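# ppikit

Toolkit for the scaffolding around heterodimeric protein-complex
structure prediction: building the two-chain multiple sequence
alignments (MSAs) a predictor such as AlphaFold2 consumes, extracting
interface confidence metrics from the predicted models, scoring those
models with **pDockQ** (a predicted DockQ) and — when a native structure
is available — with a self-contained **DockQ** implementation, and
running the evaluation statistics (ROC/AUC, PPV/FDR, success rate,
coupling-signal precision) used to rank models and to call whether two
proteins interact at all.

It is aimed at structural bioinformaticians who run complex predictors
at scale and need the surrounding plumbing to be deterministic,
testable and free of external services: every input the toolkit
consumes can also be generated synthetically (`ppikit simulate`), so
the whole pipeline is exercisable offline.

## The core quantities

**Interface definition.** Two residues from different chains are in
contact when their Cβ atoms lie within 8 Å. `IF_contacts` counts those
residue pairs, `IF_residues` the residues involved, and `IF_plDDT` is
the mean per-residue predicted confidence (plDDT, read from the PDB
B-factor column) over interface residues.

**pDockQ.** Model quality is predicted from the single combined
statistic *x* = IF_plDDT · log₁₀(IF_contacts) through a sigmoid

```
pDockQ(x) = L / (1 + exp(-k (x - x0))) + b
```

with default parameters L = 0.724, x0 = 152.611, k = 0.052, b = 0.018
(fitted against DockQ on a large AlphaFold2 heterodimer benchmark).
`fit_pdockq` re-fits all four parameters to your own (x, DockQ) data by
nonlinear least squares.

**DockQ.** Against a native structure,

```
DockQ = ( Fnat + 1/(1+(iRMS/1.5)²) + 1/(1+(LRMS/8.5)²) ) / 3
```

where Fnat is the fraction of native inter-chain contacts reproduced,
iRMS the backbone RMSD over the native interface after superposing on
it, and LRMS the ligand backbone RMSD after superposing on the
receptor. DockQ ≥ 0.23 is an "acceptable" model; the success rate (SR)
of a model set is the fraction meeting that bar.

**MSAs.** From two per-chain a3m alignments carrying UniProt `OX=`
taxonomy tokens, `pair_by_organism` concatenates the best hit of each
species shared by both chains (exposing inter-chain coevolution),
`block_diagonalize` stacks the two alignments with gap padding on the
partner's columns, and `fuse_msas` merges both views over the shared
concatenated query. Alignment depth is reported as Neff, the number of
sequence clusters at 62% identity.

## Worked example

Everything below runs offline on generated fixtures:

```
$ ppikit simulate msas --seed 11 -o msas
$ ppikit prepare msas/chain_a.a3m msas/chain_b.a3m -o prep
$ cat prep/report.json
{
  ...
  "organisms_paired": [9606, 7227],
  "rows": {"a_filtered": 4, "b_filtered": 4, "paired": 3, "block": 7, "fused": 9}
}
```

The two toy chains share two organisms, so the paired MSA holds the
query pair plus 2 rows, the block-diagonal MSA holds 1 + 3 + 3 rows,
and the fusion 9.

```
$ ppikit simulate decoys --seed 11 -o decoys
$ ppikit assess decoys/decoy_*.pdb --native decoys/native.pdb -o report.csv
$ cat report.csv
model,n_if_contacts,...,pdockq,...,fnat,irms,lrms,dockq,acceptable,top_ranked
decoys/decoy_0.pdb,5,...,0.0248,...,1.0,0.0,0.0,1.0,True,True
decoys/decoy_2.pdb,0,...,0.0,...,0.0,0.9579,2.0,0.5526,True,False
decoys/decoy_5.pdb,0,...,0.0,...,0.0,2.3992,5.0,0.3413,True,False
decoys/decoy_10.pdb,0,...,0.0,...,0.0,4.8115,10.0,0.1693,False,False
...
```

The decoy series rigidly displaces the ligand chain by 0–100 Å: DockQ
decays monotonically from 1.0, models beyond ~8 Å displacement lose all
interface contacts (pDockQ 0.0, interaction call `False`), and the
undisplaced model is ranked top. Scoring one model directly:

```
$ ppikit dockq decoys/decoy_5.pdb decoys/native.pdb
{"fnat": 0.0, "irms": 2.399, "lrms": 5.0, "dockq": 0.341, "acceptable": true}
```

— the 5 Å decoy keeps no native contact (Fnat = 0) but its interface
geometry is close enough that the two RMSD terms still place it above
the 0.23 acceptability bar.

The same operations are available as library calls
(`ppikit.pair_by_organism`, `ppikit.interface_metrics`,
`ppikit.pdockq_score`, `ppikit.dockq_score`, `ppikit.roc_curve`, ...);
see `docs/methods.md` for the scientific conventions behind each.

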