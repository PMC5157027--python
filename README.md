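# ltpminer

Mining and comparative-evolution analysis of the plant **non-specific
lipid transfer protein (nsLTP)** gene family, built around the cotton
(*Gossypium*) family survey workflow: *G. arboreum* (A genome),
*G. raimondii* (D genome) and their allotetraploid descendant
*G. hirsutum* (A\_t + D\_t subgenomes).

nsLTPs are small (~7–10 kDa) secreted plant proteins defined by an
eight-cysteine motif (8 CM) backbone

```
C-Xn-C-Xn-CC-CXC-Xn-C-Xn-C
```

whose four disulfide bonds stabilise a hydrophobic lipid-binding
cavity. The package implements the full identification and
comparative pipeline for this family:

* **Motif scanning** — enumerate every valid assignment of eight
  cysteines to the 8 CM backbone in a mature protein, anchored on the
  CC dipeptide and CXC tripeptide, under per-spacer length bounds.
* **Subfamily classification** — Boutrot-style typing (Types I–VI,
  VIII, IX) from the inter-cysteine spacing table, plus hydropathy
  classes of the CXC central residue and family composition summaries.
* **Candidate screening** — the identification cascade: valid 8 CM,
  not proline-rich, secretory signal peptide present, no GPI anchor,
  no 2S-albumin/amylase-inhibitor similarity, mature length ≤ 120 aa.
  External predictors (SignalP-like, GPI) are consumed as annotation
  flags, never re-implemented.
* **Duplication & synteny** — within-species paralog pairs by global
  alignment, tandem vs segmental calls from chromosome coordinates,
  reciprocal-best-hit (RBH) 1:1 orthologs across species, and
  collinear synteny blocks by order-monotone anchor chaining.
* **Molecular evolution** — Nei–Gojobori (NG86) Ka/Ks on codon
  alignments with equal-pathway averaging and the one-parameter
  correction K = −(3/4)·ln(1 − (4/3)p); selection calls (Ka/Ks < 1 ⇒
  purifying); divergence dating **t = Ks/2r** with r = 2.6×10⁻⁹
  substitutions·site⁻¹·yr⁻¹; Ks-distribution peaks by Gaussian KDE.
* **Gene structure** — intron counts (0–2 in this family) and intron
  offsets relative to the codon encoding Cys8.
* **Expression** — relative qPCR expression by the 2^−ΔΔCT method.
* **Synthetic data** — generators for every input with known ground
  truth: typed nsLTPs, decoys that each violate exactly one screen
  filter, chromosomes with planted tandem/segmental duplications, and
  an allotetraploid merge with controlled subgenome divergence (Ks
  target) and per-subfamily ortholog losses.

## Worked example

```python
from ltpminer import scan_8cm, classify_type, age_mya, ng86_kaks
from ltpminer.molecular_evolution import CodonAlignment

# a mature Type III nsLTP layout: C X9 C X16 CC X9 CXC X12 C X6 C
seq = ("AA" + "C" + "A"*9 + "C" + "A"*16 + "CC" + "A"*9 + "CAC"
       + "A"*12 + "C" + "A"*6 + "C" + "A")
(match,) = scan_8cm(seq)
print(match.spacing)       # SpacingVector(head=2, g12=9, g23=16, g45=9,
                           #               g67=12, g78=6, tail=1)
print(classify_type(match.spacing).label)   # III

# divergence dating from synonymous divergence, t = Ks/2r
print(round(age_mya(0.165432), 4))   # 31.8138  (million years)
print(round(age_mya(0.0180), 2))     # 3.46     (A_t subgenome vs A genome)
```

The spacing vector lists the residue counts between consecutive motif
cysteines (head/tail flank the motif); classification requires at
least four of the five core gaps to match a subfamily's observed set.
An age of 31.81 MY is what a tandem pair with Ks = 0.165 implies under
the neutral rate above; 0.0180 is the Ks peak separating an
allotetraploid subgenome from its diploid progenitor, i.e. a ~3.5 MY
old hybridisation.

A full synthetic study (two diploids with decoys and planted
duplications, plus their allotetraploid) is one command:

```sh
ltpminer simulate --seed 3 --out-dir sim/
ltpminer screen --fasta sim/Ga_proteins.fa --flags sim/Ga_flags.tsv \
    --exclusion sim/exclusion.fa --out sim/screen.tsv
# kept 58/70 candidates          (58 planted nsLTPs, 12 decoys rejected)
ltpminer dups --fasta sim/Ga_proteins.fa --genes sim/Ga_genes.tsv \
    --out sim/dups.tsv           # tandem/segmental calls per paralog pair
```

## Layout

```
src/ltpminer/
  core_io.py             records, FASTA/TSV readers and writers
  motif8cm.py            8 CM scanner
  classification.py      spacing rules, typing, CXC classes, summaries
  screening.py           identification cascade
  duplication_synteny.py paralogs, RBH orthologs, synteny chaining
  molecular_evolution.py NG86 Ka/Ks, dating, Ks peaks
  gene_structure.py      intron offsets relative to Cys8
  expression.py          2^-ddCt
  synthetic_data.py      ground-truth generators
  cli.py                 `ltpminer` command group
  data/                  spacing rules (YAML), curated Ka/Ks table (TSV)
```

See `docs/methods.md` for the underlying models, parameter choices and
known limitations.
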