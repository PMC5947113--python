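# rootmru

Phenotyping of **complex, mature root systems** by mature root units
(MRUs), with a phytohormone variation and association layer — for plant
physiologists and quantitative geneticists who work with *Arabidopsis*
root architecture past the seedling stage.

## The problem and the model

In mature plants several root axes reach comparable length and diameter,
so the classic primary-root / lateral-root trait scheme breaks down: no
single primary root can be identified. `rootmru` instead decomposes a
root system into **mature root units** — one basal *main root* (the
longest base-to-tip axis of the unit) plus its lateral roots (LR) and
secondary lateral roots (2′-LR) — and computes, per plant:

- counts and lengths: MRUN, TRL, TRTN, PRL, LRL/LRN, 2′-LRL/2′-LRN
  (tips counted for axes longer than 0.5 mm),
- densities: TRD = TRTN·TRL⁻¹, LRD = LRN·PRL⁻¹, 2′-LRD = 2′-LRN·TRL⁻¹,
- quarterly lateral distributions LRL-1Q…4Q and LRN-1Q…4Q, each main
  axis split into four equal sections from base (1Q) to tip (4Q).

Hormone tables (pg/mg dry weight; auxin, ABA, GA₉ and cytokinins) are
summarized by the variance percentage **Y = ((X − A)/A)·100** (X:
accession level, A: all-accession mean), its envelope max |Y| and the
fold range between extremes, with LOD censoring. Traits and hormones are
then associated by pairwise-complete Pearson correlation (two-sided p
via t = r√(n−2)/√(1−r²), flags at raw P < 0.05/0.01), PCA of the
correlation matrix, and hierarchical clustering (1 − r distance, average
linkage) exported as Newick.

A seeded synthetic generator emulates the full study design — multi-MRU
architectures with basipetally graded laterals, 13-accession panels with
class-wise hormone variation envelopes enforced exactly, and a latent
factor imposing hormone–trait correlation signs (IAA positive, tZ/ABA
negative) — so every stage is testable end to end. See
`docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
from rootmru import RootAxis, RootSystem, extract_traits

axes = [
    RootAxis(id="A", order=1, length=8.0),                                  # main root, MRU A
    RootAxis(id="A1", order=2, length=2.0, parent_id="A", insertion_pos=1.0),
    RootAxis(id="A2", order=2, length=1.5, parent_id="A", insertion_pos=3.0),
    RootAxis(id="A2s", order=3, length=0.4, parent_id="A2", insertion_pos=0.5),
    RootAxis(id="A3", order=2, length=0.3, parent_id="A", insertion_pos=7.0),
    RootAxis(id="B", order=1, length=5.0),                                  # bare main root, MRU B
]
plant = RootSystem(plant_id="demo", accession="demo", axes=axes)
t = extract_traits(plant)
print(f"MRUN={t.mrun}  TRL={t.trl}  TRTN={t.trtn}  TRD={t.trd:.4f}")
print(f"PRL={t.prl}  LRL={t.lrl}  LRN={t.lrn}  LRD={t.lrd:.4f}")
print(f"LRL per quarter={t.lrl_q}  LRN per quarter={t.lrn_q}")
```

prints

```
MRUN=2  TRL=17.200000000000003  TRTN=6  TRD=0.3488
PRL=13.0  LRL=3.8  LRN=3  LRD=0.2308
LRL per quarter=(2.0, 1.5, 0.0, 0.3)  LRN per quarter=(1, 1, 0, 1)
```

Two basal axes → two MRUs. TRL sums all six axes (17.2 cm); the 8 cm and
5 cm mains give PRL = 13 cm; three laterals (3.8 cm total) yield
LRD = 3/13 ≈ 0.23 laterals per cm of main axis; the laterals insert at
1, 3 and 7 cm of the 8 cm main, i.e. quarters 1Q, 2Q and 4Q.

The full pipeline (simulate → extract → summarize → associate) runs from
the shell and is byte-reproducible for a fixed seed:

```sh
rootmru run --seed 7 --out out/          # synthetic 13-accession study
rootmru extract scans/ --out traits.csv  # or start from RSML files
```

`out/` contains per-plant and per-accession trait CSVs, the hormone
summary (envelopes, fold ranges), correlation matrices with significance
flags, PCA loadings/scores/variance fractions, a Newick dendrogram and a
run manifest whose hash is stamped into every file.

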