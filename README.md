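# ethnoquant

Quantitative ethnopharmacology analysis and multi-marker DNA-barcode
consensus identification, built around the survey design of the Agusan
Manobo medicinal-plant study system (335 key informants, 122 medicinal
plant species, 16 use categories, three localities in Agusan del Sur,
Mindanao).

The package is for ethnobotanists and ethnopharmacologists who need the
standard quantitative workflow as tested, reusable code rather than a
spreadsheet: collapse raw interview citations into use-reports, compute the
relative-importance and consensus indices, compare informant knowledge
across demographic strata, and resolve uncertain specimen identities from
tabular BLAST hits plus pre-sequencing evidence.

## The quantities

The atomic unit is the **use-report (UR)**: one distinct
(informant, species, use-category) triple. An informant naming a plant for
three digestive complaints contributes one digestive use-report; naming it
in two categories contributes two. On top of UR the package computes, per
species or category:

| index | formula | meaning |
|---|---|---|
| use value | UV = UR / N | importance relative to all N informants |
| cultural importance | CIV = Σ_c UR_c / N_p | versatility, relative to the N_p informants citing the plant |
| use diversity | UD = −Σ_c p_c ln p_c | Shannon entropy of a species' reports across categories (nats) |
| informant consensus | ICF = (Nur − Nt)/(Nur − 1) | per-category agreement: 1 = few species carry all reports |
| fidelity level | FL = 100 · Ip / Iu | share of a plant's citers naming one particular ailment |
| species-list overlap | J = C/(A+B) (or C/(A+B−C)) | similarity of two localities' species lists |

Group comparisons of per-informant knowledge scores use two-sided
Mann-Whitney U (exact enumeration for small samples, tie-corrected normal
approximation otherwise) and Kruskal-Wallis H, at the survey's 0.01 level.

The barcode module implements the 5-point score ladder: all hits within
five bit-score points of the best hit are pooled, and the call is
species- / genus- / family-level depending on whether they name one
species, one genus or one family. An *optimized* winner —
max score × (query cover / identity) over the five best distinct-taxon
hits — is carried alongside, and a deterministic consensus step integrates
all markers with dictionary and morphology evidence and a regional
occurrence allow-list.

## Worked example

The published per-category and per-species count tables ship with the
package; every derived cell can be recomputed from them:

```python
from ethnoquant import datasets
from ethnoquant.indices import icf, use_value
from ethnoquant.io import round_half_up

cats = datasets.load_category_table().set_index("abbrev")
for ab in ("DDS", "ASS", "BVP"):
    row = cats.loc[ab]
    print(f"{ab}: Nur={row.n_use_reports}, Nt={row.n_species}, "
          f"ICF={round_half_up(icf(int(row.n_use_reports), int(row.n_species)), 2):.2f}")

species = datasets.load_species_table().set_index("scientific_name")
ur = int(species.loc["Anodendron borneense", "ur"])
print(f"Anodendron borneense: UR={ur}, UV={round_half_up(use_value(ur, 335), 2):.2f}")
```

prints

```
DDS: Nur=6322, Nt=82, ICF=0.99
ASS: Nur=8133, Nt=88, ICF=0.99
BVP: Nur=3588, Nt=61, ICF=0.98
Anodendron borneense: UR=1134, UV=3.39
```

i.e. strong informant agreement in the digestive (DDS), general-symptom
(ASS) and infection (BVP) categories, and a top use value of 3.39 for the
most-cited liana. The same functions run on any citation table you load
with `ethnoquant.io.read_citations` or generate with
`ethnoquant.simulate`.

A command-line layer mirrors the pipeline:

```bash
ethnoquant simulate --seed 5 --n-informants 60 --n-species 25 --out-dir demo/
ethnoquant indices demo/citations.tsv --n-informants 60 --rank-by UV --top 5 --out top5.tsv
ethnoquant groupstats demo/citations.tsv demo/profiles.tsv --n-informants 60 --variable gender
```

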