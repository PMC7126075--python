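# gutaa

Quantifying the gut microbiome's contribution of essential amino acids
(AA_ESS) to mammalian muscle from natural-abundance carbon isotopes.

## The problem

A eukaryotic host cannot synthesize the essential amino acids Thr, Lys,
Phe, Val, Ile, and Leu. Carbon in a muscle AA_ESS must therefore be either
routed intact from dietary protein or supplied by gut bacteria that built
the amino acid de novo from other dietary carbon. When the diet pairs a
C₃-plant protein (casein, δ¹³C ≈ −26.5‰) against C₄-plant carbohydrates
(sucrose −12.2‰, cornmeal −12.0‰), the two pathways carry naturally
distinct isotope labels, and the microbial share of each amino acid can be
estimated from δ¹³C alone — no isotopic enrichment needed.

`gutaa` implements the full quantitative chain for a four-diet mouse
feeding experiment of this design, plus a synthetic-data generator with
known ground truth so every stage is testable without external data:

1. **Derivatization correction** — carbon mass balance removing reagent
   carbon from measured amino-acid derivatives:
   δ_AA = [(n_AA+n_add)·δ_meas − n_add·δ_added]/n_AA.
2. **End members** — per diet and amino acid: the dietary-routing value
   (concentration-weighted casein/corn-protein mixture) and the
   microbial-synthesis value (carbohydrate-pool δ¹³C + per-compound
   fractionation offset Δ).
3. **Two-source mixing** — per mouse, p = (δ_muscle − δ_diet)/(δ_microbe −
   δ_diet), summarized per treatment as mean ± SE over six mice.
4. **Supply vs demand** — dietary amino-acid supply discounted for ileal
   digestibility and first-pass mucosal catabolism (Thr 60%, Lys 50%,
   Phe 45%, Val/Leu 40%, Ile 30%), compared with growth requirements.
5. **Community ecology** — relative abundance, Shannon diversity,
   Bray–Curtis, ANOSIM, PCoA, Spearman rank tests, and db-RDA of the
   muscle amino-acid δ¹³C matrix on leading community ordination axes.

## Worked example

```sh
python analysis/01_simulate_experiment.py --seed 0
python analysis/03_estimate_contributions.py
```

which ends with (seed 0):

```
low-protein diet: Val 63%, Ile 43% of muscle carbon is microbially sourced;
Phe stays at 4% — costly to synthesize, routed from diet.
```

i.e. on the 9% protein / 75% carbohydrate diet, roughly 60% of valine and
40% of isoleucine carbon in muscle came through microbial de novo
synthesis from dietary carbohydrates, while phenylalanine — expensive for
bacteria to build — stayed almost fully diet-routed. `max |error| vs
ground truth: 0.043` on the same run shows the pipeline recovering the
generator's known fractions to within ~4 percentage points at the default
0.5‰ measurement noise. `analysis/05_community_analysis.py` then prints
the community side — Firmicutes means of ~84% and ~65% on the two
low-protein diets against ~50% on the high-protein ones, diet-level
clustering (ANOSIM R = 0.55, p = 0.001), and an adjusted R² ≈ 0.44 for
muscle δ¹³C regressed on community axes.

The same stages run from a YAML config via the CLI:

```sh
gutaa run-all --config config.yaml --seed 0 --out-dir results/
```

with subcommands `simulate`, `endmembers`, `mix`, `supply`, `community`,
and `validate`.

## Layout

- `src/gutaa/` — the library: `correction`, `endmembers`, `mixing`,
  `supply_demand`, `community`, `synthetic`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers for the full analysis.
- `docs/methods.md` — model assumptions, parameter defaults, numerical
  choices, and limitations.
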