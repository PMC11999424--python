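# conjubot

A protocol compiler and virtual executor for semi-automated microbial genetic
engineering on an affordable open-source liquid-handling robot (OT-2 class,
12 deck slots, fixed trash at slot 12). It targets the two workflows that
bottleneck *Streptomyces* engineering campaigns:

1. **Heat-shock transformation of chemically competent *E. coli*** — chill a
   plasmid + cell mix at 4 °C, shock 30 s at 42 °C, dilute into recovery
   medium, one 96-well plate per deck.
2. ***E. coli* → *Streptomyces* conjugation** — mix 150 µL of washed donor
   culture with 150 µL of spore suspension per well, up to 18 donor tubes ×
   30 spore tubes and 192 reactions across two deep-well plates.

It is aimed at lab automation users who want a declarative design file in and
a fully traceable, auditable run out — without writing robot code by hand.

## What it does

From a tab-separated **experiment design** (antibiotics, plasmids, donor and
recipient sources, a mixing pattern with replicate counts), conjubot:

- builds a **deck layout** scaled to the design, and validates the placement
  rules that matter physically: temperature modules only on outer-edge slots
  {1, 3, 4, 6, 7, 9, 10}; a cooling module may not share a grid edge with a
  heating module (it fails to reach 4 °C); partial multi-channel tip pickup
  with a module in slots 1–3 is a head collision;
- compiles a **deterministic step plan**. Heat shock: 8-channel 300 µL head
  at ⅔ speed, air-gapped composite transfers (100 µL media / 30 µL air /
  45 µL of the 52 µL mix, leaving 7 µL behind to avoid bubbles), cooling
  module always activated before the heating module. Conjugation: one
  1000 µL tip per donor source doing repeat-dispense batches of six wells
  per aspiration (6 × 150 + 50 µL overage instead of a blow-out, overage
  returned to the source tube), and a fresh 300 µL tip per spore transfer;
- **replays the plan on a virtual deck**, enforcing tip attachment, tip and
  well capacities and tube dead volumes, conserving liquid exactly, and
  auditing cross-contamination (a tip may only aspirate from a source that
  contains everything non-sterile it has touched; sterile media are exempt);
- renders the **output suite**: consumables BOM (CSV + XLSX, tip counts
  guaranteed equal to the simulated pickups), plate maps (CSV + SVG), a run
  log with user/time/step list, the robot protocol script with an embedded
  machine-readable plan, and a minimum-media report (60 mL LB per donor
  strain: 5 mL preculture + 15 mL expansion + 2 × 20 mL washes);
- computes the **efficiency statistics**: transformation efficiency (CFU/µg),
  apparent conjugation efficiency `exconjugant CFU / spore CFU`, CFU from
  serial dilutions, the PCR **false-positive rate**
  `FP% = ⌊100·negatives/tested⌋₂` (truncated to two decimals, so 6/11 →
  54.54 %), and the corrected ("true") conjugation efficiency

  ```
  true = apparent × (1 − FP/100)   (reported to 3 significant figures)
  ```

## Worked example

```python
>>> import conjubot as cb
>>> design = cb.generate_fixture_design(seed=3, n_ecoli=8, n_strep=8, n_reactions=96)
>>> plan = cb.plan_conjugation(design, user="casey", timestamp="2026-01-05T10:00:00Z")
>>> ledger = cb.execute(plan)
>>> ledger.tip_pickups
{1000: 8, 300: 96}
>>> len(ledger.violations)
0
>>> sorted({round(w.volume_uL, 3) for a, w in ledger.final_wells.items()
...         if a.startswith("slot3:") and w.volume_uL > 0})
[300.0]
```

Eight donor sources consume eight 1000 µL tips; 96 spore transfers consume
96 fresh 300 µL tips; every reaction well ends at exactly 300 µL with its
intended (donor, recipient) pair and the audit finds no contamination.

On the statistics side:

```python
>>> from conjubot import PcrScreen, false_positive_rate, true_efficiency
>>> false_positive_rate(PcrScreen(12, 1))
8.33
>>> true_efficiency(2.96e-3, 54.54)
0.00135
```

A 1-in-12 negative PCR screen is an 8.33 % false-positive rate; an apparent
efficiency of 2.96×10⁻³ corrected for 54.54 % false positives is 1.35×10⁻³.

The same pipeline is available from the shell:

```bash
conjubot plan-conjugation --seed 5 --reactions 10 --out run/ --user casey
conjubot simulate --plan run/plan.json
conjubot stats --in counts.csv --out efficiencies.csv
```

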