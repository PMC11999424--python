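# Methods

## Scope and model

conjubot models a 12-slot liquid-handling deck (3 columns × 4 rows, slots
1–3 nearest the user, fixed trash at slot 12) and compiles two workflows
into explicit step plans: heat-shock transformation of *E. coli* and
*E. coli* → *Streptomyces* conjugation. The package deliberately stops at
the boundary of the liquid-handling run: media preparation, incubation,
streaking, antibiotic overlays and colony PCR are physical acts represented
only as `pause_for_user` / `manual_prompt` steps, and only the pass/fail
outcomes of PCR screens are consumed by the statistics module.

A step plan is a flat list of typed steps (temperature set-points, waits,
tip pickups/drops, aspirates, air gaps, dispenses, mixes, prompts), each
carrying its slot/well address, volume, channel count and speed factor. The
plan embeds the deck layout and the initial deck contents, so a serialized
plan is self-contained: it can be replayed, audited and rendered without the
design that produced it.

## Deck placement rules

Three rules are validated statically, all as hard errors:

- **Module whitelist.** Temperature modules only on slots
  {1, 3, 4, 6, 7, 9, 10} (cable routing restricts them to the deck's outer
  edges).
- **Thermal adjacency.** A cooling module that shares a grid edge with a
  heating module cannot hold 4 °C; the adjacency model is Manhattan
  distance 1 on the 3×4 grid. The shipped heat-shock layout keeps them at
  slots 7 and 9 (same row, one slot apart).
- **Partial-pickup collision.** Picking up fewer than 8 tips on the
  multi-channel head collides with a module in slots 1–3. The shipped
  planner only ever picks full columns, so this check is a safeguard for
  user-built layouts; it is exposed as a validator flag.

Deck scaling for conjugation: deep-well plates at slot 3 then 2 (second
plate only past 96 reactions), 50 mL racks (6 tubes each) at slots 4→6,
15 mL racks (15 tubes each) at slot 9 then 8, 1000 µL tips at slot 7,
300 µL tips at slot 11 then 10. The capacity report follows from labware
arithmetic: 18 donor tubes, 30 spore tubes, 192 reactions at full build.

## Heat-shock plan

Volumes per well: 50 µL competent cells + 2 µL plasmid DNA (52 µL mix);
45 µL of the mix is carried forward at each stage, leaving 7 µL behind to
avoid bubble formation; recovery wells are preloaded with 950 µL warm LB, of
which 100 µL is aspirated into the composite transfer, giving a final
recovery volume of 950 − 100 + 100 + 45 = 995 µL. All transfers run at ⅔
pipetting speed (full speed produced droplets/bubbles at these volumes), and
the cooling module is always activated before the heating module (the
reverse order leaves the cold block unable to reach 4 °C). The 30-min chill
runs on-deck at 4 °C; the 42 °C shock lasts 30 s.

Both moving transfers are air-gapped: the final recovery transfer is the
canonical composite (aspirate 100 µL media, 30 µL air, 45 µL shocked mix,
dispense all), and the cold→hot transfer uses a leading 30 µL air gap with
the same 45 µL draw. Whether the intermediate transfer needs the gap is
ambiguous at the bench; emitting it for both is harmless (75 µL ≪ 300 µL
tip) and is flagged in the step notes.

**Partial columns.** Sample counts are rounded up to whole 8-well columns so
the multi-channel head always picks a full tip column. In simulation, the
default initial contents load reagents into *all* wells of each processed
column: the head pipettes whole columns regardless, and padding wells as
reagent blanks keeps every aspirate well-defined. Consequence: reagent
consumption is counted per column of 8, not per sample — which matches what
the bench user must actually load.

Tip budget: 3 pickups of 8 tips per column (mix-in, shock transfer,
recovery transfer); tips are never reused across phases (conservative
anti-carryover default; the 4 °C mix tips in particular are not reused at
42 °C).

## Conjugation plan

Each reaction is 150 µL donor + 150 µL spores = 300 µL in a deep-well well
(2 mL capacity), filled column-major on the slot-3 plate first. Donor
transfers use one 1000 µL tip per source: batches of up to six wells are
served per aspiration, drawing `150·k + 50` µL — six is the largest batch a
1000 µL tip can carry with overage (6·150 + 50 = 950), and the 50 µL
overage replaces the blow-out (which sprays material) — with the overage
returned to the same source tube before the next draw. Returning to the
tube the liquid came from cannot contaminate. Spore transfers take a fresh
300 µL tip per reaction; this is the contamination-critical step.

An optional sterile 2xYT pre-dispense phase (off by default, since spores
are already suspended in 2xYT) runs before each source's donor transfers
and reuses its tip for them — legal because sterile-media contact is exempt
from the contamination rule. The media tube occupies the next free 50 mL
rack position, so the option caps donor sources at 17.

Media accounting: 60 mL LB per donor strain (5 mL preculture + 15 mL
expansion + two washes with an equal 20 mL volume); 2xYT per spore tube =
150 µL × reactions served + dead volume. Tube dead volumes are 500 µL
(50 mL tubes) and 100 µL (15 mL tubes) — conservative defaults, not
measured values. Source-volume checks compare a tube's stated fill against
its peak draw (net draws + one transient overage + dead volume).

## Virtual execution

Wells hold per-material volume maps; aspiration removes a proportional
slice of the mixture, so liquid is conserved exactly (the ledger reports
the largest per-material imbalance; tests require ≤ 1e-9 µL, observed 0 up
to float rounding). Air gaps are an inert compressible phase: they count
against tip capacity, are vented at dispense, and are excluded from
conservation and contamination. Dispenses move liquid first and vent air
for the remainder; residual liquid in a dropped tip goes to the trash
inventory. Hard failures (aspirating with no tip, drawing below dead
volume, overfilling a tip or well, addressing an empty slot) raise typed
`ExecError`s with the first offending step.

The contamination audit is a post-hoc scan of aspirate events: a violation
is any aspirate whose source's material set does not contain every
non-sterile material the tip has touched (on either aspiration or
dispense). Sterile materials default to {LB, 2xYT, water, TE}.

An independent oracle cross-checks the whole pipeline in the tests: final
deep-well composition is recomputed directly from the mix pattern (150 µL
of each member, column-major placement) without going through the planner
or executor, and must match exactly.

## Statistics

- Transformation efficiency: `colonies / fraction_plated / (ng/1000)`
  CFU/µg.
- Apparent conjugation efficiency: exconjugant CFU / recipient spore CFU,
  the latter estimated by serial dilution
  (`count × dilution × 1000/plated_µL` CFU/mL).
- False-positive rate: `100 × negatives / tested`, **truncated** (not
  rounded) to two decimals. Truncation is the convention that reproduces a
  6-of-11 screen as 54.54 % (rounding would give 54.55 %) and is consistent
  with 8.33 % and 45.45 %.
- Corrected ("true") efficiency: `apparent × (1 − FP/100)`, reported to 3
  significant figures. This multiplicative form reproduces four of the six
  published-style corrected values exactly from their (apparent, FP) pairs;
  where a source corrects unrounded per-replicate values before averaging,
  the last printed digit can differ by one unit (e.g. 1.61 vs 1.62 ×10⁻³
  from the rounded average 2.96×10⁻³ at 45.45 %). Screens with 11 rather
  than 12 evaluable reactions are taken at face value (one failed PCR), not
  re-imputed.

All statistics are pure functions, exact on rational inputs up to the two
stated rounding rules; exact percentage truncation uses `fractions.Fraction`
to avoid binary-float artifacts.

## Determinism and problem sizes

Every compiler and renderer is a pure function of its inputs; identical
designs produce byte-identical plans, scripts, BOMs, plate maps and run
logs (timestamps are caller-supplied, never read from the clock). The
fixture generator is seeded `random.Random`; a seed fully determines the
design. The test suite's randomized sweeps use 25 designs (unit level) and
200 designs (acceptance level) spanning 1–18 donors, 1–30 recipients and
1–192 reactions — chosen as a broad yet quick census of the design space;
the whole suite runs in a few seconds on one CPU.

## Known limitations

- No thermal or kinematic physics: temperature set-points are instantaneous
  in simulation, warm-up and incubations are explicit wait/pause steps, and
  collision modelling is limited to the static validator rules.
- The robot script targets the Opentrons Python API v2 convention as a text
  dialect; equivalence is judged by the embedded plan round-trip, not by
  driving hardware, and the API labware names are plausible defaults rather
  than calibrated definitions.
- Fixture designs emulate structure (sources, patterns, replicates), not
  biology: passing the property suite demonstrates planner/executor
  correctness and contamination safety, not wet-lab efficiency.
- Well fill order (column-major) and the design-table column schema are
  package conventions; the underlying workflow publishes neither.
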