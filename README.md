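# organodyn

Quantitative comparison of early neural development between ape species in
brain organoids. During the first weeks of telencephalon organoid culture,
neuroepithelial (NE) progenitors expand by symmetric division, constrict
their apical endfeet, and transition into neurogenic radial glia; the human
transition is delayed relative to gorilla, and human progenitors cycle
faster. `organodyn` implements the three bespoke computations such a
comparison needs, each runnable end-to-end on synthetic data with known
ground truth:

1. **Cross-species temporal transcriptome comparison** (`organodyn.exprpipe`)
   — bulk RNA-seq time courses from two species over a shared ortholog list
   are TPM-normalized, filtered (abundance > 10 TPM in every replicate at
   some timepoint; > 1.5 fold-change between some pair of timepoints;
   replicate z-score discordance D ≤ 6), z-scored per replicate as
   z_i = (x_i − μ)/σ, and pooled into one fuzzy c-means soft clustering
   (k = 10, fuzzifier m = 2) so cluster labels are comparable across
   species. A gene whose per-species majority clusters differ has *shifted*
   its temporal program; a gene whose replicate label sets are disjoint has
   shifted *robustly*. Per-cluster gene-set enrichment uses the
   hypergeometric upper tail with Benjamini-Hochberg correction, and
   species-exclusive enriched terms form a weighted arc graph between
   cluster pairs.
2. **Progenitor/neuron growth model** (`organodyn.growth`) — a discrete
   daily recursion with f divisions per day (f = 24 h / cell-cycle length):
   symmetric expansive phase p_t = p_{t−1}·2^f, then a mixed neurogenic
   phase p_t = p_{t−1}·r_a + p_{t−1}·r_s·2^f and n_t = n_{t−1} + p_{t−1}·r_a,
   where r_a (= 1 − r_s) is the asymmetric-division fraction. When two runs
   differ only in f over a w-day window, the final-count ratio is exactly
   2^(Δf·w) — independent of the starting pool, total duration and
   r_a schedule.
3. **Apical-lumen morphometry** (`organodyn.lumen3d`, `organodyn.morpho`) —
   lumens are segmented per z-slice from an apical-marker (ZO1) stack,
   boundary vertices are localized sub-pixel on the fluorescence ridge,
   contours are linked across slices and banded into a triangle mesh whose
   summed triangle areas give the lumen surface area; plus shoelace apical
   footprints, nuclear apicobasal positions, volume:surface ratios and
   fold-reduction summaries.

`organodyn.synthgen` generates every input — negative-binomial count
matrices with planted temporal archetypes and species shifts, lumen shell
phantoms with analytic surface areas, and division-event tracks.

## Worked example

Measure cell cycles from tracked divisions and predict the demographic
consequence of the species difference:

```sh
organodyn simulate tracks --out demo/h --mean-hours 18.831 --sd-hours 0 --n-cells 5 --seed 1
organodyn simulate tracks --out demo/g --mean-hours 22.099 --sd-hours 0 --n-cells 5 --seed 1
organodyn grow --out demo/grow --tracks-a demo/h/tracks.csv --tracks-b demo/g/tracks.csv
```

which prints `p ratio 1.922, n ratio 1.922` and writes
`demo/grow/summary.json`:

```json
{
  "cycle_hours": {"a": 18.831, "b": 22.099},
  "f": {"a": 1.2744941851202805, "b": 1.0860219919453369},
  "p_ratio": 1.9216704744777198,
  "n_ratio": 1.9216704744777198
}
```

The 18.831 h vs 22.099 h cell cycles convert to 1.274 vs 1.086 divisions
per day; applied over the 5 days the species' morphotype schedules differ,
both the progenitor and the neuron pool end up 2^(0.188·5) ≈ 1.9-fold
larger in the faster-cycling species — for *any* choice of the other model
parameters.

The transcriptome pipeline on synthetic data with 20% planted shifts:

```python
from organodyn import SynthExprConfig, simulate_counts, run_pipeline
from organodyn.synthgen import score_shift_recovery

cfg = SynthExprConfig(n_genes=2000, timepoints=(3, 5, 10), seed=1)
cm, truth = simulate_counts(cfg)
res = run_pipeline(cm, term_map=truth.term_map, k=10, m=2.0, seed=1)
print(score_shift_recovery(res.shifts, truth))
```

prints `{'sensitivity': 0.9725, 'precision': 0.9284..., 'n_called': 419.0,
'n_planted': 400.0}`: 389 of the 400 planted cross-species shifts are
recovered with 30 false calls, and the heaviest arc of the term-shift graph
connects the planted archetype pair (4 → 7).

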