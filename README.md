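# tubulekit

Quantitative analysis of microtubule dynamic instability and doublet
microtubule geometry, with a matched simulator so every estimator can be
validated by parameter recovery.

Microtubule-associated proteins such as the SAXO-family protein MAP6d1
stabilise microtubules by inducing *pauses* (phases in which the end
neither grows nor shrinks), promote the assembly of doublet microtubules
(an incomplete B-tubule grafted onto a complete A-tubule at the outer
junction), and localise to the proximal part of neuronal primary cilia.
Quantifying those behaviours takes three different measurements, and
`tubulekit` implements all of them for people running in vitro TIRF
reconstitution assays, cryo-ET tubule tracing, or ciliary
immunofluorescence:

1. **Kymograph dynamics.**  End trajectories are segmented into growth /
   shrink / pause phases and summarised by the four standard
   dynamic-instability parameters — growth speed `v_g`, shrinkage speed
   `v_s`, catastrophe frequency `f_cat` (events per growth time) and
   rescue frequency `f_res` (events per shrink time) — plus pause
   frequency and durations.  A pause is a segment whose speed is
   strictly below 0.24 um/min at the plus end (0.12 at the minus end).
   Includes tubulin-dilution stability classification (persistent pause /
   pauses with small catastrophes / slow depolymerisation) and
   rescue-at-junction counting.
2. **B-tubule curvature.**  Traced B-tubule coordinates are rigidly
   registered on their O–X landmarks (A-tubule centre, outer junction),
   curvature radii are measured per point triplet and per trace, groups
   are compared, and ring-shaped density slices are measured with the
   two-circle (outer + inner surface) method.
3. **Ciliary profiles.**  Fixed-width line profiles are normalised to
   0–100% length and % of channel maximum, averaged as mean ± SEM, and
   scored for proximal enrichment; cilium lengths are summarised per
   group.

A seeded event-driven simulator (three-state continuous-time Markov
chain with a seed boundary), a TIRF-style kymograph renderer (PSF +
Poisson noise) and generators for arcs, ring slices and profiles provide
ground truth for everything; see `docs/methods.md` for the model and the
estimator details.

## Worked example

Simulate one 30-minute plus-end movie, render it at SNR ~10, and run the
full analysis chain on the rendered image:

```python
import numpy as np
import tubulekit as tk
from tubulekit.pipeline import _static_trace

params = tk.DynParams(v_g=1.2, v_s=18.0, f_cat=0.4, f_res=6.0,
                      f_gp=0.3, f_pg=2.0)          # um/min and 1/min
trace = tk.simulate_end(params, duration=1800.0, x0=15.0, rng_seed=1)
kymo = tk.render_kymograph(trace, _static_trace(1800.0, 2.0), tk.KymoSpec(),
                           rng=np.random.default_rng(1))
observed = tk.extract_end_position(kymo, side="right")
segments = tk.segment_trace(observed, tk.SegmentationParams(min_segment_frames=2))
summary = tk.estimate_dynamics(segments, min_speed_event_duration=6.0)

print(f"v_g   = {summary.v_g:.2f} um/min")
print(f"v_s   = {summary.v_s:.1f} um/min")
print(f"f_cat = {summary.f_cat:.2f} /min   ({summary.n_catastrophes} catastrophes)")
print(f"f_res = {summary.f_res:.2f} /min   ({summary.n_rescues} rescues)")
print(f"pauses: {summary.n_pauses}, mean duration "
      f"{np.mean(summary.pause_durations):.0f} s")
```

prints

```
v_g   = 1.16 um/min
v_s   = 17.9 um/min
f_cat = 0.31 /min   (8 catastrophes)
f_res = 3.76 /min   (8 rescues)
pauses: 4, mean duration 35 s
```

One microtubule gives noisy frequencies (8 events here, so `f_cat` and
`f_res` carry ~35% relative standard error); pooling many traces with
`tubulekit.pipeline.pooled_dynamics` — which also applies the
detection-limit corrections described in the methods note — recovers the
generating parameters to a couple of percent at n = 500.

The same operations are available from the shell:

```bash
tubulekit simulate --config sim.json --seed 1 --out run/
tubulekit analyze-kymo --traces run/traces.csv --out run/analysis/
tubulekit curvature --traces arcs.csv --method triplet_mean --out curv/
tubulekit profile --profiles profiles.csv --out prof/
```

Every command takes `--seed` and writes a provenance record (config
hash, seed, version) next to its outputs.

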