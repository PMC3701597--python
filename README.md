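# fincam

Open-codend underwater-video fish counting, species identification, and
the factorial trawl-survey statistics it feeds.

## The problem

Delicate, endangered fishes such as the delta smelt (*Hypomesus
transpacificus*) rarely survive capture in a closed trawl codend. An
imaging codend replaces the closed bag with an open-ended viewing
chamber: a backlit grayscale camera (1600 x 1200 px, 60 fps) watches
fish pass freely through the net, so each individual is counted and
identified without handling. `fincam` implements that software chain
end to end, together with the count models used to analyse the
resulting survey:

1. **synthetic_video** — ground-truthed scenes of fish-shaped
   silhouettes (tapered body + species-specific fins, including adipose
   fins and the threadfin's trailing dorsal filament) crossing the
   chamber under configurable turbidity (NTU) and sensor noise.
2. **vision** — gradient-contour detection (temporal-median background
   subtraction, gradient magnitude, hysteresis threshold, morphological
   closing, hole fill, connected components) and constant-velocity
   nearest-neighbour tracking; one completed track = one counted fish.
3. **features** — the silhouette descriptor vector: object size, the
   seven Hu invariant moments (sign-preserving log scale), aspect
   ratio, defect from a pure ellipse, RMS deviation from normalized
   species templates, and a radial local pattern (normalized
   centroid-to-boundary radius profile).
4. **classifier** — an RBF-kernel SVM with Platt probability
   calibration producing a species label and a confidence per track,
   plus standard and inverted (train on 1/k, test on the rest) k-fold
   cross-validation.
5. **trawl_pipeline** — per-sample counts under a 2^3 factorial design
   (tide x horizontal position x depth stratum), densities per
   10,000 m^3 of flowmeter volume, depth-stratum assignment, and the
   open-codend survival accounting.
6. **count_models** — log-linear count regressions with a log-volume
   offset, written out from first principles: Poisson, quasi-Poisson
   (Pearson dispersion phi, Var = phi*mu), negative binomial NB2
   (Var = mu(1 + mu/theta)), and zero-inflated negative binomial
   (intercept-only logit zero mass pi); AIC = 2k - 2 logL comparison
   with the "within 2 units is negligible" rule, the (y-mu)^2-vs-mu
   dispersion diagnostic, Wald tests, a seeded count simulator, and
   exact noncentral-t / Monte-Carlo power analyses for the factorial
   design.

## Worked example

```python
import numpy as np
import fincam as fc
from fincam import classifier as clf, features as ft
from fincam import synthetic_video as sv, vision as vz

species = sv.default_species()
entries = (
    sv.FishEntry(species["delta_smelt"], 0, (60.0, -30.0), (0.0, 7.0)),
    sv.FishEntry(species["threadfin_shad"], 6, (210.0, -30.0), (0.0, 7.0)),
)
scene = sv.SceneSpec(duration_s=1.2, fish=entries, turbidity_ntu=20.0, seed=7)
frames, truth = sv.render_scene(scene)

tracks = vz.link_tracks(vz.detect_sequence(frames))
print(vz.count_passages(tracks), "fish counted;",
      truth.species_totals, "in ground truth")

templates = [ft.make_template(n, sv.species_silhouette(s, 0, 1.5).astype(float),
                              sv.species_silhouette(s, 0, 1.5))
             for n, s in species.items()]
pair = {k: species[k] for k in ("delta_smelt", "threadfin_shad")}
model = clf.train(clf.build_silhouette_library(pair, templates, 100, seed=0))
for ident in clf.identify_tracks(model, tracks, templates):
    print(f"track {ident.track_id}: {ident.species} "
          f"(confidence {ident.confidence:.2f})")
```

prints

```
2 fish counted; {'delta_smelt': 1, 'threadfin_shad': 1} in ground truth
track 0: delta_smelt (confidence 0.96)
track 1: threadfin_shad (confidence 0.93)
```

Both fish crossing the chamber are detected, linked into one track
each, and identified to species with high confidence — the full chain
from raw pixels to a catch record.

On the statistics side:

```python
from fincam import count_models as cm, trawl_pipeline as tp

print(tp.survival_summary(142, 55).percent_survived)          # 72
print(round(cm.power_pairwise(cm.PowerSpec(7, 2.1, 4.0)), 3)) # 0.956
```

A survey that sees 142 of 197 fish pass through alive has 72% survival,
and seven replicates per treatment with a count SD of 2.1 give ~95%
power to detect a pairwise difference of four fish.

A `fincam` console script exposes the same steps as subcommands
(`simulate`, `detect`, `track`, `train`, `classify`, `crossval`,
`count`, `summarize`, `fit-counts`, `power`); see `fincam --help`.

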