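# biofoulmon

Early biofouling detection for reverse-osmosis (RO) membrane processes.

Biofouling — microbial growth on the membrane and feed spacer — is the
dominant failure mode of RO desalination, and by the time conventional
online indicators (feed-channel pressure drop, permeability) react, the
biofilm is already protected by its extracellular matrix and nearly
impossible to clean. This package implements the computational side of two
complementary early-warning monitors plus the classical process metrics, so
that onset, plateau and cleaning efficacy can be called automatically from
the raw data streams:

* **Image analysis** — time-lapse RGB photographs of the membrane surface
  are aligned by normalized cross-correlation template matching (pure
  integer translation; a 2064×3088 frame becomes a 1937×2913 registered
  frame with the default margins), then each frame's R, G, B layers are
  compared with the clean reference frame by the 2-D Pearson coefficient

      r = Σ (A − Ā)(B − B̄) / √( Σ(A − Ā)² · Σ(B − B̄)² ).

  Growing biofilm turns the white surface brown, so r_blue drops first and
  deepest while r_red stays near 1 — the per-layer split is the indicator.
* **Fiber transmission** — polymer optical fibers in the feed channel lose
  transmitted intensity as deposits form; the toolkit models and analyses
  the conditioning decay, the daily temperature cycle, the fouling response
  and its plateau, and the stepwise recovery at cleaning-in-place (CIP)
  events.
* **Process metrics** — carbon rate `C˙ = TOC_Ret·V˙_Ret − TOC_Feed·V˙_Feed`
  (mg/h; negative during microbial attachment, positive during detachment)
  and permeability `Pw = V˙_p / (A·TMP_net)` (L m⁻² h⁻¹ bar⁻¹).
* **Onset detection** — a baseline μ ± k·σ rule with persistence, plateau
  detection by rolling least-squares slope, and CIP recovery scoring.

No experimental dataset is distributed, so the package includes a fully
seeded synthetic scenario generator (`biofoulmon.synthetic_data`) producing
camera frames with planted jitter and a white→brown color shift, fiber
transmission traces, and process tables with known phase boundaries — every
stage of the pipeline is testable against planted ground truth.

## Worked example

```python
import numpy as np
from biofoulmon import (
    ScenarioConfig, simulate_image_series, register_series, similarity_series,
    centered_roi, default_margins, carbon_rate, permeability,
)

cfg = ScenarioConfig.scaled(516, 772, seed=42, duration_h=240.0,
                            onset_h=96.0, frame_interval_h=6.0)
frames, coverage, planted = simulate_image_series(cfg)
print(f"{len(frames)} frames of {frames[0].pixels.shape}, "
      f"final coverage {coverage.fraction[-1]:.1%}")

reg = register_series(frames, centered_roi(frames[0].pixels.shape),
                      margins=default_margins(cfg))
exact = sum(1 for a, b in zip(planted,
            zip(reg.offsets['drow'], reg.offsets['dcol'])) if tuple(b) == a)
print(f"registered to {reg.frames[0].pixels.shape}; "
      f"planted jitter recovered exactly on {exact}/{len(frames)} frames")

sim = similarity_series(reg.frames)
final = sim.iloc[-1]
print(f"final Pearson r: red {final['r_red']:.3f}, "
      f"green {final['r_green']:.3f}, blue {final['r_blue']:.3f}")

print(f"carbon rate: {carbon_rate(1.0, 1.0, 11.5, 10.0):+.1f} mg/h")
print(f"permeability: {permeability(1.5, 0.01, 10.0):.1f} L/(m2 h bar)")
```

prints

```
41 frames of (516, 772, 3), final coverage 36.8%
registered to (484, 728, 3); planted jitter recovered exactly on 41/41 frames
final Pearson r: red 0.896, green 0.523, blue 0.307
carbon rate: -1.5 mg/h
permeability: 15.0 L/(m2 h bar)
```

Reading the numbers: the camera wobble was recovered exactly on every frame,
so the similarity series measures surface change, not misalignment. At 37%
biofilm coverage the blue layer has decorrelated to r ≈ 0.31 while red is
still at 0.90 — the white→brown shift in action. The carbon rate of
−1.5 mg/h (equal TOC at 11.5 L/h in, 10 L/h out) is carbon retained in the
module: attachment. Permeability of 15 is 1.5 L/h of permeate through
0.01 m² at 10 bar net TMP.

## Command line

The same pipeline stage by stage, for data on disk:

```sh
biofoulmon simulate --seed 5 --height 516 --width 772 --interval 3 --out scenario/
biofoulmon register --manifest scenario/manifest.csv --roi 226,354,64,64 \
    --margins 32,44 --out registered/
biofoulmon similarity --registered registered/ --out similarity.csv
biofoulmon process --in scenario/process.csv --out derived.csv
biofoulmon detect --similarity similarity.csv --pof scenario/pof.csv \
    --derived derived.csv --out report.json
```

`report.json` holds one onset report per signal (baseline statistics,
detection parameters, onset time or null) and CIP recovery reports when
events are configured.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline end-to-end on a seeded synthetic scenario
(reduced 516×772 frames, 3 h interval): simulation, registration,
per-layer similarity, process metrics, and onset detection, printing the
detected onset times and the indicator ordering, and writes the JSON result
file to `--out`.

## Layout

| module | contents |
| --- | --- |
| `biofoulmon.synthetic_data` | scenario generator: frames, coverage truth, POF and process series |
| `biofoulmon.image_io` | TIFF frames, manifests, BT.601 grayscale |
| `biofoulmon.registration` | template ROI, NCC map, peak, crop, series registration |
| `biofoulmon.similarity` | channel split, 2-D Pearson r, indicator series |
| `biofoulmon.process_metrics` | carbon rate, permeability, series derivation |
| `biofoulmon.onset_detection` | onset/plateau detection, CIP recovery |
| `biofoulmon.pipeline` | end-to-end scenario analysis |
| `biofoulmon.cli` | `biofoulmon` command group |

See `docs/methods.md` for the models, defaults, numerical choices and known
limitations.
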