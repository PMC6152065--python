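# hmwgs

Identification of wheat high-molecular-weight glutenin subunits (HMW-GS)
from RP-HPLC chromatograms combined with SDS-PAGE mobility evidence.

The package implements the full identification procedure as a tested
pipeline:

* **reference model** — per-subunit retention-time (RT) statistics for the
  20 canonical subunits, classification windows (`mean ± k·sd`, default
  `k = 3`), and derivation of the RT-ambiguity groups that RT alone cannot
  resolve;
* **chromatogram** — CSV trace IO and peak detection (moving-average
  smoothing, two-point linear baseline, quadratic apex interpolation for
  sub-grid RT precision, trapezoid areas);
* **gel model** — SDS-PAGE bands as ordinal mobility ranks, with
  co-migration of Bx7/Bx7OE and Dy10/Dy12;
* **caller** — exhaustive peak-to-locus assignment under composition
  constraints, then evidence reduction in fixed order: Glu-B1 pairing →
  gel mobility → peak-intensity (Bx7 vs overexpressed Bx7OE) → Dx→Dy
  linkage; residual ambiguity is flagged, Glu-A1 silence is called null;
* **synthetic data** — a seeded Gaussian-peak chromatogram/gel simulator
  plus packaged cultivar fixtures (16 standards, 38 Korean cultivars, and
  32 prior assignments including the three later-corrected ones);
* **interface** — a `hmwgs` CLI and a batch study driver with JSON reports.

## CLI

```sh
# simulate a trace (and gel lane) for a fixture cultivar
hmwgs simulate --cultivar "Chinese Spring" --jitter 1.0 --seed 7 \
    --out trace.csv --gel lane.tsv

# call the composition of a trace
hmwgs call --trace trace.csv --sample-id "Chinese Spring" --gel lane.tsv \
    --k 3 --oe-threshold 1.5 --window 25:42 --out report.json

# simulate + call every fixture cultivar and compare to prior assignments
hmwgs study --set all --jitter 0 --seed 0 --out study.json

# summarize replicate RTs per subunit (box-and-whisker numbers)
hmwgs summarize --replicates reps.tsv --out stats.tsv
```

Exit codes: 0 success, 1 validation/format error, 2 no consistent
peak-to-locus assignment. Custom reference/pairing/mobility tables can be
supplied as TSV (`--reference`, `--pairing`, `--mobility`); packaged
defaults live in `src/hmwgs/data/`.

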