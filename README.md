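# ripfit

Single-molecule force-spectroscopy analysis for repeat-protein unfolding,
with the ensemble binding assays that accompany a pharmacological-chaperone
study: nanoDSF melting-temperature extraction and fluorescence-polarization
binding fits.

`ripfit` is built for dual-trap optical-tweezers experiments in which a
tandem-repeat protein (a 15-HEAT-repeat, 589-residue scaffold) is pulled at
constant velocity through two 600 bp dsDNA handles.  It covers the complete
analysis chain —

* **extensible worm-like-chain mechanics**: Marko–Siggia with a stretch
  modulus, `F = (kBT/Lp)[1/(4(1−x/Lc+F/K)²) − 1/4 + x/Lc − F/K]`, composed
  in series over handles, folded core and unfolded polypeptide;
* **rip detection**: transitions of a minimum 10 nm size located by a
  compliance-corrected residual against the running elastic baseline, with
  forces quoted as the average over the 0.05 s before each jump;
* **contour-length quantification**: per-branch WLC fits with the handle and
  protein elastic constants clamped (Lp 30 / 0.5 nm, K 500 / 300 pN) and
  only the unfolded contour length free, giving per-transition and
  per-cycle ΔLc;
* **cycle classification**: full refolding vs misfolded (short of 90% of
  the expected 200 nm gain despite ≥ 20 pN) vs locked-unfolded (no ≥ 10 nm
  transition in stretch or relax), plus ΔLc histograms with quadratic peak
  interpolation, Welch t-tests and box-chart statistics;
* **binding assays**: Tm from the extremum of the first derivative of the
  I350/I330 fluorescence ratio, and Kd from the one-site model
  `P = Pmax·C/(Kd + C)` with `P = (I∥−I⊥)/(I∥+I⊥)`;
* **a kinetic Monte-Carlo simulator** of stretch–relax cycles (Bell-model
  block unfolding, quasi-static force balance, 100 nm/s, 100 Hz output)
  that emulates three experimental conditions — no ligand (with a 22%
  misfolding mode from the second pull), a stabilizing ligand (higher
  unfolding forces, no misfolding) and a blocking ligand (33% of molecules
  lock in the unfolded state) — with full ground-truth records, so every
  stage of the pipeline is verifiable without downloading anything.

The science, parameter choices and validation are described in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from ripfit import (SimulationConfig, simulate_cycle, detect_transitions,
                    fit_cycle_branches, cycle_delta_lc)

config = SimulationConfig()
stretch, relax, truth = simulate_cycle(config, seed=42)

transitions = detect_transitions(stretch)          # rips >= 10 nm
fits = fit_cycle_branches(stretch, transitions, config.tether)
result = cycle_delta_lc(transitions, fits, stretch)
for t in transitions:
    print(f"{t.direction}: {t.extension_jump:.1f} nm at {t.force_before:.1f} pN")
print(f"total dLc = {result.total_dlc:.1f} nm")
```

prints, for this seed,

```
unfold: 20.1 nm at 6.7 pN
unfold: 24.9 nm at 5.4 pN
unfold: 20.4 nm at 6.0 pN
total dLc = 199.2 nm
```

three unfolding rips (two small truth flips merged into the detected ones)
and a total contour-length gain of ~200 nm — the signature of all fifteen
repeats unfolding in this pull.  `examples/` holds one short script per
capability (single-cycle analysis, three-condition comparison, Tm
extraction, Kd fitting); each prints its numbers with a line on what they
mean.  A thin CLI mirrors the library
(`ripfit simulate|detect|fit|summarize|tm|fpfit|run-all`).

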