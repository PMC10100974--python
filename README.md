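# gutiron

Iron and heme budgets of gut *Bacteroidetes*, quantified from culture to
microbiome.

*Bacteroides thetaiotaomicron*, a model commensal of the anaerobic human
gastrointestinal tract, is a heme auxotroph: it cannot synthesize the
iron–protoporphyrin IX (PPIX) complex it needs, so it takes heme up from
its environment via the six-gene *hmuYRSTUV* operon, strips the iron
anaerobically, and accumulates both heme and non-heme iron. `gutiron`
implements the quantitative chain that turns routine anaerobic-culture
measurements into a whole-microbiome iron budget, together with the
comparative-genomics scoring used to map the *hmu* operon across
genomes:

1. **Growth kinetics** — OD600 time series are fitted to the modified
   Gompertz model
   `OD(t) = A·exp(−exp(k(λ−t)+1))`, `k = μₘ·e/A`,
   with asymptote *A* (au), maximum specific growth rate *μₘ* (au/h, the
   tangent slope at the inflection point) and lag time *λ* (h, the
   tangent's x-intercept).
2. **Cell accounting** — genome size (6.26 Mbp) fixes the DNA mass per
   cell (6.76 fg) and hence cells per µg DNA (1.48 × 10⁸), letting DNA
   concentration serve as a CFU surrogate; OD maps linearly onto DNA
   (6.0 µg·mL⁻¹·au⁻¹), wet pellet mass (3.4 mg·mL⁻¹·au⁻¹) and cells.
3. **Quantification** — atomic-absorption signals (total iron) and
   LC-Q-TOF-MS extracted-ion chromatograms (heme at m/z 616.17, PPIX at
   563.26) are converted through linear standard curves, dilution and
   volume bookkeeping into nmol per mL culture and pmol per µg DNA.
4. **Reservoir extrapolation** — per-µg-DNA loads scale to a reference
   GI-tract microbiome (3.8 × 10¹³ cells, ≈200 g) to give milligrams of
   total and heme iron and the number of days of host iron absorption
   (1–3 mg/day) the pool could buffer.
5. **Operon analysis** — Needleman–Wunsch global alignment and a ≥30 %
   identity threshold call Hmu homologs; each genome is scored as a
   6-character conservation pattern over {0,1,2} (absent/present/
   duplicated, ordered hmuY…V), and gene coordinates are checked for
   colocalization and order conservation (synteny).

A synthetic-data module forward-simulates every input — noisy Gompertz
curves, calibration series, Gaussian-peak chromatograms, protein
families at controlled identity, and operon layouts — so the whole
pipeline is testable end to end without instruments or databases.

## Worked example

```python
import numpy as np
from gutiron import (GompertzParams, fit_gompertz, extrapolate_iron,
                     buffer_days, heme_fraction)
from gutiron.cells import CellModel
from gutiron.reservoir import MicrobiomeModel
from gutiron.synthetic import gen_growth_curve

# fit a noisy synthetic growth curve (truth: A=1.46, mu_m=0.260, lam=4.94)
params = GompertzParams(A=1.46, mu_m=0.260, lam=4.94)
curve = gen_growth_curve(params, np.arange(0, 30.5, 0.5), noise_sd=0.02, seed=7)
fit = fit_gompertz(curve)
print(f"A = {fit.params.A:.3f} au, mu_m = {fit.params.mu_m:.3f} au/h, "
      f"lag = {fit.params.lam:.2f} h")

# a culture holding 380 pmol iron and 140 pmol heme per µg DNA …
print(f"heme fraction: {heme_fraction(140.0, 380.0)} %")

# … scaled to a 3.8e13-cell microbiome of 6.26-Mbp genomes
model = MicrobiomeModel(cell_model=CellModel(genome_bp=6.26e6))
total = extrapolate_iron(380.0, model)
lo, hi = buffer_days(total)
print(f"microbiome iron: {total:.2f} mg")
print(f"absorption buffer: {lo:.1f}-{hi:.1f} days")
```

prints

```
A = 1.461 au, mu_m = 0.249 au/h, lag = 4.88 h
heme fraction: 36.8 %
microbiome iron: 5.45 mg
absorption buffer: 1.8-5.4 days
```

so a recovered fit within noise of the generating parameters, 37 % of
cellular iron held as heme, and a ~5.5 mg community iron pool worth a
few days of host absorption.

The same flow is available from the shell:

```bash
gutiron run-all --seed 1 --out demo_run/   # growth → quantify → reservoir
gutiron simulate-growth --out plate.csv
gutiron fit-growth --plate plate.csv --out fits.json
gutiron operon-scan --baits baits.fasta --proteome genomeA.fasta --out scan.json
```

## Layout

- `src/gutiron/growth.py` — Gompertz model, fitting, lag geometry, OD regressions
- `src/gutiron/cells.py` — genome-based cell accounting, heme fraction
- `src/gutiron/quant.py` — calibration curves, EIC extraction, peak integration, unit conversion
- `src/gutiron/reservoir.py` — microbiome model and extrapolation
- `src/gutiron/operon.py` — alignment, homology calls, patterns, synteny
- `src/gutiron/synthetic.py` — forward simulators for every input
- `src/gutiron/io.py`, `pipeline.py`, `cli.py` — formats, orchestration, CLI
- `docs/methods.md` — models, assumptions, numerical choices, limitations
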