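# etamsim

Stochastic simulation of many RNA polymerases (RNAPs) co-transcribing a
highly expressed gene, with the polymerases mechanically coupled through the
torque stored in the helically twisted DNA between them.

On an *rrn* operon of *E. coli* dozens of RNAPs elongate simultaneously at
~90 nt/s, yet single-molecule work shows that an isolated RNAP pauses every
~100 bp for 1–5 s — which should produce traffic jams, not the fast, regular
transcription that is observed. `etamsim` implements a mechanistic
explanation: every translocation of an RNAP twists the DNA segments that
connect it to its neighbors, and the resulting torque feeds back on each
RNAP's hop rate, pause probability and pause duration. A trailing RNAP
over-twists the DNA behind a paused leader and pushes it back into
elongation; a leader pulls its trailer forward. The package is intended for
computational biophysicists studying transcriptional traffic, cooperativity
and supercoiling-mediated coupling.

## Model

Polymerases are 35-nt footprints on a 1-D lattice, entering at rate
`α·β`, hopping forward one nucleotide with exponential waiting times, and
leaving at rate `γ·β` (an exclusion process with open boundaries). The DNA
between the 17-nt transcription bubbles of two neighbors is an elastic rod;
shortening it from its relaxed length `L0` to `L` stores the torque

    τ(L) = (μ π² r⁴ / pitch) · ln(L0 / L)          [pN·nm]

with shear modulus `μ = Y / 2(1+ν) = 300 pN/nm²`, Poisson ratio
`ν = B/C − 1 = −0.5`, rod radius `r = 1 nm` and helical pitch 10.5 bp. The
net torque on polymerase *i* is `τᵢ = τ(Lᵢ) − τ(Lᵢ₊₁)`, clamped to the
melting/stall range `[−10, +10] pN·nm`. Measured single-molecule response
curves map torque to elongation velocity `V(τ)`, pause probability per step
`F(τ)` and pause duration `D(τ)`; velocities are scaled by
`K = β / V(0)` so a torque-free RNAP moves at `β = 90 nt/s`. Freezing the
three responses at their zero-torque values recovers a TASEP (totally
asymmetric simple exclusion process) with constant-rate pauses, which serves
as the non-cooperative control. A mean-field reduction
`v(ρ) = C·ln(1 + 2L0(ρ0 − ρ)) + β` links the model to car-following traffic
theory.

## Worked example

Simulate three replicates of each model at the top of the study's
initiation-rate grid and compare the censored summary statistics:

```python
from etamsim import build_config, run_simulation, summarize, derive_seed

def pooled(model, n=3):
    runs = [run_simulation(build_config(
        0.0115, 1000.0, derive_seed(7, 0, model, r), model,
        record_intervals=False)) for r in range(n)]
    return summarize(runs)

for model in ("tasep", "etam"):
    s = pooled(model)
    print(f"{model:6s} time={s.mean_transcription_time:6.1f} s  "
          f"pauses/RNAP={s.pauses_per_rnap:7.1f}  "
          f"pause={s.mean_pause_duration:.3f} s  "
          f"collisions/RNAP={s.collisions_per_rnap:6.1f}")
```

Output from one run of this snippet:

```
tasep  time= 151.2 s  pauses/RNAP=   69.5  pause=0.568 s  collisions/RNAP= 540.4
etam   time= 103.4 s  pauses/RNAP= 2233.7  pause=0.031 s  collisions/RNAP= 184.2
```

The torque-free control pauses ~70 times per transcript for ~0.57 s each and
piles up hundreds of collisions, taking ~150 s per 5450-nt transcript. With
torque coupling the polymerases pause thirty times *more often* but for only
tens of milliseconds — neighbors push each other out of pauses — and
transcribe in ~100 s, close to the ~60 s pause-free limit plus the residual
delay. Crowding *helps*: at low initiation rates the torque-coupled model is
slower than at high rates.

A command-line interface mirrors the library:

```bash
etamsim simulate --alpha 0.0115 --tmax 1000 --seed 7 --model etam --replicates 3
etamsim sweep --alphas 0.0001,0.0025,0.0115 --replicates 5 --tmax 2000 --out-dir runs/
etamsim meanfield --sensitivity 3 --spacing 100
```

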