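# pilsync

Simulation and analysis of a delay-differential model of
**brassinosteroid–auxin crosstalk through PILS auxin-transport
facilitators** in the *Arabidopsis* root.

Brassinosteroid (BR) and auxin signaling each close a delayed negative
feedback loop — BR synthesis is repressed by the delayed BZR homodimer
(BZR^D), and Aux/IAA repressors transcribed by the delayed ARF homodimer
(ARF^D) sequester ARF — so both pathways can oscillate on their own. PILS
proteins couple them: BZR^D represses *PILS* transcription
(competing with ARF^D activation in one saturating promoter term) and BR
promotes PILS degradation, while PILS in turn restricts nuclear auxin.
The core questions this package lets you explore computationally are
whether that coupling **phase-locks** the two hormone oscillators, how
PILS dosage (loss of function vs overexpression) and BR-pathway mutants
(*bri1-6*, *bzr1-d*) change the synchrony, and what the standard reporters
(pPILS transcription, 35S-driven PILS protein, DR5, DII) should read out
under 24-epibrassinolide (BL) treatment.

The model is ten species (μM, hours) with one shared delay τ = 10 h,
e.g. the BR and PILS equations:

```
dBR/dt   = Φ + α_BR / (1 + k_BR·BZR^D(t−τ)) − δ_BR·BR
dPILS/dt = α_bP + α_pAF·k_AF·ARF^D(t−τ) / (1 + k_AF·ARF^D(t−τ) + k_BZ·BZR^D(t−τ))
           − PILS·(δ_PIL + δ_PBR·BR)
```

It is intended for systems biologists studying hormone-signaling
crosstalk and for anyone needing a compact, fully seeded example of a
delayed-feedback oscillator pipeline: constant-lag DDE integration
(method of steps, adaptive Dormand–Prince 5(4) with dense output),
peak-based phase-difference synchrony scoring, grid + Monte-Carlo
parameter estimation against ratio observations, a ±25% robustness scan,
and a synthetic-data generator — no external data required.

## Worked example

```python
import pilsync as ps

params = ps.ParameterSet()                      # calibrated reference set

# 1. simulate wild type for 300 h from rest and count signaling peaks
traj = ps.integrate(params, ps.ScenarioSpec(), t_end=300.0)
for sig in ("BZR_dimer", "ARF_dimer"):
    pk = ps.find_peaks(traj.times, traj.signal(sig), transient_cutoff=100.0)
    print(f"{sig}: {len(pk)} peaks, mean period {pk.periods.mean():.1f} h")

# 2. does the BR->PILS coupling align the two pathways?
from pilsync.protocols import ONSET, run_scenario
runs = {
    "coupled": run_scenario(params, ps.ScenarioSpec(), ONSET),
    "uncoupled": run_scenario(params, ps.ScenarioSpec(pils_feedback=False), ONSET),
}
print(ps.synchrony_compare(runs, transient_cutoff=50.0)[["scenario", "dispersion"]])

# 3. predicted reporter responses to BL treatment
bl, ctl = ps.ScenarioSpec(treatment="BL"), ps.ScenarioSpec()
for kind in ("pPILS_transcription", "PILS_protein_35S", "DR5", "DII"):
    r = ps.predict_ratio(kind, bl, ctl, params)
    print(f"{kind}: BL/control = {r.value:.3f}")
```

prints

```
BZR_dimer: 6 peaks, mean period 30.2 h
ARF_dimer: 5 peaks, mean period 40.1 h
    scenario  dispersion
0    coupled    0.149826
1  uncoupled   83.939401
pPILS_transcription: BL/control = 0.961
PILS_protein_35S: BL/control = 0.952
DR5: BL/control = 1.058
DII: BL/control = 0.918
```

Reading the output: both signaling outputs oscillate (the settling
wild-type run still mixes ~30 h early cycles into the BZR^D count; the
locked period is ~40 h). The coupled model keeps the ARF^D/BZR^D peak
offset essentially constant (dispersion 0.15 h), while cutting the
BR → PILS coupling (k_BZ = 0, δ_PBR = 0) leaves the two pathways drifting
apart (dispersion 84 h) — PILS is what aligns them. Under BL, both PILS
reporters are repressed, the auxin-output reporter DR5 rises and the
auxin-input reporter DII falls, matching the expected response directions.

The same stages are available from the shell:

```bash
pilsync simulate --scenario pils_triple+BL --t-end 300 --out out/
pilsync synchrony --traj-dir out/ --out out/
pilsync generate-data --seed 1 --sigma 0.05 --out data/
pilsync fit --observations data/observations.csv --preset bri1_6 --seed 1 --out fits/
pilsync sensitivity --seed 1 --n-draws 100 --out scan/
```

Every run writes a `provenance.json` with the effective configuration and
seeds; identical seeds give byte-identical outputs.

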