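# gaitsim

Simulation of the brainstem–spinal circuits that control locomotor speed
and gait in quadrupeds, with the full analysis battery around it:
continuation (bifurcation) sweeps over stimulation strength, gait
classification from inter-limb phase differences, noisy gait-probability
maps, inhibitory-stimulation drive grids and connection-weight robustness
analysis.

## The science

Mice control how fast they run — and which gait they use — through
brainstem commands. Glutamatergic neurons of the cuneiform nucleus (CnF)
drive the full speed range including the synchronous escape gaits (gallop,
bound), whereas the pedunculopontine nucleus (PPN) supports only slow
alternating gaits (walk, trot); both act on the spinal cord through the
lateral paragigantocellular nucleus (LPGi) of the reticular formation.
`gaitsim` implements a rate-model connectome of this system: each of the 84
populations is an activity-based unit `C dV/dt = -I_NaP - I_L - I_SynE -
I_SynI - I_Noise` with piecewise-linear output `f(V)`; the four spinal
rhythm generators (flexor/extensor half-centres, one per limb) burst via a
slowly inactivating persistent sodium current `I_NaP = g_NaP m∞(V) h (V -
E_Na)`, and commissural (V0_D, V0_V, V3) and long propriospinal pathways
coordinate the limbs. Stimulation enters as a linear drive `D(α) = mα + b`,
`α ∈ [0, 1.05]`. Two descending pathways separate function: LPGi-Glu-1 →
rhythm generators sets frequency; LPGi-Glu-2 → inhibitory dIni relays →
V0 commissural neurons sets gait, so rising CnF drive simultaneously speeds
the rhythm and releases left–right synchronisation: walk → trot → gallop →
bound.

See `docs/methods.md` for the equations, the calibrated parameters and the
model's known limitations.

## Worked example

```python
import gaitsim as gs
from gaitsim import engine

net = gs.build_default_network()           # reference connectome, 84 populations
stim = gs.Stimulation(gs.DriveLaw("CnF-Glu", "left", m=1.35, b=3.95))
for alpha in (0.1, 0.45, 1.05):
    res = engine.settle_at_alpha(net, stim, alpha, seed=1)
    h, f, ho, di = res.phases
    print(f"alpha={alpha:4}: {res.frequency:5.2f} Hz  "
          f"hindLR={h:.2f} foreLR={f:.2f} homo={ho:.2f} diag={di:.2f}  -> {res.gait}")
```

prints (settling each strength from rest):

```
alpha= 0.1:  5.59 Hz  hindLR=0.50 foreLR=0.50 homo=0.34 diag=0.84  -> walk
alpha=0.45:  7.79 Hz  hindLR=1.00 foreLR=0.00 homo=0.43 diag=0.43  -> bound
alpha=1.05: 10.71 Hz  hindLR=0.00 foreLR=0.00 homo=0.47 diag=0.47  -> bound
```

At weak left-CnF stimulation the limbs alternate at ~5.6 Hz (walk: both
left–right phase differences at 0.5); at strong stimulation they
synchronise (bound: phases at 0/1) near 11 Hz. Cold starts at mid strength
land in the coexisting bound state — the walk→trot→gallop→bound staircase
and its hysteresis appear under *continuation*, warm-starting each step
from the last:

```python
diagram = engine.bifurcation_sweep(net, stim, n_steps=100)
print(diagram.max_frequency())             # ~10.7 Hz
print(diagram.up[["alpha", "frequency_hz", "gait"]])
```

The command line mirrors the library:

```bash
gaitsim sweep --stim CnF-Glu:left --reduced --out results/cnf
gaitsim noisy-sweep --stim CnF-Glu:left --noise 1.0 --out results/noisy
gaitsim grid --in-target PPN --reduced --out results/grid
gaitsim export-network --out network.yaml
```

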