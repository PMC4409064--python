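# striatal-dtt

Models of action selection in the striatum, the input stage of the basal
ganglia.  The package asks a single question: given the measured asymmetric
connectivity between D1 ("Go") and D2 ("No-Go") medium spiny neurons and
the feedforward inhibition from fast spiking interneurons (FSIs), when does
the network's output bias tip from the direct to the indirect pathway?

The answer is a **decision transition threshold (DTT)**: a cortical input
rate λ_CTX^tran at which the population-rate difference

    Δ_MSN = λ_D1 − λ_D2

changes sign from positive (Go bias) to negative (No-Go bias).  The package
implements, tests and cross-validates two models of this threshold, plus
the machinery to modulate it:

* **Mean-field rate model** — λ̇_D1 = −0.01·λ_D1 + S(J·λ + input) with the
  saturating transfer S(z) = z/√(z²+1); closed-form fixed points of the
  linearized balance, exact decompositions of Δ_MSN (Inp_str/Inp_add,
  D1_eff/D2_eff/comm_eff), Jacobian stability, and DTT sweeps
  (`striatal_dtt.meanfield`, `striatal_dtt.dtt`).
* **Spiking network** — 2000 + 2000 conductance-based LIF MSNs and 80 FSIs
  with alpha synapses, measured connection probabilities and peak
  conductances, numba-accelerated (`striatal_dtt.spiking`).
* **Correlated cortical input** — a two-layer multiple-interaction process
  (MIP) controlling within-pool (W) and between-pool (B = B′·W) input
  correlations at constant rate (`striatal_dtt.correlated_inputs`).
* **Protocols** — dopamine scaling of the cortical gains, GPe inhibition of
  FSIs, symmetric-FSI variants, correlation grids with W_opt extraction,
  robustness scans (`striatal_dtt.experiments`), and a CLI (`striatum-dtt`).

It is intended for computational neuroscientists studying basal-ganglia
action selection, and as a compact, fully tested reference implementation
of the striatal threshold mechanism.

## Worked example

```python
import numpy as np
from striatal_dtt.meanfield import EffectiveWeights, ScenarioInput
from striatal_dtt.dtt import sweep_delta_msn
from striatal_dtt.experiments import run_dopamine_scan

w = EffectiveWeights()          # reference striatal weights (J11 … JC2)
res = sweep_delta_msn(w, ScenarioInput("multiplicative"),
                      grid=np.arange(0.0, 20.01, 0.1))
print(res.dtt, res.n_crossings, res.direction)
# 13.009983468231209 1 pos_to_neg

print(run_dopamine_scan(alphas=(-0.005, 0.0, 0.005), weights=w))
#    alpha        dtt  n_crossings  dtt_effective
# 0 -0.005  11.074380            1      11.074380
# 1  0.000  13.009983            1      13.009983
# 2  0.005  15.775824            1      15.775824
```

The first call sweeps the multiplicative scenario (D1 cortical gain 1.06
vs 1.0 for D2, FSI rate following cortex) and finds exactly one
positive→negative crossing of Δ_MSN at ≈ 13 Hz: below it D1 MSNs outfire
D2 MSNs and the striatum is Go-biased, above it the asymmetric inhibition
wins and the bias flips to No-Go.  The dopamine scan scales the cortical
gains by (1 ± α): depletion (α < 0) pulls the threshold down, shrinking
the Go regime; extra dopamine pushes it up.

The same threshold exists in the spiking network (at ≈ 20 Hz per afferent,
each neuron pooling 250 afferents):

```bash
striatum-dtt spiking-sweep --seed 1 --out results/
# {"dtt": 20.950200343445907, "n_crossings": 1}
```

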