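# tertbn

Boolean threshold-network modelling of the **TERT** (telomerase reverse
transcriptase) transcriptional regulatory neighbourhood.

Telomerase expression in cancer cells is controlled by a dense web of
transcription factors acting on the TERT promoter. `tertbn` implements a
synchronous Boolean network model of that neighbourhood — built from a
cell-based reporter screen rather than literature curation — together with
the full analysis toolkit around it: exhaustive statespace enumeration,
in-silico knockout/overexpression scans, bit-flip noise analysis,
coherent feedforward-loop module extraction, and random network-ensemble
statistics. It is aimed at systems biologists studying transcriptional
stability and at anyone who needs a tested, reproducible implementation of
threshold Boolean network analysis for small signed gene networks.

## The model

Each gene *j* carries a binary state σ_j ∈ {0, 1}. All nodes update
synchronously under the activation-dominant threshold rule

σ_j(t+1) = 1 ⟺ Σ_i ω_ij · σ_i(t) ≥ φ_j,  with φ_j = 0,

where ω_ij = +1 for an activating and −1 for a repressive interaction.
A node is switched off only when strictly more of its active inputs repress
than activate it; an input-free node is constitutively on. Constitutive
perturbations ("rule-table mutations") clamp single nodes on or off while
they continue to feed downstream sums.

The packaged canonical network has 15 nodes (AR, JUN, TP53, SP1, E2F1,
MYCN, MXD1, RELA, MYC, FOS, HIF1A, SP3, STAT3, NR2F2, TERT) and 92 signed
interactions (50 activating / 42 repressive), inferred from a transfection
screen under the cutoffs FC ≥ 1.5 (up) or ≤ 1/1.5 (down) with p < 0.01,
plus the single retained STAT3 → TERT activation. A 16-node variant adds
ETS2 (gain-of-function modelling of TERT promoter mutations), and a variant
without the STAT3 → TERT edge is included.

Because the update is a function on the finite set of 2^N system states,
the statespace is a functional graph whose weak components are basins of
attraction, each containing one attractor (steady state or limit cycle).
`tertbn` enumerates all 2^15 = 32768 transitions by brute force in well
under a second.

## Worked example

```python
import tertbn as tb

net = tb.canonical_tert_network()
space = tb.enumerate_statespace(net, tb.RuleSet.basal())
for b in space.basins:
    print(b.size, b.attractor.cycle, b.attractor.target_class,
          "longest transient", b.longest_transient)
```

prints

```
20156 (24375,) stable_on longest transient 9
12612 (24373,) stable_on longest transient 8
```

Every one of the 32768 states flows into one of two TERT-on steady states
(basins of 20156 and 12612 states; the two fixed-point encodings 24375 and
24373 differ only in the JUN bit), so basal TERT expression is globally
stable: the longest route back to a steady state after any perturbation is
9 update steps. Simulating a GSK3 inhibitor by forcing FOS off and STAT3
on splits the statespace instead into a dominant TERT-off basin (26002
states) and a TERT-on basin (6766 states):

```python
bio = tb.RuleSet.forcing(forced_on=["STAT3"], forced_off=["FOS"])
print([(b.size, b.attractor.target_class)
       for b in tb.enumerate_statespace(net, bio).basins])
# [(26002, 'stable_off'), (6766, 'stable_on')]
```

The same analyses are available from the shell:

```bash
tertbn statespace --network canonical --output-dir out/
tertbn modules    --network canonical --output-dir out/
tertbn attack     --network canonical --seed 1 --output-dir out/
```

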