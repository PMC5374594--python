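# oncocircuit

Boolean logic-circuit analysis of oncogenic signaling networks, built
around a reference model of castration-resistant prostate cancer (CRPC)
signaling.

Cell-fate decisions in signaling pathways are switch-like, so a
gene-regulatory network can be modeled as a *combinational logic
circuit*: genes and proteins are binary nodes, activating edges feed
plain gate inputs, inhibiting edges feed inverted ones. On that
abstraction, three classic circuit-engineering tools become therapy
design tools:

* **Stuck-at faults.** An oncogenic lesion pins a node irrespective of
  its upstream signals — constitutive receptor activation is a
  stuck-at-1, loss of a tumor suppressor a stuck-at-0 — at one of P
  annotated fault sites.
* **Test-vector search.** A targeted inhibitor forces its target line to
  0 (`line AND NOT drug`). For input **x**, drug vector **d** and fault
  set *f*, the circuit computes **z** = ψ(**x**, **d**, *f*); the therapy
  problem is to pick **d** minimizing the Hamming weight ‖ψ‖₁ (the
  number of active proliferative outputs), then the drug count. Across
  all fault combinations the optimal cocktail is
  **d*** = argmin_d Σ_{j=1}^{C−1} ‖ψ(**x***, **d**, f_j)‖₁.
* **Reliability analysis.** A node's *vulnerability* is the probability,
  over random inputs, that the circuit output differs when the node is
  dysfunctional. It is estimated with stochastic logic: probabilities are
  encoded as bitstreams (non-Bernoulli streams with an exact count of
  ones), propagated through the fault-free and faulty circuits, combined
  with XNOR → AND → NOT, and decoded — and cross-checked against exact
  2^N enumeration.

The bundled CRPC netlist (`oncocircuit/data/prostate_crpc.json`) wires
the ERBB/IGF receptor layer, MAPK cascade, PTEN/NKX3.1-controlled AKT
axis, mTORC1 arm and androgen-receptor axis into such a circuit with
N=7 inputs, M=6 proliferation markers, P=24 fault sites and 7 drugs
(Lapatinib, Cixutumumab, AZD6244, BKM120, AZD5363, Temsirolimus,
Enzalutamide). `oncocircuit/data/TRANSCRIPTION_NOTES.md` documents how
the wiring is pinned down by its benchmark results, and
`oncocircuit.reference.validate_reference_network` re-derives every
benchmark from the netlist.

## Worked example

Best therapy per fault (full 128-vector search at the non-proliferative
input x* = 0000110, where only the tumor suppressors PTEN and NKX3.1 are
active):

```text
$ oncocircuit therapy table | head -7
fault  drug_vector  achieved_weight  undrugged_weight  untestable  co_optimal_vectors
1      1000000      0                3                 0           1000000
2      1000000      0                3                 0           1000000
3      0100000      0                3                 0           0100000
4      1000000      0                3                 0           1000000
5      0011000      0                3                 0           0011000
6      0011000      0                3                 0           0011000
```

Row 1 reads: with EGFR stuck on, three proliferation markers are active
(weight 3); applying Lapatinib alone (leftmost drug bit) restores the
all-zero non-proliferative output. Faults 18, 22, 23 and 24 get the
all-zero vector: no drug lies on their fan-out, so no intervention
improves them (they are *untestable*); all except fault 18 remain
minimally proliferative at weight 1, fault 18 at weight 2.

The globally optimal ≤3-drug cocktail over all C−1 = 2324 fault
combinations of up to three simultaneous lesions:

```text
$ oncocircuit therapy cocktail --top 1
drug_vector  drugs                          total_weight
0010101      AZD6244,AZD5363,Enzalutamide   2924
```

i.e. joint MEK + AKT + AR blockade minimizes the summed proliferative
weight (2924 versus 3058 for the runner-up AZD6244+BKM120+AZD5363).

Node vulnerabilities at stream length L = 10⁶ (stochastic) next to the
exact enumeration over all 2⁷ input patterns:

```text
$ oncocircuit vuln | head -4
site  v_stochastic_pct  v_exact_pct
1     6.2902            6.2500
2     6.2902            6.2500
3     6.2902            6.2500
```

Sites cluster at four exact levels — 25% (PTEN/NKX3.1 loss and the AKT
axis), 12.5% (AR axis), 6.25% (receptors, MAPK, PI3K), 1.5625% (mTORC1
arm) — so suppressor-loss/AKT dysfunction is the network's most
vulnerable point and the mTOR arm its least.

`oncocircuit validate` re-checks a netlist against every benchmark
constraint; `oncocircuit run-all -o out/` writes all reports plus a
manifest; `oncocircuit fixture random` generates synthetic netlists.

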