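# Methods

## Model

A signaling network is abstracted as a feedback-free (combinational)
Boolean circuit. Every gene/protein is a binary node; regulatory logic is
expressed with {AND, OR, NOT, NAND, NOR, XOR, BUF} gates, inhibiting
edges as per-input inversions. The model is parameter-free: no kinetics,
no dose–response, no dynamics — outputs are a pure function of inputs.
Its core assumptions are (i) switch-like node behavior, (ii) no feedback
loops (the bundled CRPC model deliberately omits the known feedback in
these pathways), and (iii) lesion effects representable as lines pinned
to a constant.

Three annotations turn the netlist into an analysis substrate:

* **Fault sites.** Site *j* pins line *ℓ_j* to a fixed value: stuck-at-1
  for constitutive activation, stuck-at-0 for suppressor loss. Each site
  carries exactly one polarity — the lesion type that dysfunction of that
  node produces — so P sites yield P single faults, not 2P.
* **Drug points.** An inhibitor on line ℓ rewrites its value to
  `ℓ AND NOT d_i`. One drug may gate several lines (Lapatinib gates all
  three ERBB receptors).
* **Line pipeline.** For each line: raw value → pre-drug faults → drug
  gates → post-drug faults. The pre/post distinction is the single
  convention that decides rectifiability: a pre-drug lesion is killed by
  a drug on its own line, a post-drug lesion is immune. In the reference
  model fault 17 (pre) and fault 18 (post) share the MEK line; this is
  exactly why fault 18 is untestable. Two lesions may occupy the same
  slot only if they agree on the stuck value (the assignment is then
  idempotent); contradictory lesions raise an error.

## Therapy search

For input **x**, drug vector **d** (7 bits, printed order Lapatinib,
Cixutumumab, AZD6244, BKM120, AZD5363, Temsirolimus, Enzalutamide) and
fault set *f*, the output ψ(**x**, **d**, *f*) has Hamming weight equal
to the number of active proliferation markers. Searches are exhaustive —
the spaces are tiny — and exact-integer throughout, so there are no
tolerance questions in any argmin.

* *Per-fault therapy*: minimize weight, then drug count, over the full
  2⁷ = 128-vector space. All co-optimal vectors are retained; the
  lexicographically smallest bit string is reported as canonical. (On the
  bundled model every row's optimum is unique, so the tie-break never
  fires there.) A fault is *untestable* when nothing beats the undrugged
  weight; the record then reports d₀.
* *Global cocktail*: minimize Σ_j ‖ψ(**x***, **d**, f_j)‖₁ over the
  ≤3-drug space (D = 64) and all non-empty fault combinations of
  cardinality ≤ 3 (C − 1 = 2324), reflecting side-effect limits on
  simultaneous drugs and tractable multi-lesion tumors. The per-fault
  table uses the full 128-vector space, the global search the ≤3-drug
  space; both bounds are CLI flags. Fault combinations are enumerated by
  cardinality then label-lexicographically, f₀ first, so reports and
  tie-breaks are reproducible; the ranking orders by (total, drug count,
  bit string).

## Vulnerability

Vulnerability of site *j* is Pr[ψ(**x**, d₀, f_j) ≠ ψ(**x**, d₀, f₀)]
under independent uniform inputs (p = 0.5 per input; ligand-binding
probabilities are unknown, so the uninformative choice is used). No
drugs are applied during this analysis.

*Stochastic estimator.* Each input is encoded as a non-Bernoulli stream
of length L: exactly round(p·L) ones, positions given by a seeded random
permutation. This fixes the marginal input frequencies exactly,
eliminating the encoding component of Monte-Carlo variance (what remains
is propagation noise from the joint patterns). The N streams use
independent child seeds spawned from the master seed; the same streams
feed both the fault-free and the faulty propagation. Outputs are
combined stochastically — XNOR per output pair, AND across the M
outputs, complement — and the resulting stream is decoded by counting
ones. By construction vulnerability + reliability = 1 exactly on the
same streams. Defaults: L = 10⁶, master seed 17 (an arbitrary fixed
default; the seed is logged in every record and report).

*Exact oracle.* For N ≤ 20 inputs, enumerate all 2^N patterns with the
scalar evaluator and count differing ones; the result is a rational with
denominator 2^N. The stochastic path runs on the vectorized stream
engine, the exact path on the scalar evaluator — two independent
implementations of the semantics, cross-checked in the test suite with
the Bernoulli-conservative band 3·√(v(1−v)/L) + 1/L (the non-Bernoulli
streams' true deviation is smaller, so the band is safe; 1/L absorbs
quantization at v near 0 or 1).

On the bundled model the exact vulnerabilities take four values — 1/4
(PTEN/NKX3.1 loss and the AKT chain), 1/8 (AR axis), 1/16 (receptors,
MAPK, PI3K), 1/64 (mTORC1 arm) — with the stochastic estimates at
L = 10⁶ within ±0.0005 of them for every seed tried.

## Reference model and validation

The CRPC netlist ships as data (`data/prostate_crpc.json`), not code, so
wiring corrections never touch the evaluator. Because the source pathway
diagram is qualitative, the gate-level wiring was fixed against the
model's benchmark results, which over-determine it; the reasoning and
the residual (behavior-preserving) freedom are in
`data/TRANSCRIPTION_NOTES.md`. `validate_reference_network` re-derives
every benchmark statement — structure (N=7, M=6, P=24), the
non-proliferative response, all 24 therapy rows, the untestable set
{18, 22, 23, 24} and its weight profile, the cocktail 0010101, and all
24 vulnerabilities within 0.002 absolute — returning an itemized report
(failures are entries, not exceptions). The 0.002 band covers the
printed benchmark values' own Monte-Carlo offset from the exact
rationals at L = 10⁶ (e.g. 24.98% versus 25%). The validator is
mutation-sensitive: single edits (gate-kind flip, stuck-polarity flip,
drug retargeting, moving fault 18 before the drug gate) each trip a
deterministic constraint, which the test suite checks.

## Synthetic fixtures

`random_circuit` draws shallow random DAGs (gates read only earlier
lines, so acyclicity holds by construction) with configurable gate-kind
mix, fault-site and drug-point densities, and outputs biased toward late
lines so most of the circuit is observable. Fixtures emulate the
*structural* variety the analyses must handle — mixed gate kinds,
inverted inputs, drugged and undrugged lines, stuck-at-0 and stuck-at-1
sites — at scales (N ≤ 10) where exhaustive oracles are instant. They do
not emulate biological topology (no scale-free structure, no pathway
motifs), so fixture-based tests certify algorithmic correctness, not
biological realism; realism claims rest entirely on the curated
reference netlist.

## Problem sizes and numerical choices

Default analysis sizes are the benchmark conditions: full 128-vector
space for the per-fault table (24 × 128 evaluations), 64 × 2324
evaluations for the cocktail, L = 10⁶ streams for vulnerability
(24 sites, ~30 uint8 arrays of 10⁶ held at once, well under 100 MB).
In-suite validator runs use L = 10⁵ where only determinism or
mutation-sensitivity is at stake; the acceptance tests rerun the
vulnerability comparison at the full L = 10⁶. Degenerate inputs are
contract errors (empty streams, out-of-range probabilities or
cardinalities, dimension mismatches), never silent clamps.

## Limitations

No dynamics or attractors, no feedback, no probabilistic Boolean
networks, no dose/toxicity model beyond drug count, single-polarity
fault sites, and vulnerability for single faults only. The reference
transcription is validated against its benchmark behavior; transcriptions
that agree on all benchmarks but differ in unobservable syntax cannot be
distinguished by the validator.
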