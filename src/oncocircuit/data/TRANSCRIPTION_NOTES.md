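# Reference netlist: transcription notes

`prostate_crpc.json` encodes the castration-resistant prostate cancer
(CRPC) signaling network — the ERBB/IGF receptor layer, the
RAS/RAF/MEK/ERK (MAPK) cascade, the PI3K and PTEN/NKX3.1-controlled AKT
axes, mTORC1 translation signaling, and the androgen-receptor (AR) axis —
as a combinational logic circuit with 7 primary inputs, 6 proliferation
outputs, 24 numbered fault sites and 7 drug intervention points.

The qualitative pathway diagram this model is based on specifies nodes,
activating/inhibiting edges and drug target points, but not gate-level
wiring. The gate-level netlist shipped here was fixed by requiring that it
simultaneously reproduce **all** machine-checkable benchmark results that
accompany the model (`oncocircuit.reference` re-derives every one of them
from this file at run time; none is hard-wired into the evaluator):

1. the non-proliferative input x* = [0,0,0,0,1,1,0] yields the all-zero
   output in the fault-free circuit;
2. the 24-row best-therapy table (each row's drug vector is the unique
   minimal-weight, minimal-cardinality optimum under the full 128-vector
   drug space — no row relies on a tie-break);
3. the untestable-fault set {18, 22, 23, 24}, with fault 18 the only
   untestable fault of output weight > 1;
4. the globally optimal three-drug cocktail 0010101
   (AZD6244 + AZD5363 + Enzalutamide) under ≤3 simultaneous faults;
5. the exact per-site vulnerabilities, which take only the four values
   1/16, 1/4, 1/8 and 1/64 under uniform independent inputs.

## What pins down what

* **Receptor layer (sites 1–4).** One buffered receptor per growth-factor
  ligand (EGF→EGFR, HBEGF→HER2, IGF→IGF1R, NRG1→HER3), ERBB receptors
  gated by Lapatinib, IGF1R by Cixutumumab. Pinned by therapy rows 1–4 and
  by vulnerability 1/16 = P(all four ligands absent) × P(ligand absent |
  site's own ligand absent) for each receptor.
* **MAPK cascade (sites 5, 6, 16, 17, 18).** GRB2/SOS → RAS → RAF → MEK →
  ERK → {SP1, SRF-ELK1}; AZD6244 gates the MEK line. Fault 18 is the
  *post-drug* lesion of that line (constitutive ERK-level activity):
  placing it downstream of the AZD6244 gate is what makes it untestable
  with weight 2, the only weight->1 untestable fault.
* **PI3K axis (sites 8, 9).** PI3K is fed by RAS and by IRS1 (itself fed
  by IGF1R) and gated by BKM120. PI3K must reach the MAPK cascade
  upstream of the AZD6244 gate (PI3K → RAF crosstalk) — otherwise a
  stuck-on PI3K site could not have vulnerability 1/16, which requires
  certain propagation to an output whenever all growth factors are absent
  — and must reach CDK2/Cyclin E through a route that neither AZD5363 nor
  Temsirolimus blocks (the direct PI3K → CDK2_CYCLINE arm) — otherwise
  therapy rows 5–6 would not uniquely require AZD6244 + BKM120.
* **Tumor-suppressor/AKT axis (sites 7, 10–13).** PIP3 = NOT PTEN,
  PDK1 = PIP3, AKT = PDK1 OR NOT NKX3.1, gated by AZD5363. The loss of
  either suppressor, or constitutive activation anywhere on the chain,
  activates AKT exactly when both suppressors are functional in the
  fault-free circuit — vulnerability 1/4 for all five sites. Growth-factor
  signaling must *not* feed this line: any PI3K → AKT OR-edge would cap
  these vulnerabilities at 1/16. In this model the BKM120 and AZD5363
  targets therefore sit on parallel arms, and "AKT-axis" damage is
  suppressor-loss-driven.
* **AR axis (sites 14, 15).** AR = Androgens OR AKT (ligand-independent
  receptor activation through the AKT crosstalk), gated by Enzalutamide,
  driving PSA and TMPRSS2. Pinned by vulnerability
  1/8 = P(androgens absent) × P(AKT off); any additional OR-input to AR
  (e.g. from PI3K or ERK) would break it.
* **mTORC1 axis (sites 19–23).** TSC = NOR(AKT, PI3K), RHEB = NOT TSC,
  MTOR = RHEB gated by Temsirolimus, then S6K and the
  4E-BP1 ⊣ eIF4E pair feeding CDK2/Cyclin E. Vulnerability
  1/64 = P(AKT off) × P(PI3K off) for all five sites; sites 22–23 sit
  below the Temsirolimus gate, hence untestable with weight 1.
* **Survival arm (site 24).** BAD = NOT AKT, BCL2 = NOT BAD. BAD loss
  fixes BCL2 on — untestable, weight 1, vulnerability 1/4. BCL2 must be
  driven by the AKT arm alone; an AR → BCL2 edge would lower the AKT-site
  vulnerabilities below 1/4.

## Residual freedom

The benchmark results determine the circuit's *behavior* at every fault
site but not every syntactic detail. Behavior-preserving rewrites remain
free, e.g. the length of pure buffer chains (RAS → RAF → MEK could carry
its three sites on differently named intermediate nodes), which of two
equivalent sites on a fan-out-free chain carries which label within the
groups {5,6}, {10,11,13}, {14,15}, {16,17} and {19,20,21}, and whether
inhibiting edges are drawn as inverted gate inputs or explicit NOT nodes
(PIP3, TSC, BAD, 4E-BP1 are explicit here because they are themselves
fault sites). The validator cannot distinguish such transcriptions, and
the labels chosen here follow pathway order. The biological reading of
two reconstruction-determined arms (PI3K → RAF and PI3K → CDK2/Cyclin E)
is RAS-adjacent MAPK cross-activation and mTORC1-independent cell-cycle
entry; they are required by the benchmark constraints as argued above,
but their node-level identity in the source diagram is the least certain
part of this transcription.
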