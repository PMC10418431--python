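# Methods

This note records the models implemented in `jamqspr`, the conventions and
calibrations adopted where the field leaves the definition open, and what
the synthetic-data experiments do and do not establish.

## Molecular descriptors

All descriptors are computed on the hydrogen-depleted molecular graph.
SMILES parsing (implicit-hydrogen filling, aromatic perception, formal
charges) is delegated to RDKit; every descriptor itself is computed by this
package from the extracted atom records and bond list, so each quantity has
one auditable definition.

Conventions that matter:

* **Atomic masses** are the two-decimal table H = 1.01, C = 12.01,
  O = 16.00 (N = 14.01, F = 19.00 for completeness). This is deliberate:
  it reproduces the reference molecular weights of the jam components
  exactly (glucose 180.18, not the IUPAC 180.156).
* **Valence delta.** δᵛ = (Zᵛ − q − h) / (Z − Zᵛ − 1), with Zᵛ the
  valence-electron count of the neutral element, q the formal charge and h
  the attached-hydrogen count; the denominator is 1 for all second-row
  atoms. Subtracting the charge makes the flavylium ring oxygen δᵛ = 5,
  which is the value that reproduces the reference X1Av = 0.297 of the
  anthocyanin core (δᵛ = 6, i.e. ignoring the charge, gives 0.295).
* **Anthocyanin structure.** The anthocyanin component is fixed as the
  flavylium (2-phenylchromenylium) cation C15H11O⁺, the aromatic core
  common to anthocyanidins; its formula mass (207.26), hydrogen count (11)
  and every connectivity index match the reference column. A saturated
  bicyclic SMILES sometimes quoted for "anthocyanin" encodes C15H26O⁺ and
  is kept only as a parse-only fixture.
* **nHDon** counts donor *hydrogens* on N/O (water = 2), not donor heavy
  atoms.
* **Single-atom molecules** return 0 for all bond-sum descriptors (the
  water column) rather than NaN.
* **Distances** are all-pairs shortest-path bond counts (scipy's BFS-based
  `shortest_path` on the adjacency matrix); disconnected pairs carry the
  sentinel −1 and never enter a descriptor sum.

### Calibrated descriptors

Dragon's exact parameterisations of XMOD, P_VSA_p_1, SAtot, VvdwMG and PDI
are proprietary, and no tested closed form reproduced the reference rows
(for XMOD we tried the plain and valence Randić-weight variants, H-included
degrees and several bond-sum hybrids). These five are therefore shipped as
additive per-atom contribution models calibrated to the five reference
component columns, and are flagged `calibrated` in the descriptor-vector
metadata:

* **XMOD**: per skeletal atom c₀ + c₁·δ + c₂·[O] + c₃·h (four
  coefficients, exactly determined by the four bonded reference
  molecules); molecules without skeletal bonds are defined as 0.
* **Bulk descriptors**: one contribution per atom class, where a class is
  (element, formal charge, skeletal degree, hydrogen count, aromaticity).
  The five reference count vectors are linearly independent over the 12
  classes, so the minimum-norm least-squares solution reproduces the
  reference columns to machine precision. A physically-motivated
  McGowan-style form for VvdwMG (atomic volumes minus a per-bond constant)
  was evaluated and rejected: it misses the water value by ~10%.

The parameter tables live in `src/jamqspr/data/bulk_contributions.json`
and are regenerated by `python -m jamqspr.calibration`. Consequence of the
calibration design: these five descriptors are reliable interpolations for
C/O molecules built from the calibrated atom classes, and raise an
`UnsupportedElementError` outside them — they are not general-purpose
reimplementations.

## Mixture features

A jam is a five-component mixture over water, citric acid, glucose,
sucrose and anthocyanin; the jam-level descriptor is the mass-fraction
weighted average MD_jam = Σ w_c·MD_c with Σ w_c = 1 (fractions are
renormalised over these five components; pectins, gum, pH and acidity are
separate covariates). The network input is exactly ten ordered features.
The study never enumerates which ten; the default here is an explicit,
overridable choice: the six tabulated covariates (time, %HM, %LM,
%xanthan, pH, acidity) plus the four mixture descriptors with the highest
variance over the dataset. Features and targets are min–max scaled to
[−1, 1] (matched to the tanh hidden units; constant columns map to 0, and
the scaler parameters are retained to invert predictions before deviations
are computed).

## Stability screening

One-way fixed-effects ANOVA per (formulation, property):
F = MS_between/MS_within with df (k−1, N−k), compared strictly against the
upper-5% F quantile computed from the data's actual degrees of freedom
(scipy). A compatibility flag reproduces published comparisons that quote
a single tabulated critical value (3.240, which corresponds to F(3,16));
note the analytic-day triplicate design actually gives F(3,8) = 4.066 —
the module always reports the df it used. Regressions are ordinary least
squares on replicate means per time (a switch allows raw replicates), with
R² = 1 − SSE/SST; low-R² fits are reported, never filtered. Anthocyanin
quantification is Beer–Lambert with ε = 26 900 L mol⁻¹ cm⁻¹ and
MW = 449.2 g/mol (cyanidin-3-glucoside equivalents), reported as
mg per 100 g.

## Network predictor and training

Architecture: 10 inputs, one or two tanh hidden layers, linear 3-output
layer (hardness N, water activity, adhesiveness mJ). Training is exact
Levenberg–Marquardt on the total squared error: the residual Jacobian is
assembled by backpropagation (verified against finite differences to
1e-10), and the damped normal equations (JᵀJ + λI)Δ = −Jᵀr are solved with
λ starting at 10⁻³, ×10 on rejected steps, ÷10 on accepted ones, capped at
10¹⁰ (hitting the cap returns a converged-with-warning status). Stopping:
absolute improvement in total SSE below 10⁻⁴ between accepted iterations,
or 500 iterations. Initial weights are uniform on [−0.5, 0.5] (seeded);
biases start at zero. The accepted-step loss history is non-increasing by
construction.

Protocol choices fixed here because the source protocol leaves them open:
multi-restart training (default 50 restarts; each restart reseeds the
weights only, not the split) selects the run with the lowest maximum
absolute percent deviation on the testing subset; the architecture search
ranks candidates by maximum absolute deviation on the prediction subset,
ties broken by average deviation, then by parameter count. The deviation
metric uses the predicted value in the denominator, as the published
tables define it; `denominator="experimental"` gives the conventional
form.

## Synthetic data generator

The generator emulates the study conditions, not the chemistry: for each
formulation × time × replicate it draws property = a + b·t + N(0, σ) from
the published linear models (hardness FA/FB/FD, adhesiveness all four,
anthocyanins FB/FC/FD, reducing sugars FC, soluble solids FA/FC, water
activity FC), with constant means where no model was published (e.g. FC
hardness 6.80 N, flat, mirroring its non-significant F test). Default
noise: hardness 0.05 N, water activity 0.005, adhesiveness 0.5 mJ,
anthocyanins 1.0 mg/100 g, sugars/solids 0.5 — chosen once to match the
scatter visible across the published record excerpts. pH and acidity are
drawn uniformly inside the tabulated per-formulation ranges, shared by the
replicates of a batch. Compositions are fixed profiles (conventional
≈ 67 °Brix: 33% water / 45% sucrose / 21.5% glucose; light ≈ 37 °Brix with
half the sucrose) with ±2% relative jitter, renormalised.

The default grid is every other day over 0–120 (61 times, which includes
the analytic days 0/30/90/120) in triplicate = 732 records, trimmed
deterministically to 680 by dropping third replicates at the latest
non-analytic days round-robin over formulations; the true sampling
schedule behind "680 points" is not documented anywhere, so this grid is a
stand-in with the right totals, not a reconstruction. The noise stream is
consumed for trimmed records too, so the retained values do not depend on
the trim. All randomness derives from one master seed; a rerun is
byte-identical.

**What passing tests show — and don't.** The generator produces exactly
linear means with Gaussian, homoscedastic, independent noise. Passing the
recovery and screening tests therefore demonstrates that the statistical
machinery and the training loop are correct, and that the study's
qualitative significance pattern follows from its published effect sizes
at these noise levels. It says nothing about real jams: no syneresis
kinetics, no batch effects, no heteroscedasticity, no measurement drift.
Likewise the teacher–student experiment (a 10-30-10-3 teacher labelling
the synthetic features, σ = 0.01 noise in scaled units, student recovered
to ~0.1% average deviation) validates the learn/test/predict machinery,
not the published deviation tables, whose underlying data and trained
weights are unavailable.

## Problem sizes

The shipped experiments use the full study-scale dataset (680 records,
585/55/40 split, 10-30-10-3 network, 3 restarts — a run takes seconds, so
no reduction is needed there). Scaled-down choices made as package
defaults: the ANOVA null calibration uses 2000 simulated series; the
cross-seed recovery and power checks use 30–60 seeds; the pipeline
determinism check runs with 1 restart and a short iteration budget, since
byte-level determinism is independent of the training budget. The
architecture-search unit test uses a rank-3 input subspace (mimicking the
strongly collinear jam covariates) so the wide network generalises from
140 learning points.

## Known limitations

* The five calibrated descriptors are interpolations anchored on five
  molecules; they are exact there by construction and should not be read
  as independent predictions.
* Only H, C, N, O, F are supported in the descriptor layer (L and mass
  tables); the calibrated descriptors are narrower still (C/O classes).
* Eq.-style percent deviations blow up near zero responses; the deviation
  routine refuses zero denominators rather than reporting unstable
  numbers.
* No post-hoc means separation (Tukey) and no multiple-testing correction
  across properties: the screen mirrors the published analysis, which
  applies none.
* The LM implementation forms JᵀJ explicitly; it is intended for networks
  of this scale (≲10⁴ parameters), not large ones.
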