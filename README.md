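# btarecruit

Quantitative models for DNA-mediated protein recruitment on supramolecular
benzene-1,3,5-tricarboxamide (BTA) polymers.

Water-soluble BTA monomers stack into micrometer-long fibers. When a
fraction of the monomers carries a short single-stranded DNA handle, DNA
recruiter strands can tether DNA-conjugated proteins to the fiber, raising
the *effective* concentration each tethered protein experiences by orders of
magnitude over its bulk concentration. With a reporter enzyme
(TEM1 β-lactamase E104D) and its weak inhibitor protein (BLIP, solution
K_i = 1.5 µM) this drives enzyme–inhibitor complex formation at low
nanomolar bulk concentrations, and a toehold-bearing recruiter makes the
recruitment fully reversible by strand displacement.

This package is for researchers modelling or designing such
scaffold-templated assays. It provides:

* **Cylinder effective-concentration model** (`geometry`) — the fiber is a
  cylinder of radius *r* (15 nm) growing by an axial rise *h* per monomer:

  C_eff = C_bulk / (C_BTA,total · N_A · π r² h)

  plus fiber length per liter, mean inter-protein spacing, and a closed-form
  calibration of *h* from a reference C_eff.
* **Hybridization equilibria** (`hybridization`) — exact bimolecular
  quadratic for one recruiter on the handle pool; guaranteed-convergent
  bisection for many recruiters competing for shared handles
  (`handle_total = x + Σ R_i·x/(K_i + x)`); stoichiometric toehold
  displacement.
* **Templated activity model** (`recruitment`) — normalized enzyme activity
  `V = (1 − f_E) + f_E(1 − θ)` with `θ = C_eff/(K_i + C_eff)`, over
  inhibitor titrations, receptor-density scans and displacement cycles.
* **Estimators** (`fitting`) — the hyperbolic inhibition fit
  `V = V_b + (1 − V_b)·K_i,app/([I] + K_i,app)`, the fixed-endpoint
  exponential exchange fit `A(t) = A_∞ + (A_0 − A_∞)e^{−kt}`, and
  initial-rate extraction from fluorescence progress traces.
* **Kinetic simulators and synthetic data** (`kinetics`, `synth`) — seeded
  generators for progress traces, titrations and exchange series with the
  assays' triplicate Gaussian-noise structure.
* **CLI and I/O** (`cli`, `io`) — a `btarecruit` command with
  `ceff`, `equilibrium`, `titration`, `density-scan`, `displace`, `fit-ki`,
  `fit-exchange`, `rates`, `simulate-*` and `synth` subcommands, YAML/JSON
  configs with explicit concentration units, documented CSV schemas, and
  provenance sidecars.

## Worked example

The reference assembly is 2 µM total BTA at 25% receptor density
(0.5 µM BTA-DNA + 1.5 µM BTA-3OH) with 10 nM bulk inhibitor:

```sh
$ btarecruit ceff --bulk 10e-9 --bta-dna 0.5e-6 --bta-3oh 1.5e-6
{
  "effective_concentration_M": 2.5986529079441745e-05,
  "fiber_length_nm_per_l": 5.44401524704e+17,
  "fold_enhancement": 2598.6529079441743,
  "mean_spacing_nm": 90.4
}
```

The 10 nM inhibitor is concentrated ~2600-fold to ~26 µM inside the fiber —
far above the 1.5 µM solution K_i, which is why the pair associates on the
scaffold but not in solution. The same model in Python, composed with the
hybridization equilibrium and the activity model:

```python
import numpy as np
import btarecruit as br

comp = br.AssemblyComposition(conc_btadna=0.5e-6, conc_bta3oh=1.5e-6)
enzyme = br.RecruitedSpecies("enzyme", recruiter_total=20e-9, protein_total=1e-9)
inhibitor = br.RecruitedSpecies("inhibitor", recruiter_total=200e-9, protein_total=10e-9)
model = br.InhibitionModel()          # K_i = 1.5 uM in solution

act, det = br.normalized_activity(
    comp, br.FiberModel(), enzyme, inhibitor, model, return_details=True
)
# act = 0.370, det: f_E = 0.683, C_eff = 17.8 uM, theta = 0.922

grid = np.concatenate([[0.0], np.geomspace(0.5e-9, 100e-9, 11)])
data = br.titration_curve(grid, comp, br.FiberModel(), enzyme, inhibitor, model)
fit = br.fit_inhibition(data)
print(f"V_b = {fit.v_b:.4f}   K_i,app = {fit.ki_app * 1e9:.3f} nM")
```

```
V_b = 0.3166   K_i,app = 0.845 nM
```

At this condition 68% of the enzyme is scaffold-bound (the 200 nM inhibitor
recruiter competes for handles), the scaffold-bound population is 92%
inhibited, and the apparent inhibition constant extracted from the model
titration is sub-nanomolar — three orders of magnitude below the solution
K_i. With only the enzyme recruiter present (20 nM on 0.5 µM handles), 75%
of the enzyme is scaffold-bound, which caps the maximal inhibition at ~75%
and leaves a residual activity plateau V_b = 0.25.

## Configuration files

Model-driven subcommands share one YAML/JSON config; concentrations take
explicit units (`M`, `mM`, `uM`/`µM`, `nM`, `pM`) or plain mol/L numbers:

```yaml
composition: {conc_btadna: 0.5 uM, conc_bta3oh: 1.5 uM}
species:
  - {name: enzyme, recruiter_total: 20 nM, protein_total: 1 nM}
  - {name: inhibitor, recruiter_total: 200 nM, protein_total: 10 nM}
seed: 1
```

Omitted parameters fall back to documented defaults (fiber radius 15 nm,
axial rise 0.452 nm, handle-duplex K_d 0.162 µM, K_i 1.5 µM); every applied
default is logged and recorded in the output's provenance sidecar.

See `docs/methods.md` for the model assumptions, parameter provenance and
known limitations.
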