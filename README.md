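# angiosprout

Cellular Potts simulation of angiogenic sprouting, with per-cell
VEGF–Dll4–Notch signaling and automated quantification of **tip-cell
overtaking** — the replacement of a sprout's leading cell by one of its
neighbors.

During angiogenesis, endothelial cells adopt one of two fates: *tip*
cells lead growing sprouts, *stalk* cells form their body.  Live-imaging
studies showed that cells shuffle within sprouts and compete for the tip
position.  This package implements two minimal sprouting models in which
that competition can be studied mechanistically, for computational
biologists who want a tested, scriptable 2D sandbox rather than a GUI
modeling environment:

- the **contact inhibition** model — cells secrete a short-lived
  diffusible attractant and chemotact toward it only at cell–ECM
  interfaces;
- the **cell elongation** model — cells carry an elongated-shape
  constraint and chemotact everywhere.

Both grow sprouts spontaneously from a spheroid.  On top of the CPM, a
per-cell ODE network implements Dll4–Notch lateral inhibition with
cis-inhibition and contact-surface-weighted trans-signaling, extended by
VEGF→VEGFR2→Dll4 signaling, so that mosaic spheroids of wild-type and
*Vegfr2*⁺/⁻ cells can be simulated and sprout-tip occupancy scored
against the random-mixing binomial null.

## Model core

The CPM minimizes

    H = Σ J(τ,τ′)(1−δ_σσ′) + λ_size Σ (A−a)² + Σ λ_length (L−l)²

by Metropolis dynamics (copy accepted with min(1, e^{−ΔH/μ})), coupled
to the attractant PDE ∂c/∂t = α[cell] − ε[ECM]c + D∇²c and the
chemotaxis bias ΔH → ΔH + λ_c(c(x)−c(x′)).  Signaling per cell i:

    dS/dt = α_S·Hill(Σ_j N_i D_j w_ij / d²) − γ_S S          (NICD)
    dD/dt = β_Dc + β_D/(1+S^m) − γ_D D − DN/k_c − trans + VEGF feedback
    dN/dt = β_N − γ_N N − ND/k_c − trans
    dR/dt = β_Rc + β_R/(1+S^m) − γ_R R     (halved for Vegfr2+/-)
    dA/dt = α_A·Hill(R·V) − γ_A A

with w_ij the shared-membrane weight.  Cells with NICD below a threshold
become tip cells.  Analysis converts the cell mask to a skeleton graph,
identifies each sprout's leader cell geometrically, tracks leaders
through time, counts overtakes (both leaders persistent ≥ 80 MCS), and
fits the axial MSD with 2Dt + (vt)².  See `docs/methods.md` for the full
specification of conventions and calibrated defaults.

## Worked example

```python
from angiosprout.config import desk_preset
from angiosprout.scenario import run_scenario, fit_pooled_msd

cfg = desk_preset(duration_mcs=12_000, analysis_window=(4000, 12_000))
run = run_scenario(cfg, seed=11)
s = run.summary
print(f"sprouts in window : {s['n_sprouts']}")
print(f"overtake events   : {s['n_events']}")
print(f"overtake rate     : {s['overtake_rate']:.3f} per sprout per 20k MCS")
print(f"mean tip lifetime : {s['tip_lifetime_min_mean']:.1f} min")
D, v, _ = fit_pooled_msd([s["msd_pool"]])
print(f"dispersion D      : {D:.6f} um^2/s")
```

prints (contact-inhibition model, desk preset, seed 11):

```
sprouts in window : 235
overtake events   : 4
overtake rate     : 0.043 per sprout per 20k MCS
mean tip lifetime : 19.7 min
dispersion D      : 0.000096 um^2/s
```

Four overtakes in an 8,000-MCS window, normalized by every sprout the
skeleton census saw (most of them short-lived protrusions), give 0.043
overtakes per sprout per 20,000 MCS — leader changes in the contact
model are rare, and cells creep along the sprout axis as a slow biased
random walk.  The elongation model (`model_variant="cell_elongation"`)
overtakes one to two orders of magnitude more often under the same
analysis, with a correspondingly larger dispersion coefficient.

A command-line interface wraps the same pipeline:

```bash
angiosprout simulate --preset desk --seed 1 --out runs/
angiosprout analyze --tracks runs/tracks_contact_inhibition_s1.csv \
    --axis 100 100 100 160 --out runs/kin.json
angiosprout report --summaries runs/summary_contact_inhibition_s1.json \
    --out runs/report.json
```

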