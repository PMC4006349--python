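# contourctl

Closed-loop interactive level-set segmentation: a narrowband
region-competition PDE augmented with a user-driven control field, an input
accumulator regulated by nonlinear diffusion, and an observer PDE that
estimates the boundary the user has in mind.

## The problem

Automatic region-based segmentation evolves an implicit boundary — the zero
level set of a field φ(x, t), positive inside the region — by a PDE of the
form

    φ_t = δ_ε(φ) · [ G(φ, I) + λ κ(φ) ],

where G is an image-driven competition term (here: global or localized
separation of interior/exterior intensity means), κ(φ) = ∇·(∇φ/|∇φ|) is the
curvature smoothing, and δ_ε confines updates to the narrowband |φ| ≤ ε.
On real anatomy this open-loop system routinely fails: the boundary
*bleeds through* into adjacent structures that share the target's intensity
statistics, because the expert's intended region ψ is not a minimizer of
the image functional.

`contourctl` closes the loop. The user clicks signed votes u_k ∈ {−1, +1}
("this voxel is mislabeled"); the votes are splatted with a kernel combining
spatial proximity and intensity similarity and accumulated into a control
field U regulated by the saturating diffusion

    U_t = h(x, t) + ∇·[ H_ε((U/U_M)² − 1) ∇U ],    U(x, 0) = 0,

so that sustained scribbling saturates near the threshold U_M = (Ḡ_M/ρ + 1)^½
that provably dominates the image force (|G| ≤ Ḡ_M). An observer field ψ̂
mediates between the segmentation and the input,

    ψ̂_t = δ_ε(ψ̂) · [ ξ̂ − e_U (αU)² ],       ξ̂ = H_ε(φ) − H_ε(ψ̂),
                                              e_U = H_ε(ψ̂) − H_ε(U),

following φ where the user is silent and driven toward the sign of U where
input has accumulated, and the segmentation itself runs under the feedback
law

    φ_t = δ_ε(φ) · [ G − ξ̂ U² + λ(t) κ(δ_ε²(φ) · ξ̂) ],    λ(t) = λ₀ + λ₁ D̂,

whose Lyapunov functionals (D̂ = ½∫ξ̂², F = ½∫(αU)² e_U²) certify that a
sufficiently insistent user can stabilize the boundary in the state they
want — and that it stays there: running longer does not bleed.

Everything is exercised end-to-end on synthetic phantoms with a scripted
simulated user, so every closed-loop behavior is reproducible without
clinical data: a two-ellipse "ventricle" phantom whose bright bridge causes
open-loop bleed-through, and a gradient phantom whose global means coincide
so only localized statistics can find the shape.

## Worked example

```python
import contourctl as cc

image, psi = cc.make_phantom()                     # phantom + ground truth
seed = cc.circle_seed(image.grid, (64, 38), 8.0)   # seed in the left ellipse

auto = cc.run_open_loop(image, seed, cc.SessionConfig(mode="open_loop",
                                                      max_steps=2500))
print("open loop  dice =", round(cc.dice(auto.phi, psi), 4))

user = cc.SimulatedUser(psi, cc.UserPolicy())      # scripted corrective user
res = cc.run_session(image, seed, cc.SessionConfig(max_steps=3000),
                     user=user, reference=psi)
print("closed loop dice =", round(cc.dice(res.phi, psi), 4))
print("actuated cells  =", res.diagnostics.actuated[-1],
      "of", cc.boundary_cell_count(psi), "boundary cells")
```

prints

```
open loop  dice = 0.7067
closed loop dice = 1.0
actuated cells  = 5 of 116 boundary cells
```

The open-loop run leaks through the bridge and segments the union of both
ellipses (Dice 0.71 against the left-ellipse reference, with the right
ellipse fully covered). The closed loop reaches the intended region exactly,
and the simulated user needed to touch only 5 cells (~4% of what a fully
manual tracing would mark): a handful of corrective clicks at the bridge
entrance, placed as the leak begins, are enough to pin the steady state.

The same loop is scriptable from a shell:

```sh
contourctl phantom --kind two_ellipse --out phantom.nii.gz --ref psi.nii.gz
contourctl simulate --out rundir --seed 1
contourctl segment --image phantom.nii.gz --init seed.yaml \
                   --clicks rundir/clicks.csv --out replay
```

`segment` replays a logged click stream on any PNG/NIfTI/NRRD image;
outputs are the label mask, φ/ψ̂/U snapshots, a per-step diagnostics CSV
(D, D̂, F, V, E, λ(t), actuated/reclassified counts) and a JSON manifest
that reproduces the run bit-exactly.

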