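# ddtv-pat

Model-based image reconstruction for two-dimensional photoacoustic
tomography (PAT), built around a **directional total-variation prior with
adaptive directivity (DDTV)**, alongside classical isotropic-TV and
filtered-back-projection (FBP) baselines.

In PAT a laser pulse launches ultrasound from optically absorbing tissue;
detectors around the sample record time traces whose integrated form
`g(r0, t)` equals the line integral of the absorption map `A` over the arc
of radius `c·t` centered at the detector. On a pixel grid this is a sparse
linear system `g = W A'`, and reconstruction solves

    A* = argmin_A ‖W A' − g‖₂² + λ · DDTV(A),

where the prior replaces the isotropic unit ball of the TV dual with a
per-pixel ellipse (unit minor axis, major axis `α ∈ [1, α_max]` along the
local texture direction θ):

    DDTV(A) = Σ_ij ‖ diag(α_ij, 1) · R(θ_ij)ᵀ · ∇A_ij ‖₂.

θ and the coherence C (which sets α) are re-estimated from the image at
every outer iteration with a block-wise gradient/structure-tensor method,
so the prior smooths along structures and preserves the edges crossing
them. `α ≡ 1` recovers classical TV exactly. The optimization alternates
normalized gradient steps on the data term with a projected-gradient dual
solve of the directional-TV proximal map (dual vectors projected onto the
unit ball, per-pixel step `1/(8α²λ²)`).

The package also provides: circular / limited-view / linear scan
geometries, two discretizations of the system matrix with exact adjoints,
an inverse-crime-free arc-quadrature signal simulator with seeded Gaussian
noise, Shepp-Logan and directional-texture phantoms, PSNR / normalized
distance metrics, and a reproducible experiment runner.

## Worked example

```python
import ddtv_pat as dp

A = dp.shepp_logan(128)                          # absorption phantom in [0, 1]
grid = dp.make_grid(128, 128, 76.8)              # 0.6 mm pixels
geom = dp.circular_scan(30, 36.0)                # 30 views on a 36 mm circle
sampling = dp.default_sampling(grid, geom)

# inverse-crime-free signals + independent system matrix
g = dp.simulate_spherical_means(A, grid, geom, sampling, upsample=8)
W = dp.build_quadrature_matrix(geom, grid, sampling, upsample=2)

cfg = dp.ReconConfig()                           # lambda=5e-5, alpha_max=2.5, 10 iterations
ddtv = dp.reconstruct_ddtv(g, W, cfg)
tv = dp.reconstruct_tv(g, W, cfg)
fbp = dp.reconstruct_fbp(dp.differentiate_to_pressure(g), grid)

for name, img in [("FBP", fbp.image), ("TV", tv.image), ("DDTV", ddtv.image)]:
    print(f"{name:5s} PSNR = {dp.psnr(img, A):.2f} dB, d = {dp.distance_d(img, A):.3f}")
```

prints (30-view sparse scan):

```
FBP   PSNR = 14.02 dB, d = 0.802
TV    PSNR = 35.04 dB, d = 0.071
DDTV  PSNR = 38.01 dB, d = 0.051
```

FBP leaves strong streak artifacts at 30 views (d ≈ 0.8 of the signal
energy); TV removes them but keeps smoothing residue after its 10-step
schedule; DDTV's direction-adaptive smoothing recovers the phantom ~3 dB
closer. With denser sampling (60-180 views) all methods improve and the
ordering DDTV > TV > FBP persists.

The same pipeline is scriptable from the shell:

```sh
ddtv-pat phantom --kind shepp_logan --n 128 --out phantom.h5
ddtv-pat simulate --phantom phantom.h5 --n-views 30 --radius-mm 36 --out sino.h5
ddtv-pat reconstruct --method ddtv --sinogram sino.h5 --out recon.h5
ddtv-pat evaluate --image recon.h5 --reference phantom.h5
```

or driven end-to-end from a YAML/JSON spec with `ddtv-pat run`.

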