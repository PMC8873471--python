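# Methods

## Imaging model and coordinate conventions

The system is a coherent inline holographic microscope: a plane wave at
vacuum wavelength λ = 632.8 nm illuminates a water volume (n = 1.33) and the
transmitted intensity is recorded through an NA 0.4, 20× relay onto a sensor
with 3.45 µm pixels, giving a 172.5 nm effective pixel. The imaged volume is
176.64 × 176.64 × 500 µm³ (1024 × 1024 pixels laterally). Two axial grids
coexist:

- a **fine grid** with step 118.4 nm (4222 slices) used by the forward
  model. The quarter-wavelength-in-medium sampling rule λ/(4n) gives
  118.95 nm; the conventional default of 118.4 nm is kept (the value is
  consistent with n ≈ 1.336) and the config validator allows 1% slack.
- a **coarse grid** with step 5 µm (100 slices) matching the axial
  resolution λₘ/(1 − √(1 − NA²)) = 5.7 µm, used for backpropagation, the
  ground-truth labels, and the network.

The hologram plane is idealized as the exit face of the volume. The
backpropagated volume and the ground truth are both indexed by **depth
behind the hologram plane**, slice j centered at (j+1)·5 µm, shallow to
deep; a particle at scene coordinate z sits at depth L − z. Fine-grid slices
are projected to the *nearest* coarse slice, and axial binning of the binary
labels is a logical OR (detection semantics).

## Forward model (split-step beam propagation)

Holograms are simulated by alternating thin phase screens and free-space
diffraction through the fine grid. The phase screen advances the field by
k₀·Δn·δz (vacuum wavenumber times index contrast), and diffraction uses the
angular-spectrum kernel of the homogeneous medium,
exp(i2πδz·√(λₘ⁻² − u² − v²)), with evanescent components set to zero rather
than decayed (stable, standard). FFT wrap-around is controlled by an integer
zero-padding factor (default 2); the illumination fills the padded domain so
padding introduces no edge discontinuity. Phase screens and band-limited
propagation are unitary on the propagating band, so scenes without
absorption conserve the L2 norm of the field — this is asserted in tests.

## Backpropagation

The linear 3D estimate is R(x,y;z) = F⁻¹{F{I}·H(u,v;z)} where H is the
*analytic* angular-spectrum (Weyl) form of the free-space Green's-function
transfer kernel, conjugated for backward propagation. The analytic kernel is
used instead of an FFT of the sampled exp(ikr)/r because it is alias-free
and exactly unit-modulus; constant prefactors are irrelevant because the
volume is standardized before entering the network.

## Particle scenes

Centers are placed by dart-throwing Poisson-disk sampling with a bounded
attempt budget (explicit failure with diagnostics if the packing is
infeasible). The default minimum distance is the particle diameter, which
prevents overlap; the sampler optionally insets centers from the box faces
by the particle radius. Heterogeneous scenes draw per-particle diameter and
index contrast from uniform distributions centered on the condition values
(±δ% of the center). Sphere membership is tested at voxel centers with no
antialiasing — the simplest rule consistent with binary ground truth.

## Network

Each **expert** is a 3D V-net: four encoder stages (two 3×3×3 conv +
instance-norm + ReLU blocks each, then 2×2×2 ceil-mode max pooling), a
bottleneck block, and a mirrored decoder with nearest-neighbor upsampling,
concatenated skip connections, and a sigmoid 1×1×1 head. With 128 × 128 × 100
inputs the bottleneck is 8 × 8 × 7. Default widths (16, 32, 64, 128, 256)
give ≈ 5.9 M parameters per expert; a √3 channel multiplier produces the
parameter-matched wide generalist (≈ 3× the expert). The **gating network**
is a small 2D VGG-style stack (conv-ReLU-pool ×4 at full scale) whose final
feature map is flattened into two dense layers and a softmax over the
n_experts weights. Flattening rather than global average pooling is
essential: mean-pooled rectified features of standardized holograms are
nearly texture-blind, whereas the flattened map retains the fringe-scale
information the gate needs to infer the scattering condition.

**Dynamic synthesis.** Per input, encoder pyramids are mixed elementwise at
every scale (F_s = Σ αᵢ Fᵢ, including skips and bottleneck) and the decoder
is synthesized at the parameter level (D_s = Σ αᵢ Dᵢ) over *all* learnable
decoder parameters — conv kernels, biases, and instance-norm affine terms
(instance normalization carries no running statistics, so nothing is
excluded from mixing). One-hot α therefore reduces the DSN exactly to the
corresponding expert; this identity is the keystone test of the mechanism.

## Training

Per-voxel binary cross-entropy (predictions clamped to [1e−7, 1−1e−7]),
optionally plus γ‖W‖² (γ = 1e−6 for the mixture network), optimized with
Adam and a seeded sample order so a fixed seed reproduces the loss history
bit for bit. Full-scale hyperparameter presets are recorded as named
configs: expert (lr 1e−4, batch 4), baseline generalist (1e−5, batch 20),
wide generalist (1e−4, batch 1), DSN (1e−5, batch 1, γ = 1e−6). Model
selection uses the lowest validation loss. Initialization is either Xavier
everywhere or pretrained-expert (experts copied from per-condition
checkpoints; the gate is always Xavier).

## Desk-scale study conditions

All stochastic end-to-end behavior is demonstrated on a miniature geometry:
a 16 × 16 × 50 µm³ volume on a 32 × 32 lateral grid (0.5 µm effective pixel,
still Nyquist for NA 0.4 in water), 10 coarse slices, and a 2-expert,
2-scale, 3-channel network (the architecture is fully grid-size agnostic).
The co-training demo uses two visually distinct scattering conditions — 20
small (0.8 µm) particles versus 5 large (3 µm) particles per volume, two
volumes each. Pure density pairs were found uninformative at this scale: a
dense-trained miniature expert transfers well to sparse scenes, so no
routing pressure arises; differing density *and* diameter gives each expert
a regime where it is genuinely the better descatterer.

Three schedule choices matter at this scale and are deliberate:

1. **Larger learning rates** (1e−2 pretraining) than at full scale — with
   ~10³ instead of ~10⁵ iterations, the output-head bias cannot otherwise
   reach the strongly negative value the sparse class prior requires.
2. **Shared expert initialization before pretraining** — experts fine-tuned
   from a common starting point remain approximately linearly connected, so
   parameter blends at intermediate α behave sensibly; independently
   initialized experts create a loss barrier at mixed α that traps the gate
   in a single-expert basin.
3. **A gate-only warm-up phase at a small step size (3e−4)** before joint
   co-training — the gate must learn to *discriminate* conditions before its
   softmax saturates; with a large common-mode gradient it otherwise
   collapses to one expert for every input and the vanishing softmax
   Jacobian prevents recovery.

With this schedule the pretrained experts specialize (each beats the other
on its own condition), co-training reduces the mixed-set loss several-fold,
and the gate's mean α vectors for the two conditions separate by ≈ 0.8 —
the desk-scale analogue of condition-dependent synthesis weights.

## Evaluation

The probability volume is binarized slice-wise by Otsu's method (256 bins
over each slice's own range; slices with dynamic range < 1e−6 become
background), 26-connected components under 10 voxels are discarded as
noise, and component centroids (voxel-center means, converted to µm) are
matched to ground truth by a minimum-total-Euclidean-distance linear
assignment. A matched pair is a true positive iff it lies inside the
4 × 4 × 12 µm elliptical gate (semi-axes 2, 2, 6 µm); outside-gate pairs
count one FP and one FN, as do unmatched members. An anisotropy-normalized
assignment metric is available behind a flag (default off). JI is reported
per 10-slice depth bin with mean/std across volumes; FP particles are binned
by their predicted depth (ground truth provides none), empty bins are
flagged nulls, and jaccard_index(0,0,0) returns a flagged null rather than a
silent zero.

## What the synthetic data does and does not show

The generator reproduces the geometry, coherent multiple scattering,
depth-dependent artifact growth, and axial elongation of the real system,
and optionally additive Gaussian sensor noise. It does not model beam
imperfections, sensor MTF, shot noise, polarization, absorption, or particle
motion; passing tests therefore demonstrate the correctness of the
algorithms and the adaptation mechanism, not end-to-end accuracy on
experimental holograms. Full-scale training (10⁴–10⁵ iterations on
1024 × 1024 × 100 volumes) is out of reach of a CPU session; the package's
problem sizes were chosen so every study completes in minutes while keeping
all code paths identical to the full-scale configuration.

## Known limitations

- The miniature co-training result depends on the schedule above; it is a
  mechanism demonstration, not a convergence guarantee.
- The backpropagation input is single-scattering in nature; at high
  densities the linear estimate itself limits achievable accuracy.
- Only spherical scatterers and uniform heterogeneity distributions are
  supported.
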