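# seguq — segmentation uncertainty, propagated through image-based simulation

Image-based simulation computes physical quantities (effective
conductivity, tortuosity, volume fraction, ...) on geometries segmented
from 3D images such as X-ray CT scans.  Any segmenter — a human with
thresholding tools or a neural network sampled many times — produces one of
many plausible segmentations, and that ambiguity propagates into the
physics.  `seguq` makes this uncertainty explicit and carries it end to
end:

1. **Probability map.** From N co-registered segmentation samples, the
   per-voxel, per-class inclusion frequency

   ε<sub>v,i</sub> = (1/N) Σ<sub>k</sub> p<sup>k</sup><sub>v,i</sub>,

   where p<sup>k</sup><sub>v,i</sub> ∈ {0, 1} marks membership of voxel *v*
   in class *i* in sample *k*.  Any tool that emits a voxel-wise
   probability volume (random walker, trainable segmentation, a Bayesian
   CNN) can be plugged in directly in place of the sample ensemble.

2. **Uncertainty map.** Normalized Shannon entropy of the class row,
   H(ε<sub>v</sub>) = −Σ<sub>i</sub> ε<sub>v,i</sub> log₂ ε<sub>v,i</sub> / log₂ n<sub>c</sub> ∈ [0, 1],
   with 1 marking a maximally ambiguous voxel, plus a per-class variant.

3. **Percentile segmentations.** Thresholding ε ≥ t keeps every voxel with
   at least a 100·t % chance of membership.  A percentile P maps to
   t = 1 − P/100, so segmentations are nested and grow with P.  The three
   *standard segmentations* at P = 15.9, 50.0, 84.1 (the standard normal
   CDF at μ−σ, μ, μ+σ) anchor the whole analysis.  Smooth level-set
   surfaces are extracted by marching cubes on the real-valued map and
   exported as STL.

4. **Voxel physics.** Volume fraction, effective transport (electrical or
   thermal conductivity, Laplace's equation with harmonic-mean face
   conductances on the structured voxel grid, unit conductivity in the
   transporting phase and 10⁻⁶ in the other), and tortuosity
   τ = porosity / effective transport of the pore phase.

5. **Characteristic distribution.** Evaluating a quantity Q on the
   standard segmentations specifies a Normal estimate of its uncertainty:
   mean = Q(50.0), σ = (Q(84.1) − Q(15.9)) / 2.  Held-out percentiles
   validate the fit; bounded or heavy-tailed alternatives (beta,
   half-Cauchy, empirical CDF) and a monotonicity guard cover the cases
   where three simulations are not enough.

A synthetic-data module generates blurred planar interfaces and Gaussian
random-field microstructures whose true probability maps are known in
closed form, so every stage is testable without any image data.

## Worked example

```python
import seguq

scene = seguq.make_blob_microstructure((32, 32, 32), phi=0.5, ell=3.0, seed=42)
stack = seguq.sample_segmentations(scene, N=48, seed=7)
pmap  = seguq.compute_probability_map(stack)

H = seguq.entropy_map(pmap)
print(f"mean entropy        : {H.H.mean():.4f}")

results = seguq.run_physics_sweep(
    pmap, class_i=1,
    percentiles=[5, 15.9, 25, 35, 50.0, 60, 70, 84.1, 90, 95],
    quantities=["volume_fraction", "effective_conductivity"], axis="z")
table = seguq.QuantityTable.from_results(results, "effective_conductivity")

dist   = seguq.fit_characteristic_normal(table)
report = seguq.assess_characteristic_fit(dist, table)
print(f"characteristic Normal : mean = {dist.params['mean']:.4f}, "
      f"sigma = {dist.params['sigma']:.4f}")
print(f"held-out max |dCDF|   : {report['max_discrepancy']:.3f} "
      f"(pass = {report['passed']})")
```

prints

```
mean entropy        : 0.3975
characteristic Normal : mean = 0.1950, sigma = 0.0791
held-out max |dCDF|   : 0.098 (pass = False)
```

The effective conductivity of the median (P = 50) segmentation is 0.195 in
units of the particle-phase conductivity, with a one-σ uncertainty of
0.079 coming purely from segmentation ambiguity.  The held-out check
*fails* here (max CDF discrepancy 0.098 > 0.05): the P = 90 and 95
segmentations connect previously isolated conductive regions and the
conductivity jumps (0.28 → 0.42 → 0.58), a heavy upper tail that a Normal
specified by three simulations cannot capture — exactly the situation in
which the package tells you to fall back on the full percentile sweep.

The same chain is scriptable from a shell: `seguq run config.yaml` executes
a YAML-configured pipeline, and `seguq synthesize`, `seguq prob-map`,
`seguq entropy`, `seguq percentiles`, `seguq physics` and `seguq fit`
expose the stages individually.

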