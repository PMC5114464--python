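# corowave

Scaling laws and pulse-wave reflection at bifurcations of branching
vascular networks.

A junction of a mother vessel and two daughters is characterised by its
area ratio `sigma = (A_d1 + A_d2) / A_m` and symmetry ratio
`gamma = A_d2 / A_d1`.  Requiring zero reflection of a forward-travelling
pressure wave (well-matchedness) under a wave-speed/area coupling
`c ~ A**(tau/2 - 1)` yields the same closed-form `sigma(gamma)` relation as
a branching power law with exponent `tau` — so adherence to a scaling law
(Murray `tau = 3`, Huo–Kassab `tau = 7/3`, ...) and well-matchedness of the
junctions are two views of one property.  The package implements this
framework in both the steady (high Womersley number) regime and the
pulsatile regime, where the complex characteristic impedance carries the
Womersley modulus/phase factors computed from complex Bessel functions.

## Layout

| module | contents |
|---|---|
| `corowave.tree_model` | rooted vessel-segment trees, CSV node-table I/O, bifurcation extraction and junction census, Weibel generations, transmural layers |
| `corowave.steady` | closed-form `sigma(gamma; tau)`, forward/backward reflection coefficients, wave speed <-> wall stiffness (`beta*`) conversions, scaling residuals |
| `corowave.womersley` | Womersley number, `M0'`/`eps0` factors, complex impedance, pulsatile reflection, self-consistent pulsatile `sigma(gamma)` and its alpha-band envelope |
| `corowave.parametrization` | per-segment wave speed / stiffness under uniform-PWS, uniform-`beta*`, uniform-`beta` and empirical wall-law hypotheses; per-junction reflection triples |
| `corowave.synthetic_data` | synthetic coronary-like trees (radius-conditioned symmetry ratios, matched area ratios, trifurcation injection, radius noise), matched `(gamma, sigma)` point clouds |
| `corowave.pipeline` | clustering, multi-start exponent fitting, summaries, rank tests, reflection distributions, bin-edge sensitivity, band coverage |

## Command line

```sh
# grow a synthetic tree (YAML config optional; seed echoed in the header)
corowave generate --config cfg.yaml --seed 1 -o tree.csv

# cluster summaries, rank tests, reflection coefficients
corowave analyze tree.csv --cluster radius --material uniform_beta_star --report out/

# steady curve or pulsatile band of the sigma-gamma relation
corowave curves --tau 2.333 --alpha-range 0.01 10 -o band.txt

# branching-exponent fit per cluster
corowave fit tree.csv --cluster radius
```

Trees are plain-text CSV node tables, one row per segment:
`id,parent,radius_mm,length_mm[,territory,transmural_depth,weibel_generation]`
with an empty `parent` marking the root; `#` lines are comments.

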