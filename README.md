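# channelscale

Cumulative hydropathic topology of ion-channel pores — atom-packing
sigmoids, hydropathic moment fields, scaling criticality, and
structure-based scoring of missense variants.

## The problem

Voltage-gated sodium channels such as NaV1.7 (the SCN9A gene product
expressed in peripheral pain-signalling neurons) carry many missense
variants whose phenotypes range from severe pain syndromes to silent
polymorphisms.  Instead of simulating each mutant, `channelscale` extracts
*wild-type* structural descriptors that encode where the channel is
sensitive to perturbation: it scans the atomic environment around the pore
with concentric spheres, models how atoms pack, maps hydropathic moment
fields and their sign topology, locates a scaling-critical point near the
selectivity filter (SF), and classifies variant sites by their distance to
two landmarks — the hydrophobic patch (HP) lining the pore and the
critical sphere around the SF.

## The model in brief

For pore points **p** ∈ P traced through the channel and sphere radii
l_α(**p**) = D(**p**) + α·(L(**p**) − D(**p**))/K_α:

* geometry:  R(**p**) = min_i(‖c_i − **p**‖ − vdW_i),
  D(**p**) = min_i ‖c_i − **p**‖,  L(**p**) = max_i(‖c_i − **p**‖ + vdW_i);
* packing:  N(**p**, l) = Σ_i θ(l − ‖c_i − **p**‖) is fitted with
  Logistic / Gompertz / modified-Gompertz / Richards models (AIC
  selection), giving the lag end s(**p**), the inflection ξ(**p**) (RDF
  peak, max packing rate t = A/(o − s)) and the asymptote start o(**p**);
* hydropathy:  m⁰ = h⁰/N with h⁰ = Σ θ(·)·HIʷ_i, and
  **m**¹ = **h**¹/N with **h**¹ = Σ θ(·)·HIʷ_i·(c_i − **p**); the axial
  component m¹_z defines "in"/"out" orientation states, and zero crossings
  of m⁰ over the (p, α) map delimit the hydrophobic patch;
* criticality:  |m¹_z| ~ l^γ with expansion (γ_I > 0) below ξ and
  contraction (γ_II < 0) above it at the critical SF pore point;
  U = |h¹_z|/l proxies the atom-packing energy;
* classification:  per-site distances d_HP (median distance to the HP
  boundary), d_SF (distance from the critical sphere) and their weighted
  average feed a ROC analysis (low score predicts pain; Youden threshold).

## Worked example

Generate a synthetic channel analogue with planted ground truth and run
the full pipeline on it:

```sh
channelscale simulate toy-channel --preset default --seed 7 --out demo
cat > demo/run.cfg <<EOF
structure = demo/structure.pdb
annotation = demo/annotation.tsv
variants = demo/variants.tsv
hydropathy_table = demo/hydropathy_toy.tsv
out_dir = demo/out
seed = 7
k_alpha = 200
EOF
channelscale run --config demo/run.cfg
```

which prints

```
toy channel written to demo (2936 atoms)
pipeline complete -> demo/out
  d_hp: AUC=1.000 thr=11.53 sens=1.000 spec=1.000
  d_sf: AUC=1.000 thr=7.27 sens=1.000 spec=1.000
  d_weighted: AUC=1.000 thr=9.41 sens=1.000 spec=1.000
```

The planted pain sites sit on the critical shell and the neutral sites far
off it, so all three distance scores separate them perfectly (AUC 1.0 with
sensitivity = specificity = 1 at the Youden threshold).  `demo/out/`
contains the pore table (index, x, y, z, R, D, L), the CDF matrices and
per-point sigmoid fits, the m⁰/m¹_z field and topology tables, the
critical-point record (`criticality.json`: here ξ(p_crit) ≈ 22.8 Å with
γ_I ≈ +3.0 and γ_II ≈ −4.1, matching the generator's planted break within
a couple of grid steps), the per-site scores and the ROC summaries, plus a
manifest echoing every parameter and seed.

The same pipeline runs on any protonated PDB: supply a segment annotation
(pore-module / voltage-sensor / selectivity-filter residue ranges and the
extracellular end) and a variant table (`residue_number`, `wt_aa`,
`mut_aa`, `label`).  A per-atom hydropathy resource and a literature-style
SCN9A variant table (36 pain-related / 48 neutral sites; synthetic filler
rows are marked in the file header) ship with the package.

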