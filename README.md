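# cadforce

Analysis toolkit for single-molecule studies of cadherin adhesion: the
statistics behind AFM unbinding-force experiments and the trajectory
statistics behind MD/SMD simulations of the E-cadherin strand-swap dimer,
together with synthetic-data generators so every stage can be validated
against known ground truth.

## Who this is for

E-cadherin (Ecad) mediates cell–cell adhesion through strand-swap dimers:
each monomer docks tryptophan 2 (W2) into a hydrophobic pocket on its
partner. Activating monoclonal antibodies can strengthen this bond, and the
evidence comes from two computational pipelines that this package
implements as reusable, tested components:

1. **Force pipeline** (AFM). A cantilever functionalised with Ecad is
   retracted from an Ecad-coated surface at constant velocity; a specific
   unbinding event appears as a polymer-tether stretch ending in an abrupt
   force drop. The pipeline detects events, fits the stretch to a
   worm-like-chain (WLC) model, filters non-specific events, and models the
   accepted rupture forces as a Gaussian mixture whose component count is
   chosen by BIC. A bimodal distribution with a ~40%-weight high-force peak
   is the signature of antibody-strengthened adhesion.
2. **Trajectory pipeline** (MD/SMD). Per-residue α-carbon RMSF over the
   equilibrated window, salt-bridge verdicts from the median charged-atom
   distance (< 4 Å), buried interface area
   ΔSASA = SASA(A) + SASA(B) − SASA(A∪B) with rupture-frame detection, and
   centre-of-mass distances such as W2 to its docking pocket.

## Core models

**WLC (Marko–Siggia)** — the tether force at extension *x* with persistence
length *Lp* and contour length *Lc*:

    F(x) = (kB·T / Lp) · [ ¼(1 − x/Lc)⁻² − ¼ + x/Lc ]

Fits constrain Lp ∈ [0.1, 1] nm and Lc > max extension; events are kept
only if the fit rmse is at most the condition mean + 1 SD and Lc ≥ 30 nm
(the full PEG-tether contour length).

**Mixture model** — rupture forces F are modelled as
Σ_k w_k·N(μ_k, σ_k²); the component count minimises
BIC = (3k−1)·ln n − 2·ln L, ties toward smaller k. Peak parameters are
reported in the histogram-fit convention: the chosen model is refined by
least squares against the Freedman–Diaconis-binned density
(bin width 2·IQR·n^(−1/3)). For k = 2, 100·w_high is the **strengthened
fraction** — the share of interactions with reinforced adhesion.

**Surface areas** — Shrake–Rupley with a golden-spiral quadrature
(default 960 points, probe 1.4 Å, Bondi radii); a decay of ΔSASA to zero
marks dimer rupture.

## Worked example

Draw 2000 rupture forces from the wild-type + 20 nM antibody condition
(60% native peak at 48.6 ± 17.3 pN, 40% strengthened peak at
73.1 ± 27.5 pN) and recover the distribution with the full pipeline:

```python
import cadforce as cf

forces = cf.sample_rupture_forces(cf.STUDY_CONDITIONS["wt_ab_20nM"], 2000, seed=7)
est = cf.BICGaussianMixture(k_max=3, random_state=7).fit(forces)
print(f"chosen k : {est.k_}")
print("BIC      :", {k: round(v, 1) for k, v in est.bic_.items()})
for w, m, s in zip(est.weights_, est.means_, est.sds_):
    print(f"peak     : {m:5.1f} ± {s:4.1f} pN   (weight {w:.2f})")
print(f"strengthened fraction: {est.strengthened_fraction_:.1f}%")
```

prints

```
chosen k : 2
BIC      : {1: 18567.5, 2: 18468.4, 3: 18490.3}
peak     :  48.8 ± 17.8 pN   (weight 0.66)
peak     :  76.7 ± 26.3 pN   (weight 0.34)
strengthened fraction: 33.9%
```

BIC correctly prefers two components; the recovered peaks straddle the
generating values (single-seed estimates of strongly overlapping
components scatter by a few pN — the acceptance analysis below reports
medians over 25 replicate draws, which land within ±3 pN).

The same analysis is available from the shell over directories of
force-curve TSVs:

```
cadforce simulate-curves --out curves/ --condition wt_ab_20nM --n 500 --seed 7
cadforce analyze-curves  --in curves/ --out events.tsv
cadforce fit-mixture     --in events.tsv --out mixture.json --kmax 3 --seed 7
```

and the trajectory statistics via `traj-rmsf`, `traj-saltbridge`,
`traj-sasa`, and `traj-comdist`.

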