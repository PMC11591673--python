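# zframan

Raman band deconvolution and PLS-DA developmental fingerprinting for
zebrafish embryo and larva organs.

In vivo Raman spectra of developing zebrafish (iris, forebrain, melanocytes,
heart, muscle, swim bladder; 24–168 hours post-fertilisation) are dense
mixtures of overlapping vibrational bands on a strong fluorescence
background.  `zframan` implements the complete analysis chain that turns
such spectra into per-organ developmental fingerprints, plus a synthetic
spectrum generator with full ground truth so the chain is testable end to
end without access to raw instrument data.

## The method

1. **Deconvolution.**  Each spectrum is fit as a polynomial background plus
   a sum of damped-harmonic-oscillator (DHO) band profiles

   I(ν) = A₀ · F²Wν / ((F² − ν²)² + (Wν)²)

   by bounded nonlinear least squares with an analytic Jacobian, yielding
   per band the natural frequency *F* (cm⁻¹), damping width *W* (cm⁻¹) and
   integrated area *A* (counts·cm⁻¹).  Seeds come from prominence-based
   peak detection plus a second-derivative shoulder detector that resolves
   strongly overlapped neighbours.

2. **Band registry.**  Fitted components are grouped across all spectra by
   single-linkage clustering on frequency (gap cut at δ = 10 cm⁻¹) into
   canonical bands ("980", "1409", …).  A band is retained for an organ iff
   at some stage strictly more than 60% of the animals measured present it;
   retained bands carry literature vibration assignments (phosphate
   symmetric stretch at 980 cm⁻¹, phenylalanine at 1002 cm⁻¹, CH
   stretching 2852–3058 cm⁻¹, O–H/water at 3213 and 3431 cm⁻¹, …).

3. **Feature matrix.**  Per organ, one row per (animal, stage) and one
   column per descriptor A\<band\>/W\<band\>/F\<band\>, autoscaled (the
   three variables live on very different scales), missing descriptors
   mean-imputed after scaling.

4. **PLS-DA fingerprint.**  NIPALS PLS2 of the centred stage-indicator
   matrix on the descriptors; the number of significant components A\* is
   chosen by requiring each component to improve leave-one-animal-out Q²
   by more than a gain threshold.  The fingerprint reports, for every stage
   k and descriptor j, the scalar projection s_kj (signed; positive =
   descriptor above its average at that stage) and per descriptor the
   vector module m_j = √(Σ_k s_kj²), an importance score that correlates
   strongly with VIP.

`PLSFingerprint` is a scikit-learn style estimator (`fit(X, y, groups)`,
`get_params`/`set_params`, trailing-underscore attributes) and composes
with sklearn tooling; `BandClusterer` and `FeatureScaler` follow the same
conventions.

## Worked example

```python
import zframan as z
from zframan import bands as B, features as FT, pls
from zframan.deconv import fit_dataset

ds = z.simulate_dataset(seed=42)            # 216 spectra, 6 animals, 6 organs
comp = fit_dataset(ds.spectra)              # deconvolution report
reg, lab = B.cluster_band_frequencies(comp, delta=10.0)
pres = B.presence_table(lab, ds.manifest)
ret = B.retain_bands(pres, threshold=0.60)
print(f"{len(reg)} bands identified, {len({b for bs in ret.values() for b in bs})} retained")
print("swim bladder bands:", ret["swim_bladder"])

mat = FT.build_features(lab, ret, "swim_bladder", ds.manifest)
tab = pls.fingerprint(mat, organ="swim_bladder")
print("significant components:", tab.n_components,
      "  R2:", tab.r2[: tab.n_components].round(3),
      "  Q2:", tab.q2[: tab.n_components].round(3))
print(tab.to_frame().head(6).round(3).to_string(index=False))
```

prints (abridged):

```
28 bands identified, 24 retained
swim bladder bands: ['980', '1002', '1156', '1409', '1603', '2929', '3213', '3431']
significant components: 2   R2: [0.325 0.643]   Q2: [0.322 0.632]
descriptor  module    s96   s120  s144   s168
     F1603   0.474 -0.330 -0.085 0.104  0.312
     W1002   0.472 -0.337 -0.076 0.112  0.301
     F1409   0.468 -0.322 -0.088 0.099  0.312
     F1156   0.460 -0.223  0.231 0.229 -0.237
     W1603   0.460 -0.225  0.230 0.230 -0.235
     W1409   0.454 -0.310 -0.089 0.093  0.306
```

Reading: the swim-bladder PLS-DA supports two cross-validated components
(Q² = 0.63).  The highest-module descriptors are frequencies and widths of
bands 1603, 1409, 1156 and 1002 — exactly the descriptors the generator
planted as stage-discriminating.  F1603 rises monotonically from 96 to
168 hpf (negative projection early, positive late), while F1156 peaks in
mid-development.

The same chain runs from the shell:

```bash
zframan simulate --seed 42 --out data/
zframan run-all --seed 42 --input-dir data/ --out results/
```

which writes the fit report, band registry, presence/retention tables,
per-organ feature matrices and fingerprint CSVs plus a run log.

## Layout

```
src/zframan/
  io.py        spectra + manifest reading/writing, validation
  deconv.py    DHO profile, background estimation, joint fitting
  bands.py     band clustering, presence, retention, annotations
  features.py  descriptor matrices, autoscaling
  pls.py       NIPALS PLS2, Q2 CV, projections, modules, VIP
  synth.py     synthetic study generator with ground truth
  pipeline.py  end-to-end orchestration
  cli.py       command-line interface
docs/methods.md   model, parameter and design documentation
```
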