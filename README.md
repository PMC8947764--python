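# interbrain

Models and analyses of the inter-brain neural relationship during social
interaction: why the activity of two (or more) interacting subjects is
correlated across brains, and why the *shared* part of that activity is
large and slow while the *divergent* part is small and fast.

The package is aimed at computational neuroscientists studying
hyperscanning-style data — simultaneously recorded slow neural activity
(e.g. band-averaged LFP power at 2.5-s resolution) from socially
interacting subjects — and at modelers who want a tested reference
implementation of the coupled-dynamics account of inter-brain synchrony.

## The core quantities and model

For a dyad with activity a1(t), a2(t), define the mean and difference
components aM = (a1 + a2)/2 and aD = (a1 − a2)/2. With hats denoting
time-mean subtraction, the inter-brain Pearson correlation is

    corr = (ÂMᵀÂM − ÂDᵀÂD) / √((ÂMᵀÂM + ÂDᵀÂD)² − 4(ÂMᵀÂD)²)

so positive correlation ⇔ Var(aM) > Var(aD). Timescales (power spectral
centroids) are *not* constrained by this identity — the package's surrogate
generator builds sessions with identical correlation and component
variances but reversed relative timescales to prove it.

The generative model couples the subjects' activity linearly,

    τ · da/dt = C a(t) + b(t),   C = [[−CS, CI], [CI, −CS]],

driven by behavioral modulation b(t) from a Markov chain over joint
behaviors. In the eigenbasis of C the components decouple: the mean
feels eigenvalue −CS + CI (positive feedback from the across-brain
coupling CI amplifies and slows it) and the difference feels −CS − CI
(negative feedback suppresses and speeds it). A reduced flat-spectrum
version yields closed forms Var-ratio ≈ (CS+CI)/(CS−CI) and
centroid-ratio ≈ (CS−CI)/(CS+CI), invertible into coupling estimates.
The model generalizes to n subjects (mean direction vs. an (n−1)-dim
difference subspace), and a two-oscillator Kuramoto model is included as
the discriminating alternative. See `docs/methods.md` for details.

## Worked example

Simulate a 100-minute shared-environment session (coupling CI = 0.4,
behavior chain calibrated to a 0.58 same-behavior probability), decompose
it, and contrast it with its own uncoupled control:

```python
import numpy as np
import interbrain as ib

chain = ib.synth_transition_matrix(ib.SynthChainSpec(target_same_prob=0.58))
cfg = ib.RunConfig()                       # one-chamber defaults
sess = ib.simulate_session(cfg, chain, seed=1)

pair = ib.decompose_pair(sess.activity)
sm = ib.spectral_summary(pair.mean, 2.5)
sd = ib.spectral_summary(pair.diff, 2.5)
print(f"correlation    = {ib.interbrain_correlation(*sess.activity.values):.3f}")
print(f"variance ratio = {pair.variance_ratio:.2f}")
print(f"centroid ratio = {pair.centroid_ratio():.3f}")

ctrl = ib.synth_uncoupled_control(sess)    # same b(t), CI = 0
_, c1, n = ib.remove_coordinated_epochs(sess.activity, sess.behavior)
_, c0, _ = ib.remove_coordinated_epochs(ctrl.activity, sess.behavior)
print(f"post-removal corr: coupled {c1:.3f}, uncoupled {c0:.3f} ({n} bins kept)")

spec = ib.ReducedSpec(cs=1.0, ci=0.4, tau=15.0, duration_s=6000.0)
est = np.mean([ib.recover_coupling(
    ib.simulate_reduced(spec, seed=s).variance_ratio, 1.0, "variance").value
    for s in range(20)])
print(f"recovered CI from variance ratio (20 seeds): {est:.3f}")
```

Output:

```
correlation    = 0.766
variance ratio = 7.54
centroid ratio = 0.225
post-removal corr: coupled 0.569, uncoupled -0.052 (1039 bins kept)
recovered CI from variance ratio (20 seeds): 0.395
```

Reading it: the coupled session shows the signature pattern — strong
inter-brain correlation, a mean component ~7× larger in variance and ~4×
slower than the difference component. After removing every bin of
coordinated behavior, correlation persists *only* with across-brain
coupling; the paired control sharing the identical modulation loses it.
And inverting the reduced-model variance-ratio formula on simulated
sessions recovers the generating coupling strength (0.4) to a few percent.

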