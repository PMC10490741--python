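# mibci

Multiclass motor-imagery brain–computer interface (MI-BCI) pipeline that
fuses **channel-local wavelet-scattering features** with **inter-channel
functional-connectivity features**, selects the most discriminative ones
with a multiclass Fisher score, and classifies them with a
one-versus-the-rest RBF-kernel SVM under session-transfer protocols.

## The problem

Decoding which of four movements (left hand, right hand, feet, tongue) a
person is imagining from 22-channel EEG is hard because the involved
cortical areas are adjacent and the discriminative signatures — μ/β-band
event-related desynchronization (ERD) and changes in inter-regional
phase synchronization — are weak, subject-specific and drift between
recording sessions. Features computed from single channels ignore the
network structure; connectivity features alone are too noisy. This
package implements the fusion of both, plus the evaluation machinery
(session-to-session and calibration-session transfer, exact paired
statistics) needed to judge whether the fusion actually helps.

## The method

Per preprocessed epoch `x` (8–30 Hz zero-phase Butterworth, baseline
correction, common average reference, 2.5–5 s window at 250 Hz):

* **TIFs** — translation-invariant features from a scattering network:
  iterated analytic-Morlet wavelet convolutions and moduli with a
  low-pass average of invariance scale *T* = 2 s,
  `S_0 = x*φ`, `S_1 = |x*ψ_λ1|*φ`, `S_2 = ||x*ψ_λ1|*ψ_λ2|*φ`,
  computed on an 11-channel sensorimotor subset;
* **BCFs** — brain-connectivity features: per channel pair, the phase
  lag index `PLI = |⟨sign Δφ(t)⟩|`, the phase correlation
  `r(φ_i, φ_j)`, or the Pearson correlation, with instantaneous phases
  from the Hilbert analytic signal; the symmetric 22×22 adjacency per
  epoch vectorizes to `nc(nc−1)/2 = 231` features;
* fusion is serial concatenation; features are ranked by the multiclass
  Fisher score `F(X_j) = Σ_k n_k(μ_kj − μ_j)² / Σ_k n_k σ_kj²` and the
  top *S* are fed to an OVR RBF-SVM whose `(C, γ, S)` are grid-searched
  by stratified 10-fold cross-validation inside the training set;
* performance: accuracy, Cohen's κ, macro precision/recall; feature
  cases are compared across subjects by the exact two-sided Wilcoxon
  signed-rank test.

Because the benchmark recordings are external, the package ships a fully
seeded synthetic generator that emulates the paradigm and lets you plant
class structure either in band power (ERD) or purely in phase coupling —
so each feature family can be validated against a known ground truth.

## Worked example

Simulate two sessions of a reduced study (8 channels, 20 trials per
class) with both ERD and phase-coupling class structure, then train on
session 1 and test on session 2 with fused features:

```python
import numpy as np
from mibci import TransferPipeline, PipelineConfig
from mibci.evaluation import TrainConfig
from mibci.scattering import ScatteringConfig
from mibci.simulate import ParadigmConfig, ClassSignature, generate_session, to_trial_set

montage = ("FC1", "FCz", "FC2", "C3", "Cz", "C4", "CP1", "CP2")
erd = {"LH": "C4", "RH": "C3", "F": "Cz", "T": "FCz"}
pairs = {"LH": ("C4", "CP2"), "RH": ("C3", "CP1"), "F": ("Cz", "FCz"), "T": ("FC1", "FC2")}
signatures = {
    cls: ClassSignature(
        erd_channels=(erd[cls],), erd_band=(18, 22), erd_depth=0.6,
        coupling_pairs=((*pairs[cls], np.pi / 2, 1.0),),
    )
    for cls in erd
}
paradigm = ParadigmConfig(n_channels=8, montage=montage, trials_per_class=20, artifact_rate=0.0)
s1 = to_trial_set(generate_session(paradigm, signatures, seed=1, session_id="S1"))
s2 = to_trial_set(generate_session(paradigm, signatures, seed=2, session_id="S2"))

config = PipelineConfig(
    tif_subset=("C3", "Cz", "C4", "FCz"),
    scattering=ScatteringConfig(wavelets_per_octave=(2, 1)),
    training=TrainConfig(c_grid=(1.0, 8.0), gamma_grid=(2**-5, 2**-3), s_grid=(30,), n_folds=5),
)
results = TransferPipeline(s1, s2, strategy="sst", case="tif+pli", config=config).fit()
print(results.summary())
```

which prints

```
Transfer classification results
==============================================
Strategy                                   SST
Feature case                           tif+pli
Training epochs                             80
Test epochs                                 80
Selected features (S)                       30
SVM C                                        1
SVM gamma                              0.03125
----------------------------------------------
Validation accuracy (%)                  92.50
Test accuracy (%)                        93.75
Cohen kappa                               0.92
Macro precision                           0.94
Macro recall                              0.94
==============================================
Confusion matrix (rows true, cols predicted):
           F    LH    RH     T
     F    17     1     1     1
    LH     0    20     0     0
    RH     1     1    18     0
     T     0     0     0    20
```

Validation accuracy is the winning mean cross-validated accuracy on the
training session; test accuracy is measured on the held-out second
session. The same data with `case="tif"` (channel features only) tests
what connectivity adds: with class structure planted purely in phase
coupling, the TIF-only case falls to chance (~25%) while the fused case
stays high — the machine-checked version of this comparison runs in
`tests/test_acceptance.py` over 20 seeded replicates.

The CLI mirrors the library (`mibci simulate`, `mibci preprocess`,
`mibci features tif|bcf|fuse`, `mibci evaluate`, `mibci compare`); run
`mibci --help` for the flags.

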