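# fedglioma

Federated classification of gliomas and their molecular subtypes from
two-modality MR images — without pooling patient data across hospitals.

Hospitals hold small, class-imbalanced, scanner-shifted glioma cohorts and
usually cannot share them.  `fedglioma` implements a complete federated
scheme for this setting at desk scale:

* a **2D two-stream CNN** (one stream per MRI modality: FLAIR and T1ce)
  with softmax **attention fusion**
  a_s = exp(w_s^T f_s) / Σ_n exp(w_n^T f_n), a bilinear layer and a
  fully connected softmax head;
* a **balanced focal loss**
  L = −[β q̂^γ p log p̂ + (1−β) p̂^γ q log q̂] for severe class imbalance
  (γ=0, β=0.5 recovers half the binary cross-entropy);
* **dynamically regularized federated training**: the local update
  direction g = ∇L(w) + λ_wd w − c_i + α(w − w_c) with gradient-correction
  state c_i, and the server update h ← h + (w_c − w̄)/N, w_c ← w̄ − h —
  plus a FedAvg baseline and a pooled central-learning reference;
* unpaired **cycle-consistent domain mapping** (least-squares GAN + L1
  cycle loss) to harmonize one site's intensity domain toward another's;
* **scan-level majority voting**: a patient is positive iff strictly more
  than half of their M = 15 tumor slices (5 per anatomical view) are
  predicted positive;
* a deterministic **synthetic multi-site cohort generator** (3D
  two-modality volumes, spherical textured lesions, binary masks,
  per-site class imbalance and scanner-style intensity shift) so the whole
  pipeline is testable without any MRI download.

Everything — including the CNN and GAN forward/backward passes — is plain
numpy with hand-written backprop, verified against finite differences.
Real data in NIfTI format (one FLAIR, one T1ce and one binary mask per
patient, plus a CSV manifest) is supported through the same interfaces.

## Worked example

```python
from dataclasses import replace

from fedglioma import (FederatedClassifier, SiteSpec, generate_site,
                       split_patients, preprocess_cohort)
from fedglioma.experiment import BENCHMARK_FL
from fedglioma.network import PRESETS

# two hospitals: a balanced site and a heavily imbalanced one
clients, tests, test_scans = {}, {}, []
for i, (sid, n0, n1) in enumerate([("siteA", 10, 10), ("siteB", 12, 4)]):
    scans = generate_site(SiteSpec(site_id=sid, n_class0=n0, n_class1=n1,
                                   seed=100 + i))
    train, test = split_patients(scans, train_fraction=0.8, seed=0)
    clients[sid] = preprocess_cohort(train, out_size=32)   # 15 slices/patient
    tests[sid] = preprocess_cohort(test, out_size=32)
    test_scans += test

model = FederatedClassifier(clients, replace(BENCHMARK_FL, seed=0),
                            PRESETS["tiny"], test_sets=tests)
results = model.fit()
print(results.summary())

patients, patient_report, slice_report = results.evaluate_patients(test_scans)
print(f"slice-level  accuracy: {slice_report.accuracy:.3f}")
print(f"patient-level accuracy: {patient_report.accuracy:.3f} "
      f"(sens {patient_report.sensitivity:.2f}, "
      f"spec {patient_report.specificity:.2f})")
```

```
Federated/central classifier fit
========================================
architecture parameters : 5482
rounds completed        : 30
algorithm               : etfeddyn
local epochs / round    : 5
alpha (dyn. reg.)       : 0.1
loss                    : focal(beta=0.25, gamma=2.0)
final train loss [   siteA]: 0.0000
final train loss [   siteB]: 0.0001
final test acc   [   siteA]: 0.8333
final test acc   [   siteB]: 0.9333
final test acc   [  pooled]: 0.8762
convergence round (2%)  : 17
```
```
slice-level  accuracy: 0.876
patient-level accuracy: 0.857 (sens 0.67, spec 1.00)
```

The federation reaches ~88% pooled slice accuracy by round 17 without
either site revealing a voxel to the other.  On this particular 7-patient
test split the scan-level vote flips one genuinely hard positive patient
(most of whose slices are misclassified), so the patient-level figure sits
a notch below the slice-level one — with so few test patients a single
scan moves the estimate by 14 points.  Averaged over repeated runs with a
larger held-out set the vote helps: `scripts/acceptance.py` reports median
patient-level accuracy above slice-level accuracy across its repetitions.

The same pipeline is scriptable from the shell:

```bash
fedglioma generate --sites sites.yaml --out cohort --seed 0
fedglioma preprocess --site-dir cohort/siteA --out siteA.h5 --out-size 32
fedglioma map-domain --source siteB.h5 --target siteA.h5 --out siteB_mapped.h5
fedglioma train --mode fl --algorithm etfeddyn \
    --client siteA=siteA.h5 --client siteB=siteB_mapped.h5 --out run/
fedglioma evaluate --checkpoint run/checkpoint.h5 --site-dir cohort/siteA \
    --out metrics.json
fedglioma compare --sites sites.yaml --out grid.csv   # ablation grid
```

## Layout

| module | contents |
|---|---|
| `fedglioma.synthetic` | site specs, cohort generator, domain shift, patient-wise splits, NIfTI IO |
| `fedglioma.preprocess` | tumor-slice extraction, mask attenuation, resize + normalize, augmentation, HDF5 slice datasets |
| `fedglioma.network` | the two-stream attention-fusion classifier (numpy forward/backward) |
| `fedglioma.losses` | balanced focal loss and its cross-entropy limit |
| `fedglioma.federated` | EtFedDyn-style and FedAvg updates, central baseline, `FederatedClassifier` / `CentralClassifier` / `FitResults` |
| `fedglioma.domain_map` | toy cycle-consistent mapper, `DomainMapper` |
| `fedglioma.evaluate` | majority vote, confusion metrics, multi-run aggregation |
| `fedglioma.experiment` | benchmark scenarios and the repeated-experiment driver |
| `fedglioma.cli` | `fedglioma` command-line entry point |

`docs/methods.md` documents the model equations, defaults, the synthetic
data's scope and limits, and every numerically load-bearing design choice.
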