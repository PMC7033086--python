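"""Generate a synthetic whole-body FBPA study and inspect it.

Builds the default 11-organ study (7 frames of 455 s, blood samples on the
0.5-50 min grid, 5% frame noise) and prints the organ TAC peaks alongside
the true distribution volumes that generated them.  Higher-Vt organs retain
more tracer; the brain is the exception, peaking late (~37 min) because of
its slow transport kinetics.
"""

import numpy as np

from fbpakin import SimulationConfig, make_study_fixture

study = make_study_fixture(SimulationConfig(noise_cv=0.05, seed=7))

print(f"{'organ':16s} {'true Vt':>8s} {'peak kBq/ml':>12s} {'peak frame':>11s}")
for _, row in study.truth.iterrows():
    tac = study.tacs[row["organ"]]
    k = int(np.argmax(tac.activity))
    print(f"{row['organ']:16s} {row['true_vt']:8.2f} {tac.activity[k]:12.2f} "
          f"{k + 1:5d} ({tac.times[k]:.1f} min)")

blood = study.blood.post_injection()
print(f"\nplasma samples (kBq/ml) at {blood.sample_times.tolist()} min:")
print(np.round(blood.plasma, 2).tolist())
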