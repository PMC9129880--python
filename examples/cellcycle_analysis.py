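"""Cell-cycle phase quantification from labelled state sequences.

Generates PCNA-like per-frame phase-label sequences for leader and follower
cohorts, extracts fully observed phase durations, compares the identities
with the normality-gated test procedure, fits one- vs two-component
Gaussian mixtures to the follower G1 distribution (bimodality), and shows
the dispersion collapse of a Notch-inhibition-like dataset.
"""

import numpy as np

from crestchain.cellcycle import (
    auto_compare,
    dispersion_ratio,
    durations_from_states,
    fit_mixture,
    onset_phase,
)
from crestchain.synth import gen_cellcycle, gen_phase_sequences, notch_inhibited_config

durations = {"leader": {}, "follower": {}}
onsets = {}
for ident in ("leader", "follower"):
    sequences = gen_phase_sequences(ident, 60, seed=8, with_onset=True)
    for phase in ("G1", "S", "G2", "M"):
        durations[ident][phase] = np.array([
            durations_from_states(s).durations[phase] for s in sequences
        ])
    onsets[ident] = np.mean(
        [onset_phase(s) == "S_or_G2" for s in sequences]
    )

print("phase durations, mean +/- SD hours (n = 60 cells each):")
for phase in ("G1", "S", "G2", "M"):
    a, b = durations["leader"][phase], durations["follower"][phase]
    res = auto_compare(a, b)
    print(f"  {phase:2s}  leaders {a.mean():4.1f} +/- {a.std():3.1f}   "
          f"followers {b.mean():4.1f} +/- {b.std():3.1f}   "
          f"{res['test_name']} p = {res['p']:.2g}")
print(f"\nmigration onset in S/G2: leaders {onsets['leader']:.0%}, "
      f"followers {onsets['follower']:.0%}")

g1 = gen_cellcycle("follower", "G1", 200, seed=9)
fit = fit_mixture(g1, seed=9)
print(f"\nfollower G1 mixture fit: k = {fit.k}, "
      f"means = {np.round(fit.means, 1)} h, "
      f"minor weight = {fit.minor_weight:.2f}")

notch = gen_cellcycle("follower", "G1", 200, notch_inhibited_config(), seed=9)
print(f"Notch-inhibited follower G1: sd {notch.std():.2f} h vs control "
      f"{g1.std():.2f} h (dispersion ratio "
      f"{dispersion_ratio(g1.std(), notch.std()):.2f})")
print("\nLeaders cycle with a short G1 and long S; followers the opposite,")
print("with a leader-like minor peak that vanishes under Notch inhibition.")
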