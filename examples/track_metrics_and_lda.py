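"""Track metrics and identity discrimination on synthetic imaging data.

Generates biased-random-walk tracks for 20 leaders and 60 followers at the
5-minute imaging cadence, computes the per-cell metric suite (mean speed,
directionality, ventral distance), and fits a Fisher linear discriminant to
ask which feature best separates the two migratory identities.
"""

from crestchain.lda import fit_lda, random_control, rank_features
from crestchain.metrics import summarize
from crestchain.synth import gen_tracks

table = gen_tracks(n_leaders=20, n_followers=60, n_frames=96, seed=3)
per_cell, aggregates = summarize(table)

print("per-identity metric means (8 h of tracking):")
for ident, stats in aggregates["identities"].items():
    print(f"  {ident:9s} n={stats['n']:2d}  "
          f"speed {stats['mean_speed']['mean']:5.1f} um/hr  "
          f"directionality {stats['directionality']['mean']:.2f}  "
          f"ventral {stats['ventral_distance']['mean']:6.1f} um")

features = per_cell[
    ["ventral_distance", "mean_speed", "directionality", "identity"]
].dropna()
model = fit_lda(features)
print("\nstandardized discriminant coefficients (leader vs follower):")
for feat, coef in zip(model.features, model.coef_standardized):
    print(f"  {feat:18s} {coef:+.3f}")
print("feature ranking:", " > ".join(rank_features(model)))

control = random_control(features, seed=0)
print(f"\nseparation statistic: data {model.separation:.1f} vs "
      f"random control {fit_lda(control).separation:.3f}")
print("\nVentral distance carries the separation, as in the in-vivo data;")
print("a random dataset with the same shape shows essentially none.")
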