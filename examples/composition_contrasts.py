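"""Chain behaviour as a function of leader/follower composition.

Simulates a few replicates of four chain architectures — all followers
(the Notch loss-of-function analogue), all leaders (gain of function),
1:1 and the 1:3 control — and prints the behavioural signature of each:
ventral advance, directionality and over-migration.
"""

import numpy as np

import crestchain as cx
from crestchain.metrics import summarize, trajectory_to_track_table
from crestchain.scoring import ScoreConfig

N_REPS = 8
arena = cx.Arena()
margin = ScoreConfig().overmigration_margin

print(f"{'composition':14s} {'front y (um)':>12s} {'ventral (um)':>12s} "
      f"{'direction.':>10s} {'leader front':>12s} {'over-migrated':>13s}")
for name in ("all-follower", "all-leader", "1:1", "1:3"):
    front, ventral, direct, lead, over = [], [], [], 0, 0
    for seed in range(N_REPS):
        traj = cx.simulate(cx.Composition.preset(name), seed=seed)
        report = cx.score_all(traj)
        per_cell, _ = summarize(trajectory_to_track_table(traj))
        front.append(traj.positions[-1, :, 1].max())
        ventral.append(per_cell["ventral_distance"].mean())
        direct.append(per_cell["directionality"].mean())
        lead += report.leader_front["pass"]
        over += report.path_completion["over_migrated"]
    print(f"{name:14s} {np.median(front):12.1f} {np.mean(ventral):12.1f} "
          f"{np.mean(direct):10.2f} {lead:9d}/{N_REPS} {over:10d}/{N_REPS}")

print(f"\n(path end y = {arena.y_end:.0f} um; over-migration = final front "
      f"beyond y = {arena.y_end + margin:.0f} um)")
print("Leaderless chains barely advance; leader-only chains scatter (low")
print("directionality); 1:1 chains overshoot the path end; 1:3 chains stop")
print("at the target — the composition the in-vivo data support.")
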