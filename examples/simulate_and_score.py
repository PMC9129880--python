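"""Simulate one trunk-neural-crest chain and score its behaviour.

Builds an 8-cell chain with one leader per three followers (the control
architecture), runs 16 simulated hours of migration down the dorsoventral
corridor, and evaluates the five in-vivo-calibrated criteria: cohesion,
single-file arrangement, follower rearrangement, leader front retention
and path completion.
"""

import crestchain as cx

traj = cx.simulate(cx.Composition.preset("1:3"), seed=42)

report = cx.score_all(traj)
front_y = traj.positions[-1, :, 1].max()

print(f"simulated {traj.n_cells} cells for {traj.times[-1]:.0f} min "
      f"({traj.n_frames} frames at 5-min sampling)")
print(f"final chain front: y = {front_y:.1f} um "
      f"(path ends at y = {cx.Arena().y_end:.0f} um)")
print()
for name, result in report.to_dict().items():
    if name == "all_pass":
        continue
    detail = {k: round(v, 3) if isinstance(v, float) else v
              for k, v in result.items() if k != "pass"}
    print(f"  {name:24s} {'PASS' if result['pass'] else 'FAIL'}  {detail}")
print(f"\nall five criteria pass: {report.all_pass}")
print("\nA passing chain migrates cohesively in single file to the end of")
print("the path with the leader in front while followers exchange ranks —")
print("the behaviour of control chains in vivo.")
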