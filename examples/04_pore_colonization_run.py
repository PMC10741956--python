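"""A short pore-colonization run from a single seeded cell.

Runs the straight-channel uniform-growth scenario on a shortened pore
(0 <= x <= 30) so the run completes in under a minute, printing the
population statistics as the tissue fills the channel.
"""

from porevertex import ChannelGeometry, make_scenario_config, run_simulation

cfg = make_scenario_config(
    "straight-uniform",
    geom=ChannelGeometry(h=4.5, epsilon=0.0, x_min=0.0, x_max=30.0),
    t_end=1500.0,
)
trajectory = run_simulation(cfg, seed=1)

frame = trajectory.frame
print("   t     N    A1     p1     E1")
for _, row in frame[frame.t % 100 == 0].iterrows():
    print(f"{row.t:6.0f} {row.N:5.0f} {row.A1:5.2f} {row.p1:6.2f} {row.E1:6.2f}")
if trajectory.fill_time is not None:
    print(f"\npore filled (>=98% area) at t = {trajectory.fill_time:g} "
          f"with {frame.N.iloc[-1]:.0f} cells")
# N grows stochastically (one seeded cell, probabilistic divisions);
# A1 < 1 and p1 > 0 at late times show the crowding-induced compression.
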