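"""Track melanophores through a simulated developmental image series.

Simulates ten daily frames of a spotted pattern consolidating (cells drifting
toward spot centers at up to 5 px/day, new cells differentiating de novo),
links detections into tracks under the 100 px/day cap, and prints motion
statistics for tracks spanning at least 7 days. A stripe-holding series with
the same cells serves as the contrast: consolidating cells move farther.
"""

import stripespot as ss

spec = ss.PatternSpec(layout="spots", n_elements=6, element_width=48,
                      image_height=256, image_width=256, seed=8)

for mode in ("spot_consolidate", "stripe_hold"):
    series = ss.gen_development_series(spec, n_days=10, appearance_rate=2.0,
                                       drift=5.0, motion_mode=mode)
    frames = [truth.cells for _, truth in series]
    tracks = ss.link_tracks(frames, max_disp=100.0, max_gap_days=1)
    table = ss.motion_stats(tracks, min_span_days=7, max_missing=1)
    print(f"{mode}: {len(tracks)} tracks, {len(table)} spanning >= 7 days")
    print(f"  median total displacement: "
          f"{table['total_displacement'].median():6.2f} px")
    print(f"  median per-day speed:      "
          f"{table['median_speed'].median():6.2f} px/day")

print("\nConsolidating series show the larger displacements that distinguish")
print("spot-forming from stripe-holding pattern development.")
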