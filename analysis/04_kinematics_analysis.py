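"""Kinematic analysis: drift correction, trajectory similarity, reach speed.

Simulates prelesion and postlesion paw-reach sets (postlesion reaches
are more variable) plus a camera drift between sessions, then runs the
kinematic chain: drift estimation and removal, endpoint alignment,
occupancy-grid smoothing, within- and cross-condition median similarity,
and reach speeds. Writes similarity.csv and speeds.csv under results/.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from srtpipe import kinematics as km
from srtpipe import synth_tasks as st

OUT = Path("results")
SEED = 27_182
SPEC = km.GridSpec(width=240, height=200, smoothing_sigma=8.0)


def scene(rng, shape=(200, 240)):
    img = rng.random(shape)
    img[40:60, 150:180] += 5.0   # lever
    img[140:160, 30:50] += 4.0   # port
    return img


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    pre_p = st.KinematicParams(start=(60, 60), end=(190, 70), apex_height=40.0,
                               mean_speed=2500.0, noise_sd=2.0)
    post_p = dataclasses.replace(pre_p, noise_sd=6.0, mean_speed=1800.0)
    pre = st.simulate_trajectory_set("paw", pre_p, 15, int(rng.integers(2**31)))
    post = st.simulate_trajectory_set("paw", post_p, 15, int(rng.integers(2**31)))

    # postlesion camera drifted by a known shift; recover and undo it
    true_shift = (7, -4)
    big = scene(rng, shape=(300, 340))
    ref = big[50:250, 50:290]
    drifted = big[50 - true_shift[1]:250 - true_shift[1],
                  50 - true_shift[0]:290 - true_shift[0]]
    dx, dy = km.estimate_drift(ref, drifted)
    post = [t.translated(dx, dy) for t in post]          # drift corrupts tracking
    post = km.apply_drift(post, dx, dy)                  # ... and is undone

    rows = []
    grids = {}
    for name, group in (("Pre", pre), ("Post", post)):
        grids[name] = [km.occupancy_grid(t, SPEC) for t in km.align_endpoints(group)]
    rows.append(dict(pair="Pre~Pre", score=km.condition_similarity(grids["Pre"])))
    rows.append(dict(pair="Post~Post", score=km.condition_similarity(grids["Post"])))
    rows.append(dict(pair="Pre~Post",
                     score=km.condition_similarity(grids["Pre"], grids["Post"])))
    pd.DataFrame(rows).to_csv(OUT / "similarity.csv", index=False)

    speed_rows = [
        dict(condition=name, trial_index=t.trial_index, speed_px_per_ms=km.reach_speed(t))
        for name, group in (("Pre", pre), ("Post", post)) for t in group
    ]
    sp = pd.DataFrame(speed_rows)
    sp.to_csv(OUT / "speeds.csv", index=False)

    sim = pd.DataFrame(rows).set_index("pair")["score"]
    print(f"recovered camera drift: ({dx}, {dy}) px")
    print(f"median similarity: Pre~Pre {sim['Pre~Pre']:.1f}, "
          f"Post~Post {sim['Post~Post']:.1f}, Pre~Post {sim['Pre~Post']:.1f}")
    med = sp.groupby("condition").speed_px_per_ms.median()
    print(f"median reach speed: Pre {med['Pre']:.2f} px/ms, Post {med['Post']:.2f} px/ms")


if __name__ == "__main__":
    main()
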