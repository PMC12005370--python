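"""Behavioral analysis of the simulated cohort.

Per rat: Pre / Post_Late trial pools, reaction-time summaries, the
anticipation function G(t) and its pre-to-post integral change, and
normalized reward-retrieval durations. For the self-timing rat, the
Gaussian mode of the uncued hold-duration distribution before and after
the lesion. Writes rt_summary.csv, anticipation_change.csv,
retrieval.csv, and selftiming_modes.csv under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from srtpipe import behavior_metrics as bm
from srtpipe import core_io

DATA = Path("results/data/sessions.csv")
OUT = Path("results")


def main() -> None:
    sessions = core_io.read_session_table(DATA)
    by_rat: dict[str, list] = {}
    for s in sessions:
        by_rat.setdefault(s.rat_id, []).append(s)

    rt_rows, change_rows, retrieval_rows, mode_rows = [], [], [], []
    for rat, rat_sessions in sorted(by_rat.items()):
        if rat_sessions[0].task == "selftiming":
            for phase in ("Pre", "Post"):
                holds = np.array([
                    lt.hold
                    for s in rat_sessions if s.phase == phase
                    for lt in bm.classify_trials(s)
                    if lt.trial.cue_kind == "uncued"
                ])
                mode_rows.append(dict(rat_id=rat, phase=phase, n=holds.size,
                                      mode_s=bm.fit_gaussian_mode(holds)))
            continue

        pools = {c: bm.pool_condition(rat_sessions, c) for c in ("Pre", "Post_Late")}
        curves = {}
        for cond, pool in pools.items():
            rts = bm.extract_reaction_times(pool.trials)
            rt_rows.append(dict(rat_id=rat, condition=cond, **bm.rt_summary(rts)))
            curves[cond] = bm.anticipation_function(pool.trials)
        change_rows.append(dict(
            rat_id=rat,
            integral_change_s=bm.anticipation_integral_change(
                curves["Pre"], curves["Post_Late"]),
        ))
        recs = bm.normalized_retrieval(bm.retrieval_durations(rat_sessions))
        for rec in recs:
            retrieval_rows.append(dict(
                rat_id=rat, phase=rec["phase"],
                sessions=":".join(map(str, rec["session_indices"])),
                median_s=rec["median"], normalized=rec["normalized"]))

    pd.DataFrame(rt_rows).to_csv(OUT / "rt_summary.csv", index=False)
    pd.DataFrame(change_rows).to_csv(OUT / "anticipation_change.csv", index=False)
    pd.DataFrame(retrieval_rows).to_csv(OUT / "retrieval.csv", index=False)
    pd.DataFrame(mode_rows).to_csv(OUT / "selftiming_modes.csv", index=False)

    rt = pd.DataFrame(rt_rows)
    med_pre = rt[rt.condition == "Pre"]["median"].median()
    med_post = rt[rt.condition == "Post_Late"]["median"].median()
    dint = pd.DataFrame(change_rows)["integral_change_s"]
    ret = pd.DataFrame(retrieval_rows)
    ret_post = ret[ret.phase == "Post"]["normalized"].median()
    print(f"median RT: Pre {med_pre:.3f} s -> Post_Late {med_post:.3f} s")
    print(f"anticipation integral change: median {dint.median():+.3f} s "
          f"(positive in {np.mean(dint > 0):.0%} of rats)")
    print(f"normalized retrieval duration Post_Late: {100 * ret_post:.0f}% of Pre")
    for row in mode_rows:
        print(f"self-timing mode ({row['phase']}): {row['mode_s']:.2f} s")


if __name__ == "__main__":
    main()
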