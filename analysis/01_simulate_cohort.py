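"""Simulate the study cohort used by the downstream analysis scripts.

Generates, for each of eight rats, three prelesion and three postlesion
SRT sessions (800 trials each). Postlesion sessions use DLS-lesion-like
parameters: the internal deadline distribution scaled to 60% (the rats
wait less, releasing prematurely more often) and reward-port poke
latency scaled by 1.7 (slower whole-body movement). A ninth rat performs
the self-timing task before and after the lesion. All tables are written
under results/data/.
"""

from pathlib import Path

from srtpipe import core_io
from srtpipe import synth_tasks as st

OUT = Path("results/data")
SEED = 20_260_928

def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    base = st.DeadlineModelParams()
    lesion = st.lesioned_params(base, deadline_scale=0.6, poke_scale=1.7)

    sessions = []
    for r in range(8):
        rat = f"rat{r:02d}"
        for i in range(3):
            sessions.append(st.simulate_srt_session(
                base, 800, seed=SEED + 100 * r + i, rat_id=rat,
                session_index=i, phase="Pre", lesion_group="bDLS"))
        for i in range(3):
            sessions.append(st.simulate_srt_session(
                lesion, 800, seed=SEED + 100 * r + 50 + i, rat_id=rat,
                session_index=3 + i, phase="Post", post_ordinal=i + 1,
                lesion_group="bDLS"))

    timing = st.SelfTimingParams()
    shifted = st.SelfTimingParams(timed_mu=0.97)  # postlesion leftward mode shift
    for i in range(2):
        sessions.append(st.simulate_selftiming_session(
            timing, 600, seed=SEED + 900 + i, rat_id="rat08",
            session_index=i, phase="Pre", lesion_group="bDLS"))
        sessions.append(st.simulate_selftiming_session(
            shifted, 600, seed=SEED + 950 + i, rat_id="rat08",
            session_index=2 + i, phase="Post", post_ordinal=i + 1,
            lesion_group="bDLS"))

    core_io.write_session_table(sessions, OUT / "sessions.csv")
    n = sum(len(s) for s in sessions)
    print(f"wrote {OUT / 'sessions.csv'}: {len(sessions)} sessions, {n} trials")


if __name__ == "__main__":
    main()
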