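"""Simulate one full data-collection session and check its bookkeeping.

The default protocol is 8 participants x 18 fifteen-second tasks (7 of them
high-risk shaking) recorded by 6 body-worn sensors at 100 Hz, so a session
holds 144 task executions and 864 recordings.
"""
from shakesense import MotionParams, default_protocol, simulate_session

protocol = default_protocol()
session = simulate_session(protocol, MotionParams(), seed=0)

counts = session.task_label_counts()
print(f"tasks performed:        {counts['n_tasks']}")
print(f"  aggressive:           {counts['n_aggressive']}")
print(f"  non-aggressive:       {counts['n_non_aggressive']}")
print(f"recordings (x6 sites):  {session.n_recordings}")

rec = session.entries[0].recording
print(f"\nfirst recording: {rec.recording_id}, {rec.n} samples at {rec.fs:g} Hz "
      f"({rec.duration_s:g} s)")
# 56 of the 144 tasks are aggressive because each participant performs the
# 7 high-risk tasks once; every recording is 15 s of triaxial acceleration.
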