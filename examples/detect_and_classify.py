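"""Detect confirmed worsening events and classify them under each PIRA rule.

A patient starts at EDSS 2.0, worsens to 3.0 at week 12 (confirmed at week
24), and has a relapse on day 100 — after the worsening onset but inside the
Standard1/2 windows. The four definitions disagree on whether this event is
progression independent of relapse activity.
"""

from pirabias import AnalysisConfig, PatientTrajectory, classify_events, detect_events

traj = PatientTrajectory.from_visits(
    "example-1",
    visits=[(0, 2.0), (84, 3.0), (168, 3.0), (252, 3.0), (336, 3.0)],
    relapses=[100],
)
config = AnalysisConfig()

events = detect_events(traj, config)
for e in events:
    print(
        f"{e.kind}: onset day {e.onset_day} (EDSS {e.onset_value}) vs reference "
        f"day {e.reference_day} (EDSS {e.reference_value}), confirmed day {e.confirmation_day}"
    )

for definition in ("standard1", "standard2", "standard3", "non_raw"):
    classified = classify_events(traj, events, definition, config)
    labels = [e.classification for e in classified if e.kind == "worsening"]
    print(f"{definition:>9}: {labels}")

print(
    "\nThe relapse on day 100 falls inside every Standard window (all three "
    "extend at least 30 days past the onset), so those rules discard the "
    "event as undefined — it is not RAW either, since the relapse came after "
    "the onset. Non-RAW only requires the 90 days before onset to be "
    "relapse-free and keeps the event as PIRA."
)
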