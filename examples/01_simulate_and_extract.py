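"""Simulate a smart-home routine and extract behavior tuples.

Generates two weeks of binary sensor events for a ten-activity elderly
routine, then runs the contextual extraction sweep that turns raw
ON/OFF readings into (time, object, location, sub-activities, activity,
duration) tuples.
"""

from caawd import default_profile, extract_instances, generate_routine

stream = generate_routine(default_profile(days=14, seed=7))
print(f"{len(stream.events)} sensor events over 14 days "
      f"({len(stream.episodes)} scheduled activity episodes)")

instances = extract_instances(stream.events, stream.sensor_map)
print(f"{len(instances)} behavior tuples extracted\n")

print("first morning of day 3:")
for inst in instances:
    if inst.start_time.day == 3 and inst.start_time.hour < 12:
        subs = ",".join(inst.sub_activities) or "-"
        print(f"  {inst.start_time:%H:%M}  {inst.activity:<10} "
              f"{inst.location or '-':<12} {inst.object:<8} "
              f"dur {inst.duration_minutes:>3} min  subs: {subs}")

# Each line is one completed activity: the sweep paired the main
# sensor's ON/OFF, collected the sub-activity burst in order, and
# computed the duration in whole minutes.
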