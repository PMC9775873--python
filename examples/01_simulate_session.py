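"""Simulate one ramped LBNP session and inspect its ground truth.

Builds a chamber-pressure protocol (5-min baseline, -6 mmHg/min down to
60 mmHg, +6 mmHg/min back up, 10-min recovery), synthesizes the 500 Hz
ABP waveform for one subject, and prints what the generator knows to be
true about the session.
"""

import crmwave as cw

subject = cw.SubjectPhysiology(subject_id=1, rng_seed=42)
trace = cw.build_protocol(down_rate=6.0, up_rate=6.0, pmax=60.0)
recording, truth = cw.synthesize_session(trace, subject, seed=42)

crm = cw.compute_reference_crm(trace, trace.pmax)
print(f"session duration      : {recording.duration:.0f} s "
      f"({recording.samples.size} samples at {recording.fs:.0f} Hz)")
print(f"beats synthesized     : {len(truth)}")
print(f"reference CRM range   : {crm.min():.0f}% to {crm.max():.0f}%")
print(f"true HRDN at baseline : {truth['hrdn'].iloc[0] * 1000:.0f} ms")
nadir = truth.loc[truth['crm'].idxmin()]
print(f"true HRDN at CRM nadir: {nadir['hrdn'] * 1000:.0f} ms")
print(f"artifact beats        : {(truth['artifact'] != '').sum()}")

# The HRDN interval (half-rise to dicrotic notch) shortens as the
# compensatory reserve is depleted -- that monotone coupling is what the
# downstream regression model exploits.
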