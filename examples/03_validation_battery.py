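"""Model verification battery: pattern behaviour, calibration anchors,
extreme conditions, conservation, and the dimensional audit.

Prints the full check report; every check passes on the unmodified model,
with two documented unit warnings inherited from the source tables.
"""

from sdbass import full_validation_report

report = full_validation_report()
print(report.to_text())

# The S-shape and the ~20%-familiarity-in-2015 anchor are the model's
# pattern-behaviour test; the extreme-condition rows confirm that an empty
# population, total disgust, a tasteless burger, or a product that never
# reaches the market all behave as their boundary logic dictates while the
# closed population stays conserved.
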