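"""The recruitment and exclusion flow of the modelled study, end to end.

The reference manifest encodes the published counts exactly: 767
participants contribute 1029 recordings; technical/surplus recordings,
drug-screen-positive and subclinical participants, and one severe-cold
recording are removed in two stages, leaving 920 recordings from 691
participants.  The patient-vs-healthy contrast then spans 801 recordings,
71 of which (8.9%) were made on stimulant medication.
"""

from prosovoice import apply_exclusions, select_contrast
from prosovoice.synthetic_voice import reference_cohort

manifest = reference_cohort()
included, report = apply_exclusions(manifest)
print(report.to_text())

rows, labels = select_contrast(included, "adhd_vs_hc")
print(f"\nADHD vs HC: {len(rows)} recordings "
      f"({labels.sum()} patient, {(1 - labels).sum()} control)")
on_med = int(rows["on_medication"].sum())
print(f"on medication: {on_med} ({100 * on_med / len(rows):.1f}%)")

sub, _ = select_contrast(included, "adhd_vs_hc", "no_stimulants")
print(f"excluding stimulant recordings leaves {len(sub)}")
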