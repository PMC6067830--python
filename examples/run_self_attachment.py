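"""Simulate the self-attachment model and compare it with the reference table.

The circuit extends the empathy-states model with a medial orbitofrontal
(mOFC) region whose ramped stimulation in phase 3 models progress in the
bonding protocols: the mOFC excites the BLMA interneuron pool (silencing
the negatively valent amygdala) and the positively valent amygdala
(sustaining caregiving output) — the compassion state.
"""

from empathynet import (
    classify_state,
    compare_to_reference,
    load_reference,
    run_model,
    summarize,
)

result = run_model("self_attachment", seed=1)
summary = summarize(result)

report = compare_to_reference(summary, load_reference("self_attachment"))
print("simulated vs reference rates (|sim - ref| <= max(0.3 Hz, 25%)):")
print(report.round(2).to_string(index=False))
print(f"\npass fraction (single seed): {report.passed.mean():.2f}")

print("\nphase labels:")
for label in classify_state(summary):
    print(f"  phase {label.phase_index}: {label.label}")
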