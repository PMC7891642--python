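"""The eDNA-adapted fish index end to end on synthetic data.

Simulates a reference network of least-disturbed sites, fits the
reference-condition models, calibrates class boundaries, and assesses
fresh undisturbed and disturbed sites with the six-metric index.
"""

from ednafi import assess_synthetic_sites, fit_synthetic_reference

reference = fit_synthetic_reference(seed=1, n_ref=150, n_calibration=150)
print("calibrated class boundaries (High/Good, Good/Mod, Mod/Poor, Poor/Bad):")
print("  ", [round(b, 3) for b in reference.boundaries])

undisturbed = assess_synthetic_sites(reference, [0.0] * 30, seed=2)
disturbed = assess_synthetic_sites(reference, [1.0] * 30, seed=3)

print("\nundisturbed sites (first 5):")
print(undisturbed.head().round(3))
print("good fraction:", (undisturbed["dichotomy"] == "good").mean())

print("\nfully disturbed sites (first 5):")
print(disturbed.head().round(3))
print("degraded fraction:", (disturbed["dichotomy"] == "degraded").mean())

# Undisturbed sites score near the reference distribution and classify
# High/Good; full disturbance collapses the sensitive-guild metrics and
# drives the index towards its floor, classifying Poor/Bad.
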