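"""Run the full detection-table study on one seeded synthetic dataset.

Simulates 88 + 88 tablets (125 calibration / 51 prediction via the
stratified split), converts to band-restricted amplitude spectra and
scores {KNN, PLS-DA} x {none, AirPLS, AsLS, BEADS}.
"""

from thzfb import PipelineConfig, run_study

report = run_study(PipelineConfig(seed=0))
print(report.to_frame().to_string(index=False))
print()
print(f"config hash: {report.config_hash}")
print(f"PLS-DA components chosen by cross-validation: {report.plsda_components}")
print()
print("Columns mirror a detection table: misclassified counts and percent")
print("accuracy per split. Under the default synthetic conditions the")
print("band amplitudes are linearly separable, so corrected and")
print("uncorrected models both sit at or near 100 %.")
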