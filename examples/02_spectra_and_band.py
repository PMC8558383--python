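"""Convert a labelled trace set to amplitude spectra and select the band.

The one-sided FFT maps each pulse to its amplitude spectrum A(f); a
pure arrival delay leaves A(f) untouched, so the 0.3-1.0 THz band
amplitudes isolate the absorption contrast between tea and insect.
"""

import numpy as np

from thzfb import band_select, fft_dataset, generate_dataset

dataset, _ = generate_dataset(n_tea=20, n_insect=20, seed=0)
spectra = fft_dataset(dataset)
band = band_select(spectra, 0.3, 1.0)

print(f"traces:          {dataset.features.shape} (samples x time points)")
print(f"full spectra:    {spectra.features.shape} over 0-{spectra.variable_axis[-1]:.1f} THz")
print(f"analysis band:   {band.features.shape} over "
      f"{band.variable_axis[0]:.3f}-{band.variable_axis[-1]:.3f} THz")

means = band.features.mean(axis=1)
tea = means[band.labels == 0]
insect = means[band.labels == 1]
print(f"band-mean amplitude, tea:    {tea.mean():.4f} (min {tea.min():.4f})")
print(f"band-mean amplitude, insect: {insect.mean():.4f} (max {insect.max():.4f})")
print()
print("Every insect band-mean sits below every tea band-mean: the")
print("attenuation contrast survives drift and noise in this band.")
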