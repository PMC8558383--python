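"""Recover a known scattering drift with AsLS, AirPLS and BEADS.

The benchmark signal is the generator's drift family plus a single
positive peak of height 1 — the situation the correctors are built
for.  AsLS and AirPLS estimate the baseline directly; BEADS splits the
record into sparse peaks, low-pass baseline and noise.
"""

import numpy as np

from thzfb import AirPLSParams, AsLSParams, airpls, asls, beads
from thzfb.synthetic import baseline_benchmark_signal

t, y, truth = baseline_benchmark_signal(seed=0)
drift = truth.true_baseline

for name, fit in (
    ("AsLS", asls(y, AsLSParams())),
    ("AirPLS", airpls(y, AirPLSParams())),
):
    rmse = np.sqrt(np.mean((fit.baseline - drift) ** 2))
    print(f"{name:7s} baseline recovery RMSE = {rmse:.4f} "
          f"({100 * rmse:.2f} % of the peak height), "
          f"{fit.n_iterations} iterations, converged = {fit.converged}")

dec = beads(y)
recon = np.max(np.abs(dec.sparse_signal + dec.baseline + dec.noise - y))
rmse_f = np.sqrt(np.mean((dec.baseline - drift) ** 2))
print(f"BEADS   baseline RMSE = {rmse_f:.4f}; "
      f"x + f + w reconstructs y to {recon:.1e}")
print()
print("Both reweighting schemes track the drift to well under 2 % of the")
print("peak; BEADS additionally returns an exact three-way decomposition.")
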