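"""Generate a synthetic heart-torso dataset and write it to disk.

Each cardiac node gets a smooth action-potential-like transmembrane
course (rest -85 mV, plateau +15 mV, staggered activation times); body
surface potentials are a linear, ill-conditioned mix of all node courses
plus measurement noise at 30 dB SNR.
"""

import tempfile
from pathlib import Path

import numpy as np

from invecg import generate_dataset, generate_forward_model, read_dataset, write_dataset

ds = generate_dataset(T=120, L=40, N=50, snr_db=30.0, seed=0)
print(f"TMP matrix: {ds.n_times} time steps x {ds.n_nodes} nodes "
      f"(range {ds.tmp.min():.1f} .. {ds.tmp.max():.1f} mV)")
print(f"BSP matrix: {ds.n_times} time steps x {ds.n_leads} leads")

fwd = generate_forward_model(L=40, N=50, decay=0.15, seed=1)
print(f"forward-map condition number: {fwd.condition_number:.0f} "
      "(the ill-posedness the inverse method must cope with)")

with tempfile.TemporaryDirectory() as d:
    write_dataset(ds, Path(d) / "bsp.csv", Path(d) / "tmp.csv")
    back = read_dataset(Path(d) / "bsp.csv", Path(d) / "tmp.csv")
    print("file round trip max error:",
          np.abs(back.bsp - ds.bsp).max(), "(lossless text storage)")
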