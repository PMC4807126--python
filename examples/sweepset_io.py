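"""Round-tripping recordings through the plain-text sweep-set dialect.

Every simulator output (and any recording converted to the format) is a
small UTF-8 file: a key:value header carrying unit, sampling rate and the
voltage protocol, then one comma-separated row of samples per sweep.
"""

import tempfile
from pathlib import Path

import numpy as np

from ikstools import read_sweep_set, simulate_uv_sweep_set, write_sweep_set
from ikstools import constructs as C

sweeps = simulate_uv_sweep_set(C.RUNDOWN["EQ+KCNE1"], seed=5,
                               cell_id="demo-cell", construct="EQ+KCNE1")
with tempfile.TemporaryDirectory() as d:
    path = write_sweep_set(sweeps, Path(d) / "demo.sweeps")
    print("header of the written file:")
    print("\n".join(path.read_text().splitlines()[:10]))
    back = read_sweep_set(path)

print(f"\nround-trip: {back.n_sweeps} sweeps x {back.n_samples} samples, "
      f"unit {back.unit}, construct {back.construct}")
print("samples preserved:",
      bool(np.allclose(back.sweeps, sweeps.sweeps, rtol=1e-8)))
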