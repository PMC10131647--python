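"""File I/O: write a trial to C3D and the CSV dialect, read it back, analyze.

The package reads marker data from C3D (the optical-capture standard
container) or from a wide CSV dialect (one row per frame, columns
``time, {label}_{x|y|z}`` in meters, z vertical). This script writes a
simulated trial in both formats into a temporary directory, reads each back
and shows that the analysis agrees.
"""

import tempfile
from pathlib import Path

from turncoord import analyze_trial, read_c3d, read_csv_trial, write_c3d, write_csv_trial
from turncoord.simulate import SimulationConfig, simulate_trial

trial, _ = simulate_trial(SimulationConfig(seed=2))

with tempfile.TemporaryDirectory() as d:
    c3d_path, csv_path = Path(d) / "trial.c3d", Path(d) / "trial.csv"
    write_c3d(trial, c3d_path)
    write_csv_trial(trial, csv_path)
    print(f"C3D: {c3d_path.stat().st_size / 1e6:.1f} MB, "
          f"CSV: {csv_path.stat().st_size / 1e6:.1f} MB")
    for name, loaded in (
        ("original", trial),
        ("via C3D", read_c3d(c3d_path)),
        ("via CSV", read_csv_trial(csv_path)),
    ):
        m = analyze_trial(loaded).metrics.means
        print(f"{name:9s} duration {m['duration_s']:.3f} s  "
              f"magnitude {m['magnitude_head']:.2f} deg  "
              f"latency pelvis-head {m['latency_pelvis_head'] * 1e3:.1f} ms")
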