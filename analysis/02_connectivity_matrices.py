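"""Compute thresholded connectivity matrices for every recording.

For each of the 96 recordings of results/study/: split into alpha, beta
and gamma bands, estimate the phase lag index over 4-s non-overlapping
epochs and magnitude-squared coherence over 2-s/50%-overlap Welch
windows, and keep the strongest 20% of edges per matrix. Matrices land
under results/matrices/ as labeled CSV.
"""

from pathlib import Path

import pandas as pd

from restconn import PipelineConfig, proportional_threshold, subject_matrices
from restconn.io import matrix_filename, read_recording, write_matrix_csv

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"
OUT = ROOT / "results" / "matrices"


def main() -> None:
    cfg = PipelineConfig(seed=1)
    manifest = pd.read_csv(STUDY / "manifest.csv")
    n = 0
    for row in manifest.itertuples():
        rec = read_recording(STUDY / row.file)
        for (metric, band), m in subject_matrices(rec, cfg).items():
            tm = proportional_threshold(m, cfg.threshold_proportion)
            write_matrix_csv(
                tm, OUT / matrix_filename(row.subject, row.session, row.phase, band, metric)
            )
            n += 1
    print(f"wrote {n} thresholded matrices ({len(manifest)} recordings x "
          f"{len(cfg.metrics)} metrics x {len(cfg.bands)} bands) to {OUT}")


if __name__ == "__main__":
    main()
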