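"""Effect sizes for the significant clusters.

Reads the effect-size table written by 03_cluster_permutation.py (one
row per edge of each significant cluster: pre/post mean and SD of the
thresholded PLI values across subjects, and Cohen's d = (M1 - M2) / s1
with M1/s1 from the post condition; undefined d renders as "-").
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    path = ROOT / "results" / "effect_sizes.csv"
    df = pd.read_csv(path)
    if df.empty:
        print("no significant clusters; no effect sizes to report")
        return
    print(df.to_string(index=False))
    print(f"\n({len(df)} cluster edge(s); source: {path})")


if __name__ == "__main__":
    main()
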