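"""dwPLI connectivity matrices per subject and band.

Time–frequency cross-spectra on the coarse grid, peak debiased wPLI per
channel pair within delta, theta and alpha. Writes one labelled CSV per
subject × band under results/connectivity/ plus the mean-dwPLI summary.

    python analysis/04_connectivity.py
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from eegspan.connectivity import (COARSE_GRID, band_connectivity,  # noqa: E402
                                  mean_connectivity, tf_cross_spectra)
from eegspan.containers import ANALYSIS_BANDS  # noqa: E402
from eegspan.io import read_recording  # noqa: E402


def main():
    src = ROOT / "results" / "clean"
    dst = ROOT / "results" / "connectivity"
    dst.mkdir(parents=True, exist_ok=True)
    summary = {}
    for path in sorted(src.glob("*.h5")):
        rec = read_recording(path, format="internal")
        grid = tf_cross_spectra(rec, COARSE_GRID)
        row = {}
        for band in ANALYSIS_BANDS:
            conn = band_connectivity(grid, band)
            frame = pd.DataFrame(conn.values, index=conn.labels,
                                 columns=conn.labels)
            frame.to_csv(dst / f"{path.stem}_{band.name}.csv")
            row[band.name] = mean_connectivity(conn)
        summary[path.stem] = row
        print(f"{path.stem}: " + "  ".join(f"{b}={v:.3f}"
                                           for b, v in row.items()))
    pd.DataFrame(summary).T.to_csv(ROOT / "results" / "mean_dwpli.csv")


if __name__ == "__main__":
    main()
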