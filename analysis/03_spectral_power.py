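"""Band power contributions and their temporal variability.

For every cleaned recording: Welch spectra (0.25 Hz bins), relative
power contribution of the five canonical bands per channel, and the
across-epoch SD of channel-averaged contributions. Writes
results/power_contributions.csv and results/power_variability.csv.

    python analysis/03_spectral_power.py
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from eegspan.containers import CANONICAL_BANDS  # noqa: E402
from eegspan.io import read_recording  # noqa: E402
from eegspan.spectral import (band_contributions, band_variability,  # noqa: E402
                              welch_spectrum)


def main():
    src = ROOT / "results" / "clean"
    names = [b.name for b in CANONICAL_BANDS]
    power_rows, var_rows = {}, {}
    for path in sorted(src.glob("*.h5")):
        rec = read_recording(path, format="internal")
        table = band_contributions(welch_spectrum(rec))
        power_rows[path.stem] = dict(zip(table.band_names,
                                         table.channel_mean()))
        var_rows[path.stem] = dict(zip(names, band_variability(rec)))
    power = pd.DataFrame(power_rows).T
    var = pd.DataFrame(var_rows).T
    power.to_csv(ROOT / "results" / "power_contributions.csv")
    var.to_csv(ROOT / "results" / "power_variability.csv")
    print("channel-averaged contributions (%) by subject:")
    print(power.round(1).to_string())


if __name__ == "__main__":
    main()
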