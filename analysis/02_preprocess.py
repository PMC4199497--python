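"""Preprocess every raw recording in the simulated cohort.

Band-pass 0.5–45 Hz, segment into 10 s epochs with baseline correction,
reject noisy channels/epochs by normalized variance, interpolate
rejected channels, average-reference. Cleaned recordings and the
rejection summary go to results/clean/.

    python analysis/02_preprocess.py
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from eegspan.io import load_montage, read_recording, write_recording  # noqa: E402
from eegspan.preprocess import preprocess_pipeline  # noqa: E402


def main():
    src = ROOT / "results" / "cohort"
    dst = ROOT / "results" / "clean"
    dst.mkdir(parents=True, exist_ok=True)
    montage = load_montage(src / "montage.txt")
    summary = {}
    for path in sorted(src.glob("*.h5")):
        raw = read_recording(path, format="internal")
        n_epochs = int(raw.data.shape[-1] // (raw.sampling_rate * 10.0))
        clean, report = preprocess_pipeline(raw, montage, n_epochs=n_epochs)
        write_recording(clean, dst / path.name)
        summary[path.stem] = {
            "rejected_channels": report.rejected_channels,
            "rejected_epochs": report.rejected_epochs,
            "epochs_retained": int(clean.n_epochs),
        }
        print(f"{path.stem}: retained {clean.n_epochs} epochs, "
              f"rejected {report.n_rejected} items")
    (dst / "rejection_report.json").write_text(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
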