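"""Regenerate the frozen regression fixtures (run from the repository root)."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from test_regression import CONFIGS, DATA, compute_qbar  # noqa: E402

if __name__ == "__main__":
    rows = []
    for tag in sorted(CONFIGS):
        q = compute_qbar(tag)
        print(f"{tag}: {q:.6f}", flush=True)
        rows.append({"tag": tag, "qbar_ml_hr": round(q, 6)})
    DATA.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(DATA, index=False)
    print(f"wrote {DATA}")
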