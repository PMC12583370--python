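"""Pipeline validation: recovery, calibration and power summaries.

Re-derives the quantities that justify trusting the measured tables:
exact topology recovery on un-rendered skeletons, noiseless end-to-end
metric recovery, calcium recovery under noise, type-I calibration of the
inference layer under a zero-effect simulation, and detection power for
the modelled effect directions.  Writes results/validation.csv.

This is a smaller-scale interactive companion to scripts/acceptance.py
(which recomputes the same quantities at full scale).
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "scripts"))
import pandas as pd

from acceptance import compute_all  # noqa: E402

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
    results = compute_all(
        seed=seed,
        n_topology=50,
        n_noiseless=10,
        n_calcium_fields=50,
        n_null_datasets=300,
        n_power_experiments=10,
    )
    ROOT.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [{"quantity": k, **v} for k, v in results.items()]
    )
    df.to_csv(ROOT / "validation.csv", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
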