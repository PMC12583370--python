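"""Simulate the study-scale factorial imaging dataset.

A 3 (KATP: ctrl / agonist / antagonist) x 2 (vehicle / rotenone) design,
five biological replicates per condition and five imaged fields per
replicate, rendered to three-channel TIFFs with known ground truth, plus
MTT absorbance and cell-count tables.  Writes results/dataset/.
"""

import pathlib
import sys

from mitomorph import io, synthetic

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "dataset"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    spec = synthetic.EffectSpec(seed=SEED)
    exp = synthetic.generate_experiment(spec, render=True)
    io.write_dataset(exp, OUT)
    n = len(exp.fields)
    print(f"wrote {n} fields ({len(spec.factor_a_levels)}x{len(spec.factor_b_levels)} "
          f"design, {spec.n_replicates} replicates x {spec.fields_per_replicate} fields) to {OUT}")


if __name__ == "__main__":
    main()
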