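"""Reproduce the class-imbalance mitigation arithmetic from the study's
training-set composition (2203 CN / 3325 MCI / 4222 AD images).

Expected output: inverse-frequency weights (1.92, 1.27, 1.00), SMOTE
synthesis counts (2019, 897, 0) up to the majority class, and
undersampling removals (0, 1122, 2019) down to the minority class.

Writes: results/mitigation_plans.json
"""

import argparse
import json
from pathlib import Path

from coronal_caps.mitigation import class_weights, smote_plan, undersample_plan

STUDY_TRAIN_COUNTS = {"CN": 2203, "MCI": 3325, "AD": 4222}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    weights = class_weights(STUDY_TRAIN_COUNTS)
    synthesis = smote_plan(STUDY_TRAIN_COUNTS).synthesis
    removal = undersample_plan(STUDY_TRAIN_COUNTS).removal

    out = {"train_counts": STUDY_TRAIN_COUNTS, "class_weights": weights,
           "smote_synthesis": synthesis, "undersample_removal": removal}
    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "mitigation_plans.json").write_text(json.dumps(out, indent=2))

    print("training counts:       ", STUDY_TRAIN_COUNTS)
    print("inverse-freq weights:  ", weights)
    print("SMOTE synthesis counts:", synthesis)
    print("undersample removals:  ", removal)
    print(f"wrote {args.out / 'mitigation_plans.json'}")


if __name__ == "__main__":
    main()
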