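"""Consensus classification of all patients by the RTBT2 model ensemble.

Loads the models from the previous step, builds the model-by-patient vote
matrix over all three cohorts, derives binary (>50%) and ternary
(>75%/<25%) consensus labels, and reports classification confidence.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from saspsurv import SimulationConfig, generate_cohorts, with_high_low_hr
from saspsurv.ensemble import load_models_jsonl
from saspsurv.voting import (build_vote_matrix, confidence_summary,
                             consensus, consensus_frame)

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
SEED = 2024


def main():
    models_path = OUT / "models_RTBT2.jsonl"
    if not models_path.exists():
        raise SystemExit("run 04_ensemble_models.py first")
    models = load_models_jsonl(models_path)
    # same calibrated cohorts the models were trained on (step 04)
    cohorts = generate_cohorts(with_high_low_hr(
        SimulationConfig(seed=SEED), 3.5, high_fraction=0.60))
    analytes = pd.concat([c.analytes for c in cohorts])
    matrix = build_vote_matrix(models, analytes)
    matrix.to_frame().to_csv(OUT / "votes_RTBT2.csv")
    assignments = consensus(matrix)
    consensus_frame(assignments).to_csv(OUT / "consensus_RTBT2.csv",
                                        index=False, float_format="%.6g")
    summary = confidence_summary(assignments)
    print(f"{len(models)} models voting on {len(assignments)} patients")
    print(f"Classified with >=75% confidence: "
          f"{summary['high_confidence_fraction']:.1%}")
    print(f"Lower-confidence (medium SASP): "
          f"{summary['low_confidence_fraction']:.1%}")
    for lbl, d in summary["by_class"].items():
        print(f"  consensus {lbl}: n={d['n']}, "
              f"high-confidence {d['high_confidence']}")


if __name__ == "__main__":
    main()
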