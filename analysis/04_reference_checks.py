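"""Closed-form checks against the published survey numbers: the two-state
structural entropy, the overall editing fraction implied by the E1/E0 set
sizes, the brain vs non-brain downstream-G two-proportion test (with
Bonferroni correction), and the shared-baseline consistency of the packaged
joint (up1, dn1, opNuc) context table.

Writes results/reference_checks.json.
"""

import argparse
import json
import math
from pathlib import Path

from aluedit.stats import bonferroni, load_reference_joint_table, two_proportion_test
from aluedit.thermo import structural_entropy

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "reference_checks.json")
    args = ap.parse_args()

    checks = {}
    checks["two_state_entropy"] = {
        "value": structural_entropy((0.5, 0.5, 0, 0, 0, 0)),
        "expected": math.log(2),
    }
    n_e1, n_e0 = 29_971, 590_206
    checks["overall_editing_fraction"] = {"value": n_e1 / (n_e1 + n_e0)}
    k1, n1, k2, n2 = 1376, 2966, 452, 1076
    p = two_proportion_test(k1, n1, k2, n2)
    checks["brain_vs_nonbrain_dn1_g"] = {
        "brain_percent": 100 * k1 / n1,
        "nonbrain_percent": 100 * k2 / n2,
        "p_value": p,
        "p_bonferroni_4_contexts": bonferroni([p], m=4)[0],
    }
    ref = load_reference_joint_table()
    rows = ref[ref["freq"] >= 0.01]
    baseline = rows["freq"] / rows["enrichment"]
    checks["joint_context_shared_baseline"] = {
        "mean": float(baseline.mean()),
        "cv_percent": 100 * float(baseline.std() / baseline.mean()),
        "n_rows_used": int(len(rows)),
    }
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(checks, indent=2))
    print(json.dumps(checks, indent=2))


if __name__ == "__main__":
    main()
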