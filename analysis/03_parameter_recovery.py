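"""Parameter-recovery study: plant known editing effects (upstream-T 2.2x,
opposite-C 3.5x, helix baseline 0.044 vs interior 0.091, entropy suppression
exp(-H)) in an isolated-effects synthetic world of ~50,000 Alu adenosines,
run the full pipeline blind, and re-estimate every effect from the called
E1/E0 table.

Writes results/recovery/recovered_effects.json and the binned
frequency-vs-entropy profile.
"""

import argparse
import json
from pathlib import Path

from aluedit.validation import (
    RECOVERY_N_PAIRS,
    RECOVERY_TRUTH,
    run_recovery_study,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n-alu-pairs", type=int, default=RECOVERY_N_PAIRS)
    ap.add_argument("--outdir", type=Path, default=ROOT / "results" / "recovery")
    args = ap.parse_args()

    recovered, helix_profile, sites = run_recovery_study(
        seed=args.seed, workdir=args.outdir / "work", n_alu_pairs=args.n_alu_pairs
    )
    args.outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "n_sites": len(sites),
        "recovered": recovered,
        "truth": RECOVERY_TRUTH,
    }
    (args.outdir / "recovered_effects.json").write_text(json.dumps(payload, indent=2))
    helix_profile.to_csv(args.outdir / "helix_entropy_profile.tsv", sep="\t", index=False)
    print(f"sites analysed: {len(sites)}")
    for name, truth in RECOVERY_TRUTH.items():
        got = recovered[name]
        print(f"  {name:22s} truth {truth:<6g} recovered {got:.4f} "
              f"({100 * (got / truth - 1):+.1f}%)")
    print("\nediting frequency vs entropy, ground-state helix:")
    print(helix_profile[["bin", "entropy_mean", "n_sites", "freq"]].to_string(index=False))


if __name__ == "__main__":
    main()
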