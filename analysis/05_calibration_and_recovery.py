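"""Monte-Carlo calibration and recovery summaries (reduced replicate counts).

Runs a condensed version of the validation experiments — null calibration
of the interaction inference and recovery of planted hubs, coupling sign
and interaction — and writes the rates to results/calibration_summary.json.
The full-size runs (200/50/25 replicates) live in the test suite and the
acceptance script; this driver uses fewer replicates for a fast look.
"""

import json
import sys
from pathlib import Path

import numpy as np
from scipy import stats as sps

from crossfc.experiments import (
    coupling_sign_replicate,
    hub_recovery_replicate,
    interaction_recovery_replicate,
    null_interaction_replicate,
)

ROOT = Path(__file__).resolve().parents[1]
SEED = 2024


def main(seed: int = SEED, n_null: int = 40, n_recovery: int = 10) -> None:
    rng = np.random.default_rng(seed)
    base = int(rng.integers(0, 2 ** 20))

    null = [null_interaction_replicate(base + i) for i in range(n_null)]
    fwe_rate = float(np.mean([r["any_significant"] for r in null]))
    spaced = np.arange(7, null[0]["t_values"].size, 89)
    pooled = np.concatenate([r["t_values"][spaced] for r in null])
    ks_p = float(sps.kstest(pooled, "t", args=(null[0]["df"],)).pvalue)

    hub = [hub_recovery_replicate(base + i) for i in range(n_recovery)]
    sign = [coupling_sign_replicate(base + i) for i in range(n_recovery)]
    inter = [interaction_recovery_replicate(base + i) for i in range(n_recovery)]

    summary = {
        "null_cluster_fwe_rate": {"value": fwe_rate, "n": n_null},
        "null_t_ks_pvalue": {"value": ks_p, "n": int(pooled.size)},
        "hub_recovery_rate": {"value": float(np.mean([r["recovered"] for r in hub])), "n": n_recovery},
        "negative_coupling_rate": {"value": float(np.mean([r["negative"] for r in sign])), "n": n_recovery},
        "interaction_detection_rate": {"value": float(np.mean([r["detected"] for r in inter])), "n": n_recovery},
        "planted_delta_for_d1": {"value": float(inter[0]["planted_delta"]), "n": 1},
    }
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "calibration_summary.json").write_text(json.dumps(summary, indent=2))
    for k, v in summary.items():
        print(f"{k}: {v['value']:.4g} (n={v['n']})")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else SEED)
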