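"""Screen every probe for circadian rhythmicity in each experimental stage.

Single-harmonic cosinor fits at tau = 24 h with Benjamini-Hochberg FDR
correction per condition; q < 0.05 flags a probe as rhythmic. Planted
circadian genes should be recovered at baseline and at the recovered
stages; after one shift the two protocols are phase-shifted in opposite
directions, so the pooled screen finds few coherent rhythms there.
"""

from pathlib import Path

import pandas as pd

from crdmarkers import normalize, pipeline, rhythm, simulate
from crdmarkers.io import write_tsv

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    config = pipeline.validate_config(None)
    design = simulate.generate_design()
    gene_config = pipeline.gene_config_from(config, SEED)
    matrix = normalize.normalize_two_channel(
        simulate.generate_expression(design, gene_config)
    )
    truth = simulate.ground_truth_table(gene_config).set_index("gene")

    screens = rhythm.screen_all_stages(matrix, design, tau=config.thresholds.tau)
    rows = []
    circadian_probes = {
        f"{g}_p1" for g in truth.index[truth["archetype"] == "circadian"]
    }
    for stage, screen in screens.items():
        flagged = set(screen.index[screen["rhythmic"]])
        rows.append(
            {
                "stage": stage,
                "rhythmic_probes": len(flagged),
                "planted_circadian_recovered": len(flagged & circadian_probes),
                "false_rhythmic": len(flagged - circadian_probes),
            }
        )
    table = pd.DataFrame(rows)
    write_tsv(table, RESULTS / "rhythmicity_by_stage.tsv", index=False)
    baseline = screens["baseline"].sort_values("q_value").head(20)
    write_tsv(baseline, RESULTS / "rhythmicity_baseline_top20.tsv")

    print(table.to_string(index=False))
    print("\ntop baseline hit:", baseline.index[0],
          f"amplitude={baseline['amplitude'].iloc[0]:.2f}",
          f"acrophase={baseline['acrophase'].iloc[0]:.1f} h")


if __name__ == "__main__":
    main()
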