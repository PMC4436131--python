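"""Generate the synthetic chronic-jet-lag study and summarize its design.

Emits the sampling design (120 liver arrays: 24 baseline, then 2 animals per
time point per rotation protocol at 1 shift, 6 shifts, 5 d and 14 d
recovery) and the planted ground truth (2,000 genes: 200 circadian, 10
CRD-responsive of which 5 secreted, rest null). The full spot-level
two-channel matrix is bulky and is written under scratch/ only.
"""

from pathlib import Path

from crdmarkers import pipeline, simulate
from crdmarkers.io import write_tsv

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main():
    config = pipeline.validate_config(None)
    design = simulate.generate_design()
    gene_config = pipeline.gene_config_from(config, SEED)
    truth = simulate.ground_truth_table(gene_config)

    cells = design.groupby(["stage", "protocol"]).size().rename("n_samples").reset_index()
    write_tsv(cells, RESULTS / "design_cells.tsv", index=False)
    # the planted (non-null) genes are the interesting part; full truth is bulky
    write_tsv(truth[truth["archetype"] != "null"], RESULTS / "planted_genes.tsv", index=False)

    probe_matrix = simulate.generate_expression(design, gene_config)
    SCRATCH.mkdir(exist_ok=True)
    truth.to_csv(SCRATCH / "ground_truth.tsv", sep="\t", index=False)
    simulate.probe_matrix_to_long(probe_matrix).to_csv(
        SCRATCH / "spots.tsv", sep="\t", index=False
    )

    print(f"design: {len(design)} samples over {design['stage'].nunique()} stages")
    print(cells.to_string(index=False))
    print(f"genes planted: {truth['archetype'].value_counts().to_dict()}")
    print(f"secreted (blood-candidate) genes: {sorted(truth[truth['secreted']]['gene'])}")
    print(f"spot matrix: {probe_matrix.shape[0]} spot rows x {probe_matrix.shape[1]} scans"
          f" -> scratch/spots.tsv")


if __name__ == "__main__":
    main()
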